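"""Ground-truth-annotated synthetic inputs for the whole pipeline.

The generator emulates the statistical structure of a liver knockout
ATAC/RNA/ChIP study at desk scale: a small multi-chromosome genome with
non-overlapping gene models; negative-binomial peak counts for two
replicates per condition (WT and KO) with accessibility effects
concentrated by feature class — losses on intergenic/intronic peaks that
drop toward closed, gains on already-open promoter peaks; peak sequences
with PWM instances planted at rates that vary monotonically with the
peak's true accessibility-change rank; binding sites placed at genes with
planted regulatory modes (the basal site set is a subset of the agonist
set); DE tables whose log2 fold changes and adjusted p-values follow the
planted mode; and per-base cut-count tracks with protection dips across
occupied motifs.

Everything is deterministic under a fixed seed, every emitted file is
readable by io_core, and every planted entity is recorded in a JSON truth
manifest so downstream stages can be tested against what was planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotate import GeneIndex
from .io_core import (BindingSiteSet, DataError, DETable, GeneModel,
                      GenomicInterval, PeakSet, logger, write_cut_track,
                      write_de_table, write_fasta, write_gene_models,
                      write_intervals, write_peakset)
from .motifs import BASES, PWM, PWMLibrary, write_pwm_library

FEATURE_MIX_DEFAULT = {"promoter": 0.15, "exon": 0.10, "intron": 0.35,
                       "intergenic": 0.40}
MODE_PROPORTIONS_DEFAULT = {
    "ligand-activated": 0.06,
    "ligand-repressed": 0.03,
    "basal-required-nonresponsive": 0.10,
    "basal-repressed-nonresponsive": 0.05,
    "agonist-only": 0.04,
    "indirect": 0.06,
}


@dataclass
class MotifPlantSpec:
    """How often a motif is planted as a function of accessibility-change
    rank. ``rate_loss_end``/``rate_gain_end`` are the plant probabilities at
    the extreme loss/gain ends of the ranking; in between the rate follows a
    logistic curve in rank fraction (or is flat when the two rates agree)."""

    rate_loss_end: float
    rate_gain_end: float
    center: float = 0.5
    width: float = 0.12

    def rate(self, rank_fraction: np.ndarray) -> np.ndarray:
        f = np.asarray(rank_fraction, dtype=float)
        lo, hi = self.rate_loss_end, self.rate_gain_end
        if lo == hi:
            return np.full_like(f, lo)
        s = 1.0 / (1.0 + np.exp((f - self.center) / self.width))
        return hi + (lo - hi) * s


@dataclass
class SimulationConfig:
    n_chroms: int = 2
    chrom_length: int = 3_000_000
    n_genes: int = 500
    n_peaks: int = 6000
    replicates_per_condition: int = 2      # "across all four samples"
    gene_length_range: tuple[int, int] = (3_000, 8_000)
    exon_count_range: tuple[int, int] = (2, 8)
    peak_width_range: tuple[int, int] = (300, 600)
    feature_mix: dict[str, float] = field(
        default_factory=lambda: dict(FEATURE_MIX_DEFAULT))
    baseline_log_mean: float = np.log(100.0)   # lognormal WT mean counts
    baseline_log_sd: float = 0.7
    promoter_baseline_factor: float = 2.0      # promoters start more open
    nb_dispersion: float = 0.05                # Var = mu + disp * mu^2
    loss_rate: float = 0.15        # fraction of intergenic/intronic peaks losing
    gain_rate: float = 0.20        # fraction of promoter peaks gaining
    loss_effect_range: tuple[float, float] = (-3.0, -1.5)   # log2 KO/WT
    gain_effect_range: tuple[float, float] = (1.0, 2.5)
    peaks_at_binding_sites: bool = True        # seed one peak per ChIP site
    binding_site_shift_range: tuple[float, float] = (-0.8, 0.15)
    down_site_effect_range: tuple[float, float] = (-2.0, -0.8)
    up_site_effect_range: tuple[float, float] = (0.2, 1.0)
    library_size: float = 2e7
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    plant_specs: dict[str, MotifPlantSpec] | None = None   # None -> defaults
    mode_proportions: dict[str, float] = field(
        default_factory=lambda: dict(MODE_PROPORTIONS_DEFAULT))
    bound_unaffected_rate: float = 0.15    # unaffected genes that still have sites
    basal_site_fraction: float = 0.4       # extra sites kept in the basal set
    sites_per_gene_range: tuple[int, int] = (1, 3)
    binding_site_width: int = 200
    de_effect_mean: float = 1.6
    de_effect_sd: float = 0.3
    cut_rate_per_count: float = 1.0        # expected cuts per peak per unit mean count
    footprint_depth: dict[str, float] = field(
        default_factory=lambda: {"WT": 0.5, "KO": 0.1})
    footprint_motifs: tuple[str, ...] = ("NFY",)
    rng_seed: int = 0

    def __post_init__(self):
        if sum(self.mode_proportions.values()) > 1 + 1e-9:
            raise DataError("mode proportions must sum to <= 1")
        if abs(sum(self.feature_mix.values()) - 1) > 1e-9:
            raise DataError("feature mix must sum to 1")
        for name in ("n_chroms", "chrom_length", "n_peaks",
                     "replicates_per_condition"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be positive")
        if self.n_genes < 0:
            raise DataError("n_genes must be >= 0")


@dataclass
class SimulationTruth:
    """Everything that was planted, keyed by the ids in the emitted files."""

    rng_seed: int
    peak_effects: dict[str, float] = field(default_factory=dict)
    peak_classes: dict[str, str] = field(default_factory=dict)
    peak_wt_means: dict[str, float] = field(default_factory=dict)
    occurrences: list[dict] = field(default_factory=list)
    gene_modes: dict[str, str] = field(default_factory=dict)
    site_targets: list[dict] = field(default_factory=list)
    de_truth: dict[str, dict] = field(default_factory=dict)

    def occurrences_for_motif(self, motif_id: str) -> list[dict]:
        return [o for o in self.occurrences if o["motif_id"] == motif_id]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# default PWM library (synthetic motifs built in code)
# ---------------------------------------------------------------------------

def _consensus_pwm(motif_id: str, family: str, consensus: str,
                   strength: float = 0.85,
                   fuzzy_positions: tuple[int, ...] = ()) -> PWM:
    """PWM with ``strength`` probability on the consensus base per column;
    columns listed in ``fuzzy_positions`` are near-uniform (spacers)."""
    L = len(consensus)
    mat = np.full((4, L), (1 - strength) / 3)
    for j, b in enumerate(consensus):
        mat[BASES.index(b), j] = strength
    for j in fuzzy_positions:
        mat[:, j] = 0.25
    return PWM(motif_id, mat, family)


def default_pwm_library() -> PWMLibrary:
    """A compact synthetic motif panel covering the TF classes the analysis
    cares about: nuclear-receptor direct repeats (DR4 with a 4-nt spacer,
    DR1 with a 1-nt spacer), a CCAAT-box (NF-Y), a long CTCF-like motif,
    forkhead (FOXA), C/EBP, and an ETS core. DR4_A/DR4_B are deliberate
    near-duplicates within the NR family to exercise similarity merging."""
    pwms = [
        _consensus_pwm("DR4_A", "NR", "AGGTCATTCCAGGTCA", strength=0.95,
                       fuzzy_positions=(6, 7, 8, 9)),
        _consensus_pwm("DR4_B", "NR", "AGGTCAGAACAGGTCA", strength=0.93,
                       fuzzy_positions=(6, 7, 8, 9)),
        _consensus_pwm("DR1", "NR", "AGGTCAAAGGTCA", strength=0.95,
                       fuzzy_positions=(6,)),
        _consensus_pwm("NFY", "CCAAT", "AGCCAATCAG", strength=0.95),
        _consensus_pwm("CTCF", "CTCF", "CCACCAGGTGGCGC", strength=0.92),
        _consensus_pwm("FOXA", "FOX", "TGTTTACTTA", strength=0.95),
        _consensus_pwm("CEBP", "bZIP", "TTGCGCAATA", strength=0.95),
        _consensus_pwm("ETS", "ETS", "ACAGGAAGTG", strength=0.95),
    ]
    return PWMLibrary(pwms)


def default_plant_specs() -> dict[str, MotifPlantSpec]:
    """Loss-associated motifs (NR, CTCF, FOXA) are planted preferentially at
    the loss end of the ranking, the CCAAT motif at the gain end, ETS flat
    across promoters, C/EBP at a low flat rate."""
    return {
        "DR4_A": MotifPlantSpec(0.35, 0.02),
        "DR4_B": MotifPlantSpec(0.20, 0.02),
        "DR1": MotifPlantSpec(0.40, 0.03),
        "CTCF": MotifPlantSpec(0.30, 0.02),
        "FOXA": MotifPlantSpec(0.30, 0.03),
        "NFY": MotifPlantSpec(0.03, 0.35),
        "ETS": MotifPlantSpec(0.10, 0.10),
        "CEBP": MotifPlantSpec(0.05, 0.05),
    }


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig
                    ) -> tuple[list[GeneModel], dict[str, int]]:
    """Non-overlapping gene models with 2-8 exons, random strand, packed
    into ``n_chroms`` chromosomes with random gaps."""
    rng = np.random.default_rng(config.rng_seed)
    chrom_sizes = {f"chr{i + 1}": config.chrom_length
                   for i in range(config.n_chroms)}
    if config.n_genes == 0:
        return [], chrom_sizes
    chrom_of = rng.integers(0, config.n_chroms, size=config.n_genes)
    genes: list[GeneModel] = []
    margin = 2_000  # keep promoter windows and flanks on-chromosome
    for ci, chrom in enumerate(chrom_sizes):
        idx = np.flatnonzero(chrom_of == ci)
        if idx.size == 0:
            continue
        lengths = rng.integers(config.gene_length_range[0],
                               config.gene_length_range[1] + 1, size=idx.size)
        free = config.chrom_length - 2 * margin - int(lengths.sum())
        if free < idx.size:  # need >= 1 bp gap between genes
            raise DataError(
                f"cannot pack {idx.size} genes of total length {lengths.sum()} "
                f"into {chrom} ({config.chrom_length} bp)")
        gaps = rng.multinomial(free - idx.size, np.full(idx.size + 1,
                                                        1 / (idx.size + 1))) + 1
        pos = margin
        for k, gi in enumerate(idx):
            pos += int(gaps[k])
            start, length = pos, int(lengths[k])
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(config.exon_count_range[0],
                                       config.exon_count_range[1] + 1))
            # split the span into alternating exon/intron blocks
            cuts = np.sort(rng.choice(np.arange(1, length),
                                      size=2 * n_exons - 2, replace=False))
            bounds = np.concatenate([[0], cuts, [length]])
            exons = [GenomicInterval(chrom, start + int(bounds[2 * j]),
                                     start + int(bounds[2 * j + 1]), strand)
                     for j in range(n_exons)]
            tss = start if strand == "+" else start + length - 1
            gid = f"G{gi:04d}"
            genes.append(GeneModel(gid, gid, chrom, strand, tss, exons))
            pos += length
    genes.sort(key=lambda g: g.gene_id)
    return genes, chrom_sizes


# ---------------------------------------------------------------------------
# peaks and counts
# ---------------------------------------------------------------------------

def _negative_binomial(rng: np.random.Generator, mean: np.ndarray,
                       dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2; collapses to
    Poisson at dispersion 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _candidate_position(rng: np.random.Generator, cls: str,
                        genes: list[GeneModel],
                        intergenic_spans: list[tuple[str, int, int]]
                        ) -> tuple[str, int]:
    if cls == "intergenic" or not genes:
        chrom, lo, hi = intergenic_spans[rng.integers(len(intergenic_spans))]
        return chrom, int(rng.integers(lo, hi))
    g = genes[rng.integers(len(genes))]
    if cls == "promoter":
        off = int(rng.integers(-500, 51))
        pos = g.tss + off if g.strand == "+" else g.tss - off
        return g.chrom, pos
    if cls == "exon":
        e = g.exons[rng.integers(len(g.exons))]
        return g.chrom, int(rng.integers(e.start, e.end))
    # intron
    exons = sorted(g.exons, key=lambda e: e.start)
    introns = [(a.end, b.start) for a, b in zip(exons, exons[1:])
               if b.start > a.end + 1]
    if not introns:
        return g.chrom, int(rng.integers(exons[0].start, exons[-1].end))
    lo, hi = introns[rng.integers(len(introns))]
    return g.chrom, int(rng.integers(lo, hi))


def _parse_site(key: str) -> tuple[str, int, int]:
    chrom, span = key.rsplit(":", 1)
    lo, hi = span.split("-")
    return chrom, int(lo), int(hi)


def simulate_peaks(genome: tuple[list[GeneModel], dict[str, int]],
                   config: SimulationConfig,
                   truth: SimulationTruth | None = None
                   ) -> tuple[PeakSet, SimulationTruth]:
    """Peaks placed by feature class with negative-binomial counts.

    The planted feature class is verified against the midpoint annotation
    index at generation time (a few resampling attempts per peak), so the
    truth manifest records the class the annotator will actually see.
    Loss effects go to a ``loss_rate`` fraction of intergenic/intronic
    peaks, gain effects to a ``gain_rate`` fraction of promoter peaks
    (which also start from a higher baseline).

    When the truth manifest already carries binding sites and DE effects
    (modes simulated first), one peak is seeded at every binding site and
    accessibility effects are coupled to binding: site-overlapping peaks
    drift mildly toward loss, sites of knockout-down genes lose strongly,
    sites of knockout-up genes gain.
    """
    genes, chrom_sizes = genome
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.rng_seed, 1]).generate_state(1)[0])
    truth = truth or SimulationTruth(rng_seed=config.rng_seed)
    index = GeneIndex(genes) if genes else None

    # intergenic territory: chromosome minus gene spans padded by 1.2 kb
    intergenic_spans: list[tuple[str, int, int]] = []
    pad = 1_200
    for chrom, size in chrom_sizes.items():
        spans = sorted((g.span.start - pad, g.span.end + pad)
                       for g in genes if g.chrom == chrom)
        pos = 1_000
        for lo, hi in spans:
            if lo - pos > 1_000:
                intergenic_spans.append((chrom, pos, lo))
            pos = max(pos, hi)
        if size - 1_000 - pos > 1_000:
            intergenic_spans.append((chrom, pos, size - 1_000))
    if not intergenic_spans:
        raise DataError("no intergenic territory left for peak placement")

    # binding sites already simulated? seed a peak at each and classify genes
    site_records: list[tuple[str, int, int, str]] = []  # chrom, lo, hi, ko_class
    if truth.site_targets:
        for rec in truth.site_targets:
            chrom, lo, hi = _parse_site(rec["site"])
            de = truth.de_truth.get(rec["gene_id"], {})
            if de.get("ko_p", 1.0) < 0.05:
                ko_cls = "down" if de["ko_lfc"] < 0 else "up"
            else:
                ko_cls = "unchanged"
            site_records.append((chrom, lo, hi, ko_cls))

    peaks: list[GenomicInterval] = []
    peak_ids: list[str] = []
    peak_classes: list[str] = []
    min_w, max_w = config.peak_width_range

    seeded = []
    if config.peaks_at_binding_sites and site_records:
        seen: set[tuple[str, int, int]] = set()
        for chrom, lo, hi, _cls in site_records:
            if (chrom, lo, hi) in seen:
                continue
            seen.add((chrom, lo, hi))
            seeded.append((chrom, (lo + hi) // 2))
        if len(seeded) > config.n_peaks:
            raise DataError(f"{len(seeded)} binding sites exceed n_peaks="
                            f"{config.n_peaks}")
    for i, (chrom, mid) in enumerate(seeded):
        width = int(rng.integers(min_w, max_w + 1))
        start = max(mid - width // 2, 0)
        end = min(start + width, chrom_sizes[chrom])
        start = max(end - width, 0)
        peaks.append(GenomicInterval(chrom, start, end, "."))
        peak_ids.append(f"peak{i:05d}")
        peak_classes.append(index.classify_midpoint(chrom, (start + end) // 2)
                            if index else "intergenic")

    classes = list(config.feature_mix)
    probs = np.array([config.feature_mix[c] for c in classes])
    n_free = config.n_peaks - len(seeded)
    wanted = rng.choice(len(classes), size=n_free, p=probs)
    for i in range(n_free):
        cls = classes[wanted[i]] if genes else "intergenic"
        width = int(rng.integers(min_w, max_w + 1))
        realized = cls
        for _attempt in range(8):
            chrom, mid = _candidate_position(rng, cls, genes, intergenic_spans)
            start = max(mid - width // 2, 0)
            end = min(start + width, chrom_sizes[chrom])
            start = max(end - width, 0)
            realized = (index.classify_midpoint(chrom, (start + end) // 2)
                        if index else "intergenic")
            if realized == cls:
                break
        peaks.append(GenomicInterval(chrom, start, end, "."))
        peak_ids.append(f"peak{len(seeded) + i:05d}")
        peak_classes.append(realized)

    # accessibility effects: feature-class background structure ...
    cls_arr = np.array(peak_classes)
    effects = np.zeros(config.n_peaks)
    loss_pool = np.flatnonzero(np.isin(cls_arr, ["intergenic", "intron"]))
    gain_pool = np.flatnonzero(cls_arr == "promoter")
    loss_idx = loss_pool[rng.random(loss_pool.size) < config.loss_rate]
    gain_idx = gain_pool[rng.random(gain_pool.size) < config.gain_rate]
    effects[loss_idx] = rng.uniform(*config.loss_effect_range, size=loss_idx.size)
    effects[gain_idx] = rng.uniform(*config.gain_effect_range, size=gain_idx.size)

    # ... plus binding-coupled structure: mild loss drift at any site,
    # strong loss at sites of knockout-down genes, gain at knockout-up genes
    if site_records:
        site_trees: dict[str, IntervalTree] = {}
        for chrom, lo, hi, ko_cls in site_records:
            site_trees.setdefault(chrom, IntervalTree())[lo:hi] = ko_cls
        for i, p in enumerate(peaks):
            tree = site_trees.get(p.chrom)
            hits = tree[p.start:p.end] if tree is not None else set()
            if not hits:
                continue
            effects[i] += rng.uniform(*config.binding_site_shift_range)
            ko_classes = {h.data for h in hits}
            if "down" in ko_classes:
                effects[i] += rng.uniform(*config.down_site_effect_range)
            elif "up" in ko_classes:
                effects[i] += rng.uniform(*config.up_site_effect_range)

    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd,
                         size=config.n_peaks)
    base[cls_arr == "promoter"] *= config.promoter_baseline_factor

    reps = config.replicates_per_condition
    sample_names = [f"WT_{r + 1}" for r in range(reps)] + \
                   [f"KO_{r + 1}" for r in range(reps)]
    conditions = ["WT"] * reps + ["KO"] * reps
    counts = np.zeros((config.n_peaks, 2 * reps), dtype=np.int64)
    ko_mean = base * np.exp2(effects)
    for s, cond in enumerate(conditions):
        mu = base if cond == "WT" else ko_mean
        counts[:, s] = _negative_binomial(rng, mu, config.nb_dispersion)
    lib = np.round(config.library_size *
                   rng.uniform(0.95, 1.05, size=2 * reps)).astype(np.int64)
    meta = pd.DataFrame({"condition": conditions, "library_size": lib},
                        index=pd.Index(sample_names, name="sample"))
    ps = PeakSet(peaks=peaks, peak_ids=peak_ids, counts=counts, sample_meta=meta)

    truth.peak_effects.update(dict(zip(peak_ids, effects.tolist())))
    truth.peak_classes.update(dict(zip(peak_ids, peak_classes)))
    truth.peak_wt_means.update(dict(zip(peak_ids, base.tolist())))
    logger.info("simulate_peaks: %d peaks (%d loss, %d gain effects)",
                config.n_peaks, loss_idx.size, gain_idx.size)
    return ps, truth


# ---------------------------------------------------------------------------
# sequences with planted motifs
# ---------------------------------------------------------------------------

def plant_motif_occurrences(peakset: PeakSet, library: PWMLibrary,
                            config: SimulationConfig,
                            truth: SimulationTruth
                            ) -> tuple[dict[str, str], SimulationTruth]:
    """Random background sequences for every peak with PWM instances planted
    at rank-dependent rates; planted instances are sampled column-wise from
    the PWM on a random strand and recorded in the truth manifest."""
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.rng_seed, 2]).generate_state(1)[0])
    specs = config.plant_specs or default_plant_specs()
    widths = peakset.widths()
    for pwm in library:
        if pwm.motif_id in specs and pwm.length > widths.min():
            raise DataError(f"motif {pwm.motif_id} ({pwm.length} bp) longer "
                            f"than the narrowest peak ({widths.min()} bp)")
    effects = np.array([truth.peak_effects[p] for p in peakset.peak_ids])
    order = np.argsort(effects, kind="stable")  # losses first
    rank_fraction = np.empty(len(effects))
    rank_fraction[order] = (np.arange(len(effects)) + 0.5) / len(effects)

    comp = np.asarray(config.base_composition)
    seqs: dict[str, str] = {}
    base_choices = rng.choice(4, size=int(widths.sum()), p=comp)
    offsets = np.concatenate([[0], np.cumsum(widths)])
    letters = np.array(list(BASES))
    for i, pid in enumerate(peakset.peak_ids):
        seq = letters[base_choices[offsets[i]:offsets[i + 1]]]
        for motif_id, spec in specs.items():
            pwm = library[motif_id]
            if rng.random() >= spec.rate(rank_fraction[i]):
                continue
            L = pwm.length
            if L > seq.size:
                continue
            pos = int(rng.integers(0, seq.size - L + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            cols = pwm.matrix if strand == "+" else \
                pwm.reverse_complement().matrix
            inst = np.array([BASES[rng.choice(4, p=cols[:, j] / cols[:, j].sum())]
                             for j in range(L)])
            seq[pos:pos + L] = inst
            truth.occurrences.append({"peak_id": pid, "motif_id": motif_id,
                                      "offset": pos, "strand": strand})
        seqs[pid] = "".join(seq)
    logger.info("plant_motif_occurrences: planted %d instances over %d peaks",
                len(truth.occurrences), len(seqs))
    return seqs, truth


# ---------------------------------------------------------------------------
# binding sites, DE tables, regulatory modes
# ---------------------------------------------------------------------------

def _small_p(rng: np.random.Generator) -> float:
    return float(10 ** -rng.uniform(2.0, 6.0))


def _null_p(rng: np.random.Generator) -> float:
    return float(rng.uniform(0.0, 1.0))


def simulate_binding_and_expression(genome: tuple[list[GeneModel], dict[str, int]],
                                    config: SimulationConfig,
                                    truth: SimulationTruth
                                    ) -> tuple[BindingSiteSet, BindingSiteSet,
                                               DETable, DETable, SimulationTruth]:
    """Assign each gene a regulatory mode, place binding sites at bound
    genes (the basal set is a subset of the agonist set; direct modes always
    keep at least one basal site), and emit mode-consistent DE tables for
    the knockout and agonist contrasts."""
    genes, _ = genome
    if not genes:
        raise DataError("gene list is empty")
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.rng_seed, 3]).generate_state(1)[0])
    modes = list(config.mode_proportions)
    probs = np.array([config.mode_proportions[m] for m in modes])
    probs = np.append(probs, 1 - probs.sum())
    mode_labels = modes + ["unaffected"]
    assignment = rng.choice(len(mode_labels), size=len(genes), p=probs)

    basal_sites: list[GenomicInterval] = []
    agonist_sites: list[GenomicInterval] = []
    de_rows_ko, de_rows_ag = [], []
    w = config.binding_site_width
    mu, sd = config.de_effect_mean, config.de_effect_sd

    for g, mi in zip(genes, assignment):
        mode = mode_labels[mi]
        truth.gene_modes[g.gene_id] = mode
        bound = mode in {"ligand-activated", "ligand-repressed",
                         "basal-required-nonresponsive",
                         "basal-repressed-nonresponsive", "agonist-only"} or \
            (mode == "unaffected" and rng.random() < config.bound_unaffected_rate)
        if bound:
            n_sites = int(rng.integers(config.sites_per_gene_range[0],
                                       config.sites_per_gene_range[1] + 1))
            span = g.span
            for s in range(n_sites):
                if s == 0:  # anchor site at the TSS
                    mid = g.tss + int(rng.integers(-200, 201))
                else:
                    mid = int(rng.integers(span.start, span.end))
                site = GenomicInterval(g.chrom, max(mid - w // 2, 0),
                                       max(mid - w // 2, 0) + w, ".")
                agonist_sites.append(site)
                in_basal = False
                if mode == "agonist-only":
                    in_basal = False
                elif s == 0 and mode != "unaffected":
                    in_basal = True  # direct modes guarantee basal evidence
                else:
                    in_basal = rng.random() < config.basal_site_fraction
                if in_basal:
                    basal_sites.append(site)
                truth.site_targets.append(
                    {"site": f"{site.chrom}:{site.start}-{site.end}",
                     "gene_id": g.gene_id, "basal": in_basal})

        # DE statistics follow the mode
        if mode == "ligand-activated":
            ko = (-rng.normal(mu, sd), _small_p(rng))
            ag = (rng.normal(mu, sd), _small_p(rng))
        elif mode == "ligand-repressed":
            ko = (rng.normal(mu, sd), _small_p(rng))
            ag = (-rng.normal(mu, sd), _small_p(rng))
        elif mode == "basal-required-nonresponsive":
            ko = (-rng.normal(mu, sd), _small_p(rng))
            ag = (rng.normal(0, 0.1), float(rng.uniform(0.2, 1.0)))
        elif mode == "basal-repressed-nonresponsive":
            ko = (rng.normal(mu, sd), _small_p(rng))
            ag = (rng.normal(0, 0.1), float(rng.uniform(0.2, 1.0)))
        elif mode == "agonist-only":
            ko = (rng.normal(0, 0.1), float(rng.uniform(0.2, 1.0)))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            ag = (sign * rng.normal(mu, sd), _small_p(rng))
        elif mode == "indirect":
            sign = 1.0 if rng.random() < 0.5 else -1.0
            ko = (sign * rng.normal(mu, sd), _small_p(rng))
            ag = (rng.normal(0, 0.1), float(rng.uniform(0.2, 1.0)))
        else:  # unaffected
            ko = (rng.normal(0, 0.15), _null_p(rng))
            ag = (rng.normal(0, 0.15), _null_p(rng))
        de_rows_ko.append({"gene_id": g.gene_id, "log2_fold_change": ko[0],
                           "adjusted_p": ko[1]})
        de_rows_ag.append({"gene_id": g.gene_id, "log2_fold_change": ag[0],
                           "adjusted_p": ag[1]})
        truth.de_truth[g.gene_id] = {"ko_lfc": float(ko[0]), "ko_p": float(ko[1]),
                                     "agonist_lfc": float(ag[0]),
                                     "agonist_p": float(ag[1])}

    de_ko = DETable(pd.DataFrame(de_rows_ko).set_index("gene_id"), "KO_vs_WT")
    de_ag = DETable(pd.DataFrame(de_rows_ag).set_index("gene_id"),
                    "agonist_vs_vehicle")
    return (BindingSiteSet(basal_sites, "basal"),
            BindingSiteSet(agonist_sites, "agonist"), de_ko, de_ag, truth)


# ---------------------------------------------------------------------------
# cut-site tracks
# ---------------------------------------------------------------------------

def simulate_cut_sites(peakset: PeakSet, truth: SimulationTruth,
                       config: SimulationConfig,
                       chrom_sizes: dict[str, int],
                       library: PWMLibrary | None = None
                       ) -> dict[str, dict[str, np.ndarray]]:
    """Per-condition per-base Poisson cut counts.

    The expected cut rate is a genome-wide field: each peak contributes a
    flat rate proportional to its condition mean spread over its width
    (overlapping peaks add), then every occupied motif span (motifs listed
    in ``footprint_motifs``) multiplies the field by ``1 - depth`` for that
    condition, and counts are drawn Poisson once per base."""
    rng = np.random.default_rng(np.random.SeedSequence(
        [config.rng_seed, 4]).generate_state(1)[0])
    library = library or default_pwm_library()
    occupied = [o for o in truth.occurrences
                if o["motif_id"] in config.footprint_motifs]
    peak_by_id = dict(zip(peakset.peak_ids, peakset.peaks))

    tracks: dict[str, dict[str, np.ndarray]] = {}
    for cond, depth in config.footprint_depth.items():
        lam = {c: np.zeros(n) for c, n in chrom_sizes.items()}
        for pid, peak in zip(peakset.peak_ids, peakset.peaks):
            base = truth.peak_wt_means[pid]
            eff = truth.peak_effects[pid]
            mean_cond = base if cond == "WT" else base * 2 ** eff
            lam[peak.chrom][peak.start:peak.end] += (
                config.cut_rate_per_count * mean_cond / peak.width)
        for o in occupied:
            peak = peak_by_id.get(o["peak_id"])
            if peak is None:
                continue
            L = library[o["motif_id"]].length
            lo = peak.start + o["offset"]
            lam[peak.chrom][lo:lo + L] *= (1.0 - depth)
        tracks[cond] = {c: rng.poisson(v) for c, v in lam.items()}
    return tracks


def footprint_sites_from_truth(truth: SimulationTruth, peakset: PeakSet,
                               motif_id: str, motif_len: int,
                               window: int) -> list:
    """Truth-occurrence footprint sites whose aggregation window lies
    entirely inside the carrying peak (so flanks see the peak's own rate
    field, not the peak edge)."""
    from .footprint import FootprintSite

    peak_by_id = dict(zip(peakset.peak_ids, peakset.peaks))
    sites = []
    for o in truth.occurrences_for_motif(motif_id):
        peak = peak_by_id.get(o["peak_id"])
        if peak is None:
            continue
        center = peak.start + o["offset"] + motif_len // 2
        if center - window >= peak.start and center + window < peak.end:
            sites.append(FootprintSite(peak.chrom, center, o["strand"]))
    return sites


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genes: list[GeneModel]
    chrom_sizes: dict[str, int]
    peakset: PeakSet
    sequences: dict[str, str]
    library: PWMLibrary
    chip_basal: BindingSiteSet
    chip_agonist: BindingSiteSet
    de_ko: DETable
    de_agonist: DETable
    cut_tracks: dict[str, dict[str, np.ndarray]]
    truth: SimulationTruth


def simulate_study(config: SimulationConfig | None = None,
                   outdir: str | Path | None = None,
                   with_cut_sites: bool = True) -> SimulatedStudy:
    """Run every generator stage under one seed; optionally write the full
    file bundle (peaks.bed, counts.tsv, samples.tsv, genes.tsv, peaks.fa,
    chip_basal.bed, chip_agonist.bed, de_ko.tsv, de_agonist.tsv,
    cuts_<cond>.tsv, pwms.jaspar, truth.json) to ``outdir``."""
    config = config or SimulationConfig()
    genome = simulate_genome(config)
    truth = SimulationTruth(rng_seed=config.rng_seed)
    # modes and binding first: accessibility effects at binding sites are
    # conditioned on the planted knockout response of the bound gene
    basal, agonist, de_ko, de_ag, truth = simulate_binding_and_expression(
        genome, config, truth)
    peakset, truth = simulate_peaks(genome, config, truth)
    library = default_pwm_library()
    seqs, truth = plant_motif_occurrences(peakset, library, config, truth)
    tracks = (simulate_cut_sites(peakset, truth, config, genome[1], library)
              if with_cut_sites else {})
    study = SimulatedStudy(config, genome[0], genome[1], peakset, seqs,
                           library, basal, agonist, de_ko, de_ag, tracks, truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_peakset(peakset, outdir / "peaks.bed", outdir / "counts.tsv",
                      outdir / "samples.tsv")
        write_gene_models(genome[0], outdir / "genes.tsv")
        write_fasta(seqs, outdir / "peaks.fa")
        write_intervals(basal.sites, [f"basal_{i}" for i in range(len(basal.sites))],
                        outdir / "chip_basal.bed")
        write_intervals(agonist.sites,
                        [f"agonist_{i}" for i in range(len(agonist.sites))],
                        outdir / "chip_agonist.bed")
        write_de_table(de_ko, outdir / "de_ko.tsv")
        write_de_table(de_ag, outdir / "de_agonist.tsv")
        write_pwm_library(library, outdir / "pwms.jaspar")
        for cond, track in tracks.items():
            write_cut_track(track, outdir / f"cuts_{cond}.tsv")
        truth.to_json(outdir / "truth.json")
    return study
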