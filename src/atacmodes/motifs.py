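"""PWM scanning and motif-enrichment landscapes.

The central object is the enrichment landscape: peaks ranked by
accessibility change are cut into equal-sized bins, each motif's occurrence
frequency in each bin is tested against the full binned peak set with a
one-sided hypergeometric upper tail, and the -log10 p values form a
motifs x bins matrix. Motifs never enriched anywhere, or flat across bins,
are filtered; near-identical PWMs within a TF family are merged
(single-linkage on best-offset Pearson similarity, reverse complement
considered) by taking the per-bin best p.

Scanning is plain log-odds against a background base composition, with a
hit threshold expressed as a fraction of the motif's maximum achievable
score. JASPAR PFM text is read and written through Bio.motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests
from Bio import motifs as bio_motifs

from .io_core import DataError, FormatError

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_NEG_INF = -1e9  # stand-in for -inf so windowed sums stay finite


@dataclass
class PWM:
    """Position weight matrix: 4 x L base probabilities (rows A,C,G,T),
    pseudocount-regularized, with a background composition."""

    motif_id: str
    matrix: np.ndarray
    family: str = ""
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4:
            raise FormatError(f"{self.motif_id}: PWM must have 4 rows, got "
                              f"{self.matrix.shape[0]}")
        colsums = self.matrix.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise FormatError(f"{self.motif_id}: PWM columns must sum to 1")
        if (self.matrix <= 0).any():
            raise FormatError(f"{self.motif_id}: PWM entries must be positive "
                              "(apply a pseudocount)")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self) -> np.ndarray:
        return np.log2(self.matrix / self.background[:, None])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.matrix[::-1, ::-1].copy(), self.family,
                   self.background[::-1].copy())


@dataclass
class PWMLibrary:
    pwms: list[PWM]

    def __post_init__(self):
        ids = [p.motif_id for p in self.pwms]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate motif ids in PWM library")
        self._by_id = {p.motif_id: p for p in self.pwms}

    def __getitem__(self, motif_id: str) -> PWM:
        return self._by_id[motif_id]

    def __iter__(self):
        return iter(self.pwms)

    def __len__(self) -> int:
        return len(self.pwms)

    @property
    def motif_ids(self) -> list[str]:
        return [p.motif_id for p in self.pwms]


def counts_to_pwm(motif_id: str, counts: np.ndarray, family: str = "",
                  background: np.ndarray | None = None,
                  pseudocount: float = 0.5) -> PWM:
    """Convert a 4 x L count (or probability) matrix to a pseudocount-
    regularized probability PWM."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise FormatError(f"{motif_id}: negative PFM entries")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise FormatError(f"{motif_id}: PFM column with non-positive total")
    probs = (counts + pseudocount) / (totals + 4 * pseudocount)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PWM(motif_id, probs, family, bg)


def read_pwm_library(path, family_map: dict[str, str] | None = None,
                     background: np.ndarray | None = None,
                     pseudocount: float = 0.5) -> PWMLibrary:
    """Read a JASPAR PFM text file into a PWMLibrary. ``family_map`` assigns
    family labels by motif id (or by name when the id is absent)."""
    family_map = family_map or {}
    pwms = []
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in BASES], dtype=float)
            mid = m.matrix_id or m.name
            fam = family_map.get(mid, family_map.get(m.name, ""))
            pwms.append(counts_to_pwm(mid, counts, fam, background, pseudocount))
    if not pwms:
        raise FormatError(f"{path}: no motifs parsed")
    return PWMLibrary(pwms)


def write_pwm_library(library: PWMLibrary, path, scale: int = 100) -> None:
    """Write a library as JASPAR PFM text (probabilities scaled to integer-
    like counts for readability)."""
    with open(path, "w") as fh:
        for p in library:
            fh.write(f">{p.motif_id} {p.family or p.motif_id}\n")
            for b, row in zip(BASES, p.matrix * scale):
                vals = " ".join(f"{v:.2f}" for v in row)
                fh.write(f"{b}  [ {vals} ]\n")


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def encode_sequence(seq: str) -> np.ndarray:
    codes = np.full(len(seq), 4, dtype=np.int8)
    for b, i in _CODE.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return codes


@dataclass(frozen=True)
class MotifHit:
    position: int
    strand: str
    score: float


def _offset_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Log-odds score at every offset; positions containing N score -inf."""
    L = lo.shape[1]
    n = codes.size - L + 1
    if n <= 0:
        return np.empty(0)
    lo_ext = np.vstack([lo, np.full((1, L), _NEG_INF)])  # row 4 = N
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return lo_ext[windows, np.arange(L)].sum(axis=1)


def scan(sequence: str, pwm: PWM, score_fraction: float = 0.8) -> list[MotifHit]:
    """All positions where the PWM log-odds score reaches ``score_fraction``
    of its maximum, on either strand. A minus-strand hit at position i means
    the motif matches the reverse complement of sequence[i:i+L]. Sequences
    shorter than the motif yield an empty list."""
    codes = encode_sequence(sequence.upper())
    threshold = score_fraction * pwm.max_score()
    hits: list[MotifHit] = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        scores = _offset_scores(codes, mat.log_odds())
        for pos in np.flatnonzero(scores >= threshold - 1e-12):
            hits.append(MotifHit(int(pos), strand, float(scores[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


@dataclass
class OccurrenceMatrix:
    """Boolean peaks x motifs presence matrix plus the per-(peak, motif)
    hit lists behind it."""

    presence: pd.DataFrame
    hits: dict[tuple[str, str], list[MotifHit]]

    @property
    def peak_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def motif_ids(self) -> list[str]:
        return list(self.presence.columns)


def occurrence_matrix(sequences: dict[str, str], library: PWMLibrary,
                      score_fraction: float = 0.8,
                      required_ids: list[str] | None = None) -> OccurrenceMatrix:
    if required_ids is not None:
        missing = [i for i in required_ids if i not in sequences]
        if missing:
            raise DataError(f"peaks without sequences: {missing[:5]}")
    peak_ids = list(sequences)
    presence = pd.DataFrame(False, index=pd.Index(peak_ids, name="peak_id"),
                            columns=library.motif_ids)
    hits: dict[tuple[str, str], list[MotifHit]] = {}
    encoded = {pid: encode_sequence(s.upper()) for pid, s in sequences.items()}
    for pwm in library:
        lo_f = pwm.log_odds()
        lo_r = pwm.reverse_complement().log_odds()
        threshold = score_fraction * pwm.max_score() - 1e-12
        for pid in peak_ids:
            codes = encoded[pid]
            hit_list: list[MotifHit] = []
            for strand, lo in (("+", lo_f), ("-", lo_r)):
                scores = _offset_scores(codes, lo)
                for pos in np.flatnonzero(scores >= threshold):
                    hit_list.append(MotifHit(int(pos), strand, float(scores[pos])))
            if hit_list:
                hit_list.sort(key=lambda h: (h.position, h.strand))
                presence.loc[pid, pwm.motif_id] = True
                hits[(pid, pwm.motif_id)] = hit_list
    return OccurrenceMatrix(presence, hits)


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentMatrix:
    """Motifs x bins matrix of -log10 hypergeometric upper-tail p-values,
    plus the family label per motif and the ids merged into each row."""

    neglogp: pd.DataFrame
    families: dict[str, str]
    merged_members: dict[str, list[str]] = field(default_factory=dict)

    @property
    def motif_ids(self) -> list[str]:
        return list(self.neglogp.index)

    def flags(self, enriched_min: float = 3.0,
              changing_min: float = 1.0) -> pd.DataFrame:
        m = self.neglogp
        return pd.DataFrame({
            "enriched_anywhere": m.max(axis=1) >= enriched_min,
            "changing_across_bins": (m.max(axis=1) - m.min(axis=1)) >= changing_min,
        })


def hypergeom_upper_p(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(hypergeom.sf(k - 1, N, K, n))


def bin_enrichment(occ: OccurrenceMatrix, bins) -> EnrichmentMatrix:
    """Per motif per rank bin, the one-sided hypergeometric upper-tail p of
    the bin's motif-bearing peak count against all binned peaks as
    background; entries are -log10 p."""
    binned_ids = bins.ranked.peak_ids
    missing = [i for i in binned_ids if i not in occ.presence.index]
    if missing:
        raise DataError(f"bins reference peaks absent from occurrence matrix: "
                        f"{missing[:5]}")
    pres = occ.presence.loc[binned_ids].to_numpy()
    bin_of = bins.bin_of
    n_bins = bins.n_bins
    N = len(binned_ids)
    K = pres.sum(axis=0)                      # per motif
    n_in_bin = np.bincount(bin_of, minlength=n_bins)
    k = np.zeros((pres.shape[1], n_bins), dtype=int)
    for b in range(n_bins):
        k[:, b] = pres[bin_of == b].sum(axis=0)
    p = hypergeom.sf(k - 1, N, K[:, None], n_in_bin[None, :])
    neglogp = -np.log10(np.clip(p, 1e-300, 1.0))
    df = pd.DataFrame(neglogp, index=pd.Index(occ.motif_ids, name="motif"),
                      columns=[f"bin_{b}" for b in range(n_bins)])
    return EnrichmentMatrix(df, families={}, merged_members={})


def pwm_similarity(a: PWM, b: PWM, min_overlap: int = 4) -> float:
    """Maximum Pearson correlation of aligned probability columns over all
    ungapped offsets with >= ``min_overlap`` overlapping columns, taking the
    better of b and its reverse complement. Symmetric in a and b."""
    def best(ma: np.ndarray, mb: np.ndarray) -> float:
        La, Lb = ma.shape[1], mb.shape[1]
        top = -np.inf
        for s in range(-(Lb - min_overlap), La - min_overlap + 1):
            lo_a, hi_a = max(0, s), min(La, s + Lb)
            if hi_a - lo_a < min_overlap:
                continue
            block_a = ma[:, lo_a:hi_a].ravel()
            block_b = mb[:, lo_a - s:hi_a - s].ravel()
            sa, sb = block_a.std(), block_b.std()
            if sa == 0 or sb == 0:
                continue
            r = float(np.corrcoef(block_a, block_b)[0, 1])
            top = max(top, r)
        return top

    score = max(best(a.matrix, b.matrix),
                best(a.matrix, b.reverse_complement().matrix))
    if not np.isfinite(score):
        raise DataError(
            f"no alignment of {a.motif_id} and {b.motif_id} satisfies the "
            f"{min_overlap}-column overlap constraint")
    return score


def filter_and_merge(matrix: EnrichmentMatrix, library: PWMLibrary,
                     similarity_threshold: float = 0.90,
                     enriched_min: float = 3.0,
                     changing_min: float = 1.0) -> EnrichmentMatrix:
    """Drop motifs that are never enriched (-log10 p < ``enriched_min`` in
    every bin) or not changing (range across bins < ``changing_min``), then
    merge same-family motifs with PWM similarity > threshold (single-linkage
    transitive closure) by taking the per-bin best (max -log10 p)."""
    flags = matrix.flags(enriched_min, changing_min)
    keep = list(matrix.neglogp.index[flags.all(axis=1)])
    if not keep:
        return EnrichmentMatrix(matrix.neglogp.iloc[0:0], families={},
                                merged_members={})
    parent = {m: m for m in keep}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, mi in enumerate(keep):
        for mj in keep[i + 1:]:
            if library[mi].family != library[mj].family or not library[mi].family:
                continue
            if pwm_similarity(library[mi], library[mj]) > similarity_threshold:
                parent[find(mi)] = find(mj)

    clusters: dict[str, list[str]] = {}
    for m in keep:
        clusters.setdefault(find(m), []).append(m)
    rows, families, members = [], {}, {}
    for group in clusters.values():
        group = sorted(group)
        row = matrix.neglogp.loc[group].max(axis=0)
        name = group[0] if len(group) == 1 else "|".join(group)
        row.name = name
        rows.append(row)
        families[name] = library[group[0]].family
        members[name] = group
    merged = pd.DataFrame(rows)
    merged.index.name = "motif"
    return EnrichmentMatrix(merged.sort_index(), families, members)


def subset_enrichment(occ: OccurrenceMatrix, subset: list[str],
                      background: list[str]) -> pd.DataFrame:
    """Hypergeometric motif enrichment of a peak subset against a background
    superset; returns per-motif p, BH q and fold enrichment, best first."""
    if not subset:
        raise DataError("empty peak subset")
    if not set(subset) <= set(background):
        raise DataError("subset must be contained in background")
    bg = occ.presence.loc[background]
    sub = occ.presence.loc[subset]
    N, n = len(background), len(subset)
    K = bg.sum(axis=0)
    k = sub.sum(axis=0)
    p = hypergeom.sf(k - 1, N, K, n)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(K > 0, (k / n) / (K / N), np.nan)
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({"k_subset": k, "K_background": K, "fold": fold,
                        "p": p, "q": q}, index=occ.presence.columns)
    out.index.name = "motif"
    return out.sort_index().sort_values("p", kind="mergesort")


def motif_cooccurrence(occ: OccurrenceMatrix, subset: list[str],
                       families: dict[str, list[str]]
                       ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Family-level co-occurrence over a peak subset.

    Returns (overlap-count matrix with per-family counts on the diagonal,
    Jaccard matrix, per-peak family-presence boolean frame)."""
    sub = occ.presence.loc[subset]
    fam_pres = pd.DataFrame(
        {fam: sub[members].any(axis=1) for fam, members in families.items()})
    mat = fam_pres.to_numpy()
    counts = mat.T.astype(int) @ mat.astype(int)
    names = list(fam_pres.columns)
    count_df = pd.DataFrame(counts, index=names, columns=names)
    union = (mat.T[:, None, :] | mat.T[None, :, :]).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        jac = np.where(union > 0, counts / union, 0.0)
    jac_df = pd.DataFrame(jac, index=names, columns=names)
    return count_df, jac_df, fam_pres
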