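"""Peak-to-gene annotation: feature classes, nearest TSS, and per-subset
feature/TSS-distance summaries.

Classification happens at the peak midpoint with precedence
promoter > TTS > exon > intron > intergenic, so every peak lands in exactly
one class. The promoter window is -promoter_upstream/+promoter_downstream
around the TSS on the gene strand; the TTS window is +/- tts_window around
the far end of the gene span. Nearest gene = nearest TSS by absolute
midpoint distance, ties to the lexicographically smaller gene id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_core import DataError, GeneModel, GenomicInterval, PeakSet, logger
from .peak_stats import rpkm

FEATURE_CLASSES = ("promoter", "TTS", "exon", "intron", "intergenic")


@dataclass
class PeakAnnotation:
    peak_id: str
    feature_class: str
    nearest_gene: str | None
    tss_distance: float  # signed bp; negative = upstream of TSS on gene strand


def _promoter_window(g: GeneModel, upstream: int, downstream: int) -> tuple[int, int]:
    if g.strand == "+":
        return g.tss - upstream, g.tss + downstream + 1
    return g.tss - downstream, g.tss + upstream + 1


def _tts_position(g: GeneModel) -> int:
    span = g.span
    return span.end - 1 if g.strand == "+" else span.start


class GeneIndex:
    """Interval-tree index over gene parts for midpoint classification plus
    sorted-TSS arrays for nearest-gene lookup."""

    def __init__(self, genes: list[GeneModel], promoter_upstream: int = 1000,
                 promoter_downstream: int = 100, tts_window: int = 100):
        self.genes = {g.gene_id: g for g in genes}
        if len(self.genes) != len(genes):
            raise DataError("duplicate gene ids in gene list")
        self.promoter_upstream = promoter_upstream
        self.promoter_downstream = promoter_downstream
        self.tts_window = tts_window
        self._trees: dict[str, dict[str, IntervalTree]] = {}
        tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
        for g in genes:
            trees = self._trees.setdefault(
                g.chrom, {k: IntervalTree() for k in ("promoter", "TTS", "exon", "intron")})
            lo, hi = _promoter_window(g, promoter_upstream, promoter_downstream)
            trees["promoter"][max(lo, 0):hi] = g.gene_id
            tts = _tts_position(g)
            trees["TTS"][max(tts - tts_window, 0):tts + tts_window + 1] = g.gene_id
            exons = sorted(g.exons, key=lambda e: e.start)
            for e in exons:
                trees["exon"][e.start:e.end] = g.gene_id
            for a, b in zip(exons, exons[1:]):
                if b.start > a.end:
                    trees["intron"][a.end:b.start] = g.gene_id
            tss_by_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
        self._tss: dict[str, tuple[np.ndarray, list[str]]] = {}
        for chrom, pairs in tss_by_chrom.items():
            pairs.sort()
            self._tss[chrom] = (np.array([p for p, _ in pairs]), [i for _, i in pairs])

    def nearest_gene(self, chrom: str, pos: int) -> tuple[str | None, float]:
        """Nearest-TSS gene and signed distance (negative = upstream on the
        gene strand)."""
        if chrom not in self._tss:
            return None, float("nan")
        positions, ids = self._tss[chrom]
        j = int(np.searchsorted(positions, pos))
        candidates = []
        for k in (j - 1, j, j + 1):
            if 0 <= k < positions.size:
                candidates.append((abs(int(positions[k]) - pos), ids[k], int(positions[k])))
        candidates.sort()  # ties -> lexicographically smaller gene id
        _, gid, tss = candidates[0]
        gene = self.genes[gid]
        dist = pos - tss if gene.strand == "+" else tss - pos
        return gid, float(dist)

    def classify_midpoint(self, chrom: str, pos: int) -> str:
        trees = self._trees.get(chrom)
        if trees is None:
            return "intergenic"
        for cls in ("promoter", "TTS", "exon", "intron"):
            if trees[cls][pos]:
                return cls
        return "intergenic"


def annotate_peak(peak: GenomicInterval, index: GeneIndex,
                  peak_id: str | None = None) -> PeakAnnotation:
    mid = peak.midpoint
    cls = index.classify_midpoint(peak.chrom, mid)
    gid, dist = index.nearest_gene(peak.chrom, mid)
    return PeakAnnotation(
        peak_id=peak_id or f"{peak.chrom}:{peak.start}-{peak.end}",
        feature_class=cls, nearest_gene=gid, tss_distance=dist)


def annotate_peaks(peaks: list[GenomicInterval], peak_ids: list[str],
                   genes: list[GeneModel], promoter_upstream: int = 1000,
                   promoter_downstream: int = 100,
                   tts_window: int = 100) -> pd.DataFrame:
    """Annotate every peak; returns a DataFrame indexed by peak id with
    columns feature_class, nearest_gene, tss_distance. With an empty gene
    list everything is intergenic with undefined (NaN) distance."""
    if not genes:
        logger.warning("annotate_peaks: empty gene list; all peaks intergenic")
        return pd.DataFrame(
            {"feature_class": "intergenic", "nearest_gene": None,
             "tss_distance": np.nan},
            index=pd.Index(peak_ids, name="peak_id"))
    index = GeneIndex(genes, promoter_upstream, promoter_downstream, tts_window)
    rows = [annotate_peak(p, index, pid) for p, pid in zip(peaks, peak_ids)]
    return pd.DataFrame(
        {"feature_class": [r.feature_class for r in rows],
         "nearest_gene": [r.nearest_gene for r in rows],
         "tss_distance": [r.tss_distance for r in rows]},
        index=pd.Index(peak_ids, name="peak_id"))


def feature_distribution(annotations: pd.DataFrame,
                         subset: list[str] | None = None) -> pd.DataFrame:
    """Counts and proportions per feature class for a peak subset."""
    if subset is None:
        sub = annotations
    else:
        unknown = [s for s in subset if s not in annotations.index]
        if unknown:
            raise DataError(f"unknown peak ids in subset: {unknown[:5]}")
        sub = annotations.loc[subset]
    counts = sub["feature_class"].value_counts().reindex(FEATURE_CLASSES, fill_value=0)
    out = pd.DataFrame({"count": counts})
    out["proportion"] = out["count"] / max(len(sub), 1)
    return out


def tss_distance_histogram(annotations: pd.DataFrame, subset: list[str] | None = None,
                           breaks: list[float] | None = None) -> pd.Series:
    """Histogram of |TSS distance| over half-open bins [lo, hi); default
    breaks 0 / 1 kb / 10 kb / inf."""
    if breaks is None:
        breaks = [0.0, 1_000.0, 10_000.0]
    if any(b >= c for b, c in zip(breaks, breaks[1:])):
        raise DataError("breaks must be strictly increasing")
    sub = annotations if subset is None else annotations.loc[subset]
    d = sub["tss_distance"].abs().dropna().to_numpy()
    edges = np.array(breaks + [np.inf])
    counts = np.histogram(d, bins=edges)[0]
    labels = [f"[{int(lo)},{'inf' if np.isinf(hi) else int(hi)})"
              for lo, hi in zip(edges[:-1], edges[1:])]
    return pd.Series(counts, index=labels, name="count")


def peaks_near_gene(gene_id: str, annotations: pd.DataFrame) -> list[str]:
    """Peaks whose nearest-gene assignment is ``gene_id``."""
    if gene_id not in set(annotations["nearest_gene"].dropna()):
        known = annotations["nearest_gene"].dropna().unique()
        if gene_id not in known:
            raise DataError(f"gene {gene_id!r} has no assigned peaks / is unknown")
    return list(annotations.index[annotations["nearest_gene"] == gene_id])


def genes_for_peaks(subset: list[str], annotations: pd.DataFrame) -> list[str]:
    """Nearest genes of a peak subset (unique, sorted)."""
    unknown = [s for s in subset if s not in annotations.index]
    if unknown:
        raise DataError(f"unknown peak ids: {unknown[:5]}")
    genes = annotations.loc[subset, "nearest_gene"].dropna().unique()
    return sorted(genes)


def gene_body_accessibility(peakset: PeakSet, genes: list[GeneModel],
                            de_classes: pd.Series, condition_a: str,
                            condition_b: str, promoter_upstream: int = 1000,
                            n_boot: int = 200,
                            rng_seed: int = 0) -> pd.DataFrame:
    """Mean accessibility change (RPKM, condition_b - condition_a) over the
    peaks overlapping each gene span (promoter window included), summarized
    per DE class (mean, median, bootstrap CI). Genes without overlapping
    peaks are excluded and counted in the log."""
    mat = rpkm(peakset)
    idx_a = peakset.sample_indices(condition_a)
    idx_b = peakset.sample_indices(condition_b)
    vals = mat.to_numpy()
    diff = vals[:, idx_b].mean(axis=1) - vals[:, idx_a].mean(axis=1)
    trees: dict[str, IntervalTree] = {}
    for i, p in enumerate(peakset.peaks):
        trees.setdefault(p.chrom, IntervalTree())[p.start:p.end] = i
    per_gene: dict[str, float] = {}
    skipped = 0
    for g in genes:
        span = g.span
        lo = span.start - (promoter_upstream if g.strand == "+" else 0)
        hi = span.end + (promoter_upstream if g.strand == "-" else 0)
        tree = trees.get(g.chrom)
        hits = sorted({iv.data for iv in tree[max(lo, 0):hi]}) if tree else []
        if not hits:
            skipped += 1
            continue
        per_gene[g.gene_id] = float(diff[hits].mean())
    if skipped:
        logger.info("gene_body_accessibility: %d genes had no overlapping peaks", skipped)
    rng = np.random.default_rng(rng_seed)
    rows = []
    for cls in de_classes.dropna().unique():
        members = [g for g in de_classes.index[de_classes == cls] if g in per_gene]
        values = np.array([per_gene[g] for g in members])
        if values.size == 0:
            rows.append({"de_class": cls, "n_genes": 0, "mean": np.nan,
                         "median": np.nan, "ci_lo": np.nan, "ci_hi": np.nan})
            continue
        boots = rng.choice(values, size=(n_boot, values.size), replace=True).mean(axis=1)
        rows.append({"de_class": cls, "n_genes": values.size,
                     "mean": float(values.mean()), "median": float(np.median(values)),
                     "ci_lo": float(np.quantile(boots, 0.025)),
                     "ci_hi": float(np.quantile(boots, 0.975))})
    return pd.DataFrame(rows).set_index("de_class")
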