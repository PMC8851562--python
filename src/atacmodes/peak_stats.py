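"""Normalization, filtering, ranking, binning and top-N selection of peaks.

The ranked analysis: peaks are RPKM-normalized, low-count peaks removed,
replicates averaged per condition, and peaks ranked by the between-condition
difference. Ranked peaks are cut into equal-sized contiguous bins that feed
the motif-enrichment landscape, and the extreme tails ("top N loss/gain")
feed the feature-distribution and signal-profile views.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import DataError, GenomicInterval, PeakSet, logger


def rpkm(peakset: PeakSet) -> pd.DataFrame:
    """Reads per kilobase of peak per million mapped reads.

    rpkm[i, s] = counts[i, s] / (width_kb_i * libsize_s / 1e6). Library sizes
    come from the sample metadata (total mapped reads), not from in-peak
    counts.
    """
    widths = peakset.widths()
    if (widths <= 0).any():
        raise DataError("zero-width peak in RPKM computation")
    width_kb = widths / 1_000.0
    lib_m = peakset.sample_meta["library_size"].to_numpy() / 1e6
    values = peakset.counts / (width_kb[:, None] * lib_m[None, :])
    return pd.DataFrame(values, index=pd.Index(peakset.peak_ids, name="peak_id"),
                        columns=peakset.samples)


def filter_low_count(peakset: PeakSet, min_total: int) -> PeakSet:
    """Drop peaks whose raw counts summed over all samples fall below
    ``min_total``; order of the survivors is preserved."""
    if min_total < 0:
        raise DataError("min_total must be >= 0")
    totals = peakset.counts.sum(axis=1)
    keep = np.flatnonzero(totals >= min_total)
    logger.info("filter_low_count: kept %d of %d peaks (min_total=%d)",
                keep.size, peakset.n_peaks, min_total)
    return peakset.subset(keep)


@dataclass
class RankedPeaks:
    """Peaks ordered by accessibility change between two conditions.

    ``table`` is indexed by peak id in rank order with columns ``mean_a``,
    ``mean_b`` (per-condition replicate means) and ``diff`` (b - a, so a
    KO-vs-WT contrast puts the largest losses first under signed ranking).
    """

    table: pd.DataFrame
    condition_a: str
    condition_b: str
    mode: str            # "signed" | "absolute"
    value: str           # "rpkm" | "raw-mean"

    @property
    def peak_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def rank_peaks(peakset: PeakSet, condition_a: str, condition_b: str,
               mode: str = "signed", value: str = "rpkm") -> RankedPeaks:
    """Rank peaks by the difference in mean accessibility (condition_b -
    condition_a).

    signed: ascending difference (largest loss first, largest gain last) —
    the ordering behind the binned landscape. absolute: descending
    |difference|. Ties break by peak id, lexicographically.
    """
    if mode not in {"signed", "absolute"}:
        raise DataError(f"unknown ranking mode {mode!r}")
    if value not in {"rpkm", "raw-mean"}:
        raise DataError(f"unknown value choice {value!r}")
    idx_a = peakset.sample_indices(condition_a)
    idx_b = peakset.sample_indices(condition_b)
    if value == "rpkm":
        mat = rpkm(peakset).to_numpy()
    else:
        mat = peakset.counts.astype(float)
    mean_a = mat[:, idx_a].mean(axis=1)
    mean_b = mat[:, idx_b].mean(axis=1)
    diff = mean_b - mean_a
    df = pd.DataFrame({"mean_a": mean_a, "mean_b": mean_b, "diff": diff},
                      index=pd.Index(peakset.peak_ids, name="peak_id"))
    if mode == "signed":
        df = df.sort_values(["diff", "peak_id"], ascending=[True, True],
                            kind="mergesort")
    else:
        df = (df.assign(_absdiff=np.abs(diff))
                .sort_values(["_absdiff", "peak_id"], ascending=[False, True],
                             kind="mergesort")
                .drop(columns="_absdiff"))
    return RankedPeaks(df, condition_a, condition_b, mode, value)


@dataclass
class PeakBins:
    """Contiguous equal-sized slices of a ranked peak list."""

    ranked: RankedPeaks
    bin_of: np.ndarray       # per-ranked-peak bin index
    bin_size: int

    @property
    def n_bins(self) -> int:
        return int(self.bin_of.max()) + 1

    def bin_sizes(self) -> np.ndarray:
        return np.bincount(self.bin_of, minlength=self.n_bins)

    def members(self, b: int) -> list[str]:
        ids = self.ranked.peak_ids
        return [ids[i] for i in np.flatnonzero(self.bin_of == b)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"peak_id": self.ranked.peak_ids, "bin": self.bin_of})


def bin_peaks(ranked: RankedPeaks, bin_size: int) -> PeakBins:
    """Partition the ranked list into floor(n / bin_size) contiguous bins
    (minimum 1) whose sizes differ by at most one; remainder peaks are
    spread over the leading bins."""
    n = len(ranked)
    if n == 0:
        raise DataError("cannot bin an empty ranked list")
    if bin_size < 1:
        raise DataError("bin_size must be >= 1")
    n_bins = max(n // bin_size, 1)
    base, extra = divmod(n, n_bins)
    # first `extra` bins take base+1 peaks, the rest take base
    sizes = np.full(n_bins, base, dtype=int)
    sizes[:extra] += 1
    bin_of = np.repeat(np.arange(n_bins), sizes)
    return PeakBins(ranked=ranked, bin_of=bin_of, bin_size=bin_size)


def top_n(ranked: RankedPeaks, n: int, direction: str) -> list[str]:
    """The n peaks with the most negative (loss) or most positive (gain)
    difference; deterministic under the lexicographic tie-break."""
    if direction not in {"loss", "gain"}:
        raise DataError(f"direction must be 'loss' or 'gain', got {direction!r}")
    if n > len(ranked):
        raise DataError(f"requested top {n} of only {len(ranked)} ranked peaks")
    df = ranked.table
    if ranked.mode != "signed":
        df = df.sort_values(["diff", "peak_id"], ascending=[True, True],
                            kind="mergesort")
    ids = list(df.index)
    return ids[:n] if direction == "loss" else ids[-n:][::-1]


def signal_profile(tracks: dict[str, dict[str, np.ndarray]],
                   regions: list[GenomicInterval], flank: int = 1000,
                   n_points: int = 101,
                   normalize: bool = True) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Average signal curves around region summits (midpoints).

    ``tracks`` maps condition -> chrom -> dense per-base signal. Each region
    window [summit-flank, summit+flank] is resampled onto an ``n_points``
    grid; windows running off a chromosome are clipped (zero-padded) with a
    warning. Returns the per-condition average curve (grid x conditions) and
    the per-region matrices. With ``normalize`` the track is scaled to
    counts-per-million of total track mass first.
    """
    grid = np.linspace(-flank, flank, n_points)
    curves: dict[str, np.ndarray] = {}
    matrices: dict[str, np.ndarray] = {}
    for cond, per_chrom in tracks.items():
        scale = 1.0
        if normalize:
            total = sum(float(a.sum()) for a in per_chrom.values())
            scale = 1e6 / total if total > 0 else 1.0
        rows = np.zeros((len(regions), n_points))
        for i, region in enumerate(regions):
            arr = per_chrom.get(region.chrom)
            if arr is None:
                raise DataError(f"no track for chromosome {region.chrom}")
            mid = region.midpoint
            lo, hi = mid - flank, mid + flank + 1
            window = np.zeros(2 * flank + 1)
            clip_lo, clip_hi = max(lo, 0), min(hi, arr.size)
            if clip_lo > lo or clip_hi < hi:
                logger.warning("signal_profile: window for %s:%d-%d clipped",
                               region.chrom, lo, hi)
            window[clip_lo - lo:clip_hi - lo] = arr[clip_lo:clip_hi]
            rows[i] = np.interp(grid, np.arange(-flank, flank + 1), window) * scale
        matrices[cond] = rows
        curves[cond] = rows.mean(axis=0)
    curve_df = pd.DataFrame(curves, index=pd.Index(grid, name="position"))
    return curve_df, matrices
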