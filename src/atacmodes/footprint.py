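"""Simplified transcription-factor footprinting from cut-site tracks.

An occupied binding site protects its motif span from transposase
insertion, so the per-base cut-count profile aggregated over many motif
occurrences dips across the motif relative to the flanks. Profiles here
are depth-normalized per condition (each aggregate sums to 1 over the
window), and protection depth is 1 - (mean in-motif rate / mean flank
rate) with the flank defined as the outer 25% of the window on each side.

This is deliberately simpler than HMM-based footprinters: no Tn5 sequence-
bias model, and no +4/-5 offset correction by default (the simulator emits
cut positions directly; an optional offset can be applied to real data).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import DataError


@dataclass
class FootprintSite:
    chrom: str
    center: int
    strand: str = "+"


@dataclass
class FootprintProfile:
    motif_id: str
    condition: str
    grid: np.ndarray            # positions -window..window
    rates: np.ndarray           # mean normalized cut rate per position, sums to 1
    n_sites: int
    motif_len: int
    site_matrix: np.ndarray | None = None  # per-site raw cut vectors (sites x grid)

    def __post_init__(self):
        if self.n_sites <= 0:
            raise DataError("footprint profile needs at least one site")
        if (self.rates < 0).any():
            raise DataError("negative cut rates")
        if self.grid.size != self.rates.size:
            raise DataError("grid/rates length mismatch")


@dataclass
class ProtectionScore:
    motif_id: str
    depth_a: float
    depth_b: float
    difference: float           # depth_a - depth_b
    ci_a: tuple[float, float] | None = None
    ci_b: tuple[float, float] | None = None


def aggregate_footprint(cuts: dict[str, np.ndarray], sites: list[FootprintSite],
                        window: int, motif_id: str, condition: str,
                        motif_len: int, tn5_offset: bool = False,
                        keep_sites: bool = True) -> FootprintProfile:
    """Aggregate per-base cut counts in +/-window around each site center,
    orienting each window by the site strand, then normalize by the total
    cuts across all aggregated windows."""
    if not sites:
        raise DataError("no sites to aggregate")
    width = 2 * window + 1
    vectors = np.zeros((len(sites), width))
    for i, site in enumerate(sites):
        arr = cuts.get(site.chrom)
        if arr is None:
            raise DataError(f"no cut track for chromosome {site.chrom}")
        center = site.center + (4 if (tn5_offset and site.strand == "+") else
                                -5 if tn5_offset else 0)
        lo, hi = center - window, center + window + 1
        if lo < 0 or hi > arr.size:
            raise DataError(
                f"site window {site.chrom}:{lo}-{hi} runs off the chromosome")
        vec = arr[lo:hi].astype(float)
        if site.strand == "-":
            vec = vec[::-1]
        vectors[i] = vec
    total = vectors.sum()
    if total <= 0:
        raise DataError("zero total cuts in aggregated windows; cannot normalize")
    profile = vectors.sum(axis=0) / total
    return FootprintProfile(
        motif_id=motif_id, condition=condition,
        grid=np.arange(-window, window + 1), rates=profile,
        n_sites=len(sites), motif_len=motif_len,
        site_matrix=vectors if keep_sites else None)


def _depth(rates: np.ndarray, window: int, motif_len: int) -> float:
    """1 - mean in-motif rate / mean flank rate. In-motif = the central
    motif_len positions; flank = outer 25% of the window per side."""
    width = rates.size
    half_motif = motif_len // 2
    center = width // 2
    in_motif = rates[center - half_motif: center - half_motif + motif_len]
    flank_n = max(int(round(0.25 * window)), 1)
    flank = np.concatenate([rates[:flank_n], rates[-flank_n:]])
    if flank.mean() <= 0:
        raise DataError("flank has zero signal; depth undefined")
    return float(1.0 - in_motif.mean() / flank.mean())


def profile_depth(profile: FootprintProfile) -> float:
    window = (profile.grid.size - 1) // 2
    return _depth(profile.rates, window, profile.motif_len)


def protection_score(profile_a: FootprintProfile, profile_b: FootprintProfile,
                     n_boot: int = 200, rng_seed: int = 0) -> ProtectionScore:
    """Per-condition protection depth and their signed difference (a - b),
    with bootstrap-over-sites CIs when per-site vectors are retained."""
    if profile_a.motif_id != profile_b.motif_id:
        raise DataError("protection_score: profiles are for different motifs")
    if profile_a.grid.size != profile_b.grid.size or \
            (profile_a.grid != profile_b.grid).any():
        raise DataError("protection_score: grid mismatch")
    window = (profile_a.grid.size - 1) // 2
    depth_a = _depth(profile_a.rates, window, profile_a.motif_len)
    depth_b = _depth(profile_b.rates, window, profile_b.motif_len)

    def boot_ci(profile: FootprintProfile) -> tuple[float, float] | None:
        if profile.site_matrix is None or profile.n_sites < 2:
            return None
        rng = np.random.default_rng(rng_seed)
        depths = np.empty(n_boot)
        n = profile.site_matrix.shape[0]
        for i in range(n_boot):
            idx = rng.integers(0, n, size=n)
            agg = profile.site_matrix[idx].sum(axis=0)
            total = agg.sum()
            depths[i] = (_depth(agg / total, window, profile.motif_len)
                         if total > 0 else np.nan)
        depths = depths[np.isfinite(depths)]
        return (float(np.quantile(depths, 0.025)),
                float(np.quantile(depths, 0.975)))

    return ProtectionScore(
        motif_id=profile_a.motif_id, depth_a=depth_a, depth_b=depth_b,
        difference=depth_a - depth_b,
        ci_a=boot_ci(profile_a), ci_b=boot_ci(profile_b))
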