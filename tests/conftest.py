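import numpy as np
import pandas as pd
import pytest

from atacmodes.io_core import GenomicInterval, PeakSet
from atacmodes.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def study():
    """One small simulated study shared by read-only tests."""
    cfg = SimulationConfig(n_peaks=1200, n_genes=150, chrom_length=1_500_000,
                           rng_seed=11)
    return simulate_study(cfg, with_cut_sites=True)


@pytest.fixture(scope="session")
def study_occurrence(study):
    from atacmodes.motifs import occurrence_matrix
    return occurrence_matrix(study.sequences, study.library, 0.8)


def make_peakset(counts, widths=None, conditions=("WT", "WT", "KO", "KO"),
                 library_sizes=None, chrom="chr1"):
    """Hand-rolled PeakSet for arithmetic tests."""
    counts = np.asarray(counts)
    n_peaks, n_samples = counts.shape
    widths = widths if widths is not None else [1000] * n_peaks
    peaks, ids = [], []
    pos = 1000
    for i, w in enumerate(widths):
        peaks.append(GenomicInterval(chrom, pos, pos + w))
        ids.append(f"p{i}")
        pos += w + 500
    lib = library_sizes if library_sizes is not None else [1_000_000] * n_samples
    meta = pd.DataFrame(
        {"condition": list(conditions), "library_size": lib},
        index=pd.Index([f"s{i}" for i in range(n_samples)], name="sample"))
    return PeakSet(peaks=peaks, peak_ids=ids, counts=counts, sample_meta=meta)
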