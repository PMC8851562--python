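"""Shared setup for the analysis drivers: one deterministic synthetic study
at desk scale, plus output locations."""

from pathlib import Path

from atacmodes.io_core import AnalysisConfig, setup_logging
from atacmodes.simulate import SimulationConfig, simulate_study

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

STUDY_SEED = 0
SIM_CONFIG = SimulationConfig(rng_seed=STUDY_SEED)
ANALYSIS_CONFIG = AnalysisConfig(rng_seed=STUDY_SEED)
# the 6,000-peak desk-scale study yields ~20 bins of ~300 ranked peaks
BIN_SIZE = 300
TOP_N = 1000


def get_study(with_cut_sites: bool = False):
    setup_logging()
    RESULTS.mkdir(exist_ok=True)
    return simulate_study(SIM_CONFIG, with_cut_sites=with_cut_sites)
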