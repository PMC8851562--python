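"""Generate the synthetic study and write its full file bundle.

Emits peaks/counts/samples, gene models, peak sequences with planted
motifs, basal and agonist ChIP site sets, two DE tables, per-condition
cut-site tracks, the PWM library, and the truth manifest — everything the
downstream stages read — under scratch/sim_data/, plus a small summary of
what was planted under results/.
"""

import json

from common import RESULTS, SCRATCH, SIM_CONFIG, get_study
from atacmodes.simulate import simulate_study

outdir = SCRATCH / "sim_data"
study = simulate_study(SIM_CONFIG, outdir=outdir, with_cut_sites=True)

modes = {}
for m in study.truth.gene_modes.values():
    modes[m] = modes.get(m, 0) + 1

summary = {
    "n_peaks": study.peakset.n_peaks,
    "n_genes": len(study.genes),
    "n_samples": len(study.peakset.samples),
    "n_basal_sites": len(study.chip_basal.sites),
    "n_agonist_sites": len(study.chip_agonist.sites),
    "n_planted_motif_instances": len(study.truth.occurrences),
    "planted_gene_modes": modes,
    "rng_seed": SIM_CONFIG.rng_seed,
}
RESULTS.mkdir(exist_ok=True)
with open(RESULTS / "simulation_summary.json", "w") as fh:
    json.dump(summary, fh, indent=1)

print(f"wrote study bundle to {outdir}")
for k, v in summary.items():
    print(f"  {k}: {v}")
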