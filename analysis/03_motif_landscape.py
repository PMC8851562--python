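"""Motif-enrichment landscape across ranked accessibility bins.

Scans every peak sequence against the PWM panel, tests each motif's
occurrence frequency per rank bin (hypergeometric, all binned peaks as
background), filters non-enriched/non-changing motifs, merges
similar same-family PWMs, and reports family co-occurrence over the
loss-end bins. Loss-associated families should peak in the loss-end bins
and the CCAAT (NF-Y) family at the gain end.
"""

import numpy as np

from common import BIN_SIZE, RESULTS, get_study
from atacmodes import motifs as mo
from atacmodes import peak_stats as pk
from atacmodes.io_core import write_matrix

study = get_study()
ps = pk.filter_low_count(study.peakset, 10)
ranked = pk.rank_peaks(ps, "WT", "KO")
bins = pk.bin_peaks(ranked, BIN_SIZE)

occ = mo.occurrence_matrix({p: study.sequences[p] for p in ps.peak_ids},
                           study.library, score_fraction=0.8)
enr = mo.bin_enrichment(occ, bins)
merged = mo.filter_and_merge(enr, study.library, similarity_threshold=0.90)

write_matrix(enr.neglogp, RESULTS / "enrichment_matrix_raw.tsv")
write_matrix(merged.neglogp, RESULTS / "enrichment_matrix_merged.tsv")

print(f"{len(enr.neglogp)} motifs scanned; {len(merged.neglogp)} family rows "
      "survive the enriched/changing filters")
for name in merged.neglogp.index:
    row = merged.neglogp.loc[name]
    peak_bin = int(np.argmax(row.to_numpy()))
    end = "loss" if peak_bin < bins.n_bins / 2 else "gain"
    print(f"  {name:18s} max -log10 p = {row.max():5.1f} at bin {peak_bin:2d} "
          f"({end} end)")

# co-occurrence of surviving families over the loss-end quarter of bins
loss_bins = range(bins.n_bins // 4)
loss_ids = [pid for b in loss_bins for pid in bins.members(b)]
counts, jaccard, _ = mo.motif_cooccurrence(occ, loss_ids,
                                           merged.merged_members)
write_matrix(jaccard, RESULTS / "family_cooccurrence_jaccard.tsv")
print(f"co-occurrence over {len(loss_ids)} loss-end peaks written")
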