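"""Integrate expression, binding and accessibility; classify regulatory
modes.

Cross-tabulates ChIP binding against knockout DE classes, measures
accessibility change at binding-site peaks per DE class, flags large RPKM
losses, classifies every gene into a regulatory-mode segment from the
joint knockout x agonist response gated on binding, and summarizes each
direct-mode segment (genes, top motifs, promoter fraction, accessibility).
"""

import json

from common import RESULTS, TOP_N, get_study
from atacmodes import annotate as an
from atacmodes import integrate as it
from atacmodes import motifs as mo
from atacmodes import peak_stats as pk

study = get_study()
ps = pk.filter_low_count(study.peakset, 10)
ann = an.annotate_peaks(ps.peaks, ps.peak_ids, study.genes)
ranked = pk.rank_peaks(ps, "WT", "KO")

ko = it.classify_de(study.de_ko, alpha=0.05)
ag = it.classify_de(study.de_agonist, alpha=0.05)
print(f"KO contrast: {sum(ko == 'down')} down, {sum(ko == 'up')} up of {len(ko)}")

binding = it.assign_binding(study.genes, [study.chip_basal, study.chip_agonist])
props, fisher = it.binding_by_class(ko, binding)
props.to_csv(RESULTS / "binding_by_class.tsv", sep="\t", index=False)
for _, r in props.iterrows():
    print(f"  {r.site_set:8s} {r.de_class:10s} bound fraction "
          f"{r.proportion:.3f} ({r.n_bound}/{r.n_genes})")

dist, utests, frac_losing = it.accessibility_at_binding(
    ps, study.chip_agonist, ko, ann, "WT", "KO")
dist.to_csv(RESULTS / "accessibility_by_class.tsv", sep="\t")
print(f"binding-site peaks losing accessibility: {frac_losing:.1%}")
flagged = it.flag_large_loss(ps, study.chip_agonist, "WT", "KO", 10.0)
print(f"{len(flagged)} binding-site peaks lost >= 10 RPKM")

modes = it.classify_modes(ko, ag, binding)
modes.table.to_csv(RESULTS / "modes.tsv", sep="\t")
print("mode segments:", dict(modes.segment_counts()))

occ = mo.occurrence_matrix({p: study.sequences[p] for p in ps.peak_ids},
                           study.library, 0.8)
site_peaks = it.binding_site_peaks(ps, study.chip_agonist, ann, "WT", "KO")
segments = it.segment_summary(modes, occ, site_peaks)
with open(RESULTS / "segment_reports.json", "w") as fh:
    json.dump(segments, fh, indent=1)
for mode, rep in segments.items():
    top = rep.get("top_motifs", [])
    label = top[0]["motif"] if top else "-"
    print(f"  {mode:30s} {rep['n_genes']:3d} genes, top motif {label}")

gain_report = it.promoter_gain_analysis(
    ranked, ann, occ, binding, "NFY",
    n_top=min(TOP_N, len(ranked) // 2), ko_classes=ko)
with open(RESULTS / "promoter_gain_NFY.json", "w") as fh:
    json.dump(gain_report, fh, indent=1)
bound = gain_report["fraction_basal_bound"] + gain_report["fraction_agonist_only"]
print(f"NF-Y gain peaks: {gain_report['n_gain_peaks_with_motif']} of the top "
      f"gains carry the motif; {bound:.1%} of their genes have binding")
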