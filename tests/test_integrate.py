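"""Binding/expression/accessibility cross-tabulation and the regulatory-mode
classifier."""

import numpy as np
import pandas as pd
import pytest

from atacmodes import annotate as an
from atacmodes import integrate as it
from atacmodes import peak_stats as pk
from atacmodes.io_core import (BindingSiteSet, DETable, GeneModel,
                               GenomicInterval)

from conftest import make_peakset


def de_table(rows, name="ko"):
    df = pd.DataFrame(rows, columns=["gene_id", "log2_fold_change",
                                     "adjusted_p"]).set_index("gene_id")
    return DETable(df, name)


def simple_genes():
    return [GeneModel("gA", "gA", "chr1", "+", 10_000,
                      [GenomicInterval("chr1", 10_000, 20_000, "+")]),
            GeneModel("gB", "gB", "chr1", "+", 50_000,
                      [GenomicInterval("chr1", 50_000, 60_000, "+")])]


class TestClassifyDE:
    @pytest.mark.parametrize("lfc,p,expected", [
        (-1.0, 0.01, "down"),
        (-1.0, 0.2, "unchanged"),
        (1.0, 0.01, "up"),
        (0.0, 0.001, "unchanged"),
    ])
    def test_examples(self, lfc, p, expected):
        de = de_table([("g", lfc, p)])
        assert it.classify_de(de)["g"] == expected

    def test_matches_planted_direction(self, study):
        classes = it.classify_de(study.de_ko)
        for g, d in study.truth.de_truth.items():
            if d["ko_p"] < 0.05:
                expected = "down" if d["ko_lfc"] < 0 else "up"
                assert classes[g] == expected


class TestAssignBinding:
    def test_site_in_gene_body_targets_gene(self):
        genes = simple_genes()
        sites = BindingSiteSet([GenomicInterval("chr1", 14_000, 14_200)], "basal")
        ba = it.assign_binding(genes, [sites])
        assert ba.counts.loc["gA", "basal"] == 1
        assert ba.counts.loc["gB", "basal"] == 0

    def test_equidistant_tie_goes_to_smaller_gene_id(self):
        genes = simple_genes()  # TSSs at 10k and 50k; midpoint 30k equidistant
        sites = BindingSiteSet([GenomicInterval("chr1", 29_900, 30_100)], "basal")
        ba = it.assign_binding(genes, [sites])
        assert ba.counts.loc["gA", "basal"] == 1

    def test_counts_match_all_pairs_scan(self, study):
        ba = it.assign_binding(study.genes, [study.chip_agonist])
        tss = {g.gene_id: (g.chrom, g.tss) for g in study.genes}
        brute = {g: 0 for g in tss}
        for s in study.chip_agonist.sites:
            mid = s.midpoint
            best = min(((abs(t - mid), gid) for gid, (c, t) in tss.items()
                        if c == s.chrom), default=None)
            if best:
                brute[best[1]] += 1
        for gid, n in brute.items():
            assert ba.counts.loc[gid, "agonist"] == n


class TestBindingByClass:
    def test_proportion_arithmetic(self):
        classes = pd.Series({f"g{i}": "down" for i in range(10)} |
                            {f"h{i}": "unchanged" for i in range(10)})
        counts = pd.DataFrame({"basal": [1] * 4 + [0] * 6 + [0] * 10},
                              index=classes.index)
        ba = it.BindingAssignment(counts=counts)
        props, tests = it.binding_by_class(classes, ba)
        down = props[(props.de_class == "down") & (props.site_set == "basal")]
        assert down["proportion"].iloc[0] == pytest.approx(0.40)

    def test_equal_margins_fisher_p_one(self):
        classes = pd.Series({f"g{i}": "down" for i in range(10)} |
                            {f"h{i}": "up" for i in range(10)})
        counts = pd.DataFrame({"basal": [1] * 5 + [0] * 5 + [1] * 5 + [0] * 5},
                              index=classes.index)
        props, tests = it.binding_by_class(classes, it.BindingAssignment(counts))
        row = tests[(tests.class_a == "down") & (tests.class_b == "up")]
        assert row["fisher_p"].iloc[0] == pytest.approx(1.0)

    def test_planted_binding_enriched_in_de_classes(self, study):
        classes = it.classify_de(study.de_ko)
        ba = it.assign_binding(study.genes, [study.chip_basal, study.chip_agonist])
        props, _ = it.binding_by_class(classes, ba)
        basal = props[props.site_set == "basal"].set_index("de_class")
        assert basal.loc["down", "proportion"] > basal.loc["unchanged", "proportion"]
        agonist = props[props.site_set == "agonist"].set_index("de_class")
        assert agonist.loc["down", "proportion"] >= basal.loc["down", "proportion"]

    def test_invariant_to_gene_order(self, study):
        classes = it.classify_de(study.de_ko)
        ba = it.assign_binding(study.genes, [study.chip_basal])
        a, _ = it.binding_by_class(classes, ba)
        rng = np.random.default_rng(0)
        shuffled = classes.iloc[rng.permutation(len(classes))]
        b, _ = it.binding_by_class(shuffled, ba)
        pd.testing.assert_frame_equal(a, b)


class TestAccessibilityAtBinding:
    def test_separated_distributions(self):
        # 40 peaks over two genes; peaks near gA drop by 4 RPKM, gB flat
        counts = np.zeros((4, 4), dtype=int)
        genes = simple_genes()
        peaks, ids, rows = [], [], []
        for i in range(40):
            gene = genes[i % 2]
            start = gene.tss + 100 + (i // 2) * 400
            peaks.append(GenomicInterval("chr1", start, start + 200))
            ids.append(f"p{i}")
            base = 100
            drop = 80 if i % 2 == 0 else 0
            rows.append([base, base, base - drop, base - drop])
        ps = make_peakset(np.array(rows), widths=None)
        ps.peaks[:] = peaks
        ps.peak_ids[:] = ids
        ann = an.annotate_peaks(peaks, ids, genes)
        sites = BindingSiteSet(
            [GenomicInterval("chr1", p.start, p.end) for p in peaks], "basal")
        classes = pd.Series({"gA": "down", "gB": "unchanged"})
        dist, tests, frac = it.accessibility_at_binding(ps, sites, classes,
                                                        ann, "WT", "KO")
        assert dist.loc["down", "mean"] < dist.loc["unchanged", "mean"]
        row = tests[(tests.class_a == "down") & (tests.class_b == "unchanged")]
        assert row["mannwhitney_p"].iloc[0] < 1e-4

    def test_truth_driven_down_class_loses_most(self, study):
        ps = pk.filter_low_count(study.peakset, 10)
        ann = an.annotate_peaks(ps.peaks, ps.peak_ids, study.genes)
        classes = it.classify_de(study.de_ko)
        dist, tests, frac = it.accessibility_at_binding(
            ps, study.chip_agonist, classes, ann, "WT", "KO")
        assert dist.loc["down", "mean"] < dist.loc["unchanged", "mean"]
        assert 0 < frac < 1


class TestFlagLargeLoss:
    def _fixture(self, drop):
        # width 1000 bp, lib 1e6 -> RPKM == counts; drop in mean RPKM
        rows = [[100, 100, 100 - drop, 100 - drop]]
        ps = make_peakset(np.array(rows, dtype=int))
        sites = BindingSiteSet([GenomicInterval("chr1", ps.peaks[0].start,
                                                ps.peaks[0].end)], "basal")
        return ps, sites

    def test_boundary_inclusive(self):
        ps, sites = self._fixture(10)
        assert it.flag_large_loss(ps, sites, "WT", "KO", 10.0) == ["p0"]

    def test_below_boundary_not_flagged(self):
        ps, sites = self._fixture(9)
        assert it.flag_large_loss(ps, sites, "WT", "KO", 10.0) == []

    def test_matches_brute_force(self, study):
        ps = study.peakset
        flagged = set(it.flag_large_loss(ps, study.chip_agonist, "WT", "KO", 10.0))
        mat = pk.rpkm(ps).to_numpy()
        ia, ib = ps.sample_indices("WT"), ps.sample_indices("KO")
        loss = mat[:, ia].mean(axis=1) - mat[:, ib].mean(axis=1)
        site_spans = [(s.chrom, s.start, s.end) for s in study.chip_agonist.sites]
        brute = set()
        for i, p in enumerate(ps.peaks):
            overlaps = any(c == p.chrom and lo < p.end and p.start < hi
                           for c, lo, hi in site_spans)
            if overlaps and loss[i] >= 10.0:
                brute.add(ps.peak_ids[i])
        assert flagged == brute


class TestClassifyModes:
    def _binding(self, genes_bound_basal=(), genes_bound_agonist=()):
        universe = sorted(set(genes_bound_basal) | set(genes_bound_agonist) |
                          {"g1", "g2", "g3", "g4"})
        counts = pd.DataFrame(
            {"basal": [1 if g in genes_bound_basal else 0 for g in universe],
             "agonist": [1 if g in (set(genes_bound_agonist) |
                                    set(genes_bound_basal)) else 0
                         for g in universe]},
            index=universe)
        return it.BindingAssignment(counts)

    def test_segment_examples(self):
        ko = pd.Series({"g1": "down", "g2": "up", "g3": "down", "g4": "up"})
        ag = pd.Series({"g1": "up", "g2": "down", "g3": "unchanged",
                        "g4": "unchanged"})
        ba = self._binding(genes_bound_basal=("g1", "g2", "g3", "g4"))
        modes = it.classify_modes(ko, ag, ba)
        assert modes.table.loc["g1", "mode"] == "ligand-activated"
        assert modes.table.loc["g2", "mode"] == "ligand-repressed"
        assert modes.table.loc["g3", "mode"] == "basal-required-nonresponsive"
        assert modes.table.loc["g4", "mode"] == "basal-repressed-nonresponsive"

    def test_binding_gate_routes_unbound_to_indirect(self):
        ko = pd.Series({"g1": "down"})
        ag = pd.Series({"g1": "unchanged"})
        modes = it.classify_modes(ko, ag, self._binding())
        assert modes.table.loc["g1", "mode"] == "indirect"

    def test_modes_partition_all_genes(self, study):
        ko = it.classify_de(study.de_ko)
        ag = it.classify_de(study.de_agonist)
        ba = it.assign_binding(study.genes, [study.chip_basal, study.chip_agonist])
        modes = it.classify_modes(ko, ag, ba)
        assert len(modes.table) == len(ko)
        assert modes.segment_counts().sum() == len(ko)
        assert set(modes.table["mode"]) <= set(it.ALL_MODES)

    def test_truth_recovery_exact_where_gates_clear(self, study):
        """Every planted gene is assigned the segment its planted statistics
        dictate; direct planted modes are recovered exactly."""
        ko = it.classify_de(study.de_ko)
        ag = it.classify_de(study.de_agonist)
        ba = it.assign_binding(study.genes, [study.chip_basal, study.chip_agonist])
        modes = it.classify_modes(ko, ag, ba)
        for g, mode in study.truth.gene_modes.items():
            if mode in ("ligand-activated", "ligand-repressed"):
                assert modes.table.loc[g, "mode"] == mode
            elif mode == "indirect":
                d = study.truth.de_truth[g]
                if d["ko_p"] < 0.05 or d["agonist_p"] < 0.05:
                    assert modes.table.loc[g, "mode"] == "indirect"


@pytest.fixture(scope="module")
def pipeline(study, study_occurrence):
    ps = pk.filter_low_count(study.peakset, 10)
    ann = an.annotate_peaks(ps.peaks, ps.peak_ids, study.genes)
    ko = it.classify_de(study.de_ko)
    ag = it.classify_de(study.de_agonist)
    ba = it.assign_binding(study.genes, [study.chip_basal, study.chip_agonist])
    modes = it.classify_modes(ko, ag, ba)
    sp = it.binding_site_peaks(ps, study.chip_agonist, ann, "WT", "KO")
    return ps, ann, ko, ba, modes, sp


class TestSegmentAndPromoterReports:
    def test_segment_reports_complete_and_consistent(self, pipeline,
                                                     study_occurrence):
        *_, modes, sp = pipeline
        reports = it.segment_summary(modes, study_occurrence, sp)
        assert set(reports) == set(it.DIRECT_MODES)
        for rep in reports.values():
            assert rep["n_genes"] == len(rep["genes"])
            if "top_motifs" in rep:
                ps_ = [m["p"] for m in rep["top_motifs"]]
                assert ps_ == sorted(ps_)
                assert 0 <= rep["promoter_fraction"] <= 1

    def test_empty_segment_no_crash(self, study_occurrence):
        table = pd.DataFrame({"mode": ["none"], "binding_evidence": ["none"],
                              "ko_class": ["unchanged"],
                              "agonist_class": ["unchanged"]},
                             index=pd.Index(["g1"], name="gene_id"))
        sp = pd.DataFrame({"diff": [], "nearest_gene": [], "feature_class": []})
        reports = it.segment_summary(it.ModeAssignment(table),
                                     study_occurrence, sp)
        for rep in reports.values():
            assert rep["n_genes"] == 0 and "note" in rep

    def test_promoter_gain_report(self, pipeline, study, study_occurrence):
        ps, ann, ko, ba, modes, sp = pipeline
        ranked = pk.rank_peaks(ps, "WT", "KO")
        rep = it.promoter_gain_analysis(ranked, ann, study_occurrence, ba,
                                        "NFY", n_top=200, ko_classes=ko)
        assert rep["n_gain_peaks_with_motif"] > 0
        total = (rep["fraction_basal_bound"] + rep["fraction_agonist_only"] +
                 rep["fraction_unbound"])
        assert total == pytest.approx(1.0)
        # NFY-gain genes are dominated by bound promoters in the generator
        genome_wide_bound = (ba.counts["agonist"] > 0).mean()
        assert rep["fraction_basal_bound"] + rep["fraction_agonist_only"] > \
            genome_wide_bound

    def test_promoter_gain_unknown_motif_rejected(self, pipeline,
                                                  study_occurrence):
        ps, ann, ko, ba, modes, sp = pipeline
        ranked = pk.rank_peaks(ps, "WT", "KO")
        with pytest.raises(it.DataError):
            it.promoter_gain_analysis(ranked, ann, study_occurrence, ba,
                                      "NOPE", n_top=10)


class TestTFExpressionAndScaling:
    def test_lookup_and_untested(self):
        de = de_table([("tf1", 0.1, 0.5), ("tf2", -2.0, 0.001)])
        rep = it.tf_expression_report(de, ["tf1", "tf2", "tf3"])
        assert rep.loc["tf1", "class"] == "unchanged"
        assert rep.loc["tf2", "class"] == "down"
        assert rep.loc["tf3", "class"] == "untested"

    def test_unit_variance_scaling(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0], [10.0, 10.0, 10.0]],
                         index=["a", "b"])
        out = it.unit_variance_scale(m)
        np.testing.assert_allclose(out.loc["a"].mean(), 0, atol=1e-12)
        np.testing.assert_allclose(out.loc["a"].std(ddof=1), 1, atol=1e-12)
        np.testing.assert_allclose(out.loc["b"], 0)  # constant row untouched
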