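"""PWM scanning, hypergeometric bin enrichment, similarity merging,
co-occurrence — each against an independent oracle where one exists."""

import itertools
import math

import numpy as np
import pytest

from atacmodes import motifs as mo
from atacmodes import peak_stats as pk
from atacmodes.io_core import DataError, FormatError
from atacmodes.simulate import default_pwm_library

RC = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(RC)[::-1]


def brute_force_scan(seq, pwm, fraction):
    """Per-offset, per-strand log-odds recomputation in plain Python."""
    lo = pwm.log_odds()
    threshold = fraction * pwm.max_score()
    hits = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else None
        for i in range(len(seq) - pwm.length + 1):
            window = seq[i:i + pwm.length]
            if strand == "-":
                window = revcomp(window)
            if "N" in window:
                continue
            score = sum(lo["ACGT".index(b), j] for j, b in enumerate(window))
            if score >= threshold - 1e-12:
                hits.append((i, strand, score))
    return sorted(hits, key=lambda h: (h[0], h[1]))


@pytest.fixture(scope="module")
def library():
    return default_pwm_library()


class TestPwmIO:
    def test_counts_to_probabilities(self):
        counts = np.array([[8, 0, 0], [0, 8, 0], [0, 0, 8], [0, 0, 0]])
        pwm = mo.counts_to_pwm("m", counts)
        np.testing.assert_allclose(pwm.matrix.sum(axis=0), 1.0)
        assert (pwm.matrix > 0).all()
        assert pwm.consensus() == "ACG"

    def test_bad_column_rejected(self):
        with pytest.raises(FormatError):
            mo.counts_to_pwm("m", np.array([[1.0], [1.0], [1.0], [-3.0]]),
                             pseudocount=0.0)

    def test_jaspar_roundtrip(self, tmp_path, library):
        path = tmp_path / "lib.jaspar"
        mo.write_pwm_library(library, path)
        fams = {p.motif_id: p.family for p in library}
        back = mo.read_pwm_library(path, family_map=fams, pseudocount=0.0)
        assert back.motif_ids == library.motif_ids
        for a, b in zip(library, back):
            # writer scales to 2-decimal counts; reader renormalizes
            np.testing.assert_allclose(a.matrix, b.matrix, atol=5e-3)
            assert a.family == b.family


class TestScan:
    def test_consensus_scores_maximum_at_origin(self, library):
        pwm = library["FOXA"]
        hits = mo.scan(pwm.consensus(), pwm, 0.99)
        assert hits and hits[0].position == 0
        assert hits[0].score == pytest.approx(pwm.max_score())

    def test_reverse_complement_hits_minus_strand(self, library):
        pwm = library["FOXA"]
        hits = mo.scan(revcomp(pwm.consensus()), pwm, 0.99)
        assert any(h.strand == "-" and
                   h.score == pytest.approx(pwm.max_score()) for h in hits)

    def test_sequence_shorter_than_motif_is_empty(self, library):
        assert mo.scan("ACG", library["CTCF"], 0.5) == []

    def test_n_positions_never_hit(self, library):
        pwm = library["NFY"]
        seq = pwm.consensus()[:4] + "N" + pwm.consensus()[5:]
        assert mo.scan(seq, pwm, 0.1) == []

    def test_brute_force_oracle_random_sequences(self, library):
        rng = np.random.default_rng(12)
        pwm = library["NFY"]
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=1000))
            got = [(h.position, h.strand, h.score)
                   for h in mo.scan(seq, pwm, 0.8)]
            expected = brute_force_scan(seq, pwm, 0.8)
            assert [(p, s) for p, s, _ in got] == [(p, s) for p, s, _ in expected]
            for (gp, gs, gscore), (_, _, escore) in zip(got, expected):
                assert gscore == pytest.approx(escore)


class TestOccurrenceMatrix:
    def test_planted_consensus_marks_presence(self, library):
        pwm = library["DR1"]
        seqs = {"pk1": "ACGT" * 10 + pwm.consensus() + "TTTT" * 5,
                "pk2": "ACGT" * 20}
        occ = mo.occurrence_matrix(seqs, library, 0.9)
        assert occ.presence.loc["pk1", "DR1"]

    def test_row_col_sums_match_hit_tallies(self, study, study_occurrence):
        occ = study_occurrence
        for pid in occ.peak_ids[:50]:
            assert occ.presence.loc[pid].sum() == \
                sum(1 for (p, _m) in occ.hits if p == pid)

    def test_missing_sequence_listed(self, library):
        with pytest.raises(DataError, match="pkX"):
            mo.occurrence_matrix({"pk1": "ACGTACGT"}, library,
                                 0.8, required_ids=["pk1", "pkX"])

    def test_strand_symmetry_of_presence(self, library):
        rng = np.random.default_rng(4)
        seqs = {f"p{i}": "".join(rng.choice(list("ACGT"), size=300))
                for i in range(40)}
        fwd = mo.occurrence_matrix(seqs, library, 0.8)
        rc = mo.occurrence_matrix({k: revcomp(v) for k, v in seqs.items()},
                                  library, 0.8)
        assert fwd.presence.equals(rc.presence)

    def test_false_positive_rate_near_analytic_tail(self, library):
        """On pure background the per-offset hit probability implied by the
        observed rate stays within 2x of the exact enumeration of the score
        distribution (independent-offset approximation)."""
        pwm = library["FOXA"]
        rng = np.random.default_rng(6)
        n_offsets, hits = 0, 0
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=10_000))
            found = mo.scan(seq, pwm, 0.95)
            hits += len(found)
            n_offsets += 2 * (len(seq) - pwm.length + 1)
        lo = pwm.log_odds()
        threshold = 0.95 * pwm.max_score()
        # exact tail mass by dynamic programming over columns
        probs = {0.0: 1.0}
        for j in range(pwm.length):
            nxt = {}
            for sc, pr in probs.items():
                for b in range(4):
                    key = round(sc + lo[b, j], 6)
                    nxt[key] = nxt.get(key, 0.0) + pr * 0.25
            probs = nxt
        tail = sum(pr for sc, pr in probs.items() if sc >= threshold - 1e-9)
        observed = hits / n_offsets
        assert observed <= 2 * tail + 3 / n_offsets
        if tail > 1e-5:
            assert observed >= tail / 2 - 3 / n_offsets


class TestBinEnrichment:
    def test_exhaustive_enumeration_small_case(self):
        """N=10 peaks, K=4 carriers, one bin of 5 holding k=4: every C(10,5)
        draw is enumerated and the upper-tail mass equals 6/252."""
        p_closed = mo.hypergeom_upper_p(10, 4, 5, 4)
        count = 0
        for draw in itertools.combinations(range(10), 5):
            k = sum(1 for i in draw if i < 4)
            if k >= 4:
                count += 1
        assert p_closed == pytest.approx(count / math.comb(10, 5))
        assert p_closed == pytest.approx(6 / 252)

    def test_background_frequency_gives_no_enrichment(self):
        rng = np.random.default_rng(0)
        import pandas as pd
        n = 400
        pres = pd.DataFrame({"m": rng.random(n) < 0.3},
                            index=[f"p{i}" for i in range(n)])
        occ = mo.OccurrenceMatrix(pres, {})
        from conftest import make_peakset
        ps = make_peakset(np.ones((n, 4), dtype=int))
        ps.peak_ids[:] = list(pres.index)
        ranked = pk.rank_peaks(ps, "WT", "KO")
        bins = pk.bin_peaks(ranked, 100)
        enr = mo.bin_enrichment(occ, bins)
        assert enr.neglogp.to_numpy().max() < 2.5

    def test_permutation_null_agreement(self):
        """The closed-form hypergeometric p matches an explicit shuffle of
        bin labels within Monte-Carlo error."""
        rng = np.random.default_rng(8)
        N, n_bin = 120, 30
        labels = np.zeros(N, dtype=bool)
        labels[:35] = True
        rng.shuffle(labels)
        k_obs = labels[:n_bin].sum()
        p_closed = mo.hypergeom_upper_p(N, int(labels.sum()), n_bin, int(k_obs))
        n_perm = 4000
        perm_k = np.array([rng.permutation(labels)[:n_bin].sum()
                           for _ in range(n_perm)])
        p_perm = (perm_k >= k_obs).mean()
        se = math.sqrt(p_closed * (1 - p_closed) / n_perm)
        assert abs(p_perm - p_closed) < 3 * se + 1e-12

    def test_planted_landscape_trends_across_bins(self, study, study_occurrence):
        """Rank-dependent planting produces a monotone-trending -log10 p
        profile along the bin axis."""
        from scipy.stats import spearmanr
        ps = pk.filter_low_count(study.peakset, 10)
        ranked = pk.rank_peaks(ps, "WT", "KO")
        bins = pk.bin_peaks(ranked, 100)
        occ = study_occurrence
        enr = mo.bin_enrichment(occ, bins)
        rho_dr1 = spearmanr(enr.neglogp.loc["DR1"],
                            np.arange(bins.n_bins)).statistic
        rho_nfy = spearmanr(enr.neglogp.loc["NFY"],
                            np.arange(bins.n_bins)).statistic
        assert rho_dr1 < -0.6   # loss-associated: maxima at loss end
        assert rho_nfy > 0.6    # gain-associated: maxima at gain end


class TestSimilarityAndMerge:
    def test_identical_pwms_similarity_one(self, library):
        assert mo.pwm_similarity(library["NFY"], library["NFY"]) == \
            pytest.approx(1.0)

    def test_reverse_complement_invariance(self, library):
        pwm = library["FOXA"]
        assert mo.pwm_similarity(pwm, pwm.reverse_complement()) == \
            pytest.approx(1.0)

    def test_symmetry_and_brute_force_offsets(self):
        rng = np.random.default_rng(3)

        def random_pwm(name, L):
            m = rng.dirichlet(np.ones(4) * 0.6, size=L).T
            return mo.PWM(name, m, "X")

        a, b = random_pwm("a", 8), random_pwm("b", 8)
        got = mo.pwm_similarity(a, b)
        assert got == pytest.approx(mo.pwm_similarity(b, a))

        def brute(ma, mb):
            best = -np.inf
            La, Lb = ma.shape[1], mb.shape[1]
            for s in range(-Lb + 4, La - 3):
                lo, hi = max(0, s), min(La, s + Lb)
                if hi - lo < 4:
                    continue
                x = ma[:, lo:hi].ravel()
                y = mb[:, lo - s:hi - s].ravel()
                best = max(best, float(np.corrcoef(x, y)[0, 1]))
            return best

        expected = max(brute(a.matrix, b.matrix),
                       brute(a.matrix, b.reverse_complement().matrix))
        assert got == pytest.approx(expected)

    def test_flat_motif_removed(self, library):
        import pandas as pd
        neglogp = pd.DataFrame(
            {"bin_0": [5.0, 0.1], "bin_1": [1.0, 0.1], "bin_2": [0.2, 0.1]},
            index=["DR1", "CEBP"])
        em = mo.EnrichmentMatrix(neglogp, {})
        merged = mo.filter_and_merge(em, library, 0.9)
        assert list(merged.neglogp.index) == ["DR1"]

    def test_identical_pwms_merge_to_elementwise_max(self):
        import pandas as pd
        m = np.full((4, 8), 0.1)
        m[0] = 0.7
        twins = mo.PWMLibrary([mo.PWM("t1", m, "FAM"), mo.PWM("t2", m, "FAM")])
        neglogp = pd.DataFrame({"bin_0": [6.0, 2.0], "bin_1": [1.0, 7.0]},
                               index=["t1", "t2"])
        merged = mo.filter_and_merge(mo.EnrichmentMatrix(neglogp, {}), twins, 0.9)
        assert list(merged.neglogp.index) == ["t1|t2"]
        assert merged.neglogp.loc["t1|t2"].tolist() == [6.0, 7.0]
        assert merged.merged_members["t1|t2"] == ["t1", "t2"]

    def test_single_linkage_transitive_closure(self):
        """A~B and B~C above threshold but A~C below: one family row."""
        import pandas as pd
        rng = np.random.default_rng(1)
        base = rng.dirichlet(np.ones(4), size=10).T

        def perturb(m, eps, seed):
            r = np.random.default_rng(seed)
            out = np.abs(m + r.normal(0, eps, size=m.shape))
            return out / out.sum(axis=0)

        A = mo.PWM("A", perturb(base, 0.02, 2), "FAM")
        B = mo.PWM("B", base, "FAM")
        C = mo.PWM("C", perturb(base, 0.02, 5), "FAM")
        sim_ab = mo.pwm_similarity(A, B)
        sim_bc = mo.pwm_similarity(B, C)
        sim_ac = mo.pwm_similarity(A, C)
        thr = sorted([sim_ab, sim_bc, sim_ac])[0] + 1e-6  # below ab and bc
        assert sim_ac < min(sim_ab, sim_bc)
        lib = mo.PWMLibrary([A, B, C])
        neglogp = pd.DataFrame({"bin_0": [5.0, 5.0, 5.0],
                                "bin_1": [0.5, 0.5, 0.5]},
                               index=["A", "B", "C"])
        merged = mo.filter_and_merge(mo.EnrichmentMatrix(neglogp, {}), lib,
                                     similarity_threshold=thr)
        assert list(merged.neglogp.index) == ["A|B|C"]


class TestSubsetEnrichment:
    def test_subset_equal_background_is_null(self, study_occurrence):
        ids = study_occurrence.peak_ids[:100]
        out = mo.subset_enrichment(study_occurrence, ids, ids)
        present = out["K_background"] > 0
        assert np.allclose(out.loc[present, "fold"], 1.0)
        assert (out.loc[present, "p"] >= 0.5).all()

    def test_small_case_matches_enumeration(self):
        import pandas as pd
        pres = pd.DataFrame({"m": [True] * 4 + [False] * 6},
                            index=[f"p{i}" for i in range(10)])
        occ = mo.OccurrenceMatrix(pres, {})
        out = mo.subset_enrichment(occ, [f"p{i}" for i in range(4)] + ["p9"],
                                   list(pres.index))
        assert out.loc["m", "p"] == pytest.approx(6 / 252)
        assert out.loc["m", "fold"] == pytest.approx((4 / 5) / (4 / 10))

    def test_empty_subset_rejected(self, study_occurrence):
        with pytest.raises(DataError):
            mo.subset_enrichment(study_occurrence, [],
                                 study_occurrence.peak_ids)


class TestCooccurrence:
    def test_disjoint_and_nested_families(self):
        import pandas as pd
        pres = pd.DataFrame({"a": [True, True, False, False],
                             "b": [False, False, True, True],
                             "c": [True, True, False, False]},
                            index=["p0", "p1", "p2", "p3"])
        occ = mo.OccurrenceMatrix(pres, {})
        counts, jac, _ = mo.motif_cooccurrence(
            occ, list(pres.index), {"A": ["a"], "B": ["b"], "C": ["c"]})
        assert counts.loc["A", "B"] == 0
        assert jac.loc["A", "C"] == pytest.approx(1.0)

    def test_matches_brute_force_sets(self, study_occurrence):
        occ = study_occurrence
        subset = occ.peak_ids[:200]
        fams = {"NR": ["DR4_A", "DR4_B", "DR1"], "CCAAT": ["NFY"],
                "FOX": ["FOXA"]}
        counts, jac, fam_pres = mo.motif_cooccurrence(occ, subset, fams)
        sets = {f: {p for p in subset
                    if occ.presence.loc[p, members].any()}
                for f, members in fams.items()}
        for f in fams:
            for g in fams:
                assert counts.loc[f, g] == len(sets[f] & sets[g])
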