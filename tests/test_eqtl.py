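import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rimap.eqtl import (
    EqtlScan,
    classify_cis_trans,
    credible_interval,
    fdr_adjust,
    lod_scores,
    lod_to_pvalue,
    peak_hit,
    permutation_pvalue,
    resolve_multilocation,
)
from rimap.expression import ExpressionSet
from rimap.genotypes import SdpPanel

from conftest import make_panel


class TestLodScores:
    def test_hand_arithmetic_oracle(self, toy_panel):
        # RSS0 about the grand mean of [1,2,3,4] is 5; group means 1.5/3.5 give RSS1=1
        prof = lod_scores(np.array([1.0, 2, 3, 4]), toy_panel)
        assert prof.lod[0] == pytest.approx(2 * np.log10(5.0), abs=1e-10)

    def test_equal_group_means_give_zero(self, toy_panel):
        prof = lod_scores(np.array([1.0, 2, 1, 2]), toy_panel)
        assert prof.lod[0] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_separation_capped(self, toy_panel, caplog):
        with caplog.at_level("WARNING"):
            prof = lod_scores(np.array([0.0, 0, 1, 1]), toy_panel)
        assert prof.lod[0] == 50.0
        assert "capped" in caplog.text

    def test_constant_trait_rejected(self, toy_panel):
        with pytest.raises(ValueError, match="constant trait"):
            lod_scores(np.array([1.0, 1, 1, 1]), toy_panel)

    def test_small_genotype_group_skipped(self):
        panel = SdpPanel(strains=list("abcd"), sdp_ids=["s0"], chrom=["1"],
                         pos=[10], patterns=np.array([[0, 1, 1, 1]]))
        prof = lod_scores(np.array([1.0, 2, 3, 4]), panel)
        assert np.isnan(prof.lod[0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    def test_affine_invariance(self, toy_panel, a, b):
        y = np.array([1.0, 2, 3, 5])
        base = lod_scores(y, toy_panel).lod[0]
        scaled = lod_scores(a * y + b, toy_panel).lod[0]
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_three_strain_two_sdp_brute_force(self):
        # direct RSS arithmetic on an asymmetric toy (groups of 2 and 2)
        panel = SdpPanel(strains=list("abcd"), sdp_ids=["s0", "s1"],
                         chrom=["1", "1"], pos=[10, 20],
                         patterns=np.array([[0, 0, 1, 1], [0, 1, 0, 1]]))
        y = np.array([2.0, 4, 5, 9])
        prof = lod_scores(y, panel)
        for k, g in enumerate(panel.patterns):
            rss0 = ((y - y.mean()) ** 2).sum()
            rss1 = sum(((y[g == v] - y[g == v].mean()) ** 2).sum() for v in (0, 1))
            assert prof.lod[k] == pytest.approx(2 * np.log10(rss0 / rss1))


class TestPeak:
    def test_tie_breaks_to_first_in_genome_order(self):
        panel = make_panel({"1": 3}, n_strains=8)
        prof = lod_scores(np.zeros(8) + np.arange(8) * 0.0 + [1, 2, 3, 4, 1, 2, 3, 4],
                          panel)
        prof.lod = np.array([1.0, 7.0, 7.0])
        idx, lod = peak_hit(prof, panel)
        assert (idx, lod) == (1, 7.0)

    def test_single_sdp_is_the_peak(self, toy_panel):
        prof = lod_scores(np.array([1.0, 2, 3, 4]), toy_panel)
        assert peak_hit(prof, toy_panel)[0] == 0


class TestPermutation:
    def test_p_floor_when_no_null_exceeds(self, small_panel):
        rng = np.random.default_rng(0)
        # plant an overwhelming effect so no permutation can reach it
        y = 10.0 * small_panel.patterns[5] + rng.normal(0, 0.1, 59)
        res = permutation_pvalue(y, small_panel, B=1000, seed=1, trait="t")
        assert res.b == 0
        assert res.p == pytest.approx(1 / 1001)
        assert f"{res.p:.4f}" == "0.0010"

    def test_pure_noise_p_not_extreme(self, small_panel):
        y = np.random.default_rng(7).normal(size=59)
        res = permutation_pvalue(y, small_panel, B=200, seed=1, trait="null")
        assert res.p > 5 / 201

    def test_p_is_one_when_observed_never_beats_null(self):
        # a 2-SDP panel where y is constant within genotype groups of another SDP
        panel = make_panel({"1": 2}, n_strains=6, seed=3)
        y = np.arange(6, dtype=float)
        res = permutation_pvalue(y, panel, B=100, seed=0, trait="x")
        assert 1 / 101 <= res.p <= 1.0

    def test_deterministic_under_trait_and_seed(self, small_panel):
        y = np.random.default_rng(8).normal(size=59)
        a = permutation_pvalue(y, small_panel, B=100, seed=4, trait="tr")
        b = permutation_pvalue(y, small_panel, B=100, seed=4, trait="tr")
        c = permutation_pvalue(y, small_panel, B=100, seed=4, trait="other")
        assert (a.p, a.b) == (b.p, b.b)
        assert a.b != c.b or a.p == c.p  # different trait stream may differ


class TestFdr:
    def test_single_pvalue_unchanged(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.001, 1, 50)
        q = fdr_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_bh_rejects_superset_of_bonferroni(self):
        rng = np.random.default_rng(1)
        p = np.concatenate([rng.uniform(1e-6, 1e-3, 5), rng.uniform(0.2, 1, 45)])
        t = 0.05
        bonf = p < t / len(p)
        bh = fdr_adjust(p) <= t
        assert (bh | ~bonf).all()

    def test_external_family_size(self):
        # 35 tests at 0.001 and 3 at 0.002 inside a family of 881
        p = np.array([0.001] * 35 + [0.002] * 3)
        q = fdr_adjust(p, m_total=881)
        assert q[0] == pytest.approx(0.001 * 881 / 35)
        assert q[-1] == pytest.approx(0.002 * 881 / 38)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.0, 0.5])


class TestCredibleInterval:
    def test_dominant_peak_expands_to_member_span(self):
        panel = make_panel({"1": 3}, n_strains=8, seed=5)
        panel.member_pos[1] = np.array([1_500_000, 2_500_000])
        prof = lod_scores(np.random.default_rng(0).normal(size=8), panel)
        prof.lod = np.array([0.0, 10.0, 0.0])
        lo, hi = credible_interval(prof, panel)
        assert (lo, hi) == (1_500_000, 2_500_000)

    def test_flat_profile_keeps_all_sdps(self):
        panel = make_panel({"1": 3}, n_strains=8, seed=6)
        prof = lod_scores(np.random.default_rng(0).normal(size=8), panel)
        prof.lod = np.array([1.0, 2.0, 1.0])
        # masses 1/12, 10/12, 1/12: need all three for 95%
        lo, hi = credible_interval(prof, panel)
        assert (lo, hi) == (int(panel.pos.min()), int(panel.pos.max()))

    def test_interval_contains_peak(self, small_panel):
        y = 2.0 * small_panel.patterns[20] + np.random.default_rng(3).normal(0, 1, 59)
        prof = lod_scores(y, small_panel)
        idx, _ = peak_hit(prof, small_panel)
        lo, hi = credible_interval(prof, small_panel)
        assert lo <= small_panel.pos[idx] <= hi


class TestCisTrans:
    @pytest.mark.parametrize(
        "peak,feat,expected",
        [
            (("1", 154_300_000), ("1", 153_899_989), "cis"),
            (("11", 74_300_000), ("11", 79_712_009), "trans"),
            (("1", 100), ("2", 100), "trans"),
            (("1", 5_000_000), ("1", 10_000_000), "cis"),  # exactly at the boundary
        ],
    )
    def test_five_mb_rule(self, peak, feat, expected):
        assert classify_cis_trans(peak[0], peak[1], feat[0], feat[1]) == expected

    def test_missing_location_is_unknown(self):
        assert classify_cis_trans("1", 100, None, None) == "unknown"


class TestResolveMultilocation:
    def test_single_candidate_returned(self, small_panel):
        prof = lod_scores(np.random.default_rng(0).normal(size=59), small_panel)
        assert resolve_multilocation([("1", 5)], prof, small_panel) == ("1", 5)

    def test_rule1_strongest_local_window_wins(self):
        panel = make_panel({"1": 40}, n_strains=20, seed=7, spacing=1_000_000)
        prof = lod_scores(np.random.default_rng(1).normal(size=20), panel)
        prof.lod = np.zeros(40)
        prof.lod[4] = 8.0  # inside the first candidate's window only
        cands = [("1", 5_000_000), ("1", 35_000_000)]
        assert resolve_multilocation(cands, prof, panel) == cands[0]

    def test_rule2_shared_window_nearest_to_strongest(self):
        panel = make_panel({"1": 10}, n_strains=20, seed=8, spacing=1_000_000)
        prof = lod_scores(np.random.default_rng(1).normal(size=20), panel)
        prof.lod = np.zeros(10)
        prof.lod[2] = 8.0  # position 3 Mb; both candidates within 5 Mb
        cands = [("1", 3_200_000), ("1", 4_200_000)]
        assert resolve_multilocation(cands, prof, panel) == cands[0]

    def test_rule3_no_window_hits_uses_chromosome_strongest(self):
        panel = make_panel({"1": 3}, n_strains=20, seed=9, spacing=1_000_000)
        prof = lod_scores(np.random.default_rng(1).normal(size=20), panel)
        prof.lod = np.array([1.0, 5.0, 1.0])  # strongest at 2 Mb
        cands = [("1", 50_000_000), ("1", 20_000_000)]
        assert resolve_multilocation(cands, prof, panel) == cands[1]


class TestEqtlScan:
    def test_one_hit_row_per_trait(self, small_panel):
        rng = np.random.default_rng(0)
        means = pd.DataFrame(rng.normal(size=(5, 59)),
                             index=[f"t{i}" for i in range(5)],
                             columns=small_panel.strains)
        res = EqtlScan(ExpressionSet(means), small_panel).fit(n_perm=50, seed=0)
        assert len(res.hits) == 5
        assert set(res.hits.columns) >= {"sdp", "lod", "perm_p", "q", "cis_trans"}

    def test_strain_mismatch_reports_offenders(self, small_panel):
        means = pd.DataFrame(np.zeros((1, 3)), index=["t"], columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="LXS001"):
            EqtlScan(ExpressionSet(means), small_panel)

    def test_raw_p_matches_f_distribution_mapping(self, small_panel):
        y = 1.5 * small_panel.patterns[7] + np.random.default_rng(5).normal(0, 1, 59)
        res = EqtlScan(
            ExpressionSet(pd.DataFrame([y], index=["t"], columns=small_panel.strains)),
            small_panel,
        ).fit(n_perm=20, seed=0)
        lod = res.hits.loc["t", "lod"]
        assert res.hits.loc["t", "raw_p"] == pytest.approx(lod_to_pvalue(lod, 59))

    def test_summary_mentions_counts(self, small_panel):
        means = pd.DataFrame(np.random.default_rng(1).normal(size=(2, 59)),
                             index=["a", "b"], columns=small_panel.strains)
        res = EqtlScan(ExpressionSet(means), small_panel).fit(n_perm=20, seed=0)
        assert "traits mapped:        2" in res.summary()
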