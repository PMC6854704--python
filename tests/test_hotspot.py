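import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rimap.eqtl import EqtlScan
from rimap.expression import ExpressionSet
from rimap.hotspot import detect_hotspots, make_bins, poisson_threshold
from rimap.simulate import HotspotSpec, SimConfig, plant_structures, simulate_genotypes

from conftest import make_panel


class TestMakeBins:
    def test_remainder_goes_to_last_bin(self):
        panel = make_panel({"1": 10}, n_strains=10, seed=0)
        grid = make_bins(panel, width=4)
        assert [len(b.sdp_indices) for b in grid.bins] == [4, 4, 2]

    def test_width_one_gives_one_bin_per_sdp(self):
        panel = make_panel({"1": 7}, n_strains=10, seed=1)
        assert make_bins(panel, width=1).n_bins == 7

    def test_1416_sdps_make_354_bins(self):
        # per-chromosome counts divisible by 4 (19 x 72 + 48 = 1416)
        counts = {str(c): 72 for c in range(1, 20)}
        counts["X"] = 48
        panel = make_panel(counts, n_strains=10, seed=2)
        assert panel.n_sdps == 1416
        for cross in (False, True):
            assert make_bins(panel, width=4, cross_chromosomes=cross).n_bins == 354

    def test_bins_partition_all_sdps(self):
        panel = make_panel({"1": 13, "2": 6}, n_strains=10, seed=3)
        grid = make_bins(panel, width=4)
        seen = [i for b in grid.bins for i in b.sdp_indices]
        assert sorted(seen) == list(range(panel.n_sdps))

    def test_bins_do_not_straddle_chromosomes_by_default(self):
        panel = make_panel({"1": 5, "2": 5}, n_strains=10, seed=4)
        grid = make_bins(panel, width=4)
        assert all(len(b.chromosomes) == 1 for b in grid.bins)
        assert [len(b.sdp_indices) for b in grid.bins] == [4, 1, 4, 1]


class TestPoissonThreshold:
    def test_study_scale_arithmetic(self):
        # lambda 0.56 over 354 bins at alpha 0.05 -> at least 6 eQTL
        assert poisson_threshold(int(round(0.56 * 354)), 354, alpha=0.05) == 6

    def test_unit_mean_oracle(self):
        # partial-sum oracle: smallest k with P(X>=k; 1) < 0.05/100
        lam, cut = 1.0, 0.05 / 100
        k_expected = 1
        while stats.poisson.sf(k_expected - 1, lam) >= cut:
            k_expected += 1
        assert k_expected == 7
        assert poisson_threshold(100, 100, alpha=0.05) == 7

    def test_trivial_cut_gives_one(self):
        assert poisson_threshold(10, 1, alpha=1.0) == 1

    def test_zero_eqtl_gives_one(self):
        assert poisson_threshold(0, 50) == 1


def _hits_at(panel, sdp_indices, raw_p=1e-12, prefix="t"):
    return pd.DataFrame(
        {
            "sdp": [panel.sdp_ids[i] for i in sdp_indices],
            "raw_p": [raw_p] * len(sdp_indices),
        },
        index=[f"{prefix}{k}" for k in range(len(sdp_indices))],
    )


class TestDetectHotspots:
    def test_counts_conserved_across_bins(self):
        panel = make_panel({"1": 20}, n_strains=10, seed=5)
        grid = make_bins(panel, width=4)
        rng = np.random.default_rng(0)
        hits = _hits_at(panel, rng.integers(0, 20, size=15))
        _, detail = detect_hotspots(hits, grid, panel, n_traits=15)
        assert detail["n_eligible"] == 15

    def test_adjacent_significant_bins_merge(self):
        panel = make_panel({"1": 40}, n_strains=10, seed=6)
        grid = make_bins(panel, width=4)
        # lambda = 12/10 = 1.2 -> minimum count 6; stack 6 peaks into each of
        # the adjacent bins 1 and 2
        hits = _hits_at(panel, [4] * 6 + [8] * 6)
        hs, detail = detect_hotspots(hits, grid, panel, n_traits=12)
        assert detail["min_count"] <= 6
        assert len(hs) == 1
        assert hs[0].bin_indices == [1, 2]
        assert hs[0].n_eqtl == 12
        assert hs[0].start_bp == panel.pos[4] and hs[0].end_bp == panel.pos[11]

    def test_bins_on_different_chromosomes_not_merged(self):
        panel = make_panel({"1": 40, "2": 40}, n_strains=10, seed=7)
        grid = make_bins(panel, width=4)
        # last bin of chr1 (index 9) and first bin of chr2 (index 10) are
        # consecutive in genome order but must stay separate hotspots
        hits = _hits_at(panel, [36] * 6 + [40] * 6)
        hs, _ = detect_hotspots(hits, grid, panel, n_traits=12)
        assert len(hs) == 2

    def test_ineligible_peaks_ignored(self):
        panel = make_panel({"1": 8}, n_strains=10, seed=8)
        grid = make_bins(panel, width=4)
        hits = _hits_at(panel, [0] * 10, raw_p=0.01)
        hs, detail = detect_hotspots(hits, grid, panel, n_traits=10)
        assert detail["n_eligible"] == 0 and hs == []

    def test_study_scale_per_test_threshold(self):
        counts = {str(c): 72 for c in range(1, 20)}
        counts["X"] = 48
        panel = make_panel(counts, n_strains=10, seed=9)
        grid = make_bins(panel, width=4)
        _, detail = detect_hotspots(
            _hits_at(panel, [0]), grid, panel, n_traits=881
        )
        assert detail["per_test_threshold"] == pytest.approx(0.05 / (881 * 1416))
        assert detail["per_test_threshold"] == pytest.approx(4e-8, rel=0.01)

    def test_null_familywise_discovery_rate(self):
        """Uniformly scattered eligible peaks rarely produce any hotspot."""
        panel = make_panel({"1": 40, "2": 40}, n_strains=10, seed=10)
        grid = make_bins(panel, width=4)
        discoveries = 0
        for s in range(200):
            rng = np.random.default_rng(s)
            hits = _hits_at(panel, rng.integers(0, 80, size=20))
            hs, _ = detect_hotspots(hits, grid, panel, n_traits=20)
            discoveries += len(hs)
        se = np.sqrt(0.05 * 0.95 / 200)
        assert discoveries / 200 <= 0.05 + 3 * se


@pytest.fixture(scope="module")
def planted():
    cfg = SimConfig(
        n_strains=59, n_reps=3, n_chromosomes=4, snps_per_chromosome=100,
        ld_persistence=0.85, n_mirna=30, n_mrna=1, icc_target=0.3, seed=77,
    )
    panel = simulate_genotypes(cfg)
    target = panel.sdp_ids[12]
    cfg = SimConfig(
        n_strains=59, n_reps=3, n_chromosomes=4, snps_per_chromosome=100,
        ld_persistence=0.85, n_mirna=30, n_mrna=1, icc_target=0.3, seed=77,
        hotspot_spec=HotspotSpec(
            target, tuple(f"miR-{i:04d}" for i in range(8)), beta=3.0),
    )
    sim = plant_structures(panel, cfg)
    scan = EqtlScan(sim.mirna, panel).fit(n_perm=50, seed=1)
    return panel, target, scan


class TestPlantedRecovery:

    def test_planted_hotspot_flagged_in_its_bin(self, planted):
        panel, target, scan = planted
        grid = make_bins(panel, width=4)
        hs, _ = detect_hotspots(scan.hits, grid, panel, n_traits=30)
        assert len(hs) == 1
        covering = [b for h in hs for b in h.bin_indices]
        assert grid.bin_of()[panel.index_of(target)] in covering
        assert hs[0].n_eqtl >= 8

    def test_detection_stable_across_bin_widths(self, planted):
        panel, target, scan = planted
        for width in (3, 4, 5):
            grid = make_bins(panel, width=width)
            hs, _ = detect_hotspots(scan.hits, grid, panel, n_traits=30)
            assert len(hs) == 1
            assert set(hs[0].traits) == {f"miR-{i:04d}" for i in range(8)}
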