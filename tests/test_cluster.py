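import numpy as np
import pytest

from microstatekit import (
    ClusterConfig,
    NoPeakError,
    TopographyBank,
    ValidationError,
    assign_maps,
    gev,
    klgev_criterion,
    make_templates,
    modified_kmeans,
    scan_and_select,
    select_k_optimal,
    spatial_correlation,
)

from oracles import assign_exhaustive, best_gev_over_labelings, gev_direct


def _bank(maps: np.ndarray) -> TopographyBank:
    maps = maps - maps.mean(axis=1, keepdims=True)
    gfp = np.sqrt(np.mean(maps**2, axis=1))
    return TopographyBank(maps, [("r", i) for i in range(maps.shape[0])], gfp)


class TestSpatialCorrelation:
    def test_identity_sign_flip_orthogonal(self):
        u = np.array([1.0, -1.0, 0.5, -0.5])
        assert spatial_correlation(u, u) == pytest.approx(1.0)
        assert spatial_correlation(u, -u) == pytest.approx(-1.0)
        assert spatial_correlation([1, -1, 0, 0], [0, 0, 1, -1]) == pytest.approx(0.0)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValidationError):
            spatial_correlation([0, 0, 0], [1, 0, -1])


class TestAssignMaps:
    def test_template_and_its_negation_share_a_label(self, rng):
        tpl = make_templates(4, 16, seed=0).templates
        assert assign_maps(tpl[2][None, :], tpl)[0] == 3
        assert assign_maps(-tpl[2][None, :], tpl)[0] == 3

    def test_matches_exhaustive_oracle(self, rng):
        tpl = make_templates(3, 12, seed=1).templates
        maps = rng.normal(size=(10, 12))
        maps -= maps.mean(axis=1, keepdims=True)
        np.testing.assert_array_equal(
            assign_maps(maps, tpl), assign_exhaustive(maps, tpl)
        )


class TestGev:
    def test_perfect_fit_gives_one(self, rng):
        tpl = make_templates(3, 12, seed=2).templates
        labels = np.array([1, 2, 3, 1, 2])
        scale = rng.uniform(0.5, 3.0, size=5)
        maps = tpl[labels - 1] * scale[:, None]
        gfp = np.sqrt(np.mean(maps**2, axis=1))
        total, per_class = gev(maps, gfp, tpl, labels)
        assert total == pytest.approx(1.0, abs=1e-12)
        assert per_class.sum() == pytest.approx(total)

    def test_orthogonal_map_gives_zero(self):
        tpl = make_templates(2, 6, seed=3, orthogonal=True).templates
        total, _ = gev(tpl[1][None, :], np.array([1.0]), tpl, np.array([2]))
        assert total == pytest.approx(1.0)
        total, _ = gev(tpl[1][None, :], np.array([1.0]), tpl, np.array([1]))
        assert total == pytest.approx(0.0, abs=1e-12)

    def test_matches_per_sample_summation_oracle(self, rng):
        tpl = make_templates(2, 8, seed=4).templates
        maps = rng.normal(size=(20, 8))
        maps -= maps.mean(axis=1, keepdims=True)
        gfp = rng.uniform(0.5, 2.0, size=20)
        labels = assign_maps(maps, tpl)
        total, per_class = gev(maps, gfp, tpl, labels)
        exp_total, exp_class = gev_direct(maps, gfp, tpl, labels)
        assert total == pytest.approx(exp_total, abs=1e-12)
        np.testing.assert_allclose(per_class, exp_class, atol=1e-12)

    def test_all_zero_gfp_rejected(self, rng):
        tpl = make_templates(2, 8, seed=5).templates
        maps = tpl.copy()
        with pytest.raises(ValidationError):
            gev(maps, np.zeros(2), tpl, np.array([1, 2]))


class TestModifiedKmeans:
    def test_recovers_planted_orthogonal_templates(self, rng):
        tpl = make_templates(2, 16, seed=6, orthogonal=True).templates
        maps = np.vstack([np.tile(tpl[0], (10, 1)), np.tile(tpl[1], (10, 1))])
        signs = rng.choice([-1.0, 1.0], size=20)
        fit = modified_kmeans(_bank(maps * signs[:, None]), 2,
                              ClusterConfig(restarts=5, seed=0))
        match = np.abs(fit.templates @ tpl.T)
        assert match.max(axis=0).min() > 0.999
        assert fit.gev_total > 0.999

    def test_polarity_invariance_of_gev(self, rng):
        maps = rng.normal(size=(30, 12))
        signs = rng.choice([-1.0, 1.0], size=30)
        cfg = ClusterConfig(restarts=5, seed=9)
        fit = modified_kmeans(_bank(maps), 3, cfg)
        flipped = modified_kmeans(_bank(maps * signs[:, None]), 3, cfg)
        assert flipped.gev_total == pytest.approx(fit.gev_total, abs=1e-12)

    def test_beats_exhaustive_labeling_oracle_on_tiny_bank(self, rng):
        maps = rng.normal(size=(6, 5))
        bank = _bank(maps)
        fit = modified_kmeans(bank, 2, ClusterConfig(restarts=30, seed=3))
        best = best_gev_over_labelings(bank.maps, bank.gfp_at_peak, 2)
        assert fit.gev_total >= best - 1e-9

    def test_k_larger_than_bank_rejected(self, rng):
        with pytest.raises(ValidationError):
            modified_kmeans(_bank(rng.normal(size=(3, 5))), 4)


class TestKlgevCriterion:
    def test_reproduces_printed_derived_columns(self, gev_tables):
        gev_by_k, C = gev_tables["seed"]
        scan = klgev_criterion(gev_by_k, C)
        assert scan.norm_gev_by_k[10] == pytest.approx(0.7013, abs=0.0005)
        assert scan.diff_by_k[10] == pytest.approx(0.0228, abs=0.0005)
        assert scan.kl_by_k[10] == pytest.approx(1.4497, abs=0.01)

    def test_constant_gev_has_no_interior_peak(self):
        gev_by_k = {k: 0.5 for k in range(2, 13)}
        scan = klgev_criterion(gev_by_k, C=32)
        diffs = np.array([scan.diff_by_k[k] for k in range(4, 13)])
        expected = 0.5 * np.array(
            [k ** (2 / 32) - (k - 2) ** (2 / 32) for k in range(4, 13)]
        )
        np.testing.assert_allclose(diffs, expected, atol=1e-12)
        with pytest.raises(NoPeakError):
            select_k_optimal(scan)

    def test_non_contiguous_grid_rejected(self):
        with pytest.raises(ValidationError):
            klgev_criterion({2: 0.4, 3: 0.5, 5: 0.6, 6: 0.7, 7: 0.8, 8: 0.9}, 32)


class TestSelectKOptimal:
    def test_published_series_select_10_and_9(self, gev_tables):
        for name, expected in [("seed", 10), ("deap", 9)]:
            gev_by_k, C = gev_tables[name]
            scan = klgev_criterion(gev_by_k, C)
            assert select_k_optimal(scan) == expected

    def test_strictly_decreasing_kl_fails(self):
        # build a GEV curve whose interval-2 increments of K^(2/C)*GEV are
        # exp(-sqrt(K)), so KL_K = exp(sqrt(K+2) - sqrt(K)) decreases in K
        C = 32
        norm_g = {2: 0.20, 3: 0.21}
        for k in range(4, 14):
            norm_g[k] = norm_g[k - 2] + np.exp(-np.sqrt(k))
        gev_by_k = {k: v / k ** (2 / C) for k, v in norm_g.items()}
        scan = klgev_criterion(gev_by_k, C=C)
        kl = [scan.kl_by_k[k] for k in sorted(scan.kl_by_k)]
        assert all(a > b for a, b in zip(kl, kl[1:]))
        with pytest.raises(NoPeakError):
            select_k_optimal(scan)


class TestScanAndSelect:
    def test_gev_nondecreasing_and_deterministic(self, planted_bank):
        cfg = ClusterConfig(restarts=10, max_iter=50, seed=7)
        scan1, fit1 = scan_and_select(planted_bank, 1, 10, cfg)
        gevs = [scan1.gev_by_k[k] for k in scan1.k_grid]
        assert all(b >= a - 1e-6 for a, b in zip(gevs, gevs[1:]))
        scan2, fit2 = scan_and_select(planted_bank, 1, 10, cfg)
        assert scan1.gev_by_k == scan2.gev_by_k
        assert scan1.k_optimal == scan2.k_optimal
        np.testing.assert_array_equal(fit1.templates, fit2.templates)

    def test_template_sign_is_gauge_freedom(self, planted_bank):
        fit = modified_kmeans(planted_bank, 4, ClusterConfig(restarts=3, seed=2))
        flipped = fit.templates * np.array([[-1], [1], [-1], [1]])
        np.testing.assert_array_equal(
            assign_maps(planted_bank, fit.templates),
            assign_maps(planted_bank, flipped),
        )
        labels = assign_maps(planted_bank, fit.templates)
        t1, _ = gev(planted_bank.maps, planted_bank.gfp_at_peak, fit.templates,
                    labels)
        t2, _ = gev(planted_bank.maps, planted_bank.gfp_at_peak, flipped, labels)
        assert t1 == pytest.approx(t2, abs=1e-12)

    def test_narrow_span_rejected(self, planted_bank):
        with pytest.raises(ValidationError):
            scan_and_select(planted_bank, 4, 7)
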