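import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

import pdise as P
from pdise.calibration import CalibrationConfig


class TestSplits:
    def test_train_size_is_rounded_fraction(self):
        config = CalibrationConfig(n_repeats=3, train_fraction=0.75, base_seed=0)
        sites = [f"s{i}" for i in range(820)]
        for train, test in P.make_splits(sites, config):
            assert len(train) == 615 and len(test) == 205
            assert set(train) | set(test) == set(sites)
            assert not set(train) & set(test)

    def test_same_base_seed_same_plan(self):
        config = CalibrationConfig(n_repeats=5, base_seed=99)
        sites = np.arange(40)
        a = P.make_splits(sites, config)
        b = P.make_splits(sites, config)
        for (ta, _), (tb, _) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)

    def test_every_site_tested_at_least_once_in_100_repeats(self):
        # P(site never in test) = 0.75^100 ≈ 3e-13 per site
        config = CalibrationConfig(n_repeats=100, base_seed=0)
        sites = np.arange(200)
        tested = set()
        for _, test in P.make_splits(sites, config):
            tested.update(test.tolist())
        assert tested == set(range(200))


class TestOccurrenceFilter:
    def _matrix(self, presence_counts, n_sites=300):
        rng = np.random.default_rng(1)
        cols = {}
        for j, k in enumerate(presence_counts):
            col = np.zeros(n_sites)
            col[rng.choice(n_sites, size=k, replace=False)] = 1.0
            cols[f"T{j}"] = col
        m = pd.DataFrame(cols, index=[f"s{i}" for i in range(n_sites)])
        return m.div(m.sum(axis=1).replace(0, 1), axis=0)

    def test_threshold_boundary(self):
        m = self._matrix([9, 10])
        kept = P.occurrence_filter(m, m.index, min_occurrences=10)
        assert kept == ["T1"]

    def test_min_one_keeps_everything_present(self):
        m = self._matrix([1, 5, 100])
        assert P.occurrence_filter(m, m.index, 1) == ["T0", "T1", "T2"]

    def test_known_presence_counts(self):
        m = self._matrix([3, 10, 250])
        assert P.occurrence_filter(m, m.index, 10) == ["T1", "T2"]


class TestWeightedProfile:
    def test_symmetric_two_sites(self):
        opt, tol = P.weighted_profile([1, 1], [10, 100])
        assert opt == pytest.approx(1.5)
        assert tol == pytest.approx(0.5)

    def test_single_site_degenerate(self):
        opt, tol = P.weighted_profile([1], [10])
        assert opt == pytest.approx(1.0)
        assert tol == 0.0

    def test_hand_computed_weighted_sd(self):
        opt, tol = P.weighted_profile([1, 2, 1], [10, 10**1.5, 100])
        assert opt == pytest.approx(1.5)
        assert tol == pytest.approx(np.sqrt(0.125))

    def test_all_zero_weights_signal_no_occurrences(self):
        with pytest.raises(ValueError, match="no occurrences"):
            P.weighted_profile([0, 0], [10, 100])

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25)
    def test_invariant_to_weight_rescaling(self, c):
        w = np.array([0.5, 1.5, 2.0])
        tp = np.array([5.0, 30.0, 400.0])
        a = P.weighted_profile(w, tp)
        b = P.weighted_profile(c * w, tp)
        assert a[0] == pytest.approx(b[0], rel=1e-9)
        assert a[1] == pytest.approx(b[1], rel=1e-9, abs=1e-12)


class TestSensitivityClass:
    @pytest.mark.parametrize(
        "optimum,expected",
        [(1.0, 1), (1.05, 1), (1.1, 2), (1.15, 2), (1.3, 3), (1.5, 4), (1.6, 4),
         (1.7, 5), (2.5, 5), (3.0, 5)],
    )
    def test_breakpoint_intervals(self, optimum, expected):
        assert P.assign_sensitivity_class(optimum) == expected

    def test_out_of_range_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert P.assign_sensitivity_class(-0.2) == 1
        with pytest.warns(UserWarning):
            assert P.assign_sensitivity_class(3.4) == 5


class TestIndicatorClasses:
    def test_hand_interval_arithmetic(self):
        v = P.assign_indicator_classes([0.0, 0.5, 1.0, 1.5])
        np.testing.assert_array_equal(v, [1, 2, 3, 3])

    def test_single_taxon_degenerate(self):
        np.testing.assert_array_equal(P.assign_indicator_classes([0.4]), [1])

    def test_all_equal_warns_class_one(self):
        with pytest.warns(UserWarning):
            v = P.assign_indicator_classes([0.3, 0.3, 0.3])
        np.testing.assert_array_equal(v, [1, 1, 1])

    def test_uniform_spread_roughly_thirds(self, rng):
        tol = rng.uniform(0.1, 0.7, 3000)
        v = P.assign_indicator_classes(tol)
        counts = np.bincount(v)[1:4] / 3000
        assert np.all(np.abs(counts - 1 / 3) < 0.05)


class TestCrossValidatedProfiles:
    def test_single_repeat_collapses_to_weighted_profile(self, small_dataset):
        matrix, chem, _, _ = small_dataset
        config = CalibrationConfig(n_repeats=1, train_fraction=0.98,
                                   min_occurrences=5, base_seed=4)
        profiles = P.cross_validated_profiles(matrix, chem, config)
        train, _ = P.make_splits(matrix.index.to_numpy(), config)[0]
        sub = matrix.loc[train]
        tp = chem.loc[train, "tp_ugl"]
        for code in profiles.index[:5]:
            opt, tol = P.weighted_profile(sub[code], tp)
            assert profiles.loc[code, "optimum"] == pytest.approx(opt)
            assert profiles.loc[code, "tolerance"] == pytest.approx(tol)

    def test_parameter_recovery_spearman(self, small_dataset):
        """Estimated optima track the generating niche optima (ρ > 0.9)."""
        matrix, chem, niches, _ = small_dataset
        config = CalibrationConfig(n_repeats=100, base_seed=2)
        profiles = P.cross_validated_profiles(matrix, chem, config)
        joined = profiles.join(niches["true_optimum"])
        rho = spearmanr(joined["optimum"], joined["true_optimum"]).statistic
        assert rho > 0.9

    def test_constant_abundance_taxon_gets_unweighted_mean(self):
        n = 60
        index = pd.Index([f"s{i}" for i in range(n)], name="site_id")
        rng = np.random.default_rng(8)
        other = rng.uniform(0.1, 1.0, n)
        m = pd.DataFrame({"CONST": np.full(n, 0.2), "OTHER": other}, index=index)
        m = m.div(m.sum(axis=1), axis=0)
        # renormalisation breaks constancy; build weights constant after it
        m["CONST"] = 0.25
        m["OTHER"] = 0.75
        chem = pd.DataFrame({"tp_ugl": rng.uniform(5, 200, n)}, index=index)
        config = CalibrationConfig(n_repeats=1, train_fraction=0.9,
                                   min_occurrences=1, base_seed=0)
        profiles = P.cross_validated_profiles(m, chem, config)
        train, _ = P.make_splits(index.to_numpy(), config)[0]
        expected = np.log10(chem.loc[train, "tp_ugl"]).mean()
        assert profiles.loc["CONST", "optimum"] == pytest.approx(expected)

    def test_optimum_within_occupied_tp_range(self, small_dataset):
        matrix, chem, _, _ = small_dataset
        config = CalibrationConfig(n_repeats=10, base_seed=3)
        profiles = P.cross_validated_profiles(matrix, chem, config)
        log_tp = np.log10(chem["tp_ugl"])
        for code in profiles.index:
            occupied = log_tp[matrix[code] > 0]
            assert occupied.min() - 1e-9 <= profiles.loc[code, "optimum"] <= occupied.max() + 1e-9

    def test_seed_stability_of_repeat_averages(self):
        """Two independent base seeds agree to < 0.02 log10 units at 100 repeats."""
        config = P.SimulationConfig(n_sites=500, n_taxa=25, seed=23)
        chem = P.generate_gradient(config)
        niches = P.generate_niches(config)
        matrix = P.generate_community(chem, niches, config)
        a = P.cross_validated_profiles(matrix, chem, CalibrationConfig(n_repeats=100, base_seed=1))
        b = P.cross_validated_profiles(matrix, chem, CalibrationConfig(n_repeats=100, base_seed=10_001))
        shared = a.index.intersection(b.index)
        assert len(shared) >= 20
        assert np.abs(a.loc[shared, "optimum"] - b.loc[shared, "optimum"]).max() < 0.02

    def test_edge_taxa_shrink_toward_gradient_centre(self):
        """Weighted averaging biases edge optima toward the centre: sign only.

        Taxa whose niches are truncated by the sampled gradient get their
        weighted-average optimum pulled inward; a centre taxon does not.
        """
        config = P.SimulationConfig(n_sites=400, tp_mean_log10=1.4,
                                    tp_sd_log10=0.3, seed=3)
        chem = P.generate_gradient(config)
        niches = pd.DataFrame(
            {"true_optimum": [0.8, 1.4, 2.0], "true_tolerance": [0.35] * 3,
             "max_capacity": [1.0] * 3,
             "pool_label": ["low", "intermediate", "high"]},
            index=pd.Index(["LOW", "MID", "HIGH"], name="code"),
        )
        m = P.generate_community(chem, niches, config)
        est_low, _ = P.weighted_profile(m["LOW"], chem["tp_ugl"])
        est_mid, _ = P.weighted_profile(m["MID"], chem["tp_ugl"])
        est_high, _ = P.weighted_profile(m["HIGH"], chem["tp_ugl"])
        assert est_low > 0.8       # pulled up toward the centre
        assert est_high < 2.0      # pulled down toward the centre
        assert abs(est_mid - 1.4) < min(est_low - 0.8, 2.0 - est_high)

    def test_misaligned_sites_rejected(self, small_dataset):
        matrix, chem, _, _ = small_dataset
        with pytest.raises(ValueError, match="differ"):
            P.cross_validated_profiles(matrix.iloc[:-5], chem, CalibrationConfig(n_repeats=1))


def test_calibrate_produces_full_coefficient_table(small_dataset):
    matrix, chem, _, _ = small_dataset
    profiles = P.calibrate(matrix, chem, CalibrationConfig(n_repeats=10, base_seed=5))
    assert set(profiles["sensitivity_class"].unique()) <= set(range(1, 6))
    assert set(profiles["indicator_class"].unique()) <= {1, 2, 3}
    assert (profiles["tolerance"] >= 0).all()
    assert (profiles["n_occurrences"] >= 1).all()


def test_config_validation():
    with pytest.raises(ValueError):
        CalibrationConfig(train_fraction=1.0)
    with pytest.raises(ValueError):
        CalibrationConfig(sensitivity_breakpoints=(1.2, 1.1))
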