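import itertools

import numpy as np
import pytest

from aquavital.association import (
    BRule,
    MicMatrix,
    REFERENCE_WEIGHTS,
    WeightVector,
    allocate_stress_weights,
    compute_mic_matrix,
    feature_label,
    gra_coefficients,
    load_reference_mic_tables,
    mic,
    screen_features,
)
from aquavital.errors import AquavitalError, ConfigurationError, UndefinedStatisticError
from aquavital.synthetic import SimulationConfig, simulate_experiment
from aquavital.wbia import NutrientPanel, StressSeries

from conftest import magnitude_series


# ---------------------------------------------------------------------------
# grey relational analysis
# ---------------------------------------------------------------------------


class TestGra:
    def test_identical_series_give_unit_coefficients(self):
        x = np.linspace(0, 1, 12)
        assert np.allclose(gra_coefficients(x, x), 1.0)

    def test_antithetic_pair_worked_example(self):
        zeta = gra_coefficients([0.0, 1.0], [1.0, 0.0], rho=0.5)
        assert np.allclose(zeta, [1.0, 1.0])

    def test_nonincreasing_in_deviation(self):
        ref = np.zeros(5)
        comp = np.array([0.0, 0.1, 0.3, 0.6, 1.0])
        zeta = gra_coefficients(ref, comp, rho=0.5)
        assert np.all(np.diff(zeta) <= 1e-12)
        assert np.all((zeta > 0) & (zeta <= 1))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            gra_coefficients([0.0, 1.0], [0.0, 1.0, 2.0])

    def test_invalid_rho_rejected(self):
        with pytest.raises(ConfigurationError):
            gra_coefficients([0.0, 1.0], [1.0, 0.0], rho=1.5)


class TestWeightAllocation:
    @staticmethod
    def _panel(times, **series):
        return NutrientPanel(times=np.asarray(times), values={k: np.asarray(v) for k, v in series.items()})

    def test_single_factor_gets_weight_one(self):
        t = np.arange(5.0)
        stress = StressSeries(times=t, values={"lactate": np.linspace(2, 10, 5)})
        nutrients = self._panel(t, glycogen=np.linspace(6, 2, 5))
        wv = allocate_stress_weights(stress, nutrients)
        assert wv.weights == {"lactate": pytest.approx(1.0)}

    def test_identical_factors_split_evenly(self):
        t = np.arange(6.0)
        rise = np.linspace(1, 9, 6)
        stress = StressSeries(times=t, values={"glucose": rise, "lactate": rise.copy()})
        nutrients = self._panel(t, glycogen=np.linspace(6, 2, 6), fat=np.linspace(45, 31, 6))
        wv = allocate_stress_weights(stress, nutrients)
        assert wv.weights["glucose"] == pytest.approx(0.5, abs=1e-9)
        assert wv.weights["lactate"] == pytest.approx(0.5, abs=1e-9)

    def test_weights_sum_to_one_on_simulated_panels(self, default_run):
        _, _, stress, nutrients, _ = default_run
        wv = allocate_stress_weights(stress, nutrients)
        assert sum(wv.weights.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(0 < g <= 1 for g in wv.relational_grades.values())

    def test_too_few_common_times_rejected(self):
        stress = StressSeries(times=np.array([0.0]), values={"lactate": np.array([2.0])})
        nutrients = self._panel([0.0], glycogen=[6.0])
        with pytest.raises(ConfigurationError):
            allocate_stress_weights(stress, nutrients)

    def test_reference_default_weights(self):
        assert REFERENCE_WEIGHTS.weights == {"glucose": 0.290, "lactate": 0.396, "cortisol": 0.314}
        assert sum(REFERENCE_WEIGHTS.weights.values()) == pytest.approx(1.0, abs=1e-9)

    def test_weight_vector_must_normalize(self):
        with pytest.raises(ConfigurationError):
            WeightVector(weights={"a": 0.7, "b": 0.7}, relational_grades={"a": 0.7, "b": 0.7})


# ---------------------------------------------------------------------------
# maximal information coefficient
# ---------------------------------------------------------------------------


def brute_force_mic(x, y, b):
    """Exhaustive MIC over every pair of axis partitions with cols*rows <= b.

    Independent oracle: enumerates all cut placements between distinct sorted
    values on both axes and computes plug-in mutual information from the
    contingency table.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size

    def partitions(vals, parts):
        order = np.argsort(vals, kind="mergesort")
        sorted_vals = vals[order]
        bounds = np.flatnonzero(np.diff(sorted_vals) > 0) + 1
        for combo in itertools.combinations(bounds.tolist(), parts - 1):
            edges = [0, *combo, n]
            labels_sorted = np.empty(n, dtype=int)
            for k in range(parts):
                labels_sorted[edges[k]:edges[k + 1]] = k
            labels = np.empty(n, dtype=int)
            labels[order] = labels_sorted
            yield labels

    best = 0.0
    for nx in range(2, b // 2 + 1):
        for ny in range(2, b // nx + 1):
            for lx in partitions(x, nx):
                for ly in partitions(y, ny):
                    joint = np.zeros((nx, ny))
                    np.add.at(joint, (lx, ly), 1.0)
                    joint /= n
                    px = joint.sum(axis=1, keepdims=True)
                    py = joint.sum(axis=0, keepdims=True)
                    nz = joint > 0
                    i_val = float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))
                    best = max(best, i_val / np.log2(min(nx, ny)))
    return min(best, 1.0)


class TestMic:
    def test_perfect_monotone_relation_scores_one(self):
        x = np.linspace(0, 1, 100)
        assert mic(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_independent_uniform_null_is_low(self):
        """Null MIC (sublinear grid bound) has a low median under independence."""
        values = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            values.append(mic(rng.random(200), rng.random(200), BRule.POWER_0_6))
        assert np.median(values) < 0.35

    def test_symmetric_in_arguments(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x, y = rng.random(40), rng.random(40)
            assert mic(x, y) == pytest.approx(mic(y, x), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        x = np.linspace(-1, 1, 100)
        assert abs(mic(x, x**3) - mic(x, x)) <= 0.05

    def test_matches_exhaustive_oracle_on_small_series(self):
        """Grid search equals an all-partitions brute force for n <= 12, B <= 16."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 50:
            n = int(rng.integers(8, 13))
            x = rng.random(n)
            y = rng.random(n) if rng.random() < 0.5 else x + 0.3 * rng.random(n)
            b = min(16, max(4, int(np.floor(0.6 * n))))
            ours = mic(x, y, BRule.FACTOR_0_6)
            oracle = brute_force_mic(x, y, b)
            assert ours == pytest.approx(oracle, abs=1e-9)
            checked += 1

    def test_constant_input_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            mic(np.ones(20), np.linspace(0, 1, 20))

    def test_short_series_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            mic(np.arange(5.0), np.arange(5.0))


# ---------------------------------------------------------------------------
# feature screening
# ---------------------------------------------------------------------------


class TestScreening:
    def test_reference_impedance_table_selects_high_frequencies(self):
        tables = load_reference_mic_tables()
        selected = screen_features(tables["impedance"], 0.9)
        assert selected == [feature_label("impedance", f) for f in (80, 90, 100)]

    def test_reference_phase_table_selects_mid_frequencies(self):
        tables = load_reference_mic_tables()
        selected = screen_features(tables["phase"], 0.9)
        assert selected == [feature_label("phase", f) for f in (70, 80, 90)]

    def test_zero_threshold_selects_everything(self):
        table = load_reference_mic_tables()["impedance"]
        assert screen_features(table, 0.0) == list(table.table.index)

    def test_any_rule_is_weaker(self):
        table = load_reference_mic_tables()["impedance"]
        all_rule = set(screen_features(table, 0.9, rule="all"))
        any_rule = set(screen_features(table, 0.9, rule="any"))
        assert all_rule <= any_rule
        assert feature_label("impedance", 70) in any_rule - all_rule

    def test_empty_matrix_rejected(self):
        import pandas as pd

        with pytest.raises(AquavitalError):
            screen_features(MicMatrix(table=pd.DataFrame()), 0.9)

    def test_recovers_coupled_frequencies_on_simulated_runs(self):
        """MIC screening finds exactly the stress-coupled impedance channels."""
        exact = 0
        seeds = range(8)
        for seed in seeds:
            cfg = SimulationConfig(seed=seed)
            frames, _, _, truth = simulate_experiment(cfg)
            features = {
                feature_label("impedance", f): magnitude_series(frames, f)
                for f in cfg.frequencies_khz
            }
            stress = {k: v for k, v in truth.stress_series.values.items()}
            matrix = compute_mic_matrix(features, stress, subsample=150)
            selected = set(screen_features(matrix, 0.9))
            expected = {feature_label("impedance", f) for f in cfg.coupled_frequencies_khz}
            exact += selected == expected
        assert exact >= len(seeds) - 1
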