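import numpy as np
import pytest

from aquavital.association import REFERENCE_WEIGHTS
from aquavital.errors import AquavitalError, ConfigurationError, ExtrapolationError, FitError
from aquavital.health import (
    HealthLevel,
    LEVEL_THRESHOLDS,
    ZMF_DEFAULTS,
    ZmfParams,
    classify,
    fit_zmf_envelope,
    health_score,
    near_death_point,
    total_stress,
    zmf,
    zmf_array,
)
from aquavital.synthetic import SimulationConfig, TempZone, simulate_experiment
from aquavital.wbia import NutrientPanel


class TestHealthScore:
    @staticmethod
    def _panel(times, **series):
        return NutrientPanel(times=np.asarray(times, float),
                             values={k: np.asarray(v, float) for k, v in series.items()})

    def test_fresh_panel_scores_one(self):
        p = self._panel([0, 1, 2], glycogen=[6.5, 4.0, 1.0], fat=[45, 40, 30])
        assert health_score(p, 0.0) == pytest.approx(1.0)

    def test_depleted_panel_scores_zero(self):
        p = self._panel([0, 1, 2], glycogen=[6.5, 4.0, 1.0], fat=[45, 40, 30])
        assert health_score(p, 2.0) == pytest.approx(0.0)

    def test_two_nutrient_mean(self):
        p = self._panel([0, 1, 2], a=[1.0, 0.8, 0.0], b=[1.0, 0.6, 0.0])
        assert health_score(p, 1.0) == pytest.approx(0.7)

    def test_rising_analyte_is_reoriented(self):
        # muscle lactate rises during depletion yet must score 1 when fresh
        p = self._panel([0, 1, 2], muscle_lactate=[2.0, 8.0, 14.0])
        assert health_score(p, 0.0) == pytest.approx(1.0)
        assert health_score(p, 2.0) == pytest.approx(0.0)

    def test_empty_panel_rejected(self):
        with pytest.raises(AquavitalError):
            health_score(NutrientPanel(times=np.array([]), values={}), 0.0)

    def test_out_of_range_time_rejected(self):
        p = self._panel([0, 1, 2], glycogen=[6.5, 4.0, 1.0])
        with pytest.raises(ExtrapolationError):
            health_score(p, 3.0)


class TestTotalStress:
    BOUNDS = {"glucose": (3.0, 9.0), "lactate": (2.0, 14.0), "cortisol": (20.0, 180.0)}

    def test_extremes(self):
        at_max = {"glucose": 9.0, "lactate": 14.0, "cortisol": 180.0}
        at_min = {"glucose": 3.0, "lactate": 2.0, "cortisol": 20.0}
        assert total_stress(at_max, REFERENCE_WEIGHTS, self.BOUNDS) == pytest.approx(1.0)
        assert total_stress(at_min, REFERENCE_WEIGHTS, self.BOUNDS) == pytest.approx(0.0)

    def test_reference_weights_worked_example(self):
        # normalized values (glucose 0.5, lactate 1.0, cortisol 0.0)
        at = {"glucose": 6.0, "lactate": 14.0, "cortisol": 20.0}
        assert total_stress(at, REFERENCE_WEIGHTS, self.BOUNDS) == pytest.approx(0.541)

    def test_missing_factor_rejected(self):
        with pytest.raises(ConfigurationError):
            total_stress({"glucose": 5.0}, REFERENCE_WEIGHTS, self.BOUNDS)

    def test_invalid_bounds_rejected(self):
        bounds = dict(self.BOUNDS, lactate=(5.0, 5.0))
        at = {"glucose": 5.0, "lactate": 6.0, "cortisol": 100.0}
        with pytest.raises(ConfigurationError):
            total_stress(at, REFERENCE_WEIGHTS, bounds)


class TestZmf:
    @pytest.mark.parametrize("zone", [TempZone.ZONE_1_3, TempZone.ZONE_3_6])
    def test_boundary_identities_at_reference_coefficients(self, zone):
        p = ZMF_DEFAULTS[zone]
        assert zmf(p.a, p) == pytest.approx(1.0)
        assert zmf(p.b, p) == pytest.approx(0.0)
        assert zmf(0.5 * (p.a + p.b), p) == pytest.approx(0.5)

    def test_zone_1_3_midpoint(self):
        assert zmf(0.5095, ZmfParams(a=0.019, b=1.0)) == pytest.approx(0.5)

    def test_quarter_point_value(self):
        assert zmf(0.25, ZmfParams(a=0.0, b=1.0)) == pytest.approx(0.875)

    def test_continuous_and_nonincreasing(self):
        p = ZmfParams(a=0.1, b=0.9)
        grid = np.linspace(-0.2, 1.2, 2001)
        vals = zmf_array(grid, p)
        assert np.all(np.diff(vals) <= 1e-12)
        for joint in (p.a, 0.5 * (p.a + p.b), p.b):
            left = zmf(joint - 1e-13, p)
            right = zmf(joint + 1e-13, p)
            assert abs(left - right) <= 1e-10

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            ZmfParams(a=1.0, b=0.5)


class TestZmfEnvelope:
    def test_exact_points_recover_parameter(self):
        truth = ZmfParams(a=0.2, b=1.0)
        s = np.linspace(0.05, 0.95, 15)
        pts = [(v, zmf(v, truth)) for v in s]
        fitted = fit_zmf_envelope(pts, b_fixed=1.0)
        assert fitted.a == pytest.approx(0.2, abs=1e-6)

    def test_jittered_points_recover_within_band(self):
        # mid-branch samples keep jittered scores interior to [0, 1]
        truth = ZmfParams(a=0.2, b=1.0)
        s = np.linspace(0.40, 0.80, 25)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pts = [(v, zmf(v, truth) + float(rng.uniform(-0.05, 0.05))) for v in s]
            fitted = fit_zmf_envelope(pts, b_fixed=1.0)
            assert 0.1 < fitted.a < 0.3

    def test_degenerate_point_returns_midpoint_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate envelope"):
            fitted = fit_zmf_envelope([(1.0, 0.0)], b_fixed=1.0)
        assert fitted.a == pytest.approx(0.0, abs=1e-9)

    def test_unenclosable_points_rejected(self):
        # a score of 1 at s = b cannot sit below any ZMF curve with a < b
        with pytest.raises(FitError):
            fit_zmf_envelope([(1.0, 1.0), (0.5, 0.2)], b_fixed=1.0)


class TestClassify:
    @pytest.mark.parametrize(
        "avg, zone, expected",
        [
            (0.30, TempZone.ZONE_1_3, HealthLevel.SLL),
            (0.70, TempZone.ZONE_1_3, HealthLevel.BLL),
            (0.50, TempZone.ZONE_1_3, HealthLevel.MLL),
            (0.786, TempZone.ZONE_1_3, HealthLevel.WLL),
            (0.95, TempZone.ZONE_1_3, HealthLevel.DS),
            (0.368, TempZone.ZONE_3_6, HealthLevel.MLL),  # boundary is left-closed
            (0.406, TempZone.ZONE_1_3, HealthLevel.MLL),
        ],
    )
    def test_zone_thresholds(self, avg, zone, expected):
        assert classify(avg, zone=zone) is expected

    def test_monotone_in_average_stress(self):
        order = {lvl: i for i, lvl in enumerate(
            [HealthLevel.SLL, HealthLevel.MLL, HealthLevel.BLL, HealthLevel.WLL, HealthLevel.DS])}
        for zone in LEVEL_THRESHOLDS:
            levels = [order[classify(v, zone=zone)] for v in np.linspace(0, 1, 101)]
            assert levels == sorted(levels)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            classify(1.2)

    def test_simulated_health_never_improves(self):
        """Rising stress through the run maps to nonincreasing health levels."""
        order = {lvl: i for i, lvl in enumerate(
            [HealthLevel.SLL, HealthLevel.MLL, HealthLevel.BLL, HealthLevel.WLL, HealthLevel.DS])}
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, noise_sd=0.0, gross_error_rate=0.0)
            _, _, _, truth = simulate_experiment(cfg)
            avg = np.cumsum(truth.stress_norm) / np.arange(1, truth.stress_norm.size + 1)
            ranks = [order[classify(float(v), zone=cfg.temp_zone)] for v in avg]
            assert ranks == sorted(ranks)


class TestNearDeath:
    SCHEDULE = [(60.0, 2), (72.0, 5), (78.0, 8), (84.0, 11)]

    def test_observed_cohort_crosses_at_84_hours(self):
        assert near_death_point(self.SCHEDULE, 25) == (84.0, pytest.approx(0.56))

    def test_no_deaths_never_crosses(self):
        assert near_death_point([(60.0, 0), (84.0, 0)], 25) is None

    def test_unit_threshold_triggers_at_first_death(self):
        assert near_death_point(self.SCHEDULE, 25, survival_threshold=1.0) == (
            60.0, pytest.approx(0.92))

    def test_malformed_schedule_rejected(self):
        with pytest.raises(ConfigurationError):
            near_death_point([(60.0, 5), (72.0, 3)], 25)
        with pytest.raises(ConfigurationError):
            near_death_point([(60.0, 30)], 25)
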