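"""Five-level fuzzy health assessment from nutrients and weighted total stress.

The health score of a nutrient panel at time ``t`` is the mean of the
min-max-normalized nutrient values, with every analyte oriented so that the
fresh (t = 0) state maps to 1 and full depletion to 0.  The total stress is
the weight-normalized sum of min-max-scaled stress factors, in [0, 1].  A
Z-shaped fuzzy membership function (ZMF) with adjustment coefficients
``a < b`` maps total stress to a health-quality value in [0, 1]; its
coefficients are fitted by enclosing the (stress, score) detection points
between the tightest upper and lower ZMF curves and averaging their
parameters.  Discrete levels (SLL, MLL, BLL, WLL, DS - strong/medium/basic/
weak live level and death status) follow zone-specific average-stress
breakpoints, which are shipped as given constants; the near-death time point
is the first observation checkpoint at which cohort survival drops below the
survival threshold (default 60%).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AquavitalError, ConfigurationError, ExtrapolationError, FitError
from .synthetic import TempZone
from .wbia import NutrientPanel
from .association import WeightVector


class HealthLevel(enum.Enum):
    SLL = "strong live level"
    MLL = "medium live level"
    BLL = "basic live level"
    WLL = "weak live level"
    DS = "death status"


LEVEL_ORDER = (HealthLevel.SLL, HealthLevel.MLL, HealthLevel.BLL, HealthLevel.WLL, HealthLevel.DS)


@dataclass(frozen=True)
class ZmfParams:
    a: float
    b: float
    temp_zone: TempZone = TempZone.ZONE_1_3

    def __post_init__(self) -> None:
        if not self.a < self.b:
            raise ConfigurationError(f"ZMF requires a < b, got a={self.a}, b={self.b}")


#: reference ZMF adjustment coefficients per temperature zone
ZMF_DEFAULTS = {
    TempZone.ZONE_1_3: ZmfParams(a=0.019, b=1.0, temp_zone=TempZone.ZONE_1_3),
    TempZone.ZONE_3_6: ZmfParams(a=0.0138, b=1.0, temp_zone=TempZone.ZONE_3_6),
}


@dataclass(frozen=True)
class LevelThresholds:
    """Average-total-stress breakpoints (4 of them -> 5 levels) per zone.

    Stress intervals are left-closed, right-open.  The companion health-score
    breakpoints are carried for reporting only.
    """

    stress_breaks: tuple[float, float, float, float]
    score_breaks: tuple[float, float, float, float] = (0.857, 0.429, 0.143, 0.131)

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.stress_breaks, self.stress_breaks[1:])):
            raise ConfigurationError("stress breakpoints must be strictly increasing")


LEVEL_THRESHOLDS = {
    TempZone.ZONE_1_3: LevelThresholds(stress_breaks=(0.406, 0.625, 0.783, 0.792)),
    TempZone.ZONE_3_6: LevelThresholds(stress_breaks=(0.368, 0.597, 0.767, 0.779)),
}


@dataclass(frozen=True)
class HealthAssessment:
    time_h: float
    total_stress: float
    hq: float
    level: HealthLevel
    zone: TempZone

    def __post_init__(self) -> None:
        if not 0.0 <= self.hq <= 1.0:
            raise ConfigurationError(f"hq must be in [0,1], got {self.hq}")


# ---------------------------------------------------------------------------
# health score and total stress
# ---------------------------------------------------------------------------


def _oriented_norm(series: np.ndarray) -> np.ndarray:
    """Min-max normalization oriented so that the t=0 value maps to 1."""
    span = series.max() - series.min()
    if span == 0.0:
        return np.ones_like(series)
    norm = (series - series.min()) / span
    return norm if norm[0] >= 0.5 else 1.0 - norm


def health_score(panel: NutrientPanel, at_time: float) -> float:
    """Mean oriented-normalized nutrient value at a time (1 fresh, 0 depleted)."""
    if not panel.values:
        raise AquavitalError("empty nutrient panel")
    t = panel.times
    if not t[0] <= at_time <= t[-1]:
        raise ExtrapolationError(f"time {at_time} outside panel range [{t[0]}, {t[-1]}]")
    vals = [float(np.interp(at_time, t, _oriented_norm(v))) for v in panel.values.values()]
    return float(np.mean(vals))


def total_stress(
    stress_at_t: dict[str, float],
    weights: WeightVector,
    normalizers: dict[str, tuple[float, float]],
) -> float:
    """Weighted sum of min-max-normalized stress factors, clipped into [0, 1]."""
    out = 0.0
    for factor, w in weights.weights.items():
        if factor not in stress_at_t:
            raise ConfigurationError(f"stress factor {factor!r} missing a value")
        if factor not in normalizers:
            raise ConfigurationError(f"stress factor {factor!r} missing normalizer bounds")
        lo, hi = normalizers[factor]
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ConfigurationError(f"invalid normalizer bounds for {factor!r}: ({lo}, {hi})")
        out += w * float(np.clip((stress_at_t[factor] - lo) / (hi - lo), 0.0, 1.0))
    return out


# ---------------------------------------------------------------------------
# Z-shaped membership function
# ---------------------------------------------------------------------------


def zmf(s: float, params: ZmfParams) -> float:
    """Z-shaped membership: 1 below ``a``, 0 above ``b``, two quadratic arcs
    joined at the midpoint; continuous and nonincreasing."""
    a, b = params.a, params.b
    if s <= a:
        return 1.0
    if s >= b:
        return 0.0
    mid = 0.5 * (a + b)
    if s <= mid:
        return 1.0 - 2.0 * ((s - a) / (b - a)) ** 2
    return 2.0 * ((s - b) / (b - a)) ** 2


def zmf_array(s, params: ZmfParams) -> np.ndarray:
    return np.array([zmf(float(v), params) for v in np.atleast_1d(np.asarray(s, dtype=float))])


def fit_zmf_envelope(points, b_fixed: float = 1.0, tol: float = 1e-9) -> ZmfParams:
    """Fit ``a`` by enclosing (total_stress, health_score) points between the
    tightest ZMF curves above and below them.

    ``zmf(s; a, b)`` is nondecreasing in ``a``, so the tightest upper envelope
    is the smallest ``a`` whose curve lies on or above every point and the
    tightest lower envelope the largest ``a`` whose curve lies on or below
    every point; both are found by monotone bisection over ``a`` in
    ``(-b_fixed, b_fixed)`` and averaged.  When every candidate encloses the
    points (degenerate input, e.g. a single point at ``s = b``), the search
    interval midpoint is returned with a warning.
    """
    pts = [(float(s), float(hs)) for s, hs in points]
    if not pts:
        raise FitError("fit_zmf_envelope requires at least one point")
    if any(not 0.0 <= hs <= 1.0 for _, hs in pts):
        raise FitError("health scores must lie in [0, 1]")
    lo, hi = -b_fixed + 1e-12, b_fixed - 1e-12

    def above(a: float) -> bool:
        p = ZmfParams(a=a, b=b_fixed)
        return all(zmf(s, p) >= hs - 1e-12 for s, hs in pts)

    def below(a: float) -> bool:
        p = ZmfParams(a=a, b=b_fixed)
        return all(zmf(s, p) <= hs + 1e-12 for s, hs in pts)

    if above(lo) and below(hi):
        warnings.warn("degenerate envelope: every ZMF encloses the points; "
                      "returning the search-interval midpoint", stacklevel=2)
        return ZmfParams(a=0.5 * (lo + hi), b=b_fixed)
    if not above(hi):
        raise FitError("no upper ZMF envelope exists within a in (-b, b)")
    if not below(lo):
        raise FitError("no lower ZMF envelope exists within a in (-b, b)")

    # smallest a with curve >= all points
    left, right = lo, hi
    while right - left > tol:
        mid = 0.5 * (left + right)
        if above(mid):
            right = mid
        else:
            left = mid
    a_upper = right
    # largest a with curve <= all points
    left, right = lo, hi
    while right - left > tol:
        mid = 0.5 * (left + right)
        if below(mid):
            left = mid
        else:
            right = mid
    a_lower = left
    return ZmfParams(a=0.5 * (a_upper + a_lower), b=b_fixed)


# ---------------------------------------------------------------------------
# classification and survival
# ---------------------------------------------------------------------------


def classify(
    total_stress_avg: float,
    thresholds: LevelThresholds | None = None,
    zone: TempZone = TempZone.ZONE_1_3,
) -> HealthLevel:
    """Discrete health level from the average total stress (left-closed bins)."""
    if not 0.0 <= total_stress_avg <= 1.0:
        raise ConfigurationError(f"average total stress must be in [0,1], got {total_stress_avg}")
    th = thresholds if thresholds is not None else LEVEL_THRESHOLDS[zone]
    for brk, level in zip(th.stress_breaks, LEVEL_ORDER):
        if total_stress_avg < brk:
            return level
    return HealthLevel.DS


def assess(
    time_h: float,
    total_stress_avg: float,
    zone: TempZone,
    zmf_params: ZmfParams | None = None,
    thresholds: LevelThresholds | None = None,
) -> HealthAssessment:
    params = zmf_params if zmf_params is not None else ZMF_DEFAULTS[zone]
    return HealthAssessment(
        time_h=time_h,
        total_stress=total_stress_avg,
        hq=zmf(total_stress_avg, params),
        level=classify(total_stress_avg, thresholds, zone),
        zone=zone,
    )


def near_death_point(
    schedule: list[tuple[float, int]],
    cohort: int,
    survival_threshold: float = 0.60,
) -> tuple[float, float] | None:
    """First checkpoint at which survival drops below the threshold.

    Returns ``(hour, survival_fraction)`` or ``None`` if the threshold is
    never crossed.
    """
    if cohort < 1:
        raise ConfigurationError(f"cohort must be >= 1, got {cohort}")
    prev = 0
    prev_hour = -np.inf
    for hour, cumulative in schedule:
        if cumulative < prev or cumulative > cohort or hour <= prev_hour:
            raise ConfigurationError(f"malformed death schedule at checkpoint {hour}")
        prev, prev_hour = cumulative, hour
        survival = (cohort - cumulative) / cohort
        if survival < survival_threshold:
            return float(hour), float(survival)
    return None
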