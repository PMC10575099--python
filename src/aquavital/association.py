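"""Stress-weight allocation (grey relational analysis) and WBIA feature
screening (maximal information coefficient).

GRA scores, per time point, how close a comparison series tracks a reference
series; the relational coefficients

    zeta(k) = (d_min + rho * d_max) / (d(k) + rho * d_max),   d(k) = |x0(k) - xi(k)|

are averaged into relational grades and normalized into weights summing to 1.
The resolution coefficient ``rho`` in (0,1) controls the spread (smaller rho,
greater resolution); extrema are taken jointly over all comparison series in
the call context, the standard GRA convention.

MIC searches bounded grid partitions of the (x, y) scatter for the one that
maximizes normalized mutual information ``I(X;Y)/log2(min(cols, rows))``,
subject to ``cols * rows <= B``.  One axis is binned by equipartition (for
small samples every distinct-value partition is enumerated, making the search
exact); the other axis is optimized exactly by dynamic programming; both
orientations are tried and the maximum taken.  Two B rules are supported:
``B = 0.6 n`` (FACTOR_0_6, the package default) and the sublinear literature
convention ``B = n^0.6`` (POWER_0_6), whose null distribution under
independence is the calibrated one.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from numba import njit

from .errors import AquavitalError, ConfigurationError, UndefinedStatisticError
from .wbia import NutrientPanel, StressSeries


# ---------------------------------------------------------------------------
# grey relational analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightVector:
    """Per-stress-factor weights (summing to 1) with their relational grades."""

    weights: dict[str, float]
    relational_grades: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"weights must sum to 1, got {total}")
        for k, g in self.relational_grades.items():
            if not 0.0 < g <= 1.0 + 1e-12:
                raise ConfigurationError(f"relational grade for {k!r} outside (0,1]: {g}")

    def __getitem__(self, factor: str) -> float:
        return self.weights[factor]


#: reference weight allocation from the original cold-dormancy study, used as
#: the default when no nutrient data are supplied
REFERENCE_WEIGHTS = WeightVector(
    weights={"glucose": 0.290, "lactate": 0.396, "cortisol": 0.314},
    relational_grades={"glucose": 0.290, "lactate": 0.396, "cortisol": 0.314},
)


def minmax_normalize(x) -> np.ndarray:
    """Min-max scale to [0, 1]; a constant series maps to all 0.5."""
    x = np.asarray(x, dtype=float)
    span = x.max() - x.min()
    if span == 0.0:
        return np.full_like(x, 0.5)
    return (x - x.min()) / span


def gra_coefficients(
    reference,
    comparison,
    rho: float = 0.5,
    delta_min: float | None = None,
    delta_max: float | None = None,
) -> np.ndarray:
    """Per-time-point grey relational coefficients of one comparison series.

    ``delta_min``/``delta_max`` may be supplied as the global extrema over a
    wider call context (several comparison series); by default they are the
    extrema of this pair.  Inputs are expected min-max normalized.  All
    coefficients lie in (0, 1]; if ``delta_max`` is 0 every coefficient is 1
    (degenerate identical-series case).
    """
    if not 0.0 < rho < 1.0:
        raise ConfigurationError(f"rho must be in (0,1), got {rho}")
    x0 = np.asarray(reference, dtype=float)
    xi = np.asarray(comparison, dtype=float)
    if x0.shape != xi.shape or x0.size < 2:
        raise ConfigurationError(
            f"reference and comparison must be equal length >= 2, got {x0.size} and {xi.size}"
        )
    delta = np.abs(x0 - xi)
    dmin = float(delta.min()) if delta_min is None else float(delta_min)
    dmax = float(delta.max()) if delta_max is None else float(delta_max)
    if dmax == 0.0:
        return np.ones_like(delta)
    return (dmin + rho * dmax) / (delta + rho * dmax)


def allocate_stress_weights(
    stress: StressSeries, nutrients: NutrientPanel, rho: float = 0.5
) -> WeightVector:
    """GRA weight allocation of the stress factors against nutrient decline.

    Each nutrient series serves in turn as the reference; each stress factor
    is the comparison; extrema are joint over the stress factors per
    reference.  The relational grade of a factor is its coefficient mean over
    time and nutrients; weights are grades normalized to sum 1.  Both panels
    must share >= 2 common checkpoint times.
    """
    common = np.intersect1d(stress.times, nutrients.times)
    if common.size < 2:
        raise ConfigurationError(
            f"need >= 2 common time points, got {common.size}"
        )
    s_idx = np.searchsorted(stress.times, common)
    n_idx = np.searchsorted(nutrients.times, common)
    s_norm = {f: minmax_normalize(v[s_idx]) for f, v in stress.values.items()}
    n_norm = {nu: minmax_normalize(v[n_idx]) for nu, v in nutrients.values.items()}
    grades = {f: [] for f in stress.values}
    for ref in n_norm.values():
        deltas = {f: np.abs(ref - s_norm[f]) for f in s_norm}
        dmin = min(float(d.min()) for d in deltas.values())
        dmax = max(float(d.max()) for d in deltas.values())
        for f in s_norm:
            zeta = gra_coefficients(ref, s_norm[f], rho, delta_min=dmin, delta_max=dmax)
            grades[f].append(float(zeta.mean()))
    grade = {f: float(np.mean(g)) for f, g in grades.items()}
    total = sum(grade.values())
    return WeightVector(
        weights={f: g / total for f, g in grade.items()},
        relational_grades=grade,
    )


# ---------------------------------------------------------------------------
# maximal information coefficient
# ---------------------------------------------------------------------------

class BRule(enum.Enum):
    FACTOR_0_6 = "factor"  # B = 0.6 * n
    POWER_0_6 = "power"  # B = n ** 0.6


#: below this sample count every distinct-value partition of the binned axis
#: is enumerated, making the grid search exhaustive (used by the small-sample
#: oracle-equivalence regime)
EXACT_MODE_MAX_N = 16
MAX_CUT_CANDIDATES = 64


def grid_bound(n: int, b_rule: BRule) -> int:
    if b_rule is BRule.FACTOR_0_6:
        return max(4, int(np.floor(0.6 * n)))
    return max(4, int(np.floor(n**0.6)))


@njit(cache=False)
def _dp_best_partition(cum, kmax):  # pragma: no cover - numba kernel
    """Max over x-partitions of sum_c sum_q n_cq*log2(n_cq/n_c), per column count.

    ``cum`` is the (m+1, ny) cumulative row-count table at candidate cut
    positions.  Returns best[k] for k = 1..kmax (index k-1), exact DP.
    """
    m = cum.shape[0] - 1
    ny = cum.shape[1]
    neg_inf = -1e30
    # val[d, e] = column contribution for points in (d, e]
    val = np.full((m + 1, m + 1), neg_inf)
    for d in range(m + 1):
        for e in range(d + 1, m + 1):
            nc = 0
            for q in range(ny):
                nc += cum[e, q] - cum[d, q]
            if nc == 0:
                val[d, e] = neg_inf
                continue
            s = 0.0
            for q in range(ny):
                ncq = cum[e, q] - cum[d, q]
                if ncq > 0:
                    s += ncq * np.log2(ncq / nc)
            val[d, e] = s
    f_prev = np.full(m + 1, neg_inf)
    for e in range(1, m + 1):
        f_prev[e] = val[0, e]
    best = np.full(kmax, neg_inf)
    best[0] = f_prev[m]
    for k in range(2, kmax + 1):
        f_cur = np.full(m + 1, neg_inf)
        for e in range(k, m + 1):
            b = neg_inf
            for d in range(k - 1, e):
                if f_prev[d] > neg_inf and val[d, e] > neg_inf:
                    c = f_prev[d] + val[d, e]
                    if c > b:
                        b = c
            f_cur[e] = b
        best[k - 1] = f_cur[m]
        f_prev = f_cur
    return best


def _candidate_cuts(x_sorted: np.ndarray, max_candidates: int) -> np.ndarray:
    """Prefix counts at which a column boundary may be placed (between distinct values)."""
    n = x_sorted.size
    distinct = np.flatnonzero(np.diff(x_sorted) > 0) + 1  # positions 1..n-1
    if distinct.size > max_candidates:
        take = np.unique(
            distinct[np.linspace(0, distinct.size - 1, max_candidates).round().astype(int)]
        )
        distinct = take
    return np.concatenate(([0], distinct, [n]))


def _row_assignment_equipartition(y: np.ndarray, ny: int) -> np.ndarray:
    """Rank-based equipartition into ny rows, ties kept together."""
    order = np.argsort(y, kind="mergesort")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(y.size)
    rows = (ranks * ny) // y.size
    # ties share the row of their first occurrence
    y_sorted = y[order]
    rows_sorted = rows[order]
    for i in range(1, y.size):
        if y_sorted[i] == y_sorted[i - 1]:
            rows_sorted[i] = rows_sorted[i - 1]
    out = np.empty_like(rows_sorted)
    out[order] = rows_sorted
    return out


def _best_over_x(x: np.ndarray, rows: np.ndarray, ny_effective: int, kmax: int,
                 max_candidates: int) -> np.ndarray:
    """Normalized-MI best values per column count for a fixed row assignment."""
    n = x.size
    order = np.argsort(x, kind="mergesort")
    x_sorted = x[order]
    rows_sorted = rows[order]
    cuts = _candidate_cuts(x_sorted, max_candidates)
    onehot = np.zeros((n + 1, ny_effective), dtype=np.int64)
    for i, q in enumerate(rows_sorted):
        onehot[i + 1, q] = 1
    cum_all = np.cumsum(onehot, axis=0)
    cum = cum_all[cuts]
    nq = cum[-1]
    pq = nq[nq > 0] / n
    h_q = float(-(pq * np.log2(pq)).sum())
    best_a = _dp_best_partition(cum, kmax)
    return best_a / n + h_q  # I(P;Q) per column count


def _iter_row_assignments(y: np.ndarray, ny: int, exact: bool):
    """Yield (rows, n_rows_nonempty) assignments for the binned axis."""
    if not exact:
        rows = _row_assignment_equipartition(y, ny)
        yield rows, ny
        return
    order = np.argsort(y, kind="mergesort")
    y_sorted = y[order]
    boundaries = np.flatnonzero(np.diff(y_sorted) > 0) + 1
    if boundaries.size < ny - 1:
        return
    for combo in itertools.combinations(boundaries.tolist(), ny - 1):
        edges = np.concatenate(([0], np.asarray(combo, dtype=int), [y.size]))
        rows_sorted = np.empty(y.size, dtype=np.int64)
        for q in range(ny):
            rows_sorted[edges[q]:edges[q + 1]] = q
        rows = np.empty_like(rows_sorted)
        rows[order] = rows_sorted
        yield rows, ny


def mic(x, y, b_rule: BRule = BRule.FACTOR_0_6, max_candidates: int = MAX_CUT_CANDIDATES) -> float:
    """Maximal information coefficient of two equal-length series, in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("x and y must be equal-length 1-D series")
    n = x.size
    if n < 8:
        raise UndefinedStatisticError(f"MIC requires n >= 8, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("MIC is undefined for constant input")
    b = grid_bound(n, b_rule)
    exact = n <= EXACT_MODE_MAX_N
    best = 0.0
    for a_vals, b_vals in ((x, y), (y, x)):
        # b_vals is binned into ny rows; a_vals is DP-optimized into columns
        for ny in range(2, b // 2 + 1):
            kmax = b // ny
            if kmax < 2:
                break
            for rows, ny_eff in _iter_row_assignments(b_vals, ny, exact):
                i_vals = _best_over_x(a_vals, rows, ny_eff, kmax, max_candidates)
                for k in range(2, kmax + 1):
                    i_k = i_vals[k - 1]
                    if i_k > 0:
                        cand = i_k / np.log2(min(k, ny))
                        if cand > best:
                            best = cand
    return float(min(best, 1.0))


# ---------------------------------------------------------------------------
# feature screening
# ---------------------------------------------------------------------------

@dataclass
class MicMatrix:
    """MIC values, WBIA feature rows (channel x frequency) by stress factors."""

    table: pd.DataFrame  # index: feature labels; columns: stress factors
    b_rule: BRule = BRule.FACTOR_0_6

    def __post_init__(self) -> None:
        vals = self.table.to_numpy(dtype=float)
        if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
            raise ConfigurationError("MIC values must lie in [0, 1]")


def feature_label(channel: str, frequency_khz: float) -> str:
    return f"{channel}@{frequency_khz:g}kHz"


def screen_features(mic_matrix: MicMatrix, threshold: float, rule: str = "all") -> list[str]:
    """Features whose MIC reaches the threshold for every stress factor.

    ``rule='all'`` (default) requires MIC >= threshold in every column,
    ``rule='any'`` in at least one; selection preserves row order.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError(f"threshold must be in [0,1], got {threshold}")
    if mic_matrix.table.empty:
        raise AquavitalError("empty MIC matrix")
    ok = mic_matrix.table >= threshold
    mask = ok.all(axis=1) if rule == "all" else ok.any(axis=1)
    return list(mic_matrix.table.index[mask])


def compute_mic_matrix(
    features: dict[str, np.ndarray],
    stress: dict[str, np.ndarray],
    b_rule: BRule = BRule.FACTOR_0_6,
    subsample: int | None = 200,
    seed: int = 0,
) -> MicMatrix:
    """MIC of every WBIA feature series against every stress factor series.

    All series must be time-aligned and equal length; when longer than
    ``subsample`` an evenly spaced subsample is scored (grid search cost grows
    quickly with n under the FACTOR_0_6 rule).
    """
    lengths = {len(v) for v in features.values()} | {len(v) for v in stress.values()}
    if len(lengths) != 1:
        raise ConfigurationError(f"feature/stress series lengths differ: {sorted(lengths)}")
    n = lengths.pop()
    idx = np.arange(n)
    if subsample is not None and n > subsample:
        idx = np.linspace(0, n - 1, subsample).round().astype(int)
    rows = {
        label: {f: mic(series[idx], s[idx], b_rule) for f, s in stress.items()}
        for label, series in features.items()
    }
    return MicMatrix(table=pd.DataFrame(rows).T, b_rule=b_rule)


def load_reference_mic_tables() -> dict[str, MicMatrix]:
    """The transcribed reference study MIC tables (impedance and phase)."""
    out = {}
    for channel, fname in (
        ("impedance", "reference_mic_impedance.csv"),
        ("phase", "reference_mic_phase.csv"),
    ):
        with resources.files("aquavital.data").joinpath(fname).open() as fh:
            df = pd.read_csv(fh)
        df.index = [feature_label(channel, f) for f in df.pop("frequency_khz")]
        out[channel] = MicMatrix(table=df)
    return out
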