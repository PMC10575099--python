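"""Gross-error removal, smoothing and checkpoint completion.

Three stages prepare raw sweeps and sparse biomarker tables for modelling:

* the Romanovsky criterion — a Student-t small-sample rule — iteratively
  rejects the single most suspicious sample while its deviation from the
  remaining data's mean exceeds ``K * sigma``;
* Savitzky–Golay least-squares polynomial smoothing denoises each channel
  without distorting trend or width;
* natural cubic splines complete the sparse hourly biomarker checkpoints to
  the sweep sampling grid (no extrapolation beyond the checkpoint range).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import medfilt, savgol_filter
from scipy.stats import t as student_t

from .errors import ConfigurationError, ExtrapolationError, InsufficientDataError
from .wbia import SweepFrame, frames_to_table, table_to_frames


@dataclass(frozen=True)
class RomanovskyConfig:
    significance_level: float = 0.05
    max_iterations: int | None = None  # None: up to the series length

    def __post_init__(self) -> None:
        if not 0.0 < self.significance_level < 1.0:
            raise ConfigurationError(
                f"significance_level must be in (0,1), got {self.significance_level}"
            )
        if self.max_iterations is not None and self.max_iterations < 1:
            raise ConfigurationError(f"max_iterations must be positive, got {self.max_iterations}")


@dataclass(frozen=True)
class SavGolConfig:
    window_half_width_w: int = 5  # 11-point window
    poly_order: int = 3

    def __post_init__(self) -> None:
        if self.window_half_width_w < 1:
            raise ConfigurationError(
                f"window_half_width_w must be positive, got {self.window_half_width_w}"
            )
        if not 0 <= self.poly_order < 2 * self.window_half_width_w + 1:
            raise ConfigurationError(
                f"poly_order must be in [0, {2 * self.window_half_width_w}], got {self.poly_order}"
            )

    @property
    def window_length(self) -> int:
        return 2 * self.window_half_width_w + 1


def romanovsky_k(n: int, significance_level: float = 0.05) -> float:
    """Romanovsky test coefficient K(n, alpha).

    The two-sided Student-t quantile at n-2 degrees of freedom with a
    Bonferroni share of alpha per candidate suspect,
    ``K = t_{1 - alpha/(2n), n-2}``: because the suspect is the *largest* of n
    deviations, an uncorrected per-sample quantile would reject a fraction of
    clean data near alpha on every pass and cascade as the spread estimate
    shrinks; the corrected coefficient holds the family-wise false-rejection
    probability of the whole iterated filter near alpha.
    """
    if n < 4:
        raise InsufficientDataError(f"Romanovsky K requires n >= 4, got {n}")
    return float(student_t.ppf(1.0 - significance_level / (2.0 * n), n - 2))


def romanovsky_filter(
    series, config: RomanovskyConfig = RomanovskyConfig()
) -> tuple[np.ndarray, set[int]]:
    """Iteratively remove gross errors from a series.

    On each pass the sample with the largest absolute deviation from the mean
    of the *other* samples is tested against ``K * sigma``, where ``sigma`` is
    the standard deviation of the others with an ``n-2`` divisor; it is
    removed if it exceeds the bound, and the pass repeats on the shortened
    series.  Removed indices refer to positions in the original series.  A
    zero ``sigma`` with a differing suspect removes the suspect (documented
    convention: any deviation from an otherwise constant series is gross).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise InsufficientDataError(f"romanovsky_filter requires >= 4 samples, got {x.size}")
    max_iter = config.max_iterations if config.max_iterations is not None else x.size
    alive = np.arange(x.size)
    removed: set[int] = set()
    for _ in range(max_iter):
        n = alive.size
        if n < 4:
            break
        vals = x[alive]
        total = vals.sum()
        # mean of the others, per candidate
        others_mean = (total - vals) / (n - 1)
        dev = np.abs(vals - others_mean)
        j = int(np.argmax(dev))
        rest = np.delete(vals, j)
        sigma = math.sqrt(float(np.sum((rest - others_mean[j]) ** 2)) / (n - 2))
        k = romanovsky_k(n, config.significance_level)
        if sigma == 0.0:
            if dev[j] > 0.0:
                removed.add(int(alive[j]))
                alive = np.delete(alive, j)
                continue
            break
        if dev[j] > k * sigma:
            removed.add(int(alive[j]))
            alive = np.delete(alive, j)
        else:
            break
    return x[alive], removed


def savgol_smooth(series, config: SavGolConfig = SavGolConfig()) -> np.ndarray:
    """Savitzky–Golay smoothing; output length equals input length.

    Interior points are the least-squares convolution ``sum x_{k+i} h_i / H``;
    edges are evaluated from the polynomial fitted to the terminal window.
    """
    x = np.asarray(series, dtype=float)
    if config.window_length > x.size:
        raise InsufficientDataError(
            f"window length {config.window_length} exceeds series length {x.size}"
        )
    return savgol_filter(x, config.window_length, config.poly_order, mode="interp")


def savgol_coefficients(config: SavGolConfig) -> np.ndarray:
    """The interior smoothing coefficients h_i / H (length 2w+1)."""
    from scipy.signal import savgol_coeffs

    return savgol_coeffs(config.window_length, config.poly_order)[::-1]


def spline_complete(checkpoints, query_times) -> np.ndarray:
    """Natural cubic spline through sparse checkpoints, evaluated at query times.

    Exact at the knots, C2 in the interior; queries outside the checkpoint
    range raise (no extrapolation).
    """
    pts = sorted((float(t), float(v)) for t, v in checkpoints)
    if len(pts) < 3:
        raise InsufficientDataError(f"spline_complete requires >= 3 checkpoints, got {len(pts)}")
    times = np.array([p[0] for p in pts])
    vals = np.array([p[1] for p in pts])
    if np.any(np.diff(times) <= 0):
        raise ConfigurationError("checkpoint times must be strictly increasing")
    q = np.asarray(query_times, dtype=float)
    if q.size and (q.min() < times[0] - 1e-12 or q.max() > times[-1] + 1e-12):
        raise ExtrapolationError(
            f"query range [{q.min()}, {q.max()}] outside checkpoints [{times[0]}, {times[-1]}]"
        )
    return CubicSpline(times, vals, bc_type="natural")(q)


# ---------------------------------------------------------------------------
# sweep-channel cleaning
# ---------------------------------------------------------------------------

#: family-wise significance for per-channel gross-error screening
CLEAN_SIGNIFICANCE = 0.05
DETREND_WINDOW = 11


def detect_gross_errors(
    series, significance_level: float = CLEAN_SIGNIFICANCE, detrend_window: int = DETREND_WINDOW
) -> set[int]:
    """Spike positions in a possibly trending channel.

    The slow trend is removed with a rolling median (robust to the spikes
    themselves) and the Romanovsky filter is applied to the residuals.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 4:
        return set()
    w = min(detrend_window, x.size if x.size % 2 else x.size - 1)
    resid = x - medfilt(x, kernel_size=w)
    _, removed = romanovsky_filter(resid, RomanovskyConfig(significance_level=significance_level))
    return removed


def clean_sweeps(
    frames: list[SweepFrame],
    sg: SavGolConfig = SavGolConfig(),
    significance_level: float = CLEAN_SIGNIFICANCE,
) -> tuple[list[SweepFrame], pd.DataFrame]:
    """Per-channel gross-error repair plus Savitzky–Golay smoothing.

    Each (frequency, r/i) channel is screened independently; flagged samples
    are replaced by linear interpolation from their clean neighbours before
    smoothing, so the output keeps one row per original timestamp.  Returns
    the cleaned frames and a log of removed points with columns
    (timestamp_iso, frequency_khz, channel, original_value).
    """
    table = frames_to_table(frames)
    log_rows = []
    wide = table.pivot(index="timestamp_iso", columns="frequency_khz")
    order = table["timestamp_iso"].drop_duplicates().tolist()
    wide = wide.reindex(order)
    n = len(wide)
    for channel, col in (("r", "r_ohm"), ("i", "i_ohm")):
        for f in wide[col].columns:
            x = wide[(col, f)].to_numpy(dtype=float)
            bad = sorted(detect_gross_errors(x, significance_level))
            if bad:
                for k in bad:
                    log_rows.append((order[k], f, channel, x[k]))
                good = np.setdiff1d(np.arange(n), bad)
                x[bad] = np.interp(np.asarray(bad, dtype=float), good.astype(float), x[good])
            if n >= sg.window_length:
                x = savgol_smooth(x, sg)
            wide[(col, f)] = x
    out = wide.stack(future_stack=True).reset_index()
    out = out.rename(columns={"level_1": "frequency_khz"})
    out = out[["timestamp_iso", "frequency_khz", "r_ohm", "i_ohm", "temperature_c"]]
    out["timestamp_iso"] = pd.Categorical(out["timestamp_iso"], categories=order, ordered=True)
    out = out.sort_values(["timestamp_iso", "frequency_khz"])
    out["timestamp_iso"] = out["timestamp_iso"].astype(str)
    cleaned = table_to_frames(out)
    log = pd.DataFrame(log_rows, columns=["timestamp_iso", "frequency_khz", "channel", "original_value"])
    return cleaned, log
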