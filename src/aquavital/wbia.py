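"""Data model and I/O for wearable bioimpedance (WBIA) sweeps and biomarker panels.

A multifrequency sweep records, per timestamp and per excitation frequency,
the real part ``R`` and imaginary part ``I`` of the measured transfer signal
together with the water/air temperature.  The impedance magnitude is
``M = sqrt(R^2 + I^2)`` and the phase is ``theta = arctan(I/R)`` (principal
value; quadrant information is not recoverable from the ratio and real
devices report phase in a limited range).  Calibration against a known
reference resistor yields a per-frequency gain factor ``K`` with
``Z = 1/(M*K)``, so that the reference magnitude maps back to the reference
resistance exactly.

Biomarker checkpoints (serum glucose, serum cortisol, muscle lactate) and
muscle nutrient panels (glycogen, fat, crude protein, ATP-related compounds,
pH, muscle lactate) are sparse time tables sampled at wet-lab checkpoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CalibrationError, DegenerateSweepError, FormatError

STRESS_FACTORS = ("glucose", "lactate", "cortisol")
NUTRIENTS = ("glycogen", "fat", "crude_protein", "atp_compounds", "ph", "muscle_lactate")

#: Analytes whose trajectory declines during cold-dormancy depletion.
DECLINING_NUTRIENTS = ("glycogen", "fat", "crude_protein", "atp_compounds", "ph")

SWEEP_COLUMNS = ("timestamp_iso", "frequency_khz", "r_ohm", "i_ohm", "temperature_c")
CHECKPOINT_COLUMNS = ("time_h", "analyte", "value", "units")


# ---------------------------------------------------------------------------
# magnitude / phase / calibration
# ---------------------------------------------------------------------------

def magnitude_phase(r_ohm: float, i_ohm: float) -> tuple[float, float]:
    """Impedance magnitude and principal-value phase from real/imaginary parts.

    Returns ``(sqrt(r^2 + i^2), arctan(i/r))``.  For ``r == 0`` the phase is
    ``+/- pi/2`` by the sign of ``i`` (documented convention); ``(0, 0)`` is a
    degenerate sweep and raises.
    """
    if r_ohm == 0.0 and i_ohm == 0.0:
        raise DegenerateSweepError("degenerate sweep: r_ohm == i_ohm == 0")
    magnitude = math.hypot(r_ohm, i_ohm)
    if r_ohm == 0.0:
        phase = math.copysign(math.pi / 2.0, i_ohm)
    else:
        phase = math.atan(i_ohm / r_ohm)
    return magnitude, phase


@dataclass(frozen=True)
class CalibrationFactor:
    """Per-frequency gain factor ``K`` from a known reference resistor."""

    gain_k: float
    reference_ohm: float

    def __post_init__(self) -> None:
        if self.gain_k <= 0:
            raise CalibrationError(f"gain_k must be positive, got {self.gain_k}")

    def impedance(self, magnitude: float) -> float:
        """Calibrated impedance ``Z = 1/(M*K)`` in ohms."""
        if magnitude <= 0:
            raise CalibrationError(f"magnitude must be positive, got {magnitude}")
        return 1.0 / (magnitude * self.gain_k)


def calibrate(reference_magnitude: float, reference_ohm: float) -> CalibrationFactor:
    """Gain factor from one measurement of a known resistor.

    ``K = 1/(M_ref * R_ref)`` so that ``impedance(M_ref) == R_ref`` exactly.
    """
    if reference_magnitude <= 0:
        raise CalibrationError(
            f"reference_magnitude must be positive, got {reference_magnitude}"
        )
    if reference_ohm <= 0:
        raise CalibrationError(f"reference_ohm must be positive, got {reference_ohm}")
    return CalibrationFactor(
        gain_k=1.0 / (reference_magnitude * reference_ohm),
        reference_ohm=reference_ohm,
    )


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelReading:
    """One (frequency, timestamp) cell of a sweep."""

    r_ohm: float
    i_ohm: float
    impedance_ohm: float | None = None  # set after calibration

    @property
    def magnitude(self) -> float:
        return magnitude_phase(self.r_ohm, self.i_ohm)[0]

    @property
    def phase_rad(self) -> float:
        return magnitude_phase(self.r_ohm, self.i_ohm)[1]


@dataclass(frozen=True)
class SweepFrame:
    """One timestamped multifrequency sweep."""

    timestamp: pd.Timestamp
    temperature_c: float
    channels: dict[float, ChannelReading]

    def __post_init__(self) -> None:
        freqs = list(self.channels)
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise FormatError(f"frequencies not strictly increasing at {self.timestamp}")

    @property
    def frequencies_khz(self) -> tuple[float, ...]:
        return tuple(self.channels)

    def calibrated(self, factors: dict[float, CalibrationFactor]) -> "SweepFrame":
        channels = {
            f: replace(c, impedance_ohm=factors[f].impedance(c.magnitude))
            for f, c in self.channels.items()
        }
        return replace(self, channels=channels)


@dataclass
class StressSeries:
    """Time-indexed glucose / lactate / cortisol values.

    ``times`` are hours since the start of monitoring; ``values`` maps each
    stress factor to an equal-length array; ``units`` records assay units
    (serum concentration for glucose/cortisol, muscle concentration for
    lactate).  ``normalized`` marks min-max-scaled series (all in [0, 1]).
    """

    times: np.ndarray
    values: dict[str, np.ndarray]
    units: dict[str, str] = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}
        for k, v in self.values.items():
            if v.shape != self.times.shape:
                raise FormatError(f"factor {k!r}: length {v.size} != times {self.times.size}")
        if self.normalized:
            for k, v in self.values.items():
                if v.size and (np.nanmin(v) < -1e-9 or np.nanmax(v) > 1 + 1e-9):
                    raise FormatError(f"normalized factor {k!r} outside [0, 1]")

    @property
    def factors(self) -> tuple[str, ...]:
        return tuple(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times, **self.values})


@dataclass
class NutrientPanel:
    """Time-indexed muscle nutrient values used for health scoring and weighting."""

    times: np.ndarray
    values: dict[str, np.ndarray]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}
        for k, v in self.values.items():
            if v.shape != self.times.shape:
                raise FormatError(f"nutrient {k!r}: length {v.size} != times {self.times.size}")

    @property
    def nutrients(self) -> tuple[str, ...]:
        return tuple(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times, **self.values})


# ---------------------------------------------------------------------------
# tidy-table conversion
# ---------------------------------------------------------------------------

def frames_to_table(frames: list[SweepFrame]) -> pd.DataFrame:
    """Long-format table, one row per (timestamp, frequency)."""
    rows = []
    for fr in frames:
        for f, ch in fr.channels.items():
            rows.append((fr.timestamp.isoformat(), f, ch.r_ohm, ch.i_ohm, fr.temperature_c))
    return pd.DataFrame(rows, columns=list(SWEEP_COLUMNS))


def table_to_frames(table: pd.DataFrame) -> list[SweepFrame]:
    frames: list[SweepFrame] = []
    for ts, grp in table.groupby("timestamp_iso", sort=False):
        grp = grp.sort_values("frequency_khz")
        channels = {
            float(row.frequency_khz): ChannelReading(float(row.r_ohm), float(row.i_ohm))
            for row in grp.itertuples()
        }
        frames.append(
            SweepFrame(
                timestamp=pd.Timestamp(ts),
                temperature_c=float(grp["temperature_c"].iloc[0]),
                channels=channels,
            )
        )
    return frames


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def _read_csv(path) -> pd.DataFrame:
    # comma or tab; sep=None sniffs the dialect
    try:
        return pd.read_csv(path, sep=None, engine="python")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file without header") from exc


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def write_sweeps(frames: list[SweepFrame], path) -> None:
    frames_to_table(frames).to_csv(path, index=False)


def read_sweeps(path) -> list[SweepFrame]:
    """Parse a sweep CSV; rejects malformed rows with their line numbers.

    Line numbers are 1-based file lines (header is line 1).
    """
    df = _read_csv(path)
    _require_columns(df, SWEEP_COLUMNS, path)
    if df.empty:
        return []
    for col in ("frequency_khz", "r_ohm", "i_ohm", "temperature_c"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(df.index[bad][0]) + 2
            raise FormatError(f"{path}: non-numeric {col} at line {line}")
        df[col] = pd.to_numeric(df[col])
    try:
        stamps = pd.to_datetime(df["timestamp_iso"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: unparseable timestamp_iso: {exc}") from exc
    dup = df.duplicated(subset=["timestamp_iso", "frequency_khz"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise FormatError(f"{path}: duplicate (timestamp, frequency) at line {line}")
    # timestamps must be non-decreasing in file order (blocks per sweep)
    first_rows = df.loc[~df["timestamp_iso"].duplicated(), :]
    block_stamps = stamps[first_rows.index]
    if not block_stamps.is_monotonic_increasing:
        drop = block_stamps.diff() < pd.Timedelta(0)
        line = int(block_stamps.index[drop][0]) + 2
        raise FormatError(f"{path}: non-monotone timestamps at line {line}")
    return table_to_frames(df)


def write_checkpoints(series: StressSeries | NutrientPanel, path) -> None:
    rows = []
    for analyte, vals in series.values.items():
        units = series.units.get(analyte, "")
        for t, v in zip(series.times, vals):
            rows.append((t, analyte, v, units))
    pd.DataFrame(rows, columns=list(CHECKPOINT_COLUMNS)).to_csv(path, index=False)


def read_checkpoints(path) -> StressSeries | NutrientPanel:
    """Parse a checkpoint CSV into a StressSeries or NutrientPanel.

    The container type is inferred from the analyte names: a table whose
    analytes are a subset of the stress factors becomes a StressSeries,
    otherwise a NutrientPanel.
    """
    df = _read_csv(path)
    _require_columns(df, CHECKPOINT_COLUMNS, path)
    bad = pd.to_numeric(df["value"], errors="coerce").isna() & df["value"].notna()
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise FormatError(f"{path}: non-numeric value at line {line}")
    df["value"] = pd.to_numeric(df["value"])
    df["time_h"] = pd.to_numeric(df["time_h"])
    analytes = list(dict.fromkeys(df["analyte"]))
    times = np.sort(df["time_h"].unique())
    values, units = {}, {}
    for a in analytes:
        sub = df[df["analyte"] == a].sort_values("time_h")
        if not np.array_equal(sub["time_h"].to_numpy(dtype=float), times):
            raise FormatError(f"{path}: analyte {a!r} not sampled at the common time grid")
        values[a] = sub["value"].to_numpy(dtype=float)
        u = sub["units"].iloc[0]
        units[a] = "" if pd.isna(u) else str(u)
    cls = StressSeries if set(analytes) <= set(STRESS_FACTORS) else NutrientPanel
    return cls(times=times, values=values, units=units)
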