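"""Seeded synthetic cold-dormancy experiments with known ground truth.

The generator emulates an 84-hour waterless, low-temperature monitoring run:
serum glucose, muscle lactate and serum cortisol rise along saturating
(logistic) trajectories whose rate depends on the temperature zone; muscle
nutrients decay exponentially toward a floor; a subset of sweep frequencies
("coupled" channels) responds affinely to the normalized total stress while
the remaining channels are stress-independent; Gaussian sensor noise and
sparse gross-error spikes of fixed magnitude are injected into the real and
imaginary sweep components, with every spike position recorded so that
downstream gross-error removal can be scored against truth.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .wbia import (
    ChannelReading,
    NutrientPanel,
    StressSeries,
    SweepFrame,
    write_checkpoints,
    write_sweeps,
)

EPOCH = pd.Timestamp("2024-01-01T00:00:00+00:00")


class TempZone(enum.Enum):
    ZONE_1_3 = "1-3"
    ZONE_3_6 = "3-6"


# (initial, saturation, midpoint hour); units per STRESS_UNITS
STRESS_CURVES = {
    "glucose": (3.0, 9.0, 36.0),
    "lactate": (2.0, 14.0, 48.0),
    "cortisol": (20.0, 180.0, 30.0),
}
STRESS_UNITS = {"glucose": "mmol/L", "lactate": "mmol/kg", "cortisol": "ng/mL"}
#: logistic growth rate per zone (1/h); the warmer zone depletes strictly faster
STRESS_RATE = {TempZone.ZONE_1_3: 0.08, TempZone.ZONE_3_6: 0.12}

# (initial, floor, decay rate 1/h in the 1-3 degC zone)
NUTRIENT_CURVES = {
    "glycogen": (6.5, 1.0, 0.030),
    "fat": (45.0, 30.0, 0.012),
    "crude_protein": (180.0, 150.0, 0.008),
    "atp_compounds": (5.2, 1.5, 0.028),
    "ph": (7.2, 6.3, 0.022),
}
NUTRIENT_UNITS = {
    "glycogen": "mg/g",
    "fat": "mg/g",
    "crude_protein": "mg/g",
    "atp_compounds": "umol/g",
    "ph": "pH",
    "muscle_lactate": "mmol/kg",
}
NUTRIENT_ZONE_FACTOR = {TempZone.ZONE_1_3: 1.0, TempZone.ZONE_3_6: 1.4}

#: baseline impedance magnitude (ohm) slope over frequency and coupling gain
MAGNITUDE_BASE_30KHZ = 1300.0
MAGNITUDE_SLOPE_PER_KHZ = -5.0
COUPLING_GAIN_OHM = 80.0
PHASE_BASE_RAD = -0.20
PHASE_SLOPE_PER_KHZ = -0.001
PHASE_COUPLING_RAD = 0.12

#: hourly biomarker checkpoints, 6-hourly nutrient panels (wet-lab cadence)
STRESS_CHECKPOINT_HOURS = 1.0
NUTRIENT_CHECKPOINT_HOURS = 6.0
ASSAY_NOISE_FRACTION = 0.015


@dataclass(frozen=True)
class SimulationConfig:
    duration_hours: float = 84.0
    sample_interval_minutes: float = 5.0
    frequencies_khz: tuple[float, ...] = (30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0)
    coupled_frequencies_khz: tuple[float, ...] = (70.0, 80.0, 90.0, 100.0)
    temp_zone: TempZone = TempZone.ZONE_1_3
    noise_sd: float = 2.0
    gross_error_rate: float = 0.002
    gross_error_magnitude_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_hours <= 0:
            raise ConfigurationError(f"duration_hours must be positive, got {self.duration_hours}")
        if self.sample_interval_minutes <= 0:
            raise ConfigurationError(
                f"sample_interval_minutes must be positive, got {self.sample_interval_minutes}"
            )
        if self.n_samples < 2:
            raise ConfigurationError(
                "duration_hours / sample_interval_minutes yields fewer than 2 samples"
            )
        if not set(self.coupled_frequencies_khz) <= set(self.frequencies_khz):
            raise ConfigurationError("coupled_frequencies_khz not a subset of frequencies_khz")
        if not 0.0 <= self.gross_error_rate <= 1.0:
            raise ConfigurationError(f"gross_error_rate must be in [0,1], got {self.gross_error_rate}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        if self.gross_error_magnitude_sd <= 0:
            raise ConfigurationError(
                f"gross_error_magnitude_sd must be positive, got {self.gross_error_magnitude_sd}"
            )
        if not isinstance(self.temp_zone, TempZone):
            raise ConfigurationError(f"temp_zone must be a TempZone, got {self.temp_zone!r}")

    @property
    def n_samples(self) -> int:
        return int(math.floor(self.duration_hours * 60.0 / self.sample_interval_minutes)) + 1

    @property
    def sample_times_h(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sample_interval_minutes / 60.0


@dataclass
class GroundTruth:
    """Noiseless trajectories and injection bookkeeping for one simulated run."""

    stress_series: StressSeries  # full sampling grid, noiseless
    nutrient_panel: NutrientPanel  # full sampling grid, noiseless
    outlier_positions: set[tuple[str, float, str]]  # (timestamp_iso, freq, 'r'|'i')
    coupling_coefficients: dict[float, float]
    stress_norm: np.ndarray = field(default_factory=lambda: np.empty(0))
    clean_channels: dict[tuple[float, str], np.ndarray] = field(default_factory=dict)


def _logistic(t: np.ndarray, lo: float, hi: float, rate: float, mid: float) -> np.ndarray:
    return lo + (hi - lo) / (1.0 + np.exp(-rate * (t - mid)))


def _stress_trajectories(cfg: SimulationConfig, rng: np.random.Generator):
    """Noiseless per-factor logistic curves with mild per-run jitter."""
    t = cfg.sample_times_h
    base_rate = STRESS_RATE[cfg.temp_zone]
    curves, norms = {}, []
    for factor, (lo, hi, mid) in STRESS_CURVES.items():
        rate = base_rate * math.exp(rng.normal(0.0, 0.08))
        mid_j = mid + rng.normal(0.0, 2.0)
        curves[factor] = _logistic(t, lo, hi, rate, mid_j)
        norms.append((curves[factor] - lo) / (hi - lo))
    return curves, np.mean(norms, axis=0)


def _nutrient_trajectories(cfg: SimulationConfig, lactate: np.ndarray) -> dict[str, np.ndarray]:
    t = cfg.sample_times_h
    zf = NUTRIENT_ZONE_FACTOR[cfg.temp_zone]
    out = {
        name: floor + (init - floor) * np.exp(-zf * rate * t)
        for name, (init, floor, rate) in NUTRIENT_CURVES.items()
    }
    out["muscle_lactate"] = lactate.copy()
    return out


def _temperature(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    t = cfg.sample_times_h
    if cfg.temp_zone is TempZone.ZONE_1_3:
        mean, amp, lo, hi = 2.0, 0.6, 1.0, 3.0
    else:
        mean, amp, lo, hi = 4.5, 0.9, 3.0, 6.0
    temp = mean + amp * np.sin(2.0 * np.pi * t / 24.0) + rng.normal(0.0, 0.05, t.size)
    return np.clip(temp, lo, hi)


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[list[SweepFrame], StressSeries, NutrientPanel, GroundTruth]:
    """Run one seeded experiment.

    Returns the sweep sequence (noisy, with gross errors), the hourly
    biomarker checkpoint series and 6-hourly nutrient panel (with small assay
    noise), and the GroundTruth carrying the noiseless trajectories, the
    recorded spike positions and the per-frequency coupling gains.
    """
    rng = np.random.default_rng(config.seed)
    t = config.sample_times_h
    stress, stress_norm = _stress_trajectories(config, rng)
    nutrients = _nutrient_trajectories(config, stress["lactate"])
    temperature = _temperature(config, rng)

    coupling = {
        f: (COUPLING_GAIN_OHM if f in config.coupled_frequencies_khz else 0.0)
        for f in config.frequencies_khz
    }

    clean_channels: dict[tuple[float, str], np.ndarray] = {}
    noisy_channels: dict[tuple[float, str], np.ndarray] = {}
    outliers: set[tuple[str, float, str]] = set()
    stamps = [EPOCH + pd.Timedelta(minutes=config.sample_interval_minutes * i) for i in range(t.size)]
    iso = [s.isoformat() for s in stamps]

    for f in config.frequencies_khz:
        mag = MAGNITUDE_BASE_30KHZ + MAGNITUDE_SLOPE_PER_KHZ * (f - 30.0) + coupling[f] * stress_norm
        phase = PHASE_BASE_RAD + PHASE_SLOPE_PER_KHZ * (f - 30.0) + (
            PHASE_COUPLING_RAD * stress_norm if coupling[f] else 0.0
        )
        for channel, clean in (("r", mag * np.cos(phase)), ("i", mag * np.sin(phase))):
            noisy = clean + rng.normal(0.0, config.noise_sd, t.size)
            if config.gross_error_rate > 0 and config.noise_sd > 0:
                hits = rng.random(t.size) < config.gross_error_rate
                signs = rng.choice([-1.0, 1.0], size=t.size)
                spike = config.gross_error_magnitude_sd * config.noise_sd
                # the spike replaces the Gaussian noise at its sample, so the
                # deviation from the noiseless value is exactly +/- spike
                noisy[hits] = clean[hits] + signs[hits] * spike
                for k in np.flatnonzero(hits):
                    outliers.add((iso[k], float(f), channel))
            clean_channels[(float(f), channel)] = clean
            noisy_channels[(float(f), channel)] = noisy

    frames = []
    for k, stamp in enumerate(stamps):
        channels = {
            float(f): ChannelReading(
                r_ohm=float(noisy_channels[(float(f), "r")][k]),
                i_ohm=float(noisy_channels[(float(f), "i")][k]),
            )
            for f in config.frequencies_khz
        }
        frames.append(SweepFrame(timestamp=stamp, temperature_c=float(temperature[k]), channels=channels))

    # sparse checkpoint tables with small assay noise
    cp_t = np.arange(0.0, config.duration_hours + 1e-9, STRESS_CHECKPOINT_HOURS)
    stress_cp = {}
    for factor, (lo, hi, _) in STRESS_CURVES.items():
        clean = np.interp(cp_t, t, stress[factor])
        stress_cp[factor] = clean + rng.normal(0.0, ASSAY_NOISE_FRACTION * (hi - lo), cp_t.size)
    stress_series = StressSeries(times=cp_t, values=stress_cp, units=dict(STRESS_UNITS))

    nu_t = np.arange(0.0, config.duration_hours + 1e-9, NUTRIENT_CHECKPOINT_HOURS)
    nutrient_cp = {}
    for name, series in nutrients.items():
        clean = np.interp(nu_t, t, series)
        span = float(series.max() - series.min()) or 1.0
        nutrient_cp[name] = clean + rng.normal(0.0, ASSAY_NOISE_FRACTION * span, nu_t.size)
    nutrient_panel = NutrientPanel(times=nu_t, values=nutrient_cp, units=dict(NUTRIENT_UNITS))

    truth = GroundTruth(
        stress_series=StressSeries(times=t, values=stress, units=dict(STRESS_UNITS)),
        nutrient_panel=NutrientPanel(times=t, values=nutrients, units=dict(NUTRIENT_UNITS)),
        outlier_positions=outliers,
        coupling_coefficients=coupling,
        stress_norm=stress_norm,
        clean_channels=clean_channels,
    )
    return frames, stress_series, nutrient_panel, truth


# ---------------------------------------------------------------------------
# mortality
# ---------------------------------------------------------------------------

#: observed cohort schedule used as the deterministic fixture:
#: 25 fish, deaths at 60/72/78/84 h
FIXTURE_DEATHS = ((60.0, 2), (72.0, 3), (78.0, 3), (84.0, 3))
RANDOM_CHECKPOINT_HOURS = (12.0, 24.0, 36.0, 48.0, 60.0, 72.0, 78.0, 84.0)
DEATH_MIDPOINT_H = {TempZone.ZONE_1_3: 88.0, TempZone.ZONE_3_6: 82.0}
DEATH_SCALE_H = 6.0


def death_schedule(
    config: SimulationConfig,
    cohort_size: int,
    mode: str = "fixture",
    hazard_scale: float = 1.0,
) -> list[tuple[float, int]]:
    """Cumulative deaths per observation checkpoint.

    ``mode='fixture'`` replays the deterministic observed schedule (clipped to
    the cohort size); ``mode='random'`` draws per-fish logistic death times
    whose hazard grows with time and temperature zone, scaled by
    ``hazard_scale`` (0 disables mortality), deterministic for a given seed.
    """
    if cohort_size < 1:
        raise ConfigurationError(f"cohort_size must be >= 1, got {cohort_size}")
    if mode == "fixture":
        out, cum = [], 0
        for hour, d in FIXTURE_DEATHS:
            cum = min(cum + d, cohort_size)
            out.append((hour, cum))
        return out
    if mode != "random":
        raise ConfigurationError(f"unknown death_schedule mode {mode!r}")
    rng = np.random.default_rng(config.seed + 1)
    u = rng.random(cohort_size)
    mid = DEATH_MIDPOINT_H[config.temp_zone]
    out = []
    for cp in RANDOM_CHECKPOINT_HOURS:
        if cp > config.duration_hours + 1e-9:
            break
        frac = hazard_scale / (1.0 + math.exp(-(cp - mid) / DEATH_SCALE_H))
        out.append((cp, int(np.sum(u < frac))))
    return out


# ---------------------------------------------------------------------------
# on-disk experiment layout
# ---------------------------------------------------------------------------

def write_simulation(config: SimulationConfig, outdir) -> dict:
    """Write one simulated run (sweeps, checkpoints, ground truth, manifest)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames, stress, nutrients, truth = simulate_experiment(config)
    write_sweeps(frames, outdir / "sweeps.csv")
    write_checkpoints(stress, outdir / "stress.csv")
    write_checkpoints(nutrients, outdir / "nutrients.csv")
    write_checkpoints(truth.stress_series, outdir / "truth_stress.csv")
    write_checkpoints(truth.nutrient_panel, outdir / "truth_nutrients.csv")
    pd.DataFrame(
        sorted(truth.outlier_positions),
        columns=["timestamp_iso", "frequency_khz", "channel"],
    ).to_csv(outdir / "truth_outliers.csv", index=False)
    manifest = {
        "seed": config.seed,
        "config": {
            "duration_hours": config.duration_hours,
            "sample_interval_minutes": config.sample_interval_minutes,
            "frequencies_khz": list(config.frequencies_khz),
            "coupled_frequencies_khz": list(config.coupled_frequencies_khz),
            "temp_zone": config.temp_zone.value,
            "noise_sd": config.noise_sd,
            "gross_error_rate": config.gross_error_rate,
            "gross_error_magnitude_sd": config.gross_error_magnitude_sd,
        },
        "files": [
            "sweeps.csv",
            "stress.csv",
            "nutrients.csv",
            "truth_stress.csv",
            "truth_nutrients.csv",
            "truth_outliers.csv",
        ],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
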