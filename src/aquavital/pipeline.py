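"""End-to-end pipeline: sweeps + checkpoints -> health assessment run directory.

Stage order: GRA weight allocation -> gross-error removal -> Savitzky–Golay
smoothing -> spline completion of biomarker checkpoints -> MIC screening of
WBIA features -> hybrid stress estimation per factor -> total-stress
normalization -> ZMF health mapping and level classification.  Every stage
writes its artifact into the run directory and the manifest records a SHA-256
digest per file, so an identical config + seed reproduces identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, estimator, health, preprocessing, synthetic, wbia
from .errors import AquavitalError, PipelineError

logger = logging.getLogger(__name__)

STAGE_EXIT_CODES = {
    "load": 3,
    "weights": 4,
    "preprocess": 5,
    "association": 6,
    "model": 7,
    "assessment": 8,
}


@dataclass
class PipelineConfig:
    sweeps_path: str | None = None
    stress_path: str | None = None
    nutrients_path: str | None = None
    zone: synthetic.TempZone = synthetic.TempZone.ZONE_1_3
    seed: int = 0
    simulation: synthetic.SimulationConfig | None = None  # used when sweeps_path is None
    savgol: preprocessing.SavGolConfig = field(default_factory=preprocessing.SavGolConfig)
    clean_significance: float = preprocessing.CLEAN_SIGNIFICANCE
    rho: float = 0.5
    mic_threshold: float = 0.9
    b_rule: association.BRule = association.BRule.FACTOR_0_6
    mic_subsample: int = 150
    model: estimator.HybridModelConfig = field(default_factory=estimator.HybridModelConfig)
    window_length: int = 15
    horizons_min: tuple[float, ...] = (5.0,)
    targets: tuple[str, ...] = wbia.STRESS_FACTORS
    log_level: str = "INFO"


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_echo(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (synthetic.TempZone, association.BRule)):
            return obj.value
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    out = {}
    for f in dataclasses.fields(config):
        out[f.name] = enc(getattr(config, f.name))
    return out


def _feature_series(frames: list[wbia.SweepFrame]) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Impedance-magnitude and phase series per frequency, plus temperature and times (h)."""
    freqs = frames[0].frequencies_khz
    t0 = frames[0].timestamp
    times_h = np.array([(fr.timestamp - t0).total_seconds() / 3600.0 for fr in frames])
    features: dict[str, np.ndarray] = {}
    for f in freqs:
        mags, phases = [], []
        for fr in frames:
            ch = fr.channels[f]
            mags.append(ch.magnitude)
            phases.append(ch.phase_rad)
        features[association.feature_label("impedance", f)] = np.asarray(mags)
        features[association.feature_label("phase", f)] = np.asarray(phases)
    temp = np.array([fr.temperature_c for fr in frames])
    return features, temp, times_h


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute the full pipeline; returns the run directory.

    Any stage failure raises PipelineError naming the stage and the input
    that provoked it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": _config_echo(config), "files": {}}
    written: list[Path] = []

    def _write_df(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        written.append(path)

    def _write_json(obj, name: str) -> None:
        path = outdir / name
        path.write_text(json.dumps(obj, indent=2, default=str))
        written.append(path)

    stage = "load"
    try:
        if config.sweeps_path is None:
            sim = config.simulation or synthetic.SimulationConfig(
                seed=config.seed, temp_zone=config.zone
            )
            frames, stress, nutrients, _ = synthetic.simulate_experiment(sim)
        else:
            frames = wbia.read_sweeps(config.sweeps_path)
            stress = wbia.read_checkpoints(config.stress_path)
            if not isinstance(stress, wbia.StressSeries):
                raise PipelineError(f"stage load: {config.stress_path} is not a stress table")
            nutrients = None
            if config.nutrients_path is not None:
                nutrients = wbia.read_checkpoints(config.nutrients_path)
        if not frames:
            raise AquavitalError(f"no sweeps in {config.sweeps_path}")

        stage = "weights"
        if nutrients is not None:
            weights = association.allocate_stress_weights(stress, nutrients, rho=config.rho)
        else:
            weights = association.REFERENCE_WEIGHTS
            logger.warning("no nutrient data supplied; substituting the reference "
                           "default stress weights %s", weights.weights)
        _write_json({"weights": weights.weights, "relational_grades": weights.relational_grades,
                     "rho": config.rho, "default_substituted": nutrients is None},
                    "weights.json")

        stage = "preprocess"
        cleaned, removed = preprocessing.clean_sweeps(
            frames, sg=config.savgol, significance_level=config.clean_significance
        )
        wbia.write_sweeps(cleaned, outdir / "clean.csv")
        written.append(outdir / "clean.csv")
        _write_df(removed, "removed.csv")

        stage = "association"
        features, temperature, times_h = _feature_series(cleaned)
        # complete sparse checkpoints to the sweep grid (no extrapolation)
        in_range = (times_h >= stress.times[0]) & (times_h <= stress.times[-1])
        times_q = times_h[in_range]
        stress_dense = {
            f: preprocessing.spline_complete(list(zip(stress.times, v)), times_q)
            for f, v in stress.values.items()
        }
        features_q = {k: v[in_range] for k, v in features.items()}
        mic_matrix = association.compute_mic_matrix(
            features_q, stress_dense, b_rule=config.b_rule,
            subsample=config.mic_subsample, seed=config.seed,
        )
        selected = association.screen_features(mic_matrix, config.mic_threshold, rule="all")
        if not selected:
            selected = association.screen_features(mic_matrix, config.mic_threshold, rule="any")
            if selected:
                logger.warning("no feature passed the all-factors MIC rule; "
                               "falling back to the any-factor rule")
        if not selected:
            selected = list(mic_matrix.table.index)
            logger.warning("no feature reached MIC >= %.2f; using all features",
                           config.mic_threshold)
        _write_json({"threshold": config.mic_threshold, "b_rule": config.b_rule.value,
                     "mic": {k: dict(v) for k, v in mic_matrix.table.iterrows()},
                     "selected": selected}, "features.json")

        stage = "model"
        fmat = np.column_stack([features_q[k] for k in selected] + [temperature[in_range]])
        forecast_rows = []
        factor_points: dict[str, dict[float, np.ndarray]] = {}
        bounds = {}
        interval_min = (times_q[1] - times_q[0]) * 60.0 if times_q.size > 1 else 5.0
        for factor in config.targets:
            target = stress_dense[factor]
            bounds[factor] = (float(target.min()), float(target.max()))
            factor_points[factor] = {}
            for hmin in config.horizons_min:
                spec = estimator.WindowSpec(
                    window_length=config.window_length,
                    horizon_steps=estimator.horizon_steps(hmin, interval_min),
                    feature_labels=tuple(selected) + ("temperature",),
                    target=factor,
                )
                windowed = estimator.build_windows(fmat, target, spec)
                model = estimator.train_hybrid(windowed, config.model)
                fc = estimator.forecast(model, factor, hmin)
                factor_points[factor][hmin] = (fc.target_index, fc.point)
                for i, idx in enumerate(fc.target_index):
                    forecast_rows.append((times_q[idx], factor, fc.point[i],
                                          fc.lower[i], fc.upper[i], hmin))
        _write_df(pd.DataFrame(forecast_rows,
                               columns=["time_h", "factor", "point", "lower95",
                                        "upper95", "horizon_min"]),
                  "forecast.csv")

        stage = "assessment"
        h0 = config.horizons_min[0]
        idx0 = factor_points[config.targets[0]][h0][0]
        rows = []
        s_total_hist: list[float] = []
        zone = config.zone
        for j, idx in enumerate(idx0):
            at = {f: float(factor_points[f][h0][1][j]) for f in config.targets}
            s_tot = health.total_stress(at, _subset_weights(association.REFERENCE_WEIGHTS
                                                            if nutrients is None else weights,
                                                            config.targets), bounds)
            s_total_hist.append(s_tot)
            avg = float(np.mean(s_total_hist))
            a = health.assess(times_q[idx], avg, zone)
            rows.append((a.time_h, s_tot, avg, a.hq, a.level.name))
        _write_df(pd.DataFrame(rows, columns=["time_h", "total_stress",
                                              "avg_total_stress", "hq", "level"]),
                  "assessment.csv")
    except AquavitalError as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage}: {exc}") from exc

    for path in written:
        manifest["files"][path.name] = _digest(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


def _subset_weights(weights: association.WeightVector, targets) -> association.WeightVector:
    if set(targets) == set(weights.weights):
        return weights
    sub = {f: weights.weights[f] for f in targets}
    total = sum(sub.values())
    return association.WeightVector(
        weights={f: w / total for f, w in sub.items()},
        relational_grades={f: weights.relational_grades[f] for f in targets},
    )
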