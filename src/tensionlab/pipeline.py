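"""Pipeline orchestration from a single YAML run configuration.

A run config selects stages and parameters; every run writes its outputs, a
resolved copy of the configuration, and a JSON run report (seed, timings,
package version) into the output directory, so results are reproducible
from the artifacts alone.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import activity as act
from . import io as tio
from . import synthetic as synth
from .optimizer import evaluate_config, stepwise_search
from .trend_model import WindowConfig, predict_tension

KNOWN_KEYS = {"out_dir", "seed", "stages", "synth", "model", "optimize", "activity"}
KNOWN_STAGES = ("synth", "predict", "optimize", "activity")


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    stages: tuple = KNOWN_STAGES
    synth: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    optimize: dict = field(default_factory=dict)
    activity: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - KNOWN_KEYS
        if unknown:
            raise tio.SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
        if "out_dir" not in raw:
            raise tio.SchemaError(f"{path}: out_dir is required")
        stages = tuple(raw.get("stages", KNOWN_STAGES))
        bad = [s for s in stages if s not in KNOWN_STAGES]
        if bad:
            raise tio.SchemaError(f"{path}: unknown stages {bad}")
        return cls(out_dir=Path(raw["out_dir"]), seed=int(raw.get("seed", 0)),
                   stages=stages, synth=raw.get("synth", {}) or {},
                   model=raw.get("model", {}) or {},
                   optimize=raw.get("optimize", {}) or {},
                   activity=raw.get("activity", {}) or {})


def run_pipeline(config_path) -> int:
    """Execute the configured stages in dependency order. Returns exit status."""
    try:
        cfg = RunConfig.from_yaml(config_path)
    except (tio.SchemaError, OSError) as exc:
        print(f"config error: {exc}")
        return 2
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    report = {"version": __version__, "seed": cfg.seed, "timings_s": {}, "stages": []}
    t_all = time.perf_counter()

    duration = float(cfg.synth.get("duration_s", 120.0))
    n_raters = int(cfg.synth.get("n_raters", 25))
    model_cfg = (tio.window_config_from_dict(cfg.model) if cfg.model
                 else WindowConfig.reference())

    feats = onsets = latent = ratings = None
    if "synth" in cfg.stages:
        t0 = time.perf_counter()
        feats, onsets = synth.generate_features(duration, seed=cfg.seed)
        latent = synth.generate_latent_tension(feats, model_cfg)
        ratings = synth.simulate_raters(latent, n=n_raters, seed=cfg.seed + 1)
        from .cli import _on_common_grid
        tio.write_features(_on_common_grid(feats), out / "features.csv")
        tio.write_onsets(onsets, out / "onsets.csv")
        tio.write_ratings(ratings, out / "ratings.csv")
        beats = onsets.beats()["clock_time_s"]
        pd.DataFrame({"beat_time_s": beats}).to_csv(out / "beats.csv", index=False,
                                                    float_format="%.6f")
        report["timings_s"]["synth"] = time.perf_counter() - t0
        report["stages"].append("synth")

    if feats is None:
        feats = tio.read_features(out / "features.csv")
        ratings = tio.read_ratings(out / "ratings.csv")

    if "predict" in cfg.stages:
        t0 = time.perf_counter()
        pred = predict_tension(feats, model_cfg)
        pd.DataFrame({"time_s": pred.times, "F_ten": pred.F_ten}).to_csv(
            out / "prediction.csv", index=False, float_format="%.6f")
        report["timings_s"]["predict"] = time.perf_counter() - t0
        report["stages"].append("predict")

    if "optimize" in cfg.stages:
        t0 = time.perf_counter()
        beats = pd.read_csv(out / "beats.csv")["beat_time_s"].to_numpy(dtype=float)
        target = tio.mean_rating_series(ratings if isinstance(ratings, pd.DataFrame)
                                        else tio.read_ratings(out / "ratings.csv"))
        grid_max = float(cfg.optimize.get("grid_max_s", 20.0))
        res = stepwise_search(feats, target, beats, grid_max=grid_max,
                              grid_step=float(cfg.optimize.get("grid_step_s", 0.5)),
                              lag=float(cfg.optimize.get("lag_s", 2.0)))
        tio.write_json({"windows": res.windows_dict(), "train_rho": res.train_rho,
                        "low_confidence": res.low_confidence},
                       out / "optimization.json")
        report["timings_s"]["optimize"] = time.perf_counter() - t0
        report["stages"].append("optimize")

    if "activity" in cfg.stages:
        t0 = time.perf_counter()
        mat = synth.ratings_matrix(ratings if isinstance(ratings, pd.DataFrame)
                                   else tio.read_ratings(out / "ratings.csv"))
        frame_s = float(cfg.activity.get("frame_s", 1.0))
        thr = float(cfg.activity.get("threshold", 1.0))
        inc = act.processes_from_collection(mat, "increase", thr)
        dec = act.processes_from_collection(mat, "decrease", thr)
        summary = {
            "activity_rate_inc": act.activity_rate(inc, frame_s),
            "activity_rate_dec": act.activity_rate(dec, frame_s),
            "coordination_inc": act.coordination_score(inc, frame_s).score,
            "coordination_dec": act.coordination_score(dec, frame_s).score,
            "coordination_alt": act.alternation_score(inc, dec, frame_s).score,
            **act.collection_summary(mat),
        }
        tio.write_json(summary, out / "activity_summary.json")
        report["timings_s"]["activity"] = time.perf_counter() - t0
        report["stages"].append("activity")

    report["timings_s"]["total"] = time.perf_counter() - t_all
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump({"out_dir": str(cfg.out_dir), "seed": cfg.seed,
                        "stages": list(cfg.stages), "synth": cfg.synth,
                        "model": cfg.model, "optimize": cfg.optimize,
                        "activity": cfg.activity}, fh, sort_keys=False)
    tio.write_json(report, out / "run_report.json")
    return 0
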