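"""CSV/JSON/YAML readers and writers for all pipeline artifacts.

All interchange is plain text: ratings and features as wide CSV with a
``time_s`` column, onsets and chords as long CSV, configurations as YAML,
results as JSON. Times are serialized with 6 decimal places; missing values
round-trip as empty fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import ChordTable, FeatureSeries
from .timebase import OnsetTable, SampledSeries, metrical_position
from .trend_model import WINDOW_GROUPS, WindowConfig, Windows

FLOAT_FMT = "%.6f"


class SchemaError(ValueError):
    pass


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _check_uniform_10hz(time_s: np.ndarray, path, period: float = 0.1) -> None:
    d = np.diff(time_s)
    if not np.allclose(d, period, atol=1e-6):
        bad = int(np.argmax(~np.isclose(d, period, atol=1e-6)))
        raise SchemaError(f"{path}: non-uniform time column near row {bad + 1} "
                          f"(step {d[bad]:.6f}, expected {period})")


# -- ratings ---------------------------------------------------------------

def read_ratings(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["time_s"], path)
    raters = [c for c in df.columns if c != "time_s"]
    if not raters:
        raise SchemaError(f"{path}: no rater columns")
    _check_uniform_10hz(df["time_s"].to_numpy(dtype=float), path)
    return df


def write_ratings(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def mean_rating_series(df: pd.DataFrame) -> SampledSeries:
    t = df["time_s"].to_numpy(dtype=float)
    vals = df.drop(columns=["time_s"]).to_numpy(dtype=float).mean(axis=1)
    return SampledSeries(float(t[0]), float(np.round(t[1] - t[0], 9)), vals)


# -- onsets ----------------------------------------------------------------

ONSET_COLUMNS = ("clock_time_s", "measure", "position_num", "position_den",
                 "voice", "midi_pitch", "is_beat")


def read_onsets(path) -> OnsetTable:
    df = pd.read_csv(path)
    _require_columns(df, ONSET_COLUMNS, path)
    rows = pd.DataFrame({
        "clock_time_s": df["clock_time_s"].astype(float),
        "measure": df["measure"].astype(int),
        "position": [metrical_position(0, int(n), int(d))
                     for n, d in zip(df["position_num"], df["position_den"])],
        "voice": df["voice"],
        "midi_pitch": df["midi_pitch"],
        "is_beat": df["is_beat"].astype(bool),
    })
    return OnsetTable(rows)


def write_onsets(table: OnsetTable, path) -> None:
    from fractions import Fraction
    df = table.frame
    frs = [Fraction(p).limit_denominator(36) for p in df["position"]]
    out = pd.DataFrame({
        "clock_time_s": df["clock_time_s"],
        "measure": df["measure"],
        "position_num": [f.numerator for f in frs],
        "position_den": [f.denominator for f in frs],
        "voice": df["voice"],
        "midi_pitch": df["midi_pitch"],
        "is_beat": df["is_beat"].astype(bool),
    })
    out.to_csv(path, index=False, float_format=FLOAT_FMT)


# -- features --------------------------------------------------------------

def read_features(path) -> dict[str, FeatureSeries]:
    df = pd.read_csv(path)
    _require_columns(df, ["time_s"], path)
    t = df["time_s"].to_numpy(dtype=float)
    period = float(np.round(t[1] - t[0], 9))
    out = {}
    for col in df.columns:
        if col == "time_s":
            continue
        out[col] = FeatureSeries(col, SampledSeries(float(t[0]), period,
                                                    df[col].to_numpy(dtype=float)))
    if not out:
        raise SchemaError(f"{path}: no feature columns")
    return out


def write_features(features: dict[str, FeatureSeries], path) -> None:
    lengths = {f.series.values.size for f in features.values()}
    starts = {round(f.series.start, 9) for f in features.values()}
    if len(lengths) != 1 or len(starts) != 1:
        raise ValueError("features must share one sampling grid to be written wide")
    any_f = next(iter(features.values())).series
    df = pd.DataFrame({"time_s": any_f.times})
    for name, f in features.items():
        df[name] = f.series.values
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_chords(path) -> ChordTable:
    df = pd.read_csv(path)
    _require_columns(df, ChordTable.REQUIRED, path)
    return ChordTable(df)


# -- window config ---------------------------------------------------------

def window_config_from_dict(d: dict) -> WindowConfig:
    known = {"windows", "beta", "step_s", "decay"}
    unknown = set(d) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    wins = {}
    for g, spec in d.get("windows", {}).items():
        if g not in WINDOW_GROUPS:
            raise SchemaError(f"unknown window group {g!r}")
        wins[g] = Windows(att=float(spec["att"]), mem=float(spec["mem"]))
    for g in WINDOW_GROUPS:
        wins.setdefault(g, Windows(att=0.0, mem=0.0))
    decay_spec = d.get("decay", {"kind": "geometric", "ratio": 0.75})
    decay = (("uniform",) if decay_spec.get("kind") == "uniform"
             else ("geometric", float(decay_spec.get("ratio", 0.75))))
    return WindowConfig(windows=wins, beta=float(d.get("beta", 5.0)),
                        h=float(d.get("step_s", 0.25)), decay=decay)


def read_window_config(path) -> WindowConfig:
    with open(path) as fh:
        return window_config_from_dict(yaml.safe_load(fh))


def write_window_config(config: WindowConfig, path) -> None:
    d = {
        "windows": {g: {"att": w.att, "mem": w.mem}
                    for g, w in config.windows.items()},
        "beta": config.beta,
        "step_s": config.h,
        "decay": ({"kind": "uniform"} if config.decay[0] == "uniform"
                  else {"kind": "geometric", "ratio": config.decay[1]}),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))
    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
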