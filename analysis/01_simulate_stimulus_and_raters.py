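#!/usr/bin/env python
"""Simulate the study's data: a stimulus feature set, a latent tension curve,
a coordinated 25-rater collection, and a matched independent (null) collection.

The stimulus is 235 s long (the duration of the performed song), features are
Z-scored, the latent curve is the trend-salience model run with the
reference per-feature windows (long harmony timescales, short loudness/
tempo/onset timescales), and raters track it through individual lags, gains,
offsets, intermittent slider movement and noise at 10 Hz on a 0-100 slider.

Writes results/data/{features,onsets,ratings_coordinated,ratings_null,beats}.csv
and the latent curve.
"""

import sys
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from tensionlab import io as tio
from tensionlab import synthetic as synth
from tensionlab.trend_model import WindowConfig

SEED = 20260922
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = WindowConfig.reference()

    feats, onsets = synth.generate_features(235.0, seed=SEED)
    latent = synth.generate_latent_tension(feats, cfg)
    coordinated = synth.simulate_raters(latent, n=25, seed=SEED + 1)
    null = synth.simulate_independent_raters(235.0, n=25,
                                             event_rate_per_frame=0.2,
                                             seed=SEED + 2)

    m = min(f.series.values.size for f in feats.values())
    feats_aligned = {n: replace(f, series=replace(f.series, values=f.series.values[:m]))
                     for n, f in feats.items()}
    tio.write_features(feats_aligned, OUT / "features.csv")
    tio.write_onsets(onsets, OUT / "onsets.csv")
    tio.write_ratings(coordinated, OUT / "ratings_coordinated.csv")
    tio.write_ratings(null, OUT / "ratings_null.csv")
    beats = onsets.beats()["clock_time_s"].drop_duplicates()
    pd.DataFrame({"beat_time_s": beats}).to_csv(OUT / "beats.csv", index=False,
                                                float_format="%.6f")
    pd.DataFrame({"time_s": latent.times, "latent": latent.values}).to_csv(
        OUT / "latent_tension.csv", index=False, float_format="%.6f")
    tio.write_window_config(cfg, OUT / "generating_windows.yaml")

    print(f"stimulus: {m} feature samples at 10 Hz, {beats.size} beats")
    print(f"latent tension range: [{latent.values.min():.1f}, "
          f"{latent.values.max():.1f}] on the 0-100 slider")
    print(f"coordinated raters: {coordinated.shape[1] - 1}, "
          f"null raters: {null.shape[1] - 1}")
    print(f"wrote data to {OUT}")


if __name__ == "__main__":
    main()
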