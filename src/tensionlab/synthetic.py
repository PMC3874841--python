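"""Synthetic stimuli and rater populations for end-to-end testing.

The generators emulate the statistical shape of a continuous tension-rating
experiment: a through-composed stimulus described by onset tables and feature
series; a latent tension curve produced by the trend-salience model itself
(so window-recovery tests have a known ground truth); a population of raters
who track that latent curve through individual response lags (1-3 s), gains,
offsets, intermittent slider movement and noise, on a 0-100 slider sampled
at 10 Hz with a ~10 s orienting period; and a null population whose rating
changes are independent stationary renewal processes with no shared timing.

These are stylized surrogates: they reproduce sampling rate, scale, lags,
event rates and (for the coordinated population) a shared latent drive, but
not verse structure, lyric semantics, or feature cross-correlations of real
music beyond a single controllable common component.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd

from . import features as feat
from .timebase import OnsetTable, SampledSeries, TICKS_PER_MEASURE
from .trend_model import WindowConfig, predict_tension

FS = 10.0  # Hz rating clock
SLIDER_RANGE = (0.0, 100.0)
BEATS_PER_MEASURE = 3


@dataclass(frozen=True)
class RaterProfile:
    """Response characteristics of one simulated rater.

    Raters do not track the latent tension continuously: the slider holds
    until the tracked value drifts more than ``move_threshold`` rating units
    away, after which the rater corrects it (with per-sample probability
    ``move_probability``, so corrections lag by a few hundred ms), landing
    with ``noise_sd`` of motor noise. This produces the stepwise slider
    trajectories and sparse discrete rating-change events (on the order of
    0.2 active 1 s frames per direction) seen in real collections.
    """
    lag_s: float = 2.0            # response delay, drawn from 1-3 s
    gain: float = 1.0
    offset: float = 0.0           # rating units
    move_probability: float = 0.35  # per-sample chance of acting on a drift
    move_threshold: float = 3.0   # dead zone before the rater bothers to move
    noise_sd: float = 1.0         # rating units, on movements
    drift_sd: float = 8.0         # slow idiosyncratic drift (shape disagreement)
    orienting_s: float = 10.0     # ramp from the interface start position


def _smooth_noise(rng: np.random.Generator, n: int, scale_samples: float) -> np.ndarray:
    """Unit-variance smooth noise via Gaussian-kernel moving average."""
    half = int(4 * scale_samples)
    kern = np.exp(-0.5 * (np.arange(-half, half + 1) / scale_samples) ** 2)
    kern /= kern.sum()
    x = np.convolve(rng.standard_normal(n + 2 * half), kern, mode="same")[half:-half]
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_onsets(duration_s: float, seed: int, mean_bpm: float = 60.0,
                    rubato: float = 0.08) -> OnsetTable:
    """Beat, subdivision and bass onsets with smooth expressive timing.

    Three beats per measure; the melody sounds on beats and on a variable
    number (0-2) of subdivisions per beat, the bass on downbeats, an inner
    voice only over the middle third of the piece (mimicking a voice active
    in a single phrase). ``rubato`` scales a smooth modulation of the beat
    period (correlation time about two beats) plus 1% motor jitter; real
    rubato is smooth, not white, so tempo slopes stay on a musical scale.
    """
    rng = np.random.default_rng(seed)
    period = 60.0 / mean_bpm
    n_guess = int(duration_s / period * 1.3) + 8
    mod = 1.0 + rubato * _smooth_noise(rng, n_guess, 2.0) \
        + 0.01 * rng.standard_normal(n_guess)
    ibis = period * np.clip(mod, 0.5, 1.6)
    beat_times = np.concatenate([[0.0], np.cumsum(ibis)])
    beat_times = beat_times[beat_times < duration_s]
    n_beats = beat_times.size
    rows = []
    mel = 64
    for b in range(n_beats):
        measure, beat_in_m = divmod(b, BEATS_PER_MEASURE)
        pos = beat_in_m / BEATS_PER_MEASURE
        # mean-reverting melodic contour around the register center
        step = int(rng.integers(-2, 3)) + (1 if mel < 62 else 0) - (1 if mel > 72 else 0)
        mel = int(np.clip(mel + step, 55, 79))
        rows.append((beat_times[b], measure, pos, "melody", mel, True))
        if beat_in_m == 0:
            bass = int(np.clip(40 + rng.integers(0, 12), 36, 59))
            rows.append((beat_times[b], measure, pos, "bass", bass, False))
        if b + 1 < n_beats:
            # 0-2 subdivisions per beat: positions land on the 1/36 grid
            # (halves -> 1/6 measure offsets, triplets -> 1/9 and 2/9)
            nsub = int(rng.choice([0, 1, 1, 2]))
            for s in range(1, nsub + 1):
                frac = s / (nsub + 1)
                sub_t = beat_times[b] + frac * (beat_times[b + 1] - beat_times[b])
                sub_pos = pos + frac / BEATS_PER_MEASURE
                mel2 = int(np.clip(mel + rng.integers(-3, 4), 55, 79))
                rows.append((sub_t, measure, sub_pos, "melody", mel2, False))
    # inner voice over the middle third only
    lo, hi = duration_s / 3, 2 * duration_s / 3
    for b in range(n_beats):
        if lo <= beat_times[b] <= hi:
            measure, beat_in_m = divmod(b, BEATS_PER_MEASURE)
            pos = beat_in_m / BEATS_PER_MEASURE + 1.0 / (4 * BEATS_PER_MEASURE)
            if pos < 1.0:
                inner = int(np.clip(58 + rng.integers(-4, 5), 50, 70))
                rows.append((beat_times[b] + 0.25 * (beat_times[min(b + 1, n_beats - 1)]
                                                     - beat_times[b]),
                             measure, pos, "inner", inner, False))
    return OnsetTable.from_rows(rows)


def generate_features(duration_s: float, seed: int, correlation: float = 0.0,
                      mean_bpm: float = 60.0, rubato: float = 0.05,
                      ) -> tuple[dict[str, feat.FeatureSeries], OnsetTable]:
    """Full normalized feature set plus its onset table.

    ``correlation`` in [0, 1) mixes one shared smooth component into every
    feature; at 0 the features are generated independently.
    """
    if duration_s < 20:
        raise ValueError("duration must be at least 20 s")
    rng = np.random.default_rng(seed)
    onsets = generate_onsets(duration_s, seed=int(rng.integers(2 ** 31)),
                             mean_bpm=mean_bpm, rubato=rubato)
    t_all = onsets.clock_times
    span = (float(t_all.min()), float(t_all.max()))
    n = int(np.floor((span[1] - span[0]) * FS)) + 1

    # loudness: smooth positive arcs in sones (correlation time ~1.5 s)
    loud = 12.0 + 6.0 * _smooth_noise(rng, n, scale_samples=15)
    loudness = feat.FeatureSeries(
        "loudness", SampledSeries(span[0], 1.0 / FS, np.clip(loud, 0.5, None)))
    # harmony: mean-reverting step function (chord-level tension, ~5.5 s/chord);
    # mean reversion keeps chance low-frequency alignment with other slow
    # features modest
    n_chords = max(4, int(duration_s / 5.5))
    walk = np.empty(n_chords)
    walk[0] = rng.standard_normal()
    for k in range(1, n_chords):
        walk[k] = 0.75 * walk[k - 1] + 0.66 * rng.standard_normal()
    chord_levels = 40.0 + 12.0 * walk
    chord_times = np.sort(rng.uniform(span[0], span[1], n_chords - 1))
    breaks = np.concatenate([[span[0]], chord_times])
    harmony = feat.FeatureSeries(
        "harmony", feat._step_sample(breaks, chord_levels, span[0], span[1], 1.0 / FS))

    raw = {
        "loudness": loudness,
        "harmony": harmony,
        "onset_frequency": feat.onset_frequency(onsets),
        "tempo": feat.tempo_series(onsets),
        "pitch_melody": feat.pitch_height(onsets, "melody", span=span),
        "pitch_inner": feat.pitch_height(onsets, "inner", span=span),
        "pitch_bass": feat.pitch_height(onsets, "bass", span=span),
    }
    normalized = feat.normalize(raw.values())
    if correlation > 0:
        # blend one shared smooth arc into every Z-scored feature, then
        # re-normalize; pairwise correlations approach correlation**2
        shared = _smooth_noise(rng, n, scale_samples=40)
        blended = []
        for name, f in normalized.items():
            v = f.series.values
            m = min(v.size, shared.size)
            out = v.copy()
            out[:m] = np.sqrt(1 - correlation ** 2) * v[:m] + correlation * shared[:m]
            blended.append(feat.FeatureSeries(name, f.series.with_values(out)))
        normalized = feat.normalize(blended)
    return normalized, onsets


def generate_latent_tension(features: Mapping[str, feat.FeatureSeries],
                            config: WindowConfig,
                            out_range: tuple[float, float] = (20.0, 80.0)
                            ) -> SampledSeries:
    """Forward model run rescaled into a comfortable slider sub-range.

    The rescaling is affine (rank-preserving); a constant model output maps
    to the middle of ``out_range``.
    """
    pred = predict_tension(features, config)
    F = pred.F_ten
    lo, hi = float(np.nanmin(F)), float(np.nanmax(F))
    mid = 0.5 * (out_range[0] + out_range[1])
    if hi - lo < 1e-12:
        vals = np.full(F.size, mid)
    else:
        vals = out_range[0] + (F - lo) * (out_range[1] - out_range[0]) / (hi - lo)
    return SampledSeries(pred.start, pred.h, vals, domain="clock")


def draw_profiles(n: int, rng: np.random.Generator,
                  move_probability: float = 0.35, move_threshold: float = 3.0,
                  noise_sd: float = 1.0, drift_sd: float = 8.0,
                  orienting_s: float = 10.0) -> list[RaterProfile]:
    return [RaterProfile(lag_s=float(rng.uniform(1.0, 3.0)),
                         gain=float(rng.uniform(0.6, 1.4)),
                         offset=float(rng.normal(0.0, 10.0)),
                         move_probability=move_probability,
                         move_threshold=move_threshold,
                         noise_sd=noise_sd,
                         drift_sd=drift_sd,
                         orienting_s=orienting_s)
            for _ in range(n)]


def simulate_raters(latent: SampledSeries, n: int, seed: int,
                    profiles: list[RaterProfile] | None = None,
                    duration_s: float | None = None) -> pd.DataFrame:
    """Simulate a coordinated rating collection tracking a latent curve.

    Each rater follows the latent tension through an individual constant lag,
    an affine (gain/offset) distortion about mid-scale, intermittent slider
    movement (each sample the rater acts with ``move_probability``, otherwise
    the slider holds), additive Gaussian noise on movements, clipping to the
    0-100 scale, and an orienting ramp from slider position 0 over the first
    ``orienting_s`` seconds.

    Returns a DataFrame with a ``time_s`` column and one column per rater.
    """
    if n < 1:
        raise ValueError("need at least one rater")
    rng = np.random.default_rng(seed)
    if profiles is None:
        profiles = draw_profiles(n, rng)
    if len(profiles) != n:
        raise ValueError("profile list must match n")
    t_end = latent.end if duration_s is None else latent.start + duration_s
    t = np.arange(latent.start, t_end + 1e-9, 1.0 / FS)
    cols = {"time_s": t}
    for r, prof in enumerate(profiles):
        lag_t = np.maximum(t - prof.lag_s, latent.start)
        idx = np.clip(np.round((lag_t - latent.start) / latent.period), 0,
                      latent.values.size - 1).astype(int)
        desired = 50.0 + prof.gain * (latent.values[idx] - 50.0) + prof.offset
        if prof.drift_sd > 0:  # slow personal re-interpretation of the scale
            desired = desired + prof.drift_sd * _smooth_noise(rng, t.size, 150.0)
        ramp = np.minimum((t - t[0]) / prof.orienting_s, 1.0) if prof.orienting_s > 0 \
            else np.ones_like(t)
        desired = desired * ramp  # orienting: rise from the slider start position 0
        acts = rng.random(t.size) < prof.move_probability
        noise = rng.normal(0.0, prof.noise_sd, t.size)
        pos = np.empty(t.size)
        current = 0.0
        for i in range(t.size):
            if acts[i] and abs(desired[i] - current) > prof.move_threshold:
                current = desired[i] + noise[i]
            pos[i] = current
        cols[f"r{r + 1:02d}"] = np.clip(pos, *SLIDER_RANGE)
    return pd.DataFrame(cols)


def _renewal_events(rng: np.random.Generator, duration_s: float,
                    mean_interval_s: float, shape: float = 2.0) -> np.ndarray:
    """Event times of a stationary gamma renewal process over [0, duration)."""
    scale = mean_interval_s / shape
    n_guess = max(16, int(2 * duration_s / mean_interval_s) + 8)
    times = np.cumsum(rng.gamma(shape, scale, n_guess))
    while times[-1] < duration_s:
        times = np.concatenate([times, times[-1] + np.cumsum(
            rng.gamma(shape, scale, n_guess))])
    return times[times < duration_s]


@lru_cache(maxsize=32)
def _calibrate_mean_interval(target_rate: float, frame_s: float,
                             shape: float = 2.0) -> float:
    """Mean renewal interval giving the requested per-frame activity rate.

    Solved by bisection on long simulated realizations under a fixed internal
    seed (the activity rate of a gamma renewal process in finite frames has
    no convenient closed form).
    """
    sim_T = 30000.0
    rng = np.random.default_rng(987654321)

    def realized(mu: float) -> float:
        ev = _renewal_events(np.random.default_rng(rng.integers(2 ** 31)), sim_T, mu, shape)
        frames = np.floor(ev / frame_s).astype(int)
        return np.unique(frames).size / int(sim_T / frame_s)

    lo, hi = frame_s * 0.05, frame_s / max(target_rate, 1e-3) * 20
    for _ in range(22):
        mid = np.sqrt(lo * hi)
        if realized(mid) > target_rate:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def simulate_independent_raters(duration_s: float, n: int,
                                event_rate_per_frame: float, seed: int,
                                frame_s: float = 1.0) -> pd.DataFrame:
    """Null rating collection with independently timed tension changes.

    Each rater's increase and decrease events are independent stationary
    gamma renewal processes (shape 2: more regular than Poisson, preserving
    the serial structure shift-shuffle tests are designed to respect),
    calibrated so the 1 s-frame activity rate of increases is approximately
    ``event_rate_per_frame``. The slider path steps up or down by slightly
    more than the 1% change threshold at each event, so binarizing the
    ratings recovers the generated events; there is no timing structure
    shared between raters.
    """
    if not (0 < event_rate_per_frame < 1):
        raise ValueError("event rate per frame must lie in (0, 1)")
    mu = _calibrate_mean_interval(event_rate_per_frame, frame_s)
    rng = np.random.default_rng(seed)
    n_samp = int(round(duration_s * FS)) + 1
    t = np.arange(n_samp) / FS
    step = 1.1  # just above the 1% change-detection threshold
    cols = {"time_s": t}
    for r in range(n):
        path = np.zeros(n_samp)
        for sign in (+1.0, -1.0):
            ev = _renewal_events(np.random.default_rng(rng.integers(2 ** 31)),
                                 duration_s, mu)
            idx = np.minimum((ev * FS).round().astype(int) + 1, n_samp - 1)
            bump = np.zeros(n_samp)
            np.add.at(bump, idx, sign * step)
            path += bump
        cols[f"r{r + 1:02d}"] = np.clip(50.0 + np.cumsum(path), *SLIDER_RANGE)
    return pd.DataFrame(cols)


def ratings_matrix(df: pd.DataFrame) -> np.ndarray:
    """(n_raters, T) array from a ratings DataFrame (time_s + rater columns)."""
    return df.drop(columns=["time_s"]).to_numpy(dtype=float).T
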