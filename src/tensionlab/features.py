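"""Quantification of the musical feature set driving tension predictions.

Five feature families are produced, all as step functions sampled onto the
10 Hz rating clock and finally Z-scored:

* ``loudness`` — consumed as a precomputed perceptual loudness series (sones).
* ``pitch_melody`` / ``pitch_inner`` / ``pitch_bass`` — MIDI pitch held
  between each voice's onsets; the three share one pooled normalization so
  register differences between voices survive scaling.
* ``harmony`` — mean tension ratings of a harmonic reduction, sampled a fixed
  lag after each chord onset and mapped back to the performance timeline.
* ``onset_frequency`` — (maximum inter-onset duration) - (current inter-onset
  duration), so denser passages score higher.
* ``tempo`` — 60 / inter-beat interval in BPM, with missing beats recovered
  by linear interpolation between surrounding onsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .timebase import OnsetTable, SampledSeries

FEATURE_NAMES = (
    "loudness", "pitch_melody", "pitch_inner", "pitch_bass",
    "harmony", "onset_frequency", "tempo",
)
PITCH_FEATURES = ("pitch_melody", "pitch_inner", "pitch_bass")

#: onsets closer than this are treated as one simultaneous event (seconds)
COINCIDENCE_WINDOW_S = 0.030


@dataclass(frozen=True)
class FeatureSeries:
    name: str
    series: SampledSeries
    normalization: tuple[float, float] | None = None  # fitted (mean, std)

    def __post_init__(self) -> None:
        if self.name not in FEATURE_NAMES:
            raise ValueError(f"unknown feature {self.name!r}; expected one of {FEATURE_NAMES}")

    @property
    def values(self) -> np.ndarray:
        return self.series.values


@dataclass
class ChordTable:
    """Chords of a harmonic reduction and their occurrences in a performance.

    One row per performance occurrence: ``chord_index`` (1-based, as chords
    are numbered in a reduction), the chord's onset time in the reduction
    recording (NaN when the performance repeats a chord the reduction omits),
    and the onset time in the performance.
    """

    frame: pd.DataFrame

    REQUIRED = ("chord_index", "reduction_onset_s", "performance_onset_s")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"ChordTable missing columns: {missing}")
        df = self.frame.sort_values(["performance_onset_s"]).reset_index(drop=True)
        red = df.dropna(subset=["reduction_onset_s"]).sort_values("chord_index")
        if np.any(np.diff(red["reduction_onset_s"].to_numpy()) <= 0):
            raise ValueError("reduction onset times must strictly increase with chord_index")
        self.frame = df


def _step_sample(breaks: np.ndarray, levels: np.ndarray, t0: float, t1: float,
                 period: float) -> SampledSeries:
    """Sample a right-continuous step function (level[i] holds from breaks[i])."""
    n = int(np.floor((t1 - t0) / period + 1e-9)) + 1
    t = t0 + period * np.arange(n)
    idx = np.searchsorted(breaks, t + 1e-12, side="right") - 1
    vals = np.full(n, np.nan)
    ok = idx >= 0
    vals[ok] = levels[idx[ok]]
    return SampledSeries(start=t0, period=period, values=vals, domain="clock")


def pooled_event_times(onsets: OnsetTable) -> np.ndarray:
    """Distinct event times pooled over voices, merging near-coincident onsets."""
    t = np.sort(onsets.clock_times)
    if t.size == 0:
        return t
    keep = [t[0]]
    for x in t[1:]:
        if x - keep[-1] > COINCIDENCE_WINDOW_S:
            keep.append(x)
    return np.asarray(keep)


def onset_frequency(onsets: OnsetTable, max_duration: float | None = None,
                    sample_period: float = 0.1) -> FeatureSeries:
    """Onset-density feature: max event duration minus current event duration.

    The duration of an event is the interval to the next pooled onset; a
    short event (dense onsets) therefore yields a high value, and the longest
    event in the input yields exactly 0 when ``max_duration`` is left at its
    default (the maximum observed inter-onset duration).
    """
    times = pooled_event_times(onsets)
    if times.size < 2:
        raise ValueError("onset_frequency requires at least 2 pooled onsets")
    durations = np.diff(times)
    if max_duration is None:
        max_duration = float(durations.max())
    if np.any(durations > max_duration + 1e-9):
        raise ValueError(
            f"inter-onset duration {durations.max():.3f} s exceeds max_duration {max_duration}"
        )
    values = max_duration - durations
    series = _step_sample(times[:-1], values, times[0], times[-1], sample_period)
    return FeatureSeries("onset_frequency", series)


def tempo_series(onsets: OnsetTable, sample_period: float = 0.1) -> FeatureSeries:
    """Local tempo in BPM from beat onsets, held constant between beats.

    Beats without a marked onset are first recovered by linear interpolation
    of metrical position against clock time over all onsets; the tempo over
    each inter-beat interval is then 60 / IBI.
    """
    beats = onsets.beats()
    if len(beats) < 2:
        raise ValueError("tempo_series requires at least 2 beat onsets")
    # interpolate beat times on the metrical grid from every available onset
    all_ticks = onsets.ticks
    all_times = onsets.clock_times
    order = np.argsort(all_ticks, kind="stable")
    grp = pd.DataFrame({"k": all_ticks[order], "t": all_times[order]}).groupby("k")["t"].mean()
    beat_ticks = np.unique(
        beats["measure"].to_numpy(dtype=int) * 36
        + np.round(beats["position"].to_numpy(dtype=float) * 36).astype(int))
    # beat grid step inferred from marked beats (e.g. 12 ticks for 3 beats/measure)
    step = int(np.gcd.reduce(np.diff(beat_ticks))) if beat_ticks.size > 1 else 12
    full_ticks = np.arange(beat_ticks[0], beat_ticks[-1] + 1, step)
    beat_times = np.interp(full_ticks, grp.index.to_numpy(dtype=float),
                           grp.to_numpy(dtype=float))
    if beat_times.size < 2:
        raise ValueError("fewer than 2 recoverable beats")
    ibi = np.diff(beat_times)
    bpm = 60.0 / ibi
    series = _step_sample(beat_times[:-1], bpm, beat_times[0], beat_times[-1], sample_period)
    return FeatureSeries("tempo", series)


def pitch_height(onsets: OnsetTable, voice: str, sample_period: float = 0.1,
                 span: tuple[float, float] | None = None) -> FeatureSeries:
    """MIDI pitch of one voice held between its onsets; missing where inactive.

    A voice active only in a sub-span of the piece (e.g. an inner voice that
    echoes the melody in a single phrase) is missing outside that sub-span.
    """
    name = f"pitch_{voice}"
    rows = onsets.voice(voice).dropna(subset=["midi_pitch"]).sort_values("clock_time_s")
    if span is None:
        t_all = onsets.clock_times
        span = (float(t_all.min()), float(t_all.max()))
    t0, t1 = span
    if len(rows) == 0:
        warnings.warn(f"voice {voice!r} has no pitched onsets; returning all-missing series")
        n = int(np.floor((t1 - t0) / sample_period + 1e-9)) + 1
        return FeatureSeries(name, SampledSeries(t0, sample_period, np.full(n, np.nan)))
    times = rows["clock_time_s"].to_numpy(dtype=float)
    pitches = rows["midi_pitch"].to_numpy(dtype=float)
    series = _step_sample(times, pitches, t0, t1, sample_period)
    vals = series.values.copy()
    vals[series.times > times[-1] + 1e-9] = np.nan  # inactive after last onset
    return FeatureSeries(name, series.with_values(vals))


def harmonic_tension(reduction_mean: SampledSeries, chords: ChordTable,
                     lag: float = 2.0, sample_period: float = 0.1,
                     span: tuple[float, float] | None = None) -> FeatureSeries:
    """Harmonic-tension feature from mean ratings of a harmonic reduction.

    Each chord's tension is the reduction's mean rating sampled ``lag``
    seconds after the chord's onset in the reduction (compensating response
    delay; samples past the series end clamp to the final sample). The value
    is then held, as a step function, from every performance onset of that
    chord. Performance chords absent from the reduction reuse the preceding
    chord's value.
    """
    df = chords.frame
    sampled: dict[int, float] = {}
    for _, row in df.dropna(subset=["reduction_onset_s"]).iterrows():
        t = float(row["reduction_onset_s"]) + lag
        if t > reduction_mean.end + 1e-9:
            warnings.warn(
                f"chord {int(row['chord_index'])}: lagged sample time {t:.2f} s past "
                "series end; clamping to final sample")
        idx = int(np.clip(round((t - reduction_mean.start) / reduction_mean.period),
                          0, reduction_mean.values.size - 1))
        sampled[int(row["chord_index"])] = float(reduction_mean.values[idx])
    perf = df.sort_values("performance_onset_s")
    times, levels = [], []
    prev = None
    for _, row in perf.iterrows():
        ci = int(row["chord_index"])
        if ci in sampled:
            prev = sampled[ci]
        elif prev is None:
            raise ValueError(f"chord_index {ci} has no reduction value and no predecessor")
        times.append(float(row["performance_onset_s"]))
        levels.append(prev)
    if len(times) == 0:
        raise ValueError("ChordTable has no performance onsets")
    if span is None:
        span = (times[0], times[-1])
    series = _step_sample(np.asarray(times), np.asarray(levels), span[0], span[1],
                          sample_period)
    return FeatureSeries("harmony", series)


def normalize(features: Iterable[FeatureSeries]) -> dict[str, FeatureSeries]:
    """Z-score a feature set; the three pitch voices share pooled moments.

    Loudness, harmony, onset frequency and tempo are each scaled by their own
    sample mean and standard deviation (n-1 denominator); the pitch voices
    are scaled by the mean and standard deviation of all three voices'
    samples combined, so their relative registers are preserved.
    """
    feats = {f.name: f for f in features}
    out: dict[str, FeatureSeries] = {}
    pitch_present = [n for n in PITCH_FEATURES if n in feats]
    if pitch_present:
        pooled = np.concatenate([feats[n].values[~np.isnan(feats[n].values)]
                                 for n in pitch_present])
        if pooled.size < 2:
            raise ValueError("pooled pitch normalization requires >= 2 samples")
        mu, sd = float(pooled.mean()), float(pooled.std(ddof=1))
        if sd < 1e-12:
            raise ValueError("zero variance in pooled pitch samples")
        for n in pitch_present:
            out[n] = _apply_norm(feats[n], mu, sd)
    for n, f in feats.items():
        if n in PITCH_FEATURES:
            continue
        v = f.values[~np.isnan(f.values)]
        if v.size < 2:
            raise ValueError(f"feature {n!r} has < 2 non-missing samples")
        mu, sd = float(v.mean()), float(v.std(ddof=1))
        if sd < 1e-12:
            raise ValueError(f"feature {n!r} has zero variance")
        out[n] = _apply_norm(f, mu, sd)
    return out


def _apply_norm(f: FeatureSeries, mu: float, sd: float) -> FeatureSeries:
    scaled = f.series.with_values((f.series.values - mu) / sd)
    return replace(f, series=scaled, normalization=(mu, sd))
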