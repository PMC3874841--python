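"""Clock-time / metrical-time conversion for stimulus-synchronous series.

Continuous ratings and audio features live in clock time (seconds); score
events live in metrical time (measures and fractions of a measure). A
performance with expressive timing maps between the two nonlinearly, so the
mapping is built empirically from marked note onsets: the clock time of every
1/36 of a measure is linearly interpolated between the nearest known onsets.
The 1/36 grid is the coarsest grid housing both quadruple (1/12-measure) and
triple (1/9-measure) subdivisions of the quarter notes of a 3/4-type measure.

Conventions: measures and within-measure positions are 0-based; measure
ranges are inclusive of both endpoints. Missing samples are ``numpy.nan``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: subdivisions of one measure on the canonical metrical grid
TICKS_PER_MEASURE = 36

VOICES = ("melody", "inner", "bass", "piano", "chord")


class AlignmentError(ValueError):
    """Raised when onset data violate monotonicity or coverage requirements."""


@dataclass(frozen=True)
class SampledSeries:
    """A uniformly sampled scalar series in clock or metrical time.

    ``start`` and ``period`` are in seconds when ``domain == "clock"`` and in
    measures when ``domain == "metrical"`` (the metrical sampling period is
    always 1/36 of a measure).
    """

    start: float
    period: float
    values: np.ndarray
    domain: str = "clock"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("SampledSeries requires a 1-D series of length > 1")
        if self.period <= 0:
            raise ValueError("sample period must be positive")
        if self.domain not in ("clock", "metrical"):
            raise ValueError(f"unknown domain {self.domain!r}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.start + self.period * np.arange(self.values.size)

    @property
    def end(self) -> float:
        return self.start + self.period * (self.values.size - 1)

    def with_values(self, values: np.ndarray) -> "SampledSeries":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class OnsetTable:
    """Timed musical events bridging clock time and score (metrical) time.

    One row per onset: clock time in seconds, 0-based measure, position
    within the measure as a fraction in [0, 1) quantized to the 1/36 grid,
    voice label, optional MIDI pitch, and a flag marking beat onsets.
    """

    frame: pd.DataFrame

    REQUIRED = ("clock_time_s", "measure", "position", "voice", "midi_pitch", "is_beat")

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"OnsetTable missing columns: {missing}")
        self.frame = df.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        df = self.frame
        pos = df["position"].to_numpy(dtype=float)
        if np.any(pos < 0) or np.any(pos >= 1):
            raise AlignmentError("positions must lie in [0, 1)")
        ticks = pos * TICKS_PER_MEASURE
        if not np.allclose(ticks, np.round(ticks), atol=1e-9):
            bad = int(np.argmax(~np.isclose(ticks, np.round(ticks), atol=1e-9)))
            raise AlignmentError(
                f"row {bad}: position {pos[bad]} is not a multiple of 1/{TICKS_PER_MEASURE}"
            )
        order = np.argsort(df["clock_time_s"].to_numpy(), kind="stable")
        tick = self.ticks[order]
        if np.any(np.diff(tick) < 0):
            bad = int(np.where(np.diff(tick) < 0)[0][0])
            raise AlignmentError(
                f"metrical position decreases with clock time at sorted row {bad + 1}"
            )
        for voice, grp in df.groupby("voice"):
            g = grp.sort_values("clock_time_s")
            t = g["clock_time_s"].to_numpy()
            k = (g["measure"].to_numpy() * TICKS_PER_MEASURE
                 + np.round(g["position"].to_numpy() * TICKS_PER_MEASURE))
            distinct = np.diff(k) != 0
            if np.any(distinct & (np.diff(t) <= 0)):
                bad = int(np.where(distinct & (np.diff(t) <= 0))[0][0])
                raise AlignmentError(
                    f"voice {voice!r}: clock time not increasing at row {bad + 1} "
                    "for distinct metrical positions"
                )

    @property
    def ticks(self) -> np.ndarray:
        """Global metrical position of each row in 1/36-measure ticks."""
        df = self.frame
        return (df["measure"].to_numpy(dtype=int) * TICKS_PER_MEASURE
                + np.round(df["position"].to_numpy(dtype=float) * TICKS_PER_MEASURE).astype(int))

    @property
    def clock_times(self) -> np.ndarray:
        return self.frame["clock_time_s"].to_numpy(dtype=float)

    def voice(self, name: str) -> pd.DataFrame:
        return self.frame[self.frame["voice"] == name]

    def beats(self) -> pd.DataFrame:
        return self.frame[self.frame["is_beat"].astype(bool)]

    @classmethod
    def from_rows(cls, rows: Iterable[tuple]) -> "OnsetTable":
        """Build from (clock_time_s, measure, position, voice, midi_pitch, is_beat) tuples."""
        df = pd.DataFrame(rows, columns=list(cls.REQUIRED))
        return cls(df)


@dataclass(frozen=True)
class MetricalMap:
    """Interpolated clock time for every 1/36 of a measure over the mapped span."""

    start_tick: int
    clock_times: np.ndarray  # one entry per tick from start_tick

    def __post_init__(self) -> None:
        object.__setattr__(self, "clock_times", np.asarray(self.clock_times, dtype=float))
        if np.any(np.diff(self.clock_times) <= 0):
            raise AlignmentError("metrical map clock times must strictly increase")

    @property
    def ticks(self) -> np.ndarray:
        return self.start_tick + np.arange(self.clock_times.size)

    @property
    def end_tick(self) -> int:
        return self.start_tick + self.clock_times.size - 1

    def clock_at(self, ticks: np.ndarray) -> np.ndarray:
        """Clock time of (possibly fractional) global ticks, linearly interpolated."""
        ticks = np.asarray(ticks, dtype=float)
        rel = ticks - self.start_tick
        if np.any(rel < 0) or np.any(rel > self.clock_times.size - 1):
            raise AlignmentError("tick outside mapped span")
        return np.interp(rel, np.arange(self.clock_times.size), self.clock_times)


def build_metrical_map(onsets: OnsetTable) -> MetricalMap:
    """Interpolate the clock time of every 1/36-measure grid point from onsets.

    Grid points between two marked onsets lie on the straight line joining
    them; clock times at marked onsets are reproduced exactly. Onsets that
    share a metrical position (e.g. a chord across voices) are collapsed to
    their mean clock time.
    """
    ticks = onsets.ticks
    times = onsets.clock_times
    df = pd.DataFrame({"tick": ticks, "t": times}).groupby("tick")["t"].mean()
    if df.size < 2:
        raise AlignmentError("need at least 2 onsets with distinct metrical positions")
    known_ticks = df.index.to_numpy(dtype=float)
    known_times = df.to_numpy(dtype=float)
    if np.any(np.diff(known_times) <= 0):
        bad = int(np.where(np.diff(known_times) <= 0)[0][0])
        raise AlignmentError(
            f"collapsed onset clock times not increasing between metrical ticks "
            f"{int(known_ticks[bad])} and {int(known_ticks[bad + 1])}"
        )
    start = int(known_ticks[0])
    grid = np.arange(start, int(known_ticks[-1]) + 1)
    clock = np.interp(grid, known_ticks, known_times)
    return MetricalMap(start_tick=start, clock_times=clock)


def resample_to_metrical(series: SampledSeries, mmap: MetricalMap) -> SampledSeries:
    """Resample a clock-domain series onto the 1/36-measure grid.

    Each grid point takes the value of the clock-domain sample nearest to its
    interpolated clock time (ties resolve to the earlier sample). Grid points
    whose clock time falls outside the sampled span are marked missing.
    """
    if series.domain != "clock":
        raise ValueError("input series must be in the clock domain")
    t0, t1 = series.start, series.end
    grid_t = mmap.clock_times
    if grid_t[-1] < t0 or grid_t[0] > t1:
        raise AlignmentError("series does not overlap the metrical map's clock span")
    # nearest index with ties to the earlier sample: ceil(x - 0.5) on the
    # fractional index puts exact half-way points on the lower neighbor
    frac = (grid_t - t0) / series.period
    idx = np.ceil(frac - 0.5).astype(int)
    out = np.full(grid_t.size, np.nan)
    ok = (grid_t >= t0 - series.period / 2) & (grid_t <= t1 + series.period / 2)
    idx = np.clip(idx, 0, series.values.size - 1)
    out[ok] = series.values[idx[ok]]
    return SampledSeries(
        start=mmap.start_tick / TICKS_PER_MEASURE,
        period=1.0 / TICKS_PER_MEASURE,
        values=out,
        domain="metrical",
    )


def resample_to_clock(series: SampledSeries, mmap: MetricalMap,
                      start: float, period: float, n: int) -> SampledSeries:
    """Inverse companion of :func:`resample_to_metrical` (nearest neighbor)."""
    if series.domain != "metrical":
        raise ValueError("input series must be in the metrical domain")
    out_t = start + period * np.arange(n)
    grid_t = mmap.clock_times[: series.values.size]
    out = np.full(n, np.nan)
    ok = (out_t >= grid_t[0]) & (out_t <= grid_t[-1])
    if not np.any(ok):
        raise AlignmentError("requested clock span does not overlap the map")
    pos = np.searchsorted(grid_t, out_t[ok])
    pos = np.clip(pos, 1, grid_t.size - 1)
    left, right = grid_t[pos - 1], grid_t[pos]
    choose_left = (out_t[ok] - left) <= (right - out_t[ok])  # ties -> earlier
    nearest = np.where(choose_left, pos - 1, pos)
    out[ok] = series.values[nearest]
    return SampledSeries(start=start, period=period, values=out, domain="clock")


def extract_excerpt(series: SampledSeries, measures: tuple[int, int],
                    omitted: Sequence[int] = (), gap_mode: str = "interpolate") -> SampledSeries:
    """Slice a metrical-domain series to an inclusive measure range.

    Measures listed in ``omitted`` (absent from a shortened variant such as a
    harmonic reduction) are filled by linear interpolation from the flanking
    samples (``gap_mode="interpolate"``) or marked missing (``"blank"``).
    Output length is exactly 36 x (number of measures in the range).
    """
    if series.domain != "metrical":
        raise ValueError("extract_excerpt operates on metrical-domain series")
    if gap_mode not in ("interpolate", "blank"):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    m0, m1 = measures
    if m1 < m0:
        raise ValueError("empty measure range")
    for m in omitted:
        if not (m0 <= m <= m1):
            raise ValueError(f"omitted measure {m} outside range {m0}..{m1}")
    start_tick = int(round(series.start * TICKS_PER_MEASURE))
    lo = m0 * TICKS_PER_MEASURE - start_tick
    hi = (m1 + 1) * TICKS_PER_MEASURE - start_tick
    if lo < 0 or hi > series.values.size:
        raise ValueError("measure range outside series span")
    vals = series.values[lo:hi].copy()
    gap = np.zeros(vals.size, dtype=bool)
    for m in omitted:
        a = (m - m0) * TICKS_PER_MEASURE
        gap[a: a + TICKS_PER_MEASURE] = True
    if gap_mode == "blank":
        vals[gap] = np.nan
    else:
        vals[gap] = np.nan
        good = ~np.isnan(vals)
        if good.sum() >= 2:
            vals[~good] = np.interp(np.where(~good)[0], np.where(good)[0], vals[good])
    return SampledSeries(start=float(m0), period=1.0 / TICKS_PER_MEASURE,
                         values=vals, domain="metrical")


def metrical_position(measure: int, num: int, den: int) -> float:
    """Within-measure position num/den validated against the 1/36 grid."""
    frac = Fraction(num, den)
    if not (0 <= frac < 1):
        raise AlignmentError(f"position {frac} outside [0, 1)")
    tick = frac * TICKS_PER_MEASURE
    if tick.denominator != 1:
        raise AlignmentError(f"position {frac} not representable on the 1/{TICKS_PER_MEASURE} grid")
    return float(frac)
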