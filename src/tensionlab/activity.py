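"""Activity analysis of continuous-rating collections.

A collection of stimulus-synchronous slider ratings is reduced to binary
*change point processes* (one per rater and direction of change), and
coordination between raters is quantified at two scales:

* **Global** — the coordination score: each slicing of the time line into
  adjacent fixed-duration frames yields a histogram of per-frame active-rater
  counts, tested (Pearson chi-square with tail-bin merging) against the
  independence null in which each rater is active with its own empirical
  frame rate (a Poisson-binomial count distribution). The score is the mean
  of -log10(p) over all distinct slicings, clamped to [0, 16]; a score of 2
  corresponds to p = 0.01.
* **Local** — per-frame significance from a circular shift shuffle: each
  rater's point process is rotated by an independent uniform time shift
  (ends looped), which preserves each response's serial structure while
  destroying the common stimulus alignment. The rank of the observed
  activity level among 1000 shuffled levels gives a per-frame p-value.

The global chi-square construction reconstructs a procedure whose full
specification is unpublished; the choices made here (per-rater empirical
rates, >= 5 expected counts per merged bin, per-slicing clamp) are documented
reconstructions, not a canonical reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

DEFAULT_FS = 10.0  # Hz
SCORE_CAP = 16.0
#: rating-change threshold: 1% of the 0-100 slider scale
DEFAULT_THRESHOLD = 1.0


@dataclass
class ChangePointProcess:
    """Binary event sequence for one rater and one direction of change."""
    rater: str
    events: np.ndarray  # uint8, length = len(rating) - 1
    direction: str      # "increase" | "decrease"
    threshold: float = DEFAULT_THRESHOLD
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.uint8)
        if not np.all((self.events == 0) | (self.events == 1)):
            raise ValueError("events must be binary")
        if self.direction not in ("increase", "decrease"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def n_events(self) -> int:
        return int(self.events.sum())


@dataclass
class ActivityLevelSeries:
    frame_s: float
    frame_starts_s: np.ndarray
    levels: np.ndarray  # proportion of responses active per frame, in [0, 1]
    n_responses: int


@dataclass
class CoordinationResult:
    score: float
    p_per_slicing: np.ndarray
    frame_s: float
    event_type: str
    warning: str | None = None


@dataclass
class LocalCoordinationResult:
    frame_starts_s: np.ndarray
    frame_durations_s: np.ndarray
    levels: np.ndarray
    p: np.ndarray
    flagged: np.ndarray          # p < alpha
    n_shuffles: int
    shift_range_s: tuple[float, float]
    alpha: float = 0.05


def change_point_process(rating: np.ndarray, direction: str,
                         threshold: float = DEFAULT_THRESHOLD,
                         rater: str = "", fs: float = DEFAULT_FS) -> ChangePointProcess:
    """Reduce a continuous rating to directional change events.

    Sample-to-sample differences are accumulated; an event fires when the
    accumulated change in the requested direction since the last event (or
    since the last reversal of direction) reaches the threshold, after which
    the accumulator resets to zero. Opposite-direction movement resets the
    accumulation reference (the accumulator clamps at zero) rather than
    building a deficit.
    """
    rating = np.asarray(rating, dtype=float)
    diffs = np.diff(rating)
    if direction == "decrease":
        diffs = -diffs
    events = np.zeros(diffs.size, dtype=np.uint8)
    acc = 0.0
    for i, d in enumerate(diffs):
        acc += d
        if acc < 0.0:
            acc = 0.0
        elif acc >= threshold:
            events[i] = 1
            acc = 0.0
    return ChangePointProcess(rater=rater, events=events, direction=direction,
                              threshold=threshold, fs=fs)


def processes_from_collection(ratings: np.ndarray, direction: str,
                              threshold: float = DEFAULT_THRESHOLD,
                              fs: float = DEFAULT_FS) -> list[ChangePointProcess]:
    """Change point processes for every rater of a (n_raters, T) array."""
    return [change_point_process(row, direction, threshold, rater=f"r{i + 1:02d}", fs=fs)
            for i, row in enumerate(np.asarray(ratings, dtype=float))]


def _event_matrix(processes: Sequence[ChangePointProcess]) -> np.ndarray:
    lengths = {p.events.size for p in processes}
    if len(lengths) != 1:
        raise ValueError("processes must share one length")
    return np.vstack([p.events for p in processes])


def _frame_active(events: np.ndarray, frame_len: int, offset: int) -> np.ndarray:
    """(n_raters, n_frames) indicator of >= 1 event per frame for one slicing."""
    n = events.shape[1]
    n_frames = (n - offset) // frame_len
    if n_frames < 1:
        raise ValueError("no complete frame at this offset")
    seg = events[:, offset: offset + n_frames * frame_len]
    return seg.reshape(events.shape[0], n_frames, frame_len).max(axis=2)


def activity_levels(processes: Sequence[ChangePointProcess], frame_s: float,
                    offset_s: float = 0.0) -> ActivityLevelSeries:
    """Proportion of responses with at least one event in each frame."""
    fs = processes[0].fs
    frame_len = int(round(frame_s * fs))
    if frame_len < 1:
        raise ValueError("frame duration must be at least one sampling interval")
    offset = int(round(offset_s * fs))
    ev = _event_matrix(processes)
    active = _frame_active(ev, frame_len, offset)
    levels = active.mean(axis=0)
    starts = (offset + frame_len * np.arange(active.shape[1])) / fs
    return ActivityLevelSeries(frame_s=frame_s, frame_starts_s=starts,
                               levels=levels, n_responses=len(processes))


def activity_rate(processes: Sequence[ChangePointProcess],
                  frame_s: float = 1.0) -> float:
    """Mean activity level over all frames (offset 0)."""
    return float(activity_levels(processes, frame_s).levels.mean())


def _poisson_binomial_pmf(ps: np.ndarray) -> np.ndarray:
    """Distribution of the number of successes among independent Bernoullis."""
    pmf = np.array([1.0])
    for p in ps:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def _merge_bins(observed: np.ndarray, expected: np.ndarray,
                min_expected: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Greedy adjacent-bin merging until every merged bin expects >= 5."""
    obs_bins, exp_bins = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(observed, expected):
        o_acc += o
        e_acc += e
        if e_acc >= min_expected:
            obs_bins.append(o_acc)
            exp_bins.append(e_acc)
            o_acc = e_acc = 0.0
    if e_acc > 0:
        if exp_bins:
            obs_bins[-1] += o_acc
            exp_bins[-1] += e_acc
        else:
            obs_bins, exp_bins = [o_acc], [e_acc]
    return np.asarray(obs_bins), np.asarray(exp_bins)


def _slicing_p(active: np.ndarray) -> float:
    """Chi-square goodness-of-fit p for one slicing's active-count histogram."""
    n_raters, n_frames = active.shape
    counts = active.sum(axis=0)
    observed = np.bincount(counts, minlength=n_raters + 1).astype(float)
    rates = active.mean(axis=1)  # per-rater empirical frame-activity rate
    pmf = _poisson_binomial_pmf(rates)
    expected = pmf * n_frames
    obs_b, exp_b = _merge_bins(observed, expected)
    if obs_b.size < 2:
        return 1.0
    chi2 = float(((obs_b - exp_b) ** 2 / exp_b).sum())
    df = obs_b.size - 1
    return float(stats.chi2.sf(chi2, df))


def coordination_score(processes: Sequence[ChangePointProcess],
                       frame_s: float) -> CoordinationResult:
    """Global coordination of one event type across a response collection.

    Evaluates every distinct slicing (all frame-grid offsets at the sampling
    resolution) and averages -log10(p) over slicings, with both per-slicing
    values and the final mean clamped to [0, 16].
    """
    fs = processes[0].fs
    frame_len = int(round(frame_s * fs))
    if frame_len < 2:
        raise ValueError("frame duration must exceed the sampling interval")
    ev = _event_matrix(processes)
    if ev.shape[1] // frame_len < 10:
        raise ValueError("need at least 10 frames for the coordination score")
    warning = None
    if ev.sum() == 0:
        warnings.warn("no events in any response; coordination score is 0")
        return CoordinationResult(0.0, np.ones(frame_len), frame_s,
                                  processes[0].direction, "no events")
    ps = np.array([_slicing_p(_frame_active(ev, frame_len, off))
                   for off in range(frame_len)])
    logs = np.minimum(-np.log10(np.maximum(ps, 1e-300)), SCORE_CAP)
    score = float(np.clip(logs.mean(), 0.0, SCORE_CAP))
    return CoordinationResult(score, ps, frame_s, processes[0].direction, warning)


def _median_split(counts: np.ndarray) -> np.ndarray | None:
    """High/low frame split at the median; ties resolved to keep both sides.

    A strict split (count > median) is preferred; when the median coincides
    with the maximum (common for near-binary count sequences) the inclusive
    split is used instead. Returns None when no split separates the frames.
    """
    med = np.median(counts)
    hi = counts > med
    if hi.any() and (~hi).any():
        return hi
    hi = counts >= med
    if hi.any() and (~hi).any():
        return hi
    return None


def alternation_score(inc: Sequence[ChangePointProcess],
                      dec: Sequence[ChangePointProcess],
                      frame_s: float) -> CoordinationResult:
    """Coordination between increase and decrease activity in one collection.

    Per slicing, frames are cross-classified by high/low increase activity
    and high/low decrease activity (median splits) and tested for
    independence; coordinated collections alternate (increase and decrease
    activity avoid the same frames), independent ones do not.
    """
    if len(inc) != len(dec):
        raise ValueError("increase and decrease sets must cover the same raters")
    fs = inc[0].fs
    frame_len = int(round(frame_s * fs))
    if frame_len < 2:
        raise ValueError("frame duration must exceed the sampling interval")
    ev_i, ev_d = _event_matrix(inc), _event_matrix(dec)
    if ev_i.shape != ev_d.shape:
        raise ValueError("increase and decrease processes must share a shape")
    if ev_i.sum() == 0 or ev_d.sum() == 0:
        warnings.warn("one event type has no events; alternation score is 0")
        return CoordinationResult(0.0, np.ones(frame_len), frame_s, "alternation",
                                  "degenerate")
    ps = []
    for off in range(frame_len):
        ci = _frame_active(ev_i, frame_len, off).sum(axis=0)
        cd = _frame_active(ev_d, frame_len, off).sum(axis=0)
        hi_i = _median_split(ci)
        hi_d = _median_split(cd)
        if hi_i is None or hi_d is None:
            ps.append(1.0)
            continue
        table = np.array([[np.sum(hi_i & hi_d), np.sum(hi_i & ~hi_d)],
                          [np.sum(~hi_i & hi_d), np.sum(~hi_i & ~hi_d)]], dtype=float)
        if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
            ps.append(1.0)
            continue
        n = table.sum()
        det = table[0, 0] * table[1, 1] - table[0, 1] * table[1, 0]
        denom = table.sum(axis=0).prod() * table.sum(axis=1).prod()
        chi2 = n * det ** 2 / denom
        ps.append(float(stats.chi2.sf(chi2, 1)))
    ps = np.asarray(ps)
    logs = np.minimum(-np.log10(np.maximum(ps, 1e-300)), SCORE_CAP)
    score = float(np.clip(logs.mean(), 0.0, SCORE_CAP))
    return CoordinationResult(score, ps, frame_s, "alternation", None)


def circular_shift(process: ChangePointProcess, shift_samples: int) -> ChangePointProcess:
    """Rotate a point process in time with the ends looped for continuity."""
    return ChangePointProcess(rater=process.rater,
                              events=np.roll(process.events, shift_samples),
                              direction=process.direction,
                              threshold=process.threshold, fs=process.fs)


def local_coordination(processes: Sequence[ChangePointProcess],
                       frames: Sequence[tuple[float, float]],
                       shift_range_s: tuple[float, float] = (-5.0, 5.0),
                       n_shuffles: int = 1000,
                       seed: int | None = None,
                       alpha: float = 0.05) -> LocalCoordinationResult:
    """Per-frame shuffle test of activity levels against shifted alignments.

    Each shuffle draws one uniform shift per rater from ``shift_range_s``
    (rounded to the sampling grid), circularly rotates that rater's point
    process, and recomputes the activity level of every requested frame
    (overlapping frames permitted). The per-frame p-value is the mid-rank of
    the observed level among the shuffled alternatives — the fraction of
    shuffled levels above it plus half the fraction tied with it (activity
    levels are discrete multiples of 1/n_raters, so ties are common and a
    strict-exceedance rank would be conservative). Frames with p < alpha
    (observed level exceeding about (1 - alpha) of the alternatives) are
    flagged.

    With a single rater every shuffle preserves the one response's event
    count, so ranks are uninformative; all p default to 1.
    """
    if n_shuffles < 100:
        warnings.warn(f"n_shuffles={n_shuffles} is small; p-value resolution is coarse")
    fs = processes[0].fs
    ev = _event_matrix(processes)
    n_raters, n = ev.shape
    starts = np.array([int(round(s * fs)) for s, _ in frames])
    lens = np.array([int(round(d * fs)) for _, d in frames])
    if np.any(starts < 0) or np.any(starts + lens > n):
        raise ValueError("frame outside the sampled span")
    frame_starts = starts / fs
    frame_durs = lens / fs
    if n_raters < 2:
        obs = np.array([float(ev[0, s: s + L].max()) for s, L in zip(starts, lens)])
        return LocalCoordinationResult(frame_starts, frame_durs, obs,
                                       np.ones(len(frames)),
                                       np.zeros(len(frames), dtype=bool),
                                       n_shuffles, shift_range_s, alpha)
    # W[r, s] = does rater r have an event in the circular window [s, s + L)?
    # computed per distinct frame length; a rater shifted by k sees frame
    # (start) f as the unshifted circular window starting at (f - k) mod n.
    rng = np.random.default_rng(seed)
    shifts = np.round(rng.uniform(shift_range_s[0], shift_range_s[1],
                                  size=(n_shuffles, n_raters)) * fs).astype(int)
    obs = np.empty(len(frames))
    gt_counts = np.zeros(len(frames))
    eq_counts = np.zeros(len(frames))
    csum = np.concatenate([np.zeros((n_raters, 1)),
                           np.cumsum(np.tile(ev, 2), axis=1)], axis=1)
    for L in np.unique(lens):
        W = (csum[:, L:n + L] - csum[:, :n]) > 0  # (n_raters, n) circular any
        sel = np.where(lens == L)[0]
        f = starts[sel]
        obs[sel] = W[:, f].mean(axis=0)
        for block in range(0, n_shuffles, 200):
            k = shifts[block: block + 200]
            idx = (f[None, None, :] - k[:, :, None]) % n  # (B, R, m)
            lev = W[np.arange(n_raters)[None, :, None], idx].mean(axis=1)
            gt_counts[sel] += (lev > obs[sel][None, :] + 1e-12).sum(axis=0)
            eq_counts[sel] += (np.abs(lev - obs[sel][None, :]) <= 1e-12).sum(axis=0)
    p = (gt_counts + 0.5 * eq_counts) / n_shuffles
    flagged = p < alpha
    return LocalCoordinationResult(frame_starts, frame_durs, obs, p, flagged,
                                   n_shuffles, shift_range_s, alpha)


def collection_summary(ratings: np.ndarray) -> dict[str, float]:
    """Mean, spread, and agreement summary of one rating collection.

    ``tension_std`` is the standard deviation over time of the across-rater
    mean series; ``std_ratio`` divides it by the time-average of the
    across-rater standard deviation. Values near 0 indicate noisy or
    contradictory responses, values near 1 strong common shape.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[0] < 2:
        raise ValueError("need a (n_raters >= 2, T) rating array")
    mean_series = ratings.mean(axis=0)
    spread = ratings.std(axis=0, ddof=1)
    denom = float(spread.mean())
    tension_std = float(mean_series.std(ddof=1))
    if denom < 1e-12:
        warnings.warn("across-rater spread is zero everywhere; STD ratio undefined")
        ratio = float("nan")
    else:
        ratio = tension_std / denom
    return {"tension_mean": float(ratings.mean()),
            "tension_std": tension_std,
            "std_ratio": ratio}
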