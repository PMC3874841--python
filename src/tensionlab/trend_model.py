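"""Trend-salience model of continuous musical tension.

The model predicts tension from the *directional trends* of musical features
rather than their absolute values. For each feature f:

1. the current trend ``s_f(t)`` is the ordinary-least-squares slope of the
   feature over an *attentional window* ``[t - d_att, t]``;
2. a *memory window* ``[t - d_att - d_mem, t - d_att]`` immediately precedes
   it; when the memory-window slope has the same (nonzero) sign as the
   current slope, the current slope is amplified by a factor ``beta`` (> 1),
   encoding that a continuing trend feels more salient than a fresh one;
3. amplified slopes from overlapping windows (step ``h`` = 250 ms) are
   merged by a decaying moving average with weights ``k`` summing to 1
   (recent windows weighted more strongly), giving the tension slope ``S(t)``;
4. the tension curve is the running integral ``F(t) = h * sum S``.

In the per-feature variant used here, steps 1-4 run independently for every
feature with feature-specific window durations, and the resulting per-feature
tension curves are merged by one final *linear* pass of the same machinery
(1 s attentional window, no memory window, equal weights). Differences in
feature contributions are carried entirely by the individual timescales; with
every memory window at 0 s the whole model is a linear operator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .features import FEATURE_NAMES, PITCH_FEATURES, FeatureSeries
from .timebase import SampledSeries

MODEL_FEATURES = ("loudness", "pitch_melody", "pitch_inner", "pitch_bass",
                  "harmony", "onset_frequency", "tempo")
#: optimization treats the three pitch voices as one timescale variable
WINDOW_GROUPS = ("loudness", "pitch", "harmony", "onset_frequency", "tempo")

_SIGN_EPS = 1e-12


@dataclass(frozen=True)
class Windows:
    """Attentional and memory window durations (seconds) for one feature."""
    att: float
    mem: float

    def __post_init__(self) -> None:
        if self.att < 0 or self.mem < 0:
            raise ValueError("window durations must be non-negative")


@dataclass(frozen=True)
class WindowConfig:
    """Full parameterization of the per-feature trend-salience model.

    ``windows`` maps window-group names (``loudness``, ``pitch``, ``harmony``,
    ``onset_frequency``, ``tempo``) to per-feature durations. ``beta`` is the
    trend-continuation amplification; ``h`` the moving-window step in
    seconds; ``decay`` the moving-average weight profile over the attentional
    span (``("geometric", ratio)`` or ``("uniform",)``). The final
    integration stage is fixed at a 1 s attentional window with no memory.
    """

    windows: Mapping[str, Windows]
    beta: float = 5.0
    h: float = 0.25
    decay: tuple = ("geometric", 0.75)
    final_att: float = 1.0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.h <= 0:
            raise ValueError("step size h must be positive")
        unknown = set(self.windows) - set(WINDOW_GROUPS)
        if unknown:
            raise ValueError(f"unknown window groups: {sorted(unknown)}")
        object.__setattr__(self, "windows", dict(self.windows))

    def for_feature(self, name: str) -> Windows:
        group = "pitch" if name in PITCH_FEATURES else name
        return self.windows[group]

    @classmethod
    def uniform(cls, att: float, mem: float, **kw) -> "WindowConfig":
        return cls(windows={g: Windows(att, mem) for g in WINDOW_GROUPS}, **kw)

    @classmethod
    def reference(cls, **kw) -> "WindowConfig":
        """Reference window assignment used throughout examples and tests:
        harmony on long timescales (8.5 s attentional, 13 s memory), pitch
        at 2 s, loudness/onset-frequency/tempo near-instantaneous."""
        return cls(windows={
            "loudness": Windows(att=2.0, mem=0.0),
            "pitch": Windows(att=2.0, mem=2.0),
            "harmony": Windows(att=8.5, mem=13.0),
            "onset_frequency": Windows(att=1.0, mem=1.0),
            "tempo": Windows(att=1.0, mem=1.5),
        }, **kw)


@dataclass(frozen=True)
class TrendPrediction:
    """All intermediate and final series of one model evaluation (h grid)."""
    start: float
    h: float
    per_feature: dict[str, np.ndarray]  # per-feature tension curves
    s_prime_final: np.ndarray
    S: np.ndarray
    F_ten: np.ndarray
    config: WindowConfig

    @property
    def times(self) -> np.ndarray:
        return self.start + self.h * np.arange(self.F_ten.size)

    def as_series(self) -> SampledSeries:
        return SampledSeries(self.start, self.h, self.F_ten, domain="clock")


def decay_weights(m: int, decay: tuple) -> np.ndarray:
    """Moving-average weights k_0..k_{m-1} (k_0 = most recent), summing to 1."""
    if m < 1:
        raise ValueError("need at least one step")
    kind = decay[0]
    if kind == "uniform":
        w = np.ones(m)
    elif kind == "geometric":
        w = decay[1] ** np.arange(m)
    else:
        raise ValueError(f"unknown decay kind {kind!r}")
    return w / w.sum()


def best_fit_slope(series: SampledSeries, t: float, d: float) -> float:
    """OLS slope of the series over the window [t - d, t] (units per second).

    Windows holding fewer than 2 non-missing samples yield NaN rather than
    raising, so gaps propagate as missing predictions.
    """
    times = series.times
    mask = (times >= t - d - 1e-9) & (times <= t + 1e-9) & ~np.isnan(series.values)
    x = times[mask]
    y = series.values[mask]
    if x.size < 2:
        return float("nan")
    xm, ym = x.mean(), y.mean()
    denom = float(((x - xm) ** 2).sum())
    if denom == 0:
        return float("nan")
    return float(((x - xm) * (y - ym)).sum() / denom)


def trend_slope(now: float, memory: float, beta: float) -> float:
    """Apply the trend-continuation rule to one current/memory slope pair.

    beta multiplies the current slope only when both slopes are nonzero
    (|slope| > 1e-12) and share a sign; otherwise the current slope passes
    through unchanged. A missing memory slope counts as sign 0.
    """
    if np.isnan(now):
        return float("nan")
    s_now = 0 if abs(now) < _SIGN_EPS else np.sign(now)
    s_mem = 0 if (memory is None or np.isnan(memory) or abs(memory) < _SIGN_EPS) \
        else np.sign(memory)
    if s_now != 0 and s_now == s_mem:
        return now * beta
    return now


def integrate_trends(s_prime: np.ndarray, h: float, d_att: float,
                     decay: tuple = ("geometric", 0.75)) -> np.ndarray:
    """Decaying moving average of amplified slopes over the attentional span.

    S(t) = sum_{tau=0}^{m-1} s'(t - tau h) k_tau with sum k = 1 and
    m = d_att / h steps; early samples (and samples next to missing values)
    use the available terms with renormalized weights. d_att < h degenerates
    to the identity (single-term sum).
    """
    s_prime = np.asarray(s_prime, dtype=float)
    m = int(round(d_att / h))
    if m <= 1:
        return s_prime.copy()
    k = decay_weights(m, decay)
    n = s_prime.size
    vals = np.nan_to_num(s_prime, nan=0.0)
    good = (~np.isnan(s_prime)).astype(float)
    # S[i] = sum_tau k[tau] * s'[i - tau], renormalized over non-missing terms
    num = np.zeros(n)
    den = np.zeros(n)
    for tau in range(m):
        if tau == 0:
            num += k[0] * vals
            den += k[0] * good
        else:
            num[tau:] += k[tau] * vals[:-tau]
            den[tau:] += k[tau] * good[:-tau]
    out = np.full(n, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def cumulative_tension(S: np.ndarray, h: float) -> np.ndarray:
    """Running integral F(t) = h * sum_{i<t/h} S(i); F(0) = 0 exactly.

    Missing S samples contribute 0 to the integral (the curve holds level
    across gaps).
    """
    S = np.nan_to_num(np.asarray(S, dtype=float), nan=0.0)
    F = np.empty(S.size)
    F[0] = 0.0
    np.cumsum(h * S[:-1], out=F[1:])
    return F


def _slopes_uniform(values: np.ndarray, h: float, d: float, *, offset: int = 0) -> np.ndarray:
    """Vectorized OLS slopes over trailing windows on a uniform grid.

    ``slopes[i]`` is the OLS slope of ``values`` over sample indices
    ``[i - offset - m, i - offset]`` where ``m = round(d / h)``; ``offset``
    shifts the window back (used for memory windows preceding the attentional
    window). Truncated startup windows use every available sample; windows
    with < 2 samples (or d == 0) give NaN.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    m = int(round(d / h))
    if m < 1:
        return np.full(n, np.nan)
    w = m + 1  # samples per full window
    out = np.full(n, np.nan)
    if np.isnan(values).any():
        # gap-aware fallback (rare: only real data with inactive voices)
        t = h * np.arange(n)
        for i in range(n):
            hi = i - offset
            lo = hi - m
            if hi < 1:
                continue
            lo = max(lo, 0)
            seg_t, seg_v = t[lo:hi + 1], values[lo:hi + 1]
            good = ~np.isnan(seg_v)
            if good.sum() < 2:
                continue
            x, y = seg_t[good], seg_v[good]
            xm = x.mean()
            den = ((x - xm) ** 2).sum()
            if den > 0:
                out[i] = ((x - xm) * (y - y.mean())).sum() / den
        return out
    # full windows: slope is a fixed linear functional of the window samples
    j = np.arange(w)
    c = (j - j.mean()) / (h * ((j - j.mean()) ** 2).sum())
    full_start = offset + m  # first index with a complete window
    if n > full_start:
        sw = np.lib.stride_tricks.sliding_window_view(values, w)
        ends = np.arange(full_start, n) - offset  # window end index per output
        out[full_start:] = sw[ends - m] @ c
    # truncated startup windows
    for i in range(min(full_start, n)):
        hi = i - offset
        if hi < 1:
            continue
        lo = max(hi - m, 0)
        x = h * np.arange(lo, hi + 1)
        y = values[lo:hi + 1]
        xm = x.mean()
        den = ((x - xm) ** 2).sum()
        if den > 0:
            out[i] = ((x - xm) * (y - y.mean())).sum() / den
    return out


def _feature_tension(values: np.ndarray, h: float, win: Windows, beta: float,
                     decay: tuple) -> np.ndarray:
    """Per-feature pipeline: slopes -> memory amplification -> Eq.2/3 integration."""
    n = values.size
    if win.att < h / 2:  # zero attentional window extracts no trend
        return np.zeros(n)
    s_now = _slopes_uniform(values, h, win.att)
    if win.mem >= h / 2:
        m_att = int(round(win.att / h))
        s_mem = _slopes_uniform(values, h, win.mem, offset=m_att)
        amp = np.ones(n)
        both = (~np.isnan(s_now)) & (~np.isnan(s_mem))
        same = both & (np.abs(s_now) > _SIGN_EPS) & (np.abs(s_mem) > _SIGN_EPS) \
            & (np.sign(s_now) == np.sign(s_mem))
        amp[same] = beta
        s_prime = s_now * amp
    else:
        s_prime = s_now
    S = integrate_trends(s_prime, h, win.att, decay)
    return cumulative_tension(S, h)


def predict_tension(features: Mapping[str, FeatureSeries | SampledSeries],
                    config: WindowConfig,
                    required: tuple[str, ...] | None = None) -> TrendPrediction:
    """Run the per-feature trend-salience model over a feature set.

    Every feature is resampled (nearest neighbor) onto the common ``h`` grid
    spanning the intersection of the feature spans. Per-feature tension
    curves are computed with that feature's own windows, then merged by a
    single linear final pass (1 s attentional window, no memory, equal
    weights) into ``F_ten``.
    """
    if required is None:
        required = tuple(features.keys())
    missing = [f for f in required if f not in features]
    if missing:
        raise ValueError(f"missing features {missing}; expected {sorted(required)}")
    series = {name: (f.series if isinstance(f, FeatureSeries) else f)
              for name, f in features.items()}
    h = config.h
    t0 = max(s.start for s in series.values())
    t1 = min(s.end for s in series.values())
    if t1 - t0 < h:
        raise ValueError("features share no usable common span")
    n = int(np.floor((t1 - t0) / h + 1e-9)) + 1
    grid_t = t0 + h * np.arange(n)
    per_feature: dict[str, np.ndarray] = {}
    for name, s in series.items():
        idx = np.ceil((grid_t - s.start) / s.period - 0.5).astype(int)
        idx = np.clip(idx, 0, s.values.size - 1)
        vals = s.values[idx]
        win = config.for_feature(name)
        per_feature[name] = _feature_tension(vals, h, win, config.beta, config.decay)
    # final linear stage: equal weights, 1 s attentional window, no memory
    w = 1.0 / len(per_feature)
    slopes = [_slopes_uniform(curve, h, config.final_att) for curve in per_feature.values()]
    s_prime_final = np.full(n, np.nan)
    stack = np.vstack(slopes)
    any_good = ~np.all(np.isnan(stack), axis=0)
    s_prime_final[any_good] = np.nansum(stack[:, any_good], axis=0) * w
    S = integrate_trends(s_prime_final, h, config.final_att, config.decay)
    F = cumulative_tension(S, h)
    return TrendPrediction(start=t0, h=h, per_feature=per_feature,
                           s_prime_final=s_prime_final, S=S, F_ten=F, config=config)
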