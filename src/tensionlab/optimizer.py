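"""Window-duration optimization for the per-feature trend-salience model.

The objective is the Spearman rank correlation between the model's tension
curve and a mean tension response, both sampled at beat times (the response
shifted by a 2 s lag to absorb reporting delay). Ten variables are searched
(five window groups x {attentional, memory}; the three pitch voices share
one group) over a 0-20 s grid in 0.5 s increments: starting from all-zero
durations, each variable is incremented until the correlation passes its
first peak, then fixed; a bounded confirmation phase perturbs each variable
by up to two grid steps and accepts improvements until a full sweep changes
nothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .features import FeatureSeries
from .timebase import SampledSeries
from .trend_model import WINDOW_GROUPS, WindowConfig, Windows, predict_tension

_TIE_EPS = 1e-12

#: default coordinate-ascent order: (group, which-window), attentional first
DEFAULT_ORDER = tuple(
    (g, w) for g in ("loudness", "pitch", "harmony", "onset_frequency", "tempo")
    for w in ("att", "mem")
)


@dataclass
class OptimizationResult:
    best_config: WindowConfig
    train_rho: float
    test_rho: float | None
    trace: list[tuple[str, float, float]]  # (variable, duration, rho) per evaluation
    low_confidence: bool = False

    def windows_dict(self) -> dict[str, dict[str, float]]:
        return {g: {"att": w.att, "mem": w.mem}
                for g, w in self.best_config.windows.items()}


def sample_at(series: SampledSeries, times: np.ndarray) -> np.ndarray:
    """Nearest-neighbor samples at arbitrary times (ties to earlier sample)."""
    idx = np.ceil((np.asarray(times, dtype=float) - series.start) / series.period - 0.5)
    idx = np.clip(idx, 0, series.values.size - 1).astype(int)
    return series.values[idx]


def spearman(a: np.ndarray, b: np.ndarray) -> float:
    good = ~(np.isnan(a) | np.isnan(b))
    if good.sum() < 3:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(a[good], b[good]).statistic
    return float(rho)


def evaluate_config(config: WindowConfig,
                    features: Mapping[str, FeatureSeries | SampledSeries],
                    target_mean: SampledSeries,
                    beat_times: Sequence[float],
                    lag: float = 2.0) -> float:
    """Spearman rho between beat-sampled prediction and lagged target mean."""
    pred = predict_tension(features, config).as_series()
    return _rho_against(pred, target_mean, np.asarray(beat_times, dtype=float), lag)


def _rho_against(pred: SampledSeries, target: SampledSeries,
                 beats: np.ndarray, lag: float) -> float:
    keep = (beats >= pred.start) & (beats <= pred.end) \
        & (beats + lag >= target.start) & (beats + lag <= target.end)
    beats = beats[keep]
    if beats.size < 3:
        raise ValueError("fewer than 3 usable beats after lag shift")
    return spearman(sample_at(pred, beats), sample_at(target, beats + lag))


class _Evaluator:
    """Caches per-feature tension curves across coordinate-ascent evaluations.

    Only the final (cheap) linear stage is recomputed when a single feature's
    windows move, which is the dominant access pattern of the search.
    """

    def __init__(self, features, target_mean, beats, lag, h, beta, decay, final_att):
        from .trend_model import _feature_tension, _slopes_uniform, \
            cumulative_tension, integrate_trends
        self._feature_tension = _feature_tension
        self._slopes = _slopes_uniform
        self._integrate = integrate_trends
        self._cumulate = cumulative_tension
        self.h, self.beta, self.decay, self.final_att = h, beta, decay, final_att
        series = {n: (f.series if isinstance(f, FeatureSeries) else f)
                  for n, f in features.items()}
        t0 = max(s.start for s in series.values())
        t1 = min(s.end for s in series.values())
        n = int(np.floor((t1 - t0) / h + 1e-9)) + 1
        grid_t = t0 + h * np.arange(n)
        self.t0, self.n = t0, n
        self.grids = {}
        for name, s in series.items():
            idx = np.clip(np.ceil((grid_t - s.start) / s.period - 0.5), 0,
                          s.values.size - 1).astype(int)
            self.grids[name] = s.values[idx]
        self.target, self.beats, self.lag = target_mean, np.asarray(beats, float), lag
        self._curve_cache: dict[tuple, np.ndarray] = {}
        self.n_evals = 0

    def curve(self, name: str, win: Windows) -> np.ndarray:
        key = (name, round(win.att, 6), round(win.mem, 6))
        if key not in self._curve_cache:
            self._curve_cache[key] = self._feature_tension(
                self.grids[name], self.h, win, self.beta, self.decay)
        return self._curve_cache[key]

    def rho(self, config: WindowConfig) -> float:
        self.n_evals += 1
        curves = [self.curve(name, config.for_feature(name)) for name in self.grids]
        w = 1.0 / len(curves)
        slopes = np.vstack([self._slopes(c, self.h, self.final_att) for c in curves])
        s_final = np.full(self.n, np.nan)
        good = ~np.all(np.isnan(slopes), axis=0)
        s_final[good] = np.nansum(slopes[:, good], axis=0) * w
        F = self._cumulate(self._integrate(s_final, self.h, self.final_att, self.decay),
                           self.h)
        pred = SampledSeries(self.t0, self.h, F, domain="clock")
        try:
            return _rho_against(pred, self.target, self.beats, self.lag)
        except ValueError:
            return float("nan")


def stepwise_search(features: Mapping[str, FeatureSeries | SampledSeries],
                    target_mean: SampledSeries,
                    beats: Sequence[float],
                    grid_max: float = 20.0,
                    grid_step: float = 0.5,
                    lag: float = 2.0,
                    order: Sequence[tuple[str, str]] = DEFAULT_ORDER,
                    beta: float = 5.0,
                    h: float = 0.25,
                    decay: tuple = ("geometric", 0.75),
                    max_sweeps: int = 6,
                    max_confirm_sweeps: int = 5,
                    joint: bool = False) -> OptimizationResult:
    """Coordinate-ascent search for per-feature window durations.

    Non-finite correlations (e.g. a constant prediction when all windows are
    zero) rank below every finite value and are never accepted. Ties within
    1e-12 prefer the shorter duration. With ``joint=True`` each window
    group's attentional and memory durations are scanned as one 2-D block
    per sweep instead of as separate 1-D variables (slower; resolves
    within-feature attentional/memory compensation better).
    """
    grid = np.round(np.arange(0.0, grid_max + grid_step / 2, grid_step), 6)
    ev = _Evaluator(features, target_mean, np.asarray(beats, float), lag,
                    h, beta, decay, final_att=1.0)
    durations = {v: 0.0 for v in order}
    trace: list[tuple[str, float, float]] = []

    def config_for(durs) -> WindowConfig:
        return WindowConfig(
            windows={g: Windows(att=durs[(g, "att")], mem=durs[(g, "mem")])
                     for g in WINDOW_GROUPS},
            beta=beta, h=h, decay=decay)

    def score(durs) -> float:
        r = ev.rho(config_for(durs))
        return -np.inf if not np.isfinite(r) else r

    best = score(durations)
    trace.append(("init", 0.0, best))

    # phase 1: one variable at a time, incremented across its grid; the
    # variable settles on the peak of its 1-D profile (ties prefer shorter
    # durations). Sweeps repeat until a full pass over all 10 variables
    # moves nothing, so variables fit early can re-adjust to ones fit later.
    # In joint mode the att/mem pair of each group moves as one 2-D block.
    groups = list(dict.fromkeys(g for g, _ in order))
    for sweep in range(max_sweeps):
        moved = False
        if joint:
            for grp in groups:
                label = f"{grp}.att+mem"
                cur = (durations[(grp, "att")], durations[(grp, "mem")])
                best_pair, best_r = cur, best
                for ga in grid:
                    for gm in grid:
                        if (ga, gm) == cur:
                            continue
                        cand = dict(durations)
                        cand[(grp, "att")], cand[(grp, "mem")] = float(ga), float(gm)
                        r = score(cand)
                        trace.append((label, float(ga), r))
                        if r > best_r + _TIE_EPS:
                            best_pair, best_r = (float(ga), float(gm)), r
                if best_pair != cur and best_r > best + _TIE_EPS:
                    durations[(grp, "att")], durations[(grp, "mem")] = best_pair
                    best = best_r
                    moved = True
        else:
            for var in order:
                label = f"{var[0]}.{var[1]}"
                best_d, best_r = durations[var], best
                for g in grid:
                    if g == durations[var]:
                        continue
                    cand = dict(durations)
                    cand[var] = float(g)
                    r = score(cand)
                    trace.append((label, cand[var], r))
                    if r > best_r + _TIE_EPS or (r >= best_r - _TIE_EPS and g < best_d):
                        best_d, best_r = float(g), r
                if best_d != durations[var] and best_r > best + _TIE_EPS:
                    durations[var] = best_d
                    best = best_r
                    moved = True
        if not moved:
            break

    # phase 2: bounded confirmation sweeps with +/- 2-step perturbations
    for _ in range(max_confirm_sweeps):
        accepted = False
        for var in order:
            label = f"confirm:{var[0]}.{var[1]}"
            pos = int(np.searchsorted(grid, durations[var]))
            cands = []
            for dp in (-2, -1, 1, 2):
                q = pos + dp
                if not (0 <= q < grid.size):
                    continue
                cand = dict(durations)
                cand[var] = float(grid[q])
                r = score(cand)
                trace.append((label, cand[var], r))
                cands.append((r, cand[var], cand))
            improving = [c for c in cands if c[0] > best + _TIE_EPS]
            if improving:
                # best rho; rho-ties (within 1e-12) resolve to shorter duration
                top = max(c[0] for c in improving)
                r, _, cand = min((c for c in improving if c[0] >= top - _TIE_EPS),
                                 key=lambda c: c[1])
                durations, best = cand, r
                accepted = True
        if not accepted:
            break

    cfg = config_for(durations)
    final_rho = best if np.isfinite(best) else float("nan")
    return OptimizationResult(best_config=cfg, train_rho=final_rho, test_rho=None,
                              trace=trace,
                              low_confidence=bool(not np.isfinite(best) or best < 0.3))


def train_test_split(series: SampledSeries, boundary: float
                     ) -> tuple[SampledSeries, SampledSeries]:
    """Split one series at a boundary time into disjoint train/test spans."""
    t = series.times
    left = t < boundary
    if left.sum() < 2 or (~left).sum() < 2:
        raise ValueError("boundary leaves a degenerate train or test span")
    train = SampledSeries(series.start, series.period, series.values[left],
                          domain=series.domain)
    test = SampledSeries(float(t[~left][0]), series.period, series.values[~left],
                         domain=series.domain)
    return train, test


def split_collection(items: Mapping[str, SampledSeries], boundary: float
                     ) -> tuple[dict[str, SampledSeries], dict[str, SampledSeries]]:
    """Apply :func:`train_test_split` across a named set of series."""
    train, test = {}, {}
    for name, s in items.items():
        train[name], test[name] = train_test_split(s, boundary)
    return train, test
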