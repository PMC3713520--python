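"""SOCE metrics from ratiometric Fura-2 traces.

The protocol defines three epochs: baseline (before thapsigargin at
``t_tg``), store release in Ca2+-free buffer (``t_tg`` to ``t_ca``), and
store-operated influx after extracellular Ca2+ re-addition at ``t_ca``.
Metrics are the baseline ratio, the store-release peak over baseline, the
influx amplitude over the pre-re-addition level, and the maximal rate of
initial rise of the ratio after re-addition.

The rate is estimated by ordinary least squares over a sliding window of
consecutive samples (default 5 points, i.e. about 10 s at 2-s sampling)
rather than two-point differencing, which is variance-dominated on noisy
ratio data. Peaks are taken on the raw ratio without smoothing. All metrics
are deterministic given a trace.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EventOrderError, GroupCountError, RatioComputationError, TooFewSamplesError
from .types import FuraTrace

__all__ = [
    "TraceMetrics",
    "compute_ratio",
    "max_rate_of_rise",
    "trace_metrics",
    "average_traces",
    "metrics_table",
]


@dataclass
class TraceMetrics:
    """Derived SOCE statistics of one trace (ratio units; rates per second)."""

    cell_id: str
    condition: str
    baseline_ratio: float
    release_peak_delta: float
    soce_amplitude: float
    max_rate_rise: float
    t_at_max_rate: float

    def as_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "condition": self.condition,
            "baseline_ratio": self.baseline_ratio,
            "release_peak_delta": self.release_peak_delta,
            "soce_amplitude": self.soce_amplitude,
            "max_rate_rise": self.max_rate_rise,
            "t_at_max_rate": self.t_at_max_rate,
        }


def compute_ratio(trace: FuraTrace, max_invalid_fraction: float = 0.2) -> FuraTrace:
    """Fill the ratio from raw channels: (F340 - bg340) / (F380 - bg380).

    Timepoints with a non-positive denominator are flagged invalid and
    excluded from downstream metrics; if more than ``max_invalid_fraction``
    of the points are invalid the whole trace is rejected.
    """
    if trace.f340 is None or trace.f380 is None:
        raise RatioComputationError(f"cell {trace.cell_id!r}: raw F340/F380 channels missing")
    denom = trace.f380 - trace.bg380
    valid = denom > 0
    n_invalid = int((~valid).sum())
    if n_invalid > max_invalid_fraction * trace.n:
        raise RatioComputationError(
            f"cell {trace.cell_id!r}: {n_invalid}/{trace.n} timepoints have "
            f"non-positive background-subtracted F380"
        )
    ratio = np.full(trace.n, np.nan)
    ratio[valid] = (trace.f340[valid] - trace.bg340) / denom[valid]
    return replace(trace, ratio=ratio, valid=valid)


def _ols_slopes(t: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    """OLS slope of y on t for every window of ``window`` consecutive samples."""
    tw = np.lib.stride_tricks.sliding_window_view(t, window)
    yw = np.lib.stride_tricks.sliding_window_view(y, window)
    tm = tw.mean(axis=1, keepdims=True)
    ym = yw.mean(axis=1, keepdims=True)
    dt = tw - tm
    return ((dt * (yw - ym)).sum(axis=1)) / (dt**2).sum(axis=1)


def max_rate_of_rise(
    time_s: np.ndarray,
    ratio: np.ndarray,
    t_start: float,
    search_window_s: float = 60.0,
    fit_window_pts: int = 5,
) -> tuple[float, float]:
    """Maximal sliding-window OLS slope of the ratio after ``t_start``.

    Every window of ``fit_window_pts`` consecutive samples whose first
    sample lies in ``[t_start, t_start + search_window_s]`` is fit by OLS;
    the maximum slope and its window-center time are returned. On exactly
    linear data the OLS slope equals the true slope for any window.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(ratio, dtype=float)
    finite = np.isfinite(y)
    t, y = t[finite], y[finite]
    in_search = (t >= t_start) & (t <= t_start + search_window_s)
    start_idx = np.nonzero(in_search)[0]
    # windows must fit within the available samples
    start_idx = start_idx[start_idx + fit_window_pts <= t.size]
    if start_idx.size == 0:
        n_avail = int(in_search.sum())
        raise TooFewSamplesError(
            f"need at least {fit_window_pts} consecutive samples starting in "
            f"[{t_start}, {t_start + search_window_s}] s; only {n_avail} start points available"
        )
    slopes = _ols_slopes(t, y, fit_window_pts)[start_idx]
    best = int(np.argmax(slopes))
    i0 = start_idx[best]
    t_center = float(t[i0 : i0 + fit_window_pts].mean())
    return float(slopes[best]), t_center


@dataclass(frozen=True)
class MetricsParams:
    """Windows used by :func:`trace_metrics` (seconds / samples)."""

    pre_readdition_pts: int = 5
    search_window_s: float = 60.0
    fit_window_pts: int = 5


def trace_metrics(trace: FuraTrace, params: MetricsParams | None = None) -> TraceMetrics:
    """Baseline, store-release peak, SOCE amplitude and maximal rise rate.

    baseline = mean ratio over [t0, t_tg); release_peak_delta = max over
    [t_tg, t_ca) - baseline; the pre-re-addition level is the mean of the
    last ``pre_readdition_pts`` samples before t_ca; soce_amplitude = max
    over [t_ca, end] - pre-re-addition level; max_rate_rise comes from
    :func:`max_rate_of_rise` starting at t_ca.
    """
    if params is None:
        params = MetricsParams()
    if trace.ratio is None:
        trace = compute_ratio(trace)
    t = trace.time_s
    r = trace.ratio
    ok = np.isfinite(r)
    if trace.valid is not None:
        ok = ok & trace.valid
    t, r = t[ok], r[ok]
    if not (t[0] <= trace.t_tg <= t[-1]) or not (t[0] <= trace.t_ca <= t[-1]):
        raise EventOrderError(
            f"cell {trace.cell_id!r}: event times t_tg={trace.t_tg}, t_ca={trace.t_ca} "
            f"outside trace span [{t[0]}, {t[-1]}]"
        )
    if trace.t_tg >= trace.t_ca:
        raise EventOrderError(f"cell {trace.cell_id!r}: t_tg must precede t_ca")
    base_sel = t < trace.t_tg
    if not base_sel.any():
        raise EventOrderError(f"cell {trace.cell_id!r}: empty baseline window before t_tg")
    baseline = float(r[base_sel].mean())
    rel_sel = (t >= trace.t_tg) & (t < trace.t_ca)
    release_delta = float(r[rel_sel].max() - baseline) if rel_sel.any() else 0.0
    pre_idx = np.nonzero(t < trace.t_ca)[0][-params.pre_readdition_pts :]
    pre_level = float(r[pre_idx].mean())
    post_sel = t >= trace.t_ca
    soce_amplitude = float(r[post_sel].max() - pre_level) if post_sel.any() else 0.0
    rate, t_at = max_rate_of_rise(
        t, r, t_start=trace.t_ca,
        search_window_s=params.search_window_s,
        fit_window_pts=params.fit_window_pts,
    )
    return TraceMetrics(
        cell_id=trace.cell_id,
        condition=trace.condition,
        baseline_ratio=baseline,
        release_peak_delta=release_delta,
        soce_amplitude=soce_amplitude,
        max_rate_rise=rate,
        t_at_max_rate=t_at,
    )


def metrics_table(traces: Sequence[FuraTrace], params: MetricsParams | None = None) -> pd.DataFrame:
    """Per-cell metrics, one row per trace."""
    return pd.DataFrame([trace_metrics(tr, params).as_dict() for tr in traces])


def average_traces(
    traces: Sequence[FuraTrace], labels: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Pointwise per-group mean and SEM of traces sharing one time grid.

    All traces must share an identical time grid; mismatches raise rather
    than silently resampling. Returns long-format columns
    (condition, time_s, mean_ratio, sem_ratio, n_cells).
    """
    if len(traces) == 0:
        raise GroupCountError("no traces to average")
    if labels is None:
        labels = [tr.condition for tr in traces]
    if len(labels) != len(traces):
        raise GroupCountError("labels must match traces one-to-one")
    t0 = traces[0].time_s
    for tr in traces[1:]:
        if tr.time_s.shape != t0.shape or not np.array_equal(tr.time_s, t0):
            raise GroupCountError(
                f"cell {tr.cell_id!r} has a different time grid; no implicit resampling"
            )
    frames = []
    for g in sorted(set(labels)):
        stack = np.stack([tr.ratio for tr, lab in zip(traces, labels) if lab == g])
        n = stack.shape[0]
        mean = stack.mean(axis=0)
        sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.full_like(mean, np.nan)
        frames.append(
            pd.DataFrame(
                {"condition": g, "time_s": t0, "mean_ratio": mean, "sem_ratio": sem, "n_cells": n}
            )
        )
    return pd.concat(frames, ignore_index=True)
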