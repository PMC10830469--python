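"""Quantitative outputs of the lysis simulations.

Degradation curves (fraction of fibers degraded vs time) are reduced to the
standard internal-lysis summary statistics: the lysis lag time (first record
with at least 5% of the clot degraded), times to 20/50/80% lysis, and
least-squares degradation rates over the 20-50%, 50-80% and 20-80% windows,
reported as fraction of clot per minute.  Pore expansion is tracked at the
5/20/50/80% degradation checkpoints by scan-line traversal, and tPA transit
times are summarized in minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .lattice import LatticeClot, measure_pores

__all__ = [
    "DegradationCurve",
    "LysisMetrics",
    "PoreExpansionSeries",
    "TransitStats",
    "lysis_metrics",
    "fold_change",
    "pore_expansion",
    "transit_stats",
    "replicate_aggregate",
]

THRESHOLDS = (0.05, 0.20, 0.50, 0.80)
RATE_WINDOWS = {"rate_20_80": (0.20, 0.80),
                "rate_20_50": (0.20, 0.50),
                "rate_50_80": (0.50, 0.80)}


@dataclass(frozen=True)
class DegradationCurve:
    """Fraction-of-fibers-degraded time series at the recording cadence."""

    times: np.ndarray            # s, strictly increasing, uniform spacing
    fraction_degraded: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fraction_degraded, dtype=float)
        if t.size != f.size:
            raise ValueError("times and fractions must have equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("record times must be strictly increasing")
        if np.any(f < -1e-12) or np.any(f > 1 + 1e-12):
            raise ValueError("fractions must lie in [0, 1]")
        if np.any(np.diff(f) < -1e-12):
            raise ValueError("degraded fraction must be non-decreasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fraction_degraded", f)


@dataclass(frozen=True)
class LysisMetrics:
    """Lag/threshold times (s) and interval regression rates (fraction/min).

    Unavailable fields (curve never reached the threshold, or fewer than two
    records in a rate window) are NaN; ``complete`` is False if the curve
    never reached 80%.
    """

    lag_5pct: float
    t20: float
    t50: float
    t80: float
    rate_20_80: float
    rate_20_50: float
    rate_50_80: float
    complete: bool = True


@dataclass(frozen=True)
class PoreExpansionSeries:
    """Mean pore size at the 5/20/50/80% degradation checkpoints."""

    checkpoints: tuple          # degradation fractions
    times: np.ndarray           # s, first record at/after each checkpoint
    mean_pore: np.ndarray       # um
    percent_change: np.ndarray  # % vs the intact-lattice mean
    rate_of_pore_change: np.ndarray  # um/s, per inter-checkpoint interval


@dataclass(frozen=True)
class TransitStats:
    mean_transit: float         # min
    episodes_min: np.ndarray    # per-episode durations, min
    available: bool = True


def _first_at(curve: DegradationCurve, threshold: float) -> float:
    idx = np.flatnonzero(curve.fraction_degraded >= threshold - 1e-12)
    return float(curve.times[idx[0]]) if idx.size else math.nan


def _window_slope(curve: DegradationCurve, lo: float, hi: float) -> float:
    sel = (curve.fraction_degraded >= lo - 1e-12) & \
          (curve.fraction_degraded <= hi + 1e-12)
    if sel.sum() < 2:
        return math.nan
    slope = np.polyfit(curve.times[sel], curve.fraction_degraded[sel], 1)[0]
    return float(slope) * 60.0  # fraction per minute


def lysis_metrics(curve: DegradationCurve) -> LysisMetrics:
    """Threshold times ("first record at or above") and OLS interval rates."""
    lag, t20, t50, t80 = (_first_at(curve, thr) for thr in THRESHOLDS)
    rates = {name: _window_slope(curve, lo, hi)
             for name, (lo, hi) in RATE_WINDOWS.items()}
    return LysisMetrics(lag_5pct=lag, t20=t20, t50=t50, t80=t80,
                        complete=not math.isnan(t80), **rates)


def fold_change(metric_a: float, metric_b: float) -> float:
    """Ratio a/b; NaN flags an undefined result (zero denominator)."""
    if not (math.isfinite(metric_a) and math.isfinite(metric_b)):
        return math.nan
    if metric_b == 0:
        return math.nan
    return metric_a / metric_b


def pore_expansion(result, checkpoints=THRESHOLDS,
                   clot: LatticeClot | None = None) -> PoreExpansionSeries:
    """Pore-size expansion at degradation checkpoints.

    ``result`` is a :class:`~fibrolat.engine.SimulationResult` (or any object
    with ``curve()``, ``intact_mask(t)`` and ``clot``).  Each checkpoint is
    evaluated on the first record at or above that degradation fraction,
    consistent with the lag-time convention; percent change is relative to
    the intact-lattice mean pore (= the lattice spacing).
    """
    clot = clot if clot is not None else result.clot
    curve = result.curve()
    base = clot.spacing
    times, means = [], []
    for c in checkpoints:
        t = _first_at(curve, c)
        if math.isnan(t):
            times.append(math.nan)
            means.append(math.nan)
            continue
        prof = measure_pores(clot, intact=result.intact_mask(t), tag=t)
        times.append(t)
        means.append(prof.mean_gap)
    times = np.asarray(times)
    means = np.asarray(means)
    pct = 100.0 * (means - base) / base
    rates = np.full(len(checkpoints), math.nan)
    for k in range(1, len(checkpoints)):
        dtk = times[k] - times[k - 1]
        if math.isfinite(dtk) and dtk > 0:
            rates[k] = (means[k] - means[k - 1]) / dtk
    return PoreExpansionSeries(checkpoints=tuple(checkpoints), times=times,
                               mean_pore=means, percent_change=pct,
                               rate_of_pore_change=rates)


def transit_stats(log) -> TransitStats:
    """Mean and per-episode tPA transit durations in minutes."""
    durations = getattr(log, "duration_s", None)
    if durations is None:
        durations = np.asarray(log, dtype=float)
    durations = np.asarray(durations, dtype=float)
    if durations.size == 0:
        return TransitStats(mean_transit=math.nan,
                            episodes_min=np.zeros(0), available=False)
    mins = durations / 60.0
    return TransitStats(mean_transit=float(mins.mean()), episodes_min=mins)


def replicate_aggregate(metrics) -> pd.DataFrame:
    """Mean and sample SD (ddof=1) per numeric field across replicates."""
    rows = []
    for m in metrics:
        if hasattr(m, "__dataclass_fields__"):
            rows.append({f.name: getattr(m, f.name) for f in fields(m)
                         if isinstance(getattr(m, f.name), (int, float))
                         and not isinstance(getattr(m, f.name), bool)})
        else:
            rows.append(dict(m))
    df = pd.DataFrame(rows)
    return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})
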