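"""Plate-reader turbidity analysis of clot formation and internal lysis.

A turbidity curve is the optical density (405 nm) of a clotting-then-lysing
plasma sample, tracked every 15 s for four hours.  Curves are normalized
twice: to the first point (background removal) and to the maximum (fractions
of the clot).  Seven parameters quantify the biphasic curve: clotting lag
time, rate of formation, time to 50% clot, maximum OD, lysis lag time
(first time after the peak at 95% of maximum, i.e. 5% degradation), time to
50% lysis (closest to 0.5 after the peak), and degradation rates over the
20-80%, 20-50% and 50-80% windows (least-squares slopes, fraction/min).

The module also fits the decaying-exponential relationship between
degradation rate and fibrinogen concentration, summarizes region-wise pore
tables from timelapse microscopy, and generates synthetic biphasic curves
for parameter-recovery testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "TurbidityCurve",
    "TurbidityMetrics",
    "DecayFit",
    "PoreRegionTable",
    "read_plate_export",
    "turbidity_metrics",
    "fit_decay",
    "pore_table_stats",
    "synth_turbidity",
]

SAMPLE_INTERVAL_S = 15.0
DURATION_S = 4 * 3600.0


@dataclass(frozen=True)
class TurbidityCurve:
    """One well's optical-density trace with both normalizations."""

    times: np.ndarray    # s
    od_raw: np.ndarray   # OD at 405 nm
    well: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od_raw, dtype=float)
        if t.size != od.size or t.size < 2:
            raise ValueError("times and od_raw must be equal-length, size >= 2")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time axis must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od_raw", od)

    @property
    def od_bg(self) -> np.ndarray:
        """Background-normalized OD: the first point subtracted."""
        return self.od_raw - self.od_raw[0]

    @property
    def od_frac(self) -> np.ndarray:
        """OD as a fraction of the clot (normalized to the maximum)."""
        bg = self.od_bg
        peak = bg.max()
        if peak <= 0:
            raise ValueError("degenerate curve: no positive signal to "
                             "normalize to")
        return bg / peak


@dataclass(frozen=True)
class TurbidityMetrics:
    clot_lag: float          # s
    formation_rate: float    # fraction/min
    t50_clot: float          # s
    max_od: float            # OD units (background-normalized)
    lysis_lag: float         # s
    t50_lysis: float         # s
    deg_rate_20_80: float    # fraction/min
    deg_rate_20_50: float
    deg_rate_50_80: float
    lysis_detected: bool = True


@dataclass(frozen=True)
class DecayFit:
    """y = amplitude * exp(-k x) least-squares fit."""

    amplitude: float
    decay_constant: float    # k, per (mg/mL)
    residual_ss: float
    degenerate: bool = False


@dataclass(frozen=True)
class PoreRegionTable:
    """Long-format pore measurements: region id, timepoint (s), pore size (um)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"region", "time_s", "pore_um"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"pore table must have columns {sorted(need)}")


# ---------------------------------------------------------------------------

def read_plate_export(path) -> list[TurbidityCurve]:
    """Read a delimited plate-reader export: a time column then one column
    per well.  Raises a format error naming the offending location."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a time column plus at least one well")
    tcol = df.columns[0]
    times = pd.to_numeric(df[tcol], errors="coerce")
    if times.isna().any():
        row = int(times.isna().idxmax())
        raise ValueError(f"{path}: non-numeric time at row {row + 2}")
    t = times.to_numpy(float)
    if not np.all(np.diff(t) > 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0])
        raise ValueError(f"{path}: non-monotone time at row {bad + 3}")
    curves = []
    for col in df.columns[1:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise ValueError(
                f"{path}: non-numeric value in well {col!r} at row {row + 2}")
        curves.append(TurbidityCurve(times=t, od_raw=vals.to_numpy(float),
                                     well=str(col)))
    return curves


def _phase_slope(times, frac, lo=0.2, hi=0.8) -> float:
    sel = (frac >= lo - 1e-12) & (frac <= hi + 1e-12)
    if sel.sum() < 2:
        return math.nan
    return float(np.polyfit(times[sel], frac[sel], 1)[0]) * 60.0


def _closest_to_half(times, frac) -> float:
    if times.size == 0:
        return math.nan
    # ties broken to the earlier time (argmin returns the first minimum)
    return float(times[np.argmin(np.abs(frac - 0.5))])


def turbidity_metrics(curve: TurbidityCurve) -> TurbidityMetrics:
    """Extract the seven formation/degradation parameters from one curve.

    The rising phase is everything up to the (first) maximum, the falling
    phase everything after it.  A curve with no post-peak decline yields NaN
    degradation fields with ``lysis_detected=False``; a curve whose phases
    are out of order (e.g. time-reversed) is rejected.
    """
    bg = curve.od_bg
    frac = curve.od_frac
    t = curve.times
    peak = int(np.argmax(bg))
    max_od = float(bg[peak])

    rise_t, rise_f = t[:peak + 1], frac[:peak + 1]
    fall_t, fall_f = t[peak:], frac[peak:]

    idx = np.flatnonzero(rise_f >= 0.05 - 1e-12)
    clot_lag = float(rise_t[idx[0]]) if idx.size else math.nan
    formation_rate = _phase_slope(rise_t, rise_f)
    t50_clot = _closest_to_half(rise_t, rise_f)

    lysis_detected = fall_f.size > 1 and fall_f.min() < 0.95
    if lysis_detected:
        after = fall_t[1:], fall_f[1:]
        idx = np.flatnonzero(after[1] <= 0.95 + 1e-12)
        lysis_lag = float(after[0][idx[0]]) if idx.size else math.nan
        t50_lysis = _closest_to_half(*after)
        # rates are reported as positive fractions of clot degraded per
        # minute, i.e. the negated falling-phase OD slope
        rates = {name: -_phase_slope(fall_t, fall_f, lo, hi)
                 for name, (lo, hi) in (("deg_rate_20_80", (0.2, 0.8)),
                                        ("deg_rate_20_50", (0.2, 0.5)),
                                        ("deg_rate_50_80", (0.5, 0.8)))}
    else:
        lysis_lag = t50_lysis = math.nan
        rates = dict(deg_rate_20_80=math.nan, deg_rate_20_50=math.nan,
                     deg_rate_50_80=math.nan)

    order = [clot_lag, t50_clot, float(t[peak])]
    if lysis_detected:
        order += [lysis_lag, t50_lysis]
    finite = [v for v in order if not math.isnan(v)]
    if any(b < a - 1e-9 for a, b in zip(finite, finite[1:])):
        raise ValueError("curve violates the biphasic ordering "
                         "(formation must precede lysis)")
    return TurbidityMetrics(clot_lag=clot_lag, formation_rate=formation_rate,
                            t50_clot=t50_clot, max_od=max_od,
                            lysis_lag=lysis_lag, t50_lysis=t50_lysis,
                            lysis_detected=bool(lysis_detected), **rates)


def fit_decay(x, y) -> DecayFit:
    """Least-squares fit of y = A exp(-k x), initialized from the log-linear
    regression so the result is deterministic in the inputs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 (x, y) points")
    if np.any(y <= 0):
        raise ValueError("y values must be positive for a decaying "
                         "exponential fit")
    if np.allclose(y, y[0]):
        return DecayFit(amplitude=float(y[0]), decay_constant=0.0,
                        residual_ss=0.0, degenerate=True)
    b, a = np.polyfit(x, np.log(y), 1)
    p0 = (math.exp(a), -b)
    popt, _ = curve_fit(lambda xx, A, k: A * np.exp(-k * xx), x, y, p0=p0,
                        maxfev=10000)
    resid = y - popt[0] * np.exp(-popt[1] * x)
    return DecayFit(amplitude=float(popt[0]), decay_constant=float(popt[1]),
                    residual_ss=float(np.sum(resid ** 2)))


def pore_table_stats(table: PoreRegionTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Region-wise pore statistics from timelapse measurements.

    Returns ``(per_timepoint, per_region)``: the spread of pore size across
    regions at each timepoint (variance and SD; NaN when only one region was
    measured), and each region's rate of pore change in um/s (least-squares
    slope of pore size vs time; NaN with fewer than two timepoints).
    """
    df = table.table
    grouped = df.groupby("time_s")["pore_um"]
    per_time = pd.DataFrame({
        "variance": grouped.var(ddof=1),
        "sd": grouped.std(ddof=1),
        "n_regions": grouped.size(),
    }).reset_index()

    def _slope(g: pd.DataFrame) -> float:
        if g["time_s"].nunique() < 2:
            return math.nan
        return float(np.polyfit(g["time_s"], g["pore_um"], 1)[0])

    rates = df.groupby("region")[["time_s", "pore_um"]].apply(_slope)
    per_region = rates.rename("rate_um_per_s").reset_index()
    return per_time, per_region


def synth_turbidity(t_clot: float, tau_clot: float, t_lysis: float,
                    tau_lysis: float, *, amplitude: float = 1.0,
                    baseline: float = 0.0, noise_sd: float = 0.0,
                    duration_s: float = DURATION_S,
                    rng: np.random.Generator | None = None,
                    well: str = "synthetic") -> TurbidityCurve:
    """Synthetic biphasic turbidity curve on the 15 s grid.

    OD(t) = baseline + amplitude * sigmoid((t-t_clot)/tau_clot)
                               * (1 - sigmoid((t-t_lysis)/tau_lysis)) + noise.

    ``t_clot``/``t_lysis`` are the half-formation and half-lysis times;
    the taus set the steepness of each phase.
    """
    if t_lysis <= t_clot:
        raise ValueError("t_lysis must exceed t_clot for a biphasic curve")
    if tau_clot <= 0 or tau_lysis <= 0:
        raise ValueError("time constants must be positive")
    t = np.arange(0.0, duration_s + SAMPLE_INTERVAL_S / 2, SAMPLE_INTERVAL_S)
    rise = 1.0 / (1.0 + np.exp(-(t - t_clot) / tau_clot))
    fall = 1.0 / (1.0 + np.exp(-(t - t_lysis) / tau_lysis))
    od = baseline + amplitude * rise * (1.0 - fall)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        od = od + rng.normal(0.0, noise_sd, size=t.size)
    return TurbidityCurve(times=t, od_raw=od, well=well)
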