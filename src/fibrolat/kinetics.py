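"""Single-fiber lysis kinetics: tPA unbinding times, fiber lysis times and the
forced-unbinding branch.

The macroscale engine is agnostic about where these distributions come from.
They may be loaded from plain-text sample files (empirical CDFs produced by a
detailed single-fiber model, sampled by inverse transform with linear
interpolation between order statistics) or constructed parametrically as
exponential surrogates.  A censored lysis draw ("inf") means that particular
tPA initiation never transects the fiber.

Two quantities are fixed by the macroscale model itself rather than by the
sampled distributions:

* the forced-unbinding probability ``q`` - per binding event, the chance that
  plasmin-mediated degradation ejects the tPA onto a small fibrin degradation
  product instead of it unbinding kinetically (0.0852 for 72.7 nm fibers,
  0.0729129 for 145.4 nm fibers);
* the small-FDP waiting time ``1/k_off`` with ``k_off = 0.036``, i.e. about
  27.78 s during which tPA on a small FDP diffuses but cannot rebind.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticsModel",
    "load_kinetics",
    "default_kinetics",
    "sample_unbind_time",
    "sample_lysis_time",
    "CENSORED",
    "K_OFF_PER_S",
    "FORCED_UNBIND_PROB",
]

K_OFF_PER_S = 0.036
#: value returned by :func:`sample_lysis_time` for a non-lytic initiation
CENSORED = np.inf

FORCED_UNBIND_PROB = {72.7: 0.0852, 145.4: 0.0729129}

# Surrogate defaults, used when no empirical CDF files are supplied.  Mean
# unbinding time is anchored at the physiological 1/k_off; single-fiber
# transection is taken an order of magnitude slower (a single tPA initiation
# needs minutes of plasmin activity to sever a fiber), and half of all
# initiations are censored, so fibers typically need several initiations.
DEFAULT_MEAN_UNBIND_S = 1.0 / K_OFF_PER_S
DEFAULT_MEAN_LYSIS_S = 300.0
DEFAULT_LYSIS_PROB = 0.5


@dataclass(frozen=True)
class KineticsModel:
    """Sampling model for one fiber diameter.

    Either ``unbind_time_samples``/``lysis_time_samples`` hold empirical CDF
    supports (sorted, seconds; lysis censoring already stripped into
    ``lysis_prob``), or they are ``None`` and the exponential means are used.
    """

    fiber_diameter: float                       # nm
    forced_unbind_prob: float                   # q, in (0, 1)
    koff_wait_s: float = 1.0 / K_OFF_PER_S      # small-FDP waiting time, s
    unbind_time_samples: np.ndarray | None = field(default=None, repr=False)
    lysis_time_samples: np.ndarray | None = field(default=None, repr=False)
    mean_unbind_s: float | None = None
    mean_lysis_s: float | None = None
    lysis_prob: float = 1.0                     # P(an initiation is lytic)

    def __post_init__(self) -> None:
        if not 0.0 < self.forced_unbind_prob < 1.0:
            raise ValueError("forced_unbind_prob must be in (0, 1)")
        if not 0.0 <= self.lysis_prob <= 1.0:
            raise ValueError("lysis_prob must be in [0, 1]")
        if self.koff_wait_s <= 0:
            raise ValueError("koff_wait_s must be positive")
        for arr in (self.unbind_time_samples, self.lysis_time_samples):
            if arr is not None and arr.size and arr.min() < 0:
                raise ValueError("time samples must be non-negative")
        if self.unbind_time_samples is None and self.mean_unbind_s is None:
            raise ValueError("need unbinding samples or a parametric mean")
        if (self.lysis_time_samples is None and self.mean_lysis_s is None
                and self.lysis_prob > 0):
            raise ValueError("need lysis samples or a parametric mean")


def _empirical_quantile(sorted_samples: np.ndarray, u: np.ndarray | float):
    """Inverse-transform draw: linear interpolation between order statistics
    (the quantile at u lies at fractional index u*(n-1))."""
    n = sorted_samples.size
    if n == 1:
        return sorted_samples[0] * np.ones_like(np.asarray(u, dtype=float))
    idx = np.asarray(u, dtype=float) * (n - 1)
    return np.interp(idx, np.arange(n), sorted_samples)


def _parse_sample_file(path) -> dict[str, np.ndarray]:
    """Read a kinetics sample file: header row naming each column, one numeric
    sample per line; the token ``inf`` marks a censored lysis outcome."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty kinetics sample file")
    header = lines[0].split()
    cols: dict[str, list[float]] = {h: [] for h in header}
    if len(cols) != len(header):
        raise ValueError(f"{path}: duplicate column names in header")
    for lineno, ln in enumerate(lines[1:], start=2):
        toks = ln.split()
        if len(toks) > len(header):
            raise ValueError(f"{path}:{lineno}: more values than columns")
        for h, tok in zip(header, toks):
            try:
                val = float(tok)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: unreadable token {tok!r}") from None
            if np.isnan(val) or (np.isfinite(val) and val < 0):
                raise ValueError(f"{path}:{lineno}: invalid sample {tok!r}")
            cols[h].append(val)
    return {h: np.asarray(v, dtype=float) for h, v in cols.items()}


def load_kinetics(path, fiber_diameter: float, *,
                  forced_unbind_prob: float | None = None) -> KineticsModel:
    """Build a kinetics model from a plain-text sample file.

    The file holds one column per distribution, named ``unbind`` and ``lysis``
    in a whitespace-separated header.  Lysis samples equal to ``inf`` are
    censored initiations; their fraction sets the complement of
    ``lysis_prob`` and only the finite samples form the sampled CDF.
    """
    cols = _parse_sample_file(path)
    try:
        unbind = cols["unbind"]
        lysis = cols["lysis"]
    except KeyError as exc:
        raise ValueError(f"{path}: missing required column {exc}") from None
    if unbind.size == 0 or lysis.size == 0:
        raise ValueError(f"{path}: empty sample column")
    if not np.all(np.isfinite(unbind)):
        raise ValueError(f"{path}: unbinding samples must be finite")
    finite = lysis[np.isfinite(lysis)]
    lysis_prob = finite.size / lysis.size
    q = forced_unbind_prob
    if q is None:
        q = FORCED_UNBIND_PROB.get(fiber_diameter)
    if q is None:
        raise ValueError(
            f"no canonical forced-unbinding probability for diameter "
            f"{fiber_diameter} nm; pass forced_unbind_prob explicitly")
    return KineticsModel(
        fiber_diameter=fiber_diameter,
        forced_unbind_prob=q,
        unbind_time_samples=np.sort(unbind),
        lysis_time_samples=np.sort(finite) if finite.size else np.zeros(0),
        lysis_prob=lysis_prob,
    )


def default_kinetics(fiber_diameter: float,
                     mean_unbind_s: float = DEFAULT_MEAN_UNBIND_S,
                     mean_lysis_s: float = DEFAULT_MEAN_LYSIS_S,
                     lysis_prob: float = DEFAULT_LYSIS_PROB, *,
                     forced_unbind_prob: float | None = None) -> KineticsModel:
    """Parametric surrogate kinetics: exponential unbinding and lysis times.

    ``q`` and the 1/k_off waiting time take their canonical values for the
    given diameter; an unsupported diameter requires an explicit ``q``.
    """
    if mean_unbind_s <= 0 or mean_lysis_s <= 0:
        raise ValueError("means must be positive")
    if not 0.0 < lysis_prob <= 1.0:
        raise ValueError("lysis_prob must be in (0, 1]")
    q = forced_unbind_prob
    if q is None:
        q = FORCED_UNBIND_PROB.get(fiber_diameter)
    if q is None:
        raise ValueError(
            f"no canonical forced-unbinding probability for diameter "
            f"{fiber_diameter} nm; pass forced_unbind_prob explicitly")
    return KineticsModel(fiber_diameter=fiber_diameter, forced_unbind_prob=q,
                         mean_unbind_s=mean_unbind_s, mean_lysis_s=mean_lysis_s,
                         lysis_prob=lysis_prob)


def sample_unbind_time(model: KineticsModel, rng: np.random.Generator,
                       size=None):
    """Draw tPA unbinding time(s) in seconds."""
    if model.unbind_time_samples is not None:
        return _empirical_quantile(model.unbind_time_samples,
                                   rng.random(size))
    return rng.exponential(model.mean_unbind_s, size)


def sample_lysis_time(model: KineticsModel, rng: np.random.Generator,
                      size=None):
    """Draw fiber lysis time(s) in seconds; ``inf`` marks a censored
    (non-lytic) initiation."""
    u = rng.random(size)
    lytic = u < model.lysis_prob
    if model.lysis_time_samples is not None:
        if model.lysis_time_samples.size == 0:
            vals = np.full(np.shape(u), CENSORED)
            return vals if size is not None else float(vals)
        draws = _empirical_quantile(model.lysis_time_samples, rng.random(size))
    else:
        draws = rng.exponential(model.mean_lysis_s, size)
    out = np.where(lytic, draws, CENSORED)
    return out if size is not None else float(out)
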