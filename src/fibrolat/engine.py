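"""Macroscale internal-lysis engine: tPA random walk, binding, kinetic and
forced unbinding, fiber degradation, FDP transport and transit bookkeeping.

The model follows the internal-lysis picture: tPA molecules start uniformly
distributed inside the clot, hop one pore per time step (the step is chosen
so a molecule diffuses one inter-fiber spacing per step), bind on contact to
an adjacent intact fiber, and on binding draw an unbinding time, a forced-
unbinding coin, and a (possibly censored) fiber lysis time.  A fiber degrades
at the minimum scheduled lysis time over all its initiations.  tPA bound to a
degrading fiber rides a large fibrin degradation product - it may drift only
through already-open pore space and is released at its previously assigned
unbinding time.  Forced-unbinding ejects tPA onto a small FDP that diffuses
freely but cannot rebind for a waiting time of 1/k_off.

Two interchangeable integrators are provided: a fast event-driven kernel
(``engine="event"``, default) and a plain synchronous per-step loop
(``engine="stepwise"``) built from the per-molecule operations below.  Both
implement the same grid-time semantics; the test-suite checks them against
each other and against hand-computed event sequences.

Within a time step the operation order is fixed: degradation events are
applied first, then each molecule moves, then it may bind.  A molecule
released at a step boundary moves and may rebind within that same step, so
the minimum transit time is one time step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .kinetics import KineticsModel, sample_lysis_time, sample_unbind_time
from .lattice import LatticeClot, ScenarioSpec, build_lattice

__all__ = [
    "TpaMolecule",
    "SimulationRecord",
    "SimulationResult",
    "TransitLog",
    "initialize_tpa",
    "step_unbound",
    "attempt_bind",
    "degrade_fiber",
    "step_large_fdp",
    "run_simulation",
    "UNBOUND",
    "BOUND",
    "ON_LARGE_FDP",
    "WAITING_SMALL_FDP",
]

UNBOUND = "UNBOUND"
BOUND = "BOUND"
ON_LARGE_FDP = "ON_LARGE_FDP"
WAITING_SMALL_FDP = "WAITING_SMALL_FDP"

#: large FDPs are bulky fragments: they attempt one hop through open pore
#: space every HOP_SLOWDOWN diffusive steps of a free tPA molecule
HOP_SLOWDOWN = 100

DEFAULT_MAX_TIME_S = 2.0e6


@dataclass
class TpaMolecule:
    """One tPA tracer."""

    id: int
    node: int
    state: str = UNBOUND
    bound_edge: int | None = None
    scheduled_unbind_time: float = math.inf   # s
    forced: bool = False
    waiting_until: float = math.inf           # s (small-FDP release)
    transit_start: float | None = None        # s, open transit episode


@dataclass(frozen=True)
class SimulationRecord:
    time: float
    degraded_fraction: float
    intact_mask: np.ndarray | None = None


@dataclass(frozen=True)
class TransitLog:
    """Per-episode transit bookkeeping: a transit starts when a molecule
    starts moving (kinetic unbind or fiber breakup) and ends at its next
    binding event."""

    molecule: np.ndarray   # episode -> molecule id
    start_s: np.ndarray
    duration_s: np.ndarray

    @property
    def end_s(self) -> np.ndarray:
        return self.start_s + self.duration_s


@dataclass
class SimulationResult:
    spec: ScenarioSpec
    seed: int
    degrade_time_s: np.ndarray        # per edge, inf if never degraded
    transit: TransitLog
    n_binds: int
    n_forced_unbinds: int
    end_time_s: float
    truncated: bool
    record_interval: float
    clot: LatticeClot = field(repr=False)

    @property
    def n_edges(self) -> int:
        return self.degrade_time_s.size

    def intact_mask(self, time: float) -> np.ndarray:
        return self.degrade_time_s > time

    def degraded_fraction_at(self, time: float) -> float:
        return float((self.degrade_time_s <= time).sum()) / self.n_edges

    def records(self, with_masks: bool = False) -> list[SimulationRecord]:
        times = self.record_times()
        out = []
        for t in times:
            mask = self.intact_mask(t) if with_masks else None
            out.append(SimulationRecord(float(t), self.degraded_fraction_at(t), mask))
        return out

    def record_times(self) -> np.ndarray:
        last = max(self.end_time_s, self.record_interval)
        n = int(math.ceil(last / self.record_interval - 1e-9))
        return np.arange(0, n + 1) * self.record_interval

    def curve(self):
        from .summaries import DegradationCurve
        times = self.record_times()
        finite = np.sort(self.degrade_time_s[np.isfinite(self.degrade_time_s)])
        frac = np.searchsorted(finite, times, side="right") / self.n_edges
        return DegradationCurve(times=times, fraction_degraded=frac)


# ---------------------------------------------------------------------------
# per-molecule operations (also the building blocks of the stepwise engine)
# ---------------------------------------------------------------------------

def initialize_tpa(clot: LatticeClot, n_tpa: int,
                   rng: np.random.Generator) -> list[TpaMolecule]:
    """Seed n_tpa unbound molecules at uniformly random lattice nodes."""
    if n_tpa < 0:
        raise ValueError("n_tpa must be non-negative")
    nodes = rng.integers(0, clot.n_nodes, size=n_tpa)
    return [TpaMolecule(id=m, node=int(nodes[m])) for m in range(n_tpa)]


def step_unbound(mol: TpaMolecule, clot: LatticeClot,
                 rng: np.random.Generator) -> TpaMolecule:
    """One diffusive hop: uniform among the four in-plane directions, with a
    move into a reflecting wall leaving the position unchanged."""
    i, j = clot.node_ij(mol.node)
    r = int(rng.integers(0, 4))
    if r == 0 and i < clot.nx - 1:
        i += 1
    elif r == 1 and i > 0:
        i -= 1
    elif r == 2 and j < clot.ny - 1:
        j += 1
    elif r == 3 and j > 0:
        j -= 1
    mol.node = clot.node_id(i, j)
    return mol


def attempt_bind(mol: TpaMolecule, clot: LatticeClot, kinetics: KineticsModel,
                 rng: np.random.Generator, time: float,
                 edge_degrade_time: np.ndarray,
                 bind_prob: float = 1.0) -> int | None:
    """Binding attempt at the molecule's current node.

    With probability ``bind_prob`` the molecule binds a uniformly chosen
    adjacent intact fiber.  On binding it is assigned an unbinding time from
    the kinetics model and a uniform number against the forced-unbinding
    probability q; a lysis time is drawn and, if lytic, the fiber's scheduled
    degradation time is lowered to the minimum of the existing schedule and
    now + lysis time.  An open transit episode closes at the bind time.
    Returns the bound edge id, or None.
    """
    candidates = [e for e in clot.incident_edges(mol.node) if clot.intact[e]]
    if not candidates:
        return None
    if bind_prob < 1.0 and rng.random() >= bind_prob:
        return None
    e = int(candidates[int(rng.integers(0, len(candidates)))])
    if not clot.intact[e]:
        raise RuntimeError("internal inconsistency: binding a degraded fiber")
    t_u = float(sample_unbind_time(kinetics, rng))
    mol.scheduled_unbind_time = time + max(t_u, 0.0)
    mol.forced = rng.random() < kinetics.forced_unbind_prob
    mol.state = BOUND
    mol.bound_edge = e
    t_l = float(sample_lysis_time(kinetics, rng))
    if math.isfinite(t_l):
        edge_degrade_time[e] = min(edge_degrade_time[e], time + t_l)
    if mol.transit_start is not None:
        mol.transit_start = None
    return e


def degrade_fiber(clot: LatticeClot, e: int, time: float,
                  molecules: list[TpaMolecule]) -> None:
    """Mark a fiber degraded; any tPA still bound to it rides a large FDP,
    keeping its previously assigned unbinding time."""
    if not clot.intact[e]:
        raise RuntimeError(f"internal inconsistency: edge {e} degraded twice")
    clot.intact[e] = False
    for mol in molecules:
        if mol.state == BOUND and mol.bound_edge == e:
            mol.state = ON_LARGE_FDP
            mol.transit_start = time


def step_large_fdp(mol: TpaMolecule, clot: LatticeClot,
                   rng: np.random.Generator) -> TpaMolecule:
    """One hop attempt of a large-FDP rider: uniformly to an adjacent
    degraded edge, staying put if no open space is adjacent."""
    e0 = mol.bound_edge
    a, b = clot.edge_endpoints(e0)
    cands = []
    for n in (a, b) if b != a else (a,):
        for e in clot.incident_edges(n):
            if e != e0 and not clot.intact[e]:
                cands.append(e)
    if cands:
        mol.bound_edge = int(cands[int(rng.integers(0, len(cands)))])
    return mol


# ---------------------------------------------------------------------------
# engines
# ---------------------------------------------------------------------------

def _kinetics_kernel_args(kin: KineticsModel):
    empty = np.zeros(1)
    if kin.unbind_time_samples is not None:
        u_mode, u_mean, u_samp = 1, 0.0, np.asarray(kin.unbind_time_samples, float)
    else:
        u_mode, u_mean, u_samp = 0, float(kin.mean_unbind_s), empty
    if kin.lysis_time_samples is not None:
        arr = np.asarray(kin.lysis_time_samples, float)
        if arr.size == 0:
            l_mode, l_mean, l_samp, lp = 0, 1.0, empty, 0.0
        else:
            l_mode, l_mean, l_samp, lp = 1, 0.0, arr, kin.lysis_prob
    else:
        l_mode, l_mean, l_samp, lp = 0, float(kin.mean_lysis_s), empty, kin.lysis_prob
    return u_mode, u_mean, u_samp, l_mode, l_mean, l_samp, lp


def run_simulation(spec: ScenarioSpec, kinetics: KineticsModel,
                   rng_seed: int | None = None, *,
                   bind_prob: float = 1.0,
                   max_time: float | None = DEFAULT_MAX_TIME_S,
                   record_interval: float | None = None,
                   engine: str = "event") -> SimulationResult:
    """Run one internal-lysis simulation until full clot degradation (or a
    truncation guard).  Same seed, same installation => identical output."""
    if abs(spec.fiber_diameter - kinetics.fiber_diameter) > 1e-9:
        raise ValueError(
            f"scenario diameter {spec.fiber_diameter} nm does not match "
            f"kinetics diameter {kinetics.fiber_diameter} nm")
    if kinetics.lysis_prob == 0.0 and max_time is None:
        raise ValueError("non-lytic kinetics with no max_time would never "
                         "terminate; set max_time")
    if max_time is None:
        max_time = DEFAULT_MAX_TIME_S
    seed = spec.rng_seed if rng_seed is None else int(rng_seed)
    dt = spec.time_step
    rec = spec.record_interval if record_interval is None else float(record_interval)
    max_steps = int(math.ceil(max_time / dt))
    koff_steps = max(1, int(math.ceil(kinetics.koff_wait_s / dt)))
    clot = build_lattice(spec)
    if engine == "event":
        u_mode, u_mean, u_samp, l_mode, l_mean, l_samp, lp = \
            _kinetics_kernel_args(kinetics)
        Qx, lx = _kernel.walk_eigensystem(spec.grid_nx)
        Qy, ly = _kernel.walk_eigensystem(spec.grid_ny)
        (dstep, t_m, t_s, t_d, n_binds, n_forced, end_step, truncated) = \
            _kernel.run_kernel(
                spec.grid_nx, spec.grid_ny, spec.n_tpa, seed, dt,
                np.int64(max_steps), float(bind_prob),
                float(kinetics.forced_unbind_prob), float(lp),
                np.int64(koff_steps), np.int64(HOP_SLOWDOWN),
                u_mode, u_mean, u_samp, l_mode, l_mean, l_samp,
                Qx, lx, Qy, ly)
        degrade_time = np.where(dstep >= _kernel.INF, np.inf, dstep * dt)
        clot.intact[:] = ~np.isfinite(degrade_time) | (degrade_time > end_step * dt)
        transit = TransitLog(molecule=t_m.astype(int), start_s=t_s * dt,
                             duration_s=t_d * dt)
        return SimulationResult(
            spec=spec, seed=seed, degrade_time_s=degrade_time,
            transit=transit, n_binds=int(n_binds),
            n_forced_unbinds=int(n_forced), end_time_s=end_step * dt,
            truncated=bool(truncated), record_interval=rec, clot=clot)
    if engine == "stepwise":
        return _run_stepwise(spec, kinetics, seed, bind_prob, max_steps,
                             koff_steps, rec, clot)
    raise ValueError(f"unknown engine {engine!r}")


def _run_stepwise(spec, kinetics, seed, bind_prob, max_steps, koff_steps,
                  rec, clot) -> SimulationResult:
    """Plain synchronous per-step reference loop (small problems only)."""
    dt = spec.time_step
    rng = np.random.default_rng(seed)
    mols = initialize_tpa(clot, spec.n_tpa, rng)
    n_edges = clot.n_edges
    edge_degrade_time = np.full(n_edges, math.inf)
    degrade_step = np.full(n_edges, np.inf)
    lf_since = {}           # molecule id -> breakup step (hop cadence)
    ep_mol, ep_start, ep_dur = [], [], []
    n_binds = 0
    n_forced = 0
    step = 0
    truncated = False
    while clot.intact.any():
        step += 1
        if step > max_steps:
            truncated = True
            step = max_steps
            break
        t = step * dt
        # 1) degradation events due at this boundary
        due = np.flatnonzero(clot.intact & (edge_degrade_time <= t + 1e-12))
        for e in due:
            degrade_step[e] = step
            degrade_fiber(clot, int(e), t, mols)
            for mol in mols:
                if mol.state == ON_LARGE_FDP and mol.bound_edge == e \
                        and mol.id not in lf_since:
                    lf_since[mol.id] = step
        # 2) molecules: transitions, movement, binding
        for mol in mols:
            if mol.state == BOUND:
                if mol.scheduled_unbind_time <= t + 1e-12:
                    mol.bound_edge = None
                    if mol.forced:
                        # ejection onto a small FDP opens no transit episode;
                        # one opens when the tPA kinetically unbinds from the
                        # small FDP at the end of the 1/k_off wait
                        mol.state = WAITING_SMALL_FDP
                        mol.waiting_until = t + koff_steps * dt
                    else:
                        mol.state = UNBOUND
                        mol.transit_start = t
                        step_unbound(mol, clot, rng)
                        self_bind = attempt_bind(mol, clot, kinetics, rng, t,
                                                 edge_degrade_time, bind_prob)
                        if self_bind is not None:
                            ep_mol.append(mol.id)
                            ep_start.append(t)
                            ep_dur.append(dt)
                            n_binds += 1
                            n_forced += mol.forced
                continue
            if mol.state == WAITING_SMALL_FDP:
                step_unbound(mol, clot, rng)
                if mol.waiting_until <= t + 1e-12:
                    mol.state = UNBOUND
                    mol.transit_start = t
                    e = attempt_bind(mol, clot, kinetics, rng, t,
                                     edge_degrade_time, bind_prob)
                    if e is not None:
                        ep_mol.append(mol.id)
                        ep_start.append(t)
                        ep_dur.append(dt)
                        n_binds += 1
                        n_forced += mol.forced
                continue
            if mol.state == ON_LARGE_FDP:
                if mol.scheduled_unbind_time <= t + 1e-12:
                    a, b = clot.edge_endpoints(mol.bound_edge)
                    start = lf_start_time(mol, degrade_step, dt)
                    mol.node = a if (b == a or rng.random() < 0.5) else b
                    mol.state = UNBOUND
                    mol.bound_edge = None
                    lf_since.pop(mol.id, None)
                    step_unbound(mol, clot, rng)
                    e = attempt_bind(mol, clot, kinetics, rng, t,
                                     edge_degrade_time, bind_prob)
                    if e is not None:
                        ep_mol.append(mol.id)
                        ep_start.append(start)
                        ep_dur.append(t - start + dt)
                        n_binds += 1
                        n_forced += mol.forced
                    else:
                        mol.transit_start = start
                elif (step - lf_since.get(mol.id, step)) % HOP_SLOWDOWN == 0 \
                        and mol.id in lf_since and step > lf_since[mol.id]:
                    step_large_fdp(mol, clot, rng)
                continue
            # UNBOUND
            start = mol.transit_start
            step_unbound(mol, clot, rng)
            e = attempt_bind(mol, clot, kinetics, rng, t,
                             edge_degrade_time, bind_prob)
            if e is not None:
                if start is not None:
                    ep_mol.append(mol.id)
                    ep_start.append(start)
                    ep_dur.append(t - start + dt)
                n_binds += 1
                n_forced += mol.forced
    degrade_time = degrade_step * dt
    transit = TransitLog(molecule=np.asarray(ep_mol, dtype=int),
                         start_s=np.asarray(ep_start, dtype=float),
                         duration_s=np.asarray(ep_dur, dtype=float))
    return SimulationResult(
        spec=spec, seed=seed, degrade_time_s=degrade_time, transit=transit,
        n_binds=n_binds, n_forced_unbinds=int(n_forced),
        end_time_s=step * dt, truncated=truncated, record_interval=rec,
        clot=clot)


def lf_start_time(mol: TpaMolecule, degrade_step: np.ndarray, dt: float) -> float:
    if mol.transit_start is not None:
        return mol.transit_start
    e = mol.bound_edge
    if e is not None and np.isfinite(degrade_step[e]):
        return degrade_step[e] * dt
    return 0.0
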