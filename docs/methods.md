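# Methods

## Model geometry and conventions

The clot is a 3D square lattice one fiber thick in the out-of-plane
direction: nodes at (i·δ, j·δ) for 0 ≤ i < nx, 0 ≤ j < ny, with δ the pore
size. Edges — one fibrin fiber each — are the in-plane bonds between
adjacent nodes plus one z-edge per node; the out-of-plane direction is
periodic with period one, so a z-fiber joins a node to its own image and
molecule motion is effectively in-plane. In-plane boundaries are
reflecting: a hop into a wall leaves the position unchanged for that step.
The edge count is 3·nx·ny − nx − ny.

The canonical scenario catalog fixes fiber counts, tPA counts, ratios and
concentrations; grid dimensions are not part of that specification, so the
catalog stores near-square best fits to the fiber counts (aspect ≤ 1.2):
exact for the 25,761-fiber loose clots at 93×93, within 0.5% elsewhere
(212×187 → 118,533; 55×46 → 7,489; 117×98 → 34,183). The stated pore sizes
are 0.22 μm (dense) and 1.0135 μm (loose); the time step scales
diffusively, Δt ∝ δ², between 1.613×10⁻⁵ s (dense) and 3.424×10⁻⁴ s
(loose). Note the printed step pair is itself rounded: the quadratic map of
the dense value gives 3.4232×10⁻⁴ s, one unit in the fourth digit from the
loose value.

## Single-fiber kinetics

The macroscale engine consumes three ingredients per fiber diameter:

* **Unbinding-time distribution** — how long a bound tPA stays before
  kinetically unbinding.
* **Lysis-time distribution with censoring** — per tPA initiation, when (or
  whether) that initiation transects the fiber. A fiber degrades at the
  minimum over its initiations' scheduled times.
* **Forced-unbinding probability q** and the small-FDP waiting time
  1/k_off: q = 0.0852 (72.7 nm) or 0.0729129 (145.4 nm); k_off = 0.036, so
  the wait is ≈ 27.78 s. These are model constants, not fitted here.

Distributions may be loaded from plain-text sample files (inverse-transform
sampling with linear interpolation between order statistics — the quantile
at u sits at fractional index u·(n−1)) or constructed as exponential
surrogates. The surrogate defaults are: mean unbinding time 1/k_off
= 27.78 s (anchored to the same physiological rate the waiting time uses);
mean lysis time 300 s — an order of magnitude slower than unbinding, so a
fiber typically needs several initiations before transection, consistent
with plasmin-mediated severing being much slower than tPA turnover; and
lysis probability 0.5 (half of initiations never sever the fiber). These
are surrogate values, not calibrated to data; users with single-fiber model
output should load it via `load_kinetics`. Unbinding and lysis draws are
treated as independent.

## Engine semantics

All event times live on the integer step grid: a scheduled event takes
effect at the first step boundary at or after its scheduled time. Within a
step the order is: degradation events, then per molecule movement, then
binding. A molecule released at a boundary moves and may rebind in that
same step, so the minimum transit duration is one Δt.

Binding is on-contact by default (`bind_prob = 1`): at a node with at least
one adjacent intact fiber (up to four in-plane edges plus the node's
z-edge) the molecule binds a uniformly chosen one. `bind_prob` is exposed
as the primary tunable against measured transit times.

State machine per molecule: UNBOUND (diffusing, bindable) → BOUND →
either kinetic unbind (→ UNBOUND), forced unbind (→ WAITING_SMALL_FDP:
diffusing freely, not bindable until the 1/k_off wait elapses), or fiber
breakup (→ ON_LARGE_FDP: hops only between adjacent degraded edges,
released at its previously assigned unbinding time at one of the edge's
endpoint nodes). Large FDPs are bulky fragments; they attempt one hop per
100 diffusive steps (`HOP_SLOWDOWN`), a two-orders-of-magnitude slower
diffusivity than free tPA. They do not block other molecules.

**Transit episodes** open when a molecule starts moving due to (a) kinetic
unbinding from an intact fiber, (b) breakup of the fiber it is bound to, or
(c) kinetic unbinding from a small FDP at the end of the 1/k_off wait; they
close at the next binding event. The forced ejection itself opens no
episode — the ejection is not a kinetic unbinding from an intact fiber, and
starting the clock at the wait's end is the only reading compatible with
transit means of a few hundredths of a minute (q·27.78 s alone is
≈ 0.04 min). Large-FDP episodes do include the non-bindable riding time.

Two integrators share these semantics. The default event-driven kernel
(numba) advances a priority queue: bound molecules sleep until unbinding or
breakup; small-FDP waits are fast-forwarded by sampling the exact k-step
distribution of the in-plane walk (the number of x-moves is Binomial(k,½);
each 1-D marginal uses the eigendecomposition of the tridiagonal
walk-with-holding-at-walls matrix), which is distribution-preserving, not
approximate; unbound molecules are stepped hop by hop. Fiber state is
lazy: each edge stores its earliest scheduled lysis time and is degraded
iff that time has been reached, so degradation records are reconstructed
exactly from the final schedule. The second integrator is a plain
synchronous per-step loop built from the public per-molecule operations;
the suite checks the two agree exactly on hand-computable event sequences
and distributionally (Kolmogorov–Smirnov on full-lysis times and transit
durations) on small lattices. Runs are bit-reproducible for a given seed
and installation. A truncation guard (default 10⁶–2×10⁶ s) bounds
non-lytic configurations, which otherwise never terminate.

## Summaries

* **Thresholds** use the "first record at or above" rule with no
  interpolation — for the lag (5%) and the 20/50/80% times, and for the
  pore-expansion checkpoints, so a single consistent convention covers
  both. With coarse record intervals the first record can overshoot the
  nominal fraction; that is a property of the recording cadence, shared by
  threshold times and checkpoints alike.
* **Rates** are ordinary least-squares slopes over the records whose
  fraction lies in the closed window, converted to fraction of clot per
  minute.
* **Pore profiles**: one horizontal scan line per lattice row crossing that
  row's y-edges and one vertical line per column crossing its x-edges
  (z-edges never intersect an in-plane line). A gap spanning k consecutive
  degraded crossings contributes (k+1)·δ; runs touching the boundary are
  truncated there (implemented as virtual intact crossings just outside the
  clot), which makes the intact-lattice mean exactly δ. The pooled mean gap
  is therefore total line length over gap count; removing fibers can only
  increase it. Rate of pore change is Δ(mean pore)/Δt per inter-checkpoint
  interval, in μm/s.
* **Replicate aggregation** is mean ± sample SD (ddof = 1).

## Turbidity analysis

Curves are normalized to the first point (background) and then to the
maximum ("fraction of the clot"); the rising phase is everything up to the
first maximum, the falling phase everything after. Defined quantities:
maximum OD (background-normalized); lysis lag = first post-peak time at or
below 0.95; time to 50% lysis = post-peak time closest to 0.5 (ties to the
earlier time); degradation rates = negated OLS slopes of the post-peak
fraction within the 0.2–0.8 / 0.2–0.5 / 0.5–0.8 bands, reported positive in
fraction/min. The clotting-side conventions mirror these (the source
assay defines only the lysis side numerically): clotting lag = first rising
time at or above 0.05; formation rate = rising-phase OLS slope over
0.2–0.8; time to 50% clot = rising time closest to 0.5. Metrics other than
the maximum OD are invariant under uniform OD scaling. A curve with no
post-peak decline gets NaN degradation fields and `lysis_detected=False`;
a non-increasing time axis is rejected at construction.

`fit_decay` fits y = A·exp(−k·x) by nonlinear least squares initialized
from the log-linear regression, hence deterministic in the inputs; exactly
exponential data are recovered to ≥ 6 significant figures. The synthetic
generator produces product-of-logistics biphasic curves on the 15 s grid
with optional Gaussian noise, for parameter-recovery testing.

## What the synthetic conditions do and do not show

The desk-scale study conditions (used by tests and `scripts/acceptance.py`)
run every catalog scenario on a 34×30 grid (2,996 fibers) with the tPA
count scaled by the fiber-count ratio, ten replicates, surrogate kinetics,
bind-on-contact, and the catalog record intervals. Problem sizes were fixed
for single-CPU runtimes before any result inspection. Passing checks on
these conditions demonstrate the mechanism — pore expansion concentrated
around half lysis, loose networks growing far larger pores in absolute
terms while dense networks change more in relative terms, transit times
longer in loose networks — under *surrogate* kinetics on *reduced* grids.
They do not calibrate absolute times against experiments: with exponential
surrogates the absolute lag/t50 values have no laboratory meaning, small
grids shorten late-stage searches, and coarse record intervals inflate
checkpoint overshoot (visible as percent-pore-change values above the
nominal expectation in the fastest-lysing scenarios).

## Known limitations

No flow or advection, no inhibitors (PAI-1), no clot contraction, no
external-lysis (bolus) mode, no conversion between OD and fibrin mass, and
no recreation of the original single-fiber biochemistry — its distributions
enter only through sample files or the surrogate family. Fiber diameter
influences the simulation only through q (and whatever diameter-specific
kinetics files a user supplies), so diameter effects are muted under the
surrogate defaults. z-fibers are sampled for binding like any other edge but, being incident to
a single node while in-plane fibers are shared by two, they accumulate
initiations at roughly half the rate; since scan lines see only in-plane
fibers, the in-plane degraded fraction runs somewhat ahead of the overall
fraction, which nudges pore-size checkpoints upward.
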