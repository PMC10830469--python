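"""Fibrin network geometry, modeling scenarios, dosing arithmetic and pore metrics.

The model clot is a 3D square lattice one fiber thick in the out-of-plane
direction: ``nx x ny`` nodes spaced ``delta`` (the pore size) apart, with an
x- and y-oriented edge between adjacent in-plane nodes and a single z-oriented
edge per node (periodic out of plane, so a z-fiber connects a node to itself
one period away).  Every lattice edge represents one fibrin fiber.  Boundaries
are reflecting in-plane and periodic out-of-plane.

Edge count of an ``nx x ny`` lattice::

    (nx - 1) * ny  x-edges  +  nx * (ny - 1)  y-edges  +  nx * ny  z-edges
      = 3 * nx * ny - nx - ny
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "ScenarioSpec",
    "LatticeClot",
    "DoseSpec",
    "PoreProfile",
    "build_lattice",
    "scenario_catalog",
    "get_scenario",
    "load_scenario",
    "scale_scenario",
    "tpa_dose",
    "scale_time_step",
    "measure_pores",
    "fit_grid",
]

#: canonical structure classes
DENSE_PORE_UM = 0.22
LOOSE_PORE_UM = 1.0135
THIN_DIAMETER_NM = 72.7
THICK_DIAMETER_NM = 145.4
DENSE_TIME_STEP_S = 1.613e-5
LOOSE_TIME_STEP_S = 3.424e-4
TOTAL_FIBRIN_MONOMERS = 5.6e7


@dataclass(frozen=True)
class ScenarioSpec:
    """All constants defining one internal-lysis simulation scenario."""

    name: str
    fiber_diameter: float        # nm
    pore_size: float             # um, lattice spacing delta
    n_tpa: int                   # number of tPA molecules seeded in the clot
    n_fibers: int                # nominal fiber (edge) count
    grid_nx: int                 # node count, x
    grid_ny: int                 # node count, y
    time_step: float             # s
    record_interval: float       # s, degradation-state recording cadence
    tpa_fibrin_ratio: float      # molecules tPA per fibrin monomer
    tpa_concentration: float     # molecules per um^3 (catalog metadata)
    total_fibrin_monomers: float = TOTAL_FIBRIN_MONOMERS
    n_replicates: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.fiber_diameter <= 0 or self.pore_size <= 0:
            raise ValueError("fiber_diameter and pore_size must be positive")
        if self.n_tpa < 0:
            raise ValueError("n_tpa must be non-negative")
        if self.n_fibers <= 0:
            raise ValueError("n_fibers must be positive")
        if self.grid_nx < 1 or self.grid_ny < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.time_step <= 0 or self.record_interval <= 0:
            raise ValueError("time_step and record_interval must be positive")

    @property
    def grid_edge_count(self) -> int:
        """Edge count actually realized by the stored grid dimensions."""
        return 3 * self.grid_nx * self.grid_ny - self.grid_nx - self.grid_ny

    @property
    def is_dense(self) -> bool:
        return self.pore_size < 0.5 * (DENSE_PORE_UM + LOOSE_PORE_UM)


@dataclass
class LatticeClot:
    """The fibrin network: node grid, edge states, boundary conventions.

    Edges are indexed x-edges first (``j*(nx-1)+i``), then y-edges
    (``offset + j*nx + i``), then z-edges (``offset + j*nx + i``).
    """

    nx: int
    ny: int
    spacing: float                       # um
    intact: np.ndarray = field(repr=False)  # bool per edge
    boundary: str = "reflecting in-plane, periodic out-of-plane"

    def __init__(self, nx: int, ny: int, spacing: float):
        if nx < 1 or ny < 1:
            raise ValueError("grid dimensions must be >= 1")
        if spacing <= 0:
            raise ValueError("spacing must be positive")
        self.nx = int(nx)
        self.ny = int(ny)
        self.spacing = float(spacing)
        self.intact = np.ones(self.n_edges, dtype=bool)
        self.boundary = "reflecting in-plane, periodic out-of-plane"

    # --- index bookkeeping -------------------------------------------------
    @property
    def n_x_edges(self) -> int:
        return (self.nx - 1) * self.ny

    @property
    def n_y_edges(self) -> int:
        return self.nx * (self.ny - 1)

    @property
    def n_z_edges(self) -> int:
        return self.nx * self.ny

    @property
    def n_edges(self) -> int:
        return self.n_x_edges + self.n_y_edges + self.n_z_edges

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    def node_id(self, i: int, j: int) -> int:
        return j * self.nx + i

    def node_ij(self, node: int) -> tuple[int, int]:
        return node % self.nx, node // self.nx

    def edge_endpoints(self, e: int) -> tuple[int, int]:
        """Node ids joined by edge ``e`` (z-edges return the node twice)."""
        nx, nxe, nye = self.nx, self.n_x_edges, self.n_y_edges
        if e < 0 or e >= self.n_edges:
            raise IndexError(f"edge {e} out of range")
        if e < nxe:
            i, j = e % (nx - 1), e // (nx - 1)
            a = j * nx + i
            return a, a + 1
        if e < nxe + nye:
            e2 = e - nxe
            a = e2
            return a, a + nx
        a = e - nxe - nye
        return a, a

    def edge_position(self, e: int) -> tuple[float, float, str]:
        """Geometric midpoint (um) and orientation of edge ``e``."""
        a, b = self.edge_endpoints(e)
        ia, ja = self.node_ij(a)
        ib, jb = self.node_ij(b)
        nxe, nye = self.n_x_edges, self.n_y_edges
        orient = "x" if e < nxe else ("y" if e < nxe + nye else "z")
        return (0.5 * (ia + ib) * self.spacing, 0.5 * (ja + jb) * self.spacing, orient)

    def incident_edges(self, node: int) -> list[int]:
        """Edges (fibers) touching a node: up to 4 in-plane plus its z-edge."""
        i, j = self.node_ij(node)
        nx, ny = self.nx, self.ny
        nxe, nye = self.n_x_edges, self.n_y_edges
        out = []
        if i > 0:
            out.append(j * (nx - 1) + (i - 1))
        if i < nx - 1:
            out.append(j * (nx - 1) + i)
        if j > 0:
            out.append(nxe + (j - 1) * nx + i)
        if j < ny - 1:
            out.append(nxe + j * nx + i)
        out.append(nxe + nye + j * nx + i)
        return out

    def node_neighbors(self, node: int) -> list[int]:
        """In-plane neighbor nodes (reflecting walls: fewer at boundaries)."""
        i, j = self.node_ij(node)
        out = []
        if i > 0:
            out.append(self.node_id(i - 1, j))
        if i < self.nx - 1:
            out.append(self.node_id(i + 1, j))
        if j > 0:
            out.append(self.node_id(i, j - 1))
        if j < self.ny - 1:
            out.append(self.node_id(i, j + 1))
        return out

    @property
    def degraded_fraction(self) -> float:
        return 1.0 - float(self.intact.sum()) / self.n_edges


@dataclass(frozen=True)
class DoseSpec:
    """tPA dose paired with a fibrinogen concentration (plate experiments)."""

    fibrinogen_conc: float   # mg/mL
    tpa_conc: float          # ng/mL
    ratio: float             # ng tPA per mg fibrinogen
    mode: str                # "fixed_concentration" | "fixed_ratio"


@dataclass(frozen=True)
class PoreProfile:
    """Gap sizes recorded along horizontal/vertical scan lines of the clot."""

    gap_sizes: np.ndarray    # um, one per inter-fiber gap
    mean_gap: float          # um
    percent_change: float    # % relative to the intact-lattice mean (= spacing)
    tag: float | None = None  # optional time or degradation-fraction label


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_lattice(spec: ScenarioSpec | None = None, *, nx: int | None = None,
                  ny: int | None = None, spacing: float | None = None) -> LatticeClot:
    """Construct the model clot for a scenario (or explicit dimensions)."""
    if spec is not None:
        nx, ny, spacing = spec.grid_nx, spec.grid_ny, spec.pore_size
    if nx is None or ny is None:
        raise ValueError("either a ScenarioSpec or nx/ny must be given")
    return LatticeClot(nx, ny, spacing if spacing is not None else 1.0)


def fit_grid(target_edges: int, max_aspect: float = 1.2) -> tuple[int, int]:
    """Near-square grid dimensions whose edge count best matches a target.

    The printed fiber counts are the ground truth; grid dimensions are free
    parameters.  Among grids with aspect ratio <= ``max_aspect`` the one with
    the smallest |edge count - target| is chosen (ties broken toward square).
    """
    if target_edges < 1:
        raise ValueError("target_edges must be positive")
    best = None
    upper = int(math.isqrt(target_edges)) * 2 + 3
    for ny in range(1, upper):
        base = (target_edges + ny) / (3 * ny - 1)
        for nx in (int(base), int(base) + 1):
            if nx < 1:
                continue
            if max(nx, ny) / min(nx, ny) > max_aspect:
                continue
            e = 3 * nx * ny - nx - ny
            key = (abs(e - target_edges), abs(nx - ny))
            if best is None or key < best[0]:
                best = (key, (nx, ny))
    if best is None:  # pathological target; fall back to 1-wide strip
        ny = 1
        nx = max(1, round((target_edges + 1) / 2))
        return nx, ny
    return best[1]


def _catalog_raw() -> list[dict]:
    text = resources.files("fibrolat.data").joinpath("scenarios.yaml").read_text()
    return yaml.safe_load(text)


def scenario_catalog() -> list[ScenarioSpec]:
    """The ten canonical modeling scenarios (thin/thick x dense/loose x tPA)."""
    return [ScenarioSpec(**row) for row in _catalog_raw()]


def get_scenario(name: str) -> ScenarioSpec:
    for spec in scenario_catalog():
        if spec.name == name:
            return spec
    raise KeyError(f"unknown scenario {name!r}")


def load_scenario(path) -> ScenarioSpec:
    """Read one scenario from a YAML file with ScenarioSpec field names."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping of ScenarioSpec fields")
    return ScenarioSpec(**doc)


def scale_scenario(spec: ScenarioSpec, max_fibers: int = 3000) -> ScenarioSpec:
    """Desk-scale version of a scenario: shrink the grid, preserve the
    tPA-per-fiber loading, keep spacing/diameter/time step unchanged."""
    if max_fibers < 1:
        raise ValueError("max_fibers must be positive")
    nx, ny = fit_grid(max_fibers)
    edges = 3 * nx * ny - nx - ny
    while edges > max_fibers and nx > 1:
        nx -= 1
        ny = max(1, ny - 1)
        edges = 3 * nx * ny - nx - ny
    n_tpa = max(1, round(spec.n_tpa * edges / spec.n_fibers)) if spec.n_tpa else 0
    return replace(spec, name=f"{spec.name} (scaled)", grid_nx=nx, grid_ny=ny,
                   n_fibers=edges, n_tpa=n_tpa)


_CANONICAL_FR_DOSES = {0.23: 8.0, 0.70: 24.0, 1.2: 40.0, 2.1: 72.0}
FIXED_CONC_NG_ML = 40.0
FIXED_RATIO_NG_MG = 40.0 / 1.2  # 33.3 ng tPA per mg fibrinogen (fulcrum)


def tpa_dose(fibrinogen_conc: float, mode: str = "fixed_concentration") -> DoseSpec:
    """tPA dose for a fibrinogen concentration under either dosing design.

    Fixed concentration always gives 40 ng/mL.  Fixed ratio scales the dose
    from the 1.2 mg/mL fulcrum (40 ng/mL); the four concentrations used in the
    plate experiments receive the doses as printed (8, 24, 40, 72 ng/mL, i.e.
    rounded to whole ng/mL), other concentrations scale exactly.
    """
    if fibrinogen_conc <= 0:
        raise ValueError("fibrinogen_conc must be positive")
    if mode == "fixed_concentration":
        tpa = FIXED_CONC_NG_ML
    elif mode == "fixed_ratio":
        tpa = _CANONICAL_FR_DOSES.get(round(fibrinogen_conc, 2))
        if tpa is None:
            tpa = FIXED_RATIO_NG_MG * fibrinogen_conc
    else:
        raise ValueError(f"unknown dosing mode {mode!r}")
    return DoseSpec(fibrinogen_conc=fibrinogen_conc, tpa_conc=tpa,
                    ratio=tpa / fibrinogen_conc, mode=mode)


def scale_time_step(reference_dt: float, reference_pore: float,
                    target_pore: float) -> float:
    """Diffusive time-step rescaling: dt ~ delta^2 so a molecule crosses one
    pore per step regardless of spacing."""
    if reference_dt <= 0 or reference_pore <= 0 or target_pore <= 0:
        raise ValueError("all arguments must be positive")
    return reference_dt * (target_pore / reference_pore) ** 2


def _line_gaps(intact_line: np.ndarray) -> np.ndarray:
    """Gap lengths (in units of spacing) along one scan line.

    A gap spans k consecutive degraded crossings and contributes k+1 spacings.
    Runs touching the clot boundary are truncated at the boundary, which is
    implemented by padding the line with virtual intact crossings just outside
    it; on a fully intact line every gap is exactly one spacing.
    """
    m = intact_line.size
    pos = np.flatnonzero(intact_line)
    padded = np.concatenate(([-1], pos, [m]))
    return np.diff(padded).astype(float)


def measure_pores(clot: LatticeClot, intact: np.ndarray | None = None,
                  tag: float | None = None) -> PoreProfile:
    """Pore-size profile by scan-line traversal of the (partially degraded) clot.

    One horizontal line per lattice row crosses that row's y-oriented edges;
    one vertical line per lattice column crosses that column's x-oriented
    edges.  The distance between consecutive intact fibers along each line is
    recorded; z-edges do not intersect in-plane lines and are excluded.
    """
    if intact is None:
        intact = clot.intact
    nx, ny = clot.nx, clot.ny
    nxe, nye = clot.n_x_edges, clot.n_y_edges
    x_int = intact[:nxe].reshape(ny, nx - 1) if nxe else None
    y_int = intact[nxe:nxe + nye].reshape(ny - 1, nx) if nye else None
    gaps: list[np.ndarray] = []
    if y_int is not None:
        for j in range(ny - 1):            # horizontal lines cross y-edges
            gaps.append(_line_gaps(y_int[j]))
    if x_int is not None:
        for i in range(nx - 1):            # vertical lines cross x-edges
            gaps.append(_line_gaps(x_int[:, i]))
    if not gaps:
        raise ValueError("lattice has no in-plane scan-line crossings")
    all_gaps = np.concatenate(gaps) * clot.spacing
    mean = float(all_gaps.mean())
    return PoreProfile(gap_sizes=all_gaps, mean_gap=mean,
                       percent_change=100.0 * (mean - clot.spacing) / clot.spacing,
                       tag=tag)
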