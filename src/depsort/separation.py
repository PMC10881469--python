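"""2D microfluidic DEP separation simulation.

A straight channel carries a laminar flow; two coplanar electrodes on the
channel floor create a non-uniform AC field: a continuous *neutral*
electrode strip running obliquely from the right wall to the left side of
the channel, and a *phase* electrode with a finger-like profile on the
left.  The field intensity is highest along the oblique gap between them.
Cells enter in a band near the right wall (sheath flow is abstracted as
the entry band).  A cell feeling positive DEP is attracted to the
high-|E|^2 diagonal path and is escorted by it toward the left wall; a
cell at its crossover frequency travels undisturbed with the flow and
exits on the right.  A lateral split coordinate at the channel end
assigns each cell to the left or right outlet.

Numerics: the RMS potential solves the Laplace equation on a regular
grid (5-point finite differences, Dirichlet values on electrode
footprints, zero-flux walls/openings, direct sparse solve); |E|^2 and its
gradient come from central differences; particle transport is inertialess
(quasi-steady Stokes balance), integrated explicitly with an adaptive
step capped at half a grid cell.

This is a deliberate 2D abstraction of the full device (no sheath-flow
junction, no outlet fork, no channel-height field decay); it preserves
the separation physics while remaining desk-scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve
from shapely.geometry import LineString, Polygon, box

from .core import (
    EPS0,
    DielectricMedium,
    DomainError,
    ShelledParticle,
    clausius_mossotti,
    first_crossover,
)
from .synthetic import PopulationModel, sample_population


@dataclass(frozen=True)
class Electrode:
    """One electrode footprint on the channel floor."""

    role: str  # "phase" or "neutral"
    footprint: Polygon

    def __post_init__(self) -> None:
        if self.role not in ("phase", "neutral"):
            raise DomainError("electrode role must be 'phase' or 'neutral'")


@dataclass(frozen=True)
class DeviceGeometry:
    """Channel and electrode layout.

    Coordinates: x along the flow (0 at inlet, ``length`` at outlet),
    y across the channel (0 = left wall, ``width`` = right wall).
    ``inlet_band`` is the fraction-of-width interval where particles
    enter; ``split_fraction`` is the lateral outlet split (left outlet
    for y < split_fraction*width).
    """

    length: float = 5e-3
    width: float = 500e-6
    electrodes: tuple[Electrode, ...] = ()
    inlet_band: tuple[float, float] = (0.70, 0.95)
    split_fraction: float = 0.4

    def __post_init__(self) -> None:
        if not (0 < self.split_fraction < 1):
            raise DomainError("split_fraction must be in (0, 1)")
        lo, hi = self.inlet_band
        if not (0 <= lo < hi <= 1):
            raise DomainError("inlet_band must satisfy 0 <= lo < hi <= 1")
        channel = box(0, 0, self.length, self.width)
        for e in self.electrodes:
            if not channel.buffer(1e-12).contains(e.footprint):
                raise DomainError("electrode footprint outside channel bounds")
        phase = [e.footprint for e in self.electrodes if e.role == "phase"]
        neutral = [e.footprint for e in self.electrodes if e.role == "neutral"]
        if phase and neutral:
            if shapely.union_all(phase).intersects(shapely.union_all(neutral)):
                raise DomainError("phase and neutral electrodes must be disjoint")

    @property
    def split_y(self) -> float:
        return self.split_fraction * self.width


def default_geometry(
    length: float = 5e-3,
    width: float = 500e-6,
    strip_width: float = 50e-6,
    gap: float = 50e-6,
    n_fingers: int = 40,
    finger_width: float = 50e-6,
    diag_start_x: float = 0.5e-3,
    diag_end_x: float = 4.5e-3,
    diag_end_y_fraction: float = 0.1,
    min_finger_height: float = 20e-6,
) -> DeviceGeometry:
    """Default sorter layout: oblique neutral strip + phase finger comb.

    The neutral strip runs from the right wall at ``diag_start_x`` down to
    ``diag_end_y_fraction * width`` at ``diag_end_x`` (it stops short of
    the no-slip left wall so that escorted cells stay in moving fluid).
    Phase fingers rise from the left wall toward the strip, their tips
    following the diagonal at a constant ``gap``.  The finger pitch is
    kept comparable to the gap so that the field crest is smooth along
    the diagonal (a coarse comb would create point traps at the tips);
    fingers that would be shorter than ``min_finger_height`` are omitted,
    so the comb ends where the diagonal approaches the left wall and
    escorted cells are released into moving fluid.
    """
    channel = box(0.0, 0.0, length, width)
    end_y = diag_end_y_fraction * width
    diag = LineString([(diag_start_x, width), (diag_end_x, end_y)])
    strip = diag.buffer(strip_width / 2.0, cap_style="flat").intersection(channel)
    electrodes = [Electrode("neutral", strip)]

    def y_line(x: float) -> float:
        t = (x - diag_start_x) / (diag_end_x - diag_start_x)
        return width + t * (end_y - width)

    centers = np.linspace(diag_start_x + finger_width, diag_end_x, n_fingers)
    for xc in centers:
        top = y_line(xc) - strip_width / 2.0 - gap
        if top < min_finger_height:
            continue
        finger = box(xc - finger_width / 2.0, 0.0, xc + finger_width / 2.0, top)
        electrodes.append(Electrode("phase", finger.intersection(channel)))
    return DeviceGeometry(length=length, width=width, electrodes=tuple(electrodes))


def parallel_plate_geometry(
    length: float = 5e-3, width: float = 500e-6, plate_width: float = 100e-6
) -> DeviceGeometry:
    """Two full-length electrodes along opposite walls (plate-capacitor surrogate)."""
    return DeviceGeometry(
        length=length,
        width=width,
        electrodes=(
            Electrode("phase", box(0, 0, length, plate_width)),
            Electrode("neutral", box(0, width - plate_width, length, width)),
        ),
    )


@dataclass(frozen=True)
class ScalarField2D:
    """Node-centred scalar on a regular rectangular grid; values[ix, iy]."""

    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.x), len(self.y)):
            raise DomainError("field shape must be (len(x), len(y))")
        if not np.all(np.isfinite(self.values)):
            raise DomainError("field contains non-finite values")

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0])


@dataclass(frozen=True)
class VectorField2D:
    """Node-centred 2-vector on a regular rectangular grid."""

    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    vx: np.ndarray = field(repr=False)
    vy: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = (len(self.x), len(self.y))
        if self.vx.shape != shape or self.vy.shape != shape:
            raise DomainError("field shape must be (len(x), len(y))")

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0])


def _grid(g: DeviceGeometry, resolution: int) -> tuple[np.ndarray, np.ndarray]:
    if resolution < 50:
        raise DomainError("need at least 50 nodes across the channel width")
    y = np.linspace(0.0, g.width, resolution)
    dy = y[1] - y[0]
    nx = int(round(g.length / dy)) + 1
    x = np.linspace(0.0, g.length, nx)
    return x, y


def _electrode_masks(g: DeviceGeometry, x: np.ndarray, y: np.ndarray):
    X, Y = np.meshgrid(x, y, indexing="ij")
    phase = np.zeros(X.shape, dtype=bool)
    neutral = np.zeros(X.shape, dtype=bool)
    # small tolerance so footprints touching the boundary rasterize onto it
    for e in g.electrodes:
        m = shapely.contains_xy(e.footprint.buffer(1e-9), X.ravel(), Y.ravel()).reshape(X.shape)
        if e.role == "phase":
            phase |= m
        else:
            neutral |= m
    return phase, neutral


def solve_potential(g: DeviceGeometry, resolution: int = 64, v_rms: float = 10.0) -> ScalarField2D:
    """RMS electric potential: Laplace solve with electrode Dirichlet values.

    ``resolution`` is the node count across the channel width (>= 50);
    the axial spacing matches it.  Phase electrodes are held at ``v_rms``,
    neutral at 0; all outer boundaries are zero-flux (mirror) Neumann.
    Direct sparse solve; the discrete Laplacian residual at free nodes is
    checked against 1e-8 of the boundary scale.
    """
    if not g.electrodes:
        raise DomainError("geometry has no electrodes")
    x, y = _grid(g, resolution)
    nx, ny = len(x), len(y)
    dx, dy = x[1] - x[0], y[1] - y[0]
    phase, neutral = _electrode_masks(g, x, y)
    dirichlet = phase | neutral
    dval = np.where(phase, float(v_rms), 0.0)

    n = nx * ny
    idx = np.arange(n).reshape(nx, ny)
    free = ~dirichlet.ravel()
    cx, cy = 1.0 / dx**2, 1.0 / dy**2

    rows, cols, data = [], [], []
    b = np.where(dirichlet.ravel(), dval.ravel(), 0.0)

    # Dirichlet rows: identity
    drows = idx.ravel()[~free]
    rows.append(drows)
    cols.append(drows)
    data.append(np.ones(drows.size))

    # Laplace rows with mirror ghosts at the outer boundary
    center = np.full((nx, ny), -2.0 * (cx + cy))
    frows = idx.ravel()[free]
    rows.append(frows)
    cols.append(frows)
    data.append(center.ravel()[free])

    shifts = [(-1, 0, cx), (1, 0, cx), (0, -1, cy), (0, 1, cy)]
    for sx, sy, c in shifts:
        nbr_ix = np.arange(nx)[:, None] + sx
        nbr_iy = np.arange(ny)[None, :] + sy
        # mirror: a neighbour outside the domain reflects to the opposite side
        nbr_ix = np.where(nbr_ix < 0, 1, np.where(nbr_ix >= nx, nx - 2, nbr_ix))
        nbr_iy = np.where(nbr_iy < 0, 1, np.where(nbr_iy >= ny, ny - 2, nbr_iy))
        nbr = idx[nbr_ix, np.broadcast_to(nbr_iy, (nx, ny))]
        rows.append(frows)
        cols.append(nbr.ravel()[free])
        data.append(np.full(frows.size, c))

    a_mat = coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsr()
    a_mat.sum_duplicates()
    v = spsolve(a_mat, b)

    scale = max(abs(float(v_rms)), 1.0)
    residual = np.abs(a_mat @ v - b).max()
    if residual > 1e-8 * scale * (cx + cy):
        raise RuntimeError(f"Laplace solve did not converge: residual {residual:.3e}")
    return ScalarField2D(x=x, y=y, values=v.reshape(nx, ny))


def e2_field(potential: ScalarField2D) -> ScalarField2D:
    """Squared field intensity |E|^2 = |∇V|^2, V^2/m^2."""
    ex = -np.gradient(potential.values, potential.x, axis=0)
    ey = -np.gradient(potential.values, potential.y, axis=1)
    return ScalarField2D(x=potential.x, y=potential.y, values=ex**2 + ey**2)


def grad_e2_field(potential: ScalarField2D) -> VectorField2D:
    """∇|E|^2 by central differences (one-sided at boundaries), V^2/m^3."""
    e2 = e2_field(potential).values
    gx = np.gradient(e2, potential.x, axis=0)
    gy = np.gradient(e2, potential.y, axis=1)
    return VectorField2D(x=potential.x, y=potential.y, vx=gx, vy=gy)


def flow_profile(g: DeviceGeometry, mean_speed: float, y) -> np.ndarray:
    """Axial speed of the fully developed laminar profile at lateral position y."""
    if mean_speed <= 0:
        raise DomainError("mean_speed must be > 0")
    yn = 2.0 * (np.asarray(y, dtype=float) - g.width / 2.0) / g.width
    return 1.5 * mean_speed * (1.0 - yn**2)


def flow_field(g: DeviceGeometry, mean_speed: float, resolution: int = 64) -> VectorField2D:
    """Fully developed 2D laminar flow: parabolic axial profile, no-slip walls,
    zero lateral component."""
    x, y = _grid(g, resolution)
    ux = np.broadcast_to(flow_profile(g, mean_speed, y)[None, :], (len(x), len(y))).copy()
    return VectorField2D(x=x, y=y, vx=ux, vy=np.zeros_like(ux))


def dep_mobility(p: ShelledParticle, m: DielectricMedium, f: float, viscosity: float) -> float:
    """DEP mobility mu = r^2 eps0 eps_med Re[K(f)] / (3 eta), m^4/(V^2 s).

    The quasi-steady drift velocity is ``mu * grad|E|^2``; equivalently the
    DEP force balanced by Stokes drag 6 pi eta r v.
    """
    if viscosity <= 0:
        raise DomainError("viscosity must be > 0")
    re_k = float(np.real(clausius_mossotti(p, m, f)))
    return p.radius**2 * EPS0 * m.rel_permittivity * re_k / (3.0 * viscosity)


def choose_operating_frequency(
    popA: PopulationModel,
    popB: PopulationModel,
    m: DielectricMedium,
    f_range: tuple[float, float] = (1e4, 5e7),
) -> float:
    """First crossover of popA's mean cell, with popB in positive DEP there.

    The separation strategy: drive the field at the first CO of one
    population (it then drifts with the flow, unaffected) while the other
    population feels pDEP and is escorted by the field maximum to the
    opposite outlet.  Raises if popA has no crossover in range or if
    popB's mean cell is not in positive DEP at the candidate frequency
    (the error suggests swapping the populations' roles).
    """
    f_co = first_crossover(popA.mean_particle(), m, *f_range)
    if f_co is None:
        raise DomainError(f"population {popA.label!r} has no crossover in range {f_range}")
    re_k_b = float(np.real(clausius_mossotti(popB.mean_particle(), m, f_co)))
    if not re_k_b > 0:
        raise DomainError(
            f"population {popB.label!r} has Re[K] = {re_k_b:.4g} <= 0 at the first crossover "
            f"of {popA.label!r} ({f_co:.4g} Hz); try swapping the population roles"
        )
    return f_co


@dataclass(frozen=True)
class SimParticle:
    """A cell instance in the sorter: geometry/dielectrics + state."""

    particle: ShelledParticle
    position: tuple[float, float]
    label: str
    re_k: float


@dataclass(frozen=True)
class SeparationOutcome:
    """Per-particle endpoints and aggregate sorting metrics.

    ``table`` has one row per particle: particle_id, population, entry_x,
    entry_y, outlet (left/right/none), exit_y, exit_time, wall_contacts.
    """

    table: pd.DataFrame

    def counts(self) -> pd.DataFrame:
        return self.table.groupby(["population", "outlet"], sort=True).size().unstack(fill_value=0)

    def summary(self) -> pd.DataFrame:
        """Purity and yield per (population, outlet) combination present."""
        rows = []
        for outlet in ("left", "right"):
            at_outlet = self.table[self.table["outlet"] == outlet]
            if at_outlet.empty:
                continue
            for pop in sorted(self.table["population"].unique()):
                n_pop_total = int((self.table["population"] == pop).sum())
                n_here = int((at_outlet["population"] == pop).sum())
                rows.append(
                    {
                        "outlet": outlet,
                        "population": pop,
                        "n_at_outlet": len(at_outlet),
                        "n_population_at_outlet": n_here,
                        "purity_pct": 100.0 * n_here / len(at_outlet),
                        "yield_pct": 100.0 * n_here / n_pop_total if n_pop_total else math.nan,
                    }
                )
        return pd.DataFrame(rows)


def purity_yield(o: SeparationOutcome, target_pop: str, target_outlet: str) -> tuple[float, float]:
    """(% of target_outlet particles from target_pop, % of target_pop recovered there)."""
    if target_outlet not in ("left", "right"):
        raise DomainError("target_outlet must be 'left' or 'right'")
    at_outlet = o.table[o.table["outlet"] == target_outlet]
    if at_outlet.empty:
        raise DomainError(f"no particles at outlet {target_outlet!r}: purity undefined")
    n_target_total = int((o.table["population"] == target_pop).sum())
    n_here = int((at_outlet["population"] == target_pop).sum())
    purity = 100.0 * n_here / len(at_outlet)
    yld = 100.0 * n_here / n_target_total if n_target_total else math.nan
    return purity, yld


def _bilinear(values: np.ndarray, x: np.ndarray, y: np.ndarray, px: np.ndarray, py: np.ndarray):
    dx, dy = x[1] - x[0], y[1] - y[0]
    fx = np.clip((px - x[0]) / dx, 0.0, len(x) - 1.0 - 1e-12)
    fy = np.clip((py - y[0]) / dy, 0.0, len(y) - 1.0 - 1e-12)
    ix = fx.astype(int)
    iy = fy.astype(int)
    tx = fx - ix
    ty = fy - iy
    v00 = values[ix, iy]
    v10 = values[ix + 1, iy]
    v01 = values[ix, iy + 1]
    v11 = values[ix + 1, iy + 1]
    return (
        v00 * (1 - tx) * (1 - ty)
        + v10 * tx * (1 - ty)
        + v01 * (1 - tx) * ty
        + v11 * tx * ty
    )


def advect_particles(
    particles: list[SimParticle],
    flow: VectorField2D,
    grad_e2: VectorField2D,
    f: float,
    m: DielectricMedium,
    viscosity: float,
    g: DeviceGeometry,
    dt: float | None = None,
    max_time: float | None = None,
    record_trajectories: bool = False,
) -> tuple[list[np.ndarray] | None, SeparationOutcome]:
    """Integrate dx/dt = u_fluid(x) + mu * grad|E|^2(x) for every particle.

    Explicit Euler with an adaptive step: the global step never moves the
    fastest particle more than half a grid cell (``dt``, if given, is an
    additional upper cap).  Particles are clamped at the lateral walls
    (contacts logged) and exit when their axial position passes the
    channel end: left outlet if y < split, right otherwise.  Particles
    still inside at ``max_time`` get outcome "none".
    """
    n = len(particles)
    if n == 0:
        raise DomainError("no particles to advect")
    pos = np.array([p.position for p in particles], dtype=float)
    mob = np.array([dep_mobility(p.particle, m, f, viscosity) for p in particles])
    labels = [p.label for p in particles]
    entry = pos.copy()

    cell = 0.5 * min(grad_e2.dx, grad_e2.dy)
    mean_ux = float(np.mean(flow.vx))
    if max_time is None:
        max_time = 5.0 * g.length / max(mean_ux, 1e-12)

    active = np.ones(n, dtype=bool)
    outlet = np.array(["none"] * n, dtype=object)
    exit_y = np.full(n, np.nan)
    exit_t = np.full(n, np.nan)
    wall_contacts = np.zeros(n, dtype=int)
    traj: list[np.ndarray] | None = [pos.copy()] if record_trajectories else None

    t = 0.0
    while np.any(active) and t < max_time:
        pa = pos[active]
        ux = _bilinear(flow.vx, flow.x, flow.y, pa[:, 0], pa[:, 1])
        uy = _bilinear(flow.vy, flow.x, flow.y, pa[:, 0], pa[:, 1])
        gx = _bilinear(grad_e2.vx, grad_e2.x, grad_e2.y, pa[:, 0], pa[:, 1])
        gy = _bilinear(grad_e2.vy, grad_e2.x, grad_e2.y, pa[:, 0], pa[:, 1])
        vx = ux + mob[active] * gx
        vy = uy + mob[active] * gy
        vmax = float(np.max(np.hypot(vx, vy)))
        step = cell / vmax if vmax > 0 else (dt if dt else max_time - t)
        if dt is not None:
            step = min(step, dt)
        step = min(step, max_time - t)
        pa = pa + np.column_stack([vx, vy]) * step

        below = pa[:, 1] < 0.0
        above = pa[:, 1] > g.width
        wall_idx = np.flatnonzero(active)
        wall_contacts[wall_idx[below | above]] += 1
        pa[:, 1] = np.clip(pa[:, 1], 0.0, g.width)
        pos[active] = pa
        t += step

        done = pa[:, 0] >= g.length
        if np.any(done):
            gids = wall_idx[done]
            outlet[gids] = np.where(pa[done, 1] < g.split_y, "left", "right")
            exit_y[gids] = pa[done, 1]
            exit_t[gids] = t
            active[gids] = False
        if record_trajectories:
            traj.append(pos.copy())

    table = pd.DataFrame(
        {
            "particle_id": np.arange(n),
            "population": labels,
            "entry_x": entry[:, 0],
            "entry_y": entry[:, 1],
            "outlet": outlet,
            "exit_y": exit_y,
            "exit_time": exit_t,
            "wall_contacts": wall_contacts,
        }
    )
    return traj, SeparationOutcome(table=table)


def make_sim_particles(
    pops: list[PopulationModel],
    n_per_pop: int,
    m: DielectricMedium,
    f: float,
    g: DeviceGeometry,
    seed: int,
) -> list[SimParticle]:
    """Draw cells from each population and place them randomly in the inlet band."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(pops) + 1)
    entry_rng = np.random.default_rng(children[-1])
    lo, hi = g.inlet_band
    out: list[SimParticle] = []
    for pop, child in zip(pops, children[:-1]):
        cells = sample_population(pop, n_per_pop, int(child.generate_state(1)[0] % 2**31))
        for cell in cells:
            y0 = entry_rng.uniform(lo * g.width, hi * g.width)
            re_k = float(np.real(clausius_mossotti(cell, m, f)))
            out.append(SimParticle(particle=cell, position=(0.0, y0), label=pop.label, re_k=re_k))
    return out


def run_separation(
    popA: PopulationModel,
    popB: PopulationModel,
    m: DielectricMedium | None = None,
    n_per_pop: int = 200,
    seed: int = 0,
    g: DeviceGeometry | None = None,
    v_rms: float = 10.0,
    mean_speed: float = 15e-3,
    frequency: float | str = "auto",
    viscosity: float = 1.0e-3,
    resolution: int = 64,
    max_time: float | None = None,
    record_trajectories: bool = False,
):
    """End-to-end sorter run; returns (operating frequency, trajectories, outcome).

    ``popA`` is the population operated at its first crossover (exits
    right, undeflected); ``popB`` must feel positive DEP there and is
    escorted to the left outlet.  ``frequency="auto"`` invokes
    :func:`choose_operating_frequency`.
    """
    if m is None:
        m = DielectricMedium(80.0, 0.04)
    if g is None:
        g = default_geometry()
    f = choose_operating_frequency(popA, popB, m) if frequency == "auto" else float(frequency)
    potential = solve_potential(g, resolution=resolution, v_rms=v_rms)
    gradient = grad_e2_field(potential)
    flow = flow_field(g, mean_speed, resolution=resolution)
    particles = make_sim_particles([popA, popB], n_per_pop, m, f, g, seed)
    traj, outcome = advect_particles(
        particles,
        flow,
        gradient,
        f,
        m,
        viscosity,
        g,
        max_time=max_time,
        record_trajectories=record_trajectories,
    )
    return f, traj, outcome
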