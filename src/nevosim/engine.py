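"""Simulation engine: initialization, stepping, trajectories, snapshot I/O.

The population is stored as a structure of numpy arrays so that every phase
of a step (density, movement, division, emigration, discard) is vectorized.
Event ordering within a step: density update -> movement -> divisions and
differentiation -> emigrations -> discard of domain exits.

Separate named RNG streams (movement, division, differentiation, emigration,
inheritance, placement) are derived from the master seed so that parameter
changes in one process do not perturb the draws of another.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import membrane_geometry as mg
from . import tissue_synthesis as ts
from .agent_dynamics import (
    OMEGA_SUPPORT,
    AgentConfig,
    DampingCurve,
    weight,
)
from .errors import ConfigurationError, NevosimError
from .migration import MovementConfig

__all__ = [
    "SimulationConfig",
    "SimulationState",
    "Snapshot",
    "Trajectory",
    "initialize",
    "step",
    "run",
]

_STREAMS = ("placement", "movement", "division", "differentiation",
            "emigration", "inheritance")


@dataclass
class SimulationConfig:
    dt: float = 1.0                     # d
    horizon: float = 100.0              # d
    extent: tuple = (1000.0, 1000.0)    # um
    membrane: mg.MembraneModel | None = None
    membrane_config: ts.MembraneConfig | None = None
    n_initial: int = 10
    initial_spread: float = 50.0        # placement disk radius, um
    agent: AgentConfig = field(default_factory=AgentConfig)
    movement: MovementConfig = field(default_factory=MovementConfig)
    A: DampingCurve = field(default_factory=lambda: DampingCurve.constant(1.0, "A"))
    B: DampingCurve = field(default_factory=lambda: DampingCurve.constant(1.0, "B"))
    A_nest: DampingCurve = field(
        default_factory=lambda: DampingCurve.constant(1.0, "A_nest"))
    B_nest: DampingCurve = field(
        default_factory=lambda: DampingCurve.constant(1.0, "B"))
    S: DampingCurve = field(default_factory=lambda: DampingCurve.constant(1.0, "S"))
    # density condition on differentiation: q_eff = q0 * Q_diff(rho)
    Q_diff: DampingCurve = field(
        default_factory=lambda: DampingCurve.constant(1.0, "Q_diff"))
    seed: int = 0
    snapshot_interval: float = 10.0     # d
    spatial: bool = True                # False: pure branching process mode
    density_method: str = "exact"       # "exact" pair sum or "grid" convolution
    founder_nested: bool = False        # start from differentiated founder(s)
    movement_substep: float = 2.0       # um, tangent-step bound
    record_events: bool = False

    def __post_init__(self):
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if self.horizon < self.dt:
            raise ConfigurationError("horizon must be at least one step")
        if self.n_initial < 0:
            raise ConfigurationError("initial count must be non-negative")


class Population:
    """Structure-of-arrays store for the living cells."""

    def __init__(self):
        self.ids = np.zeros(0, dtype=np.int64)
        self.pos = np.zeros((0, 3))
        self.radius = np.zeros(0)
        self.generation = np.zeros(0, dtype=np.int64)
        self.strain = np.full(0, -1, dtype=np.int64)
        self.strain_gen = np.zeros(0, dtype=np.int64)
        self.p0 = np.zeros(0)
        self.nested = np.zeros(0, dtype=bool)

    def __len__(self):
        return len(self.ids)

    def keep(self, mask):
        for name in ("ids", "pos", "radius", "generation", "strain",
                     "strain_gen", "p0", "nested"):
            setattr(self, name, getattr(self, name)[mask])

    def append(self, **arrays):
        self.ids = np.concatenate([self.ids, arrays["ids"]])
        self.pos = np.concatenate([self.pos, arrays["pos"]])
        self.radius = np.concatenate([self.radius, arrays["radius"]])
        self.generation = np.concatenate([self.generation, arrays["generation"]])
        self.strain = np.concatenate([self.strain, arrays["strain"]])
        self.strain_gen = np.concatenate([self.strain_gen, arrays["strain_gen"]])
        self.p0 = np.concatenate([self.p0, arrays["p0"]])
        self.nested = np.concatenate([self.nested, arrays["nested"]])


@dataclass
class SimulationState:
    config: SimulationConfig
    membrane: mg.MembraneModel
    population: Population
    time: float = 0.0
    next_id: int = 0
    next_strain: int = 0
    births: int = 0
    exits: int = 0
    initial_count: int = 0
    nest_founders: dict = field(default_factory=dict)   # strain -> founder cell id
    dissolved: dict = field(default_factory=dict)       # strain -> time
    events: list = field(default_factory=list)
    rngs: dict = field(default_factory=dict)

    def density(self):
        return _local_density(self)


@dataclass
class Snapshot:
    time: float
    table: pd.DataFrame          # one row per cell
    nests: dict                  # strain id -> {"count": int, "founder": int}

    @property
    def positions(self):
        return self.table[["x", "y", "z"]].to_numpy()


@dataclass
class Trajectory:
    config: SimulationConfig
    snapshots: list
    events: pd.DataFrame | None = None

    def population_sizes(self):
        return np.array([(s.time, len(s.table)) for s in self.snapshots])


def _spawn_rngs(seed: int) -> dict:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_STREAMS))
    return {name: np.random.default_rng(child)
            for name, child in zip(_STREAMS, children)}


def initialize(config: SimulationConfig) -> SimulationState:
    """Place the initial cells on the membrane near the domain centre."""
    rngs = _spawn_rngs(config.seed)
    membrane = config.membrane
    if membrane is None:
        mcfg = config.membrane_config or ts.MembraneConfig(extent=config.extent)
        membrane = ts.generate_membrane(mcfg, seed=config.seed)
    if membrane.extent != tuple(map(float, config.extent)):
        raise ConfigurationError("membrane extent differs from config extent")

    pop = Population()
    state = SimulationState(config=config, membrane=membrane, population=pop,
                            rngs=rngs)
    n = config.n_initial
    if n:
        rng = rngs["placement"]
        center = np.asarray(config.extent, float) / 2.0
        radius = config.agent.cell_radius
        placed = []
        attempts = 0
        while len(placed) < n:
            attempts += 1
            if attempts > 1000 * n:
                raise ConfigurationError("could not place initial cells")
            ang = rng.uniform(0, 2 * np.pi)
            rad = config.initial_spread * np.sqrt(rng.uniform())
            xy = center + rad * np.array([np.cos(ang), np.sin(ang)])
            if placed and np.min(
                np.linalg.norm(np.asarray(placed) - xy, axis=1)
            ) < 2 * radius:
                continue
            placed.append(xy)
        xy = np.asarray(placed)
        z = membrane.altitude(xy)
        if config.founder_nested:
            strain = np.arange(n, dtype=np.int64)
            p0 = np.full(n, config.agent.nested_p0)
            nested = np.ones(n, dtype=bool)
            state.next_strain = n
            for s in range(n):
                state.nest_founders[s] = s
        else:
            strain = np.full(n, -1, dtype=np.int64)
            p0 = np.full(n, config.agent.default_p0)
            nested = np.zeros(n, dtype=bool)
        pop.append(
            ids=np.arange(n, dtype=np.int64),
            pos=np.column_stack([xy, z]),
            radius=np.full(n, radius),
            generation=np.zeros(n, dtype=np.int64),
            strain=strain,
            strain_gen=np.zeros(n, dtype=np.int64),
            p0=p0,
            nested=nested,
        )
        state.next_id = n
    state.initial_count = n
    return state


# ---------------------------------------------------------------------------
# step phases
# ---------------------------------------------------------------------------

def _grid_density(state: SimulationState) -> np.ndarray:
    """Approximate the weighted density by 3D histogram convolution.

    Avoids enumerating the O(n * neighbours) pair list of the 100 um
    weighting support, which becomes quadratic inside dense nests.  Gaps are
    approximated with the mean cell diameter; the binning error is a few
    percent of the (heuristic, clamped) density signal.
    """
    from scipy.signal import fftconvolve

    pop = state.population
    pos = pop.pos
    bin_um = 12.0
    mean_diam = 2.0 * float(pop.radius.mean())
    lo = pos.min(axis=0) - bin_um
    span = pos.max(axis=0) - lo + bin_um
    shape = np.maximum((span / bin_um).astype(int) + 1, 1)
    idx = np.minimum(((pos - lo) / bin_um).astype(int), shape - 1)
    flat = np.ravel_multi_index(idx.T, shape)
    hist = np.bincount(flat, minlength=int(np.prod(shape))).reshape(shape)
    reach = int(np.ceil((OMEGA_SUPPORT + mean_diam) / bin_um))
    ax = np.arange(-reach, reach + 1) * bin_um
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    kernel = weight(np.sqrt(gx**2 + gy**2 + gz**2) - mean_diam)
    rho_grid = fftconvolve(hist.astype(float), kernel, mode="same")
    rho = rho_grid[idx[:, 0], idx[:, 1], idx[:, 2]] - float(weight(-mean_diam))
    return np.minimum(np.maximum(rho, 0.0), 1.0)


def _step_geometry(state: SimulationState):
    """Pair interactions plus the local density, one KDTree pass per step."""
    pop = state.population
    n = len(pop)
    if n == 0 or not state.config.spatial:
        empty = np.zeros((0, 2), dtype=np.intp)
        return np.zeros(n), empty, None, None, None
    rmax = pop.radius.max()
    mv = state.config.movement
    grid = state.config.density_method == "grid"
    # forces and collisions only need short-range pairs; the density support
    # is included in the cutoff only on the exact path
    cutoff = max(mv.F_a.cutoff + 2 * rmax, mv.F_r.cutoff + 2 * rmax,
                 6.0 * rmax)
    if not grid:
        cutoff = max(cutoff, OMEGA_SUPPORT + 2 * rmax)
    tree = cKDTree(pop.pos)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        rho = _grid_density(state) if grid else np.zeros(n)
        return rho, pairs, None, None, None
    i, j = pairs[:, 0], pairs[:, 1]
    diff = pop.pos[j] - pop.pos[i]
    dist = np.linalg.norm(diff, axis=1)
    gaps = dist - pop.radius[i] - pop.radius[j]
    if grid:
        rho = _grid_density(state)
    else:
        rho = np.zeros(n)
        w = weight(gaps)
        np.add.at(rho, i, w)
        np.add.at(rho, j, w)
        rho = np.minimum(rho, 1.0)
    return rho, pairs, diff, dist, gaps


def _local_density(state: SimulationState) -> np.ndarray:
    return _step_geometry(state)[0]


def _movement(state: SimulationState, rho, pairs, diffv, dist, gaps):
    """Returns the survivor mask (False where cells left the domain)."""
    cfg = state.config
    mv = cfg.movement
    pop = state.population
    n = len(pop)
    if n == 0 or not cfg.spatial:
        return np.ones(n, bool)
    dt = cfg.dt
    rng = state.rngs["movement"]

    # (i) external force + diffusive noise
    diff_scale = np.sqrt(2.0 * mv.D * mv.Q(rho) * mv.R_gen(pop.generation))
    v = diff_scale[:, None] / np.sqrt(dt) * rng.standard_normal((n, 3))
    if mv.v_ext is not None:
        if mv.v_ext_altitude_scaled:
            xi = pop.pos[:, :2]
            alt = pop.pos[:, 2] - state.membrane.chi(xi)
            scale = np.clip(alt / mv.v_ext_h_ref, 0.0, 1.0)
            v += scale[:, None] * mv.v_ext[None, :]
        else:
            v += mv.v_ext[None, :]

    has_forces = mv.F_a.cutoff > 0 or mv.F_r.cutoff > 0

    # (ii) pairwise forces with the strain rule
    if has_forces and len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        safe = np.maximum(dist, 1e-9)
        unit = diffv / safe[:, None]
        same = (pop.strain[i] == pop.strain[j]) & pop.nested[i] & pop.nested[j]
        fa = mv.F_a(gaps)
        fr = mv.F_r(gaps)
        mag_i = np.where(same, fa * mv.G_a(rho[i]) * mv.H_a(pop.generation[i]), 0.0) \
            - np.where(~same, fr * mv.G_r(rho[i]) * mv.H_r(pop.generation[i]), 0.0)
        mag_j = np.where(same, fa * mv.G_a(rho[j]) * mv.H_a(pop.generation[j]), 0.0) \
            - np.where(~same, fr * mv.G_r(rho[j]) * mv.H_r(pop.generation[j]), 0.0)
        np.add.at(v, i, mag_i[:, None] * unit)
        np.add.at(v, j, -mag_j[:, None] * unit)

    # (iii) collision corrector.  For K=1 the per-neighbour corrections are
    # iterated (damped Jacobi) until no predicted approach exceeds the gap,
    # which realizes the overlap minimization; for fractional K a single
    # simultaneous pass subtracts the K-scaled corrections literally.
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        # pairs that cannot close their gap within one step never trigger
        vnorm = np.linalg.norm(v, axis=1)
        reach = (vnorm[i] + vnorm[j]) * dt + 0.5
        near = gaps < reach
        i, j = i[near], j[near]
        safe = np.maximum(dist[near], 1e-9)
        unit = diffv[near] / safe[:, None]
        cells = np.concatenate([i, j])
        dirs = np.concatenate([unit, -unit])
        cgaps = np.concatenate([gaps[near], gaps[near]])
        if mv.K >= 1.0 and len(cells):
            # Each cell of a pair may consume half the remaining gap, so a
            # mutually approaching pair stops at contact instead of closing
            # the same gap twice.  The per-neighbour corrections are applied
            # as averaged simultaneous projections (Cimmino), which stays
            # stable at any contact number.  An entry's status depends only
            # on its own cell's velocity, so iteration is restricted to the
            # initially triggering cells.
            allowance = 0.5 * cgaps
            proj = np.einsum("ij,ij->i", dirs, v[cells])
            active = np.flatnonzero(
                np.isin(cells, cells[proj * dt - allowance > 1e-9]))
            cells, dirs, allowance = cells[active], dirs[active], allowance[active]
            for _ in range(60):
                proj = np.einsum("ij,ij->i", dirs, v[cells])
                viol = proj * dt - allowance
                trig = viol > 0.02
                if not trig.any():
                    break
                tidx = np.flatnonzero(trig)
                tc = cells[tidx]
                counts = np.bincount(tc, minlength=n).astype(float)
                corr = viol[tidx] / dt / counts[tc]
                upd = np.zeros_like(v)
                np.add.at(upd, tc, corr[:, None] * dirs[tidx])
                v -= upd
        elif len(cells):
            proj = np.einsum("ij,ij->i", dirs, v[cells])
            viol = proj * dt - cgaps
            corr = np.where(viol > 0, viol * mv.K / dt, 0.0)
            upd = np.zeros_like(v)
            np.add.at(upd, cells, corr[:, None] * dirs)
            v -= upd

    # position update
    nested = pop.nested
    exited = np.zeros(n, bool)
    if (~nested).any():
        exited_c = _advance_constrained(state, ~nested, v, dt)
        exited |= exited_c
    if nested.any():
        idx = np.flatnonzero(nested)
        v_derm = _dermal_exclusion_batch(state.membrane, pop.pos[idx], mv)
        pop.pos[idx] = pop.pos[idx] + dt * (v[idx] + v_derm)
        lx, ly = cfg.extent
        out = (
            (pop.pos[idx, 0] < 0) | (pop.pos[idx, 0] > lx)
            | (pop.pos[idx, 1] < 0) | (pop.pos[idx, 1] > ly)
        )
        exited[idx[out]] = True
    if exited.any():
        state.exits += int(exited.sum())
        pop.keep(~exited)
    return ~exited


def _advance_constrained(state, mask, v, dt) -> np.ndarray:
    """Tangent-plane stepping with vertical re-projection onto the surface.

    Bounded substeps keep the O(step^2) projection error below the noise
    scale; the geodesic-ODE route in membrane_geometry is the validated
    reference for this scheme.
    """
    membrane = state.membrane
    pop = state.population
    cfg = state.config
    idx = np.flatnonzero(mask)
    xi = pop.pos[idx, :2].copy()
    vv = v[idx]
    speeds = np.linalg.norm(vv, axis=1)
    vmax = speeds.max() if len(speeds) else 0.0
    nsub = max(1, min(5, int(np.ceil(vmax * dt / cfg.movement_substep))))
    h = dt / nsub
    alive = np.ones(len(idx), bool)
    lx, ly = cfg.extent
    for _ in range(nsub):
        act = np.flatnonzero(alive)
        if len(act) == 0:
            break
        region = membrane.locate(xi[act])
        grad = membrane.altitude_grad(xi[act], region=region)
        nrm = np.concatenate([-grad, np.ones((len(act), 1))], axis=1)
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        vt = vv[act] - np.einsum("ij,ij->i", vv[act], nrm)[:, None] * nrm
        xi[act] += h * vt[:, :2]
        out = (
            (xi[act, 0] < 0) | (xi[act, 0] > lx)
            | (xi[act, 1] < 0) | (xi[act, 1] > ly)
        )
        alive[act[out]] = False
    surv = np.flatnonzero(alive)
    if len(surv):
        z = membrane.altitude(xi[surv])
        pop.pos[idx[surv], :2] = xi[surv]
        pop.pos[idx[surv], 2] = z
    exited = np.zeros(len(pop), bool)
    exited[idx[~alive]] = True
    return exited


def _dermal_exclusion_batch(membrane, pos, mv: MovementConfig) -> np.ndarray:
    xi = pos[:, :2]
    z = pos[:, 2]
    region = membrane.locate(xi)
    surface = membrane.altitude(xi, region=region)
    base = membrane.chi(xi)
    v = np.zeros_like(pos)
    dermal = z < surface
    below = dermal & ((z < base) | (region < 0))
    inside = dermal & ~below
    v[below, 2] = mv.v_derm_vertical
    if inside.any():
        for i in np.unique(region[inside]):
            sel = inside & (region == i)
            radial = xi[sel] - membrane.papillae[i].center
            norms = np.linalg.norm(radial, axis=1)
            ok = norms > 1e-9
            v[np.flatnonzero(sel)[ok], :2] = (
                radial[ok] / norms[ok][:, None] * mv.v_derm_horizontal
            )
            v[np.flatnonzero(sel)[~ok], 2] = mv.v_derm_vertical
    return v


def _divisions(state: SimulationState, rho: np.ndarray) -> None:
    cfg = state.config
    pop = state.population
    n = len(pop)
    if n == 0:
        return
    dt = cfg.dt
    agent = cfg.agent
    nested = pop.nested

    damp = np.where(
        nested,
        cfg.A_nest(pop.strain_gen) * cfg.B_nest(rho),
        cfg.A(pop.generation) * cfg.B(rho),
    )
    prob = np.expm1(damp * pop.p0 * dt)
    if prob.max() > 1.0:
        raise ConfigurationError("division probability exceeded 1; reduce p0*dt")
    draws = state.rngs["division"].random(n)
    dividing = draws < prob
    if not dividing.any():
        return
    idx = np.flatnonzero(dividing)
    m = len(idx)
    rng_inh = state.rngs["inheritance"]
    rng_diff = state.rngs["differentiation"]

    direction = rng_inh.standard_normal((m, 3))
    norms = np.linalg.norm(direction, axis=1, keepdims=True)
    norms[norms < 1e-12] = 1.0
    direction /= norms
    offset = agent.division_offset * pop.radius[idx, None] * direction

    def inherit(sign):
        radius = np.maximum(
            pop.radius[idx] + agent.sigma_radius * rng_inh.standard_normal(m), 0.1)
        p0 = np.maximum(
            pop.p0[idx] + agent.sigma_p0 * rng_inh.standard_normal(m), 0.0)
        return {
            "pos": pop.pos[idx] + sign * offset,
            "radius": radius,
            "generation": pop.generation[idx] + 1,
            "strain": pop.strain[idx].copy(),
            "strain_gen": np.where(pop.nested[idx], pop.strain_gen[idx] + 1, 0),
            "p0": p0,
            "nested": pop.nested[idx].copy(),
        }

    d1 = inherit(+1.0)
    d2 = inherit(-1.0)

    # differentiation of default-type divisions into new strains; the
    # conditional probability is density-gated via Q_diff
    if agent.q0 > 0:
        candidates = ~pop.nested[idx]
        q_eff = agent.q0 * np.asarray(cfg.Q_diff(rho[idx]), float)
        founds = candidates & (rng_diff.random(m) < q_eff)
        for k in np.flatnonzero(founds):
            strain = state.next_strain
            state.next_strain += 1
            d1["strain"][k] = strain
            d1["strain_gen"][k] = 0
            d1["nested"][k] = True
            d1["p0"][k] = agent.nested_p0
            founder_id = state.next_id + int(k)
            state.nest_founders[strain] = founder_id
            if state.config.record_events:
                state.events.append(
                    (state.time, "differentiation", founder_id, strain))

    ids1 = np.arange(state.next_id, state.next_id + m, dtype=np.int64)
    ids2 = np.arange(state.next_id + m, state.next_id + 2 * m, dtype=np.int64)
    state.next_id += 2 * m
    state.births += m  # net +1 per division

    lx, ly = cfg.extent
    for d in (d1, d2):
        # keep daughters inside the extent and constrained ones on the surface
        d["pos"][:, 0] = np.clip(d["pos"][:, 0], 0.0, lx)
        d["pos"][:, 1] = np.clip(d["pos"][:, 1], 0.0, ly)
        constrained = ~d["nested"]
        if constrained.any():
            d["pos"][constrained, 2] = state.membrane.altitude(
                d["pos"][constrained, :2])

    pop.keep(~dividing)
    for ids, d in ((ids1, d1), (ids2, d2)):
        pop.append(ids=ids, **d)


def _emigrations(state: SimulationState) -> None:
    cfg = state.config
    pop = state.population
    nested_idx = np.flatnonzero(pop.nested)
    if len(nested_idx) == 0:
        return
    rate = cfg.agent.s0 * cfg.S(pop.strain_gen[nested_idx])
    prob = -np.expm1(-rate * cfg.dt)
    draws = state.rngs["emigration"].random(len(nested_idx))
    emigrating = nested_idx[draws < prob]
    if len(emigrating) == 0:
        return
    old_strains = pop.strain[emigrating].copy()
    pop.nested[emigrating] = False
    pop.strain[emigrating] = -1
    pop.strain_gen[emigrating] = 0
    pop.p0[emigrating] = cfg.agent.default_p0
    if state.config.record_events:
        for cid in pop.ids[emigrating]:
            state.events.append((state.time, "emigration", int(cid), -1))
    # record dissolutions
    for strain in np.unique(old_strains):
        if strain >= 0 and not np.any(pop.strain == strain):
            state.dissolved.setdefault(int(strain), state.time + cfg.dt)


def step(state: SimulationState, dt: float | None = None) -> SimulationState:
    """Advance the state by one time step (in place)."""
    cfg = state.config
    if dt is not None and dt != cfg.dt:
        state.config = replace(cfg, dt=dt)
        cfg = state.config
    # density is computed once per step, before movement; survivors keep
    # their pre-movement density for the division draw
    rho, pairs, diffv, dist, gaps = _step_geometry(state)
    keep = _movement(state, rho, pairs, diffv, dist, gaps)
    _divisions(state, rho[keep] if len(keep) else rho)
    _emigrations(state)
    state.time += cfg.dt
    return state


def take_snapshot(state: SimulationState) -> Snapshot:
    pop = state.population
    table = pd.DataFrame(
        {
            "id": pop.ids,
            "x": pop.pos[:, 0],
            "y": pop.pos[:, 1],
            "z": pop.pos[:, 2],
            "radius": pop.radius,
            "generation": pop.generation,
            "strain": pop.strain,
            "strain_generation": pop.strain_gen,
            "nested": pop.nested,
            "p0": pop.p0,
        }
    )
    nests = {}
    live = pop.strain[pop.strain >= 0]
    for strain, count in zip(*np.unique(live, return_counts=True)):
        nests[int(strain)] = {
            "count": int(count),
            "founder": state.nest_founders.get(int(strain), -1),
        }
    return Snapshot(time=state.time, table=table, nests=nests)


def run(config: SimulationConfig, progress: bool = False) -> Trajectory:
    """Run a full simulation, snapshotting at the configured interval."""
    state = initialize(config)
    snapshots = [take_snapshot(state)]
    n_steps = int(round(config.horizon / config.dt))
    every = max(1, int(round(config.snapshot_interval / config.dt)))
    for k in range(1, n_steps + 1):
        step(state)
        if k % every == 0 or k == n_steps:
            snapshots.append(take_snapshot(state))
            if progress:
                print(f"t={state.time:8.1f} d  n={len(state.population):7d}")
        # conservation audit
        expected = state.initial_count + state.births - state.exits
        if len(state.population) != expected:
            raise NevosimError(
                f"conservation audit failed at t={state.time}: "
                f"{len(state.population)} != {expected}"
            )
    events = None
    if config.record_events:
        events = pd.DataFrame(state.events,
                              columns=["time", "kind", "cell", "strain"])
    return Trajectory(config=config, snapshots=snapshots, events=events)


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

def save_trajectory(traj: Trajectory, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    manifest = {"times": [], "files": [], "nests": []}
    for k, snap in enumerate(traj.snapshots):
        fname = f"snapshot_{k:05d}.csv"
        snap.table.to_csv(os.path.join(outdir, fname), index=False)
        manifest["times"].append(snap.time)
        manifest["files"].append(fname)
        manifest["nests"].append(snap.nests)
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    if traj.events is not None:
        traj.events.to_csv(os.path.join(outdir, "events.csv"), index=False)


def load_trajectory(outdir) -> Trajectory:
    with open(os.path.join(outdir, "manifest.json")) as fh:
        manifest = json.load(fh)
    snapshots = []
    for t, fname, nests in zip(manifest["times"], manifest["files"],
                               manifest["nests"]):
        table = pd.read_csv(os.path.join(outdir, fname))
        snapshots.append(Snapshot(time=t, table=table,
                                  nests={int(k): v for k, v in nests.items()}))
    events_path = os.path.join(outdir, "events.csv")
    events = pd.read_csv(events_path) if os.path.exists(events_path) else None
    return Trajectory(config=None, snapshots=snapshots, events=events)
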