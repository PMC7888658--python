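"""Per-step velocity composition and position updates for melanocytes.

Velocities are assembled in three stages: external force plus diffusive
noise, pairwise attraction/repulsion, and the overlap-minimizing collision
corrector.  Default cells then move along the membrane (tangent projection,
pushforward, geodesic step); nested cells move unconstrained with a dermal
exclusion term.  Force magnitudes are dimensionless in origin and are
interpreted as um/d so that ``x + dt * v`` is well formed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import membrane_geometry as mg
from .agent_dynamics import DampingCurve, ForceCurve, Melanocyte
from .errors import DomainExit, ParameterDomainError

logger = logging.getLogger(__name__)

__all__ = [
    "MovementConfig",
    "NeighborView",
    "initial_velocity",
    "add_pair_forces",
    "collision_correct",
    "move_constrained",
    "move_nested",
]


@dataclass
class MovementConfig:
    """Motion parameters for one scenario."""

    D: float = 30.0                       # base diffusivity, um^2/d
    v_ext: np.ndarray | None = None       # external force direction*magnitude
    v_ext_altitude_scaled: bool = True    # ramp from 0 at base to full at h_ref
    v_ext_h_ref: float = 100.0            # papilla-tip reference altitude, um
    K: float = 1.0                        # collision correction fraction
    v_derm_vertical: float = 5.0          # upward push below the base plane, um/d
    v_derm_horizontal: float = 5.0        # outward push inside papillae, um/d
    F_a: ForceCurve = field(default_factory=ForceCurve.zero)
    F_r: ForceCurve = field(default_factory=lambda: ForceCurve.zero("F_r"))
    Q: DampingCurve = field(default_factory=lambda: DampingCurve.constant(1.0, "Q"))
    R_gen: DampingCurve = field(
        default_factory=lambda: DampingCurve.constant(1.0, "R_gen"))
    G_a: DampingCurve = field(default_factory=lambda: DampingCurve.constant(1.0, "G_a"))
    G_r: DampingCurve = field(default_factory=lambda: DampingCurve.constant(1.0, "G_r"))
    H_a: DampingCurve = field(default_factory=lambda: DampingCurve.constant(1.0, "H_a"))
    H_r: DampingCurve = field(default_factory=lambda: DampingCurve.constant(1.0, "H_r"))
    tangent_mode: str = "project"

    def __post_init__(self):
        if not (0.0 <= self.D <= 60.0):
            raise ParameterDomainError("D must lie in [0, 60] um^2/d")
        if not (0.0 < self.K <= 1.0):
            raise ParameterDomainError("K must lie in (0, 1]")
        if self.v_ext is not None:
            self.v_ext = np.asarray(self.v_ext, float)

    def external_velocity(self, altitude: float) -> np.ndarray:
        if self.v_ext is None:
            return np.zeros(3)
        if not self.v_ext_altitude_scaled:
            return self.v_ext
        scale = float(np.clip(altitude / self.v_ext_h_ref, 0.0, 1.0))
        return scale * self.v_ext


@dataclass
class NeighborView:
    """Precomputed geometry of one neighbour as seen from a cell."""

    direction: np.ndarray   # unit vector pointing at the neighbour
    gap: float              # surface gap ||x_n - x|| - r_n - r
    same_strain: bool = False
    nested_pair: bool = False  # both cells nested


def initial_velocity(cell: Melanocyte, cfg: MovementConfig, rho: float,
                     dt: float, rng) -> np.ndarray:
    """External force plus diffusive noise scaled by sqrt(2 D Q R) dt^-1/2."""
    if dt <= 0:
        raise ParameterDomainError("dt must be positive")
    scale = np.sqrt(2.0 * cfg.D * float(cfg.Q(rho)) * float(cfg.R_gen(cell.generation)))
    noise = scale / np.sqrt(dt) * rng.standard_normal(3)
    return cfg.external_velocity(cell.position[2]) + noise


def add_pair_forces(v_i: np.ndarray, cell: Melanocyte, neighbors,
                    cfg: MovementConfig, rho: float, rng=None) -> np.ndarray:
    """Modulate the initial velocity by pairwise attraction and repulsion.

    Attraction acts only within a strain (nest adhesion); repulsion only
    across strains, preventing fusion of different globules.
    """
    v = np.asarray(v_i, float).copy()
    g = cell.generation
    ga = float(cfg.G_a(rho))
    gr = float(cfg.G_r(rho))
    ha = float(cfg.H_a(g))
    hr = float(cfg.H_r(g))
    for nb in neighbors:
        direction = nb.direction
        if not np.any(direction):
            if rng is None:
                continue
            logger.debug("zero-distance neighbour; drawing random direction")
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
        attract = float(cfg.F_a(nb.gap)) * ga * ha if nb.same_strain else 0.0
        repel = float(cfg.F_r(nb.gap)) * gr * hr if not nb.same_strain else 0.0
        v = v + direction * (attract - repel)
    return v


def collision_correct(v_ii: np.ndarray, cell: Melanocyte, neighbors,
                      K: float, dt: float) -> np.ndarray:
    """Subtract the overlapping projected velocity components.

    One pass per step over the neighbours sorted by ascending gap; each
    correction uses the running velocity.  The mechanism minimizes overlap
    of the spherical agents, it is not a physical collision model.
    """
    v = np.asarray(v_ii, float).copy()
    for nb in sorted(neighbors, key=lambda n: n.gap):
        direction = nb.direction
        proj = float(direction @ v)
        if nb.gap < proj * dt:
            v = v - direction * ((proj * dt - nb.gap) * K / dt)
    return v


def move_constrained(membrane: mg.MembraneModel, cell: Melanocyte,
                     v_iii: np.ndarray, dt: float,
                     tangent_mode: str = "project") -> np.ndarray:
    """Advance a membrane-bound cell: tangent step along a geodesic.

    Raises :class:`~nevosim.errors.DomainExit` when the cell leaves the
    simulation extent (the caller discards it).
    """
    v_tan = mg.project_to_tangent(membrane, cell.position, v_iii,
                                  mode=tangent_mode)
    if not np.any(v_tan):
        return cell.position.copy()
    v_chart = mg.pushforward(membrane, cell.position, v_tan)
    u0 = mg.chart_forward(membrane, cell.position)
    u1 = mg.geodesic_step(membrane, u0, v_chart, dt)
    return mg.chart_inverse(membrane, u1)


def move_nested(cell: Melanocyte, v_iii: np.ndarray, membrane: mg.MembraneModel,
                cfg: MovementConfig, dt: float) -> np.ndarray:
    """Unconstrained Euler step with dermal exclusion.

    ``v_derm`` vanishes in the epidermis, pushes vertically up below the base
    plane of the membrane, and horizontally away from the papilla axis inside
    a papilla body.
    """
    v_derm = dermal_exclusion(cell.position, membrane, cfg)
    return cell.position + dt * (np.asarray(v_iii, float) + v_derm)


def dermal_exclusion(position, membrane: mg.MembraneModel,
                     cfg: MovementConfig) -> np.ndarray:
    x = np.asarray(position, float)
    xi = x[:2][None, :]
    z = x[2]
    surface = membrane.altitude(xi)[0]
    if z >= surface:
        return np.zeros(3)  # epidermal compartment
    base = membrane.chi(xi)[0]
    region = int(membrane.locate(xi)[0])
    if z < base or region < 0:
        return np.array([0.0, 0.0, cfg.v_derm_vertical])
    center = membrane.papillae[region].center
    radial = x[:2] - center
    norm = np.linalg.norm(radial)
    if norm < 1e-9:
        return np.array([0.0, 0.0, cfg.v_derm_vertical])
    out = radial / norm * cfg.v_derm_horizontal
    return np.array([out[0], out[1], 0.0])
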