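"""Melanocyte agent state and stochastic cellular events.

Reference (per-cell) implementations of the local density measure, the
division probability, division with inheritance/differentiation, and
emigration from nests.  The simulation engine vectorizes the same formulas;
agreement between the two routes is covered by tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import ConfigurationError, ContractViolationError, ParameterDomainError

__all__ = [
    "Melanocyte",
    "DampingCurve",
    "ForceCurve",
    "AgentConfig",
    "weight",
    "local_density",
    "division_probability",
    "divide",
    "emigration_event",
]

#: weighting function constants: maximum value at zero gap and support radius
OMEGA_MAX = 0.02
OMEGA_SUPPORT = 100.0

MAX_GENERATION = 60

_DAMPING_NAMES = {"A", "B", "Q", "R_gen", "G_a", "G_r", "H_a", "H_r", "S",
                  "A_nest", "Q_diff"}


@dataclass
class Melanocyte:
    """One melanocyte agent."""

    id: int
    position: np.ndarray            # 3D, um
    radius: float                   # um
    generation: int = 0
    strain: int | None = None       # nest identifier; None = default population
    strain_generation: int = 0      # divisions since differentiation
    p0: float = 0.05                # inherited base proliferation rate, 1/d
    nested: bool = False
    alive: bool = True

    def __post_init__(self):
        self.position = np.asarray(self.position, float)
        if self.radius <= 0:
            raise ParameterDomainError("cell radius must be positive")
        if self.p0 < 0:
            raise ParameterDomainError("p0 must be non-negative")
        if self.nested and self.strain is None:
            raise ContractViolationError("nested cell must belong to a strain")
        if self.generation > MAX_GENERATION:
            raise ParameterDomainError(
                f"generation exceeds configured maximum {MAX_GENERATION}"
            )


class DampingCurve:
    """Monotone piecewise-polynomial damping factor with range [0, 1].

    Defined by control points; evaluated with a monotone PCHIP interpolant
    and held constant beyond the outermost control points.
    """

    def __init__(self, name: str, points):
        if name not in _DAMPING_NAMES:
            raise ParameterDomainError(f"unknown damping curve name {name!r}")
        self.name = name
        pts = np.asarray(points, float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
            raise ParameterDomainError("need at least two (x, value) control points")
        if np.any(np.diff(pts[:, 0]) <= 0):
            raise ParameterDomainError("control point abscissae must increase")
        if pts[:, 1].min() < 0.0 or pts[:, 1].max() > 1.0:
            raise ParameterDomainError("damping values must lie in [0, 1]")
        self.points = pts
        self._interp = PchipInterpolator(pts[:, 0], pts[:, 1], extrapolate=False)
        self._lo, self._hi = pts[0], pts[-1]

    @classmethod
    def constant(cls, value: float, name: str = "A"):
        return cls(name, [(0.0, value), (1e9, value)])

    def __call__(self, x):
        x = np.asarray(x, float)
        out = self._interp(x)
        out = np.where(x <= self._lo[0], self._lo[1], out)
        out = np.where(x >= self._hi[0], self._hi[1], out)
        return np.clip(out, 0.0, 1.0)


class ForceCurve:
    """Distance-dependent pair-force magnitude, zero beyond its cutoff."""

    def __init__(self, name: str, points, cutoff: float):
        if name not in {"F_a", "F_r"}:
            raise ParameterDomainError(f"unknown force curve name {name!r}")
        self.name = name
        self.cutoff = float(cutoff)
        pts = np.asarray(points, float)
        if np.any(pts[:, 1] < 0.0):
            raise ParameterDomainError("force magnitudes must be non-negative")
        self.points = pts
        self._interp = PchipInterpolator(pts[:, 0], pts[:, 1], extrapolate=False)

    @classmethod
    def zero(cls, name: str = "F_a"):
        return cls(name, [(0.0, 0.0), (1.0, 0.0)], cutoff=0.0)

    def __call__(self, d):
        d = np.asarray(d, float)
        out = self._interp(np.clip(d, self.points[0, 0], self.points[-1, 0]))
        return np.where(d > self.cutoff, 0.0, np.nan_to_num(out))


@dataclass
class AgentConfig:
    """Parameters of the stochastic cellular events."""

    default_p0: float = 0.05        # base proliferation rate, 1/d
    nested_p0: float = 0.1          # within-nest proliferation rate, 1/d
    q0: float = 0.0                 # differentiation probability per division
    s0: float = 0.1                 # emigration base rate, 1/d
    sigma_p0: float = 0.01          # inheritance noise on p0
    sigma_radius: float = 0.1       # inheritance noise on radius
    cell_radius: float = 5.0        # default melanocyte radius, um
    max_generation: int = MAX_GENERATION
    division_offset: float = 0.5    # daughter offset as a fraction of radius
    _strain_counter: itertools.count = field(default_factory=itertools.count,
                                             repr=False)

    def next_strain_id(self) -> int:
        return next(self._strain_counter)


def weight(d) -> np.ndarray:
    """Quadratically decaying neighbour weight: 0.02 at contact, 0 at 100 um."""
    d = np.maximum(np.asarray(d, float), 0.0)  # overlapping gaps count as contact
    x = 1.0 - d / OMEGA_SUPPORT
    return np.where(d <= OMEGA_SUPPORT, OMEGA_MAX * x * x, 0.0)


def local_density(cell: Melanocyte, population) -> float:
    """Distance-weighted neighbourhood measure, clamped to [0, 1]."""
    total = 0.0
    for other in population:
        if other is cell or not other.alive:
            continue
        gap = (
            float(np.linalg.norm(other.position - cell.position))
            - other.radius
            - cell.radius
        )
        total += float(weight(gap))
    return min(total, 1.0)


def division_probability(g, rho, p0, dt, A: DampingCurve, B: DampingCurve) -> float:
    """Per-step division probability exp(A(g) B(rho) p0 dt) - 1."""
    if dt <= 0:
        raise ParameterDomainError("dt must be positive")
    prob = float(np.exp(float(A(g)) * float(B(rho)) * p0 * dt) - 1.0)
    if prob > 1.0:
        raise ConfigurationError(
            f"division probability {prob:.3f} exceeds 1; reduce p0*dt"
        )
    return prob


def divide(parent: Melanocyte, rng, config: AgentConfig):
    """Split a cell into two daughters with inheritance and differentiation.

    Both daughters carry generation ``parent.generation + 1``; size, position
    and p0 are inherited with clamped Gaussian noise; strain membership is
    inherited.  A default-type division differentiates one daughter into a
    freshly founded strain with probability ``q0``.
    """
    if not parent.alive:
        raise ContractViolationError("cannot divide a dead cell")
    g = parent.generation + 1
    direction = rng.normal(size=3)
    norm = np.linalg.norm(direction)
    direction = direction / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
    offset = config.division_offset * parent.radius * direction

    def make(child_id_offset, sign):
        radius = max(parent.radius + config.sigma_radius * rng.normal(), 0.1)
        p0 = max(parent.p0 + config.sigma_p0 * rng.normal(), 0.0)
        return Melanocyte(
            id=-1,  # caller assigns ids
            position=parent.position + sign * offset,
            radius=radius,
            generation=g,
            strain=parent.strain,
            strain_generation=(parent.strain_generation + 1 if parent.nested else 0),
            p0=p0,
            nested=parent.nested,
        )

    d1, d2 = make(0, +1.0), make(1, -1.0)
    if not parent.nested and config.q0 > 0 and rng.random() < config.q0:
        strain = config.next_strain_id()
        d1 = replace(
            d1,
            strain=strain,
            strain_generation=0,
            nested=True,
            p0=config.nested_p0,
        )
    return d1, d2


def emigration_event(cell: Melanocyte, s_curve, dt, rng,
                     default_p0: float = 0.05) -> bool:
    """Draw one emigration event for a nested cell.

    Per-step probability is ``1 - exp(-s(k) dt)`` with ``k`` the within-strain
    generation.  On emigration the cell reverts to the default population.
    """
    if not cell.nested:
        raise ContractViolationError("emigration_event requires a nested cell")
    rate = float(s_curve(cell.strain_generation))
    prob = 1.0 - np.exp(-rate * dt)
    if rng.random() < prob:
        cell.nested = False
        cell.strain = None
        cell.strain_generation = 0
        cell.p0 = default_p0
        return True
    return False
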