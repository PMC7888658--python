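"""Named scenario presets for reticular and globular simulations.

The exact control points of the damping curves were calibrated against the
aggregate nest-size and growth behaviour rather than transcribed from any
source; the qualitative shapes follow the scenario descriptions: senescence
damping A falls to zero at generation 60, contact inhibition B and movement
damping Q decrease with density, R decreases with generation.  Globular
scenarios add differentiation (q0 = 0.1), within-nest proliferation at
0.1/d, within-strain attraction and cross-strain repulsion, and
strain-generation-dependent emigration.
"""

from __future__ import annotations

import numpy as np

from .agent_dynamics import AgentConfig, DampingCurve, ForceCurve
from .engine import SimulationConfig
from .errors import ConfigurationError
from .migration import MovementConfig
from .tissue_synthesis import MembraneConfig

__all__ = ["scenario_config", "single_nest_config", "SCENARIOS", "nest_curves"]


def _damping_A():
    return DampingCurve("A", [(0, 1.0), (30, 1.0), (45, 0.7), (60, 0.0)])


def _damping_B():
    return DampingCurve("B", [(0.0, 1.0), (0.4, 0.95), (0.8, 0.35), (1.0, 0.0)])


def _damping_Q():
    return DampingCurve("Q", [(0.0, 1.0), (0.6, 0.8), (1.0, 0.25)])


def _damping_Rgen():
    return DampingCurve("R_gen", [(0, 1.0), (40, 0.8), (60, 0.4)])


#: nested-dynamics curves per globular scenario: (A_nest points, S points)
#: emigration rate is s0 * S(strain_generation) with s0 = 0.1/d
_NEST_CURVES = {
    1: ([(0, 1.0), (7, 1.0), (11, 0.0)],
        [(0, 0.03), (7, 0.03), (11, 0.22), (30, 0.22)]),
    2: ([(0, 1.0), (7, 1.0), (10, 0.0)],
        [(0, 0.03), (7, 0.03), (10, 0.25), (30, 0.25)]),
    3: ([(0, 1.0), (8, 1.0), (11, 0.0)],
        [(0, 0.02), (8, 0.05), (11, 0.45), (30, 0.45)]),
    4: ([(0, 1.0), (7, 1.0), (10, 0.0)],
        [(0, 0.01), (7, 0.05), (10, 0.32), (30, 0.45)]),
}

#: per-scenario movement variations (diffusivity, downward force strength)
_RETICULAR_MOTION = {
    1: (22.0, 0.0),
    2: (28.0, 0.3),
    3: (18.0, 0.5),
    4: (30.0, 0.5),
}

#: membrane size class per scenario (larger papillae in reticular 2/4 and
#: globular 1/3)
_MEMBRANE_CLASS = {
    ("reticular", 1): "small", ("reticular", 2): "large",
    ("reticular", 3): "small", ("reticular", 4): "large",
    ("globular", 1): "large", ("globular", 2): "small",
    ("globular", 3): "large", ("globular", 4): "small",
}

SCENARIOS = tuple(
    f"{kind}-{i}" for kind in ("reticular", "globular") for i in range(1, 5)
)


def nest_curves(index: int):
    """(A_nest, S) damping curves of globular scenario ``index``."""
    a_pts, s_pts = _NEST_CURVES[index]
    return DampingCurve("A_nest", a_pts), DampingCurve("S", s_pts)


def scenario_config(name: str, extent=(5000.0, 5000.0), horizon: float | None = None,
                    seed: int = 0, dt: float = 1.0) -> SimulationConfig:
    """Build a full simulation configuration for a named scenario preset."""
    try:
        kind, idx = name.rsplit("-", 1)
        idx = int(idx)
        if kind not in ("reticular", "globular") or not 1 <= idx <= 4:
            raise ValueError
    except ValueError:
        raise ConfigurationError(
            f"unknown scenario {name!r}; expected one of {SCENARIOS}"
        ) from None

    D, v_down = _RETICULAR_MOTION[idx]
    v_ext = np.array([0.0, 0.0, -v_down]) if v_down else None
    membrane_class = _MEMBRANE_CLASS[(kind, idx)]

    movement = MovementConfig(
        D=D,
        v_ext=v_ext,
        Q=_damping_Q(),
        R_gen=_damping_Rgen(),
    )
    agent = AgentConfig(default_p0=0.05, nested_p0=0.1, q0=0.0, s0=0.1)
    cfg = SimulationConfig(
        dt=dt,
        horizon=horizon if horizon is not None else
        (2000.0 if kind == "reticular" else 1000.0),
        extent=tuple(extent),
        membrane_config=MembraneConfig(extent=tuple(extent),
                                       papilla_preset=membrane_class),
        n_initial=10,
        agent=agent,
        movement=movement,
        A=_damping_A(),
        B=_damping_B(),
        seed=seed,
    )
    if kind == "globular":
        cfg.agent.q0 = 0.1
        _apply_globular(cfg, idx)
    return cfg


def _apply_globular(cfg: SimulationConfig, idx: int) -> None:
    a_nest, s_curve = nest_curves(idx)
    cfg.A_nest = a_nest
    cfg.S = s_curve
    cfg.B_nest = DampingCurve.constant(1.0, "B")
    # globular scenarios pair nest formation with higher single-cell
    # motility, which drives their faster areal growth
    cfg.movement.D = 60.0
    cfg.movement.R_gen = DampingCurve("R_gen", [(0, 1.0), (60, 0.7)])
    cfg.movement.F_a = ForceCurve(
        "F_a", [(0.0, 1.0), (15.0, 0.5), (30.0, 0.0)], cutoff=30.0)
    cfg.movement.F_r = ForceCurve(
        "F_r", [(0.0, 0.3), (10.0, 0.12), (20.0, 0.0)], cutoff=20.0)
    # movement forces are damped in congested areas: the adhesive pull is
    # needed at the nest boundary (low density), not in its saturated core
    cfg.movement.G_a = DampingCurve(
        "G_a", [(0.0, 1.0), (0.5, 0.8), (0.85, 0.25), (1.0, 0.05)])
    cfg.movement.G_r = DampingCurve(
        "G_r", [(0.0, 1.0), (0.5, 0.8), (0.85, 0.25), (1.0, 0.05)])
    # differentiation is conditioned on a sparse neighbourhood: nests are
    # founded at the expanding front of the lesion
    cfg.Q_diff = DampingCurve("Q_diff", [(0.0, 1.0), (0.04, 1.0), (0.10, 0.0)])


def single_nest_config(idx: int, horizon: float = 250.0, seed: int = 0,
                       extent=(1000.0, 1000.0), spatial: bool = True,
                       dt: float = 1.0) -> SimulationConfig:
    """Single-nest experiment: one differentiated founder at t = 0.

    Matches the isolated-nest validation setting: the simulation starts from
    one nested cell in a 1 mm^2 tissue section, no further differentiation
    occurs and emitted cells do not proliferate.  With density damping absent
    from the nested dynamics the nest-size process is spatially decoupled, so
    ``spatial=False`` reproduces the same statistics at a fraction of the
    cost (used for large replicate counts).
    """
    cfg = scenario_config(f"globular-{idx}", extent=extent, horizon=horizon,
                          seed=seed, dt=dt)
    cfg.n_initial = 1
    cfg.founder_nested = True
    cfg.agent.q0 = 0.0
    cfg.agent.default_p0 = 0.0   # emitted cells do not proliferate here
    cfg.spatial = spatial
    cfg.snapshot_interval = 5.0
    return cfg
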