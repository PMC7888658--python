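"""Papilla-shape statistics and procedural membrane generation.

Fits the shape-curve model to microanatomic measurement tuples, fits
parametric distributions to the resulting ensembles and generates densely
packed membranes by hexagonal seeding plus iterative local optimization of
disk centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial import cKDTree

from . import membrane_geometry as mg
from .errors import DomainError, FittingError, PackingError, ParameterDomainError

__all__ = [
    "PapillaMeasurement",
    "PapillaStatistics",
    "shrinkage_correct",
    "fit_shape",
    "fit_distributions",
    "sample_papillae",
    "pack_papillae",
    "PackingResult",
    "generate_membrane",
    "MembraneConfig",
    "read_microanatomy_table",
    "write_microanatomy_table",
    "MICROANATOMY_COLUMNS",
]

SHRINKAGE_FACTOR = 1.2

MICROANATOMY_COLUMNS = [
    "melanocyte_diameter_um",
    "papilla_height_um",
    "papilla_base_radius_um",
    "papilla_mid_radius_um",
    "papilla_tip_radius_um",
    "confocal_papillae_per_mm2",
]


@dataclass
class PapillaMeasurement:
    """One measured papilla: height and radii at three reference heights."""

    H_bar: float
    r_base: float
    r_mid: float
    r_tip: float

    def __post_init__(self):
        if min(self.H_bar, self.r_base, self.r_mid, self.r_tip) <= 0:
            raise DomainError("measurements must be positive")


@dataclass
class FittedShape:
    R: float
    H: float
    p: float
    residual: float
    converged: bool


@dataclass
class PapillaStatistics:
    """Distributional model of papilla geometry plus packing directives.

    ``distributions`` maps variable name (R, H, p) to a (family, params)
    pair; family is "log-normal" (params: sigma, scale) or "beta" (params:
    a, b, loc, scale).  Length samples are truncated to ``truncate`` bounds
    to keep radii ratios compatible with the packing assumptions.
    """

    distributions: dict
    density_target: float = 80.0
    shoulder_weight: float = 0.6
    truncate: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (50.0 <= self.density_target <= 160.0):
            raise ParameterDomainError(
                f"density target {self.density_target} outside [50, 160] per mm^2"
            )

    def sample(self, name: str, n: int, rng) -> np.ndarray:
        family, params = self.distributions[name]
        if family == "log-normal":
            dist = stats.lognorm(params[0], scale=params[1])
        elif family == "beta":
            dist = stats.beta(*params)
        else:
            raise ParameterDomainError(f"unknown family {family!r}")
        out = dist.rvs(size=n, random_state=rng)
        bounds = self.truncate.get(name)
        if bounds is not None:
            lo, hi = bounds
            bad = (out < lo) | (out > hi)
            while bad.any():
                out[bad] = dist.rvs(size=int(bad.sum()), random_state=rng)
                bad = (out < lo) | (out > hi)
        return out


def large_papillae_statistics() -> PapillaStatistics:
    """Default preset: confocal-scale (doubled) papilla dimensions."""
    return PapillaStatistics(
        distributions={
            "R": ("log-normal", _lognorm_params(60.0, 9.0)),
            "H": ("log-normal", _lognorm_params(100.0, 17.0)),
            "p": ("beta", (2.0, 2.0, 0.0, 1.0)),
        },
        density_target=60.0,
        shoulder_weight=0.6,
        truncate={"R": (44.0, 76.0), "H": (60.0, 150.0)},
    )


def small_papillae_statistics() -> PapillaStatistics:
    return PapillaStatistics(
        distributions={
            "R": ("log-normal", _lognorm_params(45.0, 7.0)),
            "H": ("log-normal", _lognorm_params(78.0, 13.0)),
            "p": ("beta", (2.0, 2.0, 0.0, 1.0)),
        },
        density_target=110.0,
        shoulder_weight=0.6,
        truncate={"R": (32.0, 62.0), "H": (50.0, 120.0)},
    )


PAPILLA_PRESETS = {
    "large": large_papillae_statistics,
    "small": small_papillae_statistics,
}


def _lognorm_params(mean: float, sd: float):
    """(sigma, scale) of a log-normal with the given moments."""
    var = np.log1p((sd / mean) ** 2)
    sigma = np.sqrt(var)
    scale = mean * np.exp(-0.5 * var)
    return sigma, scale


# ---------------------------------------------------------------------------
# measurement processing
# ---------------------------------------------------------------------------

def shrinkage_correct(lengths):
    """Undo histologic dehydration shrinkage by scaling lengths by 1.2."""
    arr = np.asarray(lengths, float)
    if np.any(arr < 0):
        raise DomainError("lengths must be non-negative")
    return arr * SHRINKAGE_FACTOR


@lru_cache(maxsize=8192)
def _unit_curves(p: float):
    """Unit-span shape curve pair; the construction is scale equivariant."""
    return mg.build_shape_curve(1.0, 1.0, p)


def _model_radii(R: float, H: float, p: float) -> np.ndarray:
    """Model-implied radii at heights (0, 0.5H, H-10) for parameters (R,H,p)."""
    curve = _unit_curves(round(float(p), 10))
    z_tip = max((H - 10.0) / H, 0.0)
    t_mid = curve.height_to_theta(0.5)
    t_tip = curve.height_to_theta(z_tip)
    return np.array([R, R * float(curve.r(t_mid)), R * float(curve.r(t_tip))])


def fit_shape(m: PapillaMeasurement) -> FittedShape:
    """Fit (R, H, p) of the shape model to one measurement tuple.

    H is pinned to the measured height; (R, p) minimize the squared error
    between model-implied radii at the three reference heights and the
    measured radii.  Non-convergence is flagged, not raised.
    """
    H = m.H_bar
    target = np.array([m.r_base, m.r_mid, m.r_tip])

    def residuals(x):
        R, p = x
        return _model_radii(R, H, p) - target

    best = None
    for p0 in (0.15, 0.5, 0.85):
        try:
            sol = optimize.least_squares(
                residuals,
                x0=np.array([m.r_base, p0]),
                bounds=([1e-2, 0.0], [np.inf, 1.0]),
                diff_step=[1e-4, 1e-3],
                xtol=1e-10, ftol=1e-12,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        return FittedShape(np.nan, H, np.nan, np.inf, False)
    R, p = best.x
    return FittedShape(float(R), H, float(p), float(2 * best.cost), True)


def simulate_measurement(R: float, H: float, p: float) -> PapillaMeasurement:
    """Exact model-implied measurement for known parameters (test oracle aid)."""
    base, mid, tip = _model_radii(R, H, p)
    return PapillaMeasurement(H_bar=H, r_base=base, r_mid=mid, r_tip=tip)


def fit_distributions(
    ensemble,
    families: dict | None = None,
    density_target: float = 80.0,
    shoulder_weight: float = 0.6,
) -> PapillaStatistics:
    """Maximum-likelihood marginal fits of the (R, H, p) solution ensemble.

    Correlations between the variables are deliberately ignored.  ``ensemble``
    is an iterable of (R, H, p) triples; flagged (non-finite) records are
    excluded.
    """
    arr = np.asarray([(e.R, e.H, e.p) if isinstance(e, FittedShape) else tuple(e)
                      for e in ensemble], float)
    arr = arr[np.isfinite(arr).all(axis=1)]
    if len(arr) < 10:
        raise FittingError(f"ensemble too small after filtering: {len(arr)}")
    families = families or {"R": "log-normal", "H": "log-normal", "p": "beta"}
    dists = {}
    for idx, name in enumerate(["R", "H", "p"]):
        sample = arr[:, idx]
        if np.ptp(sample) < 1e-12:
            raise FittingError(f"degenerate (constant) sample for variable {name}")
        family = families[name]
        if family == "log-normal":
            sigma, _, scale = stats.lognorm.fit(sample, floc=0.0)
            dists[name] = ("log-normal", (sigma, scale))
        elif family == "beta":
            eps = 1e-6
            clipped = np.clip(sample, eps, 1.0 - eps)
            a, b, _, _ = stats.beta.fit(clipped, floc=0.0, fscale=1.0)
            dists[name] = ("beta", (a, b, 0.0, 1.0))
        else:
            raise ParameterDomainError(f"unknown family {family!r} for {name}")
    return PapillaStatistics(
        distributions=dists,
        density_target=density_target,
        shoulder_weight=shoulder_weight,
    )


# ---------------------------------------------------------------------------
# sampling and packing
# ---------------------------------------------------------------------------

def sample_papillae(statistics: PapillaStatistics, n: int, rng) -> np.ndarray:
    """Draw n independent (R, H, p) triples; shouldered shapes over-represented."""
    if n < 1:
        raise ParameterDomainError("n must be >= 1")
    R = statistics.sample("R", n, rng)
    H = statistics.sample("H", n, rng)
    p = statistics.sample("p", n, rng)
    boost = rng.random(n) < statistics.shoulder_weight
    p[boost] = stats.beta(5.0, 1.6).rvs(size=int(boost.sum()), random_state=rng)
    return np.column_stack([R, H, p])


@dataclass
class PackingResult:
    centers: np.ndarray      # (k, 2) accepted disk centers
    indices: np.ndarray      # indices into the input radii for each center
    density_per_mm2: float


def pack_papillae(extent, radii, rng, max_rounds: int = 500) -> PackingResult:
    """Place non-overlapping disks densely inside the extent.

    Disks are seeded on a hexagonal grid with the mean diameter as pitch,
    randomly assigned radii, then iteratively relaxed: overlapping pairs are
    pushed apart with an annealed step, centers are clamped to the extent.
    Residually overlapping disks are dropped (worst offender first).
    """
    radii = np.asarray(radii, float)
    if np.any(radii <= 0):
        raise ParameterDomainError("radii must be positive")
    lx, ly = float(extent[0]), float(extent[1])
    if np.pi * np.sum(radii**2) > lx * ly:
        raise PackingError("total disk area exceeds extent area")

    rmax = radii.max()
    # seed on size-sorted hexagonal strips: similar radii end up adjacent and
    # every row is lowered to the exact clearance against all earlier disks,
    # so the seed layout is overlap-free and locally close to hexagonal
    order_full = np.argsort(radii)[::-1]

    def build_row(start_ptr, stagger):
        xs, members = [], []
        cursor = 0.0
        ptr = start_ptr
        while ptr < len(order_full):
            gi = order_full[ptr]
            r_i = radii[gi]
            x = r_i if cursor == 0.0 else cursor + r_i
            if cursor == 0.0 and stagger:
                x += r_i
            if x + r_i > lx and cursor > 0.0:
                break
            xs.append(x)
            members.append(gi)
            cursor = x + r_i
            ptr += 1
        return np.asarray(xs), np.asarray(members, int), ptr

    placed_x, placed_y, placed_r, order = [], [], [], []
    ptr = 0
    stagger = 0
    while ptr < len(order_full):
        xs, members, ptr_next = build_row(ptr, stagger)
        if len(xs) == 0:
            break
        rr_row = radii[members]
        y_row = rr_row.max()
        if placed_x:
            px = np.asarray(placed_x)
            py = np.asarray(placed_y)
            pr = np.asarray(placed_r)
            for x_i, r_i in zip(xs, rr_row):
                dx = np.abs(px - x_i)
                reach = pr + r_i
                near = dx < reach
                if near.any():
                    need = py[near] + np.sqrt(reach[near] ** 2 - dx[near] ** 2)
                    y_row = max(y_row, need.max())
        if y_row + rr_row.min() > ly:
            break
        keep_row = y_row + rr_row <= ly
        placed_x.extend(xs[keep_row])
        placed_y.extend([y_row] * int(keep_row.sum()))
        placed_r.extend(rr_row[keep_row])
        order.extend(members[keep_row])
        ptr = ptr_next
        stagger ^= 1
    if not placed_x:
        raise PackingError("extent too small for any disk")
    centers = np.column_stack([placed_x, placed_y]).astype(float)
    order = np.asarray(order, int)
    r = np.asarray(placed_r, float)
    k = len(centers)

    # shrink-and-grow relaxation: disks start down-scaled and inflate; the
    # scale only advances once the current configuration is overlap-free
    factor = 0.90
    stall = 0
    for it in range(max_rounds):
        rr = r * factor
        tree = cKDTree(centers)
        pairs = tree.query_pairs(2.0 * rmax, output_type="ndarray")
        if len(pairs):
            i, j = pairs[:, 0], pairs[:, 1]
            d = centers[i] - centers[j]
            dist = np.linalg.norm(d, axis=1)
            overlap = (rr[i] + rr[j]) - dist
            mask = overlap > 1e-9
        else:
            mask = np.zeros(0, bool)
        if not mask.any():
            if factor >= 1.0:
                break
            factor = min(1.0, factor + 0.01)
            stall = 0
            continue
        stall += 1
        if stall > 150:  # jammed at this scale: accept and finish at full size
            factor = 1.0
            stall = -np.inf
        step = 1.0 if factor >= 1.0 else 0.7
        i, j, d, dist, overlap = i[mask], j[mask], d[mask], dist[mask], overlap[mask]
        zero = dist < 1e-9
        if zero.any():
            ang = rng.uniform(0, 2 * np.pi, int(zero.sum()))
            d[zero] = np.column_stack([np.cos(ang), np.sin(ang)])
            dist[zero] = 1.0
        push = (step * overlap / dist)[:, None] * d
        np.add.at(centers, i, 0.5 * push)
        np.add.at(centers, j, -0.5 * push)
        centers[:, 0] = np.clip(centers[:, 0], rr, lx - rr)
        centers[:, 1] = np.clip(centers[:, 1], rr, ly - rr)
    centers[:, 0] = np.clip(centers[:, 0], r, lx - r)
    centers[:, 1] = np.clip(centers[:, 1], r, ly - r)

    # drop residual offenders, worst first
    keep = np.ones(k, bool)
    while True:
        idx = np.flatnonzero(keep)
        tree = cKDTree(centers[idx])
        pairs = tree.query_pairs(2.0 * rmax, output_type="ndarray")
        if len(pairs) == 0:
            break
        gi, gj = idx[pairs[:, 0]], idx[pairs[:, 1]]
        dist = np.linalg.norm(centers[gi] - centers[gj], axis=1)
        overlap = (r[gi] + r[gj]) - dist
        bad = overlap > 1e-9
        if not bad.any():
            break
        counts = np.zeros(k)
        np.add.at(counts, gi[bad], overlap[bad])
        np.add.at(counts, gj[bad], overlap[bad])
        keep[np.argmax(counts)] = False

    centers = centers[keep]
    order = order[keep]
    density = len(centers) / (lx * ly) * 1e6
    return PackingResult(centers=centers, indices=order, density_per_mm2=density)


@dataclass
class MembraneConfig:
    extent: tuple = (1000.0, 1000.0)
    papilla_preset: str = "large"          # key into PAPILLA_PRESETS, or "none"
    statistics: PapillaStatistics | None = None
    oversample: float = 1.4                # sample surplus for dense packing
    chi_bumps_per_mm2: float = 2.0
    chi_radius_range: tuple = (300.0, 600.0)
    chi_amplitude_range: tuple = (-25.0, 40.0)


def generate_membrane(config: MembraneConfig, seed: int) -> mg.MembraneModel:
    """Sample, pack and assemble a full membrane model, reproducibly."""
    rng = np.random.default_rng(seed)
    lx, ly = config.extent
    area_mm2 = lx * ly / 1e6

    papillae = []
    if config.papilla_preset != "none":
        statistics = config.statistics or PAPILLA_PRESETS[config.papilla_preset]()
        n = max(1, int(np.ceil(statistics.density_target * area_mm2
                               * config.oversample)))
        triples = sample_papillae(statistics, n, rng)
        # keep the request feasible: cap the summed disk area at 80% of the
        # extent (hexagonal packing tops out at ~90.7%)
        areas = np.pi * triples[:, 0] ** 2
        cum = np.cumsum(areas)
        n_feasible = int(np.searchsorted(cum, 0.82 * lx * ly))
        triples = triples[: max(1, n_feasible)]
        packing = pack_papillae(config.extent, triples[:, 0], rng)
        for center, idx in zip(packing.centers, packing.indices):
            R, H, p = triples[idx]
            curve = mg.build_shape_curve(float(R), float(H), float(p))
            papillae.append(mg.PapillaChart(center=center, shape=curve))

    bumps = []
    n_bumps = rng.poisson(config.chi_bumps_per_mm2 * area_mm2)
    for _ in range(n_bumps):
        radius = rng.uniform(*config.chi_radius_range)
        amplitude = rng.uniform(*config.chi_amplitude_range)
        center = rng.uniform([0.0, 0.0], [lx, ly])
        bumps.append(mg.DeformationBump(center=center, radius=radius,
                                        amplitude=amplitude))

    return mg.MembraneModel(config.extent, papillae, bumps)


# ---------------------------------------------------------------------------
# measurement table I/O (S1-style layout)
# ---------------------------------------------------------------------------

def read_microanatomy_table(path) -> pd.DataFrame:
    """Read a microanatomy measurement table (xlsx or csv, ragged columns)."""
    path = str(path)
    if path.endswith(".xlsx"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    missing = [c for c in MICROANATOMY_COLUMNS if c not in df.columns]
    if missing:
        raise FittingError(f"malformed microanatomy table, missing columns {missing}")
    return df[MICROANATOMY_COLUMNS]


def write_microanatomy_table(df: pd.DataFrame, path) -> None:
    path = str(path)
    if path.endswith(".xlsx"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)


def measurements_from_table(df: pd.DataFrame) -> list[PapillaMeasurement]:
    cols = ["papilla_height_um", "papilla_base_radius_um",
            "papilla_mid_radius_um", "papilla_tip_radius_um"]
    sub = df[cols].dropna()
    return [
        PapillaMeasurement(H_bar=row[0], r_base=row[1], r_mid=row[2], r_tip=row[3])
        for row in sub.to_numpy()
    ]
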