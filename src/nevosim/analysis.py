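"""Lesion quantification and aggregate oracle models.

Area of a lesion is measured from cell positions via the smallest enclosing
disk and the 0.9-quantile disk; growth is summarized by least-squares
slopes and compared between groups with an unpaired t-test.  The
generation-resolved expectation recursions serve as independent oracles for
the stochastic engine in non-spatial configurations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, FittingError

logger = logging.getLogger(__name__)

__all__ = [
    "smallest_enclosing_disk",
    "quantile_disk",
    "area_series",
    "AreaSeries",
    "growth_slope",
    "compare_slopes",
    "nest_statistics",
    "NestSeries",
    "vertical_distribution",
    "expected_population",
    "expected_nest_size",
    "read_growth_table",
    "GrowthSeries",
]

UM2_TO_MM2 = 1e-6


# ---------------------------------------------------------------------------
# enclosing disks
# ---------------------------------------------------------------------------

def _circumcircle(a, b, c):
    d = 2.0 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
    if abs(d) < 1e-14:
        # collinear: take the two farthest points
        pts = np.array([a, b, c])
        dists = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        i, j = np.unravel_index(np.argmax(dists), dists.shape)
        center = (pts[i] + pts[j]) / 2.0
        return center, dists[i, j] / 2.0
    ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1])
          + (c @ c) * (a[1] - b[1])) / d
    uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0])
          + (c @ c) * (b[0] - a[0])) / d
    center = np.array([ux, uy])
    return center, float(np.linalg.norm(a - center))


def smallest_enclosing_disk(points):
    """Exact minimum enclosing disk (randomized incremental, O(n) expected)."""
    pts = np.asarray(points, float).reshape(-1, 2)
    if len(pts) == 0:
        raise DomainError("need at least one point")
    if len(pts) == 1:
        return pts[0].copy(), 0.0
    # the minimum disk is determined by hull vertices only
    if len(pts) > 16:
        try:
            from scipy.spatial import ConvexHull

            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass  # degenerate input (collinear); fall through with all points
    rng = np.random.default_rng(0)
    pts = pts[rng.permutation(len(pts))]
    eps = 1e-10

    c, r = pts[0].copy(), 0.0
    for i in range(1, len(pts)):
        p = pts[i]
        if np.linalg.norm(p - c) <= r + eps:
            continue
        c, r = p.copy(), 0.0
        for j in range(i):
            q = pts[j]
            if np.linalg.norm(q - c) <= r + eps:
                continue
            c = (p + q) / 2.0
            r = np.linalg.norm(p - q) / 2.0
            for k in range(j):
                s = pts[k]
                if np.linalg.norm(s - c) <= r + eps:
                    continue
                c, r = _circumcircle(p, q, s)
    return c, float(r)


def quantile_disk(points, q: float = 0.9, center: str = "centroid"):
    """Disk covering the q-quantile of distances from the centre.

    The centre defaults to the centroid; ``center="enclosing"`` uses the
    smallest-enclosing-disk centre instead.
    """
    pts = np.asarray(points, float).reshape(-1, 2)
    if len(pts) == 0:
        raise DomainError("need at least one point")
    if center == "centroid":
        c = pts.mean(axis=0)
    elif center == "enclosing":
        c, _ = smallest_enclosing_disk(pts)
    else:
        raise DomainError(f"unknown center rule {center!r}")
    dists = np.linalg.norm(pts - c, axis=1)
    return c, float(np.quantile(dists, q))


@dataclass
class AreaSeries:
    table: pd.DataFrame  # columns: time_d, area_med_mm2, area_q90_mm2, count

    def slopes(self):
        t = self.table["time_d"].to_numpy()
        return (
            growth_slope(np.column_stack([t, self.table["area_med_mm2"]])),
            growth_slope(np.column_stack([t, self.table["area_q90_mm2"]])),
        )


def area_series(trajectory, q: float = 0.9) -> AreaSeries:
    """Per-snapshot disk areas in mm^2 (enclosing and q-quantile disks)."""
    rows = []
    for snap in trajectory.snapshots:
        pts = snap.table[["x", "y"]].to_numpy()
        if len(pts) == 0:
            logger.info("skipping empty snapshot at t=%s", snap.time)
            continue
        _, r_med = smallest_enclosing_disk(pts)
        _, r_q = quantile_disk(pts, q)
        rows.append(
            (snap.time, np.pi * r_med**2 * UM2_TO_MM2,
             np.pi * r_q**2 * UM2_TO_MM2, len(pts))
        )
    return AreaSeries(
        pd.DataFrame(rows, columns=["time_d", "area_med_mm2", "area_q90_mm2",
                                    "count"])
    )


def growth_slope(series) -> float:
    """Ordinary least-squares slope of (t, area) pairs, mm^2/d."""
    arr = np.asarray(series, float).reshape(-1, 2)
    t, y = arr[:, 0], arr[:, 1]
    if len(arr) < 2 or np.ptp(t) == 0.0:
        raise DomainError("need at least two distinct times")
    tc = t - t.mean()
    return float((tc @ (y - y.mean())) / (tc @ tc))


def compare_slopes(group_a, group_b, welch: bool = False):
    """Two-sample unpaired t-test on growth slopes (pooled variance default)."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise DomainError("each group needs at least two slopes")
    if np.ptp(a) == 0.0 and np.ptp(b) == 0.0 and a.mean() != b.mean():
        raise DomainError("degenerate variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# nests
# ---------------------------------------------------------------------------

@dataclass
class NestSeries:
    table: pd.DataFrame          # time_d, n_nests, mean_size, total_nested
    per_nest: list               # per snapshot: {strain: count}
    dissolutions: dict           # strain -> first time absent

    def time_of_max_mean_size(self, window: int = 5) -> float:
        y = self.table["mean_size"].to_numpy(float)
        if len(y) == 0:
            raise DomainError("empty nest series")
        if window > 1 and len(y) >= window:
            kernel = np.ones(window) / window
            y = np.convolve(y, kernel, mode="same")
        return float(self.table["time_d"].to_numpy()[int(np.argmax(y))])

    def max_mean_size(self, window: int = 5) -> float:
        y = self.table["mean_size"].to_numpy(float)
        if window > 1 and len(y) >= window:
            y = np.convolve(y, np.ones(window) / window, mode="same")
        return float(y.max()) if len(y) else 0.0


def nest_statistics(trajectory) -> NestSeries:
    """Temporal evolution of nest count and sizes from a trajectory."""
    rows, per_nest = [], []
    seen = set()
    dissolved = {}
    for snap in trajectory.snapshots:
        counts = {int(s): rec["count"] for s, rec in snap.nests.items()}
        per_nest.append(counts)
        total_nested = sum(counts.values())
        n_nests = len(counts)
        mean_size = total_nested / n_nests if n_nests else 0.0
        rows.append((snap.time, n_nests, mean_size, total_nested))
        for s in seen - set(counts):
            dissolved.setdefault(s, snap.time)
        seen |= set(counts)
    return NestSeries(
        table=pd.DataFrame(rows, columns=["time_d", "n_nests", "mean_size",
                                          "total_nested"]),
        per_nest=per_nest,
        dissolutions=dissolved,
    )


def vertical_distribution(trajectory, membrane, burn_in: float = 0.0,
                          bins: int = 40, z_max: float = 200.0):
    """Time-averaged altitude histogram of cells above the local base plane."""
    edges = np.linspace(0.0, z_max, bins + 1)
    acc = np.zeros(bins)
    used = 0
    for snap in trajectory.snapshots:
        if snap.time < burn_in or len(snap.table) == 0:
            continue
        xi = snap.table[["x", "y"]].to_numpy()
        alt = snap.table["z"].to_numpy() - membrane.chi(xi)
        hist, _ = np.histogram(np.clip(alt, 0.0, z_max - 1e-9), bins=edges)
        acc += hist
        used += 1
    if used == 0 or acc.sum() == 0:
        return edges, np.zeros(bins)
    return edges, acc / acc.sum()


# ---------------------------------------------------------------------------
# aggregate oracle models
# ---------------------------------------------------------------------------

def expected_population(p0: float, A, dt: float, horizon: float, M0: float,
                        max_generation: int = 80):
    """Deterministic generation-resolved expectation of the population size.

    Mass at generation g divides with per-step probability
    ``exp(A(g) p0 dt) - 1``; dividing mass is removed and twice that mass
    appears at generation g+1.  Returns (times, totals).
    """
    n_steps = int(round(horizon / dt))
    m = np.zeros(max_generation + 2)
    m[0] = M0
    gens = np.arange(max_generation + 2)
    p = np.expm1(np.asarray(A(gens), float) * p0 * dt)
    totals = [M0]
    times = [0.0]
    for k in range(1, n_steps + 1):
        div = m * p
        m = m - div
        m[1:] += 2.0 * div[:-1]
        totals.append(m.sum())
        times.append(k * dt)
    return np.asarray(times), np.asarray(totals)


def expected_nest_size(p0_nest: float, s_curve, dt: float, horizon: float,
                       A_nest=None, max_generation: int = 64):
    """Deterministic strain-generation-resolved expectation of nest size.

    Within-strain mass at generation k gains from division at probability
    ``exp(A_nest(k) p0_nest dt) - 1`` and loses emigrating mass at
    probability ``1 - exp(-s(k) dt)`` (division applied first, matching the
    engine's event ordering).  Returns (times, sizes) starting from the
    single founder cell.
    """
    n_steps = int(round(horizon / dt))
    gens = np.arange(max_generation + 2)
    a = np.ones_like(gens, float) if A_nest is None else np.asarray(
        A_nest(gens), float)
    p = np.expm1(a * p0_nest * dt)
    q = -np.expm1(-np.asarray(s_curve(gens), float) * dt)
    m = np.zeros(max_generation + 2)
    m[0] = 1.0
    sizes = [1.0]
    times = [0.0]
    for k in range(1, n_steps + 1):
        div = m * p
        m = m - div
        m[1:] += 2.0 * div[:-1]
        m = m * (1.0 - q)
        sizes.append(m.sum())
        times.append(k * dt)
    return np.asarray(times), np.asarray(sizes)


# ---------------------------------------------------------------------------
# growth tables (S2-style layout)
# ---------------------------------------------------------------------------

@dataclass
class GrowthSeries:
    lesion_id: str
    pattern: str
    t: np.ndarray
    area: np.ndarray


GROWTH_COLUMNS = ["lesion_id", "pattern", "time_d", "area_mm2"]


def read_growth_table(path) -> list[GrowthSeries]:
    """Read a longitudinal lesion-growth table (long format, csv or xlsx)."""
    path = str(path)
    if path.endswith(".xlsx"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    missing = [c for c in GROWTH_COLUMNS if c not in df.columns]
    if missing:
        raise FittingError(f"malformed growth table: missing columns {missing}")
    out = []
    for lesion_id, group in df.groupby("lesion_id", sort=True):
        patterns = group["pattern"].unique()
        if len(patterns) != 1 or patterns[0] not in ("reticular", "globular"):
            raise FittingError(f"bad pattern label for lesion {lesion_id!r}")
        group = group.sort_values("time_d")
        out.append(
            GrowthSeries(
                lesion_id=str(lesion_id),
                pattern=str(patterns[0]),
                t=group["time_d"].to_numpy(float),
                area=group["area_mm2"].to_numpy(float),
            )
        )
    return out


def write_growth_table(df: pd.DataFrame, path) -> None:
    path = str(path)
    if path.endswith(".xlsx"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)


def group_slopes(series_list) -> dict:
    """Per-pattern lists of least-squares growth slopes."""
    out = {"reticular": [], "globular": []}
    for s in series_list:
        out[s.pattern].append(growth_slope(np.column_stack([s.t, s.area])))
    return out
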