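"""Synthetic stand-ins for the deposited measurement spreadsheets.

The generators emulate the two supplementary data tables — the microanatomy
measurements (papilla dimensions, melanocyte diameters, confocal papilla
counts) and the longitudinal lesion growth series — so that the full
analysis pipeline runs without any external download.  Published summary
statistics (sample means and standard deviations) are treated as inputs:
generated samples are affinely standardized so the emulated tables
reproduce them exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .tissue_synthesis import (
    MICROANATOMY_COLUMNS,
    _model_radii,
)

# published summary statistics of the deposited tables (means, SD, n)
PAPILLA_HEIGHT_MEAN, PAPILLA_HEIGHT_SD, N_PAPILLAE = 59.7, 18.2, 100
PAPILLA_RADIUS_MEAN, PAPILLA_RADIUS_SD = 28.0, 10.1
CONFOCAL_DENSITY_MEAN, CONFOCAL_DENSITY_SD, N_CONFOCAL = 48.8, 5.29, 40
MELANOCYTE_DIAMETER_MEAN, MELANOCYTE_DIAMETER_SD, N_MELANOCYTES = 10.0, 1.8, 50

RETICULAR_SLOPE_MEAN, RETICULAR_SLOPE_SD, N_RETICULAR = 1.928e-3, 1.889e-3, 13
GLOBULAR_SLOPE_MEAN, GLOBULAR_SLOPE_SD, N_GLOBULAR = 6.005e-3, 6.099e-3, 25


def _standardized(rng, n, mean, sd, clip=2.2):
    """Normal draws rescaled to the exact sample mean and SD (ddof=1)."""
    z = np.clip(rng.standard_normal(n), -clip, clip)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


def synth_microanatomy_table(seed: int = 0) -> pd.DataFrame:
    """Emulated microanatomy table with exact published sample statistics."""
    rng = np.random.default_rng(seed)
    height = _standardized(rng, N_PAPILLAE, PAPILLA_HEIGHT_MEAN, PAPILLA_HEIGHT_SD)
    base_r = _standardized(rng, N_PAPILLAE, PAPILLA_RADIUS_MEAN, PAPILLA_RADIUS_SD)
    assert height.min() > 0 and base_r.min() > 0

    # mid/tip radii follow the shape model with a random shape parameter
    # plus mild measurement noise (these columns carry no published stats)
    p = stats.beta(2.0, 2.0).rvs(size=N_PAPILLAE, random_state=rng)
    mid = np.empty(N_PAPILLAE)
    tip = np.empty(N_PAPILLAE)
    for i in range(N_PAPILLAE):
        _, m, t = _model_radii(base_r[i], height[i], p[i])
        mid[i] = m * rng.uniform(0.97, 1.03)
        tip[i] = max(t * rng.uniform(0.94, 1.06), 0.5)

    confocal = _standardized(rng, N_CONFOCAL, CONFOCAL_DENSITY_MEAN,
                             CONFOCAL_DENSITY_SD)
    melano = _standardized(rng, N_MELANOCYTES, MELANOCYTE_DIAMETER_MEAN,
                           MELANOCYTE_DIAMETER_SD)

    n = N_PAPILLAE

    def pad(col):
        out = np.full(n, np.nan)
        out[: len(col)] = col
        return out

    return pd.DataFrame(
        {
            "melanocyte_diameter_um": pad(melano),
            "papilla_height_um": height,
            "papilla_base_radius_um": base_r,
            "papilla_mid_radius_um": mid,
            "papilla_tip_radius_um": tip,
            "confocal_papillae_per_mm2": pad(confocal),
        },
        columns=MICROANATOMY_COLUMNS,
    )


def synth_growth_table(seed: int = 0, n_obs: int = 14,
                       horizon_d: float = 1500.0) -> pd.DataFrame:
    """Emulated lesion growth table (long format).

    13 reticular and 25 globular lesions; each series is linear growth plus
    observation noise, post-adjusted so the per-lesion least-squares slope
    is exact and the group slope means reproduce the published values.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for pattern, n_lesions, mean, sd in [
        ("reticular", N_RETICULAR, RETICULAR_SLOPE_MEAN, RETICULAR_SLOPE_SD),
        ("globular", N_GLOBULAR, GLOBULAR_SLOPE_MEAN, GLOBULAR_SLOPE_SD),
    ]:
        slopes = _standardized(rng, n_lesions, mean, sd, clip=1.8)
        for k, slope in enumerate(slopes):
            t = np.sort(rng.uniform(0.0, horizon_d, n_obs))
            a0 = rng.uniform(1.0, 8.0)
            area = a0 + slope * t + rng.normal(0.0, 0.4, n_obs)
            # pin the OLS slope to the designed value, keep the noise
            tc = t - t.mean()
            realized = (tc @ (area - area.mean())) / (tc @ tc)
            area = area + (slope - realized) * tc
            area = np.maximum(area, 0.05)
            tc = t - t.mean()
            realized = (tc @ (area - area.mean())) / (tc @ tc)
            area = area + (slope - realized) * tc
            for ti, ai in zip(t, area):
                rows.append((f"{pattern[0]}{k:02d}", pattern, ti, ai))
    return pd.DataFrame(rows, columns=["lesion_id", "pattern", "time_d", "area_mm2"])
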