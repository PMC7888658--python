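"""Dermatoscopy-style, histology-style and diagnostic overhead rendering.

Dermatoscopic images are Gaussian-blurred 2D position histograms mapped
through a brown-on-skin ramp; histologic images are vertical sections with
the membrane profile and sliced cells as disks; overhead plots color-code
generation (fixed 0-60 scale), altitude (0-200 um) or strain identity.
Rendering is a pure function of (snapshot, membrane, spec).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ParameterDomainError

__all__ = [
    "RenderSpec",
    "render_dermatoscopic",
    "render_histologic",
    "render_overhead",
    "save_png",
]

GENERATION_SCALE = (0.0, 60.0)
ALTITUDE_SCALE = (0.0, 200.0)

_SKIN = np.array([0.94, 0.80, 0.70])
_PIGMENT = np.array([0.35, 0.19, 0.09])


@dataclass
class RenderSpec:
    extent: tuple = (5000.0, 5000.0)   # um
    pixel_pitch: float = 10.0          # um/px (histogram bin)
    blur_sigma: float = 20.0           # um
    mode: str = "dermatoscopic"        # or generation | altitude | strain
    normalization_quantile: float = 0.995
    # histologic slab: section along x at fixed y, +- half thickness
    slab_axis: str = "y"
    slab_position: float = 2500.0      # um
    slab_thickness: float = 40.0       # um
    slab_width: float = 1200.0         # um
    slab_height: float = 250.0         # um

    def __post_init__(self):
        if self.pixel_pitch <= 0:
            raise ParameterDomainError("pixel pitch must be positive")
        if self.blur_sigma < 0:
            raise ParameterDomainError("blur sigma must be non-negative")
        if self.slab_thickness <= 0:
            raise ParameterDomainError("slab thickness must be positive")


def position_histogram(snapshot, spec: RenderSpec) -> np.ndarray:
    """Raw 2D histogram of horizontal cell positions (mass = cell count)."""
    nx = int(np.ceil(spec.extent[0] / spec.pixel_pitch))
    ny = int(np.ceil(spec.extent[1] / spec.pixel_pitch))
    pts = snapshot.table[["x", "y"]].to_numpy()
    hist, _, _ = np.histogram2d(
        pts[:, 0], pts[:, 1],
        bins=(nx, ny), range=((0, spec.extent[0]), (0, spec.extent[1])),
    )
    return hist


def render_dermatoscopic(snapshot, spec: RenderSpec | None = None) -> np.ndarray:
    """Blurred, normalized pigmentation image, brown on skin tone (RGB)."""
    spec = spec or RenderSpec()
    hist = position_histogram(snapshot, spec)
    blurred = gaussian_filter(hist, sigma=spec.blur_sigma / spec.pixel_pitch)
    top = np.quantile(blurred, spec.normalization_quantile)
    if top <= 0:
        top = blurred.max()  # sparse image: quantile collapses to zero
    if top <= 0:
        intensity = np.zeros_like(blurred)
    else:
        intensity = np.clip(blurred / top, 0.0, 1.0)
    img = _SKIN[None, None, :] + intensity[..., None] * (_PIGMENT - _SKIN)[None, None, :]
    return np.clip(img, 0.0, 1.0)


def render_histologic(snapshot, membrane, spec: RenderSpec | None = None) -> np.ndarray:
    """Vertical section: membrane profile plus sliced cells as brown disks."""
    spec = spec or RenderSpec()
    pitch = spec.pixel_pitch / 5.0  # finer raster for the small vertical canvas
    nw = int(np.ceil(spec.slab_width / pitch))
    nh = int(np.ceil(spec.slab_height / pitch))
    img = np.ones((nh, nw, 3))
    img[...] = np.array([0.97, 0.92, 0.95])  # pale eosin background

    along = np.linspace(0.0, spec.slab_width, nw)
    if spec.slab_axis == "y":
        sect = np.column_stack([along, np.full(nw, spec.slab_position)])
    else:
        sect = np.column_stack([np.full(nw, spec.slab_position), along])
    profile = membrane.altitude(sect)
    rows = np.clip((profile / pitch).astype(int), 0, nh - 1)
    for col, row in enumerate(rows):
        img[: row + 1, col, :] = np.array([0.88, 0.70, 0.75])  # dermis below

    tab = snapshot.table
    if spec.slab_axis == "y":
        dist = np.abs(tab["y"].to_numpy() - spec.slab_position)
        a_coord = tab["x"].to_numpy()
    else:
        dist = np.abs(tab["x"].to_numpy() - spec.slab_position)
        a_coord = tab["y"].to_numpy()
    in_slab = (dist <= spec.slab_thickness / 2.0) & (a_coord >= 0) \
        & (a_coord <= spec.slab_width)
    yy, xx = np.mgrid[0:nh, 0:nw]
    for a, z, r in zip(a_coord[in_slab], tab["z"].to_numpy()[in_slab],
                       tab["radius"].to_numpy()[in_slab]):
        ca, cz = a / pitch, z / pitch
        rr = max(r / pitch, 1.0)
        mask = (xx - ca) ** 2 + (yy - cz) ** 2 <= rr**2
        img[mask] = _PIGMENT
    return np.clip(img[::-1], 0.0, 1.0)  # z up


def cells_in_slab(snapshot, spec: RenderSpec) -> int:
    """Number of cells whose centre lies inside the histologic slab."""
    tab = snapshot.table
    if spec.slab_axis == "y":
        dist = np.abs(tab["y"].to_numpy() - spec.slab_position)
        a_coord = tab["x"].to_numpy()
    else:
        dist = np.abs(tab["x"].to_numpy() - spec.slab_position)
        a_coord = tab["y"].to_numpy()
    return int(np.sum((dist <= spec.slab_thickness / 2.0)
                      & (a_coord >= 0) & (a_coord <= spec.slab_width)))


def render_overhead(snapshot, spec: RenderSpec | None = None) -> np.ndarray:
    """Scatter-style color-coded overhead image (generation/altitude/strain)."""
    spec = spec or RenderSpec(mode="generation")
    if spec.mode not in ("generation", "altitude", "strain"):
        raise ParameterDomainError(f"unknown overhead mode {spec.mode!r}")
    from matplotlib import colormaps

    nx = int(np.ceil(spec.extent[0] / spec.pixel_pitch))
    ny = int(np.ceil(spec.extent[1] / spec.pixel_pitch))
    img = np.ones((ny, nx, 3))
    tab = snapshot.table
    if len(tab) == 0:
        return img
    cols = np.clip((tab["x"].to_numpy() / spec.pixel_pitch).astype(int), 0, nx - 1)
    rows = np.clip((tab["y"].to_numpy() / spec.pixel_pitch).astype(int), 0, ny - 1)
    if spec.mode == "generation":
        lo, hi = GENERATION_SCALE
        vals = np.clip((tab["generation"].to_numpy() - lo) / (hi - lo), 0, 1)
        colors = colormaps["viridis"](vals)[:, :3]
    elif spec.mode == "altitude":
        lo, hi = ALTITUDE_SCALE
        vals = np.clip((tab["z"].to_numpy() - lo) / (hi - lo), 0, 1)
        colors = colormaps["coolwarm"](vals)[:, :3]
    else:
        strains = tab["strain"].to_numpy()
        palette = colormaps["tab20"](np.linspace(0, 1, 20))[:, :3]
        colors = np.full((len(tab), 3), 0.6)
        nested = strains >= 0
        colors[nested] = palette[strains[nested] % 20]
    img[rows, cols] = colors
    return img


def save_png(image: np.ndarray, path) -> None:
    from PIL import Image

    arr = (np.clip(image, 0.0, 1.0) * 255).astype(np.uint8)
    Image.fromarray(arr).save(path)
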