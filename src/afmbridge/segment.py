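"""Height-threshold segmentation of flattened AFM maps.

Molecules are identified as 8-connected components of pixels whose
flattened height exceeds a cutoff. The cutoff is placed a fixed number of
robust standard deviations above the background median — a reproducible
surrogate for the by-eye cutoff choice of instrument software — and is
verified on synthetic ground truth to capture ≥ 90 % of molecules under
default imaging conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .flatten import MAD_TO_SIGMA
from .heightmap import HeightMap

__all__ = [
    "Component",
    "ComponentSet",
    "estimate_background_stats",
    "choose_threshold",
    "label_components",
    "molecule_density",
    "capture_mask",
    "capture_fraction",
    "DENSITY_CLASSES",
]

#: Closed density ranges (molecules/μm²) defining the experimental classes.
DENSITY_CLASSES = {"low": (4.0, 7.0), "high": (8.0, 15.0)}


@dataclass(frozen=True)
class Component:
    id: int
    area_px: int
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    touches_border: bool


@dataclass
class ComponentSet:
    """Labelled supra-threshold components of one map.

    ``label_grid`` holds a component id per pixel (0 = background); ids are
    contiguous from 1 in raster order of first appearance.
    """

    label_grid: np.ndarray
    components: list[Component]
    threshold_nm: float

    @property
    def n_components(self) -> int:
        return len(self.components)

    def mask_of(self, component_id: int) -> np.ndarray:
        return self.label_grid == component_id


def estimate_background_stats(hmap: HeightMap) -> tuple[float, float]:
    """Median and robust σ (1.4826 × MAD) of all pixel heights.

    The substrate dominates the image by area, so whole-image robust
    statistics estimate the background level and noise even with molecules
    present. A degenerate all-equal map yields robust σ = 0.
    """
    h = hmap.heights
    med = float(np.median(h))
    sigma = float(MAD_TO_SIGMA * np.median(np.abs(h - med)))
    return med, sigma


def choose_threshold(hmap: HeightMap, k: float = 3.0) -> float:
    """Height cutoff = background median + ``k`` × robust σ.

    The default k=3 is calibrated so that on flattened default synthetic
    scenes the cutoff captures ≥ 90 % of ground-truth molecules.
    """
    if not (k > 0):
        raise ValueError(f"k must be > 0, got {k}")
    med, sigma = estimate_background_stats(hmap)
    return med + k * sigma


def label_components(
    hmap: HeightMap, threshold: float, min_area_px: int = 30
) -> ComponentSet:
    """8-connected components of ``heights >= threshold``.

    Components smaller than ``min_area_px`` pixels are discarded as noise
    specks (~a 12 nm × 20 nm blob at the default ~2 nm pixel).
    """
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    if min_area_px < 1:
        raise ValueError(f"min_area_px must be >= 1, got {min_area_px}")
    mask = hmap.heights >= threshold
    raw = sk_label(mask, connectivity=2)
    out = np.zeros_like(raw)
    comps: list[Component] = []
    rows, cols = raw.shape
    next_id = 1
    for prop in regionprops(raw):
        if prop.area < min_area_px:
            continue
        r0, c0, r1, c1 = prop.bbox
        out[raw == prop.label] = next_id
        comps.append(
            Component(
                id=next_id,
                area_px=int(prop.area),
                bbox=(r0, c0, r1, c1),
                touches_border=(r0 == 0 or c0 == 0 or r1 == rows or c1 == cols),
            )
        )
        next_id += 1
    return ComponentSet(label_grid=out, components=comps, threshold_nm=float(threshold))


def molecule_density(n_molecules: int, field_area_um2: float) -> tuple[float, str]:
    """Molecules per μm² and the experimental density class.

    Classes: [4, 7] → "low", [8, 15] → "high", anything else →
    "out_of_range".
    """
    if not (field_area_um2 > 0):
        raise ValueError(f"field_area_um2 must be > 0, got {field_area_um2}")
    density = n_molecules / field_area_um2
    for name, (lo, hi) in DENSITY_CLASSES.items():
        if lo <= density <= hi:
            return density, name
    return density, "out_of_range"


def _centerline_pixels(
    vertices_nm: np.ndarray, pixel_size: float, shape: tuple[int, int]
) -> np.ndarray:
    """Rasterize a polyline (nm, (x, y)) to the set of pixels it visits.

    Dense resampling at half-pixel spacing; returns unique (row, col) pairs
    clipped to the grid. Convention: x → col, y → row, pixel centers at
    (i + 0.5) × pixel_size.
    """
    v = np.asarray(vertices_nm, dtype=float)
    if len(v) == 0:
        return np.empty((0, 2), dtype=int)
    seg = np.diff(v, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    pts = [v[:1]]
    step = pixel_size / 2.0
    for i, L in enumerate(seglen):
        n = max(1, int(np.ceil(L / step)))
        t = np.linspace(0, 1, n + 1)[1:, None]
        pts.append(v[i] + t * seg[i])
    dense = np.vstack(pts)
    cols = np.floor(dense[:, 0] / pixel_size).astype(int)
    rows_ = np.floor(dense[:, 1] / pixel_size).astype(int)
    keep = (rows_ >= 0) & (rows_ < shape[0]) & (cols >= 0) & (cols < shape[1])
    px = np.unique(np.stack([rows_[keep], cols[keep]], axis=1), axis=0)
    return px


def capture_mask(
    components: ComponentSet, scene, pixel_size: float, min_overlap: float = 0.5
) -> np.ndarray:
    """Per-molecule capture flags against ground truth.

    A ground-truth molecule counts as captured iff at least ``min_overlap``
    of its rasterized centerline pixels fall inside some labelled
    component. This capture definition is fixed; it is the quantity the
    ≥ 90 % segmentation criterion is stated on.
    """
    labels = components.label_grid
    flags = np.zeros(len(scene.chains), dtype=bool)
    for i, chain in enumerate(scene.chains):
        px = _centerline_pixels(chain.vertices, pixel_size, labels.shape)
        if len(px) == 0:
            continue
        inside = labels[px[:, 0], px[:, 1]] > 0
        flags[i] = inside.mean() >= min_overlap
    return flags


def capture_fraction(
    components: ComponentSet, scene, pixel_size: float, min_overlap: float = 0.5
) -> float:
    """Fraction of ground-truth molecules captured (see :func:`capture_mask`)."""
    flags = capture_mask(components, scene, pixel_size, min_overlap)
    return float(flags.mean()) if len(flags) else float("nan")
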