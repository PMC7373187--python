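"""Height-map container and file formats.

A fluid-AFM scan is a rectangular grid of surface heights in nanometres,
acquired one scanline (row) at a time.  :class:`HeightMap` is the central
raster object of the pipeline; every stage consumes and produces it.

Maps are stored on disk as single-channel 32-bit float TIFF with the pixel
size embedded in the image description (JSON), or as a plain ASCII matrix
with a JSON sidecar carrying the metadata.  The pixel size is mandatory on
read: every downstream quantity (contour lengths, densities, thresholds) is
in nanometres, and a silently assumed pixel size would corrupt all of them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["HeightMap", "read_height_map", "write_height_map"]

_DESCRIPTION_KEY = "afmbridge"


@dataclass
class HeightMap:
    """A 2-D grid of heights in nm with square pixels.

    Parameters
    ----------
    heights:
        2-D float array, row index = scanline (slow axis), col index = fast
        axis. Values in nm.
    pixel_size:
        Edge length of one pixel in nm.
    metadata:
        Free-form provenance (seeds, render parameters, injected
        backgrounds, ...). Must be JSON-serializable to survive a round trip.
    """

    heights: np.ndarray
    pixel_size: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError(f"heights must be 2-D, got shape {self.heights.shape}")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights contain non-finite values")
        if not (self.pixel_size > 0):
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def field_size_nm(self) -> tuple[float, float]:
        """Physical extent (rows, cols) in nm."""
        return (self.shape[0] * self.pixel_size, self.shape[1] * self.pixel_size)

    def copy(self, heights: np.ndarray | None = None) -> "HeightMap":
        h = self.heights.copy() if heights is None else np.asarray(heights, dtype=float)
        return HeightMap(h, self.pixel_size, dict(self.metadata))


def write_height_map(hmap: HeightMap, path: str | Path) -> None:
    """Write a height map to ``path``.

    ``.tif``/``.tiff`` → 32-bit float TIFF, pixel size + metadata in the
    ImageDescription tag. Any other suffix → ASCII matrix (full float
    precision) with a ``<path>.json`` sidecar.
    """
    path = Path(path)
    meta = {"pixel_size_nm": float(hmap.pixel_size), "metadata": _jsonable(hmap.metadata)}
    if path.suffix.lower() in {".tif", ".tiff"}:
        desc = json.dumps({_DESCRIPTION_KEY: meta})
        tifffile.imwrite(path, hmap.heights.astype(np.float32), description=desc)
    else:
        np.savetxt(path, hmap.heights, fmt="%.9e")
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_height_map(path: str | Path) -> HeightMap:
    """Read a height map written by :func:`write_height_map`.

    Raises
    ------
    ValueError
        If the file carries no pixel-size metadata (a guessed pixel size
        would silently corrupt every nm-valued quantity downstream).
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            heights = page.asarray().astype(float)
            desc = page.description or ""
        meta = _parse_description(desc, path)
    else:
        heights = np.loadtxt(path, ndmin=2)
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValueError(
                f"{path}: no pixel-size sidecar ({sidecar.name}); refusing to guess a pixel size"
            )
        meta = json.loads(sidecar.read_text())
    if "pixel_size_nm" not in meta:
        raise ValueError(f"{path}: metadata lacks pixel_size_nm")
    return HeightMap(heights, float(meta["pixel_size_nm"]), dict(meta.get("metadata", {})))


def _parse_description(desc: str, path: Path) -> dict:
    try:
        blob = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        raise ValueError(f"{path}: TIFF has no parseable pixel-size metadata") from None
    if _DESCRIPTION_KEY not in blob:
        raise ValueError(f"{path}: TIFF description lacks the '{_DESCRIPTION_KEY}' metadata block")
    return blob[_DESCRIPTION_KEY]


def _jsonable(obj):
    """Best-effort conversion of metadata to JSON-serializable types."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
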