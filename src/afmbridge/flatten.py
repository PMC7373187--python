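"""Per-scanline polynomial background removal.

AFM rasters carry a slowly varying instrument background that differs from
scanline to scanline (piezo bow, thermal drift, line-to-line offsets). The
standard correction fits a low-order polynomial to each scanline
independently and subtracts it. A naive least-squares fit is biased upward
wherever molecules sit on the line, so the fit here is iterated with a
robust foreground mask: after each fit, pixels whose residual exceeds
``mask_k`` × (1.4826 × MAD) of the current background residuals are
excluded and the line is refit.

Polynomials are expressed in the power basis on the normalized coordinate
x ∈ [-1, 1] across the scanline; the synthetic generator injects its
backgrounds in the same basis, so fitted and injected coefficients are
directly comparable.
"""

from __future__ import annotations

import logging

import numpy as np

from .heightmap import HeightMap

__all__ = ["scanline_background", "flatten_scanlines", "flatten_image"]

logger = logging.getLogger(__name__)

#: Consistency factor turning the median absolute deviation into a normal-σ.
MAD_TO_SIGMA = 1.4826


def _norm_x(n: int) -> np.ndarray:
    """Normalized fast-axis coordinate in [-1, 1] for an n-pixel scanline."""
    if n == 1:
        return np.zeros(1)
    return np.linspace(-1.0, 1.0, n)


def scanline_background(
    hmap: HeightMap, order: int, n_iter: int = 3, mask_k: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the per-scanline polynomial background of ``hmap``.

    Parameters
    ----------
    order:
        Polynomial order, one of {0, 1, 2}.
    n_iter:
        Number of fit / re-mask rounds per scanline (≥ 1).
    mask_k:
        Foreground cut in robust σ units: pixels with residual
        > mask_k × 1.4826 × MAD are masked out of the next fit.

    Returns
    -------
    background : (rows, cols) array of the fitted background, nm.
    coeffs : (rows, order + 1) array of polynomial coefficients in the
        power basis on x ∈ [-1, 1], ascending order.
    """
    if order not in (0, 1, 2):
        raise ValueError(f"order must be one of 0, 1, 2; got {order}")
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    if not (mask_k > 0):
        raise ValueError(f"mask_k must be > 0, got {mask_k}")

    rows, cols = hmap.shape
    x = _norm_x(cols)
    vander = np.vander(x, order + 1, increasing=True)  # (cols, order+1)
    background = np.empty((rows, cols))
    coeffs = np.empty((rows, order + 1))

    for r in range(rows):
        y = hmap.heights[r]
        keep = np.ones(cols, dtype=bool)
        c = np.zeros(order + 1)
        for _ in range(n_iter):
            if keep.sum() < order + 1:
                logger.warning(
                    "scanline %d: only %d unmasked pixels for order-%d fit; "
                    "falling back to order 0",
                    r, int(keep.sum()), order,
                )
                c = np.zeros(order + 1)
                c[0] = float(np.median(y))
                break
            c, *_ = np.linalg.lstsq(vander[keep], y[keep], rcond=None)
            resid = y - vander @ c
            mad = np.median(np.abs(resid[keep] - np.median(resid[keep])))
            scale = MAD_TO_SIGMA * mad
            if scale == 0:
                break
            # one-sided: molecules protrude upward from the substrate
            keep = resid <= mask_k * scale
        background[r] = vander @ c
        coeffs[r] = c
    return background, coeffs


def flatten_scanlines(
    hmap: HeightMap, order: int, n_iter: int = 3, mask_k: float = 3.0
) -> HeightMap:
    """Subtract the robust per-scanline polynomial background of one order."""
    background, _ = scanline_background(hmap, order, n_iter=n_iter, mask_k=mask_k)
    out = hmap.copy(hmap.heights - background)
    orders = list(out.metadata.get("flatten_orders_applied", []))
    out.metadata["flatten_orders_applied"] = orders + [order]
    return out


def flatten_image(
    hmap: HeightMap,
    orders: tuple[int, ...] = (0, 1, 2),
    n_iter: int = 3,
    mask_k: float = 3.0,
) -> HeightMap:
    """Sequentially apply scanline flattening of each order in ``orders``.

    The default 0 → 1 → 2 sequence removes per-row offsets, tilts and bows,
    matching the usual instrument-software workflow.
    """
    out = hmap
    for order in orders:
        out = flatten_scanlines(out, order, n_iter=n_iter, mask_k=mask_k)
    return out
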