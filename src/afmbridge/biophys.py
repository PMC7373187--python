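"""Closed-form biophysical calculators.

Back-of-envelope quantities used when interpreting single-molecule DNA/NAP
experiments: B-form contour length, cell volume under a rectangular-box
approximation, and copy-number → molar concentration conversion.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.constants import Avogadro

__all__ = [
    "RISE_PER_BP_NM",
    "CellGeometry",
    "bp_to_contour_length",
    "box_volume_liters",
    "copies_to_concentration",
]

#: Axial rise of B-form duplex DNA, nm per base pair.
RISE_PER_BP_NM = 0.34

#: Litres per cubic micrometre.
_L_PER_UM3 = 1e-15


@dataclass(frozen=True)
class CellGeometry:
    """Rectangular-box approximation of a bacterial cell, dimensions in μm."""

    x_um: float
    y_um: float
    z_um: float

    def __post_init__(self) -> None:
        if not (self.x_um > 0 and self.y_um > 0 and self.z_um > 0):
            raise ValueError(f"all cell dimensions must be > 0, got {self}")


def bp_to_contour_length(n_bp: float) -> float:
    """Contour length in nm of ``n_bp`` base pairs of B-form DNA.

    A 1-kbp fragment is 340 nm; a 12-mer oligo is 4.08 nm.
    """
    if n_bp < 0:
        raise ValueError(f"n_bp must be >= 0, got {n_bp}")
    return n_bp * RISE_PER_BP_NM


def box_volume_liters(geometry: CellGeometry) -> float:
    """Volume of the box in litres (1 μm³ = 1e-15 L)."""
    return geometry.x_um * geometry.y_um * geometry.z_um * _L_PER_UM3


def copies_to_concentration(copies: float, volume_liters: float) -> float:
    """Molar concentration of ``copies`` molecules in ``volume_liters``.

    3,000 copies in a ~1e-15 L cell come out near 5 μM. No rounding is
    applied here; round only when reporting.
    """
    if copies < 0:
        raise ValueError(f"copies must be >= 0, got {copies}")
    if volume_liters <= 0:
        raise ValueError(f"volume must be > 0, got {volume_liters}")
    return copies / (Avogadro * volume_liters)
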