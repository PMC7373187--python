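"""Back-of-envelope biophysics: contour lengths and cellular concentration.

The calculators behind the interpretation numbers: the expected imaged
length of the 1-kbp substrate, and what ~3,000 copies of a protein per
bacterial cell mean in concentration terms.
"""

from afmbridge.biophys import (
    CellGeometry,
    bp_to_contour_length,
    box_volume_liters,
    copies_to_concentration,
)

L = bp_to_contour_length(1000)
print(f"1-kbp B-DNA contour length : {L:.0f} nm  (0.34 nm/bp axial rise)")

cell = CellGeometry(0.7, 0.7, 2.0)
V = box_volume_liters(cell)
print(f"cell box 0.7 x 0.7 x 2.0 um: {V:.2e} L (~1 fL)")

c = copies_to_concentration(3000, V)
print(f"3,000 copies in that volume: {c * 1e6:.1f} uM (~5 uM)")
# At micromolar total concentration, even a small dissociated fraction of
# a nucleoid-associated protein leaves a substantial DNA-free pool.
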