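"""Scanline flattening and height-cutoff segmentation, scored on truth.

Renders a field with a strong per-scanline polynomial background, removes
it with the robust sequential order-0/1/2 scanline fit, places the cutoff
at background median + 3 robust sigma, and reports what fraction of the
ground-truth molecules the resulting components capture (the pipeline's
target is >= 90%).
"""

import numpy as np

import afmbridge as ab
from afmbridge.segment import capture_fraction

scene = ab.default_scene(seed=11, density_class="high")
params = ab.RenderParams(rng_seed=11, background_coeff_scale=0.5)  # heavy drift
hmap = ab.render_height_map(scene, params)

flat = ab.flatten_image(hmap)  # sequential order 0 -> 1 -> 2 per scanline
med, sigma = ab.estimate_background_stats(flat)
thr = ab.choose_threshold(flat, k=3.0)
comps = ab.label_components(flat, thr, min_area_px=30)
captured = capture_fraction(comps, scene, flat.pixel_size)

print(f"raw height spread   : {hmap.heights.std():.3f} nm (background-dominated)")
print(f"flattened background: median {med:+.4f} nm, robust sigma {sigma:.4f} nm")
print(f"cutoff              : {thr:.3f} nm above substrate")
print(f"components          : {comps.n_components}")
print(f"molecules captured  : {100 * captured:.1f}% of {len(scene.chains)} ground truth")
# The robust sigma approximates the injected pixel noise (0.08 nm); the
# cutoff sits ~3 sigma above the substrate, far below the ~1 nm DNA ridge.
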