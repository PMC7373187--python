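"""Trace a controlled DNA crossing and measure its junction height.

Builds the minimal scene — two straight duplexes crossing once — renders
it with and without a bound bridging protein, skeletonizes the merged
component, detects the crossing as a branch node of the skeleton graph
and measures the junction height difference against the molecule's own
free-DNA level.
"""

import numpy as np

import afmbridge as ab
from afmbridge.synthetic import ChainTrace, SceneTruth, TruthJunction


def straight_chain(center, angle, length, n_seg, molecule_id):
    d = np.array([np.cos(angle), np.sin(angle)])
    p0 = np.asarray(center, float) - 0.5 * length * d
    t = np.linspace(0, 1, n_seg + 1)[:, None]
    return ChainTrace(p0 + t * length * d, length / n_seg, 500, molecule_id)


for protein in (False, True):
    center = (125.0, 125.0)
    a = straight_chain(center, 0.7, 180, 90, 0)
    b = straight_chain(center, 1.9, 180, 90, 1)
    junction = TruthJunction(np.array(center), "inter", protein, (0, 1))
    scene = SceneTruth([a, b], [junction], field_size=250.0, density=32.0)
    hmap = ab.render_height_map(
        scene, ab.RenderParams(pixel_size=250 / 128, rng_seed=3,
                               background_coeff_scale=0.0)
    )
    comps = ab.label_components(hmap, ab.choose_threshold(hmap))
    graph = ab.skeletonize_component(comps.mask_of(1))
    (detected,) = ab.detect_junctions(graph)
    dh = ab.junction_height_difference(hmap, detected, graph)
    label = "protein-occupied" if protein else "bare crossing   "
    print(f"{label}: junction height difference = {dh:.2f} nm")

print()
print("Expected: ~0.86 nm for a bare DNA-DNA overlap (two stacked duplexes)")
print("and ~1.36 nm when a bridging protein sits on the junction -- the")
print("height contrast that identifies protein-mediated bridging.")
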