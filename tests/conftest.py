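"""Shared fixtures: small deterministic scenes and the default-scene batch.

The heavy fixture (20 default synthetic images pushed through the full
flatten → segment → trace pipeline) is session-scoped; the segmentation
capture and junction-recovery checks both read from it.
"""

from __future__ import annotations

import numpy as np
import pytest

import afmbridge as ab
from afmbridge.segment import capture_mask
from afmbridge.synthetic import ChainTrace, RenderParams, SceneTruth, TruthJunction


def straight_chain(center, angle, length, n_seg, molecule_id=0, n_bp=500) -> ChainTrace:
    """A perfectly straight chain through ``center`` at ``angle`` (rad)."""
    d = np.array([np.cos(angle), np.sin(angle)])
    p0 = np.asarray(center, float) - 0.5 * length * d
    t = np.linspace(0.0, 1.0, n_seg + 1)[:, None]
    return ChainTrace(p0 + t * length * d, length / n_seg, n_bp, molecule_id)


def crossing_scene(
    angle_a=0.7,
    angle_b=1.9,
    protein_bound=False,
    field=250.0,
    arm_length=180.0,
    center=None,
) -> SceneTruth:
    """Two straight chains crossing at the field center — the minimal
    controlled junction. Arm angles are kept away from the scan (x) axis:
    scan-parallel features are degenerate for scanline flattening."""
    c = (field / 2.0, field / 2.0) if center is None else center
    a = straight_chain(c, angle_a, arm_length, 90, molecule_id=0)
    b = straight_chain(c, angle_b, arm_length, 90, molecule_id=1)
    j = TruthJunction(np.array(c), "inter", protein_bound, (0, 1))
    area = (field / 1000.0) ** 2
    return SceneTruth([a, b], [j], field, 2 / area)


def render_crossing(scene: SceneTruth, rng_seed=0, noise_sigma=0.08, n_px=128):
    params = RenderParams(
        pixel_size=scene.field_size / n_px,
        rng_seed=rng_seed,
        noise_sigma=noise_sigma,
        background_coeff_scale=0.0,
    )
    return ab.render_height_map(scene, params)


@pytest.fixture(scope="session")
def default_scene_batch():
    """20 default synthetic high-density images run through the standard
    pipeline (sequential 0/1/2 flattening, automatic threshold, labeling,
    tracing), with ground truth and capture flags retained."""
    results = []
    for seed in range(1, 21):
        scene = ab.default_scene(seed, "high")
        hmap = ab.render_height_map(scene, RenderParams(rng_seed=seed))
        flat = ab.flatten_image(hmap)
        thr = ab.choose_threshold(flat)
        comps = ab.label_components(flat, thr)
        captured = capture_mask(comps, scene, flat.pixel_size)
        molecules, junctions = ab.analyze_image(flat, comps)
        results.append(
            {
                "seed": seed,
                "scene": scene,
                "flat": flat,
                "comps": comps,
                "captured": captured,
                "molecules": molecules,
                "junctions": junctions,
            }
        )
    return results
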