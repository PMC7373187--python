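"""Skeleton graphs, junction detection/classification, height profiling."""

import math

import numpy as np
import pytest

import afmbridge as ab
from afmbridge.heightmap import HeightMap
from afmbridge.synthetic import RenderParams, SceneTruth
from afmbridge.trace import (
    InsufficientFreeDNA,
    SkelEdge,
    SkelNode,
    SkeletonGraph,
    classify_component,
    contour_length_nm,
    detect_junctions,
    measure_junction_heights,
    skeletonize_component,
)

from conftest import crossing_scene, render_crossing, straight_chain


def _bar_mask(shape, p0, p1, half_width=1):
    """Thick line mask from p0 to p1 (row, col)."""
    grid = np.zeros(shape, dtype=bool)
    n = int(4 * max(abs(p1[0] - p0[0]), abs(p1[1] - p0[1])) + 1)
    rr = np.linspace(p0[0], p1[0], n)
    cc = np.linspace(p0[1], p1[1], n)
    for r, c in zip(rr, cc):
        r0, c0 = int(round(r)), int(round(c))
        grid[max(0, r0 - half_width):r0 + half_width + 1,
             max(0, c0 - half_width):c0 + half_width + 1] = True
    return grid


# ---------------------------------------------------------------------------
# Skeleton topology


def test_straight_bar_two_endpoints_one_edge():
    mask = _bar_mask((20, 120), (10, 10), (10, 109))
    g = skeletonize_component(mask)
    assert len(g.endpoint_nodes) == 2
    assert len(g.branch_nodes) == 0
    assert len(g.edges) == 1


def test_x_shape_single_merged_degree4_node():
    mask = _bar_mask((101, 101), (10, 10), (90, 90)) | _bar_mask(
        (101, 101), (90, 10), (10, 90)
    )
    g = skeletonize_component(mask)
    assert len(g.endpoint_nodes) == 4
    assert len(g.branch_nodes) == 1
    assert g.degree(g.branch_nodes[0].id) == 4


def test_t_shape_single_degree3_node():
    mask = _bar_mask((80, 120), (40, 10), (40, 109)) | _bar_mask(
        (80, 120), (40, 60), (75, 60)
    )
    g = skeletonize_component(mask)
    assert len(g.endpoint_nodes) == 3
    assert len(g.branch_nodes) == 1
    assert g.degree(g.branch_nodes[0].id) == 3


def test_ring_is_flagged_closed_loop():
    yy, xx = np.mgrid[0:80, 0:80]
    r = np.hypot(yy - 40, xx - 40)
    mask = (r > 22) & (r < 28)
    g = skeletonize_component(mask)
    assert g.closed_loop
    assert len(g.branch_nodes) == 0
    # circumference of a radius-25 ring, loosely
    assert contour_length_nm(g, 1.0) == pytest.approx(2 * math.pi * 25, rel=0.15)


# ---------------------------------------------------------------------------
# Contour length step counting


def test_contour_length_axial_and_diagonal():
    axial = np.zeros((5, 104), dtype=bool)
    axial[2, 2:102] = True  # 100-pixel horizontal path
    g = skeletonize_component(axial, open_px=0, prune_px=0)
    assert contour_length_nm(g, 2.0) == pytest.approx(99 * 2.0)

    diag = np.zeros((104, 104), dtype=bool)
    idx = np.arange(2, 102)
    diag[idx, idx] = True  # 100-pixel 45° path
    g2 = skeletonize_component(diag, open_px=0, prune_px=0)
    assert contour_length_nm(g2, 2.0) == pytest.approx(99 * math.sqrt(2) * 2.0, rel=1e-9)


def test_contour_length_recovers_molecule_length():
    """Noise-free rendered 1-kbp chains trace back to ~340 nm within 15%
    (thinning erodes ends; pixelation adds staircase length)."""
    lengths = []
    for seed in range(50):
        chain = ab.sample_wlc_chain(1000, seed=seed)
        v = chain.vertices - chain.vertices.min(axis=0) + 60.0
        span = v.max() + 60.0
        n_px = int(np.ceil(span / 1.953125))
        field = n_px * 1.953125
        chain = ab.ChainTrace(v, chain.segment_length, 1000, 0)
        scene = SceneTruth([chain], [], field, 1.0)
        hmap = ab.render_height_map(
            scene, RenderParams(pixel_size=1.953125, noise_sigma=0.0,
                                background_coeff_scale=0.0)
        )
        comps = ab.label_components(hmap, 0.2)
        if comps.n_components != 1:
            continue
        g = skeletonize_component(comps.mask_of(comps.components[0].id))
        lengths.append(contour_length_nm(g, hmap.pixel_size))
    assert len(lengths) >= 40
    assert np.mean(lengths) == pytest.approx(340.0, rel=0.15)


# ---------------------------------------------------------------------------
# Junction detection


def test_straight_chain_has_no_junctions():
    chain = straight_chain((125, 125), 1.1, 180, 90)
    scene = SceneTruth([chain], [], 250.0, 16.0)
    hmap = ab.render_height_map(
        scene, RenderParams(pixel_size=250 / 128, noise_sigma=0.0,
                            background_coeff_scale=0.0)
    )
    comps = ab.label_components(hmap, 0.2)
    g = skeletonize_component(comps.mask_of(1))
    assert detect_junctions(g) == []


def test_forced_crossing_yields_one_junction():
    scene = crossing_scene()
    hmap = render_crossing(scene, noise_sigma=0.0)
    comps = ab.label_components(hmap, 0.2)
    g = skeletonize_component(comps.mask_of(1))
    assert len(detect_junctions(g)) == 1


def test_junction_count_invariant_under_rotation():
    scene = ab.default_scene(8, "high")
    hmap = ab.render_height_map(
        scene, RenderParams(rng_seed=8, noise_sigma=0.0, background_coeff_scale=0.0)
    )

    def count(heights):
        m = HeightMap(heights, hmap.pixel_size)
        comps = ab.label_components(m, 0.24)
        _, juncs = ab.analyze_image(m, comps)
        return len(juncs)

    assert count(np.rot90(hmap.heights).copy()) == count(hmap.heights)


def test_skeleton_follows_polyline():
    """Noise-free single-chain skeleton stays within 2 px Hausdorff of the
    true centerline (away from the eroded ends)."""
    chain = ab.sample_wlc_chain(1000, seed=13)
    v = chain.vertices - chain.vertices.min(axis=0) + 60.0
    span = float(v.max() + 60.0)
    ps = 1.953125
    n_px = int(np.ceil(span / ps))
    scene = SceneTruth([ab.ChainTrace(v, chain.segment_length, 1000, 0)], [],
                       n_px * ps, 1.0)
    hmap = ab.render_height_map(
        scene, RenderParams(pixel_size=ps, noise_sigma=0.0, background_coeff_scale=0.0)
    )
    comps = ab.label_components(hmap, 0.2)
    g = skeletonize_component(comps.mask_of(1))
    skel_nm = np.stack(
        [(g.pixels[:, 1] + 0.5) * ps, (g.pixels[:, 0] + 0.5) * ps], axis=1
    )
    # every skeleton pixel lies near the polyline
    from scipy.spatial import cKDTree

    dense = []
    for a, b in zip(v, v[1:]):
        t = np.linspace(0, 1, 8)[:, None]
        dense.append(a + t * (b - a))
    dense = np.vstack(dense)
    d_skel = cKDTree(dense).query(skel_nm)[0]
    assert d_skel.max() <= 2 * ps
    # and the polyline interior is near the skeleton
    interior = dense[(np.arange(len(dense)) > 40) & (np.arange(len(dense)) < len(dense) - 40)]
    d_poly = cKDTree(skel_nm).query(interior)[0]
    assert d_poly.max() <= 2 * ps


# ---------------------------------------------------------------------------
# Classification rule


def _graph_with(n_endpoints, length_px, n_branch=0):
    nodes = {}
    nid = 0
    for _ in range(n_endpoints):
        nodes[nid] = SkelNode(nid, (0.0, float(nid)), "endpoint", [(0, nid)])
        nid += 1
    for _ in range(n_branch):
        nodes[nid] = SkelNode(nid, (5.0, float(nid)), "branch", [(5, nid)])
        nid += 1
    edges = [SkelEdge(0, 1 if n_endpoints > 1 else 0, [], length_px)]
    return SkeletonGraph(nodes, edges, np.zeros((0, 2), int))


@pytest.mark.parametrize(
    "n_ep, length_factor, expected",
    [
        (2, 0.95, "intra"),
        (4, 2.05, "inter"),
        (3, 1.9, "inter"),
        (2, 3.2, "ambiguous"),
        (2, 0.5, "ambiguous"),
        (5, 2.0, "ambiguous"),
    ],
)
def test_classification_rule(n_ep, length_factor, expected):
    L0 = 340.0
    g = _graph_with(n_ep, length_px=length_factor * L0)  # pixel size 1 nm
    assert classify_component(g, L0, pixel_size=1.0, tol=0.25) == expected


def test_closed_loop_classifies_intra():
    g = SkeletonGraph({}, [SkelEdge(-1, -1, [], 300.0)], np.zeros((0, 2), int),
                      closed_loop=True)
    assert classify_component(g, 340.0, 1.0) == "intra"


# ---------------------------------------------------------------------------
# Junction heights


@pytest.mark.parametrize("protein, expected", [(False, 0.86), (True, 1.36)])
def test_noise_free_junction_height(protein, expected):
    scene = crossing_scene(protein_bound=protein)
    hmap = render_crossing(scene, noise_sigma=0.0)
    comps = ab.label_components(hmap, 0.2)
    g = skeletonize_component(comps.mask_of(1))
    (junction,) = detect_junctions(g)
    dh = ab.junction_height_difference(hmap, junction, g)
    assert dh == pytest.approx(expected, abs=0.02)


def test_noisy_ensemble_recovers_injected_height():
    """Mean measured Δh over ≥30 noisy protein-occupied crossings is within
    2 SEM of the injected 1.36 nm."""
    rng = np.random.default_rng(0)
    diffs = []
    i = 0
    while len(diffs) < 30:
        a1 = rng.uniform(np.pi / 6, np.pi / 3)
        a2 = a1 + rng.uniform(np.pi / 3, np.pi / 2)
        scene = crossing_scene(angle_a=a1, angle_b=a2, protein_bound=True)
        hmap = render_crossing(scene, rng_seed=100 + i, noise_sigma=0.08)
        i += 1
        comps = ab.label_components(hmap, ab.choose_threshold(hmap))
        for comp in comps.components:
            g = skeletonize_component(comps.mask_of(comp.id))
            js = detect_junctions(g)
            if len(js) == 1:
                measure_junction_heights(hmap, g, js)
                diffs.append(js[0].height_diff)
    diffs = np.asarray(diffs)
    sem = diffs.std(ddof=1) / math.sqrt(len(diffs))
    assert abs(diffs.mean() - 1.36) <= 2 * sem


def test_insufficient_free_dna_raises():
    scene = crossing_scene(arm_length=40.0)  # arms too short for a reference
    hmap = render_crossing(scene, noise_sigma=0.0)
    comps = ab.label_components(hmap, 0.2)
    g = skeletonize_component(comps.mask_of(1))
    js = detect_junctions(g)
    assert len(js) >= 1
    with pytest.raises(InsufficientFreeDNA):
        measure_junction_heights(hmap, g, js, excl_r=30.0)
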