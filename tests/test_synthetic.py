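"""Worm-like-chain scenes, ground truth and the forward renderer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import afmbridge as ab
from afmbridge.synthetic import (
    BridgingConfig,
    RenderParams,
    SceneTruth,
    TruthJunction,
    polyline_intersections,
)

from conftest import crossing_scene, render_crossing, straight_chain


# ---------------------------------------------------------------------------
# WLC sampler


@given(n_bp=st.integers(100, 3000), seed=st.integers(0, 10_000))
@settings(max_examples=30, deadline=None)
def test_contour_length_exact_by_construction(n_bp, seed):
    chain = ab.sample_wlc_chain(n_bp, seed=seed)
    assert chain.contour_length == pytest.approx(n_bp * 0.34, rel=1e-12)
    steps = np.linalg.norm(np.diff(chain.vertices, axis=0), axis=1)
    assert np.allclose(steps, chain.segment_length, rtol=1e-9)


def test_rigid_rod_limit():
    """Zero turning-angle variance (infinite persistence) gives a straight
    chain whose end-to-end distance equals the contour length."""
    chain = ab.sample_wlc_chain(1000, persistence_length=math.inf, seed=3)
    e2e = np.linalg.norm(chain.vertices[-1] - chain.vertices[0])
    assert e2e == pytest.approx(chain.contour_length, rel=1e-9)


def test_tangent_correlation_sanity():
    """MC ⟨cos θ(s)⟩ at s = 50 nm agrees with exp(−s/2ℓp) (small-n sanity;
    the full 10⁴-chain oracle runs in the acceptance suite)."""
    lp, seg, n = 50.0, 2.0, 2000
    vals = []
    for i in range(n):
        c = ab.sample_wlc_chain(1000, lp, seg, seed=i)
        v = np.diff(c.vertices, axis=0)
        th = np.arctan2(v[:, 1], v[:, 0])
        vals.append(np.cos(th[25] - th[0]))
    vals = np.asarray(vals)
    se = vals.std(ddof=1) / math.sqrt(n)
    assert abs(vals.mean() - math.exp(-50.0 / (2 * lp))) < 3 * se


@pytest.mark.parametrize(
    "kwargs",
    [dict(n_bp=1), dict(persistence_length=0.0), dict(segment_length=0.0),
     dict(segment_length=100.0, persistence_length=50.0)],
)
def test_wlc_parameter_validation(kwargs):
    args = dict(n_bp=1000, persistence_length=50.0, segment_length=2.0, seed=0)
    args.update(kwargs)
    with pytest.raises(ValueError):
        ab.sample_wlc_chain(**args)


# ---------------------------------------------------------------------------
# Scene assembly and ground truth


def _shapely_crossings(chains, cluster_radius):
    """Independent crossing enumeration via shapely per-segment
    intersections (the oracle for the package's vectorized routine)."""
    from shapely.geometry import LineString

    def segments(v):
        return [LineString([v[i], v[i + 1]]) for i in range(len(v) - 1)]

    counts = {}
    for i in range(len(chains)):
        for j in range(i, len(chains)):
            pts = []
            sa = segments(chains[i].vertices)
            sb = segments(chains[j].vertices)
            for ia, ga in enumerate(sa):
                for ib, gb in enumerate(sb):
                    if i == j and ib <= ia + 1:
                        continue
                    inter = ga.intersection(gb)
                    if inter.is_empty or inter.geom_type != "Point":
                        continue
                    pts.append([inter.x, inter.y])
            # single-linkage clustering at the same radius as the package
            clusters = []
            for p in pts:
                placed = False
                for cl in clusters:
                    if any(np.hypot(p[0] - q[0], p[1] - q[1]) <= cluster_radius for q in cl):
                        cl.append(p)
                        placed = True
                        break
                if not placed:
                    clusters.append([p])
            # merge overlapping clusters (single linkage closure)
            merged = True
            while merged:
                merged = False
                for a in range(len(clusters)):
                    for b in range(a + 1, len(clusters)):
                        if any(
                            np.hypot(p[0] - q[0], p[1] - q[1]) <= cluster_radius
                            for p in clusters[a]
                            for q in clusters[b]
                        ):
                            clusters[a] += clusters.pop(b)
                            merged = True
                            break
                    if merged:
                        break
            counts[(i, j)] = len(clusters)
    return counts


@pytest.mark.parametrize("seed", [1, 5, 9])
def test_ground_truth_matches_shapely_oracle(seed):
    """Every recorded junction corresponds to a brute-force crossing of the
    final polylines, per chain pair, at the same cluster radius."""
    scene = ab.place_molecules(
        6, density_class="low", bridging=BridgingConfig(0.5, 0.5, 0.5), seed=seed
    )
    radius = 2 * 2.0 * 1.0  # capture radius default = 2 × segment_length
    oracle = _shapely_crossings(scene.chains, cluster_radius=4.0)
    ours = {}
    for j in scene.junctions:
        ids = tuple(sorted(set(j.molecule_ids))) if j.jtype == "inter" else (
            j.molecule_ids[0], j.molecule_ids[0])
        ours[ids] = ours.get(ids, 0) + 1
    oracle_nonzero = {k: v for k, v in oracle.items() if v}
    assert ours == oracle_nonzero


def test_forced_inter_junction_links_both_molecules():
    scene = ab.place_molecules(
        2, field_size=707.0, density_class="low",
        bridging=BridgingConfig(0.0, 1.0, 0.0), seed=12,
    )
    inter = [j for j in scene.junctions if j.jtype == "inter"]
    assert len(inter) >= 1
    assert set(inter[0].molecule_ids) == {0, 1}


def test_no_bridging_config_means_only_chance_junctions():
    """With p_intra = p_inter = 0 every recorded junction is a chance
    crossing confirmed by direct segment intersection of the placements."""
    scene = ab.place_molecules(4, density_class="low", seed=21)
    for j in scene.junctions:
        assert j.protein_bound is False
    n_direct = 0
    for i in range(len(scene.chains)):
        n_direct += len(polyline_intersections(scene.chains[i].vertices)) > 0
    # junction list must be consistent with the polylines themselves
    recount = ab.synthetic.enumerate_junctions(
        scene.chains, 0.0, np.random.default_rng(0), cluster_radius=4.0
    )
    assert len(recount) == len(scene.junctions)


def test_scene_invariants():
    scene = ab.place_molecules(
        10, density_class="high", bridging=BridgingConfig(0.4, 0.6, 0.5), seed=33
    )
    assert scene.density == pytest.approx(10.0)
    for j in scene.junctions:
        assert 0 <= j.position[0] <= scene.field_size
        assert 0 <= j.position[1] <= scene.field_size
        ids = set(j.molecule_ids)
        assert len(ids) == (1 if j.jtype == "intra" else 2)
    for chain in scene.chains:
        steps = np.linalg.norm(np.diff(chain.vertices, axis=0), axis=1)
        assert np.allclose(steps, chain.segment_length, rtol=1e-9)
        if not chain.clipped:
            assert chain.contour_length == pytest.approx(chain.n_bp * 0.34, rel=1e-12)


def test_scene_truth_json_round_trip():
    scene = ab.place_molecules(
        5, density_class="low", bridging=BridgingConfig(0.5, 0.5, 0.7), seed=2
    )
    back = SceneTruth.from_dict(scene.to_dict())
    assert len(back.chains) == len(scene.chains)
    assert len(back.junctions) == len(scene.junctions)
    assert np.allclose(back.chains[0].vertices, scene.chains[0].vertices)


# ---------------------------------------------------------------------------
# Rendering


def test_render_empty_scene_is_zero():
    scene = SceneTruth([], [], 100.0, 0.0)
    hmap = ab.render_height_map(
        scene, RenderParams(pixel_size=2.0, noise_sigma=0.0, background_coeff_scale=0.0)
    )
    assert np.all(hmap.heights == 0.0)


def test_render_single_chain_peaks_at_h_dna():
    # chain aligned with a row of pixel centers: y = (64 + 0.5) × 250/128
    y = 64.5 * 250 / 128
    chain = straight_chain((125, y), 0.0, 180, 90)
    scene = SceneTruth([chain], [], 250.0, 16.0)
    hmap = ab.render_height_map(
        scene,
        RenderParams(pixel_size=250 / 128, noise_sigma=0.0, background_coeff_scale=0.0),
    )
    assert hmap.heights.max() == pytest.approx(1.0, abs=1e-6)


def test_render_protein_crossing_stacks_heights():
    """A protein-occupied crossing peaks at h_dna + h_overlap + h_protein
    = 2.36 nm, i.e. 1.36 nm above free DNA."""
    ctr = 64.5 * 250 / 128  # a pixel center, so the peak is sampled exactly
    scene = crossing_scene(protein_bound=True, center=(ctr, ctr))
    hmap = render_crossing(scene, noise_sigma=0.0)
    assert hmap.heights.max() == pytest.approx(1.0 + 0.86 + 0.50, abs=1e-6)
    free_level = 1.0  # single-duplex apparent height
    assert hmap.heights.max() - free_level == pytest.approx(1.36, abs=1e-6)


def test_render_is_deterministic():
    scene = ab.default_scene(6, "high")
    a = ab.render_height_map(scene, RenderParams(rng_seed=6))
    b = ab.render_height_map(scene, RenderParams(rng_seed=6))
    assert np.array_equal(a.heights, b.heights)


def test_render_rejects_non_integer_pixel_grid():
    scene = SceneTruth([], [], 1000.0, 0.0)
    with pytest.raises(ValueError, match="pixel"):
        ab.render_height_map(scene, RenderParams(pixel_size=3.0))


def test_render_params_validation():
    with pytest.raises(ValueError):
        RenderParams(pixel_size=0.0)
    with pytest.raises(ValueError):
        RenderParams(h_dna=-1.0)
    with pytest.raises(ValueError):
        RenderParams(background_orders=(0, 5))
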