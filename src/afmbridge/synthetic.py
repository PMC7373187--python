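"""Ground-truthed synthetic fluid-AFM scenes of DNA ± bridging protein.

No raw AFM data accompany the experiments this pipeline quantifies, so the
generator emulates them: 1 μm × 1 μm fields of ~340 nm (1-kbp) DNA
molecules deposited at 4–15 molecules/μm², rendered as nm-valued height
maps with tip broadening, per-scanline polynomial background and pixel
noise. Every crossing of the final polylines — whether forced by the
bridging configuration or arising naturally from random deposition — is
recorded in the scene's ground truth, so each downstream stage
(flattening, segmentation, tracing, statistics) can be tested against
known answers.

Molecules are 2-D worm-like chains: surface-equilibrated DNA is
conventionally treated as a planar polymer whose tangent direction
diffuses along the contour. With per-step turning angles drawn from
N(0, δ/ℓp) for step length δ and persistence length ℓp, the tangent
autocorrelation is ⟨cos θ(s)⟩ = exp(−s / 2ℓp) — the 2-D convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial import cKDTree

from .biophys import RISE_PER_BP_NM
from .heightmap import HeightMap
from .segment import DENSITY_CLASSES

__all__ = [
    "ChainTrace",
    "TruthJunction",
    "SceneTruth",
    "BridgingConfig",
    "RenderParams",
    "sample_wlc_chain",
    "place_molecules",
    "render_height_map",
    "default_scene",
    "polyline_intersections",
    "DEFAULT_BRIDGING",
    "DEFAULT_N_CHAINS",
]

#: Default number-of-molecule draw ranges per density class. The high-class
#: default covers the typical field (8–12) rather than the full 8–15 bound.
DEFAULT_N_CHAINS = {"low": (4, 7), "high": (8, 12)}


@dataclass
class ChainTrace:
    """One simulated DNA molecule as an ordered 2-D polyline.

    ``vertices`` are (x, y) positions in nm; consecutive vertices are
    exactly ``segment_length`` apart. For an unclipped chain,
    n_segments × segment_length == n_bp × 0.34 nm exactly (the segment
    length is adjusted to divide the contour evenly). Chains that left the
    field and were cut back to it carry ``clipped=True`` and a shorter
    vertex list.
    """

    vertices: np.ndarray
    segment_length: float
    n_bp: int
    molecule_id: int
    clipped: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 2:
            raise ValueError("vertices must be an (N>=2, 2) array")

    @property
    def n_segments(self) -> int:
        return len(self.vertices) - 1

    @property
    def contour_length(self) -> float:
        """Polyline length in nm (== n_bp × 0.34 for unclipped chains)."""
        return self.n_segments * self.segment_length


@dataclass
class TruthJunction:
    """A ground-truth crossing: position (nm), intra/inter label, protein flag."""

    position: np.ndarray
    jtype: str  # "intra" | "inter"
    protein_bound: bool
    molecule_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.jtype not in ("intra", "inter"):
            raise ValueError(f"jtype must be intra or inter, got {self.jtype}")
        n_ids = len(set(self.molecule_ids))
        if self.jtype == "intra" and n_ids != 1:
            raise ValueError("intra junction must reference exactly one molecule")
        if self.jtype == "inter" and n_ids != 2:
            raise ValueError("inter junction must reference exactly two molecules")


@dataclass
class SceneTruth:
    """A simulated field: chains, every crossing, field size and density."""

    chains: list[ChainTrace]
    junctions: list[TruthJunction]
    field_size: float  # nm (square field)
    density: float  # molecules per μm²

    def junction_count(self, jtype: str | None = None) -> int:
        if jtype is None:
            return len(self.junctions)
        return sum(1 for j in self.junctions if j.jtype == jtype)

    def to_dict(self) -> dict:
        """JSON-serializable form (schema-versioned)."""
        return {
            "schema_version": 1,
            "field_size_nm": self.field_size,
            "density_per_um2": self.density,
            "chains": [
                {
                    "molecule_id": c.molecule_id,
                    "n_bp": c.n_bp,
                    "segment_length_nm": c.segment_length,
                    "clipped": c.clipped,
                    "vertices_nm": c.vertices.tolist(),
                }
                for c in self.chains
            ],
            "junctions": [
                {
                    "position_nm": j.position.tolist(),
                    "type": j.jtype,
                    "protein_bound": j.protein_bound,
                    "molecule_ids": list(j.molecule_ids),
                }
                for j in self.junctions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneTruth":
        chains = [
            ChainTrace(
                vertices=np.asarray(c["vertices_nm"]),
                segment_length=c["segment_length_nm"],
                n_bp=c["n_bp"],
                molecule_id=c["molecule_id"],
                clipped=c["clipped"],
            )
            for c in d["chains"]
        ]
        junctions = [
            TruthJunction(
                position=np.asarray(j["position_nm"]),
                jtype=j["type"],
                protein_bound=j["protein_bound"],
                molecule_ids=tuple(j["molecule_ids"]),
            )
            for j in d["junctions"]
        ]
        return cls(chains, junctions, d["field_size_nm"], d["density_per_um2"])


@dataclass(frozen=True)
class BridgingConfig:
    """Per-scene bridging probabilities.

    p_intra: probability a chain is forced to cross itself.
    p_inter: probability a disjoint chain pair is forced to cross.
    p_protein: probability any ground-truth junction is protein-occupied.
    """

    p_intra: float = 0.0
    p_inter: float = 0.0
    p_protein: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_intra", "p_inter", "p_protein"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


#: Bridging configuration of the "default synthetic scene" used by the
#: recovery suites: junctions of both kinds present, half protein-occupied.
DEFAULT_BRIDGING = BridgingConfig(p_intra=0.2, p_inter=0.2, p_protein=0.5)


@dataclass(frozen=True)
class RenderParams:
    """Forward-model parameters mapping a scene to a height map.

    Heights in nm. The defaults place bare-crossing and protein-occupied
    crossing height excesses at 0.86 and 0.86 + 0.50 = 1.36 nm above free
    DNA, inside a 0–2.8 nm display range, on a 1-μm scan at 512 px.
    """

    pixel_size: float = 1000.0 / 512.0
    h_dna: float = 1.0
    h_overlap_add: float = 0.86
    h_protein_add: float = 0.50
    tip_sigma: float = 3.0
    noise_sigma: float = 0.08
    background_orders: tuple[int, ...] = (0, 1, 2)
    background_coeff_scale: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.pixel_size > 0):
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        for name in ("h_dna", "h_overlap_add", "h_protein_add", "tip_sigma",
                     "noise_sigma", "background_coeff_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not set(self.background_orders) <= {0, 1, 2}:
            raise ValueError(f"background_orders must be ⊆ {{0,1,2}}, got {self.background_orders}")


# ---------------------------------------------------------------------------
# Worm-like chains


def _wlc_vertices(
    n_segments: int,
    segment_length: float,
    persistence_length: float,
    rng: np.random.Generator,
    start: tuple[float, float] = (0.0, 0.0),
    heading: float = 0.0,
) -> np.ndarray:
    """Vertices of a 2-D WLC: cumulative sum of unit steps with Gaussian
    turning angles of variance segment_length / persistence_length."""
    sigma = math.sqrt(segment_length / persistence_length)
    turns = rng.normal(0.0, sigma, size=n_segments)
    turns[0] = 0.0  # first step continues the initial heading
    headings = heading + np.cumsum(turns)
    steps = segment_length * np.stack([np.cos(headings), np.sin(headings)], axis=1)
    verts = np.empty((n_segments + 1, 2))
    verts[0] = start
    verts[1:] = np.asarray(start) + np.cumsum(steps, axis=0)
    return verts


def _chain_geometry(n_bp: int, segment_length: float) -> tuple[int, float]:
    """Number of segments and adjusted segment length giving an exact
    n_bp × 0.34 nm contour."""
    contour = n_bp * RISE_PER_BP_NM
    n_seg = max(1, round(contour / segment_length))
    return n_seg, contour / n_seg


def sample_wlc_chain(
    n_bp: int,
    persistence_length: float = 50.0,
    segment_length: float = 2.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    molecule_id: int = 0,
) -> ChainTrace:
    """Sample one 2-D worm-like chain of ``n_bp`` base pairs.

    The chain starts at the origin heading along +x. The requested
    ``segment_length`` is adjusted (by at most half a segment) so that an
    integer number of segments gives a contour of exactly n_bp × 0.34 nm;
    a 1-kbp chain is exactly 340 nm long for any seed.
    """
    if n_bp < 2:
        raise ValueError(f"n_bp must be >= 2, got {n_bp}")
    if not (persistence_length > 0):
        raise ValueError(f"persistence_length must be > 0, got {persistence_length}")
    if not (0 < segment_length <= persistence_length):
        raise ValueError(
            f"segment_length must be in (0, persistence_length], got {segment_length}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    n_seg, seg_eff = _chain_geometry(n_bp, segment_length)
    verts = _wlc_vertices(n_seg, seg_eff, persistence_length, rng)
    return ChainTrace(verts, seg_eff, n_bp, molecule_id)


def _forced_self_crossing_vertices(
    n_seg: int,
    seg: float,
    lp: float,
    rng: np.random.Generator,
    capture_radius: float,
) -> np.ndarray:
    """WLC vertices with a forced self-crossing.

    The chain is first sampled freely; then, from a restart vertex in its
    distal half, the remainder is regenerated: it heads straight back at an
    anchor vertex in the proximal third until it has passed ``capture_radius``
    beyond it (crossing the earlier path), then resumes worm-like wandering.
    Segment lengths are untouched, so the contour stays exact.
    """
    verts = _wlc_vertices(n_seg, seg, lp, rng)
    if n_seg < 8:
        return verts  # too short to force a loop
    ia = int(rng.integers(0, n_seg // 3 + 1))
    j = int(rng.integers(n_seg // 2, 2 * n_seg // 3 + 1))
    anchor = verts[ia]
    pos = verts[j].copy()
    remaining = n_seg - j
    to_anchor = anchor - pos
    dist = float(np.hypot(*to_anchor))
    heading = math.atan2(to_anchor[1], to_anchor[0])
    n_straight = min(remaining, int(math.ceil((dist + capture_radius) / seg)))
    out = verts[: j + 1].copy()
    # straight approach through the anchor
    step = seg * np.array([math.cos(heading), math.sin(heading)])
    straight = pos + np.arange(1, n_straight + 1)[:, None] * step
    out = np.vstack([out, straight])
    n_rest = remaining - n_straight
    if n_rest > 0:
        # resume worm-like wandering from the post-crossing heading
        turns = rng.normal(0.0, math.sqrt(seg / lp), size=n_rest)
        headings = heading + np.cumsum(turns)
        steps = seg * np.stack([np.cos(headings), np.sin(headings)], axis=1)
        tail = out[-1] + np.cumsum(steps, axis=0)
        out = np.vstack([out, tail])
    return out


# ---------------------------------------------------------------------------
# Segment intersection (ground truth)


def polyline_intersections(
    a: np.ndarray, b: np.ndarray | None = None, eps: float = 1e-9
) -> np.ndarray:
    """All transversal crossing points of two polylines (or of one with
    itself when ``b`` is None), as an (k, 2) array of nm coordinates.

    Vectorized parametric segment–segment test with closed intervals, so
    crossings at shared vertices (forced inter junctions) are included;
    for self-intersection, adjacent segment pairs are excluded. Exactly
    collinear overlaps are ignored (measure-zero for sampled chains).
    """
    a = np.asarray(a, dtype=float)
    p = a[:-1]
    r = np.diff(a, axis=0)
    if b is None:
        q, s = p, r
    else:
        b = np.asarray(b, dtype=float)
        q = b[:-1]
        s = np.diff(b, axis=0)

    # (i, j) grids: segment i of a vs segment j of b
    rx, ry = r[:, 0][:, None], r[:, 1][:, None]
    sx, sy = s[:, 0][None, :], s[:, 1][None, :]
    qpx = q[None, :, 0] - p[:, 0][:, None]
    qpy = q[None, :, 1] - p[:, 1][:, None]

    denom = rx * sy - ry * sx
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (qpx * sy - qpy * sx) / denom
        u = (qpx * ry - qpy * rx) / denom
    hit = (
        (np.abs(denom) > eps)
        & (t >= -eps) & (t <= 1 + eps)
        & (u >= -eps) & (u <= 1 + eps)
    )
    if b is None:
        iu = np.triu_indices(len(p), k=2)  # skip self and adjacent pairs
        keep = np.zeros_like(hit)
        keep[iu] = hit[iu]
        hit = keep
    ii, jj = np.nonzero(hit)
    if len(ii) == 0:
        return np.empty((0, 2))
    pts = p[ii] + t[ii, jj][:, None] * r[ii]
    return pts


def _cluster_points(points: np.ndarray, radius: float) -> list[np.ndarray]:
    """Single-linkage clusters of 2-D points at the given radius; returns
    cluster centroids' member arrays."""
    n = len(points)
    if n == 0:
        return []
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    tree = cKDTree(points)
    for i, j in tree.query_pairs(radius):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [points[idx] for idx in groups.values()]


# ---------------------------------------------------------------------------
# Scene assembly


def _transform(verts: np.ndarray, theta: float, target: np.ndarray) -> np.ndarray:
    """Rotate about the centroid by theta, then move the centroid to target."""
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    centered = verts - verts.mean(axis=0)
    return centered @ rot.T + target


def _clip_to_field(verts: np.ndarray, field: float) -> tuple[np.ndarray, bool]:
    """Longest contiguous vertex run inside [0, field]²; flag if shortened."""
    inside = np.all((verts >= 0) & (verts <= field), axis=1)
    if inside.all():
        return verts, False
    best_start, best_len, start = 0, 0, None
    for i, flag in enumerate(inside):
        if flag and start is None:
            start = i
        if (not flag or i == len(inside) - 1) and start is not None:
            end = i + 1 if flag else i
            if end - start > best_len:
                best_start, best_len = start, end - start
            start = None
    if best_len < 2:
        # pathological: nearly nothing inside; clamp to the field edge
        clamped = np.clip(verts, 0.0, field)
        return clamped, True
    return verts[best_start : best_start + best_len].copy(), True


def place_molecules(
    n_chains: int,
    field_size: float = 1000.0,
    density_class: str = "high",
    bridging: BridgingConfig | None = None,
    seed: int = 0,
    n_bp: int = 1000,
    persistence_length: float = 50.0,
    segment_length: float = 2.0,
    capture_radius: float | None = None,
    max_place_tries: int = 30,
) -> SceneTruth:
    """Deposit ``n_chains`` worm-like chains on a square field and record
    every crossing as ground truth.

    Chains are placed with uniform random position and orientation;
    placements that leave the field are retried and, failing that, clipped
    at the boundary (flagged). Forced intramolecular junctions regenerate
    the distal part of a chain back through one of its own earlier
    vertices; forced intermolecular junctions translate the second chain
    of a disjoint random pair so that one of its vertices coincides with a
    vertex of the first. Ground truth then enumerates ALL crossings of the
    final polylines — forced and natural alike — and flags each
    protein-occupied with probability ``p_protein``.

    Randomness: one master seed; scene-level decisions, each chain, and
    the protein flags use substreams spawned from it in a fixed order
    (children 0, 1..n_chains, n_chains+1 of ``SeedSequence(seed)``).
    """
    bridging = bridging or BridgingConfig()
    if density_class not in DENSITY_CLASSES:
        raise ValueError(f"density_class must be one of {sorted(DENSITY_CLASSES)}")
    area_um2 = (field_size / 1000.0) ** 2
    density = n_chains / area_um2
    lo, hi = DENSITY_CLASSES[density_class]
    if not (lo <= density <= hi):
        raise ValueError(
            f"density {density:.2f}/μm² outside the {density_class} class [{lo}, {hi}]"
        )
    if capture_radius is None:
        capture_radius = 2.0 * segment_length

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_chains + 2)
    scene_rng = np.random.default_rng(children[0])
    chain_rngs = [np.random.default_rng(c) for c in children[1:-1]]
    flag_rng = np.random.default_rng(children[-1])

    n_seg, seg_eff = _chain_geometry(n_bp, segment_length)
    force_intra = scene_rng.random(n_chains) < bridging.p_intra
    perm = scene_rng.permutation(n_chains)
    pair_list = [
        (int(perm[2 * k]), int(perm[2 * k + 1])) for k in range(n_chains // 2)
    ]
    force_inter = {
        pair: bool(scene_rng.random() < bridging.p_inter) for pair in pair_list
    }

    shapes: list[np.ndarray] = []
    for i in range(n_chains):
        rng = chain_rngs[i]
        if force_intra[i]:
            verts = _forced_self_crossing_vertices(
                n_seg, seg_eff, persistence_length, rng, capture_radius
            )
        else:
            verts = _wlc_vertices(n_seg, seg_eff, persistence_length, rng)
        shapes.append(verts)

    placed: list[np.ndarray] = [None] * n_chains  # type: ignore[list-item]
    clipped = [False] * n_chains
    for i in range(n_chains):
        rng = chain_rngs[i]
        verts = shapes[i]
        final = None
        for _ in range(max_place_tries):
            theta = rng.uniform(0.0, 2.0 * math.pi)
            target = rng.uniform(0.0, field_size, size=2)
            cand = _transform(verts, theta, target)
            if np.all((cand >= 0) & (cand <= field_size)):
                final = cand
                break
        if final is None:
            final, clipped[i] = _clip_to_field(cand, field_size)
        placed[i] = final

    # forced inter pairs: re-place chain b pinned to a vertex of chain a
    for (ia, ib), forced in force_inter.items():
        if not forced:
            continue
        rng = chain_rngs[ib]
        va = placed[ia]
        vb_shape = shapes[ib]
        n_a, n_b = len(va), len(vb_shape)
        a_idx = int(rng.integers(n_a // 4, 3 * n_a // 4 + 1))
        b_idx = int(rng.integers(n_b // 4, 3 * n_b // 4 + 1))
        pivot = va[a_idx]
        final = None
        cand = vb_shape
        for _ in range(max_place_tries):
            theta = rng.uniform(0.0, 2.0 * math.pi)
            c, s = math.cos(theta), math.sin(theta)
            rot = np.array([[c, -s], [s, c]])
            cand = (vb_shape - vb_shape[b_idx]) @ rot.T + pivot
            if np.all((cand >= 0) & (cand <= field_size)):
                final = cand
                break
        if final is None:
            final, clip_b = _clip_to_field(cand, field_size)
            clipped[ib] = clip_b
        else:
            clipped[ib] = False
        placed[ib] = final

    chains = [
        ChainTrace(placed[i], seg_eff, n_bp, molecule_id=i, clipped=clipped[i])
        for i in range(n_chains)
    ]
    junctions = enumerate_junctions(
        chains, p_protein=bridging.p_protein, rng=flag_rng,
        cluster_radius=capture_radius, field_size=field_size,
    )
    return SceneTruth(chains, junctions, field_size, density)


def enumerate_junctions(
    chains: list[ChainTrace],
    p_protein: float,
    rng: np.random.Generator,
    cluster_radius: float = 4.0,
    field_size: float | None = None,
) -> list[TruthJunction]:
    """Every crossing of the final chain polylines, clustered per chain
    pair at ``cluster_radius`` (a pixelated crossing is one junction even
    if several consecutive segment pairs intersect)."""
    junctions: list[TruthJunction] = []
    n = len(chains)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                pts = polyline_intersections(chains[i].vertices)
                jtype = "intra"
                ids = (chains[i].molecule_id,)
            else:
                pts = polyline_intersections(chains[i].vertices, chains[j].vertices)
                jtype = "inter"
                ids = (chains[i].molecule_id, chains[j].molecule_id)
            for members in _cluster_points(pts, cluster_radius):
                pos = members.mean(axis=0)
                if field_size is not None:
                    pos = np.clip(pos, 0.0, field_size)
                junctions.append(
                    TruthJunction(pos, jtype, bool(rng.random() < p_protein), ids)
                )
    return junctions


def default_scene(
    seed: int,
    density_class: str = "high",
    bridging: BridgingConfig = DEFAULT_BRIDGING,
    field_size: float = 1000.0,
    **kwargs,
) -> SceneTruth:
    """The standard test scene: a 1 μm² field with the number of 1-kbp
    molecules drawn uniformly from the class's default range."""
    lo, hi = DEFAULT_N_CHAINS[density_class]
    n = int(np.random.default_rng(np.random.SeedSequence((seed, 0xD))).integers(lo, hi + 1))
    return place_molecules(
        n, field_size=field_size, density_class=density_class,
        bridging=bridging, seed=seed, **kwargs,
    )


# ---------------------------------------------------------------------------
# Rendering


def render_height_map(scene: SceneTruth, params: RenderParams) -> HeightMap:
    """Render a scene to a height map under the forward imaging model.

    Per pixel, the molecule signal is h_dna × exp(−d²/2σ²) with d the
    distance to the nearest chain segment and σ the tip-broadening width;
    a flat disk of radius σ centered on each recorded crossing adds
    h_overlap_add (two duplexes stacked), plus h_protein_add where the
    crossing is protein-occupied. A per-scanline polynomial background
    (random coefficients, power basis on x ∈ [-1, 1]) and i.i.d. Gaussian
    pixel noise are then added. Deterministic given (scene, params):
    repeated renders are bit-identical.
    """
    ps = params.pixel_size
    n_f = scene.field_size / ps
    n_px = round(n_f)
    if abs(n_f - n_px) > 1e-6 or n_px < 1:
        raise ValueError(
            f"field_size {scene.field_size} nm is not a whole number of "
            f"{ps} nm pixels"
        )
    rng = np.random.default_rng(np.random.SeedSequence(params.rng_seed))
    coeffs = rng.normal(0.0, params.background_coeff_scale, size=(n_px, 3))
    for order in range(3):
        if order not in params.background_orders:
            coeffs[:, order] = 0.0
    noise = rng.normal(0.0, params.noise_sigma, size=(n_px, n_px)) if params.noise_sigma > 0 else 0.0

    centers = (np.arange(n_px) + 0.5) * ps
    gx, gy = np.meshgrid(centers, centers)  # gx: col coordinate (x), gy: row (y)
    grid = np.stack([gx.ravel(), gy.ravel()], axis=1)

    heights = np.zeros((n_px, n_px))
    pts = _dense_chain_points(scene, ps, params.tip_sigma)
    if len(pts):
        tree = cKDTree(pts)
        d, _ = tree.query(grid, k=1)
        d = d.reshape(n_px, n_px)
        if params.tip_sigma > 0:
            heights = params.h_dna * np.exp(-(d ** 2) / (2.0 * params.tip_sigma ** 2))
        else:
            heights = params.h_dna * (d <= ps / 2.0)

    radius = params.tip_sigma if params.tip_sigma > 0 else ps / 2.0
    for junction in scene.junctions:
        _add_disk(heights, junction.position, radius, params.h_overlap_add, ps)
        if junction.protein_bound:
            _add_disk(heights, junction.position, radius, params.h_protein_add, ps)

    x = np.linspace(-1.0, 1.0, n_px) if n_px > 1 else np.zeros(1)
    vander = np.vander(x, 3, increasing=True)
    background = coeffs @ vander.T  # (rows, cols)
    heights = heights + background + noise

    meta = {
        "render_params": asdict(params),
        "background_coeffs": coeffs,
        "density_per_um2": scene.density,
        "n_molecules": len(scene.chains),
    }
    return HeightMap(heights, ps, meta)


def _dense_chain_points(scene: SceneTruth, pixel_size: float, tip_sigma: float) -> np.ndarray:
    """Chain polylines resampled finely enough that the nearest-point
    distance approximates the nearest-segment distance below pixel scale."""
    spacing = pixel_size / 2.0
    if tip_sigma > 0:
        spacing = min(spacing, tip_sigma / 2.0)
    pts = []
    for chain in scene.chains:
        v = chain.vertices
        seg = np.diff(v, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        pts.append(v[:1])
        for i, L in enumerate(seglen):
            n = max(1, int(math.ceil(L / spacing)))
            t = np.linspace(0.0, 1.0, n + 1)[1:, None]
            pts.append(v[i] + t * seg[i])
    return np.vstack(pts) if pts else np.empty((0, 2))


def _add_disk(
    heights: np.ndarray, position_nm: np.ndarray, radius_nm: float, amount: float, ps: float
) -> None:
    """Add ``amount`` to all pixels whose center lies within radius of the
    position; operates on a local window for speed."""
    if amount == 0.0:
        return
    n_rows, n_cols = heights.shape
    cx, cy = position_nm  # x → col, y → row
    r_px = radius_nm / ps
    col_c = cx / ps - 0.5
    row_c = cy / ps - 0.5
    r0 = max(0, int(math.floor(row_c - r_px)) - 1)
    r1 = min(n_rows, int(math.ceil(row_c + r_px)) + 2)
    c0 = max(0, int(math.floor(col_c - r_px)) - 1)
    c1 = min(n_cols, int(math.ceil(col_c + r_px)) + 2)
    if r0 >= r1 or c0 >= c1:
        return
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    dy = (rows[:, None] + 0.5) * ps - cy
    dx = (cols[None, :] + 0.5) * ps - cx
    disk = dx ** 2 + dy ** 2 <= radius_nm ** 2
    heights[r0:r1, c0:c1][disk] += amount
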