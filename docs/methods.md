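# Methods

This note documents the models, estimators and numerical choices behind
`afmbridge`, in the order the pipeline runs them, together with what the
synthetic data do and do not emulate and the known limitations. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Synthetic scenes

### Worm-like chains in two dimensions

Surface-equilibrated DNA is modelled as a discrete 2-D worm-like chain:
`n_seg` straight segments of equal length δ, with independent Gaussian
turning angles θᵢ ~ N(0, δ/ℓp) between consecutive segments. Summing
independent angles gives the tangent autocorrelation

    ⟨cos θ(s)⟩ = exp(−s · δ/ℓp / (2δ)) = exp(−s / 2ℓp),

the standard 2-D convention (in 3-D the decay constant would be 1/ℓp).
The test suite verifies this against the closed form at s = 10, 50 and
100 nm over 10⁴ chains, within three Monte-Carlo standard errors.

Contour length is exact by construction: for `n_bp` base pairs the
contour is n_bp × 0.34 nm (B-form axial rise) and the requested segment
length is adjusted by at most half a segment so that an integer number
of segments divides it evenly. A 1-kbp molecule is exactly 340 nm for
every seed. Defaults: ℓp = 50 nm, δ = 2 nm — the textbook persistence
length of duplex DNA and a discretization fine enough that the chain is
smooth below the imaging resolution.

### Deposition, forced crossings, ground truth

Chains are placed with uniform random position and orientation on a
square field (default 1 μm²). Placements leaving the field are retried
up to 30 times; a chain that still does not fit is clipped to its
longest in-field run and flagged (clipped molecules keep their segment
geometry but are excluded from length-based checks). Deposition density
is validated against the experimental classes: low = 4–7, high = 8–15
molecules/μm² (closed ranges); the default scene draws 4–7 (low) or
8–12 (high) molecules per field.

Bridging is imposed in two ways, both preserving segment lengths
exactly:

- **intra**: with probability `p_intra` a chain's distal part is
  regenerated so that it heads straight back through one of its own
  proximal vertices (continuing a capture radius, default 2δ, beyond it)
  before resuming worm-like wandering — a guaranteed self-crossing;
- **inter**: chains are paired at random; with probability `p_inter` the
  second chain of a pair is translated so one of its interior vertices
  coincides with an interior vertex of the first, then rotated about the
  shared point until it fits the field.

Ground truth is then computed from the *final* polylines: a vectorized
segment–segment intersection enumerates every crossing (forced and
chance alike), clustered per chain pair at the capture radius so a
pixelated crossing is one junction. Each recorded junction is flagged
protein-occupied with probability `p_protein` — applied to all
junctions, not only forced ones, since a bridging protein can occupy any
crossing; `p_protein = 0` reproduces the bare-DNA condition. The test
suite cross-checks this enumeration against an independent
shapely-based oracle.

### Rendering

The forward imaging model maps a scene to heights (nm) per pixel:

1. molecule signal h(p) = h_dna · exp(−d(p)²/2σ_tip²), with d(p) the
   distance from the pixel center to the nearest chain point (chains are
   resampled at sub-pixel spacing; nearest distances via a k-d tree).
   Taking the *nearest* chain rather than a sum makes two adjacent
   duplexes merge into a ribbon rather than pile up — overlap height is
   modelled explicitly instead;
2. a flat disk of radius σ_tip centred on every recorded crossing adds
   `h_overlap_add`, plus `h_protein_add` where the crossing is
   protein-occupied (the disk realization of "within a tip radius of two
   chain passes" is centred on the crossings the truth already
   enumerates);
3. each scanline adds a polynomial background c₀ + c₁x + c₂x² on the
   normalized coordinate x ∈ [−1, 1], coefficients ~ N(0,
   `background_coeff_scale`) per row and order;
4. i.i.d. Gaussian pixel noise of `noise_sigma`.

Defaults: 1 μm scan at 512 px (pixel 1.953 nm — 512 px is the
conventional scan resolution, not a measured value), h_dna = 1.0 nm,
h_overlap_add = 0.86 nm, h_protein_add = 0.50 nm, σ_tip = 3 nm,
noise 0.08 nm, background scale 0.3 nm. The apparent height of duplex
DNA in liquid is not sharply constrained by the experiments being
emulated (only a 0–2.8 nm display range); 1.0 nm is a typical fluid-AFM
value, and the overlap/protein increments are chosen so bare and
protein-occupied crossings sit 0.86 and 1.36 nm above free DNA — the
condition means the downstream estimator must recover. Rendering is
deterministic given (scene, parameters): repeated renders are
bit-identical, with all randomness drawn from substreams of one seed in
a fixed order.

## 2. Scanline flattening

Each scanline is fit independently with a polynomial of order 0, 1 or 2
on x ∈ [−1, 1] and the fit subtracted; the default applies the three
orders sequentially (0 → 1 → 2), matching common instrument-software
practice. A naive least-squares fit is biased by molecules, so each fit
is iterated (default 3 rounds): pixels whose residual exceeds
`mask_k` × (1.4826 × MAD) of the current background residuals — a
one-sided cut, since molecules protrude upward — are masked out of the
next round. A scanline left with fewer unmasked pixels than coefficients
falls back to an order-0 median fit with a logged warning.

Properties verified in the suite: the subtracted correction is exactly a
per-row polynomial of the requested order; injected nm-scale ramp
coefficients are recovered within 2 % in the presence of a molecule;
flattening is idempotent to < 1e-6 nm RMS; junction height differences
on noise-free images change by < 0.02 nm.

One caveat is inherent to per-scanline fitting: a molecule segment lying
*along* the scan axis occupies a large fraction of its row in a small
image and can be partially absorbed into the background fit. Real
workflows share this artifact; the controlled test scenes therefore keep
arms away from the fast axis, and on 512-px fields the masking protects
molecules spanning ≲ 10 % of a row.

## 3. Segmentation

The height cutoff is τ = median + k × (1.4826 × MAD) over all pixels of
the flattened image (the substrate dominates by area, so whole-image
robust statistics estimate background level and noise). Defaults k = 3
and a minimum component area of 30 px (≈ a 12 × 20 nm blob) to reject
specks; components are 8-connected so diagonal chain rasters stay
intact. The by-eye cutoff choice of the original workflow is replaced by
this reproducible rule and *verified against its stated criterion*: on
20 seeded default fields, ≥ 90 % of ground-truth molecules must be
captured, where a molecule counts as captured iff at least half of its
rasterized centerline pixels fall in some labelled component. Measured
capture at the defaults is 100 % (acceptance suite); capture is monotone
non-increasing in the threshold.

## 4. Tracing and junctions

Each component mask is cleaned by one round of binary opening
(4-connected cross), thinned to a one-pixel skeleton, and converted to a
graph: endpoint nodes (degree 1), branch nodes (skeleton pixels of
degree ≥ 3, clustered within `r_merge`), and pixel-path edges whose
lengths count 1 px per axial and √2 px per diagonal step. Terminal twigs
shorter than `prune_px` that end at a branch pixel are removed (thinning
artifacts of rough mask edges); twigs that terminate the whole path —
real molecule ends — are kept. Ring components with neither endpoints
nor branches are flagged closed loops and classified intramolecular.

Defaults r_merge = 6 px and prune_px = 6 px correspond to the apparent
ribbon width (~10 nm / ~5 px at default imaging parameters): a single
pixelated crossing typically thins into two degree-3 pixels up to a
ribbon width apart, and edge twigs up to half a width long. With the
4-px values the detector over-counted junctions by ~20 % on noisy
default fields; at 6 px the 20-scene aggregate recovery is within 4 % of
ground truth (acceptance suite; the ±10 % band is the requirement).
Without the mask opening, raw noisy masks over-detected by ~60 %.

**Classification** is component-level: 2 endpoints and total skeleton
length within ±25 % of L₀ → intramolecular; 3–4 endpoints and length
within ±25 % of 2L₀ → intermolecular pair; closed loops →
intramolecular; everything else (multi-molecule tangles,
border-touching components) → ambiguous/excluded. The manual five-fold
freehand length measurement of the original workflow is replaced by the
skeleton length; thinning erodes ends and pixelation adds staircase
length, so single-molecule skeletons recover the 340 nm contour within
15 % (measured bias is a few per cent short).

**Junction height difference.** For each junction, Δh = (max height
within `window_r` = 3 px of the branch node) − (free-DNA level). The
free-DNA level is the median, over skeleton pixels farther than
`excl_r` = 8 px from every junction of the component, of the *local max
within the same window* around each pixel. Using the same order
statistic on both sides is deliberate: the max of ~30 noisy pixels is
biased upward by ~2 noise σ, and a plain median of skeleton-pixel
heights is biased downward wherever the skeleton runs a pixel off the
ridge crest; matching the statistic cancels both effects to first
order. On noise-free images the estimator returns the injected values
exactly (0.86 / 1.36 nm); on noisy ensembles of ≥ 30 protein-occupied
crossings the sample mean lands within 2 SEM of the injected value
(acceptance suite). A component with fewer than 20 junction-free
skeleton pixels raises an "insufficient free DNA" error and is skipped
with a logged reason. Enlarging the window to cover the branch-node
localization error of tangled fields was evaluated and rejected: at
window_r = 6 px the free reference inflates faster than the junction
peak and the controlled ensemble acquires a ~0.04 nm downward bias.

## 5. Condition statistics

An intermolecular component contains two molecules and contributes two
junction-bearing molecules; intra and ambiguous components contribute
one. Percentages are per observed molecule; SEM uses the n−1 sample
standard deviation; summaries are additive (pooling halves equals
summarizing the whole). Between conditions the package uses the
unpaired *equal-variance* Student's t test (t = Δx̄ / s_p√(1/n_a+1/n_b),
df = n_a+n_b−2, two-sided), computed from the closed form with the
scipy t distribution for p; degenerate zero-variance inputs return
(t=0, p=1) for equal means and a flagged p→0 otherwise. Junctions are
pooled across images by default (per-image aggregation is available by
grouping the output frames); no multiple-testing correction is applied.
Density effects are reported as fold changes of the intermolecular
percentage (high/low) and intramolecular percentage (low/high), with
zero denominators flagged as infinite.

Condition presets (p_intra, p_inter, p_protein, h_protein_add):
bare DNA (0.10, 0.05, 0, 0), bridging protein (0.45, 0.25, 0.9,
0.50 nm), binding-deficient mutant (0.12, 0.06, 0.2, 0.45 nm). These
were fixed once so the three conditions reproduce the qualitative
experimental structure — junction frequency protein ≫ bare ≈ mutant,
expected junction height excesses ≈ 0.86 / 1.36 / ≈0.95 nm (the mutant's
residual binding shows as occasional, slightly lower protein signal).

## 6. What the synthetic data do and do not emulate

Emulated: field size, scan resolution, molecule length and density
classes, apparent height scale and display range, junction height
increments, scanline background, pixel noise, chance overlaps at
realistic surface coverage, boundary clipping.

Not emulated: tip–sample mechanics and force curves, tip shape beyond an
isotropic Gaussian, scar/streak artifacts, surface-interaction
correlations between molecules (chains are placed independently, so
chance-crossing rates at high density exceed what electrostatically
repelling molecules show in practice), protein aggregates and
off-junction binding, over/under-strand topology at crossings, and 3-D
conformation. Passing tests therefore demonstrate that the *analysis*
recovers what the forward model injects, not that the forward model
reproduces any particular instrument.

Known limitations of the mechanized detector, measured on default
high-density fields: aggregate junction counts recover within ~5 %, but
per-junction matching is weaker — roughly 40 % of true crossings thin
without a branch node within 6 px (shallow-angle merges; end-stubs
shorter than the prune length), while a comparable number of branch
nodes arise where chains touch without crossing and carry no height
excess. Pooled junction-height statistics on crowded fields are
therefore diluted toward zero, and condition contrasts in Δh should be
read from controlled ensembles (as the significance tests in the suite
do); the junction-frequency contrast between conditions is robust to
this. A human analyst in the original workflow implicitly filtered
these cases by eye.

## 7. Problem sizes and determinism

The test and acceptance workloads use 20 default 512-px fields for
capture and count recovery, 10⁴ chains for the tangent-correlation
oracle, and 30–40 controlled crossings per arm for height recovery and
significance — sizes chosen to hold Monte-Carlo error comfortably below
the tested tolerances while keeping the whole suite around a minute.
Every random draw in the package flows from an explicit seed through
fixed-order substreams (`numpy` SeedSequence); the end-to-end pipeline
writes byte-identical outputs when re-run with the same configuration,
and the run log records seed, parameters and package version (no
timestamps).
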