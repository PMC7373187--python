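# afmbridge

Quantification of protein-mediated DNA bridging in fluid-AFM height maps.

Nucleoid-associated proteins (NAPs) such as GapR compact bacterial
chromosomes in part by *bridging* — holding two double-helix segments
together. In fluid atomic-force microscopy a bridge shows up as a
junction: a crossing of two DNA paths whose height exceeds the
single-duplex level by roughly one duplex (a bare overlap) plus the bound
protein. `afmbridge` is a reusable, fully tested implementation of the
image-analysis workflow behind such experiments, for microscopists and
single-molecule biophysicists who want the quantification to be
scripted, seeded and scored against ground truth rather than done by
hand:

1. **synthetic** — ground-truthed scene generation: 2-D worm-like-chain
   (WLC) DNA molecules (tangent correlation ⟨cos θ(s)⟩ = e^(−s/2ℓp),
   contour L₀ = n_bp × 0.34 nm) deposited on a 1 μm² field at controlled
   density, with forced intra-/intermolecular crossings and optional
   protein occupancy, rendered to nm-valued height maps with Gaussian tip
   broadening, per-scanline polynomial background and pixel noise;
2. **flatten** — robust per-scanline polynomial background removal
   (orders 0/1/2 applied sequentially, iterative foreground masking);
3. **segment** — height-cutoff segmentation, τ = median + k·σ_MAD,
   verified to capture ≥ 90 % of ground-truth molecules, plus the
   low (4–7 /μm²) / high (8–15 /μm²) density classification;
4. **trace** — skeleton-graph molecule tracing: contour lengths by pixel
   step counting, junctions as merged branch nodes, intra/inter
   classification from endpoint count and total length, and the junction
   height difference Δh against the molecule's own free-DNA level;
5. **stats** — per-condition summaries (% of molecules with junctions,
   mean ± SEM of Δh), unpaired equal-variance Student's t tests and
   density fold changes;
6. **biophys** — the closed-form side calculations (bp → nm,
   copy number → concentration).

Every stage is scored against the generator's ground truth in the test
suite; no external data are required.

## Worked example

The minimal controlled experiment — two duplexes crossing once, with and
without a bound bridging protein (`examples/03_trace_junctions.py`):

```text
bare crossing   : junction height difference = 0.91 nm
protein-occupied: junction height difference = 1.41 nm
```

With the default render noise of 0.08 nm these land on the injected
0.86 nm (two stacked duplexes) and 1.36 nm (plus protein) within a few
hundredths of a nanometre — the height contrast that distinguishes a
protein-occupied junction from a chance overlap.

The full condition comparison (`examples/04_condition_comparison.py`,
three condition presets × two densities × four images, master seed 1)
prints, among other columns:

```text
condition density_class  n_molecules  n_junctions  pct_molecules_with_junction
      dna           low           23           20                       34.783
      dna          high           30           36                       50.000
     gapr           low           22           35                       72.727
     gapr          high           29           63                       75.862
   mutant           low           19           13                       47.368
   mutant          high           28           49                       60.714
```

The bridging-protein condition (`gapr`) carries the highest fraction of
junction-bearing molecules at both deposition densities, while the
binding-deficient mutant stays near bare DNA — the frequency signature
of active bridging. On crowded fields the pooled Δh statistics are
diluted by branch points where chains touch without crossing (no height
excess); the controlled ensemble above isolates the height signal. See
`docs/methods.md` for what the synthetic fields do and do not emulate.

Each example in `examples/` is a short, self-contained script; the
`afmbridge` CLI exposes the same stages (`simulate`, `flatten`,
`segment`, `trace`, `analyze`, `report`, `calc`, `run`) for shell use.

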