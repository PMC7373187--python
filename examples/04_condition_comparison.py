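"""End-to-end condition comparison: bare DNA vs bridging protein vs mutant.

Runs the full simulate -> flatten -> segment -> trace -> summarize
pipeline for the three condition presets at both deposition densities and
prints the per-condition summary plus the pairwise junction-height t
tests. All randomness derives from the single master seed, so the run is
reproducible byte for byte.
"""

import pandas as pd

from afmbridge.pipeline import RunConfig, run_pipeline

pd.set_option("display.width", 160)

config = RunConfig(
    out_dir="example_output/run",
    conditions=("dna", "gapr", "mutant"),
    density_classes=("low", "high"),
    n_images=4,
    seed=1,
    write_images=False,
)
result = run_pipeline(config)

cols = ["condition", "density_class", "n_molecules", "n_junctions",
        "pct_molecules_with_junction", "mean_height_diff"]
print(result.summary[cols].round(3).to_string(index=False))
print()
print(result.comparisons.round(4).to_string(index=False))
print()
print("The bridging-protein condition carries the highest fraction of")
print("junction-bearing molecules at both densities; the binding-deficient")
print("mutant sits near bare DNA. On crowded fields the pooled height")
print("statistics are diluted by skeleton branch points where chains touch")
print("without crossing (no height excess) -- the controlled crossing of")
print("example 03 isolates the 0.86 vs 1.36 nm height signal. density_fold")
print("rows list (fold_inter high/low, fold_intra low/high) per condition.")
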