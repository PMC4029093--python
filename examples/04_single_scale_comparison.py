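"""Compare multiscale peak calling against the legacy single-scale mode.

The legacy mode reproduces the classic treatment: pooled counts, a raw
tag-count threshold (>= 30), per-cluster stability >= 2, length <= 200 bp
and collapse to outermost clusters only. The partition of gene-level DE
calls shows what the multi-scale, reproducibility-filtered analysis adds.
"""

import warnings

from cagepeaks import SimConfig, compare_modes, run_pipeline, simulate_ctss

warnings.filterwarnings("ignore")
sim = simulate_ctss(SimConfig(seed=4))
multiscale = run_pipeline(sim.tables, sim.truth.gene_tss)
legacy = run_pipeline(sim.tables, sim.truth.gene_tss, mode="legacy")

parts = compare_modes(multiscale, legacy)
print(f"genes called by both modes:      {len(parts['both'])}")
print(f"genes called only by multiscale: {len(parts['multiscale_only'])}")
print(f"genes called only by legacy:     {len(parts['legacy_only'])}")

truth = sim.truth.promoters
shift_genes = {
    f"gene{p:04d}" for p in truth.loc[truth['de_class'] == 'shift', 'promoter']
}
print(f"\nof the multiscale-only genes, "
      f"{len(parts['multiscale_only'] & shift_genes)} carry a planted sub-peak"
      f" shift (truth: {len(shift_genes)} shift genes)")
print(
    "\nThe multiscale-only set is dominated by sub-peak shifts: promoters"
    " whose total output is constant, invisible to a single outermost"
    " cluster, but clearly differential at the level of individual TSS."
)
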