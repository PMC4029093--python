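"""Detect differential TSS usage at two scales with the full pipeline.

Simulates two conditions in duplicate with planted effects — whole-promoter
fold changes and sub-peak shifts where fine-scale TSS usage moves while the
promoter's total output stays constant — then runs clustering, replicate
merging, IDR selection, top/bottom extraction and the NB exact test, and
scores recovery against the planted truth.
"""

import warnings

from cagepeaks import SimConfig, evaluate_shift_recovery, run_pipeline, simulate_ctss

warnings.filterwarnings("ignore")
sim = simulate_ctss(SimConfig(seed=2))
result = run_pipeline(sim.tables, sim.truth.gene_tss)

for entry in result.stage_log:
    print(entry)

top, bottom = result.de["top"], result.de["bottom"]
print(f"\nsignificant top peaks:    {int(top['significant'].sum())} / {len(top)}")
print(f"significant bottom peaks: {int(bottom['significant'].sum())} / {len(bottom)}")

called = result.genes.loc[result.genes["called"]]
print(f"differentially expressed genes: {len(called)}")
print(called["trigger"].value_counts().to_string())

ev = evaluate_shift_recovery(result, sim.truth)
print(f"\nplanted sub-peak shifts recovered: "
      f"{ev['n_recovered']:.0f}/{ev['n_shift_promoters']:.0f}")
print(
    "\nGenes triggered only by 'top' peaks changed their fine-scale TSS"
    " usage while the whole promoter (the 'bottom' peak) stayed flat —"
    " exactly the pattern a single-scale analysis misses."
)
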