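"""Extract counts for a pre-specified phenotype on new samples.

Thresholds standardized on one experiment can be applied to fresh data:
counts for a pre-specified marker combination (possibly partial, or with
coarsened levels such as '+' for dim-or-bright) are exact cell tallies
against the new samples' own standardized thresholds.
"""
import pandas as pd

import phenoforest as pf
from phenoforest.io_core import ExperimentDesign
from phenoforest.pipeline import PipelineConfig, run_discover, run_target

# five samples from one mixture design: discover on three, target the
# remaining two as "new" data
exp = pf.simulate_gaussian_experiment(3, n_samples=5, n_obs=4000, seed=21)
disc, held_out = exp.samples[:3], exp.samples[3:]
design = ExperimentDesign(
    pd.DataFrame({"sample": [s.sample_id for s in disc]})
)
res = run_discover(disc, design, PipelineConfig(n_trees=3, seed=2))

new_design = ExperimentDesign(
    pd.DataFrame({"sample": [s.sample_id for s in held_out]})
)
new_res = run_discover(held_out, new_design,
                       PipelineConfig(n_trees=3, seed=3))

# target the first phenotype discovered on the original data, restricted
# to markers that also carry thresholds in the new panel
full = res.selected_phenotypes[0]
parts = dict(zip(res.selected_markers, full.split(" ")))
common = [m for m in parts if m in new_res.spec]
full_cond = {m: [parts[m][len(m):]] for m in common}
m0 = common[0]
targets = {full: full_cond, f"{m0} positive only": {m0: ["+"]}}
cm = run_target(held_out, new_res.spec, targets)
print("targeted counts on the new samples:")
print(cm.counts)
print("\nEach row is a new sample; each column counts the cells matching "
      "every marker condition of that pre-specified phenotype.")
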