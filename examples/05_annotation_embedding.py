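"""Prepare expression data for an annotation embedding.

Each marker gets an equispaced landmark per expression level; every
annotation group is standardized and translated to its landmarks so that
groups cannot overlap.  Feeding the transformed matrix to a 2-D embedding
(e.g. UMAP) then yields islands that coincide with phenotypes.
"""
import numpy as np

import phenoforest as pf
from phenoforest.io_core import ExpressionMatrix
from phenoforest.standardization import standardize_all

rng = np.random.default_rng(3)
n = 3000
lab = rng.random(n) < 0.35
x0 = np.where(lab, rng.normal(8, 1, n), rng.normal(0, 1, n))
x1 = rng.normal(2, 1, n)
em = ExpressionMatrix("s1", ["CD4", "CD8"],
                      np.column_stack([x0, x1]), unit_id="s1")
spec = standardize_all({"CD4": {"s1": (4.0,)}, "CD8": {"s1": (4.0,)}})

out, labels, layout = pf.prepare_annotation_embedding(
    em, spec, ["CD4", "CD8"], seed=0
)
print("landmark grid per marker:", layout.landmarks)
for g in sorted(set(labels)):
    rows = [i for i, l in enumerate(labels) if l == g]
    lo, hi = out[rows, 0].min(), out[rows, 0].max()
    print(f"group {g}: CD4-axis support [{lo:.2f}, {hi:.2f}] "
          f"({len(rows)} cells)")
print("Supports of different CD4 levels occupy disjoint intervals around "
      "their landmarks (0 and 10), so a downstream embedding separates "
      "the phenotypes cleanly.")
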