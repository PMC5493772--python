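"""Gene-set enrichment of a hit list by the hypergeometric right tail.

Terms are filtered to 5-300 genes within the analysis universe, p-values are
Holm-adjusted, and a term passes at adjusted p <= 5e-4. The example plants a
hit list drawn almost entirely from one term.
"""

import numpy as np
import pandas as pd

import ykofit as yk

rng = np.random.default_rng(33)
universe = {f"gene{i:03d}" for i in range(400)}
terms = {
    "ribosome biogenesis": [f"gene{i:03d}" for i in range(0, 40)],
    "vacuolar transport": [f"gene{i:03d}" for i in range(40, 70)],
    "mitochondrial translation": [f"gene{i:03d}" for i in range(70, 120)],
}
annotations = pd.DataFrame(
    [{"term_id": f"T{j}", "term_name": name, "gene_id": g}
     for j, (name, genes) in enumerate(terms.items()) for g in genes]
)

# 15 hits from "vacuolar transport" plus 10 random genes
query = set(rng.choice(terms["vacuolar transport"], 15, replace=False))
query |= set(rng.choice(sorted(universe), 10, replace=False))

results = yk.hypergeometric_enrichment(query, universe, annotations)
for r in results:
    print(f"{r.term_name:28s} k={r.k:2d}/{r.K:3d} n={r.n} "
          f"p={r.p_raw:.3g} p_adj={r.p_adj:.3g} "
          f"{'PASS' if r.passed else 'ns'}")
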