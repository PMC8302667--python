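"""Gene-based association of a quantitative risk score with rare variants.

Simulates genotypes for 10 genes (one causal: its rare-variant burden
shifts the score), fits a covariate-adjusted inverse-Gaussian null model,
and runs the per-gene battery — Beta(1,25)-weighted burden and dispersion
tests by frequency partition, ultra-rare aggregation, single-variant tests
— combined with the aggregated Cauchy test.  The causal gene should stand
out; everything else should look null.
"""

import numpy as np
import pandas as pd

from qrs.genetics import fit_null_model, gene_combined_test, significance_threshold
from qrs.synthetic import CohortSpec, simulate_genotypes

spec = CohortSpec(n_subjects=3000, seed=4, causal_effects={"GENE03": 0.5})
blocks, increment = simulate_genotypes(spec)

rng = np.random.default_rng(4)
subjects = increment.index
score = pd.Series(increment.values + rng.standard_normal(len(subjects)), index=subjects)
covariates = pd.DataFrame(
    {
        "age": rng.uniform(30, 80, len(subjects)),
        "sex": rng.integers(0, 2, len(subjects)),
        **{f"PC{k}": rng.standard_normal(len(subjects)) for k in range(1, 11)},
    },
    index=subjects,
)

null = fit_null_model(score, covariates, family="inverse-gaussian")
print(f"null model family: {null.family} (shift {null.shift:.3f})")

rows = []
for gene, block in sorted(blocks.items()):
    res = gene_combined_test(null, block)
    rows.append({"gene": gene, "p.all": res.p_all, "p.common": res.p_common,
                 "p.rare": res.p_rare})
table = pd.DataFrame(rows).sort_values("p.all")
print(table.to_string(index=False, float_format=lambda v: f"{v:.3e}"))

thr = significance_threshold(0.05, 18000)
print(f"\nexome-wide significance threshold 0.05/18000 = {thr:.2e}")
print(f"genes below threshold: {list(table.loc[table['p.all'] < thr, 'gene'])}")
print("(the causal gene is GENE03; its signal sits in the rare partition)")
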