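"""Fit the three risk scores on a synthetic EHR cohort and compare them.

Simulates a latent-liability cohort with 20 disease-driving and 200
irrelevant phecodes, trains PheRS, LPC and PheNorm on half of the labeled
subjects, and reports out-of-sample AUROC for each score.  Higher AUROC
means the score ranks true cases above controls more reliably.
"""

import numpy as np

from qrs.evaluation import auroc
from qrs.features import build_presence_matrix, split_cohort
from qrs.pipeline import fit_model, score_model
from qrs.synthetic import CohortSpec, simulate_cohort

spec = CohortSpec(n_subjects=3000, n_relevant=20, n_noise=200, seed=1)
records, labels, staging, util, _ = simulate_cohort(spec)
print(f"cohort: {len(labels)} subjects, {len(records)} code-occurrence records")
print(f"labels: {labels.value_counts().to_dict()}")

presence = build_presence_matrix(
    records,
    roster=list(labels.index),
    features=spec.relevant_phecodes + spec.noise_phecodes,
)
train, test = split_cohort(labels, 0.5, seed=1)
known_test = [s for s in test if labels[s] in ("case", "control")]

for method in ("phers", "lpc", "phenorm"):
    model = fit_model(
        method,
        presence.subset_subjects(train),
        labels,
        case_phecodes=spec.case_defining_phecodes,
        util=util,
        seed=1,
        bootstrap=20_000,
        alpha_grid=np.round(np.arange(0, 2.01, 0.1), 2),
    )
    scores = score_model(
        model,
        presence.subset_subjects(known_test),
        case_phecodes=spec.case_defining_phecodes,
        util=util,
    )
    print(f"{method:8s} test AUROC = {auroc(scores, labels):.3f}")

# With this much irrelevant-feature noise the eigenvalue-weighted LPC score
# typically stays near its clean-feature accuracy, while the
# inverse-prevalence PheRS weighting loses ground.
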