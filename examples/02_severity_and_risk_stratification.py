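"""Use the LPC score for severity grading and risk stratification.

Correlates the fitted score with an ordinal disease staging (emulating
eGFR-based kidney-disease grades) and tabulates case prevalence across
score-percentile bins: a useful score concentrates nearly all cases in the
top bins.
"""

from qrs.evaluation import bin_prevalence, spearman_with_staging
from qrs.features import build_presence_matrix, split_cohort, standardize
from qrs.scores import fit_lpc, score_lpc
from qrs.synthetic import CohortSpec, simulate_cohort

spec = CohortSpec(n_subjects=3000, n_relevant=20, n_noise=100, seed=2)
records, labels, staging, util, _ = simulate_cohort(spec)
presence = build_presence_matrix(
    records,
    roster=list(labels.index),
    features=spec.relevant_phecodes + spec.noise_phecodes,
)
train, test = split_cohort(labels, 0.5, seed=2)
known = [s for s in test if labels[s] in ("case", "control")]

x_train = standardize(presence.subset_subjects(train))
model = fit_lpc(x_train, labels)
x_test = standardize(presence.subset_subjects(known), stats=x_train.stats())
scores = score_lpc(model, x_test)

rho, p = spearman_with_staging(scores, staging)
print(f"Spearman rho vs. staging = {rho:.3f} (p = {p:.2e})")
print("(positive rho: higher scores track more advanced disease stages)")

table = bin_prevalence(scores, labels, n_bins=10)
print("\ncase prevalence by score-percentile bin:")
for row in table.itertuples(index=False):
    bar = "#" * int(40 * row.prevalence)
    print(f"  bin {row.bin:2d} [{row.pct_low:5.1f}-{row.pct_high:5.1f}%] "
          f"prev {row.prevalence:5.3f} {bar}")
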