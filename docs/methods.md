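# Methods

## Problem setting

Given longitudinal code-occurrence records (subject, phecode, age at
observation), the package builds a binary presence matrix — phecode j is
present for subject i when it occurs at least `min_occurrences` times
(default 2, guarding against one-off miscoding) — and derives quantitative
disease risk scores as weighted linear sums of the (standardized) presence
indicators.  Absence of a phecode is ambiguous (never assessed vs. healthy),
which is why all three scores avoid treating absence as informative beyond
the linear form.  Standardization centers each column and divides by its
sample standard deviation (n−1 denominator); zero-variance columns are
dropped and recorded; training statistics are reapplied verbatim to test
subjects so train and test scores live on one scale.

## PheRS

Weights w_j = log(N/n_j) with n_j the count of reference subjects (training
controls) carrying phecode j.  A phecode absent from the reference is
smoothed to n_j = 1 rather than dropped, because test subjects may still
carry it; this is the only point where the weights can exceed log N.  The
score is the weight sum over present phecodes on the raw 0/1 scale.

## LPC

Q is the sample correlation matrix of the standardized training features;
its eigendecomposition gives loadings u_k and eigenvalues λ_k.  The score
uses the top K components weighted by their raw eigenvalues (not normalized
shares — scores differ only by a constant factor, and rank-based metrics are
unaffected).  Two free choices are resolved as follows:

* **K by sequential Tracy–Widom testing.**  At each step the leading
  remaining eigenvalue is normalized Patterson-style against the remaining
  m eigenvalues (l₁ = m λ / Σλ; centering and scaling from the
  Marchenko–Pastur edge with effective sample size n−1) and compared with
  the TW1 critical value at α = 0.05; testing stops at the first
  non-significant eigenvalue.  The TW1 distribution function is evaluated
  with the moment-matched shifted-gamma approximation
  TW1 ≈ Gamma(k≈46.446, θ≈0.18605) − 9.84801, which reproduces the published
  0.10/0.05/0.01/0.001 critical values within 0.04 — well below the
  Monte-Carlo noise of any component-count decision and smooth in α.  If no
  eigenvalue is significant the model scores everyone 0 and warns; callers
  can override K explicitly.
* **Component signs from weak labels.**  Eigenvector signs are arbitrary, so
  each component is oriented so the mean PC value among weakly-labeled cases
  is at least that among controls; exact ties keep +1.  This is the only
  use of labels in LPC.

The score is linear in the features, LPC_i = x_i·w with w = Σ λ_k s_k u_k;
`effective_feature_weights` exposes w for weight-enrichment comparisons.

## PheNorm

x_PHECODE is the per-subject count of case-defining phecodes and u the
utilization proxy (number of distinct ages in the code history).  The
normalized count z = log(1+x) − α log(1+u) should look like a two-component
equal-variance Gaussian mixture if α removes the utilization effect.  α is
chosen on a grid (default 0–2, step 0.01) by minimizing the
Kolmogorov–Smirnov distance between the empirical distribution of z and a
two-component tied-variance Gaussian mixture fitted by EM (k-means
initialization, 500 iterations, tolerance 1e-8); grid points where EM fails
are skipped with a warning.  The KS distance is this package's concrete
choice of "distance to the mixture approximation" — the objective is
deliberately simple and distribution-level rather than likelihood-based.

Denoising: α is selected on the full training set first; then one bootstrap
of B rows (default 1e5) is drawn with replacement from [z, candidate
features], corrupted entrywise (each entry kept with probability 1−r,
otherwise replaced by its column mean; r = 0.3 by default), and the
*uncorrupted* z is regressed on the corrupted matrix by OLS with intercept.
A rank-deficient design falls back to a minimal ridge (1e-8 on the
normal-equation diagonal) with a logged warning.  Scoring applies β to the
uncorrupted feature vector.  Candidate features are the standardized
presence values; case-defining phecodes are excluded from the candidates
(they enter only through the count), while PheRS and LPC exclude them from
their feature sets entirely.

## Evaluation

AUROC is the Mann–Whitney probability of a case outranking a control with
ties half-weighted; AUPRC is average precision (step interpolation — values
differ slightly from trapezoidal integration).  Severity validation is
Spearman correlation on midranks against an ordinal staging grade, p from
the large-sample approximation.  Bin prevalence ranks subjects by score
with stable tie-breaking and cuts them into bins whose sizes differ by at
most one; unknown-status subjects are excluded unless explicitly counted as
non-cases.  Weight enrichment uses the one-sided Wilcoxon rank-sum test
(exact enumeration when both groups have ≤10 members and no ties, otherwise
the tie-corrected normal approximation).

## PRS-based phecode pre-selection

The PRS is a plain weighted allele sum over a supplied weight table (log
relative risks); weight optimization is upstream and out of scope.  Each
phecode's presence is regressed on the standardized PRS by logistic
regression and retained at Wald p < 1e-5 (the Wald test is the package's
choice; the regression is unadjusted by default with a covariate hook).
Phecodes with zero or full prevalence are skipped with a warning rather
than penalized-fitted, keeping the behavior transparent.

## Gene-based association

The null model regresses the score on covariates (age, sex, genetic PCs)
under a GLM.  Right-skewed scores use the inverse-Gaussian family with a
log link (chosen over the canonical 1/μ² link for numerical stability); the
response is shifted to positive support by s′ = s − min(s) + 0.01·IQR *only
when* min(s) ≤ 0, so already-positive responses keep their scale and
planted covariate effects are recovered without distortion.
Non-convergence falls back to the Gaussian family with a warning.  If the
covariates reproduce the score to numerical precision the null is flagged
degenerate and every test returns p = 1.

Variant QC applies GATK-style hard filters (SNVs: QD < 2, MQ < 40, FS > 60,
SOR > 3, MQRankSum < −12.5, ReadPosRankSum < −8; indels: QD < 2,
ReadPosRankSum < −20, FS > 200, SOR > 10); absent metrics pass vacuously.
Dosages are oriented to the minor allele; MAF/MAC are computed on observed
calls before per-variant mean imputation of missing genotypes, so
missingness cannot move a variant between partitions.  Partitions are
disjoint with precedence: MAC 0 excluded; MAC < 5 ultra-rare regardless of
MAF; otherwise MAF ≥ 0.01 common/low-frequency (the boundary is assigned to
the common side), else rare.

All tests are GLM score tests against the shared null: burden collapses the
partition to a Beta(MAF; 1, 25)-weighted dosage sum (1-df chi-square);
dispersion uses Q = Σ w_j²(g_jᵀe)² with e the null score residuals, and the
null mixture-of-chi-squares is approximated by moment matching on
mean/variance/kurtosis (exact for a single eigenvalue, hence burden ≡
dispersion ≡ single-variant for one-variant partitions; accuracy degrades
in the far tail, p < 1e-8).  The ultra-rare test is an unweighted aggregate
dosage sum.  Functional-weighted rare tests multiply the Beta weight by the
supplied functional weight, restricted to flagged qualifying variants.
Single-variant tests cover the common and rare (MAC ≥ 5) partitions;
their p-values enter ACAT individually.  ACAT combines component p-values
via the tangent transform with equal weights and inputs clipped to
[1e-15, 1−1e-15]; p.all combines everything, p.common/p.rare the respective
sides.  Exome-wide significance defaults to 0.05/18 000 = 2.78e-06.

## Synthetic cohorts

The generator draws a latent liability L ~ N(0,1) per subject; relevant
phecodes are Bernoulli with logit a_j + b_j L + c·log(1+u), noise phecodes
share only the utilization term.  Defaults: 20 relevant (loading 1.5; the 2
case-defining phecodes 2.5) + 200 noise phecodes, intercepts −2.5/−2.2
(≈8–10% baseline prevalence), utilization from a shifted negative binomial
(mean 8 distinct ages, dispersion 2) with confounding strength c = 0.3 —
chosen as a mid-sized EHR slice where utilization confounding is material
but not dominant.  Labels threshold L at 1.0 (case) and 0.0 (control, the
band between being unknown), staging cutpoints 1.0/1.5/2.0/2.5 emulate an
ordinal severity grid.  Present phecodes emit 2 + Poisson(1) occurrence
records at ages drawn from the subject's personal age grid, so the
two-occurrence rule and the distinct-age utilization measure are both
exercised.  Genotypes are Hardy–Weinberg at MAFs log-uniform on
(0.001, 0.05); causal genes add effect × standardized Beta-weighted
rare-variant burden to the quantitative response; QC metrics are drawn
nominal with a configurable failure fraction.

What the generator does *not* emulate: real phecode hierarchies and their
correlation structure, visit-level temporal dynamics, informative
missingness beyond the utilization term, coding-practice drift, linkage
disequilibrium, and population structure.  Passing tests therefore show
that the algorithms behave as specified under the stated generative
assumptions, not that the scores attain any particular accuracy on real
EHR cohorts.

## Problem sizes and numerical choices

The test and acceptance runs use cohorts of 600–4 000 subjects, 60–220
phecodes, genes of 10–30 variants, 2 000 null replicates for calibration
(3·MC-SE bands), 50 replicates for the α-recovery check (grid step 0.1),
20 replicates for the robustness comparison, and PheNorm bootstraps of
2 000–50 000 rows — sizes at which every check is stable across seeds while
the whole suite stays desk-scale.  Eigendecompositions use symmetric
`eigh`; eigenvalues are clipped at zero; LPC loadings are orthonormal to
1e-8.  All simulation entry points take explicit seeds and are
deterministic given them.

## Known limitations

* The dispersion-test moment matching misstates extreme tails (p < 1e-8);
  rankings are unaffected but exact far-tail p-values would need Davies
  inversion.
* The TW1 shifted-gamma approximation introduces ≤1e-3 distortion in tail
  probability — irrelevant for component counting, but this module is not a
  general TW1 quantile oracle.
* α selection by KS distance is one defensible reading of "distance to the
  normal-mixture approximation"; likelihood- or moment-based objectives
  would pick slightly different exponents on discrete, low-count data.
* Binary-trait saddlepoint corrections, kinship adjustment, and genetic PC
  computation are out of scope; PCs arrive as covariates.
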