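"""PRS computation and PRS-driven pre-selection of disease-relevant phecodes.

A polygenic risk score is the weighted allele sum over a supplied weight
table (log relative risks from external GWAS; the weight optimization
itself is upstream and out of scope).  Pre-selection then regresses each
phecode's presence indicator on the standardized PRS by logistic regression
and keeps phecodes whose Wald p-value falls under a stringent threshold
(default 1e-5).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .features import PresenceMatrix

__all__ = ["read_prs_weights", "compute_prs", "preselect_phecodes"]


def read_prs_weights(path) -> pd.DataFrame:
    """Read a TSV of (variant_id, effect_allele, weight)."""
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "effect_allele", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"weights file missing columns: {sorted(missing)}")
    if not np.isfinite(df["weight"]).all():
        raise ValueError("non-finite PRS weights")
    return df


def compute_prs(dosages: pd.DataFrame, weights: pd.DataFrame) -> pd.Series:
    """PRS_i = sum_v dosage_iv * weight_v.

    ``dosages`` is subjects x variants with effect-allele dosages in [0, 2];
    ``weights`` holds variant_id and weight columns.  Every weighted variant
    must be present in the dosage matrix.
    """
    w = weights.set_index("variant_id")["weight"]
    missing = [v for v in w.index if v not in dosages.columns]
    if missing:
        raise ValueError(f"dosage matrix lacks weighted variants: {missing}")
    prs = dosages[list(w.index)].to_numpy(dtype=float) @ w.to_numpy(dtype=float)
    return pd.Series(prs, index=dosages.index, name="prs")


def preselect_phecodes(
    p: PresenceMatrix,
    prs: pd.Series,
    threshold: float = 1e-5,
    covariates: pd.DataFrame | None = None,
    min_overlap: int = 50,
) -> pd.DataFrame:
    """Per-phecode logistic regression against the PRS.

    For each phecode: presence ~ standardized PRS (+ optional covariates);
    the Wald p-value on the PRS coefficient decides retention at
    ``p < threshold``.  Phecodes with zero or full prevalence in the overlap
    cohort are skipped with a warning (separation).

    Returns a DataFrame (phecode, coefficient, p_value, selected) sorted by
    p-value.
    """
    common = [s for s in p.subjects if s in prs.index]
    if len(common) < min_overlap:
        raise ValueError(
            f"only {len(common)} subjects shared between matrix and PRS (need >= {min_overlap})"
        )
    sub = p.subset_subjects(common)
    x = prs.loc[common].to_numpy(dtype=float)
    x = (x - x.mean()) / x.std(ddof=1)
    design = np.column_stack([np.ones(len(x)), x])
    if covariates is not None:
        design = np.column_stack([design, covariates.loc[common].to_numpy(dtype=float)])

    rows = []
    for j, phecode in enumerate(sub.features):
        y = sub.values[:, j]
        prev = y.mean()
        if prev == 0.0 or prev == 1.0:
            warnings.warn(f"phecode {phecode} has degenerate prevalence; skipped", stacklevel=2)
            continue
        try:
            fit = sm.GLM(y, design, family=sm.families.Binomial()).fit()
            coef, pval = fit.params[1], fit.pvalues[1]
        except Exception as exc:
            warnings.warn(f"phecode {phecode} regression failed ({exc}); skipped", stacklevel=2)
            continue
        rows.append(
            {
                "phecode": phecode,
                "coefficient": float(coef),
                "p_value": float(pval),
                "selected": bool(pval < threshold),
            }
        )
    return pd.DataFrame(rows).sort_values("p_value", ignore_index=True)
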