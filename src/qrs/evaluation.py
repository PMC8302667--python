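"""Score evaluation: discrimination, severity correlation, bin prevalence,
and weight enrichment for disease-relevant phecodes.

AUROC is the Mann-Whitney probability that a random case outscores a random
control (ties half-weighted); AUPRC is average precision (step
interpolation).  Severity validation uses Spearman correlation against an
ordinal staging grade.  Bin prevalence splits the scored cohort into
equal-size percentile bins and reports the case fraction per bin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics

__all__ = [
    "auroc",
    "auprc",
    "spearman_with_staging",
    "bin_prevalence",
    "weight_enrichment_test",
    "roc_curve_points",
    "pr_curve_points",
]


def _aligned(scores: pd.Series, labels: pd.Series, keep=("case", "control")):
    labels = labels.astype(str)
    common = scores.index.intersection(labels.index)
    s = scores.loc[common]
    l = labels.loc[common]
    mask = l.isin(keep)
    return s[mask].to_numpy(dtype=float), (l[mask] == "case").to_numpy()


def auroc(scores: pd.Series, labels: pd.Series) -> float:
    """P(score_case > score_control) + 0.5 P(tie), the Mann-Whitney AUROC."""
    s, y = _aligned(scores, labels)
    if y.sum() == 0 or (~y).sum() == 0:
        raise ValueError("need at least one case and one control")
    return float(metrics.roc_auc_score(y, s))


def auprc(scores: pd.Series, labels: pd.Series) -> float:
    """Area under precision-recall as average precision."""
    s, y = _aligned(scores, labels)
    if y.sum() == 0:
        raise ValueError("need at least one case")
    return float(metrics.average_precision_score(y, s))


def roc_curve_points(scores: pd.Series, labels: pd.Series) -> pd.DataFrame:
    s, y = _aligned(scores, labels)
    fpr, tpr, thr = metrics.roc_curve(y, s)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def pr_curve_points(scores: pd.Series, labels: pd.Series) -> pd.DataFrame:
    s, y = _aligned(scores, labels)
    prec, rec, thr = metrics.precision_recall_curve(y, s)
    return pd.DataFrame(
        {"precision": prec, "recall": rec, "threshold": np.append(thr, np.nan)}
    )


def spearman_with_staging(scores: pd.Series, staging: pd.Series):
    """Spearman rho between scores and an ordinal severity grade.

    Returns ``(rho, p)``; p from the large-sample t approximation.
    """
    common = scores.index.intersection(staging.index)
    if len(common) < 3:
        raise ValueError("need at least 3 jointly observed subjects")
    g = pd.to_numeric(staging.loc[common])
    if g.nunique() < 2:
        raise ValueError("staging is constant")
    rho, p = stats.spearmanr(scores.loc[common], g)
    return float(rho), float(p)


def bin_prevalence(
    scores: pd.Series,
    labels: pd.Series,
    n_bins: int = 60,
    include_unknown_as_control: bool = False,
) -> pd.DataFrame:
    """Case prevalence in ``n_bins`` score-percentile bins.

    Subjects are ranked by score (ties broken by stable subject order) and
    cut into bins whose sizes differ by at most one.  Unknown-status
    subjects count as non-cases when ``include_unknown_as_control`` is set,
    else they are excluded.

    Returns a DataFrame with columns bin, pct_low, pct_high, n, n_cases,
    prevalence.
    """
    keep = ("case", "control", "unknown") if include_unknown_as_control else ("case", "control")
    labels = labels.astype(str).where(labels.astype(str).isin(["case", "control"]), "unknown")
    s, y = _aligned(scores, labels, keep=keep)
    n = len(s)
    if n < n_bins:
        raise ValueError(f"only {n} subjects for {n_bins} bins; reduce n_bins")
    order = np.argsort(s, kind="stable")
    bin_of = np.empty(n, dtype=int)
    # equal-size bins: first (n % n_bins) bins get one extra subject
    edges = np.linspace(0, n, n_bins + 1).round().astype(int)
    for b in range(n_bins):
        bin_of[order[edges[b]:edges[b + 1]]] = b
    rows = []
    for b in range(n_bins):
        mask = bin_of == b
        nb = int(mask.sum())
        nc = int(y[mask].sum())
        rows.append(
            {
                "bin": b + 1,
                "pct_low": 100.0 * edges[b] / n,
                "pct_high": 100.0 * edges[b + 1] / n,
                "n": nb,
                "n_cases": nc,
                "prevalence": nc / nb if nb else np.nan,
            }
        )
    return pd.DataFrame(rows)


def weight_enrichment_test(weights: pd.Series, relevant) -> float:
    """One-sided Wilcoxon rank-sum p-value that relevant features get larger
    weights than the rest.

    Exact enumeration when both groups have at most 10 members and no ties;
    otherwise the normal approximation with tie correction.
    """
    relevant = [f for f in relevant if f in weights.index]
    rest = [f for f in weights.index if f not in set(relevant)]
    if len(relevant) == 0 or len(rest) == 0:
        raise ValueError("both feature groups must be non-empty")
    a = weights.loc[relevant].to_numpy(dtype=float)
    b = weights.loc[rest].to_numpy(dtype=float)
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 10 and len(b) <= 10 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="greater", method=method)
    return float(res.pvalue)
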