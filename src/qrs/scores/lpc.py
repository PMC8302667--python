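"""Eigenvalue-weighted linear combination of principal components (LPC).

The score for subject i is sum_k lambda_k s_k PC_ik over the K significant
components of the phecode correlation matrix Q, where PC = X U with X the
standardized feature matrix and U the eigenvectors of Q.  K comes from the
sequential Tracy-Widom test; the sign s_k of each component is fixed so the
mean component value among weakly-labeled cases exceeds that among controls
(the signs of eigenvectors being otherwise arbitrary).  The score is linear
in the features: LPC_i = x_i . w with w = sum_k lambda_k s_k u_k, which is
how per-phecode weights are reported.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..features import StandardizedFeatureMatrix
from .tracy_widom import tracy_widom_k

logger = logging.getLogger(__name__)

__all__ = ["LPCModel", "fit_lpc", "score_lpc", "effective_feature_weights"]


@dataclass
class LPCModel:
    features: list
    col_means: np.ndarray
    col_sds: np.ndarray
    loadings: np.ndarray  # J x K orthonormal columns
    eigenvalues: np.ndarray  # length K, non-increasing, positive
    signs: np.ndarray  # length K, +/-1
    n_components: int

    def stats(self):
        return (
            pd.Series(self.col_means, index=self.features),
            pd.Series(self.col_sds, index=self.features),
        )

    def to_json(self) -> dict:
        return {
            "kind": "lpc",
            "features": list(self.features),
            "col_means": [float(v) for v in self.col_means],
            "col_sds": [float(v) for v in self.col_sds],
            "loadings": np.asarray(self.loadings).tolist(),
            "eigenvalues": [float(v) for v in self.eigenvalues],
            "signs": [int(v) for v in self.signs],
            "n_components": int(self.n_components),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "LPCModel":
        return cls(
            list(obj["features"]),
            np.asarray(obj["col_means"], float),
            np.asarray(obj["col_sds"], float),
            np.asarray(obj["loadings"], float),
            np.asarray(obj["eigenvalues"], float),
            np.asarray(obj["signs"], int),
            int(obj["n_components"]),
        )

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1)


def fit_lpc(
    x: StandardizedFeatureMatrix,
    labels: pd.Series,
    alpha: float = 0.05,
    n_components: int | None = None,
) -> LPCModel:
    """Fit the LPC model on a standardized training matrix.

    Parameters
    ----------
    x
        Standardized feature matrix (training mode, own statistics).
    labels
        Weak labels ("case"/"control"/other) indexed by subject id; used only
        to orient component signs.
    alpha
        Significance level of the Tracy-Widom component-count test.
    n_components
        Override the Tracy-Widom choice of K (e.g., for diagnostics).
    """
    X = x.values
    n, J = X.shape
    # columns are standardized with the n-1 convention, so Q = X'X/(n-1)
    Q = (X.T @ X) / (n - 1)
    evals, evecs = np.linalg.eigh(Q)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]

    if n_components is None:
        K = tracy_widom_k(evals, n, alpha)
        if K == 0:
            logger.warning(
                "Tracy-Widom test found no significant eigenvalues; LPC scores will be 0"
            )
    else:
        K = int(n_components)
        if not 0 < K <= J:
            raise ValueError("n_components must be in 1..J")

    labels = labels.astype(str)
    case_ids = [s for s in x.subjects if labels.get(s) == "case"]
    control_ids = [s for s in x.subjects if labels.get(s) == "control"]
    if len(case_ids) == 0 or len(control_ids) == 0:
        raise ValueError("need at least one labeled case and one labeled control")
    sub_idx = {s: i for i, s in enumerate(x.subjects)}
    case_rows = [sub_idx[s] for s in case_ids]
    control_rows = [sub_idx[s] for s in control_ids]

    U = evecs[:, :K]
    PC = X @ U
    signs = np.ones(K, dtype=int)
    for k in range(K):
        if PC[case_rows, k].mean() < PC[control_rows, k].mean():
            signs[k] = -1

    return LPCModel(
        list(x.features),
        np.asarray(x.col_means, float),
        np.asarray(x.col_sds, float),
        U,
        evals[:K],
        signs,
        K,
    )


def score_lpc(model: LPCModel, x: StandardizedFeatureMatrix) -> pd.Series:
    """LPC_i = sum_k lambda_k s_k (x_i . u_k); x must be on the model's scale."""
    if list(x.features) != list(model.features):
        raise ValueError("feature set/order mismatch with fitted model")
    if model.n_components == 0:
        return pd.Series(np.zeros(len(x.subjects)), index=x.subjects, name="lpc")
    PC = x.values @ model.loadings
    scores = PC @ (model.eigenvalues * model.signs)
    return pd.Series(scores, index=x.subjects, name="lpc")


def effective_feature_weights(model: LPCModel) -> pd.Series:
    """Per-feature weights w = sum_k lambda_k s_k u_k of the linear form."""
    if model.n_components == 0:
        w = np.zeros(len(model.features))
    else:
        w = model.loadings @ (model.eigenvalues * model.signs)
    return pd.Series(w, index=model.features, name="lpc_weight")
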