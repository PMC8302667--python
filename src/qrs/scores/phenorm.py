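"""PheNorm: utilization-normalized phecode counts denoised by dropout regression.

The raw count of case-defining phecodes x_PHECODE is inflated for subjects
with heavy healthcare contact regardless of true disease status, so it is
normalized against a utilization proxy u (distinct ages-at-observation):

    z = log(1 + x_PHECODE) - alpha * log(1 + u)

with alpha chosen so that z best resembles a two-component Gaussian mixture
(the implied latent case/control structure).  A denoising step then
regresses z on a randomly corrupted copy of the full feature matrix
[z, candidate features] over a large bootstrap; the fitted coefficients
define the final score z_i' beta on uncorrupted features.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from ..features import StandardizedFeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PheNormModel",
    "phenorm_normalize",
    "select_alpha",
    "corrupt_matrix",
    "fit_phenorm",
    "score_phenorm",
]

DEFAULT_ALPHA_GRID = np.round(np.arange(0.0, 2.0 + 1e-9, 0.01), 2)


@dataclass
class PheNormModel:
    candidate_features: list
    col_means: np.ndarray  # scaling stats of candidate features
    col_sds: np.ndarray
    alpha: float
    dropout_rate: float
    beta: np.ndarray  # intercept followed by [z, candidates] coefficients
    bootstrap_size: int
    seed: int

    def stats(self):
        return (
            pd.Series(self.col_means, index=self.candidate_features),
            pd.Series(self.col_sds, index=self.candidate_features),
        )

    def to_json(self) -> dict:
        return {
            "kind": "phenorm",
            "candidate_features": list(self.candidate_features),
            "col_means": [float(v) for v in self.col_means],
            "col_sds": [float(v) for v in self.col_sds],
            "alpha": float(self.alpha),
            "dropout_rate": float(self.dropout_rate),
            "beta": [float(v) for v in self.beta],
            "bootstrap_size": int(self.bootstrap_size),
            "seed": int(self.seed),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "PheNormModel":
        return cls(
            list(obj["candidate_features"]),
            np.asarray(obj["col_means"], float),
            np.asarray(obj["col_sds"], float),
            float(obj["alpha"]),
            float(obj["dropout_rate"]),
            np.asarray(obj["beta"], float),
            int(obj["bootstrap_size"]),
            int(obj["seed"]),
        )

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1)


def phenorm_normalize(counts, utilization, alpha: float) -> np.ndarray:
    """z = log(1 + count) - alpha * log(1 + utilization), elementwise."""
    x = np.asarray(counts, dtype=float)
    u = np.asarray(utilization, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    return np.log1p(x) - alpha * np.log1p(u)


def _mixture_ks_distance(z: np.ndarray, seed: int = 0) -> float:
    """KS distance between z and its fitted 2-component equal-variance mixture."""
    gm = GaussianMixture(
        n_components=2,
        covariance_type="tied",
        tol=1e-8,
        max_iter=500,
        init_params="kmeans",
        random_state=seed,
    )
    gm.fit(z.reshape(-1, 1))
    if not gm.converged_:
        raise RuntimeError("EM did not converge")
    w = gm.weights_
    mu = gm.means_.ravel()
    sd = float(np.sqrt(gm.covariances_.ravel()[0]))

    def cdf(t):
        return w[0] * stats.norm.cdf(t, mu[0], sd) + w[1] * stats.norm.cdf(t, mu[1], sd)

    return stats.kstest(z, cdf).statistic


def select_alpha(counts, utilization, grid=None, seed: int = 0) -> float:
    """Pick the normalization exponent minimizing mixture misfit.

    For each alpha in the grid a two-component equal-variance Gaussian
    mixture is fitted to z(alpha) by EM, and the Kolmogorov-Smirnov distance
    between the empirical distribution of z and the fitted mixture is the
    misfit; the minimizing alpha wins.  Grid points where EM fails are
    skipped with a warning.
    """
    grid = DEFAULT_ALPHA_GRID if grid is None else np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("alpha grid is empty")
    best_alpha, best_d = None, np.inf
    for a in grid:
        z = phenorm_normalize(counts, utilization, a)
        try:
            d = _mixture_ks_distance(z, seed=seed)
        except Exception as exc:  # EM failure at this grid point only
            warnings.warn(f"alpha={a:g} skipped: {exc}", stacklevel=2)
            continue
        if d < best_d:
            best_alpha, best_d = float(a), d
    if best_alpha is None:
        raise RuntimeError("mixture fit failed at every alpha in the grid")
    return best_alpha


def corrupt_matrix(Z: np.ndarray, r: float, seed: int) -> np.ndarray:
    """Dropout corruption: each entry kept with probability 1 - r, otherwise
    replaced by its column mean.  Deterministic given seed."""
    if not 0 <= r < 1:
        raise ValueError("dropout rate must satisfy 0 <= r < 1")
    Z = np.asarray(Z, dtype=float)
    if r == 0:
        return Z.copy()
    rng = np.random.default_rng(seed)
    keep = rng.random(Z.shape) >= r
    col_means = Z.mean(axis=0)
    return np.where(keep, Z, col_means[np.newaxis, :])


def fit_phenorm(
    x_candidates: StandardizedFeatureMatrix,
    case_code_counts,
    utilization,
    r: float = 0.3,
    B: int = 100_000,
    seed: int = 0,
    alpha: float | None = None,
    alpha_grid=None,
) -> PheNormModel:
    """Train PheNorm on a standardized candidate-feature matrix.

    The case-defining phecodes enter only through ``case_code_counts`` (their
    per-subject count); they must not appear among the candidate features.
    alpha is selected on the full training set first, then a single bootstrap
    of B rows is drawn, corrupted at dropout rate r, and the uncorrupted
    normalized count z is regressed on the corrupted [z, candidates] by OLS.
    """
    if not 0 <= r < 1:
        raise ValueError("dropout rate must satisfy 0 <= r < 1")
    x = np.asarray(case_code_counts, dtype=float)
    u = np.asarray(utilization, dtype=float)
    n = len(x_candidates.subjects)
    if not (len(x) == len(u) == n):
        raise ValueError("counts/utilization must align with the candidate matrix rows")

    if alpha is None:
        alpha = select_alpha(x, u, grid=alpha_grid, seed=seed)
    z = phenorm_normalize(x, u, alpha)

    Z = np.column_stack([z, x_candidates.values])
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, n, size=int(B))
    Zb = Z[rows]
    Zb_tilde = corrupt_matrix(Zb, r, seed=int(rng.integers(0, 2**31 - 1)))
    y = Zb[:, 0]

    design = np.column_stack([np.ones(len(y)), Zb_tilde])
    try:
        beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rank < design.shape[1]:
            raise np.linalg.LinAlgError("rank deficient")
    except np.linalg.LinAlgError:
        logger.warning("singular denoising design; falling back to minimal ridge")
        G = design.T @ design + 1e-8 * np.eye(design.shape[1])
        beta = np.linalg.solve(G, design.T @ y)

    return PheNormModel(
        list(x_candidates.features),
        np.asarray(x_candidates.col_means, float),
        np.asarray(x_candidates.col_sds, float),
        float(alpha),
        float(r),
        beta,
        int(B),
        int(seed),
    )


def score_phenorm(
    model: PheNormModel,
    x_candidates: StandardizedFeatureMatrix,
    case_code_counts,
    utilization,
) -> pd.Series:
    """Score = [1, z, candidates] . beta on UNcorrupted features."""
    if list(x_candidates.features) != list(model.candidate_features):
        raise ValueError("candidate feature mismatch with fitted model")
    x = np.asarray(case_code_counts, dtype=float)
    u = np.asarray(utilization, dtype=float)
    z = phenorm_normalize(x, u, model.alpha)
    design = np.column_stack([np.ones(len(z)), z, x_candidates.values])
    return pd.Series(design @ model.beta, index=x_candidates.subjects, name="phenorm")
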