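"""Phenotype risk score: log inverse-prevalence weighting of present phecodes."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..features import PresenceMatrix

__all__ = ["PheRSModel", "fit_phers", "score_phers"]


@dataclass
class PheRSModel:
    """Per-phecode weights w_j = log(N / n_j) from a reference cohort.

    N is the reference cohort size and n_j the number of reference subjects
    carrying phecode j, so rarer phecodes get larger weights.  A phecode
    absent from the reference (n_j = 0) is smoothed to n_j = 1 to keep the
    weight finite.
    """

    features: list
    weights: np.ndarray
    n_reference: int

    def to_json(self) -> dict:
        return {
            "kind": "phers",
            "features": list(self.features),
            "weights": [float(w) for w in self.weights],
            "n_reference": int(self.n_reference),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "PheRSModel":
        return cls(list(obj["features"]), np.asarray(obj["weights"], float), int(obj["n_reference"]))

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1)


def fit_phers(p: PresenceMatrix, reference_ids) -> PheRSModel:
    """Estimate PheRS weights from the reference (typically training controls).

    w_j = log(N / n_j); n_j = 0 is smoothed to 1.
    """
    reference_ids = list(reference_ids)
    if len(reference_ids) == 0:
        raise ValueError("reference cohort is empty")
    ref = p.subset_subjects(reference_ids)
    N = len(reference_ids)
    n_j = ref.values.sum(axis=0)
    n_j = np.where(n_j == 0, 1.0, n_j)
    weights = np.log(N / n_j)
    return PheRSModel(list(p.features), weights, N)


def score_phers(model: PheRSModel, p: PresenceMatrix) -> pd.Series:
    """Sum of weights over phecodes present for each subject."""
    missing = set(model.features) - set(p.features)
    if missing:
        raise ValueError(f"matrix lacks model features: {sorted(missing)}")
    sub = p.subset_features(model.features)
    scores = sub.values @ model.weights
    return pd.Series(scores, index=p.subjects, name="phers")
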