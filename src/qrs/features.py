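"""Phecode feature-matrix construction and standardization.

Raw EHR billing-code histories arrive as long-format occurrence records
(subject, phecode, age at observation).  A phecode counts as *present* for a
subject only when it occurs at least ``min_occurrences`` times (default 2),
which guards against one-off miscodings.  The resulting binary presence
matrix is the input to every score; the principal-component score
additionally requires columns centered and scaled to unit sample standard
deviation, with the training-set statistics reapplied verbatim to test
subjects.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PresenceMatrix",
    "StandardizedFeatureMatrix",
    "build_presence_matrix",
    "standardize",
    "utilization",
    "split_cohort",
    "read_occurrences",
    "map_codes_to_phecodes",
]


@dataclass
class PresenceMatrix:
    """Binary subjects x phecodes matrix of qualifying code presence."""

    subjects: list
    features: list
    values: np.ndarray  # n x J, {0,1} float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.subjects)) != len(self.subjects):
            raise ValueError("duplicate subject ids")
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate feature ids")
        if self.values.shape != (len(self.subjects), len(self.features)):
            raise ValueError("matrix shape does not match subjects/features")
        bad = ~np.isin(self.values, (0.0, 1.0))
        if bad.any():
            raise ValueError("presence matrix entries must be 0 or 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subjects, columns=self.features)

    def subset_subjects(self, ids) -> "PresenceMatrix":
        idx = {s: i for i, s in enumerate(self.subjects)}
        rows = [idx[s] for s in ids]
        return PresenceMatrix(list(ids), list(self.features), self.values[rows])

    def subset_features(self, feats) -> "PresenceMatrix":
        idx = {f: j for j, f in enumerate(self.features)}
        cols = [idx[f] for f in feats]
        return PresenceMatrix(list(self.subjects), list(feats), self.values[:, cols])


@dataclass
class StandardizedFeatureMatrix:
    """Centered/unit-variance feature matrix with its scaling statistics.

    ``col_means``/``col_sds`` are stored so test subjects can be placed on
    the training scale; zero-variance columns are dropped and recorded in
    ``dropped_features``.
    """

    subjects: list
    features: list
    values: np.ndarray
    col_means: np.ndarray
    col_sds: np.ndarray
    dropped_features: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subjects, columns=self.features)

    def stats(self) -> tuple[pd.Series, pd.Series]:
        return (
            pd.Series(self.col_means, index=self.features),
            pd.Series(self.col_sds, index=self.features),
        )

    def save(self, matrix_path, sidecar_path) -> None:
        self.to_frame().to_csv(matrix_path, sep="\t", index_label="subject_id")
        sidecar = {
            "features": list(self.features),
            "col_means": [float(v) for v in self.col_means],
            "col_sds": [float(v) for v in self.col_sds],
            "dropped_features": list(self.dropped_features),
        }
        with open(sidecar_path, "w") as fh:
            json.dump(sidecar, fh, indent=1)


def read_occurrences(path, sep=None) -> pd.DataFrame:
    """Read a delimited occurrence file with columns subject_id, phecode, age.

    The delimiter is sniffed (tab vs comma) unless given.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    required = {"subject_id", "phecode", "age"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"occurrence file missing columns: {sorted(missing)}")
    return df.rename(columns={"age": "age_at_observation"})


def map_codes_to_phecodes(records: pd.DataFrame, code_map: pd.DataFrame) -> pd.DataFrame:
    """Translate raw billing codes to phecodes via a two-column (code, phecode) map.

    Records whose code has no mapping are dropped with a logged count.
    """
    merged = records.merge(
        code_map.rename(columns={code_map.columns[0]: "code", code_map.columns[1]: "phecode"}),
        left_on=records.columns[1],
        right_on="code",
        how="left",
    )
    n_unmapped = merged["phecode"].isna().sum()
    if n_unmapped:
        logger.warning("%d records had codes with no phecode mapping; dropped", n_unmapped)
    out = merged.dropna(subset=["phecode"])
    return pd.DataFrame(
        {
            "subject_id": out.iloc[:, 0].values,
            "phecode": out["phecode"].values,
            "age_at_observation": out["age_at_observation"].values,
        }
    )


def _clean_records(records: pd.DataFrame) -> pd.DataFrame:
    records = records.copy()
    neg = records["age_at_observation"] < 0
    if neg.any():
        warnings.warn(f"dropping {int(neg.sum())} records with negative age", stacklevel=3)
        records = records[~neg]
    empty = records["phecode"].astype(str).str.len() == 0
    if empty.any():
        raise ValueError("empty phecode identifiers in records")
    return records


def build_presence_matrix(
    records: pd.DataFrame,
    min_occurrences: int = 2,
    roster=None,
    features=None,
) -> PresenceMatrix:
    """Binary presence matrix: entry (i, j) = 1 iff subject i has at least
    ``min_occurrences`` occurrence records of phecode j.

    Parameters
    ----------
    records
        Long-format DataFrame with columns subject_id, phecode,
        age_at_observation.  Records with negative age are rejected with a
        warning.
    min_occurrences
        Occurrence threshold for presence (default 2).
    roster
        Optional explicit subject list; subjects without qualifying codes get
        all-zero rows.  Defaults to the subjects seen in ``records``.
    features
        Optional explicit phecode list (columns); defaults to phecodes seen.
    """
    if min_occurrences < 1:
        raise ValueError("min_occurrences must be a positive integer")
    records = _clean_records(records)
    if len(records) == 0 and roster is None:
        raise ValueError("empty record set and no subject roster supplied")

    counts = records.groupby(["subject_id", "phecode"], sort=False).size()
    present = counts[counts >= min_occurrences]

    subjects = list(roster) if roster is not None else sorted(records["subject_id"].unique())
    if features is not None:
        feats = list(features)
    else:
        feats = sorted(records["phecode"].unique())
    if len(subjects) == 0:
        raise ValueError("empty subject roster")

    sub_idx = {s: i for i, s in enumerate(subjects)}
    feat_idx = {f: j for j, f in enumerate(feats)}
    values = np.zeros((len(subjects), len(feats)))
    for (s, p) in present.index:
        i = sub_idx.get(s)
        j = feat_idx.get(p)
        if i is not None and j is not None:
            values[i, j] = 1.0
    return PresenceMatrix(subjects, feats, values)


def standardize(p: PresenceMatrix, stats=None) -> StandardizedFeatureMatrix:
    """Center each column and scale by its sample standard deviation (n-1).

    With ``stats`` (a ``(means, sds)`` pair of Series indexed by feature, as
    returned by :meth:`StandardizedFeatureMatrix.stats`), the supplied
    training statistics are applied instead — the test-set mode.  In
    training mode zero-variance columns are dropped and recorded.
    """
    X = p.values
    if stats is not None:
        means, sds = stats
        feats = list(means.index)
        missing = set(feats) - set(p.features)
        if missing:
            raise ValueError(f"matrix lacks features required by stats: {sorted(missing)}")
        sub = p.subset_features(feats)
        mu = means.to_numpy(dtype=float)
        sd = sds.to_numpy(dtype=float)
        if (sd <= 0).any():
            raise ValueError("supplied col_sds must be positive")
        vals = (sub.values - mu) / sd
        return StandardizedFeatureMatrix(sub.subjects, feats, vals, mu, sd, [])

    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
    keep = sd > 0
    if not keep.any():
        raise ValueError("all feature columns have zero variance")
    dropped = [f for f, k in zip(p.features, keep) if not k]
    if dropped:
        logger.info("dropped %d zero-variance features", len(dropped))
    feats = [f for f, k in zip(p.features, keep) if k]
    vals = (X[:, keep] - mu[keep]) / sd[keep]
    return StandardizedFeatureMatrix(list(p.subjects), feats, vals, mu[keep], sd[keep], dropped)


def utilization(records: pd.DataFrame, roster=None) -> pd.Series:
    """Healthcare-utilization proxy: distinct ages-at-observation per subject.

    Subjects on the roster with no records get count 0.
    """
    records = _clean_records(records)
    counts = records.groupby("subject_id")["age_at_observation"].nunique()
    if roster is not None:
        counts = counts.reindex(list(roster), fill_value=0)
    return counts.astype(int).rename("utilization")


def split_cohort(labels: pd.Series, case_fraction: float, seed: int):
    """Stratified train/test split of a weak-label cohort.

    ``case_fraction`` of cases and the same fraction of controls go to
    training; unknown-status subjects always go to the test set.

    Returns ``(train_ids, test_ids)`` as lists, deterministic given ``seed``.
    """
    if not 0 < case_fraction < 1:
        raise ValueError("case_fraction must be in (0, 1)")
    labels = labels.astype(str)
    cases = labels.index[labels == "case"].tolist()
    controls = labels.index[labels == "control"].tolist()
    unknown = labels.index[~labels.isin(["case", "control"])].tolist()
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("need at least 2 cases and 2 controls to split")
    rng = np.random.default_rng(seed)
    train = []
    test = list(unknown)
    for group in (cases, controls):
        k = int(round(case_fraction * len(group)))
        k = max(1, min(k, len(group) - 1))
        perm = rng.permutation(len(group))
        train.extend(group[i] for i in perm[:k])
        test.extend(group[i] for i in perm[k:])
    return train, test
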