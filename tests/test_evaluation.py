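import itertools

import numpy as np
import pandas as pd
import pytest

from qrs.evaluation import (
    auprc,
    auroc,
    bin_prevalence,
    spearman_with_staging,
    weight_enrichment_test,
)


def brute_force_auroc(scores, labels):
    """O(n_case * n_control) pair-counting oracle."""
    cases = [s for s, l in zip(scores, labels) if l == "case"]
    controls = [s for s, l in zip(scores, labels) if l == "control"]
    total = wins = 0
    for c, k in itertools.product(cases, controls):
        total += 1
        wins += 1.0 if c > k else (0.5 if c == k else 0.0)
    return wins / total


def brute_force_average_precision(scores, labels):
    """Exhaustive threshold-sweep oracle for average precision."""
    y = np.asarray([l == "case" for l in labels])
    s = np.asarray(scores, float)
    order = np.argsort(-s, kind="stable")
    y = y[order]
    s = s[order]
    ap, tp = 0.0, 0
    n_pos = y.sum()
    i = 0
    prev_recall = 0.0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        tp += y[i:j].sum()
        precision = tp / j
        recall = tp / n_pos
        ap += precision * (recall - prev_recall)
        prev_recall = recall
        i = j
    return ap


class TestAuroc:
    def test_small_worked_example_vs_oracle(self):
        scores = [3, 2, 1, 2, 0]
        labels = ["case", "case", "case", "control", "control"]
        expected = brute_force_auroc(scores, labels)
        assert expected == pytest.approx(4.5 / 6)  # 4 wins + 1 tie of 6 pairs
        s = pd.Series(scores, index=list("abcde"))
        l = pd.Series(labels, index=list("abcde"))
        assert auroc(s, l) == pytest.approx(expected, abs=1e-12)

    def test_oracle_agreement_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 200))
            scores = rng.choice(np.arange(10), size=n).astype(float)
            labels = rng.choice(["case", "control"], size=n)
            if (labels == "case").sum() == 0 or (labels == "control").sum() == 0:
                continue
            idx = [f"s{i}" for i in range(n)]
            got = auroc(pd.Series(scores, index=idx), pd.Series(labels, index=idx))
            assert got == pytest.approx(brute_force_auroc(scores, labels), abs=1e-12)

    def test_perfect_separation(self):
        s = pd.Series([5, 4, 1, 0], index=list("abcd"))
        l = pd.Series(["case", "case", "control", "control"], index=list("abcd"))
        assert auroc(s, l) == 1.0

    def test_monotone_transform_invariance(self, rng):
        n = 100
        idx = [f"s{i}" for i in range(n)]
        s = pd.Series(rng.standard_normal(n), index=idx)
        l = pd.Series(rng.choice(["case", "control"], size=n), index=idx)
        assert auroc(s, l) == pytest.approx(auroc(np.exp(s), l), abs=1e-12)

    def test_one_class_errors(self):
        s = pd.Series([1, 2], index=list("ab"))
        with pytest.raises(ValueError):
            auroc(s, pd.Series(["case", "case"], index=list("ab")))


class TestAuprc:
    def test_perfect_separation(self):
        s = pd.Series([5, 4, 1, 0], index=list("abcd"))
        l = pd.Series(["case", "case", "control", "control"], index=list("abcd"))
        assert auprc(s, l) == 1.0

    def test_random_scores_near_prevalence(self, rng):
        n = 4000
        idx = [f"s{i}" for i in range(n)]
        s = pd.Series(rng.standard_normal(n), index=idx)
        l = pd.Series(np.where(rng.random(n) < 0.2, "case", "control"), index=idx)
        assert auprc(s, l) == pytest.approx(0.2, abs=0.05)

    def test_oracle_agreement(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 60))
            scores = rng.choice(np.arange(6), size=n).astype(float)
            labels = rng.choice(["case", "control"], size=n)
            if (labels == "case").sum() == 0:
                continue
            idx = [f"s{i}" for i in range(n)]
            got = auprc(pd.Series(scores, index=idx), pd.Series(labels, index=idx))
            expected = brute_force_average_precision(scores, labels)
            assert got == pytest.approx(expected, abs=1e-10)


class TestSpearman:
    def test_perfect_and_reversed(self):
        idx = [f"s{i}" for i in range(10)]
        s = pd.Series(np.arange(10, dtype=float), index=idx)
        g = pd.Series(np.arange(10), index=idx)
        assert spearman_with_staging(s, g)[0] == pytest.approx(1.0)
        assert spearman_with_staging(s, g[::-1].set_axis(idx))[0] == pytest.approx(-1.0)

    def test_tied_heavy_vs_rank_formula(self):
        idx = [f"s{i}" for i in range(8)]
        s = pd.Series([1, 1, 2, 2, 3, 3, 4, 4], index=idx, dtype=float)
        g = pd.Series([0, 0, 0, 1, 1, 1, 2, 2], index=idx)
        # Pearson correlation of midranks as the oracle
        rs = s.rank()
        rg = g.rank()
        expected = np.corrcoef(rs, rg)[0, 1]
        assert spearman_with_staging(s, g)[0] == pytest.approx(expected, abs=1e-12)

    def test_constant_staging_errors(self):
        idx = list("abc")
        with pytest.raises(ValueError):
            spearman_with_staging(
                pd.Series([1.0, 2.0, 3.0], index=idx), pd.Series([1, 1, 1], index=idx)
            )


class TestBinPrevalence:
    def test_scores_equal_labels_two_bins(self):
        idx = [f"s{i}" for i in range(10)]
        l = pd.Series(["control"] * 5 + ["case"] * 5, index=idx)
        s = pd.Series([0.0] * 5 + [1.0] * 5, index=idx)
        tab = bin_prevalence(s, l, n_bins=2)
        assert list(tab["prevalence"]) == [0.0, 1.0]

    def test_all_cases(self):
        idx = [f"s{i}" for i in range(12)]
        l = pd.Series("case", index=idx)
        s = pd.Series(np.arange(12, dtype=float), index=idx)
        tab = bin_prevalence(s, l, n_bins=3)
        assert (tab["prevalence"] == 1.0).all()

    def test_case_conservation_and_bin_sizes(self, rng):
        n = 123
        idx = [f"s{i}" for i in range(n)]
        l = pd.Series(rng.choice(["case", "control"], size=n), index=idx)
        s = pd.Series(rng.standard_normal(n), index=idx)
        tab = bin_prevalence(s, l, n_bins=10)
        assert tab["n_cases"].sum() == (l == "case").sum()
        assert tab["n"].max() - tab["n"].min() <= 1

    def test_uniform_scores_flat_prevalence(self, rng):
        n = 6000
        idx = [f"s{i}" for i in range(n)]
        l = pd.Series(np.where(rng.random(n) < 0.3, "case", "control"), index=idx)
        s = pd.Series(rng.random(n), index=idx)
        tab = bin_prevalence(s, l, n_bins=10)
        se = np.sqrt(0.3 * 0.7 / 600)
        assert (np.abs(tab["prevalence"] - 0.3) < 4 * se).all()

    def test_unknown_handling(self):
        idx = [f"s{i}" for i in range(8)]
        l = pd.Series(["case"] * 4 + ["unknown"] * 4, index=idx)
        s = pd.Series(np.arange(8, dtype=float), index=idx)
        with pytest.raises(ValueError):
            bin_prevalence(s, l, n_bins=6)  # unknowns excluded -> too few
        tab = bin_prevalence(s, l, n_bins=4, include_unknown_as_control=True)
        assert tab["n"].sum() == 8

    def test_too_few_subjects(self):
        idx = list("ab")
        with pytest.raises(ValueError, match="bins"):
            bin_prevalence(
                pd.Series([1.0, 2.0], index=idx),
                pd.Series(["case", "control"], index=idx),
                n_bins=60,
            )


class TestWeightEnrichment:
    def test_extreme_arrangement_exact_p(self):
        w = pd.Series([10.0, 9.0, 1.0, 2.0], index=["r1", "r2", "x1", "x2"])
        assert weight_enrichment_test(w, ["r1", "r2"]) == pytest.approx(1 / 6)

    def test_identical_groups_near_half(self, rng):
        vals = rng.standard_normal(100)
        w = pd.Series(np.concatenate([vals, vals]), index=[f"f{i}" for i in range(200)])
        p = weight_enrichment_test(w, [f"f{i}" for i in range(100)])
        assert p == pytest.approx(0.5, abs=0.02)

    def test_label_swap_antisymmetry(self):
        w = pd.Series([5.0, 3.0, 4.0, 1.0, 2.0], index=list("abcde"))
        p_fwd = weight_enrichment_test(w, ["a", "c"])
        p_rev = weight_enrichment_test(w, ["b", "d", "e"])
        # exact distribution without ties: strictly-greater one-sided tails
        # of the two orientations sum to 1 + P(T = t_obs)
        assert p_fwd + p_rev > 1.0
        assert p_fwd < 0.5 < p_rev

    def test_empty_group_errors(self):
        w = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            weight_enrichment_test(w, [])
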