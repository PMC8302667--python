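"""Gene-based score-test battery and aggregated Cauchy combination.

For a gene's genotype block and a fitted null model the battery is:

1. burden + dispersion tests on common/low-frequency variants (MAF >= 0.01)
   with Beta(MAF; 1, 25) weights;
2. burden + dispersion tests on rare variants (MAF < 0.01, MAC >= 5), same
   weights;
3. the same rare tests with Beta weights multiplied by supplied functional
   weights, restricted to qualifying (deleterious missense / LoF) variants;
4. an unweighted burden test aggregating ultra-rare variants (MAC < 5);
5. single-variant score tests for common, low-frequency and rare variants.

All component p-values are combined by ACAT into p.all; the common-side and
rare-side components are also combined separately (p.common, p.rare).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .blocks import GenotypeBlock, beta_weight, partition_variants
from .null_model import NullScoreModel

__all__ = [
    "GeneTestResult",
    "burden_test",
    "dispersion_test",
    "ultra_rare_burden",
    "single_variant_tests",
    "acat_combine",
    "gene_combined_test",
    "significance_threshold",
]


@dataclass
class GeneTestResult:
    gene: str
    component_p: dict = field(default_factory=dict)
    single_variant_p: dict = field(default_factory=dict)  # variant_id -> p
    p_all: float | None = None
    p_common: float | None = None
    p_rare: float | None = None

    def to_row(self) -> dict:
        row = {"gene": self.gene, "p.all": self.p_all, "p.common": self.p_common,
               "p.rare": self.p_rare}
        row.update(self.component_p)
        return row


def burden_test(null: NullScoreModel, G: np.ndarray, weights: np.ndarray) -> float:
    """Score test on the weighted dosage sum B_i = sum_j w_j g_ij."""
    G = np.atleast_2d(np.asarray(G, float))
    if G.shape[1] == 0:
        raise ValueError("empty variant partition")
    b = G @ np.asarray(weights, float)
    if np.ptp(b) == 0:
        warnings.warn("constant burden score; p = 1", stacklevel=2)
        return 1.0
    _, _, p = null.score_test(b)
    return p


def _liu_pvalue(Q: float, lam: np.ndarray) -> float:
    """Tail probability of sum_i lam_i chi2_1 at Q by moment matching.

    Matches mean, variance and kurtosis to a (noncentral) chi-square; exact
    for a single eigenvalue.  Accuracy degrades in the far tail (p < 1e-8).
    """
    lam = lam[lam > 1e-12 * lam.max()] if lam.size else lam
    if lam.size == 0:
        return 1.0
    c1, c2, c3, c4 = (np.sum(lam**k) for k in (1, 2, 3, 4))
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        df = 1.0 / s2
        a = np.sqrt(df)
        delta = 0.0
    mu_q, sigma_q = c1, np.sqrt(2 * c2)
    mu_x, sigma_x = df + delta, np.sqrt(2 * df + 4 * delta)
    t = (Q - mu_q) / sigma_q * sigma_x + mu_x
    if delta > 0:
        return float(stats.ncx2.sf(t, df, delta))
    return float(stats.chi2.sf(t, df))


def dispersion_test(null: NullScoreModel, G: np.ndarray, weights: np.ndarray) -> float:
    """SKAT-type variance-component score test.

    Q = sum_j w_j^2 (g_j' e)^2 with e the null score residuals; the null
    distribution is the matching mixture of chi-squares, approximated by
    moment matching.
    """
    G = np.atleast_2d(np.asarray(G, float))
    if G.shape[1] == 0:
        raise ValueError("empty variant partition")
    if null.degenerate:
        return 1.0
    w = np.asarray(weights, float)
    U = G.T @ null.score_residuals
    Q = float(np.sum((w * U) ** 2))
    K = (w[:, None] * null.score_cov(G)) * w[None, :]
    lam = np.linalg.eigvalsh((K + K.T) / 2.0)
    lam = lam[lam > 0]
    if lam.size == 0:
        warnings.warn("zero genotype variance in partition; p = 1", stacklevel=2)
        return 1.0
    return min(1.0, _liu_pvalue(Q, lam))


def ultra_rare_burden(null: NullScoreModel, G: np.ndarray) -> float:
    """Unweighted aggregate test of ultra-rare (MAC < 5) variants."""
    G = np.atleast_2d(np.asarray(G, float))
    if G.shape[1] == 0:
        raise ValueError("no ultra-rare variants")
    b = G.sum(axis=1)
    if np.ptp(b) == 0:
        warnings.warn("no ultra-rare carriers; p = 1", stacklevel=2)
        return 1.0
    _, _, p = null.score_test(b)
    return p


def single_variant_tests(null: NullScoreModel, G: np.ndarray, variant_ids=None) -> dict:
    """Per-variant 1-df score tests; monomorphic variants are skipped."""
    G = np.atleast_2d(np.asarray(G, float))
    ids = variant_ids if variant_ids is not None else list(range(G.shape[1]))
    out = {}
    for j, vid in enumerate(ids):
        g = G[:, j]
        if np.ptp(g) == 0:
            continue
        _, _, p = null.score_test(g)
        out[vid] = p
    return out


def acat_combine(p_values, weights=None) -> float:
    """Aggregated Cauchy association test.

    T = sum_i w_i tan((0.5 - p_i) pi) / sum_i w_i; combined
    p = 0.5 - arctan(T)/pi.  Inputs are clipped to [1e-15, 1 - 1e-15];
    identical inputs are returned unchanged.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if ((p <= 0) | (p >= 1)).any():
        p = np.clip(p, 1e-15, 1 - 1e-15)
    w = np.ones_like(p) if weights is None else np.asarray(list(weights), float)
    if w.shape != p.shape or (w < 0).any() or w.sum() == 0:
        raise ValueError("invalid ACAT weights")
    T = float(np.sum(w * np.tan((0.5 - p) * np.pi)) / w.sum())
    return float(0.5 - np.arctan(T) / np.pi)


def gene_combined_test(
    null: NullScoreModel,
    block: GenotypeBlock,
    beta_shapes: tuple = (1.0, 25.0),
    use_functional: bool = True,
) -> GeneTestResult:
    """Run the full battery on one gene and combine by ACAT.

    Empty partitions are skipped (their components absent); p.all combines
    every computed component, p.common the common/low-frequency side, p.rare
    the rare plus ultra-rare side, mirroring a results table with p.all /
    p.common / p.rare columns.
    """
    res = GeneTestResult(block.gene)
    parts = partition_variants(block)
    a, b = beta_shapes
    fw = block.functional_weights()
    qual = block.qualifying()
    ids = block.variant_ids()

    common_ps, rare_ps = [], []

    idx = parts["common_lowfreq"]
    if idx.size:
        w = beta_weight(block.maf[idx], a, b)
        G = block.dosages[:, idx]
        res.component_p["p.burden.common"] = burden_test(null, G, w)
        res.component_p["p.dispersion.common"] = dispersion_test(null, G, w)
        common_ps += [res.component_p["p.burden.common"], res.component_p["p.dispersion.common"]]

    idx = parts["rare"]
    if idx.size:
        w = beta_weight(block.maf[idx], a, b)
        G = block.dosages[:, idx]
        res.component_p["p.burden.rare"] = burden_test(null, G, w)
        res.component_p["p.dispersion.rare"] = dispersion_test(null, G, w)
        rare_ps += [res.component_p["p.burden.rare"], res.component_p["p.dispersion.rare"]]
        if use_functional:
            fidx = idx[qual[idx]]
            if fidx.size:
                wf = beta_weight(block.maf[fidx], a, b) * fw[fidx]
                Gf = block.dosages[:, fidx]
                res.component_p["p.burden.rare.func"] = burden_test(null, Gf, wf)
                res.component_p["p.dispersion.rare.func"] = dispersion_test(null, Gf, wf)
                rare_ps += [
                    res.component_p["p.burden.rare.func"],
                    res.component_p["p.dispersion.rare.func"],
                ]

    idx = parts["ultra_rare"]
    if idx.size:
        res.component_p["p.burden.ultrarare"] = ultra_rare_burden(null, block.dosages[:, idx])
        rare_ps.append(res.component_p["p.burden.ultrarare"])

    sv_idx = np.concatenate([parts["common_lowfreq"], parts["rare"]]).astype(int)
    if sv_idx.size:
        sv = single_variant_tests(
            null, block.dosages[:, sv_idx], [ids[j] for j in sv_idx]
        )
        res.single_variant_p = sv
        common_set = {ids[j] for j in parts["common_lowfreq"]}
        for vid, p in sv.items():
            (common_ps if vid in common_set else rare_ps).append(p)

    all_ps = common_ps + rare_ps
    if all_ps:
        res.p_all = acat_combine(all_ps)
    if common_ps:
        res.p_common = acat_combine(common_ps)
    if rare_ps:
        res.p_rare = acat_combine(rare_ps)
    return res


def significance_threshold(alpha: float = 0.05, n_genes: int = 18000) -> float:
    """Bonferroni exome-wide significance level alpha / n_genes."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return alpha / n_genes
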