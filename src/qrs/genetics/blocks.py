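"""Per-gene genotype blocks: allele-frequency bookkeeping and MAF weights.

Dosages are oriented to the minor allele (flipped when the alt-allele
frequency exceeds 0.5).  MAF and MAC are computed on observed calls before
missing genotypes are mean-imputed, so missingness never changes a
variant's frequency partition.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["GenotypeBlock", "partition_variants", "beta_weight"]


class GenotypeBlock:
    """Dosage matrix for one gene with per-variant MAF/MAC.

    Parameters
    ----------
    gene : str
    subjects : sequence of subject ids
    dosages : (n_subjects, n_variants) array of alt-allele dosages in [0, 2];
        NaN marks missing calls.
    variants : sequence of VariantRecord (aligned with columns).
    """

    def __init__(self, gene, subjects, dosages, variants):
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2 or dosages.shape != (len(subjects), len(variants)):
            raise ValueError("dosage matrix shape mismatch")
        with np.errstate(invalid="ignore"):
            if np.nanmin(dosages, initial=0) < 0 or np.nanmax(dosages, initial=0) > 2:
                raise ValueError("dosages must lie in [0, 2]")
        self.gene = gene
        self.subjects = list(subjects)
        self.variants = list(variants)

        observed = ~np.isnan(dosages)
        n_obs = observed.sum(axis=0)
        if (n_obs == 0).any():
            raise ValueError("variant with no observed genotype calls")
        af = np.nansum(dosages, axis=0) / (2.0 * n_obs)
        flip = af > 0.5
        oriented = np.where(flip[np.newaxis, :], 2.0 - dosages, dosages)
        self.flipped = flip
        self.maf = np.where(flip, 1.0 - af, af)
        self.mac = np.rint(np.nansum(oriented, axis=0)).astype(int)

        col_means = np.nansum(oriented, axis=0) / n_obs
        self.dosages = np.where(np.isnan(oriented), col_means[np.newaxis, :], oriented)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_ids(self) -> list:
        return [v.variant_id for v in self.variants]

    def functional_weights(self) -> np.ndarray:
        return np.asarray([v.functional_weight for v in self.variants], float)

    def qualifying(self) -> np.ndarray:
        return np.asarray([v.qualifying for v in self.variants], bool)


def partition_variants(block: GenotypeBlock) -> dict:
    """Disjoint frequency partitions as column-index arrays.

    * ``common_lowfreq`` — MAF >= 0.01 (boundary assigned here) and MAC >= 5
    * ``rare`` — MAF < 0.01 and MAC >= 5
    * ``ultra_rare`` — 1 <= MAC < 5 (regardless of MAF)

    Monomorphic variants (MAC = 0) appear in no partition.
    """
    maf, mac = block.maf, block.mac
    poly = mac >= 1
    ultra = poly & (mac < 5)
    common = poly & ~ultra & (maf >= 0.01)
    rare = poly & ~ultra & (maf < 0.01)
    return {
        "common_lowfreq": np.flatnonzero(common),
        "rare": np.flatnonzero(rare),
        "ultra_rare": np.flatnonzero(ultra),
    }


def beta_weight(maf, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta(MAF; a, b) density weight, upweighting rarer variants.

    With the default shapes (1, 25): w = 25 (1 - maf)^24.
    """
    maf = np.asarray(maf, dtype=float)
    if (maf <= 0).any():
        raise ValueError("maf must be positive")
    if (maf > 0.5).any():
        raise ValueError("maf must not exceed 0.5")
    return stats.beta.pdf(maf, a, b)
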