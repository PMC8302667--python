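"""Synthetic EHR cohorts and genotypes with the structure the scores assume.

The cohort model is a latent-liability factor model: each subject carries a
liability L ~ N(0, 1); disease-relevant phecodes are Bernoulli with logit
a_j + b_j L + c log(1 + u), where u is the subject's healthcare-utilization
level (negative-binomial) and c induces the utilization confounding that
PheNorm's normalization targets; noise phecodes share the utilization term
but are independent of L.  Case/control/unknown labels and an ordinal
severity staging are thresholds/cutpoints on L.  Present phecodes emit
2 + Poisson occurrence records (so the two-occurrence presence rule is
exercised) at ages drawn from the subject's personal age grid.

Genotypes are Hardy-Weinberg dosages at MAFs drawn log-uniformly; causal
genes add effect x Beta-weighted rare-variant burden to the subject's
liability-driven quantitative score.  QC metric fields are drawn nominal,
with a configurable fraction forced to fail each hard filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .features import utilization as _utilization_op
from .genetics.blocks import GenotypeBlock, beta_weight
from .genetics.qc import VariantRecord

__all__ = ["CohortSpec", "simulate_cohort", "simulate_genotypes", "write_vcf"]


@dataclass
class CohortSpec:
    """Knobs of the synthetic cohort; defaults give a mid-sized EHR slice
    with 20 disease-driving and 200 irrelevant phecodes."""

    n_subjects: int = 4000
    n_relevant: int = 20
    n_noise: int = 200
    n_case_defining: int = 2  # leading relevant phecodes, used by PheNorm only
    # logistic intercepts: relevant phecodes around 8% baseline prevalence,
    # noise phecodes around 10%
    intercept_relevant: float = -2.5
    intercept_noise: float = -2.2
    loading: float = 1.5  # liability loading b_j of relevant phecodes
    loading_case_defining: float = 2.5
    utilization_confounding: float = 0.3  # c on log(1 + u)
    nb_mean: float = 8.0  # negative-binomial utilization (distinct ages)
    nb_dispersion: float = 2.0
    case_threshold: float = 1.0  # L >= -> case
    control_threshold: float = 0.0  # L < -> control; between -> unknown
    staging_cutpoints: tuple = (1.0, 1.5, 2.0, 2.5)  # stages G1..G4 on L
    # genetic architecture
    n_genes: int = 10
    variants_per_gene: int = 30
    maf_range: tuple = (0.001, 0.05)
    causal_effects: dict = field(default_factory=dict)  # gene name -> effect
    qc_fail_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_subjects, self.n_relevant, self.n_noise, self.n_genes) <= 0:
            raise ValueError("counts must be positive")
        if not 0 < self.n_case_defining <= self.n_relevant:
            raise ValueError("n_case_defining must be in 1..n_relevant")
        if any(np.diff(self.staging_cutpoints) <= 0):
            raise ValueError("staging cutpoints must be strictly increasing")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not 0 <= self.qc_fail_fraction < 1:
            raise ValueError("qc_fail_fraction must be in [0, 1)")

    @property
    def relevant_phecodes(self) -> list:
        return [f"REL.{j:03d}" for j in range(self.n_relevant)]

    @property
    def case_defining_phecodes(self) -> list:
        return self.relevant_phecodes[: self.n_case_defining]

    @property
    def noise_phecodes(self) -> list:
        return [f"NOI.{j:03d}" for j in range(self.n_noise)]

    @property
    def genes(self) -> list:
        return [f"GENE{g:02d}" for g in range(self.n_genes)]


def simulate_cohort(spec: CohortSpec, seed: int | None = None):
    """Draw one cohort.

    Returns ``(records, labels, staging, utilization, liability)``:
    long-format occurrence records, weak labels (case/control/unknown),
    ordinal staging (0 for controls, 1..len(cutpoints) for cases), the
    realized utilization vector, and the latent liability (for downstream
    construction of quantitative responses).  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_subjects
    subjects = [f"S{i:06d}" for i in range(n)]

    L = rng.standard_normal(n)
    # distinct-age utilization: NB with mean nb_mean, shifted to >= 1
    r = spec.nb_dispersion
    p_nb = r / (r + spec.nb_mean - 1.0)
    u = 1 + rng.negative_binomial(r, p_nb, size=n)

    feats = spec.relevant_phecodes + spec.noise_phecodes
    logits = np.empty((n, len(feats)))
    conf = spec.utilization_confounding * np.log1p(u)
    for j, f in enumerate(feats):
        if f in set(spec.relevant_phecodes):
            b = (
                spec.loading_case_defining
                if f in set(spec.case_defining_phecodes)
                else spec.loading
            )
            logits[:, j] = spec.intercept_relevant + b * L + conf
        else:
            logits[:, j] = spec.intercept_noise + conf
    present = rng.random((n, len(feats))) < expit(logits)

    # per-subject age grid of u_i distinct ages in [30, 80)
    rows = []
    for i in range(n):
        ages = np.round(30 + 50 * rng.random(u[i]), 2)
        js = np.flatnonzero(present[i])
        for j in js:
            k = 2 + rng.poisson(1.0)
            occ_ages = rng.choice(ages, size=k, replace=True)
            for a in occ_ages:
                rows.append((subjects[i], feats[j], a))
    records = pd.DataFrame(rows, columns=["subject_id", "phecode", "age_at_observation"])

    label = np.where(
        L >= spec.case_threshold,
        "case",
        np.where(L < spec.control_threshold, "control", "unknown"),
    )
    labels = pd.Series(label, index=subjects, name="label")
    stage = np.searchsorted(np.asarray(spec.staging_cutpoints), L, side="left")
    stage = np.where(label == "case", np.maximum(stage, 1), 0)
    staging = pd.Series(stage, index=subjects, name="stage")
    util = _utilization_op(records, roster=subjects)
    liability = pd.Series(L, index=subjects, name="liability")
    return records, labels, staging, util, liability


def simulate_genotypes(spec: CohortSpec, seed: int | None = None):
    """Draw Hardy-Weinberg genotype blocks for every gene in the spec.

    Returns ``(blocks, genetic_increment)``: a ``{gene: GenotypeBlock}`` map
    and the per-subject score increment contributed by causal genes
    (effect x Beta(1,25)-weighted rare burden, standardized per gene).
    """
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 1)
    n = spec.n_subjects
    subjects = [f"S{i:06d}" for i in range(n)]
    lo, hi = spec.maf_range
    blocks = {}
    increment = np.zeros(n)
    for g, gene in enumerate(spec.genes):
        m = spec.variants_per_gene
        mafs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=m))
        doses = rng.binomial(2, mafs[np.newaxis, :], size=(n, m)).astype(float)
        recs = []
        for v in range(m):
            is_snv = rng.random() < 0.85
            ref = "A"
            alt = "G" if is_snv else "GT"
            metrics = {
                "qd": float(rng.uniform(5, 30)),
                "mq": float(rng.uniform(50, 60)),
                "fs": float(rng.uniform(0, 10)),
                "sor": float(rng.uniform(0.5, 2.0)),
                "mq_rank_sum": float(rng.normal(0, 1)),
                "read_pos_rank_sum": float(rng.normal(0, 1)),
            }
            if rng.random() < spec.qc_fail_fraction:
                which = rng.choice(["qd", "fs", "sor"])
                metrics[which] = {"qd": 0.5, "fs": 300.0, "sor": 20.0}[which]
            recs.append(
                VariantRecord(
                    chrom="1",
                    pos=1000 * (g + 1) * 100 + 10 * v + 1,
                    ref=ref,
                    alt=alt,
                    gene=gene,
                    qualifying=bool(rng.random() < 0.7),
                    functional_weight=float(rng.uniform(0.5, 1.5)),
                    **metrics,
                )
            )
        block = GenotypeBlock(gene, subjects, doses, recs)
        blocks[gene] = block
        effect = spec.causal_effects.get(gene, 0.0)
        if effect:
            rare = (block.maf < 0.01) & (block.mac >= 5)
            idx = np.flatnonzero(rare)
            if idx.size == 0:
                idx = np.flatnonzero(block.mac >= 1)
            w = beta_weight(np.maximum(block.maf[idx], 1e-6))
            burden = block.dosages[:, idx] @ w
            sd = burden.std()
            if sd > 0:
                increment += effect * (burden - burden.mean()) / sd
    return blocks, pd.Series(increment, index=subjects, name="genetic_increment")


def write_vcf(blocks: dict, path) -> None:
    """Write blocks as an uncompressed VCF 4.2 with QC/annotation INFO fields."""
    genes = list(blocks.values())
    if not genes:
        raise ValueError("no blocks to write")
    subjects = genes[0].subjects
    info_defs = [
        ("GENE", "String", "Assigned gene"),
        ("QD", "Float", "Quality by depth"),
        ("MQ", "Float", "RMS mapping quality"),
        ("FS", "Float", "Fisher strand"),
        ("SOR", "Float", "Strand odds ratio"),
        ("MQRankSum", "Float", "Mapping quality rank-sum"),
        ("ReadPosRankSum", "Float", "Read position rank-sum"),
        ("QUALIFYING", "Integer", "Deleterious missense/LoF flag"),
        ("FWEIGHT", "Float", "Functional weight"),
    ]
    entries = []
    for block in genes:
        for j, rec in enumerate(block.variants):
            # write original-orientation alt dosages (flip back if oriented)
            d = block.dosages[:, j]
            if block.flipped[j]:
                d = 2.0 - d
            entries.append((rec, d))
    entries.sort(key=lambda e: (e[0].chrom, e[0].pos))

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, typ, desc in info_defs:
            fh.write(f'##INFO=<ID={name},Number=1,Type={typ},Description="{desc}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(subjects) + "\n")
        for rec, dose in entries:
            info = [f"GENE={rec.gene}"]
            for attr, name in (
                ("qd", "QD"),
                ("mq", "MQ"),
                ("fs", "FS"),
                ("sor", "SOR"),
                ("mq_rank_sum", "MQRankSum"),
                ("read_pos_rank_sum", "ReadPosRankSum"),
            ):
                val = getattr(rec, attr)
                if val is not None:
                    info.append(f"{name}={val:.4g}")
            info.append(f"QUALIFYING={int(rec.qualifying)}")
            info.append(f"FWEIGHT={rec.functional_weight:.4g}")
            gts = []
            for d in dose:
                k = int(round(d))
                gts.append("./." if np.isnan(d) else ["0/0", "0/1", "1/1"][k])
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.variant_id}\t{rec.ref}\t{rec.alt}"
                f"\t.\tPASS\t{';'.join(info)}\tGT\t" + "\t".join(gts) + "\n"
            )
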