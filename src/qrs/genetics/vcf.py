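"""VCF input: variant records, QC metrics, and per-gene dosage blocks.

Reading is delegated to cyvcf2.  Multi-allelic records are split into
biallelic variants before anything else.  Gene assignment comes from either
a BED-like interval table (chrom, start, end, gene; 0-based half-open) or a
per-variant INFO field.  The INFO fields QD, MQ, FS, SOR, MQRankSum and
ReadPosRankSum feed the hard filters; optional INFO fields carry the
qualifying-variant flag and the functional weight.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .blocks import GenotypeBlock
from .qc import VariantRecord, qc_filter

__all__ = ["read_vcf_blocks", "blocks_to_dosage_frame", "read_gene_intervals"]

_QC_INFO = {
    "qd": "QD",
    "mq": "MQ",
    "fs": "FS",
    "sor": "SOR",
    "mq_rank_sum": "MQRankSum",
    "read_pos_rank_sum": "ReadPosRankSum",
}


def read_gene_intervals(path) -> pd.DataFrame:
    """Read a BED-like TSV (chrom, start, end, gene), no header required."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "gene"]
    return df


def _gene_lookup(intervals: pd.DataFrame):
    by_chrom: dict = {}
    for row in intervals.itertuples(index=False):
        by_chrom.setdefault(str(row.chrom), []).append((int(row.start), int(row.end), row.gene))

    def lookup(chrom, pos):  # pos is 1-based
        for start, end, gene in by_chrom.get(str(chrom), ()):
            if start <= pos - 1 < end:
                return gene
        return None

    return lookup


def read_vcf_blocks(
    path,
    gene_intervals: pd.DataFrame | None = None,
    gene_info_field: str | None = None,
    qualifying_info_field: str = "QUALIFYING",
    functional_info_field: str = "FWEIGHT",
    apply_qc: bool = True,
) -> dict:
    """Read a VCF into per-gene :class:`GenotypeBlock` objects.

    Returns ``{gene: GenotypeBlock}``.  Variants mapping to no gene are
    dropped; genotype calls with any missing allele become NaN dosages.
    """
    from cyvcf2 import VCF

    if gene_intervals is None and gene_info_field is None:
        raise ValueError("supply gene_intervals or gene_info_field")
    lookup = _gene_lookup(gene_intervals) if gene_intervals is not None else None

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    per_gene: dict = {}
    for var in vcf:
        genotypes = var.genotypes  # [[a0, a1, phased], ...]
        for alt_i, alt in enumerate(var.ALT, start=1):
            if gene_info_field is not None:
                gene = var.INFO.get(gene_info_field)
            else:
                gene = lookup(var.CHROM, var.POS)
            if gene is None:
                continue
            dose = np.empty(len(subjects))
            for i, gt in enumerate(genotypes):
                alleles = gt[:-1]
                if any(a < 0 for a in alleles):
                    dose[i] = np.nan
                else:
                    dose[i] = sum(a == alt_i for a in alleles)
            metrics = {k: var.INFO.get(f) for k, f in _QC_INFO.items()}
            metrics = {k: (None if v is None else float(v)) for k, v in metrics.items()}
            qual = var.INFO.get(qualifying_info_field)
            fweight = var.INFO.get(functional_info_field)
            rec = VariantRecord(
                chrom=str(var.CHROM),
                pos=int(var.POS),
                ref=var.REF,
                alt=alt,
                gene=gene,
                qualifying=bool(int(qual)) if qual is not None else True,
                functional_weight=float(fweight) if fweight is not None else 1.0,
                **metrics,
            )
            per_gene.setdefault(gene, []).append((rec, dose))

    blocks = {}
    for gene, pairs in per_gene.items():
        recs = [r for r, _ in pairs]
        if apply_qc:
            keep = set(id(r) for r in qc_filter(recs))
            pairs = [(r, d) for r, d in pairs if id(r) in keep]
        if not pairs:
            continue
        doses = np.column_stack([d for _, d in pairs])
        observed_any = ~np.all(np.isnan(doses), axis=0)
        pairs = [p for p, ok in zip(pairs, observed_any) if ok]
        if not pairs:
            continue
        doses = np.column_stack([d for _, d in pairs])
        blocks[gene] = GenotypeBlock(gene, subjects, doses, [r for r, _ in pairs])
    return blocks


def blocks_to_dosage_frame(blocks: dict) -> pd.DataFrame:
    """Subjects x variants dosage table (minor-allele oriented, imputed)."""
    frames = []
    for block in blocks.values():
        frames.append(
            pd.DataFrame(block.dosages, index=block.subjects, columns=block.variant_ids())
        )
    return pd.concat(frames, axis=1)
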