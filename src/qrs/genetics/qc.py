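"""Variant records and hard-filter quality control.

Hard filters follow GATK-style best-practice thresholds, applied separately
to SNVs and indels; a variant is removed if ANY metric fails.  A metric
absent from the call set passes vacuously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["VariantRecord", "qc_filter", "SNV_FILTERS", "INDEL_FILTERS"]


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str | None = None
    qd: float | None = None
    mq: float | None = None
    fs: float | None = None
    sor: float | None = None
    mq_rank_sum: float | None = None
    read_pos_rank_sum: float | None = None
    qualifying: bool = True  # deleterious-missense/LoF flag, supplied upstream
    functional_weight: float = 1.0  # e.g. CADD-derived, supplied upstream
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be 1-based positive")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def variant_type(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


# metric -> (direction, threshold); "lt" fails when metric < threshold
SNV_FILTERS = {
    "qd": ("lt", 2.0),
    "mq": ("lt", 40.0),
    "fs": ("gt", 60.0),
    "sor": ("gt", 3.0),
    "mq_rank_sum": ("lt", -12.5),
    "read_pos_rank_sum": ("lt", -8.0),
}

INDEL_FILTERS = {
    "qd": ("lt", 2.0),
    "read_pos_rank_sum": ("lt", -20.0),
    "fs": ("gt", 200.0),
    "sor": ("gt", 10.0),
}


def _fails(value, rule) -> bool:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return False  # absent metric passes
    direction, threshold = rule
    return value < threshold if direction == "lt" else value > threshold


def qc_filter(variants) -> list:
    """Return the variants passing the hard filters for their type."""
    retained = []
    for v in variants:
        rules = SNV_FILTERS if v.variant_type == "SNV" else INDEL_FILTERS
        if not any(_fails(getattr(v, metric), rule) for metric, rule in rules.items()):
            retained.append(v)
    return retained
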