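"""Germline variant triage: quality, rarity and deleteriousness filters.

The triage cascade defines the candidate "LoF germline variant" set used by
the downstream burden and two-hit analyses: a call must pass caller quality
metrics, be rare in the matched reference population (East-Asian allele
fraction below 1%), and be predicted damaging (non-synonymous coding or
splice-site change with CADD above 20).  Within that set, truncating
consequences (stop gain, frameshift, canonical splice disruption, exon loss)
are additionally graded into high- and low-confidence loss-of-function calls
in the style of LOFTEE: truncations in the terminal 5% of the coding sequence
or at non-canonical splice positions are demoted to low confidence.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "CONSEQUENCES",
    "LOF_CONSEQUENCES",
    "GermlineVariant",
    "FilterThresholds",
    "LofCategory",
    "LofCall",
    "passes_quality",
    "is_rare",
    "is_damaging",
    "classify_lof",
    "select_candidate_lof",
    "allele_frequency",
    "chrom_sort_key",
]

#: Controlled consequence vocabulary.
CONSEQUENCES = frozenset(
    {
        "missense",
        "stop_gained",
        "frameshift",
        "splice_donor",
        "splice_acceptor",
        "splice_region",
        "synonymous",
        "intronic",
        "inframe_indel",
        "exon_loss",
    }
)

#: Truncating consequences eligible for a loss-of-function call.
LOF_CONSEQUENCES = frozenset(
    {"stop_gained", "frameshift", "splice_donor", "splice_acceptor", "exon_loss"}
)

# Coding / splice-site consequences ("exonic/splicing"): everything except
# pure intronic changes.  Synonymous changes are excluded separately by the
# damaging predicate.
_EXONIC_OR_SPLICING = CONSEQUENCES - {"intronic"}


class LofCategory(str, enum.Enum):
    NOT_LOF = "not_lof"
    LOW_CONFIDENCE = "low_confidence_lof"
    HIGH_CONFIDENCE = "high_confidence_lof"


@dataclass
class GermlineVariant:
    """One annotated small-variant (or structural) call in one sample.

    ``quality`` holds caller metrics keyed by name (TLOD, FS, SEQQ, MQ,
    STRANDQ, DP); metrics absent from the map are simply not filtered on.
    ``vaf`` is only populated for somatic calls.
    """

    patient_id: str
    gene: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    consequence: str
    cadd: Optional[float] = None
    af_eas: Optional[float] = None
    af_global: Optional[float] = None
    quality: Mapping[str, float] = field(default_factory=dict)
    cds_relative_position: Optional[float] = None
    canonical_splice: Optional[bool] = None
    hgvs_c: Optional[str] = None
    vaf: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        for name in ("af_eas", "af_global"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} out of [0, 1]: {v}")


@dataclass(frozen=True)
class FilterThresholds:
    """Thresholds of the triage cascade (caller quality, rarity, CADD).

    Comparison directions are fixed: TLOD > tlod_min, FS < fs_max,
    SEQQ > seqq_min, MQ >= mq_min, STRANDQ > strandq_min, DP > dp_min,
    af_eas < maf_max, CADD > cadd_min.  Note MQ is the only non-strict one.
    """

    tlod_min: float = 12.0
    fs_max: float = 10.0
    seqq_min: float = 60.0
    mq_min: float = 60.0
    strandq_min: float = 40.0
    dp_min: float = 10.0
    maf_max: float = 0.01
    cadd_min: float = 20.0
    # LOFTEE-style demotion rules
    end_of_transcript_fraction: float = 0.95
    dmaf: None = None  # reserved

    def __post_init__(self) -> None:
        for name in (
            "tlod_min", "fs_max", "seqq_min", "mq_min",
            "strandq_min", "dp_min", "maf_max", "cadd_min",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"threshold {name} must be finite")
        if not (0.0 < self.maf_max < 1.0):
            raise ValueError("maf_max must lie in (0, 1)")


@dataclass(frozen=True)
class LofCall:
    variant: GermlineVariant
    category: LofCategory


def passes_quality(v: GermlineVariant, t: FilterThresholds = FilterThresholds()) -> bool:
    """True iff every caller quality metric *present* on ``v`` passes.

    The germline and somatic call sets carry different metric vocabularies
    (GATK emits FS/MQ/DP, Mutect2 adds TLOD/SEQQ/STRANDQ); one filter string
    is applied to both, so absent metrics never fail a variant.
    """
    q = v.quality
    checks = (
        ("TLOD", lambda x: x > t.tlod_min),
        ("FS", lambda x: x < t.fs_max),
        ("SEQQ", lambda x: x > t.seqq_min),
        ("MQ", lambda x: x >= t.mq_min),
        ("STRANDQ", lambda x: x > t.strandq_min),
        ("DP", lambda x: x > t.dp_min),
    )
    return all(ok(q[name]) for name, ok in checks if q.get(name) is not None)


def is_rare(v: GermlineVariant, t: FilterThresholds = FilterThresholds()) -> bool:
    """East-Asian reference allele fraction strictly below ``maf_max``.

    A variant never observed in the reference panel has no recorded
    frequency; absence is treated as frequency zero.
    """
    af = v.af_eas if v.af_eas is not None else 0.0
    return af < t.maf_max


def is_damaging(v: GermlineVariant, t: FilterThresholds = FilterThresholds()) -> bool:
    """Exonic/splicing, non-synonymous, with CADD strictly above ``cadd_min``."""
    if v.consequence not in _EXONIC_OR_SPLICING or v.consequence == "synonymous":
        return False
    return v.cadd is not None and v.cadd > t.cadd_min


def classify_lof(
    v: GermlineVariant,
    end_of_transcript_fraction: float = 0.95,
) -> LofCall:
    """Grade a variant's loss-of-function confidence.

    Only truncating consequences can be LoF.  Truncations landing in the
    terminal 5% of the coding sequence, or splice variants not at a canonical
    splice dinucleotide, are demoted to low confidence; otherwise high.
    """
    if v.consequence not in LOF_CONSEQUENCES:
        return LofCall(v, LofCategory.NOT_LOF)
    demote = False
    if v.cds_relative_position is not None and v.cds_relative_position > end_of_transcript_fraction:
        demote = True
    if v.canonical_splice is False:
        demote = True
    return LofCall(v, LofCategory.LOW_CONFIDENCE if demote else LofCategory.HIGH_CONFIDENCE)


_CHROM_ORDER = {str(i): i for i in range(1, 23)}
_CHROM_ORDER.update({"X": 23, "Y": 24, "MT": 25, "M": 25})


def chrom_sort_key(chrom: str) -> tuple:
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (0, _CHROM_ORDER[c]) if c in _CHROM_ORDER else (1, c)


def select_candidate_lof(
    variants: Iterable[GermlineVariant],
    gene_set: Sequence[str] | frozenset | set,
    t: FilterThresholds = FilterThresholds(),
) -> list[LofCall]:
    """Run the full cascade over ``variants`` restricted to ``gene_set``.

    Returns the surviving variants (quality AND rare AND damaging AND gene in
    set), each graded by :func:`classify_lof`, in stable (chrom, pos, alt)
    order.
    """
    genes = set(gene_set)
    if not genes:
        raise ValueError("gene_set must be nonempty")
    kept = [
        v
        for v in variants
        if v.gene in genes and passes_quality(v, t) and is_rare(v, t) and is_damaging(v, t)
    ]
    kept.sort(key=lambda v: (chrom_sort_key(v.chrom), v.pos, v.alt))
    return [classify_lof(v, t.end_of_transcript_fraction) for v in kept]


def allele_frequency(allele_count: int, allele_number: int) -> float:
    """Minor allele fraction from observed allele counts (e.g. gnomAD AC/AN)."""
    if allele_number <= 0:
        raise ValueError("allele_number must be positive")
    if not (0 <= allele_count <= allele_number):
        raise ValueError("allele_count out of range")
    return allele_count / allele_number
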