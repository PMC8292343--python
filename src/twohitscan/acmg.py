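"""ACMG/AMP evidence-combination engine.

Combines coded evidence criteria (PVS1, PS1-4, PM1-6, PP1-5 on the
pathogenic side; BA1, BS1-4, BP1-7 on the benign side) into one of five
classification labels following the standard combining rules of the
ACMG/AMP sequence-variant interpretation framework.  Criteria are consumed
as codes — no automatic evidence assignment from annotations is attempted —
and each code carries its default strength (no strength modifiers).

PP5/BP6 (reputable source) are accepted even though later ClinGen guidance
deprecated them; clinical reports in circulation still use them.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "VALID_CODES",
    "Classification",
    "CriteriaSet",
    "combine",
    "classify_cohort",
    "CohortClassification",
]

VALID_CODES = frozenset(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
)


class Classification(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "uncertain_significance"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"

    @property
    def short(self) -> str:
        return {
            Classification.PATHOGENIC: "P",
            Classification.LIKELY_PATHOGENIC: "LP",
            Classification.VUS: "VUS",
            Classification.LIKELY_BENIGN: "LB",
            Classification.BENIGN: "B",
        }[self]


# Rank order used by the monotonicity contract (benign lowest).
_RANK = {
    Classification.BENIGN: 0,
    Classification.LIKELY_BENIGN: 1,
    Classification.VUS: 2,
    Classification.LIKELY_PATHOGENIC: 3,
    Classification.PATHOGENIC: 4,
}


@dataclass(frozen=True)
class CriteriaSet:
    codes: frozenset[str]

    def __init__(self, codes: Iterable[str]):
        codes = frozenset(codes)
        unknown = codes - VALID_CODES
        if unknown:
            raise ValueError(f"unknown ACMG criteria code(s): {sorted(unknown)}")
        object.__setattr__(self, "codes", codes)

    def strength_counts(self) -> Counter:
        c = Counter()
        for code in self.codes:
            prefix = code.rstrip("0123456789")
            c[prefix] += 1
        return c


def combine(criteria: CriteriaSet | Iterable[str]) -> Classification:
    """Apply the ACMG/AMP combining rules to a set of criteria codes.

    Conflicting evidence (a pathogenic-side rule and a benign-side rule both
    satisfied), or no rule satisfied at all, yields uncertain significance.
    """
    if not isinstance(criteria, CriteriaSet):
        criteria = CriteriaSet(criteria)
    n = criteria.strength_counts()
    pvs, ps, pm, pp = n["PVS"], n["PS"], n["PM"], n["PP"]
    ba, bs, bp = n["BA"], n["BS"], n["BP"]

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps >= 1 and (pm >= 3 or (pm >= 2 and pp >= 2) or (pm >= 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs >= 1 and pm >= 1)
        or (ps >= 1 and pm >= 1)
        or (ps >= 1 and pp >= 2)
        or pm >= 3
        or (pm >= 2 and pp >= 2)
        or (pm >= 1 and pp >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs >= 1 and bp >= 1) or bp >= 2

    path_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if path_side and benign_side:
        return Classification.VUS
    if pathogenic:
        return Classification.PATHOGENIC
    if likely_pathogenic:
        return Classification.LIKELY_PATHOGENIC
    if benign:
        return Classification.BENIGN
    if likely_benign:
        return Classification.LIKELY_BENIGN
    return Classification.VUS


def rank(label: Classification) -> int:
    """Position of a label on the benign-to-pathogenic axis (0..4)."""
    return _RANK[label]


@dataclass
class CohortClassification:
    """Classified criteria assignments rolled up to patient and gene level."""

    calls: list  # (patient_id, gene, CriteriaSet, Classification)
    carriers: set  # patients with >=1 P/LP call
    gene_counts: Mapping[str, int]  # gene -> number of distinct P/LP carriers

    def carrier_fraction(self, cohort_size: int) -> float:
        return len(self.carriers) / cohort_size


def classify_cohort(
    assignments: Iterable[tuple[str, str, CriteriaSet | Iterable[str]]],
) -> CohortClassification:
    """Classify each (patient, gene, criteria) assignment and roll up.

    A patient is a carrier iff at least one of their variants classifies
    pathogenic or likely pathogenic; per-gene counts are numbers of distinct
    carrier patients, not variants.
    """
    calls = []
    carriers: set[str] = set()
    by_gene: dict[str, set[str]] = {}
    for patient, gene, crit in assignments:
        label = combine(crit)
        calls.append((patient, gene, crit, label))
        if label in (Classification.PATHOGENIC, Classification.LIKELY_PATHOGENIC):
            carriers.add(patient)
            by_gene.setdefault(gene, set()).add(patient)
    return CohortClassification(
        calls=calls,
        carriers=carriers,
        gene_counts={g: len(p) for g, p in by_gene.items()},
    )
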