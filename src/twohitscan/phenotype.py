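"""Patient- and tumor-level phenotype labels.

Derives the clinical group labels the association analyses condition on:

* tumor MSI status — a tumor is MSI-high if any one assay is positive:
  >=2 of the 5 Bethesda PCR markers unstable, loss of any MMR protein by
  immunohistochemistry (dMMR), or an MSIsensor score above 3.5;
* early onset — second primary diagnosed at or under 55 years;
* concurrency — synchronous when the two diagnoses fall within a year;
* family-history burden — two or more first-degree relatives with cancer,
  with unknown history propagated (and excluded from downstream tables).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

__all__ = [
    "PCR_MARKERS",
    "MMR_PROTEINS",
    "Diagnosis",
    "PatientRecord",
    "TumorAssay",
    "MsiStatus",
    "Concurrency",
    "msi_status",
    "is_early_onset",
    "concurrency",
    "strong_family_history",
]

#: Bethesda microsatellite marker panel (2 mono-, 3 dinucleotide repeats).
PCR_MARKERS = ("BAT25", "BAT26", "D5S346", "D2S123", "D17S250")
#: Mismatch-repair proteins assayed by IHC.
MMR_PROTEINS = ("MLH1", "MSH2", "MSH6", "PMS2")


class MsiStatus(str, enum.Enum):
    MSI_H = "MSI-H"
    MSS = "MSS"
    UNKNOWN = "unknown"


class Concurrency(str, enum.Enum):
    SYNCHRONOUS = "synchronous"
    METACHRONOUS = "metachronous"


@dataclass(frozen=True)
class Diagnosis:
    cancer_type: str  # GC, CRC, EC, other
    age_at_dx: float  # years
    dx_date_offset: int  # days from the first diagnosis

    def __post_init__(self) -> None:
        if self.age_at_dx <= 0:
            raise ValueError("age_at_dx must be positive")


@dataclass
class PatientRecord:
    """One multiple-primary-cancer patient (>=2 histologically distinct cancers)."""

    patient_id: str
    diagnoses: Sequence[Diagnosis]
    n_first_degree_relatives_with_cancer: Optional[int] = None
    tumors: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.diagnoses) < 2:
            raise ValueError("a multiple-primary-cancer record needs >=2 diagnoses")
        if len({d.cancer_type for d in self.diagnoses}) < 2:
            raise ValueError("diagnoses must span >=2 histologically distinct types")

    def ordered_diagnoses(self) -> list[Diagnosis]:
        return sorted(self.diagnoses, key=lambda d: d.dx_date_offset)


@dataclass
class TumorAssay:
    """MSI/MMR assay results for one tumor; any assay may be absent."""

    tumor_id: str
    msi_pcr: Optional[Mapping[str, bool]] = None  # marker -> unstable?
    ihc_loss: Optional[Mapping[str, bool]] = None  # protein -> expression lost?
    msisensor_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.msi_pcr is not None:
            bad = set(self.msi_pcr) - set(PCR_MARKERS)
            if bad:
                raise ValueError(f"unknown PCR marker(s): {sorted(bad)}")
        if self.ihc_loss is not None:
            bad = set(self.ihc_loss) - set(MMR_PROTEINS)
            if bad:
                raise ValueError(f"unknown MMR protein(s): {sorted(bad)}")
        if self.msisensor_score is not None and self.msisensor_score < 0:
            raise ValueError("msisensor_score must be non-negative")


def msi_status(
    a: TumorAssay,
    pcr_unstable_min: int = 2,
    msisensor_cutoff: float = 3.5,
) -> MsiStatus:
    """Integrate the MSI/MMR assays by logical OR (any positive => MSI-H)."""
    any_present = False
    if a.msi_pcr is not None:
        any_present = True
        if sum(bool(v) for v in a.msi_pcr.values()) >= pcr_unstable_min:
            return MsiStatus.MSI_H
    if a.ihc_loss is not None:
        any_present = True
        if any(a.ihc_loss.values()):
            return MsiStatus.MSI_H
    if a.msisensor_score is not None:
        any_present = True
        if a.msisensor_score > msisensor_cutoff:
            return MsiStatus.MSI_H
    return MsiStatus.MSS if any_present else MsiStatus.UNKNOWN


def is_early_onset(p: PatientRecord, cutoff: float = 55.0) -> bool:
    """Second primary diagnosed at or under ``cutoff`` years (non-strict)."""
    second = p.ordered_diagnoses()[1]
    return second.age_at_dx <= cutoff


def concurrency(p: PatientRecord, max_interval_days: int = 365) -> Concurrency:
    """Synchronous iff first and second diagnoses are under a year apart."""
    dx = p.ordered_diagnoses()
    interval = dx[1].dx_date_offset - dx[0].dx_date_offset
    return Concurrency.SYNCHRONOUS if interval < max_interval_days else Concurrency.METACHRONOUS


def strong_family_history(p: PatientRecord, min_fdr: int = 2) -> Optional[bool]:
    """>= ``min_fdr`` first-degree relatives with cancer; None if unknown."""
    n = p.n_first_degree_relatives_with_cancer
    if n is None:
        return None
    return n >= min_fdr
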