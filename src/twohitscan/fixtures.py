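"""Packaged fixtures encoding the study's printed summary tables.

The study deposited no raw data; its printed tables are therefore the only
machine-checkable ground truth.  Three tables are shipped as plain TSV
inside the package:

* table 1 — the 16 germline P/LP variants (15 patients) with their ACMG
  criteria codes and printed classifications;
* table 2 — per-gene candidate-LoF carrier counts in the 12 non-LS and 7 LS
  WES patients versus the 70-patient ancestry-matched sporadic reference;
* table 3 — per-patient candidate germline LoF gene lists with
  high-confidence flags and the genes bi-allelically altered in tumors;

plus the printed cohort margins (group sizes) the association tables are
rebuilt from.  MSI labels for patients outside table 1 are synthetic
placeholders in the generator, never part of these fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import pandas as pd

from .acmg import CriteriaSet

__all__ = [
    "Table1Entry",
    "Table3Entry",
    "StudyFixtures",
    "study_fixtures",
    "DEFAULT_PANEL_GENES",
]


@dataclass(frozen=True)
class Table1Entry:
    case_id: str
    cancer_types: tuple[str, ...]
    age_range: str  # "<55" or ">55"
    gene: str
    nucleotide_change: str
    protein_change: Optional[str]
    consequence: str
    criteria: CriteriaSet
    printed_class: str  # "P" or "LP"
    msi_status: tuple[str, ...]


@dataclass(frozen=True)
class Table3Entry:
    group: str  # "LS" or "non_LS"
    case_id: str
    germline_genes: tuple[str, ...]
    high_confidence: frozenset[str]
    n_tumors: int
    n_sequenced: int
    msi_status: tuple[str, ...]
    biallelic_genes: frozenset[str]


@dataclass(frozen=True)
class StudyFixtures:
    table1: tuple[Table1Entry, ...]
    table2: pd.DataFrame
    table3: tuple[Table3Entry, ...]
    cohort_margins: dict


def _read(name: str) -> pd.DataFrame:
    with resources.files("twohitscan.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#", dtype=str, keep_default_na=False)


def study_fixtures() -> StudyFixtures:
    """Load the packaged printed-table fixtures."""
    t1 = tuple(
        Table1Entry(
            case_id=r.case_id,
            cancer_types=tuple(r.cancer_types.split("/")),
            age_range=r.age_range,
            gene=r.gene,
            nucleotide_change=r.nucleotide_change,
            protein_change=None if r.protein_change == "NA" else r.protein_change,
            consequence=r.consequence,
            criteria=CriteriaSet(r.acmg_criteria.split(",")),
            printed_class=r.printed_class,
            msi_status=tuple(r.msi_status.split("/")),
        )
        for r in _read("table1.tsv").itertuples()
    )

    t2 = _read("table2.tsv")
    for col in ("n_nonls", "n_ls", "n_total", "n_reference"):
        t2[col] = t2[col].astype(int)

    rows = []
    for r in _read("table3.tsv").itertuples():
        genes, hc = [], set()
        for tok in r.germline_lof_genes.split(","):
            if tok.endswith(":hc"):
                tok = tok[:-3]
                hc.add(tok)
            genes.append(tok)
        bial = frozenset(g for g in r.biallelic_genes.split(",") if g)
        rows.append(
            Table3Entry(
                group=r.group,
                case_id=r.case_id,
                germline_genes=tuple(genes),
                high_confidence=frozenset(hc),
                n_tumors=int(r.n_tumors),
                n_sequenced=int(r.n_sequenced),
                msi_status=tuple(r.msi_status.split("/")),
                biallelic_genes=bial,
            )
        )

    margins = {
        r.key: int(r.value) for r in _read("cohort_margins.tsv").itertuples()
    }
    return StudyFixtures(t1, t2, tuple(rows), margins)


def _panel_genes() -> tuple[str, ...]:
    fx = study_fixtures()
    genes = {e.gene for e in fx.table1}
    genes |= set(fx.table2["gene"])
    for e in fx.table3:
        genes |= set(e.germline_genes)
    genes |= {"MLH1", "MSH2", "MSH6", "PMS2", "BRCA1", "BRCA2"}
    return tuple(sorted(genes))


#: Every gene named in the printed tables plus the four MMR genes and
#: BRCA1/2 — the self-contained default for the configurable gene panel.
DEFAULT_PANEL_GENES: tuple[str, ...] = _panel_genes()
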