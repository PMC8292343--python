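"""Synthetic multiple-primary-cancer cohorts with planted ground truth.

Generates a case cohort (default 71 patients, of which 15 are Lynch-syndrome
carriers with a pathogenic-strength mismatch-repair variant, an MSI-high
tumor, and a planted somatic second hit in the same gene) and a sporadic
reference cohort (default 70) carrying background candidate-LoF variants at
configurable per-gene rates.  Every planted quantity is recorded in a
:class:`SimulatedTruth` so recovery can be scored exactly.

Randomness is hierarchical: one global integer seed keys independent
per-patient (and per-tumor) substreams, so adding a patient never perturbs
the data generated for the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .filtering import GermlineVariant
from .phenotype import Diagnosis, PatientRecord, TumorAssay
from .secondhit import CNData, PhasedHetSite
from .fixtures import DEFAULT_PANEL_GENES

__all__ = [
    "CohortConfig",
    "SimulatedTruth",
    "TumorProfile",
    "Cohort",
    "GENE_SPANS",
    "generate_cohort",
    "simulate_phased_baf",
]

# ---------------------------------------------------------------------------
# synthetic gene model: 1 Mb genes laid out deterministically over 22 autosomes

def _build_gene_spans(genes: Sequence[str]) -> dict[str, tuple[str, int, int]]:
    spans = {}
    for i, gene in enumerate(sorted(genes)):
        chrom = str(1 + i % 22)
        slot = i // 22
        start = 2_000_000 + slot * 4_000_000
        spans[gene] = (chrom, start, start + 999_999)
    return spans


#: Strandless 1-based-inclusive spans for the default gene panel.
GENE_SPANS: dict[str, tuple[str, int, int]] = _build_gene_spans(DEFAULT_PANEL_GENES)

# printed carrier gene pattern of the study cohort (MLH1 x10, MSH6 x2, PMS2 x2, MSH2 x1)
_MMR_PATTERN = ["MLH1"] * 10 + ["MSH6", "MSH6", "PMS2", "PMS2", "MSH2"]
# Criteria-code patterns drawn from the printed classifications
_CRITERIA_PATTERNS = [
    ("splice_acceptor", frozenset({"PVS1", "PM2", "PP5"})),
    ("frameshift", frozenset({"PVS1", "PM2"})),
    ("stop_gained", frozenset({"PVS1", "PM2", "PP5"})),
    ("missense", frozenset({"PM2", "PP1", "PP2", "PP3", "PP5"})),
]

_GOOD_QUALITY = {"TLOD": 60.0, "FS": 2.0, "SEQQ": 90.0, "MQ": 60.0, "STRANDQ": 60.0, "DP": 80.0}


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the synthetic cohorts.

    Defaults mirror the printed cohort margins: 71 MPC patients with 15 LS
    carriers, a 70-patient sporadic reference, 42% early-onset, every LS
    carrier with an MSI-high tumor, and background per-tumor MSI-high
    probability giving roughly a fifth of non-carriers an MSI-high tumor.
    ``planted_gene_rates`` maps gene -> (case carrier probability, reference
    carrier probability) for the candidate-gene burden structure.
    """

    n_patients: int = 71
    n_ls_carriers: int = 15
    n_reference: int = 70
    cancer_type_mix: Mapping[str, float] = field(
        default_factory=lambda: {"GC": 0.42, "CRC": 0.45, "EC": 0.11, "other": 0.02}
    )
    eo_fraction: float = 30 / 71
    msih_given_ls: float = 1.0
    msih_background: float = 0.10
    planted_gene_rates: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "RECQL5": (4 / 12, 1 / 70),
            "EME2": (2 / 12, 1 / 70),
            "MSH3": (2 / 12, 2 / 70),
        }
    )
    seed: int = 0
    # secondary knobs (not printed; field-realistic defaults)
    ls_eo_fraction: float = 13 / 15
    fh_known_fraction: float = 56 / 71
    ai_delta: float = 0.2
    ai_depth_mean: float = 60.0
    ai_phase_error: float = 0.02

    def __post_init__(self) -> None:
        probs = [
            self.eo_fraction, self.msih_given_ls, self.msih_background,
            self.ls_eo_fraction, self.fh_known_fraction,
        ] + [p for pair in self.planted_gene_rates.values() for p in pair]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.n_ls_carriers > self.n_patients:
            raise ValueError("n_ls_carriers cannot exceed n_patients")
        if abs(sum(self.cancer_type_mix.values()) - 1.0) > 1e-9:
            raise ValueError("cancer_type_mix must sum to 1")


@dataclass
class SimulatedTruth:
    ls_patient_ids: set[str] = field(default_factory=set)
    planted_germline: list = field(default_factory=list)  # (patient, gene, variant, is_hc)
    planted_second_hits: list = field(default_factory=list)  # (patient, tumor, gene, mechanism)
    planted_ai_regions: list = field(default_factory=list)  # (tumor, chrom, start, end, delta)


@dataclass
class TumorProfile:
    """Somatic call set, copy-number data and phased het sites for one tumor."""

    tumor_id: str
    patient_id: str
    cancer_type: str
    assay: TumorAssay
    somatic_calls: list = field(default_factory=list)
    cn: CNData = field(default_factory=lambda: CNData([], []))
    het_sites: list = field(default_factory=list)


@dataclass
class Cohort:
    patients: list  # PatientRecord
    tumors: list  # TumorProfile
    germline: dict  # patient_id -> list[GermlineVariant]
    truth: SimulatedTruth
    criteria: list  # (patient_id, gene, criteria codes) for the ACMG stage
    reference_ids: list
    reference_germline: dict  # ref patient_id -> list[GermlineVariant]

    def reference_carriers(self) -> dict[str, set]:
        out: dict[str, set] = {}
        for pid, variants in self.reference_germline.items():
            for v in variants:
                out.setdefault(v.gene, set()).add(pid)
        return out


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


def simulate_phased_baf(
    tumor: TumorProfile,
    regions: Sequence[tuple[str, int, int]],
    depth_mean: float = 60.0,
    delta: float = 0.2,
    phase_error: float = 0.02,
    seed: int = 0,
) -> list[PhasedHetSite]:
    """Draw phased allele counts at the tumor's het-site positions.

    Inside any of ``regions`` the haplotype-A count at a site is
    Binomial(depth, 0.5 + delta), flipped to 0.5 - delta with probability
    ``phase_error``; outside, exactly Binomial(depth, 0.5).  Depths are
    Poisson around ``depth_mean`` (floored at 1).  Region membership is a
    set property, so permuting the region list leaves the output unchanged.
    """
    if not (0.0 <= delta < 0.5):
        raise ValueError("delta must lie in [0, 0.5)")
    if not (0.0 <= phase_error <= 0.5):
        raise ValueError("phase_error must lie in [0, 0.5]")
    rng = _rng(seed, 7)
    out = []
    region_set = [(c, s, e) for (c, s, e) in regions]
    for site in tumor.het_sites:
        depth = max(1, int(rng.poisson(depth_mean)))
        inside = any(
            c == site.chrom and s <= site.pos <= e for (c, s, e) in region_set
        )
        if inside:
            p = 0.5 - delta if rng.random() < phase_error else 0.5 + delta
        else:
            p = 0.5
        out.append(
            PhasedHetSite(
                tumor_id=site.tumor_id,
                chrom=site.chrom,
                pos=site.pos,
                hapA_count=int(rng.binomial(depth, p)),
                depth=depth,
                phase_block=site.phase_block,
            )
        )
    return out


def _site_scaffold(tumor_id: str, gene: str, n_sites: int = 240) -> list[PhasedHetSite]:
    """Evenly spaced het-site positions over a window around the gene."""
    chrom, gstart, gend = GENE_SPANS[gene]
    w_start = max(1, gstart - 700_000)
    w_end = gend + 700_000
    step = (w_end - w_start) // n_sites
    return [
        PhasedHetSite(tumor_id, chrom, w_start + i * step, 0, 1, phase_block=gene)
        for i in range(n_sites)
    ]


def _background_variant(pid: str, gene: str, rng: np.random.Generator) -> GermlineVariant:
    chrom, gstart, _ = GENE_SPANS[gene]
    consequence = rng.choice(
        ["missense", "synonymous", "intronic", "frameshift", "stop_gained", "splice_region"],
        p=[0.45, 0.2, 0.1, 0.1, 0.05, 0.1],
    )
    return GermlineVariant(
        patient_id=pid,
        gene=gene,
        chrom=chrom,
        pos=int(gstart + rng.integers(0, 1_000_000)),
        ref="A",
        alt="G",
        consequence=str(consequence),
        cadd=float(rng.uniform(0, 40)),
        af_eas=float(rng.choice([0.0, 0.001, 0.004, 0.02, 0.1], p=[0.3, 0.2, 0.2, 0.15, 0.15])),
        quality=dict(_GOOD_QUALITY),
        cds_relative_position=float(rng.uniform(0, 1)),
    )


def _planted_lof(pid: str, gene: str, consequence: str, rng: np.random.Generator) -> GermlineVariant:
    chrom, gstart, _ = GENE_SPANS[gene]
    return GermlineVariant(
        patient_id=pid,
        gene=gene,
        chrom=chrom,
        pos=int(gstart + rng.integers(100_000, 900_000)),
        ref="AT" if consequence == "frameshift" else "C",
        alt="A" if consequence == "frameshift" else "T",
        consequence=consequence,
        cadd=float(rng.uniform(25, 40)),
        af_eas=float(rng.choice([0.0, 0.001, 0.004])),
        quality=dict(_GOOD_QUALITY),
        cds_relative_position=float(rng.uniform(0.1, 0.9)),
        canonical_splice=True if consequence.startswith("splice") else None,
    )


def _assay(msih: bool, lost_protein: Optional[str], rng: np.random.Generator, tumor_id: str) -> TumorAssay:
    markers = ("BAT25", "BAT26", "D5S346", "D2S123", "D17S250")
    if msih:
        n_unstable = int(rng.integers(2, 6))
        unstable = set(rng.choice(markers, size=n_unstable, replace=False))
        pcr = {m: m in unstable for m in markers}
        score = float(rng.uniform(5, 25))
        ihc = {p: p == lost_protein for p in ("MLH1", "MSH2", "MSH6", "PMS2")} if lost_protein else None
    else:
        pcr = {m: False for m in markers}
        score = float(rng.uniform(0, 2))
        ihc = None
    return TumorAssay(tumor_id, msi_pcr=pcr, ihc_loss=ihc, msisensor_score=score)


def _neutral_cn(rng: np.random.Generator) -> CNData:
    # sample-level aneuploidy noise on chromosome "0" (outside every gene):
    # guarantees the >=3-changed-segments QC is exercised realistically
    segs, bins = [], []
    pos = 1
    for _ in range(4):
        length = int(rng.integers(2_000_000, 5_000_000))
        lr = float(rng.choice([-0.5, 0.45, 0.6, -0.4]))
        segs.append(("0", pos, pos + length - 1, lr, 4))
        for b in range(4):
            bl = length // 4
            bs = pos + b * bl
            bins.append(("0", bs, bs + bl - 1, lr + float(rng.normal(0, 0.05))))
        pos += length + 1_000_000
    return CNData(bins=bins, segments=segs)


def _add_gene_segment(cn: CNData, gene: str, log2: float, rng: np.random.Generator) -> None:
    chrom, gstart, gend = GENE_SPANS[gene]
    start, end = gstart - 500_000, gend + 500_000
    n_bins = 8
    cn.segments.append((chrom, start, end, log2, n_bins))
    bl = (end - start + 1) // n_bins
    for b in range(n_bins):
        bs = start + b * bl
        cn.bins.append((chrom, bs, bs + bl - 1, log2 + float(rng.normal(0, 0.03))))


def generate_cohort(config: CohortConfig = CohortConfig()) -> Cohort:
    """Generate the case cohort, its tumors, germline calls and ground truth.

    The first ``n_ls_carriers`` patients are the LS carriers (deterministic
    planting, so group sizes match the configuration exactly).  Each carrier
    receives one pathogenic-strength MMR variant with a Table-1-style
    criteria pattern, at least one MSI-high tumor, and one somatic second
    hit (allelic imbalance, deletion, or somatic LoF mutation) in the same
    gene in that tumor.  Identical seeds give bit-identical cohorts.
    """
    cfg = config
    truth = SimulatedTruth()
    patients, tumors = [], []
    germline: dict[str, list] = {}
    criteria: list = []
    types = list(cfg.cancer_type_mix)
    type_p = np.array([cfg.cancer_type_mix[t] for t in types], dtype=float)

    n_nonls = cfg.n_patients - cfg.n_ls_carriers
    # background early-onset rate chosen so the cohort margin matches eo_fraction
    if n_nonls > 0:
        p_eo_bg = (cfg.eo_fraction * cfg.n_patients - cfg.ls_eo_fraction * cfg.n_ls_carriers) / n_nonls
        p_eo_bg = min(1.0, max(0.0, p_eo_bg))
    else:
        p_eo_bg = 0.0

    for i in range(cfg.n_patients):
        pid = f"sim_{i + 1:03d}"
        rng = _rng(cfg.seed, 1000 + i)
        is_ls = i < cfg.n_ls_carriers

        # --- diagnoses
        n_dx = 3 if rng.random() < 0.04 else 2
        dx_types = list(rng.choice(types, size=min(n_dx, len(types)), replace=False, p=type_p))
        eo = rng.random() < (cfg.ls_eo_fraction if is_ls else p_eo_bg)
        second_age = float(rng.uniform(30, 55) if eo else rng.uniform(56, 78))
        synchronous = rng.random() < 0.4
        interval = int(rng.integers(0, 365)) if synchronous else int(rng.integers(365, 3650))
        first_age = max(20.0, second_age - interval / 365.25)
        diagnoses = [
            Diagnosis(dx_types[0], first_age, 0),
            Diagnosis(dx_types[1], second_age, interval),
        ]
        if n_dx == 3:
            extra = int(interval + rng.integers(365, 2000))
            diagnoses.append(Diagnosis(dx_types[2], second_age + extra / 365.25, extra))

        # --- family history
        if rng.random() < cfg.fh_known_fraction:
            p_ge2 = 0.9 if is_ls else 15 / 46
            n_fdr = int(rng.integers(2, 5)) if rng.random() < p_ge2 else int(rng.integers(0, 2))
        else:
            n_fdr = None

        # --- germline variants
        variants: list[GermlineVariant] = []
        candidate_genes: list[str] = []
        if is_ls:
            gene = _MMR_PATTERN[i % len(_MMR_PATTERN)]
            consequence, codes = _CRITERIA_PATTERNS[i % len(_CRITERIA_PATTERNS)]
            v = _planted_lof(pid, gene, consequence, rng)
            variants.append(v)
            criteria.append((pid, gene, codes))
            truth.ls_patient_ids.add(pid)
            truth.planted_germline.append(
                (pid, gene, v, consequence in ("frameshift", "stop_gained", "splice_acceptor", "splice_donor"))
            )
            candidate_genes.append(gene)
            ls_gene = gene
        else:
            ls_gene = None
            for gene, (p_case, _) in cfg.planted_gene_rates.items():
                if rng.random() < p_case:
                    v = _planted_lof(pid, gene, "frameshift", rng)
                    variants.append(v)
                    truth.planted_germline.append((pid, gene, v, True))
                    candidate_genes.append(gene)
            if rng.random() < 0.4:  # VUS-level criteria assignment
                criteria.append((pid, str(rng.choice(DEFAULT_PANEL_GENES)), frozenset({"PM2"})))
        for _ in range(int(rng.poisson(3))):
            variants.append(_background_variant(pid, str(rng.choice(DEFAULT_PANEL_GENES)), rng))
        germline[pid] = variants

        # --- tumors
        tumor_ids = []
        mechanism = None
        if is_ls:
            mechanism = str(
                rng.choice(["allelic_imbalance", "deletion", "somatic_lof_mutation"], p=[0.6, 0.2, 0.2])
            )
        for j, dx in enumerate(diagnoses):
            tid = f"{pid}_t{j + 1}"
            tumor_ids.append(tid)
            carries_hit = is_ls and j == 0
            if carries_hit:
                msih = rng.random() < cfg.msih_given_ls
            elif is_ls:
                msih = rng.random() < 0.7
            else:
                msih = rng.random() < cfg.msih_background
            lost = ls_gene if (is_ls and msih) else None
            tumor = TumorProfile(
                tumor_id=tid,
                patient_id=pid,
                cancer_type=dx.cancer_type,
                assay=_assay(msih, lost, rng, tid),
                cn=_neutral_cn(rng),
            )
            # het-site tracks around each candidate gene of the patient
            ai_regions: list[tuple[str, int, int]] = []
            for gene in candidate_genes:
                tumor.het_sites.extend(_site_scaffold(tid, gene))
                _add_gene_segment(tumor.cn, gene, float(rng.normal(0, 0.05)), rng)
            if carries_hit and mechanism == "allelic_imbalance":
                chrom, gstart, gend = GENE_SPANS[ls_gene]
                ai_regions.append((chrom, gstart, gend))
                truth.planted_ai_regions.append((tid, chrom, gstart, gend, cfg.ai_delta))
            if carries_hit and mechanism == "deletion":
                # overwrite the neutral gene segment with a deletion
                tumor.cn.segments = [
                    s for s in tumor.cn.segments if GENE_SPANS[ls_gene][0] != s[0]
                ]
                tumor.cn.bins = [
                    b for b in tumor.cn.bins if GENE_SPANS[ls_gene][0] != b[0]
                ]
                _add_gene_segment(tumor.cn, ls_gene, -0.8, rng)
            if carries_hit and mechanism == "somatic_lof_mutation":
                chrom, gstart, _ = GENE_SPANS[ls_gene]
                tumor.somatic_calls.append(
                    GermlineVariant(
                        patient_id=pid,
                        gene=ls_gene,
                        chrom=chrom,
                        pos=int(gstart + rng.integers(100_000, 900_000)),
                        ref="CT",
                        alt="C",
                        consequence="frameshift",
                        cadd=float(rng.uniform(25, 40)),
                        quality=dict(_GOOD_QUALITY),
                        vaf=float(rng.uniform(0.15, 0.45)),
                    )
                )
            if tumor.het_sites:
                tumor.het_sites.sort(key=lambda s: (s.chrom, s.pos))
                tumor.het_sites = simulate_phased_baf(
                    tumor,
                    ai_regions,
                    depth_mean=cfg.ai_depth_mean,
                    delta=cfg.ai_delta,
                    phase_error=cfg.ai_phase_error,
                    seed=cfg.seed * 1000 + i * 10 + j,
                )
            if carries_hit:
                truth.planted_second_hits.append((pid, tid, ls_gene, mechanism))
            tumors.append(tumor)

        patients.append(
            PatientRecord(
                patient_id=pid,
                diagnoses=diagnoses,
                n_first_degree_relatives_with_cancer=n_fdr,
                tumors=tuple(tumor_ids),
            )
        )

    # --- reference cohort
    reference_ids = [f"ref_{i + 1:03d}" for i in range(cfg.n_reference)]
    reference_germline: dict[str, list] = {}
    for i, rid in enumerate(reference_ids):
        rng = _rng(cfg.seed, 500_000 + i)
        variants = []
        for gene, (_, p_ref) in cfg.planted_gene_rates.items():
            if rng.random() < p_ref:
                variants.append(_planted_lof(rid, gene, "frameshift", rng))
        if variants:
            reference_germline[rid] = variants

    return Cohort(
        patients=patients,
        tumors=tumors,
        germline=germline,
        truth=truth,
        criteria=criteria,
        reference_ids=reference_ids,
        reference_germline=reference_germline,
    )
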