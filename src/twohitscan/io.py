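"""File formats, pipeline configuration and the end-to-end orchestrator.

Internal coordinates are 1-based inclusive (VCF convention) everywhere;
BED input is converted at the boundary.  Variant annotations travel as VCF
INFO keys (GENE, CSQ, CADD, AF_EAS, AF, CDSPOS, CANON, VAF and the caller
quality metrics TLOD/FS/SEQQ/MQ/STRANDQ/DP); fields absent from a record
stay absent on the parsed object — no defaults are invented.

The orchestrator runs the stages in method order — phenotype labels,
germline triage, ACMG classification, somatic second hits, gene burden,
clinical associations — writing one TSV per stage plus a JSON run manifest
(inputs, thresholds, seed, version) sufficient to re-execute the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .acmg import CriteriaSet, classify_cohort
from .burden import association_tables, burden_scan, exact_2x2
from .cohort import GENE_SPANS, Cohort
from .filtering import FilterThresholds, GermlineVariant, select_candidate_lof
from .phenotype import (
    Concurrency,
    Diagnosis,
    PatientRecord,
    TumorAssay,
    concurrency,
    is_early_onset,
    msi_status,
    strong_family_history,
    PCR_MARKERS,
    MMR_PROTEINS,
)
from .secondhit import (
    AIConfig,
    CNData,
    PhasedHetSite,
    call_biallelic,
    detect_ai,
    gene_cn_call,
    somatic_damaging,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_vcf",
    "write_vcf",
    "read_seg",
    "read_bed",
    "write_bed",
    "read_tsv_sites",
    "write_tsv_sites",
    "run_pipeline",
    "write_cohort",
]

_INFO_FLOAT = ("CADD", "AF_EAS", "AF", "CDSPOS", "VAF", "TLOD", "FS", "SEQQ", "MQ", "STRANDQ", "DP")
_QUALITY_KEYS = ("TLOD", "FS", "SEQQ", "MQ", "STRANDQ", "DP")

_VCF_HEADER = "\n".join(
    ["##fileformat=VCFv4.2"]
    + [f"##contig=<ID={c}>" for c in ["0"] + [str(i) for i in range(1, 23)] + ["X", "Y"]]
    + [
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">',
        '##INFO=<ID=CANON,Number=1,Type=Integer,Description="Canonical splice site (1/0)">',
    ]
    + [
        f'##INFO=<ID={k},Number={"A" if k == "AF" else 1},'
        f'Type={"Integer" if k == "DP" else "Float"},Description="{k}">'
        for k in _INFO_FLOAT
    ]
    + [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
)


def write_vcf(variants: Sequence[GermlineVariant], path, sample: str) -> None:
    """Write a single-sample VCF carrying the pipeline's annotation keys."""
    from .filtering import chrom_sort_key

    lines = [_VCF_HEADER, f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}"]
    for v in sorted(variants, key=lambda v: (chrom_sort_key(v.chrom), v.pos, v.alt)):
        info = [f"GENE={v.gene}", f"CSQ={v.consequence}"]
        for key, attr in (("CADD", "cadd"), ("AF_EAS", "af_eas"), ("AF", "af_global"),
                          ("CDSPOS", "cds_relative_position"), ("VAF", "vaf")):
            val = getattr(v, attr)
            if val is not None:
                info.append(f"{key}={val:.6g}")
        if v.canonical_splice is not None:
            info.append(f"CANON={int(v.canonical_splice)}")
        for key in _QUALITY_KEYS:
            if v.quality.get(key) is not None:
                val = v.quality[key]
                info.append(f"{key}={int(val)}" if key == "DP" else f"{key}={val:.6g}")
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{';'.join(info)}\tGT\t0/1"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path, patient_id: Optional[str] = None) -> list[GermlineVariant]:
    """Read an annotated VCF into variant records, one per ALT allele."""
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # unreadable header is a hard error
        raise OSError(f"cannot read VCF header of {path}: {exc}") from exc
    sample = patient_id or (vcf.samples[0] if vcf.samples else "unknown")
    out = []
    for rec in vcf:
        info = dict(rec.INFO)
        quality = {
            k: float(info[k]) for k in _QUALITY_KEYS if k in info and info[k] is not None
        }
        if "DP" not in quality:
            try:  # FORMAT DP is an accepted fallback when INFO lacks it
                fmt_dp = rec.format("DP")
            except KeyError:
                fmt_dp = None
            if fmt_dp is not None:
                quality["DP"] = float(fmt_dp[0][0])

        def f(key):
            v = info.get(key)
            return float(v) if v is not None else None

        canon = info.get("CANON")
        for alt in rec.ALT:
            out.append(
                GermlineVariant(
                    patient_id=sample,
                    gene=str(info.get("GENE", "")),
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    consequence=str(info.get("CSQ", "missense")),
                    cadd=f("CADD"),
                    af_eas=f("AF_EAS"),
                    af_global=f("AF"),
                    quality=quality,
                    cds_relative_position=f("CDSPOS"),
                    canonical_splice=None if canon is None else bool(int(canon)),
                    vaf=f("VAF"),
                )
            )
    vcf.close()
    return out


def write_seg(cn: CNData, path, sample: str) -> None:
    rows = [
        {"ID": sample, "chrom": c, "start": s, "end": e, "num_mark": nm, "seg_mean": lr}
        for (c, s, e, lr, nm) in cn.segments
    ]
    pd.DataFrame(rows, columns=["ID", "chrom", "start", "end", "num_mark", "seg_mean"]).to_csv(
        path, sep="\t", index=False
    )


def read_seg(path) -> dict[str, list]:
    """SEG file -> sample -> [(chrom, start, end, log2, n_bins)], validated
    for overlapping segments within a sample (hard error listing offenders)."""
    df = pd.read_csv(path, sep="\t")
    need = {"ID", "chrom", "start", "end", "num_mark", "seg_mean"}
    if not need <= set(df.columns):
        raise ValueError(f"SEG file {path} missing columns {sorted(need - set(df.columns))}")
    out: dict[str, list] = {}
    for sid, grp in df.groupby("ID"):
        segs = [
            (str(r.chrom), int(r.start), int(r.end), float(r.seg_mean), int(r.num_mark))
            for r in grp.itertuples()
        ]
        segs.sort(key=lambda s: (s[0], s[1]))
        offenders = [
            (a, b)
            for a, b in zip(segs, segs[1:])
            if a[0] == b[0] and b[1] <= a[2]
        ]
        if offenders:
            raise ValueError(f"overlapping segments in sample {sid}: {offenders}")
        out[str(sid)] = segs
    return out


def write_bins(cn: CNData, path) -> None:
    pd.DataFrame(cn.bins, columns=["chrom", "start", "end", "log2"]).to_csv(
        path, sep="\t", index=False
    )


def read_bins(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [(r.chrom, int(r.start), int(r.end), float(r.log2)) for r in df.itertuples()]


def write_bed(gene_spans: dict, path) -> None:
    """Gene spans (1-based inclusive) -> BED (0-based half-open)."""
    with open(path, "w") as fh:
        for gene, (chrom, start, end) in sorted(gene_spans.items(), key=lambda kv: kv[0]):
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{gene}\n")


def read_bed(path) -> dict[str, tuple[str, int, int]]:
    """BED -> gene -> (chrom, start, end) in 1-based inclusive coordinates."""
    spans = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"{path}:{ln}: BED needs 4 columns (chrom start end name)")
        chrom, start, end, name = parts[:4]
        spans[name] = (chrom, int(start) + 1, int(end))
    return spans


_SITE_COLUMNS = ["chrom", "pos", "hapA_count", "depth", "phase_block"]


def write_tsv_sites(sites: Sequence[PhasedHetSite], path) -> None:
    pd.DataFrame(
        [
            {"chrom": s.chrom, "pos": s.pos, "hapA_count": s.hapA_count,
             "depth": s.depth, "phase_block": s.phase_block}
            for s in sites
        ],
        columns=_SITE_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_tsv_sites(path, tumor_id: str) -> list[PhasedHetSite]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "phase_block": str})
    sites = [
        PhasedHetSite(tumor_id, r.chrom, int(r.pos), int(r.hapA_count), int(r.depth), str(r.phase_block))
        for r in df.itertuples()
    ]
    ordered = sorted(sites, key=lambda s: (s.chrom, s.phase_block, s.pos))
    if [s.pos for s in sites] != [s.pos for s in ordered]:
        warnings.warn(f"het-site TSV {path} was not position-sorted; sorting")
    return ordered


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """All inputs, thresholds and cutoffs of a pipeline run."""

    outdir: str
    phenotype_tsv: str
    assays_tsv: str
    criteria_tsv: str
    germline_dir: str
    somatic_dir: str
    sites_dir: str
    seg_dir: str
    bins_dir: str
    genes_bed: str
    reference_carriers_tsv: str
    n_reference: int
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    ai: AIConfig = field(default_factory=AIConfig)
    deletion_log2: float = -0.3
    min_changed_segments: int = 3
    change_log2: float = 0.3
    onset_cutoff: float = 55.0
    sync_interval_days: int = 365
    pcr_unstable_min: int = 2
    msisensor_cutoff: float = 3.5
    gene_set: Sequence[str] = ()
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        d["ai"] = dataclasses.asdict(self.ai)
        d["gene_set"] = list(self.gene_set)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        thr = d.pop("thresholds", {})
        thr.pop("dmaf", None)
        d["thresholds"] = FilterThresholds(**thr)
        d["ai"] = AIConfig(**d.pop("ai", {}))
        return cls(**d)


# ---------------------------------------------------------------------------
# cohort serialization (simulate -> files) and phenotype round-trip


def write_cohort(cohort: Cohort, outdir, config=None) -> PipelineConfig:
    """Serialize a generated cohort into the pipeline's input formats and
    return a ready-to-run :class:`PipelineConfig` (also written as YAML)."""
    out = Path(outdir)
    for sub in ("germline", "somatic", "sites", "seg", "bins"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    pheno_rows, assay_rows = [], []
    for p in cohort.patients:
        for k, d in enumerate(p.diagnoses):
            pheno_rows.append(
                {
                    "patient_id": p.patient_id,
                    "dx_index": k,
                    "cancer_type": d.cancer_type,
                    "age_at_dx": round(d.age_at_dx, 2),
                    "dx_date_offset": d.dx_date_offset,
                    "n_fdr_with_cancer": (
                        "" if p.n_first_degree_relatives_with_cancer is None
                        else p.n_first_degree_relatives_with_cancer
                    ),
                    "tumors": ",".join(p.tumors),
                }
            )
    for t in cohort.tumors:
        row = {
            "tumor_id": t.tumor_id,
            "patient_id": t.patient_id,
            "cancer_type": t.cancer_type,
            "msisensor_score": "" if t.assay.msisensor_score is None else t.assay.msisensor_score,
        }
        for m in PCR_MARKERS:
            row[f"pcr_{m}"] = "" if t.assay.msi_pcr is None else int(t.assay.msi_pcr.get(m, False))
        for pr in MMR_PROTEINS:
            row[f"ihc_loss_{pr}"] = "" if t.assay.ihc_loss is None else int(t.assay.ihc_loss.get(pr, False))
        assay_rows.append(row)
    pd.DataFrame(pheno_rows).to_csv(out / "phenotype.tsv", sep="\t", index=False)
    pd.DataFrame(assay_rows).to_csv(out / "assays.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            {"patient_id": pid, "gene": gene, "hgvs": "NA", "criteria": ",".join(sorted(codes))}
            for pid, gene, codes in cohort.criteria
        ]
    ).to_csv(out / "criteria.tsv", sep="\t", index=False)

    for pid, variants in cohort.germline.items():
        write_vcf(variants, out / "germline" / f"{pid}.vcf", pid)
    for t in cohort.tumors:
        write_vcf(t.somatic_calls, out / "somatic" / f"{t.tumor_id}.vcf", t.tumor_id)
        write_tsv_sites(t.het_sites, out / "sites" / f"{t.tumor_id}.tsv")
        write_seg(t.cn, out / "seg" / f"{t.tumor_id}.seg", t.tumor_id)
        write_bins(t.cn, out / "bins" / f"{t.tumor_id}.tsv")

    write_bed(GENE_SPANS, out / "genes.bed")
    ref_rows = [
        {"patient_id": rid, "gene": v.gene}
        for rid, variants in cohort.reference_germline.items()
        for v in variants
    ]
    pd.DataFrame(ref_rows, columns=["patient_id", "gene"]).to_csv(
        out / "reference_carriers.tsv", sep="\t", index=False
    )

    pc = PipelineConfig(
        outdir=str(out / "results"),
        phenotype_tsv=str(out / "phenotype.tsv"),
        assays_tsv=str(out / "assays.tsv"),
        criteria_tsv=str(out / "criteria.tsv"),
        germline_dir=str(out / "germline"),
        somatic_dir=str(out / "somatic"),
        sites_dir=str(out / "sites"),
        seg_dir=str(out / "seg"),
        bins_dir=str(out / "bins"),
        genes_bed=str(out / "genes.bed"),
        reference_carriers_tsv=str(out / "reference_carriers.tsv"),
        n_reference=len(cohort.reference_ids),
        gene_set=list(GENE_SPANS),
        seed=config.seed if config is not None else 0,
    )
    pc.to_yaml(out / "config.yaml")
    return pc


def read_phenotypes(phenotype_tsv, assays_tsv):
    """Phenotype + assay TSVs -> (PatientRecords, {tumor_id: TumorAssay},
    {tumor_id: patient_id})."""
    pdf = pd.read_csv(phenotype_tsv, sep="\t")
    patients = []
    for pid, grp in pdf.groupby("patient_id", sort=False):
        grp = grp.sort_values("dx_index")
        diagnoses = [
            Diagnosis(r.cancer_type, float(r.age_at_dx), int(r.dx_date_offset))
            for r in grp.itertuples()
        ]
        first = grp.iloc[0]
        n_fdr = first["n_fdr_with_cancer"]
        n_fdr = None if pd.isna(n_fdr) or n_fdr == "" else int(n_fdr)
        tumors = tuple(str(first["tumors"]).split(",")) if first["tumors"] else ()
        patients.append(PatientRecord(str(pid), diagnoses, n_fdr, tumors))

    adf = pd.read_csv(assays_tsv, sep="\t")
    assays, tumor_patient = {}, {}
    for r in adf.itertuples():
        pcr_vals = {m: getattr(r, f"pcr_{m}") for m in PCR_MARKERS}
        pcr = None if any(pd.isna(v) for v in pcr_vals.values()) else {
            m: bool(int(v)) for m, v in pcr_vals.items()
        }
        ihc_vals = {p: getattr(r, f"ihc_loss_{p}") for p in MMR_PROTEINS}
        ihc = None if any(pd.isna(v) for v in ihc_vals.values()) else {
            p: bool(int(v)) for p, v in ihc_vals.items()
        }
        score = None if pd.isna(r.msisensor_score) else float(r.msisensor_score)
        assays[r.tumor_id] = TumorAssay(r.tumor_id, msi_pcr=pcr, ihc_loss=ihc, msisensor_score=score)
        tumor_patient[r.tumor_id] = str(r.patient_id)
    return patients, assays, tumor_patient


# ---------------------------------------------------------------------------
# orchestrator


def _fmt_or(x) -> str:
    if x is None:
        return "NA"
    return "Inf" if x == float("inf") else f"{x:.2f}"


def _result_row(res) -> dict:
    if res is None:
        return {"p": "NA", "or_cmle": "NA", "ci_low": "NA", "ci_high": "NA"}
    return {
        "p": f"{res.p_two_sided:.4g}",
        "or_cmle": _fmt_or(res.or_cmle),
        "ci_low": _fmt_or(res.ci_low),
        "ci_high": _fmt_or(res.ci_high),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order; returns the report bundle as a dict of
    DataFrames (also written as TSVs plus a JSON manifest under outdir)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if not config.gene_set:
        raise ValueError("gene_set must be nonempty")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": dataclasses.asdict(config.thresholds),
        "ai": dataclasses.asdict(config.ai),
        "inputs": {
            k: getattr(config, k)
            for k in (
                "phenotype_tsv", "assays_tsv", "criteria_tsv", "germline_dir",
                "somatic_dir", "sites_dir", "seg_dir", "bins_dir", "genes_bed",
                "reference_carriers_tsv",
            )
        },
        "stages": [],
    }
    report: dict = {}

    def _checkpoint(stage: str, **counts) -> None:
        manifest["stages"].append({"stage": stage, **counts})
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    try:
        # 1. phenotype
        patients, assays, tumor_patient = read_phenotypes(config.phenotype_tsv, config.assays_tsv)
        msi = {tid: msi_status(a, config.pcr_unstable_min, config.msisensor_cutoff) for tid, a in assays.items()}
        derived = pd.DataFrame(
            [
                {
                    "patient_id": p.patient_id,
                    "early_onset": is_early_onset(p, config.onset_cutoff),
                    "concurrency": concurrency(p, config.sync_interval_days).value,
                    "strong_family_history": strong_family_history(p),
                    "any_msih_tumor": any(msi.get(t) is not None and msi[t].value == "MSI-H" for t in p.tumors),
                }
                for p in patients
            ]
        )
        derived.to_csv(out / "phenotype_labels.tsv", sep="\t", index=False)
        _checkpoint("phenotype", patients=len(patients), tumors=len(assays))

        # 2. germline triage
        gene_set = set(config.gene_set)
        gene_spans = read_bed(config.genes_bed)
        candidates: dict[str, list] = {}
        n_in = n_out = 0
        for p in patients:
            vpath = Path(config.germline_dir) / f"{p.patient_id}.vcf"
            variants = read_vcf(vpath, p.patient_id) if vpath.exists() else []
            n_in += len(variants)
            calls = select_candidate_lof(variants, gene_set, config.thresholds)
            n_out += len(calls)
            candidates[p.patient_id] = calls
        logger.info("triage kept %d/%d germline variants", n_out, n_in)
        pd.DataFrame(
            [
                {"patient_id": pid, "gene": c.variant.gene, "chrom": c.variant.chrom,
                 "pos": c.variant.pos, "alt": c.variant.alt, "category": c.category.value}
                for pid, calls in candidates.items()
                for c in calls
            ]
        ).to_csv(out / "candidates.tsv", sep="\t", index=False)
        _checkpoint("filter", variants_in=n_in, candidates=n_out)

        # 3. ACMG classification
        cdf = pd.read_csv(config.criteria_tsv, sep="\t")
        assignments = [
            (str(r.patient_id), str(r.gene), CriteriaSet(str(r.criteria).split(",")))
            for r in cdf.itertuples()
        ]
        cohort_cls = classify_cohort(assignments)
        pd.DataFrame(
            [
                {"patient_id": pid, "gene": gene, "criteria": ",".join(sorted(crit.codes)),
                 "classification": label.short}
                for pid, gene, crit, label in cohort_cls.calls
            ]
        ).to_csv(out / "classifications.tsv", sep="\t", index=False)
        _checkpoint("classify", assignments=len(assignments), carriers=len(cohort_cls.carriers))

        # 4. somatic second hits
        tumors_by_patient = {p.patient_id: list(p.tumors) for p in patients}
        ai_events, cn_calls, somatic_by_tumor = {}, {}, {}
        for p in patients:
            cand_genes = {c.variant.gene for c in candidates[p.patient_id]}
            for tid in p.tumors:
                spath = Path(config.sites_dir) / f"{tid}.tsv"
                sites = read_tsv_sites(spath, tid) if spath.exists() else []
                ai_events[tid] = detect_ai(sites, config.ai) if sites else []
                segpath = Path(config.seg_dir) / f"{tid}.seg"
                binpath = Path(config.bins_dir) / f"{tid}.tsv"
                if segpath.exists() and binpath.exists():
                    segs = read_seg(segpath).get(tid, [])
                    cn = CNData(bins=read_bins(binpath), segments=segs)
                    cn_calls[tid] = {
                        g: gene_cn_call(cn, g, gene_spans[g], config.deletion_log2,
                                        config.min_changed_segments, config.change_log2)
                        for g in cand_genes
                        if g in gene_spans
                    }
                else:
                    cn_calls[tid] = {}
                vpath = Path(config.somatic_dir) / f"{tid}.vcf"
                som = read_vcf(vpath, tid) if vpath.exists() else []
                somatic_by_tumor[tid] = somatic_damaging(som, gene_set, config.thresholds)
        biallelic = call_biallelic(
            candidates, tumors_by_patient, ai_events, cn_calls, somatic_by_tumor, gene_spans
        )
        pd.DataFrame(
            [
                {"patient_id": b.patient_id, "tumor_id": b.tumor_id, "gene": b.gene,
                 "mechanisms": ",".join(sorted(b.mechanisms)),
                 "germline_category": b.germline_category}
                for b in biallelic
            ]
        ).to_csv(out / "biallelic.tsv", sep="\t", index=False)
        _checkpoint("second_hit", biallelic_calls=len(biallelic))

        # 5. gene burden
        carriers = cohort_cls.carriers
        case_carriers: dict[str, dict[str, set]] = {}
        for pid, calls in candidates.items():
            group = "LS" if pid in carriers else "non_LS"
            for c in calls:
                case_carriers.setdefault(c.variant.gene, {"non_LS": set(), "LS": set()})[group].add(pid)
        rdf = pd.read_csv(config.reference_carriers_tsv, sep="\t")
        reference_carriers: dict[str, set] = {}
        for r in rdf.itertuples():
            reference_carriers.setdefault(str(r.gene), set()).add(str(r.patient_id))
        group_sizes = {
            "LS": len(carriers),
            "non_LS": len(patients) - len(carriers),
            "reference": config.n_reference,
        }
        rows = burden_scan(case_carriers, reference_carriers, group_sizes)
        pd.DataFrame(
            [
                {
                    "gene": r.gene, "n_nonls": r.n_case_nonls, "n_ls": r.n_case_ls,
                    "n_total": r.n_case_total, "n_reference": r.n_reference,
                    "p_nonls_vs_ref": f"{r.nonls_vs_ref.p_two_sided:.4g}",
                    "or_nonls_vs_ref": _fmt_or(r.nonls_vs_ref.or_cmle),
                    "p_ls_vs_ref": f"{r.ls_vs_ref.p_two_sided:.4g}",
                    "significant": r.significant,
                }
                for r in rows
            ]
        ).to_csv(out / "burden.tsv", sep="\t", index=False)
        _checkpoint("burden", genes_tested=len(rows))

        # 6. clinical associations
        @dataclass
        class _P:
            is_carrier: bool
            early_onset: bool
            strong_fh: Optional[bool]
            synchronous: bool

        labeled = [
            _P(
                is_carrier=p.patient_id in carriers,
                early_onset=is_early_onset(p, config.onset_cutoff),
                strong_fh=strong_family_history(p),
                synchronous=concurrency(p, config.sync_interval_days) is Concurrency.SYNCHRONOUS,
            )
            for p in patients
        ]
        assoc = association_tables(labeled)
        pd.DataFrame(
            [
                {"label": label, "a": t.a, "b": t.b, "c": t.c, "d": t.d, **_result_row(res)}
                for label, t, res in assoc
            ]
        ).to_csv(out / "associations.tsv", sep="\t", index=False)
        _checkpoint("associations", tables=len(assoc))

        report = {
            "phenotype_labels": derived,
            "candidates": candidates,
            "classification": cohort_cls,
            "biallelic": biallelic,
            "burden": rows,
            "associations": assoc,
        }
    except Exception:
        # manifest of completed stages is already on disk
        raise
    return report
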