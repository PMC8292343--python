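"""Somatic second-hit calling: allelic imbalance, deletion, somatic mutation.

Under the two-hit model, a germline candidate variant becomes far more
suspicious when the tumor has lost or mutated the remaining wild-type
allele.  This module calls the three somatic mechanisms and joins them with
the germline candidates into bi-allelic alterations:

* **allelic imbalance (AI)** — a two-state hidden Markov model over phased
  heterozygous-site allele counts.  In the balanced state the haplotype-A
  read count is Binomial(depth, 1/2); in the imbalanced state the success
  probability shifts to 1/2 + delta, contaminated by phase-switch errors
  that flip it to 1/2 - delta with probability epsilon.  The chain's
  stationary distribution fixes the event prevalence (0.1 by default) and
  the expected event length sets the self-transition of the imbalanced
  state.  Sites with posterior probability of imbalance above 0.9 (strict)
  are merged into events.
* **deletion** — gene-level log2 copy-number ratio, the bin-length-weighted
  mean over all bins of every segment overlapping the gene; below -0.3
  (strict) is a deletion, gated by a sample-level QC requiring at least 3
  segments of copy-number change genome-wide.
* **somatic damaging mutation** — the same quality/deleteriousness
  predicates as the germline triage applied to the tumor's somatic calls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import binom

from .filtering import (
    FilterThresholds,
    GermlineVariant,
    LofCall,
    is_damaging,
    passes_quality,
)

__all__ = [
    "PhasedHetSite",
    "AIConfig",
    "AIEvent",
    "CNData",
    "GeneCNCall",
    "BiallelicCall",
    "MMR_GENES",
    "ai_posteriors",
    "extract_ai_events",
    "detect_ai",
    "gene_cn_call",
    "somatic_damaging",
    "has_double_somatic_mmr",
    "call_biallelic",
]

logger = logging.getLogger(__name__)

MMR_GENES = frozenset({"MLH1", "MSH2", "MSH6", "PMS2"})


@dataclass(frozen=True)
class PhasedHetSite:
    tumor_id: str
    chrom: str
    pos: int  # 1-based
    hapA_count: int
    depth: int
    phase_block: str = "pb0"

    def __post_init__(self) -> None:
        if not (0 <= self.hapA_count <= self.depth):
            raise ValueError("need 0 <= hapA_count <= depth")


@dataclass(frozen=True)
class AIConfig:
    """Allelic-imbalance HMM parameters.

    prevalence is the stationary probability of the imbalanced state and
    posterior_cutoff the (strict) event threshold; delta is the allele-
    fraction shift under imbalance, phase_error the per-site probability of
    a phase flip, and mean_event_sites the expected sojourn length of an
    imbalance event in sites.
    """

    prevalence: float = 0.1
    posterior_cutoff: float = 0.90
    delta: float = 0.10
    phase_error: float = 0.02
    mean_event_sites: float = 100.0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if not (0.0 <= self.delta < 0.5):
            raise ValueError("delta must lie in [0, 0.5)")
        if not (0.0 < self.posterior_cutoff < 1.0):
            raise ValueError("posterior_cutoff must lie in (0, 1)")
        if self.mean_event_sites < 1.0:
            raise ValueError("mean_event_sites must be >= 1")

    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic transitions [balanced, imbalanced] with the
        required stationary distribution (1 - prevalence, prevalence)."""
        q_ib = 1.0 / self.mean_event_sites  # imbalanced -> balanced
        # stationary pi = q_bi / (q_bi + q_ib)  =>  q_bi below
        q_bi = self.prevalence * q_ib / (1.0 - self.prevalence)
        if q_bi > 1.0:
            raise ValueError("prevalence/mean_event_sites imply an invalid chain")
        return np.array([[1.0 - q_bi, q_bi], [q_ib, 1.0 - q_ib]])


@dataclass(frozen=True)
class AIEvent:
    tumor_id: str
    chrom: str
    start: int  # 1-based inclusive, first site position
    end: int  # last site position
    n_sites: int
    mean_posterior: float

    def __post_init__(self) -> None:
        if self.start > self.end or self.n_sites < 1:
            raise ValueError("malformed AI event")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= end and start <= self.end


def _log_emissions(counts: np.ndarray, depths: np.ndarray, cfg: AIConfig) -> np.ndarray:
    """(n, 2) log emission matrix: column 0 balanced, column 1 imbalanced."""
    lb = binom.logpmf(counts, depths, 0.5)
    up = binom.logpmf(counts, depths, 0.5 + cfg.delta)
    dn = binom.logpmf(counts, depths, 0.5 - cfg.delta) if cfg.phase_error > 0 else None
    if cfg.phase_error > 0:
        li = np.logaddexp(
            math.log1p(-cfg.phase_error) + up, math.log(cfg.phase_error) + dn
        )
    else:
        li = up
    return np.column_stack([lb, li])


def _forward_backward(
    log_emis: np.ndarray, trans: np.ndarray, init: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Scaled forward-backward. Returns (posteriors, loglik_fwd, loglik_bwd)."""
    n = log_emis.shape[0]
    emis = np.exp(log_emis - log_emis.max(axis=1, keepdims=True))
    shift = log_emis.max(axis=1)  # re-added to both likelihoods

    alpha = np.empty((n, 2))
    scale = np.empty(n)
    a = init * emis[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for i in range(1, n):
        a = (alpha[i - 1] @ trans) * emis[i]
        scale[i] = a.sum()
        alpha[i] = a / scale[i]
    loglik_fwd = float(np.log(scale).sum() + shift.sum())

    beta = np.empty((n, 2))
    beta[-1] = 1.0
    for i in range(n - 2, -1, -1):
        beta[i] = (trans @ (emis[i + 1] * beta[i + 1])) / scale[i + 1]
    # backward-pass likelihood: sum_j init_j e_j(1) beta_1(j) * prod(scale)
    loglik_bwd = float(
        np.log((init * emis[0] * beta[0]).sum()) + np.log(scale[1:]).sum() + shift.sum()
    )

    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post, loglik_fwd, loglik_bwd


def ai_posteriors(
    sites: Sequence[PhasedHetSite], cfg: AIConfig = AIConfig()
) -> np.ndarray:
    """Per-site posterior probability of the imbalanced state.

    Sites must lie on a single chromosome and be position-sorted; the caller
    splits multi-chromosome (and multi-phase-block) site lists.
    """
    if not sites:
        return np.zeros(0)
    chroms = {s.chrom for s in sites}
    if len(chroms) > 1:
        raise ValueError(f"sites span multiple chromosomes: {sorted(chroms)}")
    pos = [s.pos for s in sites]
    if any(b < a for a, b in zip(pos, pos[1:])):
        raise ValueError("sites must be sorted by position")
    if any(s.depth < 1 for s in sites):
        raise ValueError("site depths must be >= 1")
    counts = np.array([s.hapA_count for s in sites])
    depths = np.array([s.depth for s in sites])
    trans = cfg.transition_matrix()
    init = np.array([1.0 - cfg.prevalence, cfg.prevalence])
    post, _, _ = _forward_backward(_log_emissions(counts, depths, cfg), trans, init)
    return post[:, 1]


def extract_ai_events(
    posteriors: np.ndarray, sites: Sequence[PhasedHetSite], cfg: AIConfig = AIConfig()
) -> list[AIEvent]:
    """Maximal runs of consecutive sites with posterior strictly above cutoff."""
    if len(posteriors) != len(sites):
        raise ValueError("posteriors not aligned to sites")
    events: list[AIEvent] = []
    run_start: Optional[int] = None
    for i, p in enumerate(list(posteriors) + [-1.0]):  # sentinel flushes last run
        if p > cfg.posterior_cutoff:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            run = sites[run_start:i]
            events.append(
                AIEvent(
                    tumor_id=run[0].tumor_id,
                    chrom=run[0].chrom,
                    start=run[0].pos,
                    end=run[-1].pos,
                    n_sites=len(run),
                    mean_posterior=float(np.mean(posteriors[run_start:i])),
                )
            )
            run_start = None
    return events


def detect_ai(
    sites: Iterable[PhasedHetSite], cfg: AIConfig = AIConfig()
) -> list[AIEvent]:
    """Run the HMM independently per (chromosome, phase block) and pool events.

    Phase is only comparable within a block, so events never span blocks.
    """
    groups: dict[tuple[str, str], list[PhasedHetSite]] = {}
    for s in sites:
        groups.setdefault((s.chrom, s.phase_block), []).append(s)
    events: list[AIEvent] = []
    for key in sorted(groups):
        block = sorted(groups[key], key=lambda s: s.pos)
        post = ai_posteriors(block, cfg)
        events.extend(extract_ai_events(post, block, cfg))
    return events


# ---------------------------------------------------------------------------
# copy number


@dataclass
class CNData:
    """Copy-number bins and segments for one tumor (1-based inclusive)."""

    bins: list  # (chrom, start, end, log2_ratio)
    segments: list  # (chrom, start, end, log2_ratio, n_bins)


@dataclass
class GeneCNCall:
    gene: str
    weighted_mean_log2: Optional[float]
    is_deletion: bool
    qc_pass: bool


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    # 1-based inclusive intervals; half-open arithmetic internally
    return a_start < b_end + 1 and b_start < a_end + 1


def gene_cn_call(
    cn: CNData,
    gene: str,
    gene_span: tuple[str, int, int],
    deletion_log2: float = -0.3,
    min_changed_segments: int = 3,
    change_log2: float = 0.3,
) -> GeneCNCall:
    """Gene-level copy-number call from segmented bin-level log2 ratios.

    The gene mean is the bin-length-weighted mean over *all* bins falling in
    any segment that overlaps the gene span (the whole segment counts, not
    just its in-gene part).  A deletion requires that mean strictly below
    ``deletion_log2`` and a sample-level QC of at least
    ``min_changed_segments`` segments with \\|log2\\| >= ``change_log2``.
    """
    chrom, gstart, gend = gene_span
    if gstart > gend:
        raise ValueError("invalid gene span")
    n_changed = sum(1 for (_, _, _, lr, *_) in cn.segments if abs(lr) >= change_log2)
    qc_pass = n_changed >= min_changed_segments

    seg_hits = [
        (c, s, e)
        for (c, s, e, _, *_) in cn.segments
        if c == chrom and _overlap(s, e, gstart, gend)
    ]
    if not seg_hits:
        return GeneCNCall(gene, None, False, False)

    wsum = 0.0
    lsum = 0.0
    for (bc, bs, be, blr) in cn.bins:
        if any(bc == c and _overlap(bs, be, s, e) for (c, s, e) in seg_hits):
            length = be - bs + 1
            wsum += blr * length
            lsum += length
    mean = wsum / lsum if lsum > 0 else None
    is_del = qc_pass and mean is not None and mean < deletion_log2
    return GeneCNCall(gene, mean, is_del, qc_pass)


# ---------------------------------------------------------------------------
# somatic mutations and bi-allelic integration


def somatic_damaging(
    somatic_calls: Iterable[GermlineVariant],
    gene_set: Iterable[str],
    thresholds: FilterThresholds = FilterThresholds(),
) -> dict[str, list[GermlineVariant]]:
    """Somatic calls passing the quality + damaging predicates, by gene.

    Somatic calls reuse the germline record shape (with ``vaf`` set); the
    rarity filter does not apply to somatic events.
    """
    genes = set(gene_set)
    by_gene: dict[str, list[GermlineVariant]] = {}
    for v in somatic_calls:
        if v.gene in genes and passes_quality(v, thresholds) and is_damaging(v, thresholds):
            by_gene.setdefault(v.gene, []).append(v)
    return by_gene


def has_double_somatic_mmr(somatic_by_gene: Mapping[str, list]) -> bool:
    """Two or more somatic damaging mutations across the MMR genes in one
    tumor — the double-somatic mismatch-repair phenocopy flag."""
    return sum(len(calls) for g, calls in somatic_by_gene.items() if g in MMR_GENES) >= 2


@dataclass(frozen=True)
class BiallelicCall:
    patient_id: str
    tumor_id: str
    gene: str
    mechanisms: frozenset[str]  # subset of the three mechanism names
    germline_category: str

    def __post_init__(self) -> None:
        allowed = {"somatic_lof_mutation", "allelic_imbalance", "deletion"}
        if not self.mechanisms or not self.mechanisms <= allowed:
            raise ValueError(f"mechanisms must be a nonempty subset of {allowed}")


def call_biallelic(
    candidates_by_patient: Mapping[str, Sequence[LofCall]],
    tumors_by_patient: Mapping[str, Sequence[str]],
    ai_events_by_tumor: Mapping[str, Sequence[AIEvent]],
    cn_calls_by_tumor: Mapping[str, Mapping[str, GeneCNCall]],
    somatic_by_tumor: Mapping[str, Mapping[str, list]],
    gene_spans: Mapping[str, tuple[str, int, int]],
) -> list[BiallelicCall]:
    """Join germline candidates with somatic second-hit evidence per tumor.

    For every (patient, tumor, candidate gene): a somatic damaging mutation
    in the gene contributes mechanism ``somatic_lof_mutation``; an AI event
    overlapping the gene body contributes ``allelic_imbalance``; a gene-level
    deletion contributes ``deletion``.  All applicable mechanisms are kept;
    nothing is emitted when none applies.  Genes missing from the gene model
    are skipped with a warning.
    """
    calls: list[BiallelicCall] = []
    for patient, cands in candidates_by_patient.items():
        for tumor in tumors_by_patient.get(patient, ()):
            for cand in cands:
                gene = cand.variant.gene
                span = gene_spans.get(gene)
                if span is None:
                    logger.warning(
                        "gene %s (patient %s) has no span in the gene model; skipped",
                        gene, patient,
                    )
                    continue
                mechanisms = set()
                if somatic_by_tumor.get(tumor, {}).get(gene):
                    mechanisms.add("somatic_lof_mutation")
                if any(
                    ev.overlaps(*span) for ev in ai_events_by_tumor.get(tumor, ())
                ):
                    mechanisms.add("allelic_imbalance")
                cncall = cn_calls_by_tumor.get(tumor, {}).get(gene)
                if cncall is not None and cncall.is_deletion:
                    mechanisms.add("deletion")
                if mechanisms:
                    calls.append(
                        BiallelicCall(
                            patient_id=patient,
                            tumor_id=tumor,
                            gene=gene,
                            mechanisms=frozenset(mechanisms),
                            germline_category=cand.category.value,
                        )
                    )
    return calls
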