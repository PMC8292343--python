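"""Allelic-imbalance HMM, gene-level copy number, and bi-allelic calling."""

import itertools
import logging
import math

import numpy as np
import pytest

from twohitscan.filtering import FilterThresholds, GermlineVariant, LofCategory, classify_lof
from twohitscan.secondhit import (
    AIConfig,
    AIEvent,
    CNData,
    PhasedHetSite,
    _forward_backward,
    _log_emissions,
    ai_posteriors,
    call_biallelic,
    detect_ai,
    extract_ai_events,
    gene_cn_call,
    has_double_somatic_mmr,
    somatic_damaging,
)

GOOD_Q = {"TLOD": 50.0, "FS": 2.0, "SEQQ": 90.0, "MQ": 60.0, "STRANDQ": 60.0, "DP": 80.0}


def sites_from(counts, depths, chrom="1", tumor="t"):
    return [
        PhasedHetSite(tumor, chrom, 100 + 10 * i, int(c), int(d))
        for i, (c, d) in enumerate(zip(counts, depths))
    ]


def brute_force_posteriors(counts, depths, cfg):
    """Exhaustive path-sum marginalization over all 2^n state sequences."""
    le = _log_emissions(np.asarray(counts), np.asarray(depths), cfg)
    T = cfg.transition_matrix()
    init = np.array([1 - cfg.prevalence, cfg.prevalence])
    n = len(counts)
    logps = []
    for path in itertools.product([0, 1], repeat=n):
        lp = math.log(init[path[0]]) + le[0, path[0]]
        for i in range(1, n):
            lp += math.log(T[path[i - 1], path[i]]) + le[i, path[i]]
        logps.append((path, lp))
    z = np.logaddexp.reduce([lp for _, lp in logps])
    post = np.zeros(n)
    for path, lp in logps:
        w = math.exp(lp - z)
        for i, s in enumerate(path):
            post[i] += w * s
    return post


class TestAiPosteriors:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_path_sum(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        depths = rng.integers(5, 80, n)
        counts = [int(rng.integers(0, d + 1)) for d in depths]
        cfg = AIConfig()
        got = ai_posteriors(sites_from(counts, depths), cfg)
        expected = brute_force_posteriors(counts, depths, cfg)
        assert np.max(np.abs(got - expected)) < 1e-8

    def test_uninformative_likelihood_returns_prevalence(self):
        # with delta=0 both states emit identically, so every posterior is
        # the stationary prevalence
        cfg = AIConfig(delta=0.0, phase_error=0.0)
        rng = np.random.default_rng(3)
        depths = rng.integers(10, 60, 50)
        counts = [int(rng.binomial(d, 0.5)) for d in depths]
        post = ai_posteriors(sites_from(counts, depths), cfg)
        assert np.max(np.abs(post - cfg.prevalence)) < 1e-9

    def test_posteriors_normalized_and_likelihood_symmetric(self):
        rng = np.random.default_rng(4)
        depths = rng.integers(5, 100, 300)
        counts = np.array([rng.integers(0, d + 1) for d in depths])
        cfg = AIConfig()
        le = _log_emissions(counts, depths, cfg)
        post, lf, lb = _forward_backward(
            le, cfg.transition_matrix(), np.array([0.9, 0.1])
        )
        assert np.max(np.abs(post.sum(axis=1) - 1.0)) < 1e-9
        assert abs(lf - lb) <= 1e-9 * abs(lf)

    def test_planted_event_separates_posteriors(self):
        rng = np.random.default_rng(5)
        n, depth = 500, 60
        inside = np.zeros(n, bool)
        inside[200:320] = True
        counts = [
            int(rng.binomial(depth, 0.7 if inside[i] else 0.5)) for i in range(n)
        ]
        cfg = AIConfig(delta=0.2, phase_error=0.0)
        post = ai_posteriors(sites_from(counts, [depth] * n), cfg)
        assert post[inside].mean() > 0.9
        assert post[~inside].mean() < 0.1

    def test_rejects_multi_chromosome_and_unsorted_input(self):
        s1 = PhasedHetSite("t", "1", 100, 5, 10)
        s2 = PhasedHetSite("t", "2", 200, 5, 10)
        with pytest.raises(ValueError, match="chromosom"):
            ai_posteriors([s1, s2])
        with pytest.raises(ValueError, match="sorted"):
            ai_posteriors([PhasedHetSite("t", "1", 200, 5, 10), s1])

    def test_empty_site_list(self):
        assert len(ai_posteriors([])) == 0


class TestEventExtraction:
    def test_no_events_below_cutoff(self):
        sites = sites_from([5] * 4, [10] * 4)
        assert extract_ai_events(np.full(4, 0.1), sites) == []

    def test_run_semantics(self):
        sites = sites_from([5] * 4, [10] * 4)
        events = extract_ai_events(np.array([0.95, 0.95, 0.2, 0.95]), sites)
        assert [e.n_sites for e in events] == [2, 1]
        assert events[0].start == 100 and events[0].end == 110

    def test_cutoff_is_strict(self):
        sites = sites_from([5], [10])
        assert extract_ai_events(np.array([0.90]), sites) == []
        assert len(extract_ai_events(np.array([0.900001]), sites)) == 1

    def test_events_never_span_phase_blocks(self):
        # identical high-imbalance signal in two blocks yields two events
        sites = [
            PhasedHetSite("t", "1", 100 + i, 58, 60, phase_block="a") for i in range(30)
        ] + [
            PhasedHetSite("t", "1", 200 + i, 58, 60, phase_block="b") for i in range(30)
        ]
        events = detect_ai(sites, AIConfig(delta=0.45))
        assert len(events) == 2


class TestGeneCopyNumber:
    def cn(self, bins, segments):
        return CNData(bins=bins, segments=segments)

    def test_uniform_deleted_segment(self):
        cn = self.cn(
            bins=[("1", 1, 100, -0.5), ("1", 101, 200, -0.5)],
            segments=[("1", 1, 200, -0.5, 2)] + [("2", i, i + 9, 0.5, 1) for i in (1, 20, 40)],
        )
        call = gene_cn_call(cn, "G", ("1", 50, 150))
        assert call.weighted_mean_log2 == pytest.approx(-0.5)
        assert call.qc_pass and call.is_deletion

    def test_shallow_loss_is_not_deletion(self):
        cn = self.cn(
            bins=[("1", 1, 100, -0.2), ("1", 101, 200, -0.2)],
            segments=[("1", 1, 200, -0.2, 2)] + [("2", i, i + 9, 0.5, 1) for i in (1, 20, 40)],
        )
        call = gene_cn_call(cn, "G", ("1", 50, 150))
        assert call.weighted_mean_log2 == pytest.approx(-0.2)
        assert not call.is_deletion

    def test_length_weighted_mean(self):
        # -1.0 over 100 bp with 0.0 over 300 bp averages to -0.25
        cn = self.cn(
            bins=[("1", 1, 100, -1.0), ("1", 101, 400, 0.0)],
            segments=[("1", 1, 400, -0.25, 2)] + [("2", i, i + 9, 0.5, 1) for i in (1, 20, 40)],
        )
        call = gene_cn_call(cn, "G", ("1", 10, 50))
        assert call.weighted_mean_log2 == pytest.approx(-0.25)
        assert not call.is_deletion

    def test_whole_segment_bins_count_not_only_in_gene_part(self):
        # gene overlaps only the neutral tail, but the whole segment's bins
        # enter the mean
        cn = self.cn(
            bins=[("1", 1, 100, -1.0), ("1", 101, 200, 0.0)],
            segments=[("1", 1, 200, -0.5, 2)],
        )
        call = gene_cn_call(cn, "G", ("1", 150, 180))
        assert call.weighted_mean_log2 == pytest.approx(-0.5)

    def test_sample_qc_gates_deletion(self):
        cn = self.cn(
            bins=[("1", 1, 200, -0.8)],
            segments=[("1", 1, 200, -0.8, 1)],  # only one changed segment
        )
        call = gene_cn_call(cn, "G", ("1", 50, 150))
        assert call.weighted_mean_log2 == pytest.approx(-0.8)
        assert not call.qc_pass and not call.is_deletion

    def test_gene_without_segment_overlap(self):
        cn = self.cn(bins=[("1", 1, 100, 0.0)], segments=[("1", 1, 100, 0.0, 1)])
        call = gene_cn_call(cn, "G", ("2", 50, 150))
        assert call.weighted_mean_log2 is None and not call.is_deletion


def somatic(gene, consequence="frameshift", vaf=0.2, **kw):
    return GermlineVariant(
        patient_id="t1", gene=gene, chrom="1", pos=kw.pop("pos", 500), ref="CT", alt="C",
        consequence=consequence, cadd=kw.pop("cadd", 33.0), quality=dict(GOOD_Q),
        vaf=vaf, **kw,
    )


class TestSomaticDamaging:
    def test_double_somatic_mmr_hit(self):
        calls = [somatic("MLH1", vaf=0.186), somatic("PMS2", vaf=0.188, pos=900)]
        by_gene = somatic_damaging(calls, {"MLH1", "PMS2", "CASP8"})
        assert set(by_gene) == {"MLH1", "PMS2"}
        assert has_double_somatic_mmr(by_gene)

    def test_synonymous_excluded(self):
        by_gene = somatic_damaging([somatic("MLH1", consequence="synonymous")], {"MLH1"})
        assert by_gene == {}

    def test_empty_input(self):
        assert somatic_damaging([], {"MLH1"}) == {}

    def test_no_rarity_requirement_for_somatic(self):
        # common-population-frequency somatic call still counts
        v = somatic("MLH1", af_eas=0.2)
        assert "MLH1" in somatic_damaging([v], {"MLH1"})


def lof_call(patient, gene, consequence="frameshift"):
    return classify_lof(
        GermlineVariant(
            patient_id=patient, gene=gene, chrom="1", pos=100, ref="AT", alt="A",
            consequence=consequence, cadd=35.0, quality=dict(GOOD_Q),
            cds_relative_position=0.3,
        )
    )


class TestBiallelicCalling:
    spans = {"MLH1": ("3", 100, 2000), "RECQL5": ("17", 100, 2000)}

    def test_ai_overlap_yields_loh_mechanism(self):
        cands = {"p1": [lof_call("p1", "MLH1")]}
        ai = {"t1": [AIEvent("t1", "3", 500, 1500, 50, 0.99)]}
        calls = call_biallelic(cands, {"p1": ["t1"]}, ai, {}, {}, self.spans)
        assert len(calls) == 1
        assert calls[0].mechanisms == {"allelic_imbalance"}
        assert calls[0].germline_category == LofCategory.HIGH_CONFIDENCE.value

    def test_mutation_and_ai_carry_both_mechanisms(self):
        cands = {"p1": [lof_call("p1", "MLH1")]}
        ai = {"t1": [AIEvent("t1", "3", 500, 1500, 50, 0.99)]}
        som = {"t1": {"MLH1": [somatic("MLH1")]}}
        calls = call_biallelic(cands, {"p1": ["t1"]}, ai, {}, som, self.spans)
        assert calls[0].mechanisms == {"allelic_imbalance", "somatic_lof_mutation"}

    def test_no_mechanism_emits_nothing(self):
        cands = {"p1": [lof_call("p1", "RECQL5", "missense")]}
        assert call_biallelic(cands, {"p1": ["t1"]}, {}, {}, {}, self.spans) == []

    def test_missing_gene_span_skipped_with_warning(self, caplog):
        cands = {"p1": [lof_call("p1", "MLH1")]}
        with caplog.at_level(logging.WARNING, logger="twohitscan.secondhit"):
            calls = call_biallelic(cands, {"p1": ["t1"]}, {}, {}, {}, {})
        assert calls == []
        assert any("no span" in r.message for r in caplog.records)

    def test_referential_integrity(self):
        # every emitted call's gene belongs to the patient's candidate set
        cands = {
            "p1": [lof_call("p1", "MLH1")],
            "p2": [lof_call("p2", "RECQL5")],
        }
        ai = {
            "t1": [AIEvent("t1", "3", 500, 1500, 50, 0.99)],
            "t2": [AIEvent("t2", "3", 500, 1500, 50, 0.99)],  # MLH1 locus, p2 tumor
        }
        calls = call_biallelic(
            cands, {"p1": ["t1"], "p2": ["t2"]}, ai, {}, {}, self.spans
        )
        for c in calls:
            genes = {lc.variant.gene for lc in cands[c.patient_id]}
            assert c.gene in genes
        # p2 has no MLH1 candidate, so the MLH1-locus AI in t2 produces nothing
        assert {c.patient_id for c in calls} == {"p1"}
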