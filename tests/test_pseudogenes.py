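"""Pseudogene metrics, classification rules and the intergenic scan."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from conftest import backtranslate, random_protein
from synloss.genomeio import GeneModel, GenomeBundle, revcomp
from synloss.pseudogenes import (PseudoMetrics, classify_pseudogene,
                                 high_confidence_filter, scan_intergenic)


def _metrics(identity=0.6, ratio=0.8, exons=1, match=100, dis=False):
    return PseudoMetrics(identity=identity, align_ratio=ratio,
                         exon_number=exons, match_length_aa=match,
                         has_disablement=dis)


class TestHighConfidenceFilter:
    @pytest.mark.parametrize("identity,match,expected", [
        (0.31, 51, True),    # both just above: accepted
        (0.30, 100, False),  # identity bound is strict
        (0.90, 50, False),   # match-length bound is strict
        (0.31, 50, False),
        (0.30, 51, False),
    ])
    def test_strict_inequalities(self, identity, match, expected):
        m = _metrics(identity=identity, match=match)
        assert high_confidence_filter(m) is expected


class TestClassifyPseudogene:
    @pytest.mark.parametrize("kwargs,expected", [
        (dict(exons=1, ratio=0.80, identity=0.60), "PSSD"),
        (dict(exons=3, identity=0.50, dis=True), "DUP"),
        (dict(exons=1, ratio=0.50, identity=0.40), "FRAG"),
        # align ratio exactly 0.7 is excluded by both the PSSD strict ">"
        # and the FRAG strict "<"
        (dict(exons=1, ratio=0.70, identity=0.50), "OTHER"),
        (dict(exons=1, ratio=0.96, identity=0.60), "OTHER"),
        (dict(exons=1, ratio=0.80, identity=0.96), "OTHER"),
        (dict(exons=2, identity=0.50, dis=False), "OTHER"),
        (dict(exons=1, ratio=0.80, identity=0.20), "OTHER"),
    ])
    def test_worked_boundary_cases(self, kwargs, expected):
        assert classify_pseudogene(_metrics(**kwargs)) == expected

    @given(identity=st.floats(0, 1), ratio=st.floats(0, 1),
           exons=st.integers(1, 5), dis=st.booleans())
    @settings(deadline=None, max_examples=300, derandomize=True)
    def test_total_and_deterministic(self, identity, ratio, exons, dis):
        m = _metrics(identity=identity, ratio=ratio, exons=exons, dis=dis)
        klass = classify_pseudogene(m)
        assert klass in ("PSSD", "DUP", "FRAG", "OTHER")
        assert classify_pseudogene(m) == klass


def _bundle_with_insert(rng, inserts, n_genes=3):
    """A one-chromosome bundle of annotated genes with given intergenic
    inserts: inserts is [(offset_in_spacer, dna), ...] one per spacer."""
    parts, genes, pos = [], [], 0
    spacer = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
    for i in range(n_genes):
        pre = spacer(800)
        if i < len(inserts):
            at, dna = inserts[i]
            pre = pre[:at] + dna + pre[at:]
        parts.append(pre)
        pos += len(pre)
        protein = "M" + random_protein(rng, 59)
        cds = backtranslate(rng, protein) + "TAA"
        genes.append(GeneModel(f"g{i}", "chr1", pos, pos + len(cds), "+",
                               ((pos, pos + len(cds)),), protein))
        parts.append(cds)
        pos += len(cds)
    parts.append(spacer(500))
    return GenomeBundle(genome_id="t", chromosomes={"chr1": "".join(parts)},
                        genes={"chr1": genes})


def _decay(rng, dna, rate=0.08):
    chars = list(dna)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = rng.choice([c for c in "ACGT" if c != chars[i]])
    return "".join(chars)


def test_scan_finds_single_implant_with_right_seed():
    """A genome whose only intergenic signal is one decayed copy of seed S
    yields exactly one high-confidence call naming S."""
    rng = random.Random(41)
    seed_protein = "M" + random_protein(rng, 119)
    copy = _decay(rng, backtranslate(rng, seed_protein))
    bundle = _bundle_with_insert(rng, [(400, copy)])
    calls = scan_intergenic(bundle, {"seedS": seed_protein,
                                     "other": "M" + random_protein(rng, 99)})
    assert len(calls) == 1
    call = calls[0]
    assert call.seed_id == "seedS"
    assert call.high_confidence
    assert call.metrics.exon_number == 1
    assert 380 <= call.start <= 420


def test_scan_reports_minus_strand_implants():
    rng = random.Random(42)
    seed_protein = "M" + random_protein(rng, 119)
    copy = revcomp(backtranslate(rng, seed_protein))
    bundle = _bundle_with_insert(rng, [(300, copy)])
    calls = scan_intergenic(bundle, {"seedS": seed_protein})
    assert len(calls) == 1
    assert calls[0].strand == "-"
    assert calls[0].metrics.identity == 1.0


def test_overlapping_calls_resolved_by_score():
    """Two seeds hitting the same locus: only the better-scoring call
    survives the >= 50% overlap suppression."""
    rng = random.Random(43)
    seed1 = "M" + random_protein(rng, 119)
    seed2 = seed1[:60] + random_protein(rng, 60)  # half-related decoy
    copy = backtranslate(rng, seed1)
    bundle = _bundle_with_insert(rng, [(400, copy)])
    calls = scan_intergenic(bundle, {"s1": seed1, "s2": seed2})
    assert [c.seed_id for c in calls] == ["s1"]


def test_scan_without_intergenic_sequence_warns():
    protein = "M" + "K" * 30
    cds = "ATG" + "AAA" * 30
    bundle = GenomeBundle(
        genome_id="t", chromosomes={"chr1": cds},
        genes={"chr1": [GeneModel("g0", "chr1", 0, len(cds), "+",
                                  ((0, len(cds)),), protein)]})
    with pytest.warns(UserWarning, match="no intergenic"):
        assert scan_intergenic(bundle, {"s": protein}) == []


def test_empty_seed_set_is_hard_error(analysis):
    with pytest.raises(ValueError):
        scan_intergenic(analysis["bundle_b"], {})


class TestOnSimulatedImplants:
    def test_processed_implants_are_single_exon(self, analysis):
        """Every implanted retro-copy (PSSD) call has exon_number 1."""
        truth, calls = analysis["truth"], analysis["pseudo_calls"]
        for ev in truth.of_kind("pseudogene_PSSD"):
            overlapping = [c for c in calls if c.chrom == ev.chrom
                           and min(c.end, ev.end) - max(c.start, ev.start)
                           >= 1]
            assert overlapping, f"no call at PSSD locus {ev.source_gene}"
            assert overlapping[0].metrics.exon_number == 1

    def test_dup_implants_show_disablements(self, analysis):
        truth, calls = analysis["truth"], analysis["pseudo_calls"]
        for ev in truth.of_kind("pseudogene_DUP"):
            overlapping = [c for c in calls if c.chrom == ev.chrom
                           and min(c.end, ev.end) - max(c.start, ev.start)
                           >= 1]
            assert overlapping
            assert overlapping[0].metrics.has_disablement
            assert overlapping[0].metrics.exon_number > 1
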