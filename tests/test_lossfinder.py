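"""Flanking-gene deletion tracing, re-prediction filter, SV tagging."""

import random
import warnings

import pytest

from conftest import backtranslate, random_protein
from synloss.genomeio import GeneModel, GenomeBundle
from synloss.homology import OrthologPair
from synloss.lossfinder import (LossCandidate, recovery_check,
                                repredict_in_interval, tag_sv_losses,
                                trace_deletions)
from synloss.simulate import SimConfig, simulate_genome_pair
from synloss.synteny import build_microsynteny


def _bundles_with_missing_middle(names_a, names_b):
    """Two toy bundles sharing gene names; orthologs by name identity."""
    def build(genome_id, names):
        rng = random.Random(1)
        parts, genes, pos = [], [], 0
        for name in names:
            parts.append("".join(rng.choice("ACGT") for _ in range(300)))
            pos += 300
            protein = "M" + "K" * 30
            cds = "ATG" + "AAA" * 30 + "TAA"
            genes.append(GeneModel(f"{name}_{genome_id}", "chr1", pos,
                                   pos + len(cds), "+",
                                   ((pos, pos + len(cds)),), protein))
            parts.append(cds)
            pos += len(cds)
        parts.append("ACGT" * 50)
        return GenomeBundle(genome_id=genome_id,
                            chromosomes={"chr1": "".join(parts)},
                            genes={"chr1": genes})

    a = build("a", names_a)
    b = build("b", names_b)
    pairs = [OrthologPair(f"{n}_a", f"{n}_b", 100.0)
             for n in names_a if n in names_b]
    return a, b, pairs


def test_abc_rule_emits_one_candidate_for_missing_middle_gene():
    """Orders v,w,A,B,C,x,y vs the same without B: exactly one candidate,
    for B, flanked by the A/C anchors."""
    a, b, pairs = _bundles_with_missing_middle("vwxyz", "vwyz")
    blocks = build_microsynteny(pairs, a, b)
    cands = trace_deletions(blocks, a, b)
    assert len(cands) == 1
    cand = cands[0]
    assert cand.missing_gene == "x_a"
    assert cand.genome_with_gene == "a"
    assert cand.anchor_left.gene_a == "w_a"
    assert cand.anchor_right.gene_a == "y_a"
    # target interval lies strictly between the orthologs of the anchors
    wb, yb = b.gene("w_b"), b.gene("y_b")
    assert cand.target_interval == ("chr1", wb.end, yb.start)


def test_no_candidate_when_middle_gene_is_anchored():
    a, b, pairs = _bundles_with_missing_middle("vwxyz", "vwxyz")
    blocks = build_microsynteny(pairs, a, b)
    assert trace_deletions(blocks, a, b) == []


def test_losses_found_in_both_directions():
    """A gene missing from genome A (present in B) is also traced."""
    a, b, pairs = _bundles_with_missing_middle("vwyz", "vwxyz")
    blocks = build_microsynteny(pairs, a, b)
    cands = trace_deletions(blocks, a, b)
    assert len(cands) == 1
    assert cands[0].missing_gene == "x_b"
    assert cands[0].genome_with_gene == "b"


def _candidate(interval=("chr1", 0, 0)):
    pair = OrthologPair("l_a", "l_b", 1.0)
    return LossCandidate(missing_gene="m_a", genome_with_gene="a",
                         missing_rank=5, missing_chrom="chr1",
                         anchor_left=pair, anchor_right=pair,
                         target_interval=interval)


_RNG = random.Random(51)
_SEED_PROTEIN = "M" + random_protein(_RNG, 149)
_SEED_CDS = backtranslate(_RNG, _SEED_PROTEIN)
_FLANK = "".join(_RNG.choice("ACGT") for _ in range(400))


class TestRepredictInInterval:
    seed = _SEED_PROTEIN
    cds = _SEED_CDS
    flank = _FLANK

    def test_intact_hidden_copy_is_false_positive(self):
        cand = repredict_in_interval(_candidate(), self.seed,
                                     self.flank + self.cds + self.flank)
        assert cand.status == "false_positive"
        assert cand.evidence["coverage"] > 0.95
        assert cand.evidence["frameshifts"] == 0
        assert cand.evidence["premature_stops"] == 0

    def test_random_dna_is_confirmed_lost(self):
        rng = random.Random(52)
        junk = "".join(rng.choice("ACGT") for _ in range(2000))
        cand = repredict_in_interval(_candidate(), self.seed, junk)
        assert cand.status == "confirmed_lost"
        assert cand.evidence["coverage"] < 0.70

    def test_copy_with_inserted_base_is_confirmed_lost(self):
        broken = self.cds[:200] + "G" + self.cds[200:]
        cand = repredict_in_interval(_candidate(), self.seed,
                                     self.flank + broken + self.flank)
        assert cand.status == "confirmed_lost"
        assert cand.evidence["frameshifts"] >= 1

    def test_empty_interval_is_confirmed_lost_with_zero_coverage(self):
        cand = repredict_in_interval(_candidate(), self.seed, "")
        assert cand.status == "confirmed_lost"
        assert cand.evidence["coverage"] == 0.0

    def test_false_positive_rule_semantics(self, analysis):
        """Across all traced candidates of the simulated pair:
        status false_positive <=> coverage > 0.70 and zero frameshifts and
        zero premature stops (sv_associated implies the rule failed)."""
        for cand in analysis["candidates"]:
            ev = cand.evidence
            intact = (ev["coverage"] > 0.70 and ev["frameshifts"] == 0
                      and ev["premature_stops"] == 0)
            assert (cand.status == "false_positive") == intact


class TestTagSvLosses:
    def test_zero_breakpoints_is_identity(self):
        cand = _candidate()
        cand.status = "confirmed_lost"
        tag_sv_losses([cand], [])
        assert cand.status == "confirmed_lost"

    def test_mid_block_loss_stays_confirmed(self, analysis):
        truth = analysis["truth"]
        sv_ids = {e.source_gene for e in truth.of_kind("deletion")
                  if e.details.get("sv_adjacent")}
        for cand in analysis["candidates"]:
            if cand.status == "confirmed_lost":
                assert cand.missing_gene not in sv_ids

    def test_inversion_adjacent_losses_are_tagged(self, analysis):
        truth = analysis["truth"]
        sv_ids = {e.source_gene for e in truth.of_kind("deletion")
                  if e.details.get("sv_adjacent")}
        tagged = {c.missing_gene for c in analysis["candidates"]
                  if c.status == "sv_associated"}
        assert sv_ids <= tagged


class TestRecoveryCheck:
    def test_empty_loss_list_returns_zero_with_warning(self, sim_pair):
        bundle_a, bundle_b, _ = sim_pair
        with pytest.warns(UserWarning, match="no confirmed losses"):
            assert recovery_check([], bundle_b, bundle_a) == 0.0

    def test_relocated_intact_copy_is_recovered(self):
        """Of 5 hard deletions plus 1 relocation, only the relocated gene
        is found intact genome-wide: fraction 1/6."""
        cfg = SimConfig(seed=6, n_chromosomes=1, genes_per_chromosome=60,
                        n_deletions=5, n_hidden_intact_copies=0,
                        n_pseudogenes_per_class=(0, 0, 0), n_inversions=0,
                        n_relocated_intact_copies=1)
        bundle_a, bundle_b, truth = simulate_genome_pair(cfg)
        pairs = [OrthologPair(g.gene_id, "gb" + g.gene_id[2:], 1.0)
                 for g in bundle_a.all_genes()
                 if "gb" + g.gene_id[2:] in bundle_b]
        blocks = build_microsynteny(pairs, bundle_a, bundle_b)
        cands = trace_deletions(blocks, bundle_a, bundle_b)
        assert len(cands) == 6
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            frac = recovery_check(cands, bundle_b, bundle_a)
        assert frac == pytest.approx(1 / 6)


def test_swapped_genomes_find_the_same_losses(analysis):
    """Running the chain with genomes exchanged finds the losses implanted
    on the other lineage (roles swapped)."""
    bundle_a, bundle_b = analysis["bundle_a"], analysis["bundle_b"]
    swapped_pairs = [OrthologPair(p.gene_b, p.gene_a, p.score)
                     for p in analysis["pairs"]]
    blocks = build_microsynteny(swapped_pairs, bundle_b, bundle_a)
    cands = trace_deletions(blocks, bundle_b, bundle_a)
    original = {c.missing_gene for c in analysis["candidates"]}
    swapped = {c.missing_gene for c in cands}
    assert swapped == original
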