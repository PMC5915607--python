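"""4DTv, Fisher gene-family tests and TE proximity statistics."""

import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import fisher_greater, fisher_two_sided
from synloss.evostats import (CodonPairAlignment, FamilyCountTable,
                              build_codon_alignment, compute_4dtv,
                              fisher_family_test, fourdtv_distribution,
                              te_proximity)
from synloss.simulate import simulate_codon_pairs, simulate_te_layout


def _aln(*cols):
    return CodonPairAlignment("gx", "gy", tuple(cols))


class TestCompute4dtv:
    def test_identical_sequences_give_zero(self):
        aln = _aln(("GGT", "GGT"), ("CCA", "CCA"), ("GCG", "GCG"))
        assert compute_4dtv(aln) == 0.0

    def test_hand_enumerated_three_codon_example(self):
        """(GGT|GGG), (CCT|CCC), (GCA|GCA): three eligible fourfold sites,
        one transversion (T<->G), one transition (T<->C) -> 1/3."""
        aln = _aln(("GGT", "GGG"), ("CCT", "CCC"), ("GCA", "GCA"))
        assert compute_4dtv(aln) == pytest.approx(1 / 3)

    def test_no_eligible_sites_is_undefined_not_zero(self):
        aln = _aln(("ATG", "ATG"), ("TGG", "TGG"))
        assert compute_4dtv(aln) is None

    def test_differing_first_two_positions_are_ineligible(self):
        # both codons fourfold (GGN vs GCN) but prefixes differ
        aln = _aln(("GGT", "GCT"))
        assert compute_4dtv(aln) is None

    def test_bad_codon_column_is_hard_error(self):
        with pytest.raises(ValueError):
            _aln(("GG", "GGT"))

    def test_empty_alignment_is_hard_error(self):
        with pytest.raises(ValueError):
            compute_4dtv(_aln())

    @given(st.lists(st.tuples(
        st.sampled_from(["CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG",
                         "AT", "TG"]),
        st.sampled_from("ACGT"), st.sampled_from("ACGT")), min_size=1,
        max_size=30))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_bounded_and_symmetric(self, rows):
        cols = [(p + x, p + y) for p, x, y in rows]
        fwd = compute_4dtv(_aln(*cols))
        rev = compute_4dtv(CodonPairAlignment(
            "gy", "gx", tuple((b, a) for a, b in cols)))
        if fwd is None:
            assert rev is None
        else:
            assert 0.0 <= fwd <= 1.0
            assert fwd == rev

    def test_corrected_value_exceeds_raw(self):
        aln = _aln(*[("GGT", "GGG")] * 3 + [("GGT", "GGT")] * 7)
        raw = compute_4dtv(aln)
        corrected = compute_4dtv(aln, corrected=True)
        assert corrected > raw


class TestFourdtvDistribution:
    def test_planted_transversion_rate_recovered(self):
        """Substitutions only at fourfold sites at transversion rate q:
        the histogram mode falls within 2 binomial SD of q."""
        q, n_codons = 0.10, 300
        pairs = simulate_codon_pairs(200, n_codons, q, seed=1)
        values = [compute_4dtv(p) for p in pairs]
        counts, edges = np.histogram(values, bins=np.arange(0, 1.01, 0.01))
        mode = edges[int(np.argmax(counts))] + 0.005
        sd = np.sqrt(q * (1 - q) / n_codons)
        assert abs(mode - q) <= 2 * sd

    def test_empty_pair_list_gives_empty_distribution(self, sim_pair):
        bundle_a, bundle_b, _ = sim_pair
        records, hist = fourdtv_distribution([], bundle_a, bundle_b)
        assert records == [] and hist == []

    def test_duplicated_pairs_give_identical_values(self, analysis):
        pairs = analysis["pairs"][:5]
        a, b = analysis["bundle_a"], analysis["bundle_b"]
        r1, _ = fourdtv_distribution(pairs, a, b)
        r2, _ = fourdtv_distribution(pairs + pairs, a, b)
        assert r2[:5] == r1 and r2[5:] == r1

    def test_blocks_accepted_and_values_in_range(self, analysis):
        records, hist = fourdtv_distribution(
            analysis["blocks"], analysis["bundle_a"], analysis["bundle_b"])
        assert len(records) == sum(len(b) for b in analysis["blocks"])
        defined = [v for _, _, v in records if v is not None]
        assert defined and all(0 <= v <= 1 for v in defined)
        assert sum(c for _, c in hist) == len(defined)


def test_codon_alignment_threads_protein_alignment_onto_cds():
    rng = random.Random(61)
    from conftest import backtranslate, random_protein

    protein = "M" + random_protein(rng, 49)
    cds = backtranslate(rng, protein)
    aln = build_codon_alignment("g1", "g2", protein, protein, cds,
                                cds + "TAA")
    assert len(aln.codons) == len(protein)
    assert all(ca == cb for ca, cb in aln.codons)
    with pytest.raises(ValueError, match="does not match"):
        build_codon_alignment("g1", "g2", protein, protein, cds[:-3], cds)


class TestFisherFamilyTest:
    def test_equal_proportions_two_sided_is_one(self):
        t = FamilyCountTable(5, 100, 5, 100)
        assert fisher_family_test(t, "two_sided") == pytest.approx(1.0)

    def test_zero_counts_give_p_one(self):
        t = FamilyCountTable(0, 50, 0, 80)
        assert fisher_family_test(t, "greater") == pytest.approx(1.0)
        assert fisher_family_test(t, "two_sided") == pytest.approx(1.0)

    def test_urease_style_expansion_matches_oracle(self):
        """9 family members in an 18,969-gene proteome versus 2 in a
        29,431-gene proteome: one-sided enrichment p equals the exhaustive
        hypergeometric tail to 1e-12."""
        t = FamilyCountTable(9, 18969, 2, 29431)
        p = fisher_family_test(t, "greater")
        expected = fisher_greater(9, 18969 - 9, 2, 29431 - 2)
        assert p == pytest.approx(expected, abs=1e-12)
        assert p < 0.01  # a genuine expansion signal

    def test_two_sided_matches_summation_oracle_on_small_tables(self):
        """Exhaustive over all tables with both genome totals <= 12."""
        for ft in range(1, 13):
            for rt in range(1, 13):
                for fc in range(ft + 1):
                    for rc in range(rt + 1):
                        t = FamilyCountTable(fc, ft, rc, rt)
                        p = fisher_family_test(t, "two_sided")
                        o = fisher_two_sided(fc, ft - fc, rc, rt - rc)
                        assert p == pytest.approx(o, abs=1e-9), \
                            (fc, ft, rc, rt)

    def test_zero_total_is_hard_error(self):
        with pytest.raises(ValueError):
            fisher_family_test(FamilyCountTable(0, 0, 1, 10))

    def test_count_exceeding_total_is_invalid(self):
        with pytest.raises(ValueError):
            FamilyCountTable(11, 10, 1, 10)


class TestTeProximity:
    def test_gap_arithmetic(self):
        dists, _ = te_proximity({"functional": [("chr1", 100, 200)]},
                                [("chr1", 250, 300)])
        assert dists["functional"] == [50]

    def test_overlap_gives_zero(self):
        dists, _ = te_proximity({"functional": [("chr1", 100, 200)]},
                                [("chr1", 150, 400)])
        assert dists["functional"] == [0]

    def test_translation_invariance(self):
        loci = [("chr1", 1000, 1100), ("chr1", 5000, 5200)]
        tes = [("chr1", 2000, 2300), ("chr1", 7000, 7100)]
        d1, _ = te_proximity({"x": loci}, tes)
        shift = 10_000
        d2, _ = te_proximity(
            {"x": [(c, s + shift, e + shift) for c, s, e in loci]},
            [(c, s + shift, e + shift) for c, s, e in tes])
        assert d1 == d2
        assert all(d >= 0 for d in d1["x"])

    def test_chromosome_without_te_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="no TE"):
            dists, _ = te_proximity(
                {"x": [("chr1", 0, 10), ("chr2", 0, 10)]},
                [("chr1", 50, 60)])
        assert dists["x"] == [40]

    def test_planted_proximity_effect_detected(self):
        """Functional loci placed next to TEs versus uniform pseudogene
        and SV loci: the U test flags the pair comparisons involving the
        functional class at p < 0.01."""
        genes, tes = simulate_te_layout(n_per_class=50, effect=True, seed=1)
        _, pvalues = te_proximity(genes, tes)
        assert pvalues[("functional", "pseudogene")] < 0.01
        assert pvalues[("functional", "sv")] < 0.01

    def test_null_placement_gives_no_signal(self):
        genes, tes = simulate_te_layout(n_per_class=50, effect=False, seed=1)
        _, pvalues = te_proximity(genes, tes)
        assert all(p > 0.05 for p in pvalues.values())
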