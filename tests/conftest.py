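"""Shared fixtures: one simulated genome pair and its full analysis.

The default simulation (two chromosomes of 100 genes, 80% ortholog
identity, 10 deletions, 5 hidden intact copies, 10+10+10 pseudogene
implants, 2 inversions, seed 1) is expensive enough that it is built once
per session and shared by the module and acceptance tests.
"""

import random

import pytest

from synloss.homology import all_vs_all_hits, filter_hits, \
    reciprocal_best_hits
from synloss.lossfinder import repredict_all, tag_sv_losses, trace_deletions
from synloss.pseudogenes import scan_intergenic
from synloss.simulate import SimConfig, simulate_genome_pair
from synloss.synteny import build_microsynteny, find_breakpoints


@pytest.fixture(scope="session")
def sim_pair():
    """(bundle_a, bundle_b, truth) for the default simulated world."""
    return simulate_genome_pair(SimConfig(seed=1))


@pytest.fixture(scope="session")
def analysis(sim_pair):
    """Full pipeline products on the default simulated pair."""
    bundle_a, bundle_b, truth = sim_pair
    hits_ab, hits_ba = all_vs_all_hits(bundle_a.proteins(),
                                       bundle_b.proteins())
    pairs = reciprocal_best_hits(filter_hits(hits_ab), filter_hits(hits_ba))
    blocks = build_microsynteny(pairs, bundle_a, bundle_b)
    breakpoints = find_breakpoints(blocks, bundle_a, bundle_b)
    candidates = trace_deletions(blocks, bundle_a, bundle_b)
    repredict_all(candidates, bundle_a, bundle_b)
    tag_sv_losses(candidates, breakpoints)
    pseudo_calls = scan_intergenic(bundle_b, bundle_a.proteins())
    return {
        "bundle_a": bundle_a,
        "bundle_b": bundle_b,
        "truth": truth,
        "hits_ab": hits_ab,
        "hits_ba": hits_ba,
        "pairs": pairs,
        "blocks": blocks,
        "breakpoints": breakpoints,
        "candidates": candidates,
        "pseudo_calls": pseudo_calls,
    }


AA20 = "ARNDCQEGHILKMFPSTWYV"

_CODONS_BY_AA = {}


def _codon_table():
    global _CODONS_BY_AA
    if not _CODONS_BY_AA:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, aa in sorted(standard_dna_table.forward_table.items()):
            _CODONS_BY_AA.setdefault(aa, []).append(codon)
    return _CODONS_BY_AA


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA20) for _ in range(length))


def backtranslate(rng: random.Random, protein: str) -> str:
    """Uniform-random synonymous back-translation (no stop appended)."""
    table = _codon_table()
    return "".join(rng.choice(table[aa]) for aa in protein)
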