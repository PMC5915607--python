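"""Pairwise protein similarity and reciprocal-best-hit orthology.

A Smith–Waterman local aligner (BLOSUM62, affine gaps in the BLAST 11/1
convention: a gap of length k costs 11 + k) stands in for a BLASTP search at
desk scale; precomputed BLAST/DIAMOND tabular output (12-column format 6)
can be supplied instead.  Hits are filtered on identity >= 30% and coverage
> 30% — note the asymmetry: the identity threshold is inclusive, the
coverage threshold strict — and reciprocal best hits across two genomes are
taken as putative orthologs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "HomologyHit",
    "OrthologPair",
    "align_protein_pair",
    "all_vs_all_hits",
    "filter_hits",
    "reciprocal_best_hits",
    "parse_tabular_hits",
]

GAP_OPEN = 11
GAP_EXTEND = 1


@dataclass(frozen=True)
class HomologyHit:
    """One directed similarity hit between two proteins.

    ``identity`` is identical columns / aligned (residue-residue) columns;
    coverages are aligned residues over the respective sequence length.
    """

    query_id: str
    subject_id: str
    identity: float
    query_coverage: float
    subject_coverage: float
    score: float
    aligned_length: int

    def __post_init__(self):
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity {self.identity} outside [0,1]")
        if self.query_coverage > 1.0 + 1e-9 or self.subject_coverage > 1.0 + 1e-9:
            raise ValueError("coverage exceeds 1")
        if self.aligned_length < 1:
            raise ValueError("aligned_length < 1")


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal-best-hit link between one gene of each genome."""

    gene_a: str
    gene_b: str
    score: float


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # Biopython charges open_gap_score for the first gapped position, so a
    # gap of length k costs (GAP_OPEN + 1) + (k - 1) = GAP_OPEN + k.
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


_ALIGNER = None


def align_protein_pair(seq_a: str, seq_b: str, id_a: str = "query",
                       id_b: str = "subject") -> HomologyHit:
    """Locally align two proteins and summarize the best alignment."""
    global _ALIGNER
    if not seq_a or not seq_b:
        raise ValueError("empty protein sequence")
    if _ALIGNER is None:
        _ALIGNER = make_aligner()
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    segs_a, segs_b = aln.aligned
    identical = aligned = 0
    for (qs, qe), (ss, se) in zip(segs_a, segs_b):
        aligned += qe - qs
        identical += sum(seq_a[qs + i] == seq_b[ss + i] for i in range(qe - qs))
    aligned = max(aligned, 1)
    return HomologyHit(
        query_id=id_a, subject_id=id_b,
        identity=identical / aligned,
        query_coverage=min(1.0, aligned / len(seq_a)),
        subject_coverage=min(1.0, aligned / len(seq_b)),
        score=float(aln.score), aligned_length=aligned)


def _kmer_set(seq: str, k: int):
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def all_vs_all_hits(proteins_a: dict, proteins_b: dict, k: int = 4,
                    min_shared_kmers: int = 2, min_score: float = 40.0):
    """All-vs-all similarity between two protein sets.

    Returns (hits_ab, hits_ba); each pair is aligned once and reported in
    both directions (the raw local score is symmetric, coverages swap).
    A shared-k-mer prefilter (default: two exact amino-acid 4-mers) skips
    clearly unrelated pairs; ``min_shared_kmers=0`` disables it.  Hits below
    ``min_score`` are dropped as noise.
    """
    kmers_a = {g: _kmer_set(s, k) for g, s in proteins_a.items()}
    kmers_b = {g: _kmer_set(s, k) for g, s in proteins_b.items()}
    hits_ab, hits_ba = [], []
    for ga, gb in itertools.product(sorted(proteins_a), sorted(proteins_b)):
        if min_shared_kmers > 0:
            shared = len(kmers_a[ga] & kmers_b[gb])
            if shared < min_shared_kmers:
                continue
        hit = align_protein_pair(proteins_a[ga], proteins_b[gb], ga, gb)
        if hit.score < min_score:
            continue
        hits_ab.append(hit)
        hits_ba.append(HomologyHit(
            query_id=gb, subject_id=ga, identity=hit.identity,
            query_coverage=hit.subject_coverage,
            subject_coverage=hit.query_coverage,
            score=hit.score, aligned_length=hit.aligned_length))
    return hits_ab, hits_ba


def filter_hits(hits, min_identity: float = 0.30, min_coverage: float = 0.30,
                require_both_coverages: bool = False):
    """Retain hits with identity >= min_identity and coverage > min_coverage.

    The identity bound is inclusive ("at least 30% identity"), the coverage
    bound strict ("coverage higher than 30%").  Coverage is query-sided by
    default; ``require_both_coverages`` additionally applies the strict
    bound to the subject side.
    """
    out = []
    for h in hits:
        if h.identity < min_identity:
            continue
        if not h.query_coverage > min_coverage:
            continue
        if require_both_coverages and not h.subject_coverage > min_coverage:
            continue
        out.append(h)
    return out


def _best_subject(hits_by_query: dict) -> dict:
    best = {}
    for q, hs in hits_by_query.items():
        # best = max score, ties by higher identity, then lexicographically
        # smaller subject id
        best[q] = min(hs, key=lambda h: (-h.score, -h.identity, h.subject_id))
    return best


def reciprocal_best_hits(hits_ab, hits_ba):
    """Reciprocal best hits between two filtered directed hit sets.

    (a, b) is emitted iff b is a's best subject in ``hits_ab`` and a is b's
    best subject in ``hits_ba``.  Self hits are ignored.  Output is sorted
    by ``gene_a``.
    """
    by_q_ab, by_q_ba = {}, {}
    for h in hits_ab:
        if h.query_id != h.subject_id:
            by_q_ab.setdefault(h.query_id, []).append(h)
    for h in hits_ba:
        if h.query_id != h.subject_id:
            by_q_ba.setdefault(h.query_id, []).append(h)
    best_ab = _best_subject(by_q_ab)
    best_ba = _best_subject(by_q_ba)
    pairs = []
    for a, hit in sorted(best_ab.items()):
        b = hit.subject_id
        back = best_ba.get(b)
        if back is not None and back.subject_id == a:
            pairs.append(OrthologPair(gene_a=a, gene_b=b, score=hit.score))
    return pairs


def parse_tabular_hits(path: str, query_lengths: dict, subject_lengths: dict,
                       max_evalue: float = 1e-7):
    """Parse 12-column BLAST/DIAMOND tabular output (outfmt 6).

    Columns: query, subject, pident, length, mismatch, gapopen, qstart,
    qend, sstart, send, evalue, bitscore.  The E-value threshold (search
    tools report it; the internal aligner does not) is applied here.
    Coverages are computed from the aligned query/subject spans over the
    supplied sequence lengths.
    """
    hits = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            q, s = f[0], f[1]
            evalue = float(f[10])
            if evalue > max_evalue:
                continue
            qspan = abs(int(f[7]) - int(f[6])) + 1
            sspan = abs(int(f[9]) - int(f[8])) + 1
            hits.append(HomologyHit(
                query_id=q, subject_id=s, identity=float(f[2]) / 100.0,
                query_coverage=min(1.0, qspan / query_lengths[q]),
                subject_coverage=min(1.0, sspan / subject_lengths[s]),
                score=float(f[11]), aligned_length=int(f[3])))
    return hits
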