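"""Spliced, frameshift-aware local alignment of a protein to genomic DNA.

A transparent stand-in for GeneWise-style pseudogene alignment.  Dynamic
programming over (seed residue, DNA position) with three states:

* ``M`` — the seed residue is matched to a "codon" of 1..5 nucleotides.
  Length-3 codons score BLOSUM62 against their translation (stop codons are
  matchable but flagged); lengths 1, 2, 4, 5 are frameshift codons costing
  a fixed penalty instead of a substitution score.
* ``X`` — a whole DNA codon is skipped (DNA-side gap, linear penalty).
* ``Y`` — a seed residue is skipped (protein-side gap, linear penalty).

Between two ordinary codons the DNA may additionally jump an *intron gap*
of at least ``min_intron`` nucleotides for a flat penalty; no splice-site
motif is required, because pseudogene splice sites decay.  The best local
path (starting and ending on a match state) is reported together with
frameshift and premature-stop counts, coding blocks and intron gaps.

The recurrence is quadratic; a numba kernel is used when available, with a
pure-Python fallback of identical semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

__all__ = ["ProteinGenomeAlignment", "align_protein_to_dna",
           "best_strand_alignment", "DEFAULT_FRAMESHIFT_PENALTY",
           "DEFAULT_INTRON_PENALTY", "DEFAULT_GAP_PENALTY",
           "DEFAULT_MIN_INTRON"]

DEFAULT_FRAMESHIFT_PENALTY = 15
# An intron must "pay for itself": with BLOSUM62 match scores a flat cost of
# 30 demands roughly eight well-matching codons beyond the gap, which admits
# real (even decayed) exons but rejects the few lucky codons a cheaper gap
# would pick up in random intergenic DNA.
DEFAULT_INTRON_PENALTY = 30
DEFAULT_GAP_PENALTY = 10
DEFAULT_MIN_INTRON = 40

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_STOP = _AA_INDEX["*"]
_X_AA = _AA_INDEX["X"]

NEG = -(10 ** 8)


def _build_tables():
    blosum = substitution_matrices.load("BLOSUM62")
    sub = np.zeros((24, 24), dtype=np.int32)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            sub[i, j] = int(blosum[a, b])
    codon_aa = np.full(5 * 5 * 5, _X_AA, dtype=np.int8)
    for n1 in "ACGT":
        for n2 in "ACGT":
            for n3 in "ACGT":
                codon = n1 + n2 + n3
                idx = (_NT_INDEX[n1] * 5 + _NT_INDEX[n2]) * 5 + _NT_INDEX[n3]
                if codon in standard_dna_table.stop_codons:
                    codon_aa[idx] = _STOP
                else:
                    codon_aa[idx] = _AA_INDEX[
                        standard_dna_table.forward_table[codon]]
    return sub, codon_aa


_SUB, _CODON_AA = _build_tables()


def encode_protein(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(c.upper(), _X_AA) for c in seq],
                    dtype=np.int8)


def encode_dna(seq: str) -> np.ndarray:
    return np.array([_NT_INDEX.get(c.upper(), 4) for c in seq],
                    dtype=np.int8)


def _fill_kernel(seed, dna, sub, codon_aa, fpen, ipen, gpen, min_intron):
    """Fill DP matrices.  Returns (M, X, Y, rowmax, rowarg, best, bi, bj).

    ``rowmax[i, j] = max(0, B[i, 0..j])`` with ``B = max(M, X, Y)``;
    ``rowarg`` is its earliest argmax.  ``best`` is the maximum of ``M``
    (local alignments end on a match), at the smallest (i, j).
    """
    n = seed.shape[0]
    m = dna.shape[0]
    M = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    Xm = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    Ym = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    rowmax = np.zeros((n + 1, m + 1), dtype=np.int32)
    rowarg = np.zeros((n + 1, m + 1), dtype=np.int32)
    best = 0
    bi = -1
    bj = -1
    for i in range(1, n + 1):
        ai = seed[i - 1]
        for j in range(0, m + 1):
            mv = NEG
            if j >= 3:
                c0 = dna[j - 3]
                c1 = dna[j - 2]
                c2 = dna[j - 1]
                if c0 < 4 and c1 < 4 and c2 < 4:
                    aa = codon_aa[(c0 * 5 + c1) * 5 + c2]
                else:
                    aa = 22  # X
                s = sub[ai, aa]
                prev = M[i - 1, j - 3]
                if Xm[i - 1, j - 3] > prev:
                    prev = Xm[i - 1, j - 3]
                if Ym[i - 1, j - 3] > prev:
                    prev = Ym[i - 1, j - 3]
                if i == 1 or prev < 0:
                    prev = 0  # local start
                mv = s + prev
                # intron gap before this codon
                jo = j - 3 - min_intron
                if jo >= 0 and i > 1 and rowmax[i - 1, jo] > 0:
                    cand = s + rowmax[i - 1, jo] - ipen
                    if cand > mv:
                        mv = cand
            # frameshift codons (lengths 1, 2, 4, 5)
            for L in (1, 2, 4, 5):
                if j >= L and i > 1:
                    prev = M[i - 1, j - L]
                    if Xm[i - 1, j - L] > prev:
                        prev = Xm[i - 1, j - L]
                    if Ym[i - 1, j - L] > prev:
                        prev = Ym[i - 1, j - L]
                    if prev > 0:
                        cand = prev - fpen
                        if cand > mv:
                            mv = cand
            M[i, j] = mv
            # DNA-side gap: skip one codon
            xv = NEG
            if j >= 3:
                p = M[i, j - 3]
                if Xm[i, j - 3] > p:
                    p = Xm[i, j - 3]
                if Ym[i, j - 3] > p:
                    p = Ym[i, j - 3]
                if p > NEG // 2:
                    xv = p - gpen
            Xm[i, j] = xv
            # protein-side gap: skip seed residue i
            yv = NEG
            p = M[i - 1, j]
            if Xm[i - 1, j] > p:
                p = Xm[i - 1, j]
            if Ym[i - 1, j] > p:
                p = Ym[i - 1, j]
            if p > NEG // 2:
                yv = p - gpen
            Ym[i, j] = yv
            # running row max of max(0, M, X, Y)
            b = mv
            if xv > b:
                b = xv
            if yv > b:
                b = yv
            if b < 0:
                b = 0
            if j == 0:
                rowmax[i, j] = b
                rowarg[i, j] = 0
            elif b > rowmax[i, j - 1]:
                rowmax[i, j] = b
                rowarg[i, j] = j
            else:
                rowmax[i, j] = rowmax[i, j - 1]
                rowarg[i, j] = rowarg[i, j - 1]
            if mv > best:
                best = mv
                bi = i
                bj = j
    return M, Xm, Ym, rowmax, rowarg, best, bi, bj


try:  # optional acceleration; semantics identical to the Python path
    from numba import njit

    _fill_fast = njit(cache=True, fastmath=False)(_fill_kernel)
except ImportError:  # pragma: no cover
    _fill_fast = None


@dataclass
class ProteinGenomeAlignment:
    """Result of aligning a seed protein to a stretch of DNA.

    DNA coordinates are 0-based half-open offsets into the aligned string;
    callers scanning a larger sequence use :meth:`shift` to lift them into
    chromosome space.  ``aligned_seed_residues`` counts seed residues in
    match or frameshift columns (gap-skipped residues excluded);
    ``identity`` is identical matches over those columns.
    """

    seed_id: str = ""
    chrom: str = ""
    strand: str = "+"
    coding_blocks: list = field(default_factory=list)  # (start, end, frame)
    intron_gaps: list = field(default_factory=list)    # (start, end)
    frameshifts: int = 0
    premature_stops: int = 0
    identity: float = 0.0
    aligned_seed_residues: int = 0
    score: int = 0
    seed_start: int = 0          # aligned seed interval, 0-based half-open
    seed_end: int = 0
    dna_start: int = 0
    dna_end: int = 0
    n_gap_events: int = 0        # X/Y ops inside the aligned region

    @property
    def exon_number(self) -> int:
        return len(self.coding_blocks)

    @property
    def has_disablement(self) -> bool:
        """Insertion, deletion, premature termination or frameshift present."""
        return (self.frameshifts + self.premature_stops
                + self.n_gap_events) >= 1

    def shift(self, offset: int, chrom: str = "", strand: str = "+",
              dna_len: int = 0):
        """Lift DNA coordinates into a parent sequence.

        For a minus-strand alignment (performed against the reverse
        complement) ``dna_len`` is the length of the aligned subsequence;
        intervals are mirrored back onto the forward strand before the
        offset is added.
        """
        def mapiv(s, e):
            if strand == "-":
                s, e = dna_len - e, dna_len - s
            return (s + offset, e + offset)

        self.coding_blocks = sorted(
            (*mapiv(s, e), f) for s, e, f in self.coding_blocks)
        self.intron_gaps = sorted(mapiv(s, e) for s, e in self.intron_gaps)
        self.dna_start, self.dna_end = mapiv(self.dna_start, self.dna_end)
        if chrom:
            self.chrom = chrom
        self.strand = strand
        return self


def align_protein_to_dna(seed: str, dna: str,
                         min_intron: int = DEFAULT_MIN_INTRON,
                         frameshift_penalty: int = DEFAULT_FRAMESHIFT_PENALTY,
                         intron_penalty: int = DEFAULT_INTRON_PENALTY,
                         gap_penalty: int = DEFAULT_GAP_PENALTY,
                         seed_id: str = "seed",
                         use_numba: bool = True) -> ProteinGenomeAlignment:
    """Best local spliced alignment of a seed protein to a DNA string.

    Deterministic: score ties resolve to the smallest (seed, DNA) end
    position and, within a cell, normal codon > frameshift (shortest
    first) > intron origin.  Raises ``ValueError`` for a seed shorter than
    10 aa or DNA shorter than 30 nt.  A best score <= 0 yields an empty
    alignment (zero aligned residues).
    """
    if len(seed) < 10:
        raise ValueError(f"seed too short ({len(seed)} aa < 10)")
    if len(dna) < 30:
        raise ValueError(f"dna too short ({len(dna)} nt < 30)")
    es = encode_protein(seed)
    ed = encode_dna(dna)
    fill = _fill_fast if (use_numba and _fill_fast is not None) \
        else _fill_kernel
    M, Xm, Ym, rowmax, rowarg, best, bi, bj = fill(
        es, ed, _SUB, _CODON_AA, frameshift_penalty, intron_penalty,
        gap_penalty, min_intron)
    if best <= 0 or bi < 0:
        return ProteinGenomeAlignment(seed_id=seed_id)
    events = _traceback(es, ed, M, Xm, Ym, rowmax, rowarg, int(bi), int(bj),
                        frameshift_penalty, intron_penalty, gap_penalty,
                        min_intron)
    return _summarize(events, es, int(best), seed_id)


def best_strand_alignment(seed: str, dna: str, **kwargs):
    """Align against both strands of ``dna``; return (alignment, strand).

    The higher raw score wins; ties go to the forward strand.  Coordinates
    of a minus-strand result refer to the reverse complement until lifted
    with :meth:`ProteinGenomeAlignment.shift`.
    """
    from .genomeio import revcomp

    fwd = align_protein_to_dna(seed, dna, **kwargs)
    rev = align_protein_to_dna(seed, revcomp(dna), **kwargs)
    if rev.score > fwd.score:
        return rev, "-"
    return fwd, "+"


def _codon_aa_at(ed, j):
    c0, c1, c2 = int(ed[j - 3]), int(ed[j - 2]), int(ed[j - 1])
    if c0 >= 4 or c1 >= 4 or c2 >= 4:
        return _X_AA
    return int(_CODON_AA[(c0 * 5 + c1) * 5 + c2])


def _pick_state(M, Xm, Ym, i, j):
    b = max(int(M[i, j]), int(Xm[i, j]), int(Ym[i, j]))
    if int(M[i, j]) == b:
        return "M"
    if int(Xm[i, j]) == b:
        return "X"
    return "Y"


def _traceback(es, ed, M, Xm, Ym, rowmax, rowarg, bi, bj,
               fpen, ipen, gpen, min_intron):
    """Reconstruct the optimal path ending at M[bi, bj].

    Emits events, end-to-start, later reversed:
    ("match", i, js, je, aa) ("fs", i, js, je) ("ins", js, je) ("del", i)
    ("intron", js, je).
    """
    events = []
    i, j, state = bi, bj, "M"
    while True:
        if state == "M":
            val = int(M[i, j])
            ai = int(es[i - 1])
            moved = False
            if j >= 3:
                aa = _codon_aa_at(ed, j)
                s = int(_SUB[ai, aa])
                prev = max(int(M[i - 1, j - 3]), int(Xm[i - 1, j - 3]),
                           int(Ym[i - 1, j - 3]))
                if i == 1 or prev < 0:
                    prev = 0
                if val == s + prev:
                    events.append(("match", i, j - 3, j, aa))
                    if prev == 0:
                        break  # local start
                    i, j = i - 1, j - 3
                    state = _pick_state(M, Xm, Ym, i, j)
                    moved = True
            if moved:
                continue
            for L in (1, 2, 4, 5):
                if j >= L and i > 1:
                    prev = max(int(M[i - 1, j - L]), int(Xm[i - 1, j - L]),
                               int(Ym[i - 1, j - L]))
                    if prev > 0 and val == prev - fpen:
                        events.append(("fs", i, j - L, j))
                        i, j = i - 1, j - L
                        state = _pick_state(M, Xm, Ym, i, j)
                        moved = True
                        break
            if moved:
                continue
            if j >= 3 and i > 1:
                aa = _codon_aa_at(ed, j)
                s = int(_SUB[ai, aa])
                jo = j - 3 - min_intron
                if jo >= 0 and int(rowmax[i - 1, jo]) > 0 and \
                        val == s + int(rowmax[i - 1, jo]) - ipen:
                    jp = int(rowarg[i - 1, jo])
                    events.append(("match", i, j - 3, j, aa))
                    events.append(("intron", jp, j - 3))
                    i, j = i - 1, jp
                    state = _pick_state(M, Xm, Ym, i, j)
                    continue
            raise AssertionError("protein-DNA traceback failed (state M)")
        elif state == "X":
            events.append(("ins", j - 3, j))
            j -= 3
            state = _pick_state(M, Xm, Ym, i, j)
        else:  # Y
            events.append(("del", i))
            i -= 1
            state = _pick_state(M, Xm, Ym, i, j)
    events.reverse()
    return events


def _summarize(events, es, score, seed_id):
    frameshifts = sum(1 for ev in events if ev[0] == "fs")
    n_gap_events = sum(1 for ev in events if ev[0] in ("ins", "del"))
    introns = [(ev[1], ev[2]) for ev in events if ev[0] == "intron"]
    seed_len = len(es)

    identical = premature = 0
    aligned = 0
    seed_idx = []
    for ev in events:
        if ev[0] == "match":
            _, i, js, je, aa = ev
            aligned += 1
            seed_idx.append(i)
            if aa == int(es[i - 1]):
                identical += 1
            if aa == _STOP and i < seed_len:
                premature += 1
        elif ev[0] == "fs":
            aligned += 1
            seed_idx.append(ev[1])
        elif ev[0] == "del":
            seed_idx.append(ev[1])

    # coding blocks: DNA spans of consuming ops, split at intron gaps
    blocks, cur = [], None
    for ev in events:
        if ev[0] == "intron":
            if cur is not None:
                blocks.append(cur)
                cur = None
        elif ev[0] in ("match", "fs", "ins"):
            js, je = ev[-2], ev[-1]
            if ev[0] != "ins":
                js, je = ev[2], ev[3]
            cur = (js, je) if cur is None else (min(cur[0], js),
                                                max(cur[1], je))
    if cur is not None:
        blocks.append(cur)

    return ProteinGenomeAlignment(
        seed_id=seed_id,
        coding_blocks=[(s, e, s % 3) for s, e in blocks],
        intron_gaps=introns,
        frameshifts=frameshifts,
        premature_stops=premature,
        identity=identical / aligned if aligned else 0.0,
        aligned_seed_residues=aligned,
        score=score,
        seed_start=min(seed_idx) - 1 if seed_idx else 0,
        seed_end=max(seed_idx) if seed_idx else 0,
        dna_start=blocks[0][0] if blocks else 0,
        dna_end=blocks[-1][1] if blocks else 0,
        n_gap_events=n_gap_events)
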