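"""Intergenic pseudogene discovery and PSSD / DUP / FRAG classification.

Annotated gene spans are masked, seed proteins from a related genome are
searched against the remaining intergenic DNA, and each hit is refined with
the spliced frameshift-aware aligner.  High-confidence calls require amino
acid identity > 30% and match length > 50 aa (both strict).  Classes:

* **PSSD** (processed/retrotransposed): exon number = 1,
  0.7 < align ratio <= 0.95, 0.3 <= identity <= 0.95.
* **DUP** (duplicated): exon number > 1, 0.3 <= identity <= 0.95, and an
  insertion, deletion, termination or frameshift present.
* **FRAG** (pseudogenic fragment): exon number = 1, align ratio < 0.7,
  0.3 <= identity <= 0.95.

Anything matching none of the three rule sets (e.g. align ratio exactly
0.7 with one exon, identity above 0.95, or a multi-exon hit without any
disablement — i.e. an intact unannotated gene) is ``OTHER``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .genomeio import GenomeBundle, revcomp
from .pgalign import (DEFAULT_MIN_INTRON, ProteinGenomeAlignment,
                      align_protein_to_dna)

__all__ = ["PseudoMetrics", "PseudogeneCall", "high_confidence_filter",
           "classify_pseudogene", "metrics_from_alignment",
           "scan_intergenic", "search_protein_in_chromosomes",
           "write_pseudogene_gff3"]


@dataclass(frozen=True)
class PseudoMetrics:
    """Alignment-derived metrics a pseudogene call is judged on."""

    identity: float
    align_ratio: float           # aligned seed residues / seed length
    exon_number: int
    match_length_aa: int         # aligned seed residues
    has_disablement: bool

    def __post_init__(self):
        if not (0.0 <= self.align_ratio <= 1.0 + 1e-9):
            raise ValueError(f"align_ratio {self.align_ratio} outside [0,1]")
        if self.match_length_aa > 0 and self.exon_number < 1:
            raise ValueError("aligned metrics require >= 1 exon")


@dataclass
class PseudogeneCall:
    """One intergenic locus resembling a (decayed) copy of a seed protein."""

    chrom: str
    start: int
    end: int
    strand: str
    seed_id: str
    metrics: PseudoMetrics
    klass: str                   # PSSD | DUP | FRAG | OTHER
    high_confidence: bool
    score: int
    alignment: ProteinGenomeAlignment | None = None


def high_confidence_filter(metrics: PseudoMetrics) -> bool:
    """Identity > 30% and match length > 50 aa — both strictly."""
    return metrics.identity > 0.30 and metrics.match_length_aa > 50


def classify_pseudogene(metrics: PseudoMetrics) -> str:
    """Assign PSSD / DUP / FRAG per the rule inequalities, else OTHER."""
    ident_ok = 0.3 <= metrics.identity <= 0.95
    if not ident_ok:
        return "OTHER"
    if metrics.exon_number == 1 and 0.7 < metrics.align_ratio <= 0.95:
        return "PSSD"
    if metrics.exon_number > 1 and metrics.has_disablement:
        return "DUP"
    if metrics.exon_number == 1 and metrics.align_ratio < 0.7:
        return "FRAG"
    return "OTHER"


def metrics_from_alignment(aln: ProteinGenomeAlignment,
                           seed_length: int) -> PseudoMetrics:
    return PseudoMetrics(
        identity=aln.identity,
        align_ratio=min(1.0, aln.aligned_seed_residues / seed_length),
        exon_number=max(aln.exon_number, 1 if aln.aligned_seed_residues else 0),
        match_length_aa=aln.aligned_seed_residues,
        has_disablement=aln.has_disablement)


# -- seeding ---------------------------------------------------------------
#
# Candidate loci are found by shared k-mers between the seed protein and the
# six-frame translation of the DNA, in the Murphy reduced 10-letter alphabet
# (LVIM / C / A / G / ST / P / FYW / EDNQ / KR / H).  BLOSUM-plausible
# substitutions usually stay within a class, so a 5-mer in reduced space
# survives far more divergence than an exact one.  Matches must agree on a
# DNA diagonal (within a band), which suppresses the background the coarse
# alphabet lets through.

_MURPHY10 = {}
for _cls in ("LVIM", "C", "A", "G", "ST", "P", "FYW", "EDNQ", "KR", "H"):
    for _aa in _cls:
        _MURPHY10[_aa] = _cls[0]
_MURPHY_TABLE = str.maketrans(
    "".join(_MURPHY10), "".join(_MURPHY10.values()))


def _reduce(seq: str) -> str:
    return seq.translate(_MURPHY_TABLE)


def _translate_frames(dna: str):
    """Translations of the three forward frames (stop -> '*', other -> 'X')."""
    from .pgalign import _CODON_AA, AA_ALPHABET, encode_dna

    ed = encode_dna(dna)
    out = []
    for f in range(3):
        aas = []
        for j in range(f, len(dna) - 2, 3):
            c0, c1, c2 = int(ed[j]), int(ed[j + 1]), int(ed[j + 2])
            if c0 >= 4 or c1 >= 4 or c2 >= 4:
                aas.append("X")
            else:
                aas.append(AA_ALPHABET[_CODON_AA[(c0 * 5 + c1) * 5 + c2]])
        out.append("".join(aas))
    return out


def _kmers(seq: str, k: int):
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


_TIGHT_BAND_NT = 4      # substitution-only copies stay on one DNA diagonal
_LOOSE_BAND_NT = 48     # multi-exon copies scatter across intron-sized shifts
_LOOSE_MIN_KMERS = 8
_VERIFY_MIN_SCORE = 55


def build_seed_index(seed_proteins: dict, k: int = 5) -> dict:
    """Reduced-alphabet k-mer index: kmer -> [(seed_id, aa position)]."""
    index: dict = {}
    for sid in sorted(seed_proteins):
        red = _reduce(seed_proteins[sid])
        for i in range(len(red) - k + 1):
            index.setdefault(red[i:i + k], []).append((sid, i))
    return index


def _seed_hits(dna: str, seed_index: dict, k: int, min_kmers: int):
    """Diagonal-consistent reduced k-mer matches on either strand of ``dna``.

    Returns {seed_id: {strand: [(frame, aa_lo, aa_hi), ...]}} — candidate
    windows (in frame-translation coordinates) to hand to the verification
    aligner.  Two tiers: ``min_kmers`` matches within a tight 4 nt diagonal
    band catch short substitution-only copies, while a looser 48 nt band
    with a higher count catches spliced multi-exon copies whose diagonals
    shift by intron lengths.  This stage is deliberately permissive;
    candidates are confirmed by :func:`_verify_windows` before the
    expensive spliced DP.
    """
    hits: dict = {}
    for strand, seq in (("+", dna), ("-", revcomp(dna))):
        occ: dict = {}
        for f, tr in enumerate(_translate_frames(seq)):
            red = _reduce(tr)
            for t in range(len(red) - k + 1):
                for sid, spos in seed_index.get(red[t:t + k], ()):
                    occ.setdefault(sid, []).append((f + 3 * (t - spos), f, t))
        for sid, lst in occ.items():
            windows = []
            for bw, thr in ((_TIGHT_BAND_NT, min_kmers),
                            (_LOOSE_BAND_NT, _LOOSE_MIN_KMERS)):
                counts: dict = {}
                for d, _f, _t in lst:
                    counts[d // bw] = counts.get(d // bw, 0) + 1
                # only the strongest qualifying band (smallest on ties)
                best = None
                for b in sorted(counts):
                    c3 = (counts[b] + counts.get(b - 1, 0)
                          + counts.get(b + 1, 0))
                    if c3 >= thr and (best is None or c3 > best[0]):
                        best = (c3, b)
                if best is None:
                    continue
                band = {best[1] - 1, best[1], best[1] + 1}
                by_frame: dict = {}
                for d, f, t in lst:
                    if d // bw in band:
                        lo, hi = by_frame.get(f, (t, t))
                        by_frame[f] = (min(lo, t), max(hi, t))
                windows.extend((f, lo, hi + k)
                               for f, (lo, hi) in by_frame.items())
            if windows:
                hits.setdefault(sid, {})[strand] = _merge_windows(windows)
    return hits


def _merge_windows(windows, pad: int = 40):
    """Merge overlapping (frame, lo, hi) windows, padded by ``pad`` aa."""
    out = []
    for f, lo, hi in sorted(windows):
        lo = max(0, lo - pad)
        hi = hi + pad
        if out and out[-1][0] == f and lo <= out[-1][2]:
            out[-1] = (f, out[-1][1], max(out[-1][2], hi))
        else:
            out.append((f, lo, hi))
    return out


_VERIFY_ALIGNER = None


def _verify_windows(seed: str, frames, windows, min_score: float) -> bool:
    """Cheap local protein-vs-translated-window alignment check.

    A true (even decayed) copy has at least one exon whose frame
    translation aligns to the seed well above random; k-mer noise does
    not.  Windows are small, so this costs microseconds against the
    spliced DP's milliseconds.
    """
    global _VERIFY_ALIGNER
    if _VERIFY_ALIGNER is None:
        from Bio import Align
        from Bio.Align import substitution_matrices

        a = Align.PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -12
        a.extend_gap_score = -1
        _VERIFY_ALIGNER = a
    for f, lo, hi in windows:
        chunk = frames[f][lo:hi]
        if not chunk:
            continue
        if _VERIFY_ALIGNER.score(seed, chunk) >= min_score:
            return True
    return False


def _refine(seed_id, seed, dna, offset, chrom, strands, aln_kwargs):
    """Run the spliced aligner on the seeded strand(s); best score wins,
    forward strand on ties.  Returns a chromosome-space alignment or None."""
    best = None
    for strand in ("+", "-"):
        if strand not in strands:
            continue
        target = dna if strand == "+" else revcomp(dna)
        aln = align_protein_to_dna(seed, target, seed_id=seed_id,
                                   **aln_kwargs)
        if aln.aligned_seed_residues == 0:
            continue
        aln.shift(offset, chrom=chrom, strand=strand, dna_len=len(dna))
        if best is None or aln.score > best.score:
            best = aln
    return best


def scan_intergenic(bundle: GenomeBundle, seed_proteins: dict,
                    min_score: int = 60, overlap_frac: float = 0.5,
                    kmer_size: int = 5, min_seed_kmers: int = 3,
                    verify_min_score: float = _VERIFY_MIN_SCORE,
                    min_intron: int = DEFAULT_MIN_INTRON,
                    **aln_kwargs) -> list:
    """Scan a genome's intergenic DNA for decayed copies of seed proteins.

    Annotated gene spans are masked; candidate (segment, seed, strand)
    triples are located by diagonal-consistent reduced-alphabet k-mer
    sharing with the six-frame translation of the segment, confirmed with
    a fast protein-vs-frame alignment, then refined with
    :func:`align_protein_to_dna` and summarized into classified calls.
    Overlapping calls are resolved greedily by score: a call whose locus
    overlaps an already accepted call by >= ``overlap_frac`` of the shorter
    locus is suppressed.  Spliced alignments scoring below ``min_score``
    are treated as noise.
    """
    if not seed_proteins:
        raise ValueError("empty seed protein set")
    aln_kwargs = dict(aln_kwargs, min_intron=min_intron)
    seed_index = build_seed_index(seed_proteins, kmer_size)

    raw = []
    any_intergenic = False
    for chrom in sorted(bundle.chromosomes):
        seq = bundle.chromosomes[chrom]
        for (s, e) in bundle.intergenic_segments(chrom):
            if e - s < 30:
                continue
            any_intergenic = True
            segment = seq[s:e]
            frames = {"+": _translate_frames(segment),
                      "-": _translate_frames(revcomp(segment))}
            for sid, by_strand in sorted(_seed_hits(
                    segment, seed_index, kmer_size, min_seed_kmers).items()):
                seed = seed_proteins[sid]
                strands = {st for st, windows in by_strand.items()
                           if _verify_windows(seed, frames[st], windows,
                                              verify_min_score)}
                if not strands:
                    continue
                aln = _refine(sid, seed, segment, s, chrom,
                              strands, aln_kwargs)
                if aln is not None and aln.score >= min_score:
                    raw.append(aln)
    if not any_intergenic:
        warnings.warn(f"{bundle.genome_id}: no intergenic sequence to scan")
        return []

    raw.sort(key=lambda a: (-a.score, a.chrom, a.dna_start, a.seed_id))
    kept = []
    for aln in raw:
        drop = False
        for other in kept:
            if other.chrom != aln.chrom:
                continue
            ov = (min(other.dna_end, aln.dna_end)
                  - max(other.dna_start, aln.dna_start))
            shorter = min(other.dna_end - other.dna_start,
                          aln.dna_end - aln.dna_start)
            if shorter > 0 and ov / shorter >= overlap_frac:
                drop = True
                break
        if not drop:
            kept.append(aln)

    calls = []
    for aln in kept:
        metrics = metrics_from_alignment(aln, len(seed_proteins[aln.seed_id]))
        calls.append(PseudogeneCall(
            chrom=aln.chrom, start=aln.dna_start, end=aln.dna_end,
            strand=aln.strand, seed_id=aln.seed_id, metrics=metrics,
            klass=classify_pseudogene(metrics),
            high_confidence=high_confidence_filter(metrics),
            score=aln.score, alignment=aln))
    calls.sort(key=lambda c: (c.chrom, c.start, c.seed_id))
    return calls


def search_protein_in_chromosomes(seed: str, chromosomes: dict,
                                  seed_id: str = "seed", kmer_size: int = 5,
                                  min_seed_kmers: int = 3,
                                  window_pad: int = 3000,
                                  **aln_kwargs):
    """Genome-wide search for one seed protein; returns the best alignment
    in chromosome space, or None.

    Chromosomes are scanned for exact amino-acid k-mer matches against all
    six translation frames (the recovery question is whether a still-intact,
    therefore little-diverged, copy exists — exact seeding suffices and
    keeps the genome-wide scan cheap); match clusters, padded by
    ``window_pad`` nt, are refined with the spliced aligner.
    """
    skmers = _kmers(seed, kmer_size)
    best = None
    for chrom in sorted(chromosomes):
        seq = chromosomes[chrom]
        for strand in ("+", "-"):
            target = seq if strand == "+" else revcomp(seq)
            # nucleotide positions (on `target`) of seed k-mer matches
            positions = []
            for f, tr in enumerate(_translate_frames(target)):
                for i in range(len(tr) - kmer_size + 1):
                    if tr[i:i + kmer_size] in skmers:
                        positions.append(f + 3 * i)
            if len(positions) < min_seed_kmers:
                continue
            positions.sort()
            # cluster positions closer than the window pad
            clusters, cur = [], [positions[0]]
            for p in positions[1:]:
                if p - cur[-1] <= window_pad:
                    cur.append(p)
                else:
                    clusters.append(cur)
                    cur = [p]
            clusters.append(cur)
            for cl in clusters:
                if len(cl) < min_seed_kmers:
                    continue
                ws = max(0, cl[0] - window_pad)
                we = min(len(target), cl[-1] + 3 * kmer_size + window_pad)
                aln = align_protein_to_dna(seed, target[ws:we],
                                           seed_id=seed_id, **aln_kwargs)
                if aln.aligned_seed_residues == 0:
                    continue
                # lift window -> target -> forward strand
                aln.shift(ws, chrom=chrom, strand="+",
                          dna_len=we - ws)
                if strand == "-":
                    s, e = aln.dna_start, aln.dna_end
                    L = len(target)
                    aln.dna_start, aln.dna_end = L - e, L - s
                    aln.coding_blocks = sorted(
                        (L - be, L - bs, (L - be) % 3)
                        for bs, be, _f in aln.coding_blocks)
                    aln.intron_gaps = sorted(
                        (L - ge, L - gs) for gs, ge in aln.intron_gaps)
                    aln.strand = "-"
                aln.chrom = chrom
                if best is None or aln.score > best.score:
                    best = aln
    return best


def write_pseudogene_gff3(calls, path: str):
    """Write calls as GFF3 ``pseudogene`` features (class in attributes)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(calls, 1):
            attrs = (f"ID=pseudogene{i:05d};seed={c.seed_id};"
                     f"pseudogene_class={c.klass};"
                     f"identity={c.metrics.identity:.4f};"
                     f"align_ratio={c.metrics.align_ratio:.4f};"
                     f"exon_number={c.metrics.exon_number};"
                     f"match_length_aa={c.metrics.match_length_aa};"
                     f"disablement={int(c.metrics.has_disablement)};"
                     f"high_confidence={int(c.high_confidence)}")
            fh.write(f"{c.chrom}\tsynloss\tpseudogene\t{c.start + 1}\t"
                     f"{c.end}\t{c.score}\t{c.strand}\t.\t{attrs}\n")
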