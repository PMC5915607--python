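"""Supporting evolutionary statistics.

* **4DTv** — the proportion of transversion substitutions at fourfold
  degenerate third codon positions between two aligned coding sequences;
  peaks in its distribution over syntenic gene pairs mark whole-genome
  duplications.
* **Fisher's exact test** on gene-family size: copy number of the tested
  family over the whole-proteome gene total, focal genome versus a
  reference genome.
* **TE proximity** — per-class distances from genes/pseudogene loci to the
  nearest transposable element, compared pairwise with Mann-Whitney U.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

__all__ = ["CodonPairAlignment", "FamilyCountTable", "compute_4dtv",
           "build_codon_alignment", "fourdtv_distribution",
           "fisher_family_test", "te_proximity", "FOURFOLD_PREFIXES"]

# codon families whose third position is fully degenerate:
# Leu-CTN, Val-GTN, Ser-TCN, Pro-CCN, Thr-ACN, Ala-GCN, Arg-CGN, Gly-GGN
FOURFOLD_PREFIXES = frozenset(
    {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"})

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


@dataclass(frozen=True)
class CodonPairAlignment:
    """Gap-free aligned codon columns for one gene pair."""

    gene_a: str
    gene_b: str
    codons: tuple               # ((codon_a, codon_b), ...)

    def __post_init__(self):
        for ca, cb in self.codons:
            if len(ca) != 3 or len(cb) != 3:
                raise ValueError(f"codon column ({ca!r}, {cb!r}) "
                                 "is not a pair of triplets")


@dataclass(frozen=True)
class FamilyCountTable:
    """Gene-family size versus proteome size in two genomes."""

    focal_count: int
    focal_total: int
    reference_count: int
    reference_total: int

    def __post_init__(self):
        if min(self.focal_count, self.focal_total, self.reference_count,
               self.reference_total) < 0:
            raise ValueError("negative count")
        if (self.focal_count > self.focal_total
                or self.reference_count > self.reference_total):
            raise ValueError("family count exceeds genome total")


def _is_transversion(x: str, y: str) -> bool:
    return (x in _PURINES) != (y in _PURINES)


def compute_4dtv(alignment: CodonPairAlignment,
                 corrected: bool = False):
    """4DTv distance of one aligned codon pair, or None when undefined.

    Eligible sites are third positions of columns where both codons belong
    to a fourfold-degenerate family and the first two positions are
    identical.  The raw proportion of transversions at eligible sites is
    returned; ``corrected=True`` applies the Kimura-style divergence
    correction -0.5*ln(1 - 2q) (None when q >= 0.5).
    """
    if not alignment.codons:
        raise ValueError("empty codon alignment")
    eligible = transversions = 0
    for ca, cb in alignment.codons:
        ca, cb = ca.upper(), cb.upper()
        if any(c not in "ACGT" for c in ca + cb):
            continue
        if ca[:2] != cb[:2] or ca[:2] not in FOURFOLD_PREFIXES:
            continue
        eligible += 1
        if _is_transversion(ca[2], cb[2]):
            transversions += 1
    if eligible == 0:
        return None
    q = transversions / eligible
    if corrected:
        if q >= 0.5:
            return None
        return -0.5 * math.log(1.0 - 2.0 * q)
    return q


_GLOBAL_ALIGNER = None


def _protein_aligner():
    global _GLOBAL_ALIGNER
    if _GLOBAL_ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -12
        a.extend_gap_score = -1
        _GLOBAL_ALIGNER = a
    return _GLOBAL_ALIGNER


def build_codon_alignment(gene_a: str, gene_b: str, protein_a: str,
                          protein_b: str, cds_a: str,
                          cds_b: str) -> CodonPairAlignment:
    """Back-thread a global protein alignment onto the two CDS.

    A trailing stop codon on either CDS is ignored.  Raises ``ValueError``
    when a CDS length does not equal 3x its protein length.
    """
    for name, prot, cds in ((gene_a, protein_a, cds_a),
                            (gene_b, protein_b, cds_b)):
        if len(cds) % 3 == 0 and len(cds) == 3 * (len(prot) + 1):
            continue  # trailing stop codon
        if len(cds) != 3 * len(prot):
            raise ValueError(f"{name}: CDS length {len(cds)} does not match "
                             f"protein length {len(prot)}")
    aln = _protein_aligner().align(protein_a, protein_b)[0]
    segs_a, segs_b = aln.aligned
    cols = []
    for (qs, qe), (ss, se) in zip(segs_a, segs_b):
        for k in range(qe - qs):
            ia, ib = qs + k, ss + k
            cols.append((cds_a[3 * ia:3 * ia + 3],
                         cds_b[3 * ib:3 * ib + 3]))
    return CodonPairAlignment(gene_a=gene_a, gene_b=gene_b,
                              codons=tuple(cols))


def fourdtv_distribution(pairs_or_blocks, bundle_a, bundle_b,
                         bin_width: float = 0.01, corrected: bool = False):
    """Per-pair 4DTv values plus a binned histogram table.

    Accepts either a list of ortholog pairs or of synteny blocks (whose
    anchor pairs are used).  Pairs whose CDS and protein disagree in
    length are skipped with a warning; pairs with no eligible site are
    flagged (value None) and excluded from the histogram.
    Returns (records, histogram): records are (gene_a, gene_b, value) and
    the histogram is a list of (bin_start, count).
    """
    pairs = []
    for item in pairs_or_blocks:
        pairs.extend(item.pairs if hasattr(item, "pairs") else [item])
    records = []
    for p in pairs:
        try:
            codaln = build_codon_alignment(
                p.gene_a, p.gene_b,
                bundle_a.gene(p.gene_a).protein,
                bundle_b.gene(p.gene_b).protein,
                bundle_a.cds(p.gene_a), bundle_b.cds(p.gene_b))
        except ValueError as exc:
            warnings.warn(f"skipping pair ({p.gene_a}, {p.gene_b}): {exc}")
            continue
        records.append((p.gene_a, p.gene_b,
                        compute_4dtv(codaln, corrected=corrected)))
    values = [v for _, _, v in records if v is not None]
    hist = []
    if values:
        n_bins = int(max(values) / bin_width) + 1
        counts = [0] * n_bins
        for v in values:
            counts[min(n_bins - 1, int(v / bin_width))] += 1
        hist = [(round(i * bin_width, 10), c) for i, c in enumerate(counts)]
    return records, hist


def fisher_family_test(table: FamilyCountTable,
                       alternative: str = "greater") -> float:
    """Exact hypergeometric p-value for a gene-family size difference.

    The 2x2 table is (family, non-family) x (focal, reference).  The
    default alternative ``greater`` tests family expansion in the focal
    genome; ``less`` and ``two_sided`` are available.
    """
    if table.focal_total == 0 or table.reference_total == 0:
        raise ValueError("zero genome total")
    a, b = table.focal_count, table.focal_total - table.focal_count
    c, d = table.reference_count, table.reference_total - table.reference_count
    if alternative == "two_sided":
        return float(stats.fisher_exact([[a, b], [c, d]],
                                        alternative="two-sided")[1])
    n_total = a + b + c + d
    k_draw = a + b          # focal genome size
    K_succ = a + c          # family size overall
    hg = stats.hypergeom(n_total, K_succ, k_draw)
    if alternative == "greater":
        return float(hg.sf(a - 1))
    if alternative == "less":
        return float(hg.cdf(a))
    raise ValueError(f"unknown alternative {alternative!r}")


def te_proximity(genes_by_class: dict, te_intervals):
    """Distance-to-nearest-TE per element class, with pairwise U tests.

    ``genes_by_class`` maps a class name (e.g. functional / pseudogene /
    sv) to (chrom, start, end) loci.  The distance is the edge-to-edge gap
    to the closest TE on the same chromosome (0 when overlapping); loci on
    chromosomes without any TE are excluded with a warning.  Returns
    (distances, pvalues): per-class distance lists and two-sided
    Mann-Whitney U p-values for every class pair.
    """
    te_by_chrom: dict = {}
    for chrom, s, e in te_intervals:
        te_by_chrom.setdefault(chrom, []).append((s, e))
    starts, ends = {}, {}
    for chrom, ivs in te_by_chrom.items():
        ivs.sort()
        starts[chrom] = np.array([s for s, _ in ivs])
        ends[chrom] = np.array([e for _, e in ivs])

    distances = {}
    for klass, loci in genes_by_class.items():
        dists, skipped = [], 0
        for chrom, s, e in loci:
            if chrom not in te_by_chrom:
                skipped += 1
                continue
            ts, te_ = starts[chrom], ends[chrom]
            # nearest edge-to-edge gap; 0 if any overlap
            left = te_ <= s
            right = ts >= e
            d = 0
            if bool(np.any(~left & ~right)):
                d = 0
            else:
                cands = []
                if left.any():
                    cands.append(s - te_[left].max())
                if right.any():
                    cands.append(ts[right].min() - e)
                d = min(cands)
            dists.append(int(d))
        if skipped:
            warnings.warn(f"{klass}: {skipped} loci on chromosomes with no "
                          "TE were excluded")
        distances[klass] = dists

    pvalues = {}
    names = sorted(distances)
    for i, x in enumerate(names):
        for y in names[i + 1:]:
            if distances[x] and distances[y]:
                p = float(stats.mannwhitneyu(
                    distances[x], distances[y],
                    alternative="two-sided").pvalue)
            else:
                p = float("nan")
            pvalues[(x, y)] = p
    return distances, pvalues
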