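"""Micro-synteny block construction and rank-space breakpoint detection.

Ortholog pairs are chained in *gene-rank space*: each gene carries its
0-based position in the start-sorted gene order of its chromosome.  A block
is a maximal run of anchors whose ranks increase strictly in genome A and
increase (``same`` orientation) or decrease (``inverted``) strictly in
genome B, with at most ``max_gap`` intervening genes between consecutive
anchors on either genome.  Breakpoints between adjacent blocks approximate
rearrangement boundaries; this is a gene-order approximation to
nucleotide-level whole-genome alignment and is labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["SyntenyBlock", "Breakpoint", "build_microsynteny",
           "find_breakpoints"]


@dataclass
class SyntenyBlock:
    """A maximal chain of collinear ortholog anchors."""

    block_id: str
    pairs: list                 # OrthologPair, ordered by rank_a
    chrom_a: str
    chrom_b: str
    orientation: str            # "same" | "inverted"
    span_a: tuple               # (min_rank, max_rank) inclusive, genome A
    span_b: tuple
    ranks_a: tuple = ()         # anchor ranks, parallel to ``pairs``
    ranks_b: tuple = ()

    def __len__(self):
        return len(self.pairs)


@dataclass(frozen=True)
class Breakpoint:
    """A collinearity discontinuity between two adjacent blocks."""

    chrom_a: str
    interval_a: tuple           # (rank_left, rank_right) exclusive bounds
    chrom_b: str
    interval_b: tuple
    kind: str                   # "inversion" | "translocation" | "block_end"


def _rank_maps(bundle):
    """gene_id -> (chrom, rank) for every annotated gene."""
    return {g.gene_id: (g.chrom, g.rank) for g in bundle.all_genes()}


def _best_chain(anchors, max_gap, sign):
    """Lexicographically smallest maximum-length chain over ``anchors``.

    ``anchors`` is a list of (rank_a, rank_b, pair) sorted ascending;
    ``sign`` is +1 (rank_b increasing) or -1 (decreasing).  A step from
    anchor u to v is valid when 1 <= ra_v - ra_u <= max_gap + 1 and
    1 <= sign * (rb_v - rb_u) <= max_gap + 1.
    """
    n = len(anchors)
    if n == 0:
        return []
    step = max_gap + 1

    def ok(u, v):
        da = anchors[v][0] - anchors[u][0]
        db = sign * (anchors[v][1] - anchors[u][1])
        return 1 <= da <= step and 1 <= db <= step

    # L[i] = longest chain starting at i
    L = [1] * n
    for i in range(n - 1, -1, -1):
        for j in range(i + 1, n):
            if anchors[j][0] - anchors[i][0] > step:
                break
            if ok(i, j) and L[j] + 1 > L[i]:
                L[i] = L[j] + 1
    best = max(L)
    # greedy lexicographic reconstruction: smallest start achieving the
    # maximum, then at each step the smallest valid successor that keeps
    # the remaining length
    i = min(k for k in range(n) if L[k] == best)
    chain = [i]
    need = best - 1
    while need:
        j = min(k for k in range(i + 1, n) if ok(i, k) and L[k] == need)
        chain.append(j)
        i, need = j, need - 1
    return [anchors[k] for k in chain]


def build_microsynteny(pairs, bundle_a, bundle_b, min_block_pairs: int = 3,
                       max_gap: int = 2):
    """Chain RBH ortholog pairs into micro-synteny blocks.

    Chaining is greedy longest-first within each (chrom_a, chrom_b) anchor
    group: the longest valid chain (ties: lexicographically smallest anchor
    sequence, ``same`` orientation preferred) is extracted, its anchors are
    removed, and the process repeats while chains of at least
    ``min_block_pairs`` anchors remain.  Every pair lands in at most one
    block; blocks are sorted by (chrom_a, span_a).
    """
    ranks_a = _rank_maps(bundle_a)
    ranks_b = _rank_maps(bundle_b)
    groups: dict = {}
    for p in pairs:
        ca, ra = ranks_a[p.gene_a]
        cb, rb = ranks_b[p.gene_b]
        groups.setdefault((ca, cb), []).append((ra, rb, p))

    blocks = []
    for (ca, cb) in sorted(groups):
        anchors = sorted(groups[(ca, cb)])
        while len(anchors) >= min_block_pairs:
            fwd = _best_chain(anchors, max_gap, +1)
            rev = _best_chain(anchors, max_gap, -1)
            # prefer longer; ties by smaller anchor sequence, then "same"
            cand = max(
                (len(fwd), [(-r[0], -r[1]) for r in fwd], 1, fwd),
                (len(rev), [(-r[0], -r[1]) for r in rev], 0, rev),
            )
            chain = cand[3]
            orientation = "same" if cand[2] == 1 else "inverted"
            if len(chain) < min_block_pairs:
                break
            ra = [a[0] for a in chain]
            rb = [a[1] for a in chain]
            blocks.append(SyntenyBlock(
                block_id="", pairs=[a[2] for a in chain], chrom_a=ca,
                chrom_b=cb, orientation=orientation,
                span_a=(min(ra), max(ra)), span_b=(min(rb), max(rb)),
                ranks_a=tuple(ra), ranks_b=tuple(rb)))
            used = set(id(a[2]) for a in chain)
            anchors = [a for a in anchors if id(a[2]) not in used]

    blocks.sort(key=lambda b: (b.chrom_a, b.span_a))
    for i, b in enumerate(blocks, 1):
        b.block_id = f"block{i:04d}"
    return blocks


def _continuous(b1: SyntenyBlock, b2: SyntenyBlock, max_gap: int) -> bool:
    """True when b2 continues b1 collinearly on genome B."""
    if b1.chrom_b != b2.chrom_b or b1.orientation != b2.orientation:
        return False
    if b1.orientation == "same":
        gap = b2.span_b[0] - b1.span_b[1] - 1
    else:
        gap = b1.span_b[0] - b2.span_b[1] - 1
    return 0 <= gap <= max_gap


def find_breakpoints(blocks, bundle_a, bundle_b, max_gap: int = 2):
    """Breakpoints between adjacent blocks along each genome-A chromosome.

    Adjacent blocks whose orientations differ yield an ``inversion``
    breakpoint; same-orientation blocks that are not a collinear
    continuation on genome B (different chromosome, wrong order, or a rank
    gap beyond ``max_gap``) yield a ``translocation``.  Chromosome ends of
    the outermost blocks are reported as ``block_end``.
    """
    by_chrom: dict = {}
    for b in blocks:
        by_chrom.setdefault(b.chrom_a, []).append(b)
    out = []
    for ca in sorted(by_chrom):
        bs = sorted(by_chrom[ca], key=lambda b: b.span_a)
        n_a = len(bundle_a.genes.get(ca, []))
        first, last = bs[0], bs[-1]
        out.append(Breakpoint(ca, (-1, first.span_a[0]), first.chrom_b,
                              (-1, -1), "block_end"))
        for b1, b2 in zip(bs, bs[1:]):
            if _continuous(b1, b2, max_gap):
                continue
            kind = ("inversion" if b1.orientation != b2.orientation
                    else "translocation")
            if b1.orientation == "same":
                left_b = b1.span_b[1]
            else:
                left_b = b1.span_b[0]
            if b2.orientation == "same":
                right_b = b2.span_b[0]
            else:
                right_b = b2.span_b[1]
            out.append(Breakpoint(
                ca, (b1.span_a[1], b2.span_a[0]), b1.chrom_b,
                tuple(sorted((left_b, right_b))), kind))
        out.append(Breakpoint(ca, (last.span_a[1], n_a), last.chrom_b,
                              (-1, -1), "block_end"))
    return out
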