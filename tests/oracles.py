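"""Independent brute-force oracles used to validate the fast implementations.

Each oracle is written top-down / by enumeration, deliberately sharing no
code with the implementation it checks.
"""

from functools import lru_cache

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_BLOSUM = substitution_matrices.load("BLOSUM62")


def sw_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Textbook Smith-Waterman with affine gaps (gap of length k costs
    gap_open + k * gap_extend), three-matrix formulation."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in b (a consumed)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            Ix[i][j] = max(M[i - 1][j] - gap_open - gap_extend,
                           Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - gap_open - gap_extend,
                           Iy[i][j - 1] - gap_extend)
            s = _BLOSUM[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0,
                          max(M[i - 1][j - 1], Ix[i - 1][j - 1],
                              Iy[i - 1][j - 1]) + s)
            best = max(best, M[i][j], Ix[i][j], Iy[i][j])
    return best


def rbh_bruteforce(hits_ab, hits_ba):
    """Reciprocal best hits by exhaustive pairwise comparison.

    For every (a, b) pair with a hit in both directions, check explicitly
    that no competing hit beats it under (score, identity, smaller subject
    id) preference.  Returns a sorted list of (gene_a, gene_b).
    """
    def better(h1, h2):
        """True when h1 is strictly preferred over h2 as a best subject."""
        k1 = (-h1.score, -h1.identity, h1.subject_id)
        k2 = (-h2.score, -h2.identity, h2.subject_id)
        return k1 < k2

    ab = {}
    for h in hits_ab:
        if h.query_id != h.subject_id:
            ab.setdefault(h.query_id, []).append(h)
    ba = {}
    for h in hits_ba:
        if h.query_id != h.subject_id:
            ba.setdefault(h.query_id, []).append(h)
    out = []
    for a, hs in ab.items():
        for h in hs:
            b = h.subject_id
            if any(better(other, h) for other in hs if other is not h):
                continue
            back = [x for x in ba.get(b, []) if x.subject_id == a]
            if not back:
                continue
            hb = back[0]
            if any(better(other, hb) for other in ba[b] if other is not hb):
                continue
            out.append((a, b))
    return sorted(out)


def chains_bruteforce(anchors, max_gap, min_block_pairs):
    """Greedy longest-first chaining by complete enumeration.

    ``anchors`` is a list of (rank_a, rank_b) tuples.  All strictly
    monotone chains (rank_b increasing or decreasing) satisfying the gap
    constraint are enumerated; the longest — ties broken by
    lexicographically smallest anchor sequence, then by "same" orientation
    — is extracted and the process repeats.  Returns a list of
    (orientation, [anchor, ...]) in extraction order.
    """
    step = max_gap + 1

    def extend(chain, remaining, sign):
        yield list(chain)
        last = chain[-1]
        for nxt in remaining:
            da = nxt[0] - last[0]
            db = sign * (nxt[1] - last[1])
            if 1 <= da <= step and 1 <= db <= step:
                yield from extend(chain + [nxt],
                                  [x for x in remaining if x[0] > nxt[0]],
                                  sign)

    blocks = []
    pool = sorted(anchors)
    while True:
        candidates = []
        for sign, orient in ((1, "same"), (-1, "inverted")):
            for i, start in enumerate(pool):
                for chain in extend([start], pool[i + 1:], sign):
                    candidates.append((len(chain), chain, orient))
        if not candidates:
            break
        best = max(candidates,
                   key=lambda c: (c[0],
                                  [(-r[0], -r[1]) for r in c[1]],
                                  c[2] == "same"))
        if best[0] < min_block_pairs:
            break
        blocks.append((best[2], best[1]))
        chosen = set(best[1])
        pool = [x for x in pool if x not in chosen]
    return blocks


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by summation of hypergeometric point
    probabilities <= that of the observed table (with a tiny relative
    tolerance, as in the conventional definition)."""
    from math import comb

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pt(k):
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = pt(a)
    return sum(pt(k) for k in range(lo, hi + 1)
               if pt(k) <= p_obs * (1 + 1e-7))


def fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher p by direct tail summation."""
    from math import comb

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    hi = min(r1, c1)
    return sum(comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)
               for k in range(a, hi + 1))


def protein_dna_score(seed: str, dna: str, min_intron: int = 40,
                      fpen: int = 15, ipen: int = 30, gpen: int = 10) -> int:
    """Best local spliced-alignment score by memoized path recursion.

    Paths start and end on a codon-match op; ops are: match codon (3 nt,
    BLOSUM62 on the translation, stops matchable), frameshift codon (1, 2,
    4 or 5 nt, flat penalty), DNA codon skip, seed residue skip, and an
    intron jump of >= ``min_intron`` nt between codons.
    """
    NEG = float("-inf")

    def codon_score(i, j, L):
        if L != 3:
            return -fpen
        aa = str(Seq(dna[j:j + 3]).translate())
        return _BLOSUM[seed[i], aa]

    @lru_cache(maxsize=None)
    def best_end(i, j):
        """Best score of a path consuming seed[..i] and dna[..j] (both
        exclusive ends) whose last op is a codon match ending at j."""
        out = NEG
        for L in (1, 2, 3, 4, 5):
            if j - L < 0:
                continue
            s = codon_score(i - 1, j - L, L)
            if L == 3:
                out = max(out, s)  # path start
            prev = prefix_best(i - 1, j - L)
            if prev > 0:
                out = max(out, s + prev)
            if L == 3 and i >= 2:
                for jp in range(0, j - L - min_intron + 1):
                    p = prefix_best(i - 1, jp)
                    if p > 0:
                        out = max(out, s + p - ipen)
        return out

    @lru_cache(maxsize=None)
    def prefix_best(i, j):
        """Best path ending anywhere at (i, j) via match / skip ops."""
        if i == 0:
            return NEG
        out = best_end(i, j)
        if j >= 3:
            p = prefix_best(i, j - 3)      # skip a DNA codon
            if p > NEG:
                out = max(out, p - gpen)
        p = prefix_best(i - 1, j)          # skip a seed residue
        if p > NEG:
            out = max(out, p - gpen)
        return out

    best = 0
    for i in range(1, len(seed) + 1):
        for j in range(1, len(dna) + 1):
            v = best_end(i, j)
            if v > best:
                best = v
    best_end.cache_clear()
    prefix_best.cache_clear()
    return int(best)
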