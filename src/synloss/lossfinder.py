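"""Flanking-gene deletion tracing with a re-prediction false-positive filter.

The A-B-C rule: if genes A and C are collinear ortholog anchors in a
micro-synteny block and, between them, one genome carries gene(s) B while
the other carries none, each such B is a candidate loss in the genome that
lacks it.  To guard against annotation failure, the intergenic interval
between the orthologs of A and C is re-examined by aligning B's protein to
it (both strands): a prediction covering more than 70% of the seed with no
frameshift and no premature stop marks the event a false positive
(an intact but unannotated copy); everything else is a confirmed loss.
Confirmed losses adjacent to rearrangement breakpoints are re-labelled
``sv_associated``.  A final genome-wide recovery check reports the
fraction of confirmed losses whose protein can still be found intact
anywhere in the target genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .genomeio import GenomeBundle
from .pgalign import align_protein_to_dna
from .pseudogenes import search_protein_in_chromosomes

__all__ = ["LossCandidate", "trace_deletions", "repredict_in_interval",
           "repredict_all", "tag_sv_losses", "recovery_check",
           "COVERAGE_THRESHOLD", "DEFAULT_INTERVAL_PADDING"]

COVERAGE_THRESHOLD = 0.70       # seed-protein coverage marking a false positive
DEFAULT_INTERVAL_PADDING = 2000  # nt beyond the anchors' inner boundaries


@dataclass
class LossCandidate:
    """A putative deleted gene with its flanking anchors and evidence.

    ``missing_gene`` lives in ``genome_with_gene`` ('a' or 'b'); the
    ``target_interval`` is the span strictly between the orthologs of the
    flanking anchors in the genome that lacks the gene.  ``status`` is one
    of candidate / confirmed_lost / false_positive / sv_associated.
    """

    missing_gene: str
    genome_with_gene: str
    missing_rank: int            # rank on the chromosome that retains it
    missing_chrom: str
    anchor_left: object          # OrthologPair
    anchor_right: object
    target_interval: tuple       # (chrom, start, end) in the lacking genome
    status: str = "candidate"
    evidence: dict = field(default_factory=dict)


def _interval_between(bundle: GenomeBundle, gene_left: str,
                      gene_right: str) -> tuple:
    gl = bundle.gene(gene_left)
    gr = bundle.gene(gene_right)
    lo, hi = sorted([gl, gr], key=lambda g: g.start)
    return (gl.chrom, lo.end, hi.start)


def trace_deletions(blocks, bundle_a: GenomeBundle, bundle_b: GenomeBundle,
                    max_run: int = 3):
    """Candidate losses from consecutive anchors of every block.

    For consecutive anchors (A, C) within one block, if the rank gap on one
    genome contains 1..``max_run`` unanchored genes while the gap on the
    other genome is zero, one candidate per unanchored gene is emitted —
    runs count as individual deletion events.  Both directions (gene
    present in A and missing from B, and vice versa) are examined.
    """
    out = []
    for block in blocks:
        for k in range(len(block.pairs) - 1):
            pl, pr = block.pairs[k], block.pairs[k + 1]
            ra0, ra1 = block.ranks_a[k], block.ranks_a[k + 1]
            rb0, rb1 = block.ranks_b[k], block.ranks_b[k + 1]
            gap_a = ra1 - ra0 - 1
            gap_b = abs(rb1 - rb0) - 1
            if 1 <= gap_a <= max_run and gap_b == 0:
                genes_a = bundle_a.genes[block.chrom_a]
                iv = _interval_between(bundle_b, pl.gene_b, pr.gene_b)
                for r in range(ra0 + 1, ra1):
                    out.append(LossCandidate(
                        missing_gene=genes_a[r].gene_id,
                        genome_with_gene="a", missing_rank=r,
                        missing_chrom=block.chrom_a, anchor_left=pl,
                        anchor_right=pr, target_interval=iv))
            elif 1 <= gap_b <= max_run and gap_a == 0:
                genes_b = bundle_b.genes[block.chrom_b]
                iv = _interval_between(bundle_a, pl.gene_a, pr.gene_a)
                lo = min(rb0, rb1)
                for r in range(lo + 1, lo + 1 + gap_b):
                    out.append(LossCandidate(
                        missing_gene=genes_b[r].gene_id,
                        genome_with_gene="b", missing_rank=r,
                        missing_chrom=block.chrom_b, anchor_left=pl,
                        anchor_right=pr, target_interval=iv))
    out.sort(key=lambda c: (c.genome_with_gene, c.missing_chrom,
                            c.missing_rank))
    return out


def repredict_in_interval(candidate: LossCandidate, seed_protein: str,
                          target_dna: str,
                          coverage_threshold: float = COVERAGE_THRESHOLD,
                          **aln_kwargs) -> LossCandidate:
    """Re-predict the missing gene inside its intergenic interval.

    Both strands of ``target_dna`` (the padded interval sequence) are
    aligned against the seed protein; the higher-scoring strand counts.
    ``false_positive`` iff seed coverage > 70% with zero frameshifts and
    zero premature stops, else ``confirmed_lost``.
    """
    from .genomeio import revcomp

    best, strand = None, "+"
    if len(target_dna) >= 30:
        for st, dna in (("+", target_dna), ("-", revcomp(target_dna))):
            aln = align_protein_to_dna(seed_protein, dna, **aln_kwargs)
            if best is None or aln.score > best.score:
                best, strand = aln, st
    if best is None or best.aligned_seed_residues == 0:
        candidate.evidence = {"coverage": 0.0, "frameshifts": 0,
                              "premature_stops": 0, "score": 0,
                              "strand": "."}
        candidate.status = "confirmed_lost"
        return candidate
    coverage = best.aligned_seed_residues / len(seed_protein)
    candidate.evidence = {
        "coverage": coverage,
        "frameshifts": best.frameshifts,
        "premature_stops": best.premature_stops,
        "score": best.score,
        "strand": strand,
    }
    intact = (coverage > coverage_threshold and best.frameshifts == 0
              and best.premature_stops == 0)
    candidate.status = "false_positive" if intact else "confirmed_lost"
    return candidate


def repredict_all(candidates, bundle_a: GenomeBundle, bundle_b: GenomeBundle,
                  padding: int = DEFAULT_INTERVAL_PADDING, **aln_kwargs):
    """Run the re-prediction filter over all candidates.

    The interval is padded by ``padding`` nt beyond the anchors' inner
    boundaries (clamped to the chromosome) to tolerate annotation boundary
    noise.
    """
    for cand in candidates:
        retain = bundle_a if cand.genome_with_gene == "a" else bundle_b
        lack = bundle_b if cand.genome_with_gene == "a" else bundle_a
        seed = retain.gene(cand.missing_gene).protein
        chrom, s, e = cand.target_interval
        seq = lack.chromosomes[chrom]
        s = max(0, s - padding)
        e = min(len(seq), e + padding)
        repredict_in_interval(cand, seed, seq[s:e], **aln_kwargs)
    return candidates


def tag_sv_losses(candidates, breakpoints, window_genes: int = 1):
    """Re-label confirmed losses that sit next to a rearrangement breakpoint.

    A confirmed loss whose missing gene's rank lies within ``window_genes``
    of an inversion or translocation breakpoint interval (on the genome
    that retains the gene) becomes ``sv_associated``.  Chromosome-end
    breakpoints do not count: they are not rearrangements.
    """
    for cand in candidates:
        if cand.status != "confirmed_lost":
            continue
        r = cand.missing_rank
        for bp in breakpoints:
            if bp.kind == "block_end":
                continue
            if cand.genome_with_gene == "a":
                chrom, (lo, hi) = bp.chrom_a, bp.interval_a
            else:
                chrom, (lo, hi) = bp.chrom_b, bp.interval_b
            if chrom != cand.missing_chrom or lo < 0:
                continue
            dist = 0 if lo < r < hi else min(abs(r - lo), abs(r - hi))
            if dist <= window_genes:
                cand.status = "sv_associated"
                break
    return candidates


def recovery_check(confirmed_losses, target_bundle: GenomeBundle,
                   retaining_bundle: GenomeBundle,
                   coverage_threshold: float = COVERAGE_THRESHOLD,
                   **search_kwargs) -> float:
    """Genome-wide recovery rate of confirmed losses.

    Each lost gene's seed protein is searched against the *whole* target
    genome (not just the A-C interval); a loss is "recovered" when an
    alignment anywhere covers more than 70% of the seed with no
    disablement (no frameshift, no premature stop).  Returns the recovered
    fraction; an empty loss list returns 0.0 with a warning.
    """
    losses = list(confirmed_losses)
    if not losses:
        warnings.warn("recovery_check called with no confirmed losses")
        return 0.0
    recovered = 0
    for cand in losses:
        seed = retaining_bundle.gene(cand.missing_gene).protein
        aln = search_protein_in_chromosomes(
            seed, target_bundle.chromosomes, seed_id=cand.missing_gene,
            **search_kwargs)
        if aln is None:
            continue
        coverage = aln.aligned_seed_residues / len(seed)
        if (coverage > coverage_threshold and aln.frameshifts == 0
                and aln.premature_stops == 0):
            recovered += 1
    return recovered / len(losses)
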