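# Methods

`synloss` infers gene losses between two annotated genomes from gene order
and sequence alone, and classifies the decayed remnants of former genes.
This note documents the models, the parameters that matter, the synthetic
world the test suite runs on, and the numerical choices behind the
defaults.

## Coordinate and data model

All coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
and BED (0-based) are converted at the I/O boundary.  A `GenomeBundle`
couples chromosome sequences with start-sorted `GeneModel`s (exon
structure, strand, protein) and optional transposable-element intervals.
Each gene carries a *rank*, its position in the chromosome's gene order;
the synteny and loss machinery operates entirely in rank space.

## Orthology

Proteins are compared with Smith–Waterman local alignment (BLOSUM62,
affine gaps in the BLAST convention: a gap of length *k* costs 11 + *k*).
Hits are retained at identity ≥ 30% and coverage > 30% — the identity
bound inclusive, the coverage bound strict, matching the asymmetric
phrasing of the retention rule.  Coverage is query-sided by default
(the rule's sidedness is otherwise ambiguous); a strict mode demanding
both sides is available (`require_both_coverages`).  Reciprocal best hits
(best = highest score, ties by identity then by lexicographically smaller
subject id) define ortholog pairs.  Precomputed BLAST/DIAMOND 12-column
tabular hits can replace the internal aligner; the E-value cutoff
(default 1e-7) applies only there, because E-values are search-space
dependent and the internal aligner does not compute them.

An all-vs-all helper prunes clearly unrelated pairs with a shared
amino-acid 4-mer prefilter before aligning; disabling the prefilter
(`min_shared_kmers=0`) reproduces the exhaustive result.

## Micro-synteny and breakpoints

Ortholog anchors are chained per chromosome pair: ranks must increase
strictly in genome A and increase (`same`) or decrease (`inverted`)
strictly in genome B, with at most `max_gap` intervening genes between
consecutive anchors on either genome.  Chaining is greedy longest-first
with a deterministic tie-break (lexicographically smallest anchor
sequence, `same` preferred) — reproducibility over optimality, validated
against exhaustive enumeration at small n.  Defaults `min_block_pairs=3`,
`max_gap=2` keep an A–B–C triple with a missing middle gene inside one
block.

Breakpoints are called between blocks that are adjacent along a genome-A
chromosome but do not continue collinearly on genome B: an orientation
flip is an `inversion`, anything else a `translocation`; chromosome ends
are reported as `block_end` and never treated as rearrangements.  This is
a gene-order approximation to nucleotide-level whole-genome alignment:
rearrangements smaller than a block or falling between anchors are
invisible to it.

## Loss tracing and the re-prediction filter

For consecutive anchors (A, C) inside one block, a rank gap of 1..
`max_run` genes on one genome opposite a gap of 0 on the other yields one
loss candidate per unanchored gene (runs count as individual events;
`max_run=3` caps what a single interval is asked to explain).  The
candidate's *target interval* is the span strictly between the orthologs
of A and C in the genome that lacks the gene, padded by 2 kb into the
anchors to absorb annotation boundary noise.

Each candidate is re-predicted: the missing gene's protein is aligned to
both strands of the target interval with the spliced aligner (below).
Coverage (aligned seed residues / seed length, i.e. seed-sided)
above 70% with zero frameshifts and zero premature stops marks the event
a **false positive** — an intact gene the annotation missed — otherwise
it is **confirmed lost**.  Confirmed losses whose rank lies within
`window_genes=1` of an inversion or translocation breakpoint are
relabelled **sv_associated**.  Finally, `recovery_check` searches each
lost protein against the *whole* target genome (the translocation case
the interval test cannot see) and reports the fraction found intact
anywhere.

## The spliced protein-to-DNA aligner

A transparent stand-in for GeneWise-style pseudogene alignment: dynamic
programming over (seed residue, DNA position) with match, DNA-codon-skip
and seed-residue-skip states.  A residue may consume 1, 2, 4 or 5
nucleotides (a frameshift codon, flat penalty F=15, no substitution
score) instead of 3; between ordinary codons the DNA may jump an intron
gap of ≥ `min_intron`=40 nt for a flat penalty I; stop codons are
matchable but flagged, and a stop aligned before the seed's final residue
counts as premature.  No splice-site motif is required — pseudogene
splice sites decay.  The best local path (starting and ending on a
match) is reported with per-event counts; ties resolve deterministically
(smallest end position; normal codon over frameshift over intron within
a cell).

**Intron penalty I=30.**  An intron must "pay for itself" with roughly
eight well-matching codons beyond the gap.  At I=20 the aligner
profitably extended decayed single-exon copies with spurious terminal
"exons" of a few lucky codons found in flanking random intergenic DNA,
inflating exon counts (and mis-classifying processed pseudogenes as
duplicated ones); at I=40 genuine short terminal exons of decayed
multi-exon copies start being dropped.  I=30 eliminated every spurious
intron observed across simulation seeds while preserving every real one.
Gap penalties are linear (10 per skipped codon/residue); `identity` is
computed over match+frameshift columns, `aligned_seed_residues` excludes
gap-skipped residues and is the coverage/align-ratio numerator.

The recurrence is quadratic and runs through a numba kernel when
available, with a pure-Python fill of identical semantics as fallback;
both are checked against a memoized path-recursion oracle in the tests.

## Pseudogene discovery and classification

Annotated gene spans are masked and seed proteins from the counterpart
genome are searched against the remaining intergenic segments in three
stages:

1. **Seeding** — shared 5-mers between the seed and the six-frame
   translation, in the Murphy reduced 10-letter alphabet (LVIM / C / A /
   G / ST / P / FYW / EDNQ / KR / H); BLOSUM-plausible substitutions
   usually stay within a class, so reduced k-mers survive far more
   divergence than exact ones.  Matches must agree on a DNA diagonal:
   ≥ 3 within a tight 4-nt band (substitution-only copies) or ≥ 8 within
   a loose 48-nt band (spliced copies, whose diagonals shift by intron
   lengths).
2. **Verification** — a windowed C-level local protein alignment against
   the implicated frame region must reach score 55 (roughly E < 0.01 for
   these search-space sizes); this absorbs the permissive seeding's
   background at microsecond cost.
3. **Refinement** — the spliced aligner on the seeded strand(s); calls
   below raw score 60 are discarded as noise.

Overlapping calls are resolved greedily by score: a call overlapping an
accepted one by ≥ 50% of the shorter locus is suppressed.  Metrics:
`align_ratio` = aligned seed residues / seed length (seed-sided, the
PseudoPipe convention), `exon_number` = coding blocks separated by intron
gaps, `has_disablement` = any frameshift, premature stop, or ≥ 1-codon
gap inside the aligned region (the literal reading of "insertion,
deletion, termination, or frameshift").

High-confidence calls require identity > 0.30 **and** match length > 50
aa, both strict.  Classification (identity within [0.3, 0.95]
throughout):

| class | exon number | align ratio | disablement |
|-------|-------------|-------------|-------------|
| PSSD  | = 1         | 0.7 < r ≤ 0.95 | — |
| DUP   | > 1         | — (no ratio constraint, taken literally) | required |
| FRAG  | = 1         | r < 0.7     | — |

Everything else — ratio exactly 0.7, ratio > 0.95, identity > 0.95,
multi-exon without disablement (an intact unannotated gene) — is
`OTHER`.  The three rule domains are provably disjoint (property-tested
on a 20k-point grid).

## Supporting statistics

**4DTv.**  Eligible sites are third positions of aligned codon columns
whose first two positions are identical and whose codons belong to one
of the eight fourfold-degenerate families (Leu-CTN, Val-GTN, Ser-TCN,
Pro-CCN, Thr-ACN, Ala-GCN, Arg-CGN, Gly-GGN); 4DTv is the transversion
fraction at those sites, `None` (never 0) when no site is eligible.  Raw
proportion by default; a Kimura-style correction −½ln(1−2q) is available
behind a flag and off by default.  Codon alignments are built by
threading a global protein alignment back onto the CDS.

**Fisher family test.**  The 2×2 table is (family, non-family) ×
(focal, reference genome); one-sided `greater` (expansion) is the
default, with `less` and `two_sided` available.  Computation delegates to
scipy's exact hypergeometric routines and is checked in the tests against
a from-scratch summation oracle.

**TE proximity.**  Distance is the edge-to-edge gap to the nearest TE on
the same chromosome (0 when overlapping; midpoints would penalize long
elements).  Classes are compared pairwise with two-sided Mann–Whitney U.
Loci on chromosomes without any TE are excluded with a warning rather
than given an arbitrary distance.

## The simulated world

The generator builds an ancestral gene set — proteins sampled from
empirical amino-acid background frequencies (mean length 150 aa, 1–4
exons, GT-AG introns of 60–200 nt, intergenic spacers of 500–3000 nt at
GC 0.40) — and realizes it in two genomes.  Genome B's proteins carry
per-gene BLOSUM62-weighted substitutions hitting the configured ortholog
identity (default 0.8; realized mean within ±2% by construction); CDSs
are back-translated with uniform synonymous codon choice *independently*
per genome, so fourfold-degenerate sites diverge and 4DTv is exercised
non-trivially (near saturation, as expected for independent draws).
Genome B then receives, per the default configuration: 10 whole-gene
deletions, 5 hidden intact copies (annotation deleted, sequence kept),
10+10+10 pseudogene implants, 2 inversions, and TE intervals at
5/100 kb.  All randomness flows from a single seeded generator in fixed
code order; identical (config, seed) reproduces byte-identical files.

Implant construction: PSSD = spliced, intron-less 3′ fragment of
71–95% of the source, 8% nucleotide decay; DUP = full genomic multi-exon
copy, decay plus at least one engineered frameshift indel and/or
in-frame stop; FRAG = 20–60% spliced fragment with decay.  Implants land
on a random strand, ≥ 500 nt from annotated genes, to keep the overlap
resolution unambiguous in tests.

Two geometry choices matter and were made deliberately:

* **Inversions span 6–8 genes.**  For shorter segments a collinear chain
  can "thread" through the inverted run within the default `max_gap=2`
  (entering k genes in costs a B-rank gap of seg−k), which nests block
  spans and garbles breakpoint calls; at ≥ 6 genes threading is
  impossible and each inversion cleanly becomes its own inverted block.
* **One deletion per inversion sits two genes outside the inverted
  segment.**  A deletion exactly at the boundary has its A and C anchors
  in different blocks, where the flanking-gene rule is blind by
  construction; one gene further out both anchors stay in the flanking
  collinear block while the missing gene's rank still touches the
  breakpoint window, so the loss is both found and tagged SV-associated.

What the simulator does **not** model: indels within orthologous
proteins, substitution-rate heterogeneity or realistic phylogenetic
models, repeat-driven sequence structure (TE intervals are annotation
only; intergenic DNA is i.i.d.), transcribed pseudogenes, and
segmental duplication.  A green end-to-end test therefore establishes
that the machinery implements its rules correctly on cleanly separable
events — not that recall would be 1.0 on a gigabase genome with
fragmented assemblies and noisy annotations, where the original numbers
came from.

The separate TE-layout world (`simulate_te_layout`) plants the
`functional` class 0–100 bp from a random element against uniform
`pseudogene`/`sv` classes, with 60 elements of 0.2–3 kb on 1 Mb (~10%
coverage) so that uniform placement sits kilobases away and adjacency is
a detectable contrast at n=50 per class.

## Pipeline and reproducibility

`pipeline.run_all` chains simulate → homology → synteny → losses →
pseudo → stats → evaluate through a run directory of flat TSV/GFF3/JSON
files; every stage re-reads its inputs from disk (which exercises the
I/O round trip), nothing is timestamped, and `manifest.json` records
every parameter, so two runs from one manifest are byte-identical —
the determinism audit in the test suite asserts exactly that.

## Known limitations

* Breakpoint detection works in gene-rank space; it approximates, and
  cannot fully substitute for, nucleotide-level whole-genome alignment.
* The re-prediction filter inherits the aligner's scoring: a hidden copy
  more diverged than ~50% identity may fall below the 70% coverage bar
  and be confirmed as lost.
* Whether candidate counts should be read before or after the
  false-positive filter is ambiguous in the underlying event-counting
  convention; the loss summary therefore reports both (`n_candidates`
  and the per-status counts).
* The seeding stage trades a small sensitivity loss for speed: fragments
  shorter than ~20 aa of well-diverged sequence can escape both diagonal
  tiers.
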