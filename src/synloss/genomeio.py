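"""Reading, writing and validation of annotated genome bundles.

All coordinates are 0-based half-open internally.  GFF3 files are 1-based
inclusive and are converted at the I/O boundary; BED input is consumed as-is.
A *bundle* couples a genome's nucleotide sequences with its gene models
(coordinates, strand, exon structure, protein) and optional transposable
element intervals, which is exactly the per-species input needed by the
orthology / synteny / gene-loss stages.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "GenomeBundle",
    "read_genome_bundle",
    "write_genome_bundle",
    "translate_cds",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHNacgtrykmbvdhn",
                            "TGCAYRMKVBHDNtgcayrmkvbhdn")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds: str) -> str:
    """Translate a spliced CDS with the standard code (table 1).

    Ambiguous or partial codons translate to ``X``; a single trailing stop is
    stripped.  A CDS whose length is not a multiple of 3 triggers a warning
    and is translated in the truncated frame.
    """
    if len(cds) % 3 != 0:
        warnings.warn(f"CDS length {len(cds)} not divisible by 3; "
                      "translating truncated frame")
        cds = cds[: len(cds) - len(cds) % 3]
    prot = str(Seq(cds).translate(table=1))
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


@dataclass(frozen=True)
class GeneModel:
    """One annotated protein-coding gene.

    ``exons`` are absolute chromosome intervals (0-based half-open), sorted
    and non-overlapping; for the purposes of this pipeline exon and CDS
    structure coincide (no UTRs).  ``rank`` is the 0-based position of the
    gene in its chromosome's start-sorted gene order.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple
    protein: str
    rank: int = -1

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.protein:
            raise ValueError(f"{self.gene_id}: empty protein")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside "
                                 f"gene span ({self.start},{self.end})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeBundle:
    """An annotated genome: sequences, ordered gene models, TE intervals."""

    genome_id: str
    chromosomes: dict = field(default_factory=dict)
    genes: dict = field(default_factory=dict)  # chrom -> [GeneModel] by start
    te_intervals: list = field(default_factory=list)  # (chrom, start, end)

    def __post_init__(self):
        self.sort_and_rank()
        self.validate()

    # -- bookkeeping ------------------------------------------------------

    def sort_and_rank(self):
        """Sort genes by start per chromosome and (re)assign ranks."""
        new = {}
        for chrom in self.chromosomes:
            models = sorted(self.genes.get(chrom, []), key=lambda g: g.start)
            new[chrom] = [replace(g, rank=i) for i, g in enumerate(models)]
        self.genes = new
        self._by_id = {g.gene_id: g for gs in self.genes.values() for g in gs}

    def validate(self):
        seen = set()
        for chrom, models in self.genes.items():
            if chrom not in self.chromosomes:
                raise ValueError(f"unknown chromosome {chrom!r}")
            clen = len(self.chromosomes[chrom])
            for g in models:
                if g.gene_id in seen:
                    raise ValueError(f"duplicate gene id {g.gene_id!r}")
                seen.add(g.gene_id)
                if not (0 <= g.start < g.end <= clen):
                    raise ValueError(f"{g.gene_id}: interval ({g.start},"
                                     f"{g.end}) outside chromosome "
                                     f"{chrom} (len {clen})")
        for chrom, s, e in self.te_intervals:
            if chrom not in self.chromosomes:
                raise ValueError(f"TE interval on unknown chromosome {chrom!r}")
            if not (0 <= s < e <= len(self.chromosomes[chrom])):
                raise ValueError(f"TE interval ({s},{e}) outside {chrom}")

    # -- accessors --------------------------------------------------------

    def gene(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def all_genes(self):
        for chrom in sorted(self.genes):
            yield from self.genes[chrom]

    @property
    def n_genes(self) -> int:
        return len(self._by_id)

    def proteins(self) -> dict:
        return {g.gene_id: g.protein for g in self.all_genes()}

    def cds(self, gene_id: str) -> str:
        """Spliced, strand-oriented coding sequence of a gene."""
        g = self._by_id[gene_id]
        seq = self.chromosomes[g.chrom]
        spliced = "".join(seq[s:e] for s, e in g.exons)
        return revcomp(spliced) if g.strand == "-" else spliced

    def intergenic_segments(self, chrom: str):
        """(start, end) spans of ``chrom`` not covered by annotated genes."""
        clen = len(self.chromosomes[chrom])
        pos, out = 0, []
        for g in self.genes.get(chrom, []):
            if g.start > pos:
                out.append((pos, g.start))
            pos = max(pos, g.end)
        if pos < clen:
            out.append((pos, clen))
        return out

    def __eq__(self, other):
        if not isinstance(other, GenomeBundle):
            return NotImplemented
        return (self.genome_id == other.genome_id
                and self.chromosomes == other.chromosomes
                and self.genes == other.genes
                and sorted(self.te_intervals) == sorted(other.te_intervals))


# -- reading ---------------------------------------------------------------


def _read_te_intervals(path: str) -> list:
    """TE intervals from BED (0-based half-open) or GFF3 (1-based inclusive),
    auto-detected by extension."""
    lower = path.lower()
    gff = lower.endswith((".gff", ".gff3"))
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if gff:
                out.append((f[0], int(f[3]) - 1, int(f[4])))
            else:
                out.append((f[0], int(f[1]), int(f[2])))
    return out


def read_genome_bundle(fasta_path, gff3_path, te_path=None,
                       protein_fasta=None, genome_id=None) -> GenomeBundle:
    """Load a genome bundle from FASTA + GFF3 (+ optional TE and protein files).

    GFF3 coordinates are converted to the internal 0-based half-open
    convention.  Proteins come from ``protein_fasta`` when given, otherwise
    from strand-aware translation of the spliced CDS.  A GFF3 feature on a
    sequence absent from the FASTA is a hard error naming the sequence.
    """
    chroms = {rec.id: str(rec.seq).upper()
              for rec in SeqIO.parse(fasta_path, "fasta")}
    prot_by_id = {}
    if protein_fasta is not None:
        prot_by_id = {rec.id: str(rec.seq)
                      for rec in SeqIO.parse(protein_fasta, "fasta")}

    genes: dict = {c: [] for c in chroms}
    try:
        # multi-line CDS features legitimately share one ID
        db = gffutils.create_db(gff3_path, ":memory:",
                                merge_strategy="create_unique",
                                keep_order=True)
    except gffutils.exceptions.EmptyInputError:
        db = None
    for gf in (db.features_of_type("gene", order_by=("seqid", "start"))
               if db is not None else ()):
        if gf.seqid not in chroms:
            raise ValueError(f"GFF3 references sequence {gf.seqid!r} "
                             "absent from FASTA")
        cds = sorted(db.children(gf, featuretype="CDS"), key=lambda c: c.start)
        if cds:
            exons = tuple((c.start - 1, c.end) for c in cds)
        else:  # fall back to exon features
            exs = sorted(db.children(gf, featuretype="exon"),
                         key=lambda c: c.start)
            exons = tuple((c.start - 1, c.end) for c in exs)
        if not exons:
            exons = ((gf.start - 1, gf.end),)
        strand = gf.strand if gf.strand in ("+", "-") else "+"
        if gf.id in prot_by_id:
            protein = prot_by_id[gf.id]
        else:
            spliced = "".join(chroms[gf.seqid][s:e] for s, e in exons)
            if strand == "-":
                spliced = revcomp(spliced)
            protein = translate_cds(spliced)
        genes[gf.seqid].append(GeneModel(
            gene_id=gf.id, chrom=gf.seqid, start=gf.start - 1, end=gf.end,
            strand=strand, exons=exons, protein=protein))

    te = _read_te_intervals(te_path) if te_path else []
    if genome_id is None:
        genome_id = os.path.splitext(os.path.basename(fasta_path))[0]
    return GenomeBundle(genome_id=genome_id, chromosomes=chroms,
                        genes=genes, te_intervals=te)


# -- writing ---------------------------------------------------------------

def _wrap(seq: str, width: int = 60):
    return "\n".join(seq[i:i + width] for i in range(0, len(seq), width))


def write_genome_bundle(bundle: GenomeBundle, out_dir: str) -> dict:
    """Write FASTA / GFF3 / protein FASTA / TE BED for a bundle.

    Output is byte-stable for a fixed bundle: sequences are 60-column
    wrapped, GFF3 is 1-based inclusive with gene -> mRNA -> exon + CDS
    features, TE intervals go to BED3 (0-based half-open).  Returns a dict
    of the written paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "fasta": os.path.join(out_dir, f"{bundle.genome_id}.fa"),
        "gff3": os.path.join(out_dir, f"{bundle.genome_id}.gff3"),
        "proteins": os.path.join(out_dir, f"{bundle.genome_id}.proteins.fa"),
        "te": os.path.join(out_dir, f"{bundle.genome_id}.te.bed"),
    }
    with open(paths["fasta"], "w") as fh:
        for chrom in sorted(bundle.chromosomes):
            fh.write(f">{chrom}\n{_wrap(bundle.chromosomes[chrom])}\n")

    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(bundle.chromosomes):
            fh.write(f"##sequence-region {chrom} 1 "
                     f"{len(bundle.chromosomes[chrom])}\n")
        for chrom in sorted(bundle.chromosomes):
            for g in bundle.genes.get(chrom, []):
                s1, e1 = g.start + 1, g.end
                base = f"{chrom}\tsynloss\t"
                fh.write(base + f"gene\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                         f"ID={g.gene_id}\n")
                mrna = f"{g.gene_id}.t1"
                fh.write(base + f"mRNA\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                         f"ID={mrna};Parent={g.gene_id}\n")
                # CDS phase: cumulative coding length modulo 3, in
                # translation order (right-to-left on the minus strand).
                exons = list(g.exons)
                order = exons if g.strand == "+" else exons[::-1]
                phases, acc = {}, 0
                for ex in order:
                    phases[ex] = (3 - acc % 3) % 3
                    acc += ex[1] - ex[0]
                for i, (es, ee) in enumerate(exons, 1):
                    fh.write(base + f"exon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t"
                             f"ID={mrna}.exon{i};Parent={mrna}\n")
                for es, ee in exons:
                    fh.write(base + f"CDS\t{es + 1}\t{ee}\t.\t{g.strand}\t"
                             f"{phases[(es, ee)]}\tID={mrna}.cds;"
                             f"Parent={mrna}\n")

    with open(paths["proteins"], "w") as fh:
        for g in bundle.all_genes():
            fh.write(f">{g.gene_id}\n{_wrap(g.protein)}\n")

    with open(paths["te"], "w") as fh:
        for chrom, s, e in sorted(bundle.te_intervals):
            fh.write(f"{chrom}\t{s}\t{e}\n")
    return paths
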