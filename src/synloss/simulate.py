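"""Synthetic genome-pair generation with a known event ground truth.

Two annotated genomes, A and B, descend from a common ancestral gene set:
proteins are sampled from empirical amino-acid background frequencies,
back-translated with uniform random synonymous codon choice (independently
per genome, so fourfold-degenerate sites diverge), split into exons by
GT-AG introns, and separated by i.i.d. intergenic DNA at a configured GC
content.  Genome B's proteins carry BLOSUM62-weighted substitutions tuned
to the configured ortholog identity.  Genome B then receives:

* whole-gene **deletions** (sequence and annotation removed) — when
  inversions are requested, one deletion per inversion is placed
  immediately adjacent to the inverted segment so that rearrangement-
  associated losses exist;
* **hidden intact copies** (annotation removed, sequence kept) — decoys
  the re-prediction filter must reject as false positives;
* decayed **pseudogene implants** of three classes (PSSD: intron-less,
  71-95% of the seed; DUP: multi-exon with at least one frameshift or
  premature stop; FRAG: under 70% of the seed), placed at least 500 nt
  away from annotated genes;
* **inversions** and **translocations** of contiguous gene runs;
* annotated TE intervals placed uniformly (annotation only — intergenic
  sequence carries no repeat structure).

All randomness flows from one seeded generator in a fixed draw order, so
a given (config, seed) reproduces byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .genomeio import GeneModel, GenomeBundle, revcomp

__all__ = ["SimConfig", "TruthEvent", "TruthTable", "simulate_genome_pair",
           "evaluate_calls", "simulate_codon_pairs", "simulate_te_layout",
           "write_truth_table", "read_truth_table"]

# Robinson & Robinson-style amino-acid background frequencies
_AA_BG = {
    "A": 0.078, "R": 0.051, "N": 0.045, "D": 0.054, "C": 0.019,
    "Q": 0.043, "E": 0.063, "G": 0.074, "H": 0.022, "I": 0.051,
    "L": 0.091, "K": 0.057, "M": 0.022, "F": 0.039, "P": 0.052,
    "S": 0.071, "T": 0.058, "W": 0.013, "Y": 0.032, "V": 0.064,
}
_AAS = sorted(_AA_BG)
_AA_P = np.array([_AA_BG[a] for a in _AAS])
_AA_P = _AA_P / _AA_P.sum()

_CODONS_BY_AA: dict = {}
for codon, aa in sorted(standard_dna_table.forward_table.items()):
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
_STOP_CODONS = sorted(standard_dna_table.stop_codons)


def _blosum_substitution_weights():
    """P(new residue | old residue) proportional to 2**BLOSUM62, diagonal
    excluded."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    weights = {}
    for a in _AAS:
        w = np.array([0.0 if b == a else 2.0 ** float(blosum[a, b])
                      for b in _AAS])
        weights[a] = w / w.sum()
    return weights


_SUB_WEIGHTS = _blosum_substitution_weights()


@dataclass
class SimConfig:
    """The stated world of the simulated genome pair.

    Defaults are the end-to-end evaluation regime: two chromosomes of 100
    genes, 80% ortholog protein identity, ten deletions, five hidden
    intact copies, ten pseudogene implants per class and two inversions.
    """

    seed: int = 1
    n_chromosomes: int = 2
    genes_per_chromosome: int = 100
    mean_protein_length: int = 150
    n_exons_range: tuple = (1, 4)
    intergenic_length_range: tuple = (500, 3000)
    target_protein_identity: float = 0.8
    n_deletions: int = 10
    n_hidden_intact_copies: int = 5
    n_pseudogenes_per_class: tuple = (10, 10, 10)  # PSSD, DUP, FRAG
    n_inversions: int = 2
    n_translocations: int = 0
    n_relocated_intact_copies: int = 0
    te_density: float = 5.0       # elements per 100 kb
    gc_content: float = 0.4
    pseudogene_decay_rate: float = 0.08   # nt substitution rate in implants
    intron_length_range: tuple = (60, 200)
    min_exon_nt: int = 30

    def __post_init__(self):
        if not (0.0 < self.target_protein_identity <= 1.0):
            raise ValueError("identity outside (0, 1]")


@dataclass
class TruthEvent:
    kind: str                    # deletion | hidden_copy | pseudogene_PSSD |
    #                              pseudogene_DUP | pseudogene_FRAG |
    #                              inversion | translocation
    source_gene: str             # id in the genome that retains the gene
    chrom: str = ""              # target locus (genome B)
    start: int = -1
    end: int = -1
    details: dict = field(default_factory=dict)


@dataclass
class TruthTable:
    events: list = field(default_factory=list)

    def of_kind(self, *kinds):
        return [e for e in self.events if e.kind in kinds]


def write_truth_table(truth: TruthTable, path: str):
    with open(path, "w") as fh:
        fh.write("kind\tsource_gene\tchrom\tstart\tend\tdetails\n")
        for e in truth.events:
            fh.write(f"{e.kind}\t{e.source_gene}\t{e.chrom}\t{e.start}\t"
                     f"{e.end}\t{json.dumps(e.details, sort_keys=True)}\n")


def read_truth_table(path: str) -> TruthTable:
    events = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            kind, src, chrom, s, e, det = line.rstrip("\n").split("\t")
            events.append(TruthEvent(kind, src, chrom, int(s), int(e),
                                     json.loads(det)))
    return TruthTable(events)


# -- sequence helpers ------------------------------------------------------


def _random_dna(rng, n, gc):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _random_protein(rng, length):
    body = "".join(np.array(_AAS)[rng.choice(len(_AAS), size=length - 1,
                                             p=_AA_P)])
    return "M" + body


def _mutate_protein(rng, protein, n_sub):
    if n_sub == 0:
        return protein
    aa = list(protein)
    pos = rng.choice(len(aa), size=n_sub, replace=False)
    for p in sorted(int(x) for x in pos):
        old = aa[p]
        if old not in _SUB_WEIGHTS:  # non-standard residue: leave it
            continue
        aa[p] = _AAS[int(rng.choice(len(_AAS), p=_SUB_WEIGHTS[old]))]
    return "".join(aa)


def _backtranslate(rng, protein):
    out = []
    for a in protein:
        codons = _CODONS_BY_AA[a]
        out.append(codons[int(rng.integers(len(codons)))])
    out.append(_STOP_CODONS[int(rng.integers(len(_STOP_CODONS)))])
    return "".join(out)


def _split_cds(rng, cds_len, n_exons, min_exon):
    """Exon chunk lengths summing to cds_len, each >= min_exon."""
    n_exons = min(n_exons, max(1, cds_len // min_exon))
    if n_exons == 1:
        return [cds_len]
    while True:
        cuts = sorted(int(x) for x in
                      rng.choice(cds_len - 1, size=n_exons - 1,
                                 replace=False) + 1)
        bounds = [0] + cuts + [cds_len]
        lens = [b - a for a, b in zip(bounds, bounds[1:])]
        if min(lens) >= min_exon:
            return lens


def _gene_pieces(rng, cds, exon_lens, strand, intron_range, gc):
    """Genomic pieces [(kind, seq), ...] left-to-right on the chromosome."""
    chunks, pos = [], 0
    for L in exon_lens:
        chunks.append(cds[pos:pos + L])
        pos += L
    if strand == "-":
        chunks = [revcomp(c) for c in reversed(chunks)]
    pieces = []
    for k, chunk in enumerate(chunks):
        if k > 0:
            ilen = int(rng.integers(intron_range[0], intron_range[1] + 1))
            iseq = "GT" + _random_dna(rng, ilen - 4, gc) + "AG"
            pieces.append(("intron", iseq))
        pieces.append(("exon", chunk))
    return pieces


# -- element model ---------------------------------------------------------


class _Gene:
    __slots__ = ("gene_id", "strand", "pieces", "protein", "annotated",
                 "truth_idx")

    def __init__(self, gene_id, strand, pieces, protein, annotated=True,
                 truth_idx=None):
        self.gene_id = gene_id
        self.strand = strand
        self.pieces = pieces
        self.protein = protein
        self.annotated = annotated
        self.truth_idx = truth_idx

    @property
    def seq(self):
        return "".join(s for _, s in self.pieces)

    def invert(self):
        self.strand = "-" if self.strand == "+" else "+"
        self.pieces = [(k, revcomp(s)) for k, s in reversed(self.pieces)]


class _Dna:
    __slots__ = ("seq", "truth_idx")

    def __init__(self, seq, truth_idx=None):
        self.seq = seq
        self.truth_idx = truth_idx


class _Mark:
    __slots__ = ("truth_idx",)
    seq = ""

    def __init__(self, truth_idx):
        self.truth_idx = truth_idx


def _spacer(rng, cfg):
    lo, hi = cfg.intergenic_length_range
    return _Dna(_random_dna(rng, int(rng.integers(lo, hi + 1)),
                            cfg.gc_content))


# -- the generator ---------------------------------------------------------


def _check_feasible(cfg: SimConfig):
    n_genes = cfg.n_chromosomes * cfg.genes_per_chromosome
    n_events = (cfg.n_deletions + cfg.n_hidden_intact_copies
                + cfg.n_relocated_intact_copies
                + cfg.n_inversions * 7 + cfg.n_translocations * 6)
    if cfg.genes_per_chromosome < 20 and (cfg.n_inversions
                                          or cfg.n_translocations):
        raise ValueError("rearrangements need >= 20 genes per chromosome")
    if n_events + sum(cfg.n_pseudogenes_per_class) > n_genes // 2:
        raise ValueError(
            f"configured events ({n_events} gene slots + "
            f"{sum(cfg.n_pseudogenes_per_class)} implants) exceed half the "
            f"gene total ({n_genes})")


def simulate_genome_pair(config: SimConfig):
    """Generate (bundle_a, bundle_b, truth) for a configured genome pair."""
    cfg = config
    _check_feasible(cfg)
    rng = np.random.default_rng(cfg.seed)
    chrom_names = [f"chr{c + 1}" for c in range(cfg.n_chromosomes)]

    # 1. ancestral gene table + per-genome realizations -------------------
    elements_a, elements_b = {}, {}
    gene_pos: dict = {}          # gene index -> (chrom, position-in-order)
    realized_identities = []
    gidx = 0
    for chrom in chrom_names:
        ea, eb = [_spacer(rng, cfg)], [_spacer(rng, cfg)]
        for _ in range(cfg.genes_per_chromosome):
            L = max(60, int(round(rng.normal(cfg.mean_protein_length,
                                             0.25 * cfg.mean_protein_length))))
            prot_a = _random_protein(rng, L)
            n_sub = int(round((1 - cfg.target_protein_identity) * L))
            prot_b = _mutate_protein(rng, prot_a, n_sub)
            realized_identities.append(
                sum(x == y for x, y in zip(prot_a, prot_b)) / L)
            n_ex = int(rng.integers(cfg.n_exons_range[0],
                                    cfg.n_exons_range[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            cds_a = _backtranslate(rng, prot_a)
            cds_b = _backtranslate(rng, prot_b)
            exon_lens = _split_cds(rng, len(cds_a), n_ex, cfg.min_exon_nt)
            pieces_a = _gene_pieces(rng, cds_a, exon_lens, strand,
                                    cfg.intron_length_range, cfg.gc_content)
            pieces_b = _gene_pieces(rng, cds_b, exon_lens, strand,
                                    cfg.intron_length_range, cfg.gc_content)
            ea.append(_Gene(f"ga{gidx:05d}", strand, pieces_a, prot_a))
            eb.append(_Gene(f"gb{gidx:05d}", strand, pieces_b, prot_b))
            ea.append(_spacer(rng, cfg))
            eb.append(_spacer(rng, cfg))
            gene_pos[gidx] = (chrom, len(eb) - 2)
            gidx += 1
        elements_a[chrom], elements_b[chrom] = ea, eb
    n_genes = gidx
    mean_ident = float(np.mean(realized_identities))
    assert abs(mean_ident - cfg.target_protein_identity) <= 0.02, \
        f"realized identity {mean_ident:.3f} off target"

    truth = TruthTable()
    per_chrom = cfg.genes_per_chromosome
    used = set()                 # global gene indices consumed by events

    def reserve(idx, buffer=2):
        for k in range(idx - buffer, idx + buffer + 1):
            used.add(k)

    def chrom_of(idx):
        return idx // per_chrom

    # 2. choose inversion segments ---------------------------------------
    inversions = []              # (first_gene_idx, last_gene_idx)
    attempts = 0
    while len(inversions) < cfg.n_inversions:
        attempts += 1
        if attempts > 10000:
            raise ValueError("could not place inversions; config infeasible")
        # segments of 6-8 genes: long enough that, at the default chaining
        # gap (max_gap=2), a collinear chain cannot thread through the
        # inverted run and the segment resolves as its own inverted block
        seg_len = int(rng.integers(6, 9))
        start = int(rng.integers(0, n_genes - seg_len))
        if chrom_of(start) != chrom_of(start + seg_len - 1):
            continue
        local = start % per_chrom
        if local < 5 or local + seg_len > per_chrom - 5:
            continue
        if any(k in used for k in range(start - 4, start + seg_len + 4)):
            continue
        inversions.append((start, start + seg_len - 1))
        for k in range(start - 1, start + seg_len + 2):
            used.add(k)

    # 3. choose translocation segments -----------------------------------
    translocations = []          # (first, last, dest_chrom)
    attempts = 0
    while len(translocations) < cfg.n_translocations:
        attempts += 1
        if attempts > 10000:
            raise ValueError("could not place translocations")
        seg_len = int(rng.integers(3, 6))
        start = int(rng.integers(0, n_genes - seg_len))
        if chrom_of(start) != chrom_of(start + seg_len - 1):
            continue
        local = start % per_chrom
        if local < 5 or local + seg_len > per_chrom - 5:
            continue
        if any(k in used for k in range(start - 4, start + seg_len + 4)):
            continue
        dest = chrom_names[(chrom_of(start) + 1) % cfg.n_chromosomes]
        translocations.append((start, start + seg_len - 1, dest))
        for k in range(start - 1, start + seg_len + 2):
            used.add(k)

    def pick_isolated(n, require_multi_exon=False, buffer=2, margin=3):
        picked, tries = [], 0
        while len(picked) < n:
            tries += 1
            if tries > 100000:
                raise ValueError("could not place events; config infeasible")
            idx = int(rng.integers(0, n_genes))
            local = idx % per_chrom
            if local < margin or local >= per_chrom - margin:
                continue
            if idx in used:
                continue
            if require_multi_exon:
                chrom, pos = gene_pos[idx]
                if sum(1 for k, _ in elements_b[chrom][pos].pieces
                       if k == "exon") < 2:
                    continue
            picked.append(idx)
            reserve(idx, buffer)
        return picked

    # 4. deletions: one adjacent to each inversion flank, rest isolated ---
    # A deletion *at* an inversion boundary leaves its flanking anchors in
    # different blocks, where the A-B-C rule cannot see it; one gene further
    # out both anchors stay in the flanking collinear block while the rank
    # still touches the breakpoint window.
    deletion_sites = []
    n_sv = min(cfg.n_inversions, cfg.n_deletions)
    for (s, _e) in inversions[:n_sv]:
        deletion_sites.append((s - 2, True))
        reserve(s - 2, 2)
    for idx in pick_isolated(cfg.n_deletions - n_sv):
        deletion_sites.append((idx, False))

    hidden_sites = pick_isolated(cfg.n_hidden_intact_copies)
    relocated_sites = pick_isolated(cfg.n_relocated_intact_copies)

    # 5. pseudogene sources: untouched genes (DUP needs >= 2 exons) -------
    n_pssd, n_dup, n_frag = cfg.n_pseudogenes_per_class
    pssd_src = pick_isolated(n_pssd, buffer=0, margin=0)
    dup_src = pick_isolated(n_dup, require_multi_exon=True, buffer=0,
                            margin=0)
    frag_src = pick_isolated(n_frag, buffer=0, margin=0)

    # 6. apply gene-level events to B -------------------------------------
    def b_gene(idx):
        chrom, pos = gene_pos[idx]
        return elements_b[chrom][pos]

    for idx, sv_adjacent in deletion_sites:
        chrom, pos = gene_pos[idx]
        ev = TruthEvent("deletion", f"ga{idx:05d}",
                        details={"sv_adjacent": bool(sv_adjacent)})
        truth.events.append(ev)
        elements_b[chrom][pos] = _Mark(len(truth.events) - 1)

    for idx in hidden_sites:
        g = b_gene(idx)
        g.annotated = False
        truth.events.append(TruthEvent("hidden_copy", f"ga{idx:05d}"))
        g.truth_idx = len(truth.events) - 1

    # 7. pseudogene implants ----------------------------------------------
    implants = []                # (truth_idx, seq)
    decay = cfg.pseudogene_decay_rate

    def decay_seq(seq):
        nts = list(seq)
        n_sub = int(round(decay * len(nts)))
        if n_sub:
            for p in sorted(int(x) for x in
                            rng.choice(len(nts), size=n_sub, replace=False)):
                alt = [c for c in "ACGT" if c != nts[p]]
                nts[p] = alt[int(rng.integers(3))]
        return "".join(nts)

    def spliced_cds(idx):
        g = b_gene(idx)
        s = "".join(seq for k, seq in g.pieces if k == "exon")
        return revcomp(s) if g.strand == "-" else s

    for idx in pssd_src:
        cds = spliced_cds(idx)
        n_aa = len(cds) // 3 - 1
        frac = float(rng.uniform(0.71, 0.95))
        keep = int(round(frac * n_aa))
        seq = decay_seq(cds[3 * (n_aa - keep):])   # 3'-biased retro copy
        truth.events.append(TruthEvent(
            "pseudogene_PSSD", f"ga{idx:05d}",
            details={"fraction_copied": round(keep / n_aa, 4),
                     "n_frameshifts": 0, "n_stops": 0}))
        implants.append((len(truth.events) - 1, seq))

    for idx in dup_src:
        g = b_gene(idx)
        pieces = [(k, decay_seq(s) if k == "exon" else s)
                  for k, s in g.pieces]
        # coding frame bookkeeping in genomic order (left-to-right for '+',
        # right-to-left for '-'): apply disablements within exon interiors
        order = range(len(pieces)) if g.strand == "+" else \
            range(len(pieces) - 1, -1, -1)
        exon_order = [i for i in order if pieces[i][0] == "exon"]
        n_fs = int(rng.integers(0, 2))
        n_stop = int(rng.integers(0 if n_fs else 1, 3))
        done_fs = done_stop = 0
        coding_before = {}
        acc = 0
        for i in exon_order:
            coding_before[i] = acc
            acc += len(pieces[i][1])
        for _ in range(n_fs):
            i = exon_order[int(rng.integers(len(exon_order)))]
            seq = pieces[i][1]
            if len(seq) < 50:
                continue
            p = int(rng.integers(20, len(seq) - 20))
            pieces[i] = ("exon", seq[:p] + seq[p + 1:])
            done_fs += 1
        for _ in range(n_stop):
            i = exon_order[int(rng.integers(len(exon_order)))]
            seq = pieces[i][1]
            off = coding_before[i]
            # codon-aligned position in CDS coordinates, inside this exon
            lo = (off + 21) // 3
            hi = (off + len(seq) - 21) // 3
            if hi <= lo:
                continue
            cpos = int(rng.integers(lo, hi)) * 3 - off
            if g.strand == "+":
                pieces[i] = ("exon", seq[:cpos] + "TAA" + seq[cpos + 3:])
            else:
                rseq = revcomp(seq)
                rseq = rseq[:cpos] + "TAA" + rseq[cpos + 3:]
                pieces[i] = ("exon", revcomp(rseq))
            done_stop += 1
        if done_fs + done_stop == 0:   # guarantee one disablement
            i = exon_order[0]
            seq = pieces[i][1]
            p = max(1, len(seq) // 2)
            pieces[i] = ("exon", seq[:p] + seq[p + 1:])
            done_fs = 1
        seq = "".join(s for _, s in pieces)
        truth.events.append(TruthEvent(
            "pseudogene_DUP", f"ga{idx:05d}",
            details={"fraction_copied": 1.0, "n_frameshifts": done_fs,
                     "n_stops": done_stop}))
        implants.append((len(truth.events) - 1, seq))

    for idx in frag_src:
        cds = spliced_cds(idx)
        n_aa = len(cds) // 3 - 1
        frac = float(rng.uniform(0.2, 0.6))
        keep = max(20, int(round(frac * n_aa)))
        start_aa = int(rng.integers(0, n_aa - keep + 1))
        seq = decay_seq(cds[3 * start_aa:3 * (start_aa + keep)])
        truth.events.append(TruthEvent(
            "pseudogene_FRAG", f"ga{idx:05d}",
            details={"fraction_copied": round(keep / n_aa, 4),
                     "n_frameshifts": 0, "n_stops": 0}))
        implants.append((len(truth.events) - 1, seq))

    # relocated intact copies: delete at origin, intact copy elsewhere ----
    for idx in relocated_sites:
        chrom, pos = gene_pos[idx]
        g = elements_b[chrom][pos]
        truth.events.append(TruthEvent(
            "deletion", f"ga{idx:05d}",
            details={"sv_adjacent": False, "relocated": True}))
        tix = len(truth.events) - 1
        elements_b[chrom][pos] = _Mark(tix)
        implants.append((tix, g.seq))

    # place implants into sufficiently long spacers, >= 500 nt from genes -
    margin = 500
    spacer_slots = []
    for chrom in chrom_names:
        for pos, el in enumerate(elements_b[chrom]):
            if isinstance(el, _Dna) and el.truth_idx is None:
                spacer_slots.append((chrom, pos))
    order = rng.permutation(len(spacer_slots))
    slot_iter = iter(int(i) for i in order)
    placements = {}
    for tix, seq in implants:
        placed = False
        for si in slot_iter:
            chrom, pos = spacer_slots[si]
            spacer = elements_b[chrom][pos]
            room = len(spacer.seq) - 2 * margin - len(seq)
            if room < 0 or pos in placements.get(chrom, set()):
                continue
            at = margin + int(rng.integers(room + 1))
            flip = rng.random() < 0.5
            placements.setdefault(chrom, set()).add(pos)
            ins = revcomp(seq) if flip else seq
            elements_b[chrom][pos] = [
                _Dna(spacer.seq[:at]),
                _Dna(ins, truth_idx=tix),
                _Dna(spacer.seq[at:]),
            ]
            truth.events[tix].details["strand"] = "-" if flip else "+"
            placed = True
            break
        if not placed:
            raise ValueError("no spacer long enough for an implant; "
                             "increase intergenic lengths")

    # flatten nested placements
    for chrom in chrom_names:
        flat = []
        for el in elements_b[chrom]:
            if isinstance(el, list):
                flat.extend(el)
            else:
                flat.append(el)
        elements_b[chrom] = flat

    # 8. structural rearrangements ---------------------------------------
    def element_span(chrom, first_idx, last_idx):
        """Element positions spanning genes first..last inclusive."""
        els = elements_b[chrom]
        pi = [i for i, el in enumerate(els)
              if isinstance(el, _Gene)
              and el.gene_id in {f"gb{k:05d}"
                                 for k in range(first_idx, last_idx + 1)}]
        return min(pi), max(pi)

    for (first, last) in inversions:
        chrom, _ = gene_pos[first]
        lo, hi = element_span(chrom, first, last)
        seg = elements_b[chrom][lo:hi + 1]
        for el in seg:
            if isinstance(el, _Gene):
                el.invert()
            elif isinstance(el, _Dna):
                el.seq = revcomp(el.seq)
        elements_b[chrom][lo:hi + 1] = seg[::-1]
        truth.events.append(TruthEvent(
            "inversion", f"ga{first:05d}", chrom=chrom,
            details={"genes": [f"ga{k:05d}" for k in range(first, last + 1)]}))

    for (first, last, dest) in translocations:
        chrom, _ = gene_pos[first]
        lo, hi = element_span(chrom, first, last)
        seg = elements_b[chrom][lo:hi + 1]
        del elements_b[chrom][lo:hi + 1]
        # insert after a spacer boundary in the middle of the destination
        dels = elements_b[dest]
        spacers = [i for i, el in enumerate(dels) if isinstance(el, _Dna)]
        at = spacers[len(spacers) // 2]
        elements_b[dest][at + 1:at + 1] = seg
        truth.events.append(TruthEvent(
            "translocation", f"ga{first:05d}",
            details={"genes": [f"ga{k:05d}" for k in range(first, last + 1)],
                     "dest_chrom": dest}))

    # 9. assemble bundles --------------------------------------------------
    bundle_a = _assemble("A", chrom_names, elements_a, None)
    bundle_b = _assemble("B", chrom_names, elements_b, truth)

    # 10. TE intervals ------------------------------------------------------
    for bundle in (bundle_a, bundle_b):
        te = []
        for chrom in chrom_names:
            clen = len(bundle.chromosomes[chrom])
            n_te = int(round(clen / 1e5 * cfg.te_density))
            for _ in range(n_te):
                tlen = int(rng.integers(200, 3001))
                if clen <= tlen:
                    continue
                s = int(rng.integers(0, clen - tlen))
                te.append((chrom, s, s + tlen))
        bundle.te_intervals = sorted(te)
        bundle.validate()
    return bundle_a, bundle_b, truth


def _assemble(genome_id, chrom_names, elements, truth):
    chroms, genes = {}, {}
    for chrom in chrom_names:
        parts, models, pos = [], [], 0
        for el in elements[chrom]:
            seq = el.seq
            if isinstance(el, _Gene) and el.annotated:
                exons, off = [], pos
                for kind, s in el.pieces:
                    if kind == "exon":
                        exons.append((off, off + len(s)))
                    off += len(s)
                models.append(GeneModel(
                    gene_id=el.gene_id, chrom=chrom, start=pos,
                    end=pos + len(seq), strand=el.strand,
                    exons=tuple(exons), protein=el.protein))
            tix = getattr(el, "truth_idx", None)
            if truth is not None and tix is not None:
                ev = truth.events[tix]
                if ev.start < 0:
                    ev.chrom, ev.start, ev.end = chrom, pos, pos + len(seq)
                else:  # extend (multi-element events)
                    ev.end = pos + len(seq)
            parts.append(seq)
            pos += len(seq)
        chroms[chrom] = "".join(parts)
        genes[chrom] = models
    return GenomeBundle(genome_id=genome_id, chromosomes=chroms, genes=genes)


# -- evaluation ------------------------------------------------------------


def evaluate_calls(truth: TruthTable, loss_candidates, pseudo_calls) -> dict:
    """Score pipeline calls against the simulator's ground truth.

    Loss candidates are matched to deletion / hidden-copy events by source
    gene id; pseudogene calls are matched to implant loci by >= 1 bp
    overlap.  Precision is None (undefined) when nothing was called.
    """
    report = {}

    deletions = truth.of_kind("deletion")
    del_ids = {e.source_gene for e in deletions}
    called_lost = [c for c in loss_candidates
                   if c.status in ("confirmed_lost", "sv_associated")]
    matched = {c.missing_gene for c in called_lost} & del_ids
    sv_truth = [e for e in deletions if e.details.get("sv_adjacent")]
    sv_tagged = sum(
        1 for e in sv_truth
        if any(c.missing_gene == e.source_gene and c.status == "sv_associated"
               for c in loss_candidates))
    report["deletion"] = {
        "n_truth": len(deletions),
        "n_called": len(called_lost),
        "recall": len(matched) / len(deletions) if deletions else None,
        "precision": (len(matched) / len(called_lost)
                      if called_lost else None),
        "sv_adjacent_total": len(sv_truth),
        "sv_tagged": sv_tagged,
    }

    hidden = truth.of_kind("hidden_copy")
    hidden_ids = {e.source_gene for e in hidden}
    rejected = {c.missing_gene for c in loss_candidates
                if c.status == "false_positive"} & hidden_ids
    wrongly_confirmed = {c.missing_gene for c in called_lost} & hidden_ids
    report["hidden_copy"] = {
        "n_truth": len(hidden),
        "n_rejected": len(rejected),
        "n_wrongly_confirmed": len(wrongly_confirmed),
        "rejection_rate": (len(rejected) / len(hidden)) if hidden else None,
    }

    implants = truth.of_kind("pseudogene_PSSD", "pseudogene_DUP",
                             "pseudogene_FRAG")
    confusion: dict = {}
    n_matched = n_class_ok = 0
    matched_calls = set()
    for ev in implants:
        klass_true = ev.kind.split("_")[1]
        best = None
        for ci, call in enumerate(pseudo_calls):
            if call.chrom != ev.chrom:
                continue
            ov = min(call.end, ev.end) - max(call.start, ev.start)
            if ov >= 1 and (best is None or ov > best[0]):
                best = (ov, ci)
        row = confusion.setdefault(klass_true, {})
        if best is None:
            row["MISSED"] = row.get("MISSED", 0) + 1
            continue
        n_matched += 1
        matched_calls.add(best[1])
        klass_called = pseudo_calls[best[1]].klass
        row[klass_called] = row.get(klass_called, 0) + 1
        if klass_called == klass_true:
            n_class_ok += 1
    report["pseudogene"] = {
        "n_truth": len(implants),
        "n_called": len(pseudo_calls),
        "locus_recall": (n_matched / len(implants)) if implants else None,
        "precision": (len(matched_calls) / len(pseudo_calls)
                      if pseudo_calls else None),
        "class_accuracy": (n_class_ok / n_matched) if n_matched else None,
        "confusion": confusion,
    }
    return report


# -- focused statistical worlds -------------------------------------------


def simulate_codon_pairs(n_pairs: int, n_codons: int, transversion_rate: float,
                         seed: int = 1):
    """Codon-pair alignments whose only substitutions are third-position
    transversions at fourfold-degenerate sites, at the given rate."""
    from .evostats import CodonPairAlignment, FOURFOLD_PREFIXES

    rng = np.random.default_rng(seed)
    prefixes = sorted(FOURFOLD_PREFIXES)
    tv_partner = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
    out = []
    for k in range(n_pairs):
        cols = []
        for _ in range(n_codons):
            pre = prefixes[int(rng.integers(len(prefixes)))]
            third = "ACGT"[int(rng.integers(4))]
            ca = pre + third
            if rng.random() < transversion_rate:
                cb = pre + tv_partner[third][int(rng.integers(2))]
            else:
                cb = ca
            cols.append((ca, cb))
        out.append(CodonPairAlignment(f"pa{k:04d}", f"pb{k:04d}",
                                      tuple(cols)))
    return out


def simulate_te_layout(n_per_class: int = 50, genome_length: int = 1_000_000,
                       n_te: int = 60, effect: bool = True, seed: int = 1,
                       near_gap_range: tuple = (0, 100)):
    """A planted TE-proximity world on one chromosome.

    With ``effect=True`` the ``functional`` class is placed next to a
    random TE (edge gap uniform in ``near_gap_range``) while ``pseudogene``
    and ``sv`` loci are uniform; with ``effect=False`` all three classes
    are uniform (the null).  The default density (60 elements of 0.2-3 kb
    on 1 Mb, ~10% coverage) leaves uniformly placed loci kilobases from
    the nearest element, so planted adjacency is a real contrast.
    Returns (genes_by_class, te_intervals).
    """
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    te = []
    for _ in range(n_te):
        tlen = int(rng.integers(200, 3001))
        s = int(rng.integers(0, genome_length - tlen))
        te.append((chrom, s, s + tlen))
    te.sort()

    def uniform_locus():
        L = 1000
        s = int(rng.integers(0, genome_length - L))
        return (chrom, s, s + L)

    genes_by_class = {}
    for klass in ("functional", "pseudogene", "sv"):
        loci = []
        for _ in range(n_per_class):
            if effect and klass == "functional":
                _, ts, te_end = te[int(rng.integers(len(te)))]
                gap = int(rng.integers(near_gap_range[0],
                                       near_gap_range[1] + 1))
                s = te_end + gap
                loci.append((chrom, s, s + 1000))
            else:
                loci.append(uniform_locus())
        genes_by_class[klass] = loci
    return genes_by_class, te
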