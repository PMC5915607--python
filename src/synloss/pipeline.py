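"""Staged pipeline runner with flat-file interchange and a run manifest.

Each stage reads its inputs from the run directory, computes, and writes
TSV/GFF3/JSON outputs there; no stage mutates another stage's files, so
reruns are idempotent and two runs from the same manifest are
byte-identical (nothing is timestamped).  The stages chain the full
workflow: simulate -> homology -> synteny -> losses -> pseudo -> stats ->
evaluate.  Use :func:`run_all` for the whole chain or the ``run_*``
functions individually; every parameter lands in ``manifest.json``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

from . import __version__
from .genomeio import read_genome_bundle, write_genome_bundle
from .homology import OrthologPair, all_vs_all_hits, filter_hits, \
    reciprocal_best_hits
from .synteny import Breakpoint, SyntenyBlock, build_microsynteny, \
    find_breakpoints
from .lossfinder import repredict_all, recovery_check, tag_sv_losses, \
    trace_deletions
from .pseudogenes import scan_intergenic, write_pseudogene_gff3
from .evostats import fourdtv_distribution, te_proximity
from .simulate import SimConfig, evaluate_calls, read_truth_table, \
    simulate_genome_pair, write_truth_table

__all__ = ["RunConfig", "run_all", "run_simulate", "run_homology",
           "run_synteny", "run_losses", "run_pseudo", "run_stats",
           "run_evaluate"]

STAGES = ("simulate", "homology", "synteny", "losses", "pseudo", "stats",
          "evaluate")


@dataclass
class RunConfig:
    """Every tunable of the whole workflow, serialized into the manifest."""

    sim: SimConfig = field(default_factory=SimConfig)
    min_identity: float = 0.30
    min_coverage: float = 0.30
    min_block_pairs: int = 3
    max_gap: int = 2
    max_run: int = 3
    interval_padding: int = 2000
    sv_window_genes: int = 1
    pseudo_min_score: int = 60
    fourdtv_bin_width: float = 0.01

    def to_dict(self):
        d = asdict(self)
        return d


def _log(run_dir, message):
    with open(os.path.join(run_dir, "run.log"), "a") as fh:
        fh.write(message + "\n")


def _json_dump(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _bundle_paths(run_dir, which):
    d = os.path.join(run_dir, "sim")
    return dict(fasta_path=os.path.join(d, f"{which}.fa"),
                gff3_path=os.path.join(d, f"{which}.gff3"),
                protein_fasta=os.path.join(d, f"{which}.proteins.fa"),
                te_path=os.path.join(d, f"{which}.te.bed"))


def _load_bundles(run_dir):
    a = read_genome_bundle(**_bundle_paths(run_dir, "A"), genome_id="A")
    b = read_genome_bundle(**_bundle_paths(run_dir, "B"), genome_id="B")
    return a, b


# -- stages ----------------------------------------------------------------


def run_simulate(config: RunConfig, run_dir: str):
    os.makedirs(os.path.join(run_dir, "sim"), exist_ok=True)
    bundle_a, bundle_b, truth = simulate_genome_pair(config.sim)
    write_genome_bundle(bundle_a, os.path.join(run_dir, "sim"))
    write_genome_bundle(bundle_b, os.path.join(run_dir, "sim"))
    write_truth_table(truth, os.path.join(run_dir, "sim", "truth.tsv"))
    _log(run_dir, f"simulate: {bundle_a.n_genes} genes in A, "
         f"{bundle_b.n_genes} in B, {len(truth.events)} truth events")
    return bundle_a, bundle_b, truth


def run_homology(config: RunConfig, run_dir: str):
    a, b = _load_bundles(run_dir)
    hits_ab, hits_ba = all_vs_all_hits(a.proteins(), b.proteins())
    kw = dict(min_identity=config.min_identity,
              min_coverage=config.min_coverage)
    pairs = reciprocal_best_hits(filter_hits(hits_ab, **kw),
                                 filter_hits(hits_ba, **kw))
    with open(os.path.join(run_dir, "orthologs.tsv"), "w") as fh:
        fh.write("gene_a\tgene_b\tscore\n")
        for p in pairs:
            fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.score:g}\n")
    _log(run_dir, f"homology: {len(hits_ab)} hits, {len(pairs)} RBH pairs")
    return pairs


def _load_pairs(run_dir):
    pairs = []
    with open(os.path.join(run_dir, "orthologs.tsv")) as fh:
        next(fh)
        for line in fh:
            ga, gb, score = line.rstrip("\n").split("\t")
            pairs.append(OrthologPair(ga, gb, float(score)))
    return pairs


def run_synteny(config: RunConfig, run_dir: str):
    a, b = _load_bundles(run_dir)
    pairs = _load_pairs(run_dir)
    blocks = build_microsynteny(pairs, a, b,
                                min_block_pairs=config.min_block_pairs,
                                max_gap=config.max_gap)
    breakpoints = find_breakpoints(blocks, a, b, max_gap=config.max_gap)
    with open(os.path.join(run_dir, "blocks.tsv"), "w") as fh:
        fh.write("block_id\tgene_a\tgene_b\trank_a\trank_b\tchrom_a\t"
                 "chrom_b\torientation\n")
        for blk in blocks:
            for p, ra, rb in zip(blk.pairs, blk.ranks_a, blk.ranks_b):
                fh.write(f"{blk.block_id}\t{p.gene_a}\t{p.gene_b}\t{ra}\t"
                         f"{rb}\t{blk.chrom_a}\t{blk.chrom_b}\t"
                         f"{blk.orientation}\n")
    with open(os.path.join(run_dir, "breakpoints.tsv"), "w") as fh:
        fh.write("chrom_a\ta_left\ta_right\tchrom_b\tb_left\tb_right\t"
                 "kind\n")
        for bp in breakpoints:
            fh.write(f"{bp.chrom_a}\t{bp.interval_a[0]}\t{bp.interval_a[1]}"
                     f"\t{bp.chrom_b}\t{bp.interval_b[0]}\t"
                     f"{bp.interval_b[1]}\t{bp.kind}\n")
    _log(run_dir, f"synteny: {len(blocks)} blocks, "
         f"{len(breakpoints)} breakpoints")
    return blocks, breakpoints


def _load_blocks(run_dir):
    rows: dict = {}
    with open(os.path.join(run_dir, "blocks.tsv")) as fh:
        next(fh)
        for line in fh:
            (bid, ga, gb, ra, rb, ca, cb, orient) = \
                line.rstrip("\n").split("\t")
            rows.setdefault(bid, []).append(
                (OrthologPair(ga, gb, 0.0), int(ra), int(rb), ca, cb,
                 orient))
    blocks = []
    for bid in sorted(rows):
        anchors = rows[bid]
        ranks_a = tuple(r[1] for r in anchors)
        ranks_b = tuple(r[2] for r in anchors)
        blocks.append(SyntenyBlock(
            block_id=bid, pairs=[r[0] for r in anchors],
            chrom_a=anchors[0][3], chrom_b=anchors[0][4],
            orientation=anchors[0][5],
            span_a=(min(ranks_a), max(ranks_a)),
            span_b=(min(ranks_b), max(ranks_b)),
            ranks_a=ranks_a, ranks_b=ranks_b))
    blocks.sort(key=lambda blk: (blk.chrom_a, blk.span_a))
    return blocks


def _load_breakpoints(run_dir):
    out = []
    with open(os.path.join(run_dir, "breakpoints.tsv")) as fh:
        next(fh)
        for line in fh:
            ca, al, ar, cb, bl, br, kind = line.rstrip("\n").split("\t")
            out.append(Breakpoint(ca, (int(al), int(ar)), cb,
                                  (int(bl), int(br)), kind))
    return out


def run_losses(config: RunConfig, run_dir: str):
    a, b = _load_bundles(run_dir)
    blocks = _load_blocks(run_dir)
    breakpoints = _load_breakpoints(run_dir)
    cands = trace_deletions(blocks, a, b, max_run=config.max_run)
    repredict_all(cands, a, b, padding=config.interval_padding)
    tag_sv_losses(cands, breakpoints, window_genes=config.sv_window_genes)
    confirmed = [c for c in cands
                 if c.status in ("confirmed_lost", "sv_associated")]
    losses_b = [c for c in confirmed if c.genome_with_gene == "a"]
    losses_a = [c for c in confirmed if c.genome_with_gene == "b"]
    recovery = {}
    if losses_b:
        recovery["lost_in_B"] = recovery_check(losses_b, b, a)
    if losses_a:
        recovery["lost_in_A"] = recovery_check(losses_a, a, b)

    with open(os.path.join(run_dir, "losses.tsv"), "w") as fh:
        fh.write("missing_gene\tgenome_with_gene\tmissing_chrom\t"
                 "missing_rank\tanchor_left\tanchor_right\ttarget_chrom\t"
                 "target_start\ttarget_end\tstatus\tcoverage\t"
                 "n_frameshift\tn_stop\n")
        for c in cands:
            ev = c.evidence
            fh.write(
                f"{c.missing_gene}\t{c.genome_with_gene}\t"
                f"{c.missing_chrom}\t{c.missing_rank}\t"
                f"{c.anchor_left.gene_a}|{c.anchor_left.gene_b}\t"
                f"{c.anchor_right.gene_a}|{c.anchor_right.gene_b}\t"
                f"{c.target_interval[0]}\t{c.target_interval[1]}\t"
                f"{c.target_interval[2]}\t{c.status}\t"
                f"{ev.get('coverage', 0.0):.4f}\t"
                f"{ev.get('frameshifts', 0)}\t"
                f"{ev.get('premature_stops', 0)}\n")
    summary = {
        "n_candidates": len(cands),
        "n_confirmed_lost": sum(1 for c in cands
                                if c.status == "confirmed_lost"),
        "n_sv_associated": sum(1 for c in cands
                               if c.status == "sv_associated"),
        "n_false_positive": sum(1 for c in cands
                                if c.status == "false_positive"),
        "recovery_fraction": recovery,
    }
    _json_dump(summary, os.path.join(run_dir, "loss_summary.json"))
    _log(run_dir, f"losses: {summary['n_candidates']} candidates, "
         f"{summary['n_confirmed_lost']} confirmed, "
         f"{summary['n_sv_associated']} SV-associated, "
         f"{summary['n_false_positive']} false positives")
    return cands, summary


def run_pseudo(config: RunConfig, run_dir: str):
    a, b = _load_bundles(run_dir)
    calls = scan_intergenic(b, a.proteins(),
                            min_score=config.pseudo_min_score)
    write_pseudogene_gff3(calls, os.path.join(run_dir, "pseudogenes.gff3"))
    with open(os.path.join(run_dir, "pseudogene_metrics.tsv"), "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\tseed\tclass\tidentity\t"
                 "align_ratio\texon_number\tmatch_length_aa\tdisablement\t"
                 "high_confidence\tscore\n")
        for c in calls:
            m = c.metrics
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.strand}\t"
                     f"{c.seed_id}\t{c.klass}\t{m.identity:.4f}\t"
                     f"{m.align_ratio:.4f}\t{m.exon_number}\t"
                     f"{m.match_length_aa}\t{int(m.has_disablement)}\t"
                     f"{int(c.high_confidence)}\t{c.score}\n")
    _log(run_dir, f"pseudo: {len(calls)} calls "
         f"({sum(1 for c in calls if c.high_confidence)} high-confidence)")
    return calls


def run_stats(config: RunConfig, run_dir: str):
    a, b = _load_bundles(run_dir)
    blocks = _load_blocks(run_dir)
    records, hist = fourdtv_distribution(
        blocks, a, b, bin_width=config.fourdtv_bin_width)
    with open(os.path.join(run_dir, "fourdtv.tsv"), "w") as fh:
        fh.write("gene_a\tgene_b\tfourdtv\n")
        for ga, gb, v in records:
            fh.write(f"{ga}\t{gb}\t{'NA' if v is None else f'{v:.6f}'}\n")
    with open(os.path.join(run_dir, "fourdtv_hist.tsv"), "w") as fh:
        fh.write("bin_start\tcount\n")
        for start, count in hist:
            fh.write(f"{start:.2f}\t{count}\n")

    classes = {"functional": [(g.chrom, g.start, g.end)
                              for g in b.all_genes()]}
    pseudo_loci, sv_loci = [], []
    path = os.path.join(run_dir, "pseudogene_metrics.tsv")
    if os.path.exists(path):
        with open(path) as fh:
            next(fh)
            for line in fh:
                f = line.split("\t")
                pseudo_loci.append((f[0], int(f[1]), int(f[2])))
    losses_path = os.path.join(run_dir, "losses.tsv")
    if os.path.exists(losses_path):
        with open(losses_path) as fh:
            next(fh)
            for line in fh:
                f = line.rstrip("\n").split("\t")
                if f[9] == "sv_associated" and f[1] == "a":
                    sv_loci.append((f[6], int(f[7]), int(f[8])))
    if pseudo_loci:
        classes["pseudogene"] = pseudo_loci
    if sv_loci:
        classes["sv"] = sv_loci
    distances, pvalues = te_proximity(classes, b.te_intervals)
    with open(os.path.join(run_dir, "te_distances.tsv"), "w") as fh:
        fh.write("class\tdistance\n")
        for klass in sorted(distances):
            for d in distances[klass]:
                fh.write(f"{klass}\t{d}\n")
    _json_dump({f"{x}_vs_{y}": p for (x, y), p in pvalues.items()},
               os.path.join(run_dir, "te_tests.json"))
    _log(run_dir, f"stats: {len(records)} 4DTv pairs, TE classes "
         f"{sorted(distances)}")
    return records, distances, pvalues


class _CallRow:
    """Pseudogene call as reloaded from the metrics table."""

    def __init__(self, chrom, start, end, klass):
        self.chrom, self.start, self.end, self.klass = chrom, start, end, \
            klass


class _LossRow:
    def __init__(self, missing_gene, status):
        self.missing_gene, self.status = missing_gene, status


def run_evaluate(config: RunConfig, run_dir: str):
    truth = read_truth_table(os.path.join(run_dir, "sim", "truth.tsv"))
    cands = []
    with open(os.path.join(run_dir, "losses.tsv")) as fh:
        next(fh)
        for line in fh:
            f = line.rstrip("\n").split("\t")
            cands.append(_LossRow(f[0], f[9]))
    calls = []
    with open(os.path.join(run_dir, "pseudogene_metrics.tsv")) as fh:
        next(fh)
        for line in fh:
            f = line.rstrip("\n").split("\t")
            calls.append(_CallRow(f[0], int(f[1]), int(f[2]), f[5]))
    report = evaluate_calls(truth, cands, calls)
    _json_dump(report, os.path.join(run_dir, "evaluation.json"))
    _log(run_dir, "evaluate: report written")
    return report


def run_all(config: RunConfig, run_dir: str) -> dict:
    """Run the full workflow into ``run_dir``; returns the evaluation.

    Writes ``manifest.json`` (all parameters, package version, stage list)
    first, then executes every stage in order.
    """
    os.makedirs(run_dir, exist_ok=True)
    log_path = os.path.join(run_dir, "run.log")
    if os.path.exists(log_path):
        os.remove(log_path)
    _json_dump({"package": "synloss", "version": __version__,
                "stages": list(STAGES), "config": config.to_dict()},
               os.path.join(run_dir, "manifest.json"))
    run_simulate(config, run_dir)
    run_homology(config, run_dir)
    run_synteny(config, run_dir)
    run_losses(config, run_dir)
    run_pseudo(config, run_dir)
    run_stats(config, run_dir)
    return run_evaluate(config, run_dir)
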