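"""Trace gene deletions with the flanking-gene rule and filter false
positives by re-prediction.

If orthologs of A and C are adjacent in genome B but separated by gene B
in genome A, B is a candidate loss in genome B.  The intergenic interval
between A' and C' is then re-examined with a spliced protein-to-DNA
alignment of B's protein: coverage > 70% with no frameshift and no
premature stop means the gene is actually there (annotation failure), and
the event is discarded as a false positive.
"""

import collections

from synloss import (SimConfig, all_vs_all_hits, build_microsynteny,
                     filter_hits, find_breakpoints, recovery_check,
                     reciprocal_best_hits, repredict_all, simulate_genome_pair,
                     tag_sv_losses, trace_deletions)

bundle_a, bundle_b, truth = simulate_genome_pair(SimConfig(seed=1))
hits_ab, hits_ba = all_vs_all_hits(bundle_a.proteins(), bundle_b.proteins())
pairs = reciprocal_best_hits(filter_hits(hits_ab), filter_hits(hits_ba))
blocks = build_microsynteny(pairs, bundle_a, bundle_b)
breakpoints = find_breakpoints(blocks, bundle_a, bundle_b)

candidates = trace_deletions(blocks, bundle_a, bundle_b)
print(f"{len(candidates)} loss candidates from the A-B-C rule")

repredict_all(candidates, bundle_a, bundle_b)
tag_sv_losses(candidates, breakpoints)
status = collections.Counter(c.status for c in candidates)
print("after re-prediction filter and SV tagging:", dict(sorted(status.items())))
# false_positive = hidden intact copies the filter caught;
# sv_associated  = losses sitting next to an inversion breakpoint

confirmed = [c for c in candidates
             if c.status in ("confirmed_lost", "sv_associated")]
frac = recovery_check(confirmed, bundle_b, bundle_a)
print(f"genome-wide recovery of confirmed losses: {frac:.2f} "
      "(0.0 = the sequences are truly gone, not mis-annotated)")
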