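"""Simulate a pair of diverged annotated genomes with known ground truth.

Genome A keeps every ancestral gene; genome B carries deletions, hidden
(unannotated but intact) gene copies, decayed pseudogene implants of three
classes, and inversions.  The truth table records every event.
"""

import collections

from synloss import SimConfig, simulate_genome_pair

config = SimConfig(seed=1)
bundle_a, bundle_b, truth = simulate_genome_pair(config)

print(f"genome A: {bundle_a.n_genes} annotated genes on "
      f"{len(bundle_a.chromosomes)} chromosomes "
      f"({sum(map(len, bundle_a.chromosomes.values())):,} bp)")
print(f"genome B: {bundle_b.n_genes} annotated genes "
      f"({sum(map(len, bundle_b.chromosomes.values())):,} bp)")

counts = collections.Counter(e.kind for e in truth.events)
print("implanted events:", dict(sorted(counts.items())))
# Genome B has fewer annotated genes than A by exactly the number of
# deletions plus hidden copies (whose sequence remains, unannotated).
missing = bundle_a.n_genes - bundle_b.n_genes
print(f"A - B annotated gene difference: {missing} "
      f"(= {counts['deletion']} deletions + "
      f"{counts['hidden_copy']} hidden copies)")
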