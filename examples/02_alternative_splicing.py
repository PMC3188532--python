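"""Classify alternative-splicing events from junction reads.

Junctions come from the block gaps of spliced alignments; a junction is
kept only with >= 2 unambiguous reads and >= 5 aligned bases on both
sides.  Validated junctions (plus coverage, for intron retention) are
classified against the annotation into the four analyzed models: exon
skipping (ES), intron retention (IR), alternative 5'/3' splice site
(A5SS/A3SS).
"""
from collections import Counter

import tarscribe as ts

cfg = ts.SimulationConfig(seed=1)
annotation, truth = ts.generate_annotation(cfg)
alignments = ts.simulate_alignments(annotation, truth, cfg)
coverage = ts.compute_coverage(alignments, cfg.chrom_sizes)

junctions = ts.extract_junctions(alignments)
valid = ts.validate_junctions(junctions, min_reads=2, min_overhang=5)
events, outside = ts.classify_events(valid, annotation, coverage)

print(f"junctions: {len(junctions)} raw, {len(valid)} validated, {len(outside)} outside genes")
print("events by type:", dict(Counter(e.type for e in events)))
planted = truth.as_event_keys()
print(f"planted events recovered: {len(planted & {e.key for e in events})}/{len(planted)}")

# Pooling across samples removes redundancy, as when merging tissues:
pooled, per_gene, multiplicity = ts.pool_events([events, events])
print(f"pooled (2 identical samples): {len(pooled)} distinct events; "
      f"genes with >1 event: {sum(v for k, v in multiplicity.items() if k > 1)}")
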