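"""Protein characterization and histidine-box scanning.

Computes length / molecular weight / isoelectric point for a simulated
desaturase and scans it with the packaged degenerate H-box patterns.
Membrane desaturases carry three boxes, soluble FAB2-type two; a product
missing its final box is flagged as truncated.
"""
from famsurvey import features
from famsurvey.simulate import simulate_proteins_with_boxes

records, truth = simulate_proteins_with_boxes("FAD2", n=1, length=250, seed=4)
pid, seq = records[0]

stats = features.protein_stats(seq)
print(f"{pid}: {stats.length} aa, "
      f"MW {stats.molecular_weight / 1000:.1f} kDa, pI {stats.isoelectric_point:.2f}")

patterns = features.subfamily_patterns("FAD2")
hits, complete = features.scan_hboxes(seq, patterns)
print(f"H-boxes found ({'complete' if complete else 'TRUNCATED'}):")
for h in hits:
    print(f"  {h.pattern:12s} at residue {h.start}: {h.match}")

# truncate before the last box: the completeness flag drops, the way a
# C-terminally truncated gene model is detected
last = max(s for _, s in truth[pid])
_, complete_short = features.scan_hboxes(seq[:last - 1], patterns)
print(f"after C-terminal truncation: complete = {complete_short}")
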