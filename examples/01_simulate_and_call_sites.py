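"""Simulate a quiescent-cell 5'P degradome and call cleavage sites.

Builds the toy 2-kb pre-rRNA transcription unit, simulates three wild-type
replicate libraries (100k reads each) whose 5' ends are drawn from 14
planted processing sites plus uniform decay background, aligns the reads,
piles up per-base 5'-end counts, and calls single-nucleotide sites that
reproduce across replicates.
"""

import cleavemap as cm

ref = cm.default_reference(seed=42)
profile = cm.default_profile(ref)

pairs = []
for rep in (1, 2, 3):
    lib = cm.simulate_library(ref, profile, "wt", rep, seed=42)
    alns = cm.align_reads(ref, lib)
    pairs.append(cm.normalize_pair(cm.build_end_track(alns, ref)))

per_rep = [cm.call_track_pair(pair) for pair in pairs]
merged = cm.annotate_sites(cm.merge_replicates(per_rep, tracks=pairs), ref)

print(f"{'site':>6} {'pos':>5} strand {'mean RP10M':>11} {'enrichment':>10}  q")
for c in sorted(merged, key=lambda c: c.position):
    print(f"{c.label:>6} {c.position:>5}   {c.strand}   {c.rp10m_mean:>11.0f} {c.enrichment:>10.1f}  {c.q_value:.2e}")
rec = cm.score_recovery(merged, profile, "wt")
print(f"\nrecall {rec['recall']:.2f}, precision {rec['precision']:.2f} vs planted truth")
# Each row is one cleavage position recovered at single-nucleotide
# resolution; RP10M is its 5'-end signal per ten million aligned ends, and
# enrichment is signal over the local decay background.
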