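"""RNase III duplex-cut signatures on a folded hairpin.

RNase III enzymes (Dicer, Rnt1) cut both strands of a helix leaving 2-nt
(canonical) or 1-nt 3' overhangs.  With 5'P coordinates the overhang
offset is d = antisense_cut - partner[sense_cut] - 1.  This example folds
a hairpin, classifies planted cut pairs, and recovers the planted B0/B'
pair from simulated small-RNA 5'-end tracks.
"""

import cleavemap as cm
from cleavemap._util import to_rna

ref = cm.default_reference(seed=42)
cass = ref.cassette("B0")
pt = cm.fold_nussinov(to_rna(ref.sequence[cass.start : cass.end]))
print("hairpin:", pt.to_dotbracket())

b0 = ref.site("B0")
i_local = b0.position - cass.start
for d in (0, 1, 2):
    j_local = int(pt.partner[i_local]) + 1 + d
    sig = cm.classify_cut_pair(pt, i_local, j_local)
    print(f"planted offset {d} -> classified {sig.klass} (d={sig.offset})")

# recover the canonical 2-nt-overhang geometry from small-RNA duplex reads
lib = cm.simulate_smallrna(ref, [cm.DuplexSpec(b0.position, ref.site("B'").position, 21)], depth=500, seed=1)
plus, minus = cm.end_track_from_origins(lib, ref)
[sig] = cm.smallrna_duplex_signature(
    plus, minus, {(cass.start, cass.end): cm.parse_dotbracket(to_rna(ref.sequence[cass.start:cass.end]), cass.dotbracket())},
    site_positions=[(b0.position, "+"), (ref.site("B'").position, "-")],
)
print(f"\nsmall-RNA duplex: {sig.signature.klass} at {sig.signature.sense_cut}/{sig.signature.antisense_cut}, "
      f"5' ends coincide with degradome sites: {sig.sense_matches_site and sig.antisense_matches_site}")
# 'overhang2' is the canonical RNase III signature: the antisense cut sits
# 2 nt past the pairing partner of the sense cut, leaving 2-nt 3' overhangs.
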