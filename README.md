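# cleavemap

Single-nucleotide cleavage-site mapping from 5'-monophosphate (degradome /
PARE-style) sequencing, with RNase III duplex-signature classification and
lncRNA↔pre-rRNA complementarity scanning — benchmarked end to end on
synthetic libraries with planted ground truth.

## The problem

Endonucleolytic cleavage of RNA — by RNase III enzymes such as Dicer and
Rnt1 during pre-rRNA processing — leaves a free 5'-monophosphate on the
downstream product. Degradome sequencing captures those 5'P ends by adapter
ligation, so each read's first nucleotide marks a cut with single-nucleotide
precision. Turning such libraries into biology requires several linked
analyses:

1. **pileup** — strand-aware per-base 5'-end count tracks, normalized to
   RP10M (reads per ten million aligned 5'-end events);
2. **site calling** — single-nucleotide peaks against a local Poisson
   background, reproducible at the *exact* nucleotide across replicates;
3. **differential cleavage** — per-site condition ratios (e.g. residual
   cleavage in a Dicer deletion) with Welch *t*-tests and BH correction,
   plus site-preference folds such as the A0/B0 balance of the two early
   pre-rRNA processing sites;
4. **duplex signatures** — RNase III enzymes cut both strands of a helix;
   with 5'P coordinates the overhang offset is `d = j − partner[i] − 1`
   (sense cut `i`, antisense cut `j`, pairing map `partner`), and
   `d = 2` is the canonical 2-nt 3'-overhang, `d = 1` a 1-nt overhang,
   `d = 0` a blunt cut;
5. **antisense element scanning** — exact *k*-mer seed search
   (default k = 14) for lncRNA regions complementary to a target RNA,
   extended with Watson-Crick (+1) and G:U wobble (+0.5) scoring into a
   full recognition duplex.

Because real degradome data is bulky and its truth unknown, the package
ships a first-class synthetic module: a collapsed ~2-kb rDNA transcription
unit (5'ETS–18S–ITS1–5.8S–ITS2–28S–3'ETS) carrying named processing sites
(TSS, A0, A1, hp3, B0, B', B1, C1, plus novel 5'ETS sites), hairpin
cassettes with known secondary structure at the duplex-cut sites, read
libraries whose 5' ends are drawn from planted per-condition cleavage
efficiencies plus uniform decay background, Ago-IP-style small-RNA duplexes
with planted overhang geometry, and a lncRNA catalog with one planted
complementarity element and its 8-substitution seed mutant. Every
downstream claim is therefore testable against exact ground truth.

## Worked example

```python
import cleavemap as cm

ref = cm.default_reference(seed=42)
profile = cm.default_profile(ref)           # wt + dcr1d, 3 replicates, 1e5 reads

pairs = []
for rep in (1, 2, 3):
    lib = cm.simulate_library(ref, profile, "wt", rep, seed=42)
    pairs.append(cm.normalize_pair(cm.build_end_track(cm.align_reads(ref, lib), ref)))

per_rep = [cm.call_track_pair(p) for p in pairs]
merged = cm.annotate_sites(cm.merge_replicates(per_rep, tracks=pairs), ref)
for c in sorted(merged, key=lambda c: c.position)[:3]:
    print(c.label, c.position, c.strand, round(c.rp10m_mean), round(c.enrichment, 1))
```

prints (seed 42):

```
TSS 0 + 802367 543.0
n1 100 + 151900 105.9
n2 140 + 152700 102.4
```

Each line is one recovered cleavage site: its canonical label, exact
nucleotide position, strand, mean RP10M signal across replicates, and
enrichment over the local decay background. On this run all 14 planted
sites are recovered at their exact nucleotide with no false calls
(`cm.score_recovery(merged, profile, "wt")` → recall 1.00, precision 1.00).

The `examples/` directory has one short narrative script per capability:
site calling (`01`), differential cleavage and A0/B0 preference (`02`),
duplex-cut signatures and small-RNA geometry (`03`), and the lncRNA
antisense scan (`04`). A thin CLI mirrors the stages
(`cleavemap simulate | pileup | call | diff | signature | scan | run |
report`); real data enters as pre-aligned BED6 of 5'-end positions via
`cleavemap pileup --bed`.

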