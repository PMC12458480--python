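# Methods

This note documents the models behind cleavemap: what the synthetic data
emulates, how each analysis stage works, the defaults and why, and what the
passing test suite does and does not demonstrate about real data.

## Coordinates and the 5'P convention

All coordinates are 0-based, half-open. A cleavage position is the
5'-monophosphate position: the index of the first nucleotide of the
downstream product, so the scissile bond lies between `position−1` and
`position`. A plus-strand read contributes one 5'-end event at its
alignment start; a minus-strand read's biological 5' end is at
`start + read_length − 1` in reference coordinates. These conventions match
BED and make the overhang algebra of duplex cuts exact.

## The synthetic reference

`make_reference` builds one collapsed rDNA transcription unit
(5'ETS 700 nt, 18S 300, ITS1 150, 5.8S 120, ITS2 150, 28S 400, 3'ETS 180;
2 kb total). Collapsing the tandem rDNA repeat to a single unit sidesteps
multi-mapping; we document this as the repeat-collapse convention. Random
sequence is drawn per seed; 14 canonical/novel sites are planted at fixed
feature offsets (TSS, six novel 5'ETS sites, hp3, A0, A1, B1, C1, B0, and
the antisense B' partner). A 13-novel-site layout (`novel13_site_spec`) is
available for the site-discovery analysis.

Sites that biologically sit on double-stranded RNA (A0, B0/B', hp3) are
embedded in hairpin cassettes: a 22-bp stem with a 6-nt loop, arms C/G-only
and loop A-only. With that alphabet no base outside the designed stem can
form a Watson-Crick or G:U pair, so the designed stem is the unique
maximum-pairing structure — the cassette's secondary structure is ground
truth, not a prediction. B' is planted at `partner(B0) + 3`, i.e. the
canonical 2-nt 3'-overhang geometry (`d = 2`); the small-RNA duplex planted
at A0 uses `d = 1`. These cassettes emulate the *geometry* of the 5'ETS /
3'ETS hairpins, not their true sequences or lengths.

## The read model

Each library read's 5' end is one categorical draw: a planted site with
probability equal to its per-condition efficiency, or uniform plus-strand
background ("exonucleolytic decay") with the remaining mass
`1 − Σ efficiencies`. Keeping per-site probabilities equal to the planted
efficiencies across conditions makes planted between-condition ratios
recoverable without renormalization bias. Replicates are independent
multinomial draws — no overdispersion by default, because no empirical
dispersion estimate exists for the toy unit. Reads are error-free by
default (a uniform substitution rate is available) so the alignment oracle
stays exact; read length is 30 nt, depth 1e5 per library, three replicates
per condition, global seed 42.

Background 5' ends are restricted to positions that support a full-length
read (`[0, L − read_length]`): this keeps every simulated read uniquely
alignable, at the cost of an empty zone at the unit's 3' edge (see the
capture-support mask below).

Default per-condition efficiencies (wild-type quiescent cells): mature-end
sites strongest (A1 0.15, B1 0.13, C1 0.12), TSS 0.08, A0 0.068, hp3 0.05,
B0 0.010, B' 0.008, novel sites 0.015 each — sites carry ~70% of reads,
background ~30%, and the A0/B0 ratio is 6.8, the quiescent preference for
the co-transcriptional early site. The Dicer-deletion condition (`dcr1d`)
retains 10% of A0, 21% of B0/B', 20% of hp3, 40% of the mature ends, and
10% of every novel site except the last (one Dicer-independent novel site).
A cycling-cell preset instead sets B0/A0 = 3.8 with A0 Dicer-independent.
The four-condition preset orders hp3 as
dcr1d (0.01) < wt (0.05) < ribocop_d = dcr1d_ribocop_d (0.15): hp3
cleavage requires Dicer and is de-repressed when the occluding lncRNA is
deleted.

## Alignment and tracks

The aligner is ungapped exact (optionally ≤ *k* mismatches) search over
both strands of the single short reference — a deliberate desk-scale
stand-in, exhaustively checked against a brute-force all-position,
both-strand oracle. Placement policy: plus strand preferred over minus,
leftmost within a strand, multi-mappers flagged. For error-free simulated
reads the aligned tracks equal the tracks built directly from ground-truth
origins (`end_track_from_origins`), which the fast multi-seed analyses use.

Normalization is RP10M: `counts / total_aligned × 1e7`, with
`total_aligned` pooled over both strands so a library's two normalized
strand tracks sum to 1e7 exactly. Real data enters as pre-aligned BED6 of
5'-end positions; no BAM parsing is attempted.

## Site calling

A candidate is a position with raw count ≥ `min_count` (10) that is a
strict local maximum within ±2 nt (runs of ties keep the leftmost). The
local background λ is the mean raw count in a 41-nt window centred on the
candidate, excluding ±2 nt around it, floored at a pseudocount of 0.5;
significance is the Poisson upper tail `P(X ≥ count | λ)`,
Benjamini–Hochberg corrected across candidates per track at
`alpha_q = 0.01`. The Poisson-with-local-window model was chosen for
transparency and testability; nothing in it is fitted.

Capture-support mask: a 5'P end within one read length of the unit's 3'
terminus cannot be captured at full read length, so `call_track_pair`
truncates the plus-strand track at `L − read_length + 1` for both
candidacy and background estimation (the window is clipped at the support
edge exactly as at position 0). Without the mask, the structurally empty
tail biases λ low and can produce reproducible false calls near the edge.

Replicate merging requires the identical (position, strand) in ≥ 2
replicates — tolerance 0 operationalizes single-nucleotide
reproducibility; replicate counts are recorded for all replicates, zeros
included; merged p-values combine replicate Poisson tails by Fisher's
method and are BH-corrected across merged sites. Annotation assigns a
canonical label only at the exact planted nucleotide and strand
(tolerance 0; with a positive tolerance the nearest site wins, leftmost on
ties).

## Differential cleavage

The site × (condition, replicate) matrix holds RP10M at each called
position in every library (union of calls across conditions; zeros
allowed). Per site, `ratio_percent = 100 × (mean_test + p)/(mean_ref + p)`
with pseudocount p = 1 RP10M, and a two-sided Welch *t*-test on the
untransformed per-replicate RP10M values, BH-corrected across sites. Welch
was chosen over the pooled-variance *t* as the safer default and is named
in output headers; zero-variance ties yield p = 1 by convention. With
fewer than two replicates only the ratio is reported.

`site_matrix(..., background_correct=True)` substitutes
`max(count − λ, 0)` on the RP10M scale, with λ the windowed local
background at that position in that replicate. The additive decay floor
otherwise inflates condition ratios at weakly cleaved sites (in the
high-background deletion condition it contributes ~36 counts per position
at the defaults); correction recovers the planted residual percentages.
The uncorrected scale remains the default because it is the directly
observed signal.

`preference_ratio` compares two sites' condition means
(`(mean_a + p)/(mean_b + p)`, ties to the first site), and
`expression_ratio` applies the same pseudocounted fold to a transcript's
total normalized counts.

## Duplex signatures

Structures are nested pair tables, built either by the built-in
maximum-pairing (Nussinov) dynamic program — min_loop 3, G:U allowed,
deterministic traceback, verified against exhaustive enumeration for all
test sequences ≤ 12 nt — or parsed from dot-bracket strings produced by
external thermodynamic folders. The pipeline scans cut pairs against the
cassettes' designed structures (which are ground truth); the folder is for
exploratory use and external-structure ingestion.

A sense cut *i* on a helix and an antisense cut *j* classify as
`d = j − partner[i] − 1`: 0 blunt, 1 one-nt 3' overhang, 2 the canonical
RNase III two-nt 3' overhang, anything else non-canonical. `scan_signatures`
pairs sense and antisense 5'-end peaks across each annotated helix,
keeping offsets in [−2, 4] and reporting the highest-joint-count partner
(ties: smaller |d|, then smaller j). The pipeline masks the scanned tracks
to reproducibly called sites first, since signatures are a property of
called cleavage events, not of raw background piles. The same geometry
applied to Ago-IP small-RNA 5'-end tracks also reports whether each
small-RNA 5' end coincides with a degradome 5'P site at the same
nucleotide — the concordance expected when the small RNA is a direct
cleavage product.

## Antisense (RHB-style) scanning

A seed is an exact reverse-complement match of a 14-nt lncRNA window to a
target window (G:U not credited in the seed; a mismatch budget is
available). Both orientations of each lncRNA are scanned. Extension walks
outward counting Watson-Crick matches (+1) and G:U wobbles (+0.5) against
included mismatches (−1), stopping at two consecutive non-pairing
positions, a mismatch budget of 2, or a sequence end, then trimming back
to the last pairing position. The score is a dimensionless count, not an
energy — thermodynamic interaction prediction is explicitly out of scope.
Ranked hits require score ≥ 18: a bare seed scores 14, the planted 25-nt
duplex 25, so the threshold separates full-length recognition elements
from chance seeds; seeds extending to the identical duplex are collapsed.

The generator plants the element with non-pairing two-base boundaries, so
its extendable complementarity is exactly 25 nt by construction, and
always mutates the 5'-most seed position in the 8-substitution mutant, so
the mutant yields no exact seed hit. Expected chance seed hits among
decoys are ≈ `2 · n_query_windows · n_target_windows · 4^−14`
(both orientations); the measured decoy rate is asserted to stay within
10× that bound.

## Pipeline, determinism, problem sizes

`run_pipeline` chains the stages from one config (YAML-serializable),
writes plain-text artifacts (FASTA, bedGraph, TSV, JSON), scores recovery
against the planted truth by exact-position matching, and hashes a
canonical JSON rendering of the results — identical seed, identical hash.
All RNG streams derive from the one seed via per-stage tags, so stages are
reproducible independently of call order.

The acceptance analyses use the default study conditions (2-kb unit,
depth 1e5, 3 replicates) across 10–20 seeds per quantity; multi-seed loops
that only read 5'-end positions build tracks from ground-truth origins,
whose identity with aligned tracks is itself part of the aligner-oracle
tests. The type-I-error check simulates 1000 null sites at the
site-matrix level (Poisson replicate values), since the operation under
test is the per-site Welch/BH procedure rather than the read simulator.

## Limitations

The synthetic benchmark demonstrates correctness of the statistical and
geometric machinery against planted truth, not performance on real
libraries: it has no ligation or PCR bias, no sequencing errors or quality
variation by default, no adapters or UMIs, no tandem-repeat copy-number
variation, no overdispersion between replicates, and hairpin cassettes
rather than the true 5'ETS fold. The aligner is not a general-purpose
mapper; real data should arrive as externally aligned 5'-end BED. Poisson
backgrounds and Welch tests on three replicates are transparent defaults,
not fitted noise models.
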