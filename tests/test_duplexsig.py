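import numpy as np
import pytest

import cleavemap as cm
from cleavemap._util import revcomp_rna
from conftest import max_pairs_exhaustive


def test_simple_hairpin_folds_to_full_stem():
    pt = cm.fold_nussinov("GGGAAACCC")
    assert pt.n_pairs == 3
    assert pt.to_dotbracket() == "(((...)))"


def test_unpairable_sequence_has_no_pairs():
    assert cm.fold_nussinov("AAAAA").n_pairs == 0


def test_invalid_residue_rejected():
    with pytest.raises(ValueError):
        cm.fold_nussinov("ACGTX")  # T and X both invalid for RNA folding


@pytest.mark.parametrize("allow_gu", [True, False])
def test_nussinov_pair_count_matches_exhaustive_oracle(allow_gu):
    rng = np.random.default_rng(12)
    for _ in range(120):
        n = int(rng.integers(1, 13))
        seq = "".join(rng.choice(list("ACGU"), size=n))
        pt = cm.fold_nussinov(seq, allow_gu=allow_gu)
        assert pt.n_pairs == max_pairs_exhaustive(seq, allow_gu=allow_gu), seq
        # traceback output is a valid structure (PairTable validated it)
        assert len(pt.to_dotbracket()) == n


def test_designed_cassette_stem_is_recovered_exactly():
    # C/G arms + A loop: the designed stem is the unique maximum pairing
    for seed in range(5):
        cass = cm.HairpinCassette("x", 0)
        from cleavemap.reference import _cassette_sequence
        from cleavemap._util import rng_for, to_rna

        seq = to_rna(_cassette_sequence(rng_for(seed, "c")))
        pt = cm.fold_nussinov(seq)
        for k in range(cass.length):
            assert pt.partner[k] == cass.partner_of(k)


# --- dot-bracket -----------------------------------------------------------

def test_parse_dotbracket_direct_reading():
    pt = cm.parse_dotbracket("GGGAAACCC", "(((...)))")
    assert pt.partner[0] == 8 and pt.partner[1] == 7 and pt.partner[2] == 6
    assert pt.partner[3] == -1


def test_parse_dotbracket_unbalanced_rejected_with_position():
    with pytest.raises(ValueError, match="index 0"):
        cm.parse_dotbracket("GGAAC", "((..)")
    with pytest.raises(ValueError, match="index"):
        cm.parse_dotbracket("GGAAC", "(..))")


def test_dotbracket_round_trip_identity():
    s = "((((...)))).((...))."
    seq = "GGGGAAACCCCAGGAAACCA"
    pt = cm.parse_dotbracket(seq, s)
    assert pt.to_dotbracket() == s
    pt2 = cm.parse_dotbracket(seq, pt.to_dotbracket())
    assert np.array_equal(pt.partner, pt2.partner)


def test_crossing_pairs_rejected():
    with pytest.raises(ValueError, match="involution|crossing"):
        partner = np.array([4, 6, -1, -1, 0, -1, 1])
        cm.PairTable("GGAAACC", partner, min_loop=2)


# --- cut-pair geometry -----------------------------------------------------

@pytest.fixture(scope="module")
def stem14():
    # pairs 0-13, 1-12, 2-11, 3-10, 4-9
    return cm.parse_dotbracket("GGGGGAAAACCCCC", "(((((....)))))")


@pytest.mark.parametrize("j, d, klass", [(13, 2, "overhang2"), (11, 0, "blunt"), (12, 1, "overhang1")])
def test_classify_cut_pair_hand_geometry(stem14, j, d, klass):
    sig = cm.classify_cut_pair(stem14, 3, j)
    assert sig.offset == d and sig.klass == klass


def test_classify_requires_helix_at_sense_cut(stem14):
    with pytest.raises(ValueError, match="no helix"):
        cm.classify_cut_pair(stem14, 7, 10)  # loop position


def test_classify_round_trip_on_random_folded_hairpins():
    # plant cuts with offset d on designed stems; classification returns d
    rng = np.random.default_rng(3)
    for _ in range(100):
        arm = int(rng.integers(8, 15))
        left = "".join(rng.choice(list("CG"), size=arm))
        seq = left + "A" * 4 + revcomp_rna(left)
        pt = cm.fold_nussinov(seq)
        i = int(rng.integers(1, arm))
        designed_partner = len(seq) - 1 - i  # ground-truth stem geometry
        for d in (0, 1, 2):
            j = designed_partner + 1 + d
            if j > len(seq):
                continue
            assert cm.classify_cut_pair(pt, i, j).offset == d


# --- signature scanning ----------------------------------------------------

def tracks_with_peaks(length, plus_peaks, minus_peaks):
    plus = np.zeros(length, dtype=np.int64)
    minus = np.zeros(length, dtype=np.int64)
    for p, c in plus_peaks:
        plus[p] = c
    for p, c in minus_peaks:
        minus[p] = c
    total = int(plus.sum() + minus.sum())
    return cm.EndTrack("toy", "+", plus, total), cm.EndTrack("toy", "-", minus, total)


def test_scan_recovers_planted_canonical_pair(ref):
    cass = ref.cassette("B0")
    b0, bp = ref.site("B0"), ref.site("B'")
    pt = cm.parse_dotbracket(
        ref.sequence[cass.start : cass.end].replace("T", "U"), cass.dotbracket()
    )
    plus, minus = tracks_with_peaks(ref.length, [(b0.position, 500)], [(bp.position, 400)])
    sigs = cm.scan_signatures(plus, minus, {(cass.start, cass.end): pt}, min_count=10)
    assert len(sigs) == 1
    s = sigs[0]
    assert (s.sense_cut, s.antisense_cut, s.offset, s.klass) == (b0.position, bp.position, 2, "overhang2")


def test_sense_peak_in_unpaired_loop_yields_nothing(ref):
    cass = ref.cassette("B0")
    pt = cm.parse_dotbracket(ref.sequence[cass.start : cass.end].replace("T", "U"), cass.dotbracket())
    loop_pos = cass.start + cass.arm + 1
    plus, minus = tracks_with_peaks(ref.length, [(loop_pos, 500)], [(cass.end - 1, 400)])
    assert cm.scan_signatures(plus, minus, {(cass.start, cass.end): pt}, min_count=10) == []


def test_scan_tie_rules_smaller_offset_then_smaller_j(ref):
    cass = ref.cassette("B0")
    b0 = ref.site("B0")
    pt = cm.parse_dotbracket(ref.sequence[cass.start : cass.end].replace("T", "U"), cass.dotbracket())
    partner = cass.partner_of(b0.position)
    # two antisense candidates with equal counts at d=1 and d=3: d=1 wins
    plus, minus = tracks_with_peaks(
        ref.length, [(b0.position, 500)], [(partner + 2, 100), (partner + 4, 100)]
    )
    [s] = cm.scan_signatures(plus, minus, {(cass.start, cass.end): pt}, min_count=10)
    assert s.offset == 1
    # equal counts at d=-1 and d=+1 (same |d|): smaller j wins
    plus, minus = tracks_with_peaks(
        ref.length, [(b0.position, 500)], [(partner, 100), (partner + 2, 100)]
    )
    [s] = cm.scan_signatures(plus, minus, {(cass.start, cass.end): pt}, min_count=10)
    assert s.antisense_cut == partner and s.offset == -1


def test_offsets_outside_window_not_reported(ref):
    cass = ref.cassette("B0")
    b0 = ref.site("B0")
    pt = cm.parse_dotbracket(ref.sequence[cass.start : cass.end].replace("T", "U"), cass.dotbracket())
    partner = cass.partner_of(b0.position)
    plus, minus = tracks_with_peaks(ref.length, [(b0.position, 500)], [(partner + 8, 400)])
    assert cm.scan_signatures(plus, minus, {(cass.start, cass.end): pt}, min_count=10) == []


# --- small-RNA geometry ----------------------------------------------------

def test_smallrna_duplex_round_trip_and_concordance(ref):
    cass = ref.cassette("B0")
    b0, bp = ref.site("B0"), ref.site("B'")
    spec = [cm.DuplexSpec(b0.position, bp.position, 21)]
    lib = cm.simulate_smallrna(ref, spec, depth=400, seed=2)
    plus, minus = cm.end_track_from_origins(lib, ref)
    pt = cm.parse_dotbracket(ref.sequence[cass.start : cass.end].replace("T", "U"), cass.dotbracket())
    sigs = cm.smallrna_duplex_signature(
        plus, minus, {(cass.start, cass.end): pt},
        site_positions=[(b0.position, "+"), (bp.position, "-")],
    )
    assert len(sigs) == 1
    s = sigs[0]
    assert s.signature.klass == "overhang2"
    assert s.sense_matches_site and s.antisense_matches_site


def test_smallrna_empty_input_empty_output(ref):
    cass = ref.cassette("B0")
    pt = cm.parse_dotbracket(ref.sequence[cass.start : cass.end].replace("T", "U"), cass.dotbracket())
    plus, minus = tracks_with_peaks(ref.length, [], [])
    assert cm.smallrna_duplex_signature(plus, minus, {(cass.start, cass.end): pt}) == []
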