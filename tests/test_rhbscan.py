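import numpy as np
import pytest

import cleavemap as cm
from cleavemap._util import revcomp


def brute_force_seed_windows(catalog, target, k):
    """Independent all-window comparison oracle (orientation '+' only)."""
    hits = []
    for rid, seq in catalog:
        for qs in range(len(seq) - k + 1):
            probe = revcomp(seq[qs : qs + k])
            for ts in range(len(target) - k + 1):
                if target[ts : ts + k] == probe:
                    hits.append((rid, qs, ts))
    return sorted(hits)


def planted_seed_hit(records, plant, target):
    return [
        h
        for h in cm.seed_scan(records, target)
        if h.lncrna_id == plant.lncrna_id
        and h.orientation == "+"
        and h.query_start == plant.seed_query_interval[0]
    ]


def test_planted_seed_found_at_exact_coordinates(ref):
    records, plant = cm.make_lncrna_catalog(ref, seed=5)
    hits = [h for h in cm.seed_scan(records, ref.sequence) if h.lncrna_id == plant.lncrna_id]
    # the planted seed itself is recovered with 0 mismatches...
    [exact] = planted_seed_hit(records, plant, ref.sequence)
    assert exact.target_start == plant.seed_target_interval[0]
    assert exact.mismatches == 0
    # ...and every other hit is a subwindow of the same planted duplex
    # (a perfect 25-nt complement contains 12 matching 14-mers)
    q0, q1 = plant.query_interval
    assert all(q0 <= h.query_start and h.query_start + h.k <= q1 for h in hits)


def test_mutant_record_yields_no_hits_at_default_thresholds(ref):
    records, plant = cm.make_lncrna_catalog(ref, seed=5)
    mutant_only = [r for r in records if r[0] == plant.mutant_id]
    # exact-seed scan finds nothing at the planted seed coordinates
    assert planted_seed_hit(mutant_only, plant, ref.sequence) == []
    # and the full seed+extend+rank scan rejects the mutant entirely
    assert cm.scan_catalog(mutant_only, ref.sequence) == []


def test_target_vs_own_revcomp_saturates(ref):
    target = ref.sequence[100:200]
    hits = cm.seed_scan([("rc", revcomp(target))], target, orientations="+")
    starts = {h.query_start for h in hits}
    assert starts == set(range(len(target) - 14 + 1))


def test_seed_scan_agrees_with_brute_force_window_oracle(ref):
    rng = np.random.default_rng(8)
    target = ref.sequence[:300]
    catalog = [("d1", "".join(rng.choice(list("ACGT"), 80))), ("d2", revcomp(target[40:70]))]
    expected = brute_force_seed_windows(catalog, target, 14)
    got = sorted(
        (h.lncrna_id, h.query_start, h.target_start)
        for h in cm.seed_scan(catalog, target, orientations="+")
    )
    assert got == expected and len(expected) >= 17


def test_short_record_skipped_with_warning(ref):
    with pytest.warns(UserWarning, match="short"):
        hits = cm.seed_scan([("tiny", "ACGTACGT")], ref.sequence)
    assert hits == []


def test_scan_invariant_under_catalog_order(ref):
    records, _ = cm.make_lncrna_catalog(ref, n_decoys=5, seed=9)
    fwd = cm.scan_catalog(records, ref.sequence)
    rev = cm.scan_catalog(records[::-1], ref.sequence)
    assert fwd == rev


# --- extension -------------------------------------------------------------

def test_planted_duplex_extends_to_exactly_25(ref):
    records, plant = cm.make_lncrna_catalog(ref, seed=5)
    seqs = dict(records)
    [hit] = planted_seed_hit(records, plant, ref.sequence)
    rh = cm.extend_duplex(hit, seqs[plant.lncrna_id], ref.sequence)
    assert rh.duplex_len == 25
    assert rh.query_interval == plant.query_interval
    assert rh.target_interval == plant.target_interval
    assert rh.matches == 25 and rh.mismatches == 0 and rh.score == 25.0


MID = "ACGTACGTACGTAC"  # 14-nt non-repetitive seed target


def test_immediate_double_mismatch_keeps_seed_only():
    # C flanks on the query cannot pair (WC or GU) with the T flanks of
    # the target: extension stops immediately on both sides
    target = "TT" + MID + "TT"
    query = "CC" + revcomp(MID) + "CC"
    [hit] = cm.seed_scan([("q", query)], target, orientations="+")
    rh = cm.extend_duplex(hit, query, target)
    assert rh.duplex_len == 14
    assert rh.score == 14.0


def test_perfect_flanks_extend_and_never_lower_score(ref):
    records, plant = cm.make_lncrna_catalog(ref, seed=5)
    seqs = dict(records)
    [hit] = planted_seed_hit(records, plant, ref.sequence)
    rh = cm.extend_duplex(hit, seqs[plant.lncrna_id], ref.sequence)
    assert rh.score >= hit.k  # monotone: perfect flanks only add


def test_gu_wobble_counts_half_in_extension():
    # one G:U wobble on the left query flank (G against target T), then
    # non-pairing C flanks stop the extension everywhere else
    target = "TT" + MID + "TT"
    query = "CCG" + revcomp(MID) + "CC"
    [hit] = cm.seed_scan([("q", query)], target, orientations="+")
    rh = cm.extend_duplex(hit, query, target)
    assert rh.gu_pairs == 1
    assert rh.duplex_len == 15
    assert rh.mismatches == 0
    assert rh.score == 14.5


# --- ranking ---------------------------------------------------------------

def test_default_catalog_yields_exactly_one_passing_hit(ref):
    records, plant = cm.make_lncrna_catalog(ref, seed=13)
    hits = cm.scan_catalog(records, ref.sequence)
    assert len(hits) == 1
    assert hits[0].lncrna_id == plant.lncrna_id


def test_rank_empty_and_tie_rules():
    assert cm.rank_hits([]) == []
    mk = lambda dl, ts, score=20.0: cm.RhbHit(
        "x", "+", (0, dl), (ts, ts + dl), 14, 0, dl, dl, 0, 0, score
    )
    ranked = cm.rank_hits([mk(20, 50), mk(25, 90), mk(25, 10)])
    assert [h.duplex_len for h in ranked] == [25, 25, 20]
    assert ranked[0].target_interval[0] == 10  # leftmost target on full tie
    assert cm.rank_hits([mk(20, 0, score=10.0)], min_score=18.0) == []


def test_decoy_false_positive_rate_within_analytic_bound(ref):
    # expected spurious exact 14-mer seed hits ~ n_query_windows *
    # n_target_windows * 4^-14 per orientation; measured rate must stay
    # within 10x of the two-orientation bound
    n_seeds = 60
    total_hits = 0
    n_q = n_t = None
    for seed in range(n_seeds):
        records, plant = cm.make_lncrna_catalog(ref, n_decoys=20, seed=seed)
        decoys = [r for r in records if r[0].startswith("decoy")]
        hits = cm.seed_scan(decoys, ref.sequence)
        total_hits += len(hits)
        n_q = sum(len(s) - 13 for _, s in decoys)
        n_t = len(ref.sequence) - 13
    expected_per_seed = 2 * n_q * n_t * 4.0**-14
    assert total_hits / n_seeds <= max(10 * expected_per_seed, 0.2)
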