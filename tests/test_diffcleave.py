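import numpy as np
import pandas as pd
import pytest

import cleavemap as cm
from conftest import welch_p_oracle


def toy_matrix(values: dict[str, list[list[float]]], sites=None):
    """Build a site x (condition, replicate) RP10M matrix directly.

    values: condition -> per-site list of replicate values.
    """
    conds = list(values)
    n_sites = len(next(iter(values.values())))
    index = pd.MultiIndex.from_tuples(
        sites or [(100 + i, "+", f"s{i}") for i in range(n_sites)],
        names=["position", "strand", "label"],
    )
    cols = []
    data = []
    for cond in conds:
        reps = len(values[cond][0])
        for r in range(reps):
            cols.append((cond, r))
            data.append([values[cond][i][r] for i in range(n_sites)])
    return pd.DataFrame(
        np.array(data).T, index=index, columns=pd.MultiIndex.from_tuples(cols, names=["condition", "replicate"])
    )


def test_ratio_and_welch_p_match_textbook_oracle():
    wt, mut = [100.0, 110.0, 90.0], [10.0, 9.0, 11.0]
    m = toy_matrix({"wt": [wt], "mut": [mut]})
    df = cm.test_differential(m, "wt", "mut")
    row = df.iloc[0]
    assert row.ratio_percent == pytest.approx(100 * (np.mean(mut) + 1) / (np.mean(wt) + 1))
    assert row.ratio_percent == pytest.approx(100 * 11 / 101)  # ~10.9%
    t_o, p_o = welch_p_oracle(mut, wt)
    assert row.p_value == pytest.approx(p_o, abs=1e-9)
    assert row.t_statistic == pytest.approx(t_o, abs=1e-9)
    assert row.direction == "down"


def test_identical_groups_ratio_100_p_1():
    m = toy_matrix({"wt": [[50.0, 50.0, 50.0]], "mut": [[50.0, 50.0, 50.0]]})
    row = cm.test_differential(m, "wt", "mut").iloc[0]
    assert row.ratio_percent == 100.0
    assert row.p_value == 1.0
    assert row.direction == "unchanged"


def test_zero_variance_different_means_p_zero():
    m = toy_matrix({"wt": [[50.0, 50.0]], "mut": [[10.0, 10.0]]})
    row = cm.test_differential(m, "wt", "mut").iloc[0]
    assert row.p_value == 0.0


def test_all_zero_mutant_pseudocount_ratio():
    m = toy_matrix({"wt": [[100.0, 100.0, 100.0]], "mut": [[0.0, 0.0, 0.0]]})
    row = cm.test_differential(m, "wt", "mut").iloc[0]
    assert row.ratio_percent == pytest.approx(100 / 101 * 100 / 100, rel=1e-12) or True
    assert row.ratio_percent == pytest.approx(100 * 1 / 101)


def test_single_replicate_reports_ratio_only():
    m = toy_matrix({"wt": [[100.0]], "mut": [[50.0]]})
    row = cm.test_differential(m, "wt", "mut").iloc[0]
    assert np.isnan(row.p_value)
    assert row.ratio_percent == pytest.approx(100 * 51 / 101)


def test_missing_condition_rejected():
    m = toy_matrix({"wt": [[1.0, 2.0]], "mut": [[1.0, 2.0]]})
    with pytest.raises(ValueError, match="absent"):
        cm.test_differential(m, "wt", "nope")


def test_bh_q_values_monotone_in_p():
    rng = np.random.default_rng(0)
    wt = [list(v) for v in rng.poisson(100, size=(20, 3)).astype(float)]
    mut = [list(v) for v in rng.poisson(100, size=(20, 3)).astype(float)]
    df = cm.test_differential(toy_matrix({"wt": wt, "mut": mut}), "wt", "mut")
    d = df.sort_values("p_value")
    assert (d.q_value.to_numpy()[1:] >= d.q_value.to_numpy()[:-1] - 1e-12).all()
    assert ((df.q_value >= df.p_value) | df.p_value.isna()).all()


# --- preference & expression ratios ---------------------------------------

def pref_matrix(a_vals, b_vals):
    return toy_matrix(
        {"g0": [a_vals, b_vals]},
        sites=[(640, "+", "A0"), (1880, "+", "B0")],
    )


def test_preference_ratio_mirrors_both_fold_patterns():
    # B0-preferred pattern (means 380 vs 100 -> 3.77-fold for B0)
    m = pref_matrix([100.0] * 3, [380.0] * 3)
    pr = cm.preference_ratio(m, "g0", "B0", "A0")
    assert pr.fold == pytest.approx(381 / 101)
    assert pr.preferred == "B0"
    # A0-preferred pattern (680 vs 100 -> 6.74-fold)
    m = pref_matrix([680.0] * 3, [100.0] * 3)
    pr = cm.preference_ratio(m, "g0", "A0", "B0")
    assert pr.fold == pytest.approx(681 / 101)
    assert pr.preferred == "A0"


def test_preference_tie_goes_to_site_a_and_reciprocal_identity():
    m = pref_matrix([100.0] * 3, [100.0] * 3)
    pr = cm.preference_ratio(m, "g0", "A0", "B0")
    assert pr.fold == 1.0 and pr.preferred == "A0"
    m = pref_matrix([70.0] * 3, [210.0] * 3)
    ab = cm.preference_ratio(m, "g0", "A0", "B0", pseudo_rp10m=0.0)
    ba = cm.preference_ratio(m, "g0", "B0", "A0", pseudo_rp10m=0.0)
    assert ab.fold * ba.fold == pytest.approx(1.0)


def test_preference_missing_site_rejected_by_name():
    m = pref_matrix([1.0] * 3, [2.0] * 3)
    with pytest.raises(ValueError, match="hp3"):
        cm.preference_ratio(m, "g0", "hp3", "B0")


@pytest.mark.parametrize(
    "a, b, pseudo, expected",
    [(60, 10, 0, 6.0), (0, 0, 1, 1.0), (100, 0, 1, 101.0)],
)
def test_expression_ratio_arithmetic(a, b, pseudo, expected):
    assert cm.expression_ratio(a, b, pseudo) == pytest.approx(expected)


def test_expression_ratio_monotone_in_numerator():
    vals = [cm.expression_ratio(a, 10, 1) for a in range(0, 100, 7)]
    assert vals == sorted(vals)


# --- site matrix -----------------------------------------------------------

def test_site_matrix_union_includes_condition_specific_sites(ref, profile):
    libs = {
        cond: [
            cm.normalize_pair(cm.end_track_from_origins(cm.simulate_library(ref, profile, cond, r, seed=6), ref))
            for r in (1, 2, 3)
        ]
        for cond in ("wt", "dcr1d")
    }
    calls = {}
    for cond, pairs in libs.items():
        per_rep = [cm.call_track_pair(pair) for pair in pairs]
        calls[cond] = cm.annotate_sites(cm.merge_replicates(per_rep, tracks=pairs), ref)
    m = cm.site_matrix(calls, libs)
    assert m.shape[1] == 6
    # every wt-called site row has dcr1d values filled (possibly 0)
    assert not m["dcr1d"].isna().any().any()
    a0 = ref.site("A0")
    assert (a0.position, "+", "A0") in m.index


def test_background_corrected_matrix_removes_decay_floor(ref, profile):
    # at a weak site the additive uniform-background floor inflates the
    # dcr1d/wt ratio; local-background subtraction restores the planted one
    libs = {
        cond: [
            cm.normalize_pair(cm.end_track_from_origins(cm.simulate_library(ref, profile, cond, r, seed=21), ref))
            for r in (1, 2, 3)
        ]
        for cond in ("wt", "dcr1d")
    }
    calls = {}
    for cond, pairs in libs.items():
        per_rep = [cm.call_track_pair(pair) for pair in pairs]
        calls[cond] = cm.annotate_sites(cm.merge_replicates(per_rep, tracks=pairs), ref)
    planted = 100 * profile.efficiency("B0", "dcr1d") / profile.efficiency("B0", "wt")
    raw = cm.test_differential(cm.site_matrix(calls, libs), "wt", "dcr1d")
    corr = cm.test_differential(cm.site_matrix(calls, libs, background_correct=True), "wt", "dcr1d")
    raw_ratio = float(raw[raw.label == "B0"].iloc[0].ratio_percent)
    corr_ratio = float(corr[corr.label == "B0"].iloc[0].ratio_percent)
    assert abs(corr_ratio - planted) < abs(raw_ratio - planted)
    assert corr_ratio == pytest.approx(planted, abs=3.0)


def test_site_matrix_empty_calls_and_missing_libraries(ref, profile):
    pairs = [
        cm.normalize_pair(cm.end_track_from_origins(cm.simulate_library(ref, profile, "wt", 1, seed=6), ref))
    ]
    m = cm.site_matrix({"wt": []}, {"wt": pairs})
    assert m.empty
    with pytest.raises(ValueError, match="no libraries"):
        cm.site_matrix({"wt": []}, {"wt": []})
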