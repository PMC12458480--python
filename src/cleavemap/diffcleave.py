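"""Differential cleavage between conditions and site-preference ratios.

Per-site testing uses a two-sided Welch (unequal-variance) t-test on
untransformed RP10M values across replicates, with Benjamini-Hochberg
correction across sites.  All ratios carry a pseudocount (default
1 RP10M) so that fully silenced sites yield finite fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sitecall import SiteCall


@dataclass(frozen=True)
class PreferenceRatio:
    condition: str
    site_a: str
    site_b: str
    fold: float
    preferred: str


def site_matrix(
    merged_calls_by_condition: dict[str, list[SiteCall]],
    tracks_by_condition: dict[str, list[tuple]],
    union_rule: str = "union",
    background_correct: bool = False,
) -> pd.DataFrame:
    """Sites x (condition, replicate) matrix of RP10M values.

    Rows are the union of merged call positions across conditions; each
    cell is the RP10M value at that exact position in that library
    (possibly 0).  Row index: (position, strand, label).  The conditions
    that called each site are kept in df.attrs['called_in'].

    With background_correct=True each cell is the local-background-
    subtracted signal max(count - lambda, 0) on the RP10M scale, where
    lambda is the windowed background estimate at that position in that
    replicate: this removes the additive exonucleolytic-decay floor from
    per-site quantification, which otherwise inflates condition ratios at
    weakly cleaved sites.
    """
    if union_rule != "union":
        raise ValueError(f"unsupported union_rule {union_rule!r}")
    for cond, tracks in tracks_by_condition.items():
        if not tracks:
            raise ValueError(f"condition {cond!r} has no libraries")

    rows: dict[tuple[int, str, str], set[str]] = {}
    for cond, calls in merged_calls_by_condition.items():
        for c in calls:
            key = (c.position, c.strand, c.label)
            rows.setdefault(key, set()).add(cond)
    index = sorted(rows)
    columns = []
    data = []
    for cond, tracks in tracks_by_condition.items():
        for rep, pair in enumerate(tracks):
            columns.append((cond, rep))
            plus, minus = pair
            col = []
            for pos, strand, _label in index:
                tr = plus if strand == "+" else minus
                if tr.normalized is None:
                    raise ValueError("tracks must be normalized before building the site matrix")
                if background_correct:
                    from .sitecall import estimate_background

                    lam = estimate_background(tr, pos, pseudo=0.0)
                    signal = max(float(tr.counts[pos]) - lam, 0.0)
                    col.append(signal / tr.total_aligned * 1e7 if tr.total_aligned else 0.0)
                else:
                    col.append(float(tr.normalized[pos]))
            data.append(col)
    df = pd.DataFrame(
        np.array(data).T if data else np.empty((0, 0)),
        index=pd.MultiIndex.from_tuples(index, names=["position", "strand", "label"])
        if index
        else pd.MultiIndex.from_tuples([], names=["position", "strand", "label"]),
        columns=pd.MultiIndex.from_tuples(columns, names=["condition", "replicate"]),
    )
    df.attrs["called_in"] = {k: sorted(v) for k, v in rows.items()}
    return df


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch t-test (test vs reference), degenerate-safe.

    Zero variance in both groups: p = 1 when the means are equal (by
    convention), p = 0 when they differ.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return float("inf") if a.mean() > b.mean() else float("-inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def test_differential(
    matrix: pd.DataFrame,
    reference_condition: str,
    test_condition: str,
    pseudo_rp10m: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-site differential cleavage: test condition vs reference.

    ratio_percent = 100 * (mean_test + pseudo) / (mean_ref + pseudo).
    With fewer than 2 replicates in either condition only the ratio is
    reported (t and p are NaN).  direction is 'down'/'up' for sites
    significant at q < alpha, else 'unchanged'.
    """
    for cond in (reference_condition, test_condition):
        if cond not in matrix.columns.get_level_values("condition"):
            raise ValueError(f"condition {cond!r} absent from matrix")
    ref_vals = matrix[reference_condition].to_numpy(dtype=float)
    test_vals = matrix[test_condition].to_numpy(dtype=float)
    n_ref, n_test = ref_vals.shape[1], test_vals.shape[1]

    records = []
    for i, key in enumerate(matrix.index):
        a, b = ref_vals[i], test_vals[i]
        mean_ref, mean_test = float(a.mean()), float(b.mean())
        ratio = 100.0 * (mean_test + pseudo_rp10m) / (mean_ref + pseudo_rp10m)
        if n_ref >= 2 and n_test >= 2:
            t, p = welch_t(b, a)
        else:
            t, p = float("nan"), float("nan")
        records.append(
            {
                "position": key[0],
                "strand": key[1],
                "label": key[2],
                "mean_ref_rp10m": mean_ref,
                "mean_test_rp10m": mean_test,
                "ratio_percent": ratio,
                "t_statistic": t,
                "p_value": p,
            }
        )
    df = pd.DataFrame.from_records(records)
    if df.empty:
        df["q_value"] = []
        df["direction"] = []
        return df
    finite = df["p_value"].notna()
    q = np.full(len(df), np.nan)
    if finite.any():
        q[finite.to_numpy()] = stats.false_discovery_control(df.loc[finite, "p_value"].clip(1e-300, 1.0))
    df["q_value"] = q
    sig = df["q_value"] < alpha
    df["direction"] = np.where(
        sig & (df["ratio_percent"] < 100.0), "down", np.where(sig & (df["ratio_percent"] > 100.0), "up", "unchanged")
    )
    df.attrs["test"] = "welch_two_sided_t_on_rp10m"
    df.attrs["pseudocount_rp10m"] = pseudo_rp10m
    df.attrs["reference_condition"] = reference_condition
    df.attrs["test_condition"] = test_condition
    return df


def preference_ratio(
    matrix: pd.DataFrame,
    condition: str,
    site_a: str = "A0",
    site_b: str = "B0",
    pseudo_rp10m: float = 1.0,
) -> PreferenceRatio:
    """Fold preference of site_a over site_b from condition means.

    fold = (mean_a + pseudo) / (mean_b + pseudo); 'preferred' is the site
    with the larger mean (ties go to site_a).
    """
    if condition not in matrix.columns.get_level_values("condition"):
        raise ValueError(f"condition {condition!r} absent from matrix")
    means = {}
    for site in (site_a, site_b):
        rows = matrix.index.get_level_values("label") == site
        if not rows.any():
            raise ValueError(f"site {site!r} absent from the matrix")
        means[site] = float(matrix.loc[rows, condition].to_numpy().mean())
    fold = (means[site_a] + pseudo_rp10m) / (means[site_b] + pseudo_rp10m)
    preferred = site_a if means[site_a] >= means[site_b] else site_b
    return PreferenceRatio(condition, site_a, site_b, float(fold), preferred)


def expression_ratio(count_a: float, count_b: float, pseudo: float = 1.0) -> float:
    """Fold change of transcript abundance: (a + pseudo) / (b + pseudo)."""
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be >= 0")
    return (count_a + pseudo) / (count_b + pseudo)


def write_differential_tsv(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# test={df.attrs.get('test', 'NA')} pseudocount_rp10m={df.attrs.get('pseudocount_rp10m', 'NA')}\n")
        df.to_csv(fh, sep="\t", index=False)
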