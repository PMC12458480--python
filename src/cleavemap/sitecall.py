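"""Single-nucleotide cleavage-site calling against a local Poisson background.

Candidate positions must carry at least min_count raw 5'-end events and be
a strict local maximum within +/-2 nt (ties resolved to the leftmost
position).  The background at a candidate is the mean raw count in a
window centred on it, excluding the candidate's immediate +/-exclusion
neighbourhood, floored at a pseudocount; significance is the Poisson
upper tail P(X >= count | lambda), Benjamini-Hochberg corrected across all
candidates of the track.  Replicate merging requires the identical
nucleotide by default, operationalizing single-nucleotide reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .endmap import EndTrack
from .reference import ReferenceModel


@dataclass
class ReplicateCall:
    position: int
    strand: str
    count: int
    background_lambda: float
    p_value: float
    q_value: float


@dataclass
class SiteCall:
    position: int
    strand: str
    raw_counts_by_replicate: list[int]
    rp10m_mean: float
    background_lambda: float
    enrichment: float
    p_value: float
    q_value: float
    n_replicates_detected: int
    label: str = "novel"


def estimate_background(
    track: EndTrack,
    position: int,
    window: int = 41,
    exclusion: int = 2,
    pseudo: float = 0.5,
) -> float:
    """Local background rate (expected count) at a position.

    Mean raw count over the window centred on `position`, excluding
    positions within +/-exclusion of it; the window is truncated at the
    track ends; the result is floored at `pseudo`.
    """
    if window % 2 == 0 or window <= 2 * exclusion + 1:
        raise ValueError("window must be odd and larger than 2*exclusion+1")
    half = window // 2
    lo = max(0, position - half)
    hi = min(track.length, position + half + 1)
    idx = np.arange(lo, hi)
    flank = idx[np.abs(idx - position) > exclusion]
    if flank.size == 0:
        return float(pseudo)
    return float(max(track.counts[flank].mean(), pseudo))


def _local_maxima(counts: np.ndarray, min_count: int, span: int = 2) -> np.ndarray:
    """Positions whose count is >= every neighbour within +/-span and
    strictly greater than every *left* neighbour in the window (so runs of
    tied maxima keep only their leftmost position)."""
    cand = np.nonzero(counts >= min_count)[0]
    keep = []
    n = counts.size
    for i in cand:
        c = counts[i]
        lo, hi = max(0, i - span), min(n, i + span + 1)
        if np.any(counts[lo:i] >= c):
            continue
        if np.any(counts[i + 1 : hi] > c):
            continue
        keep.append(i)
    return np.array(keep, dtype=np.int64)


def call_sites(
    track: EndTrack,
    min_count: int = 10,
    alpha_q: float = 0.01,
    window: int = 41,
    exclusion: int = 2,
    pseudo: float = 0.5,
    support: int | None = None,
) -> list[ReplicateCall]:
    """Call candidate single-nucleotide sites on one replicate track.

    `support` restricts a plus-strand track to its first `support`
    positions for both candidacy and background estimation: a 5'P end
    within one read length of the unit's 3' terminus cannot be captured
    at full read length, so positions past the support edge carry no
    background and would bias the local lambda downward (mappability-
    style mask; the background window is truncated at the support edge
    exactly as at position 0).
    """
    eff = track
    if support is not None and track.strand == "+" and support < track.length:
        from dataclasses import replace as _replace

        eff = _replace(track, counts=track.counts[:support])
    cand = _local_maxima(eff.counts, min_count)
    if cand.size == 0:
        return []
    lambdas = np.array([estimate_background(eff, int(p), window, exclusion, pseudo) for p in cand])
    counts = eff.counts[cand]
    pvals = stats.poisson.sf(counts - 1, lambdas)
    qvals = stats.false_discovery_control(pvals)
    out = []
    for pos, c, lam, p, q in zip(cand, counts, lambdas, pvals, qvals):
        if q <= alpha_q:
            out.append(ReplicateCall(int(pos), track.strand, int(c), float(lam), float(p), float(q)))
    return out


def call_track_pair(
    pair: tuple[EndTrack, EndTrack],
    read_length: int = 30,
    **kwargs,
) -> list[ReplicateCall]:
    """Call both strand tracks of one replicate with the standard recipe:
    the plus strand is masked past its capture-support edge
    (length - read_length + 1)."""
    plus, minus = pair
    support = max(1, plus.length - read_length + 1)
    return call_sites(plus, support=support, **kwargs) + call_sites(minus, **kwargs)


def merge_replicates(
    per_replicate_calls: list[list[ReplicateCall]],
    tracks: list[EndTrack] | None = None,
    min_reps: int = 2,
    position_tolerance: int = 0,
) -> list[SiteCall]:
    """Merge per-replicate calls into reproducible sites.

    A merged site requires the identical (position, strand) in at least
    min_reps replicates (position_tolerance 0; with a tolerance > 0,
    replicate calls are greedily clustered around the most-supported
    position).  Replicate raw counts at the merged position are recorded
    for every replicate, zeros included, when per-replicate `tracks`
    (normalized, same strand split as the calls) are provided.

    tracks: list over replicates of (plus_track, minus_track) tuples with
    normalized values filled; optional but required for rp10m_mean.
    """
    n_reps = len(per_replicate_calls)
    if min_reps > n_reps:
        raise ValueError(f"min_reps {min_reps} exceeds number of replicates {n_reps}")

    keys: dict[tuple[int, str], list[tuple[int, ReplicateCall]]] = {}
    for rep, calls in enumerate(per_replicate_calls):
        for c in calls:
            keys.setdefault((c.position, c.strand), []).append((rep, c))

    if position_tolerance > 0:
        keys = _cluster_keys(keys, position_tolerance)

    merged: list[SiteCall] = []
    for (pos, strand), hits in sorted(keys.items()):
        reps_detected = {rep for rep, _ in hits}
        if len(reps_detected) < min_reps:
            continue
        raw_counts = []
        rp10m_vals = []
        lambdas = []
        pvals = []
        per_rep = {rep: c for rep, c in hits}
        for rep in range(n_reps):
            if tracks is not None:
                tr = _track_for(tracks[rep], strand)
                raw_counts.append(int(tr.counts[pos]))
                if tr.normalized is not None:
                    rp10m_vals.append(float(tr.normalized[pos]))
            elif rep in per_rep:
                raw_counts.append(per_rep[rep].count)
            else:
                raw_counts.append(0)
            if rep in per_rep:
                lambdas.append(per_rep[rep].background_lambda)
                pvals.append(per_rep[rep].p_value)
        lam = float(np.mean(lambdas))
        # Fisher combination over the replicates that called the site
        _, p_comb = stats.combine_pvalues(np.clip(pvals, 1e-300, 1.0), method="fisher")
        mean_count = float(np.mean(raw_counts))
        merged.append(
            SiteCall(
                position=pos,
                strand=strand,
                raw_counts_by_replicate=raw_counts,
                rp10m_mean=float(np.mean(rp10m_vals)) if rp10m_vals else float("nan"),
                background_lambda=lam,
                enrichment=mean_count / lam if lam > 0 else float("inf"),
                p_value=float(p_comb),
                q_value=float("nan"),
                n_replicates_detected=len(reps_detected),
            )
        )
    if merged:
        qs = stats.false_discovery_control(np.clip([m.p_value for m in merged], 1e-300, 1.0))
        for m, q in zip(merged, qs):
            m.q_value = float(q)
    return merged


def _track_for(pair, strand: str) -> EndTrack:
    if isinstance(pair, EndTrack):
        return pair
    plus, minus = pair
    return plus if strand == "+" else minus


def _cluster_keys(keys, tol: int):
    """Greedy clustering of nearby per-replicate calls (tolerance > 0)."""
    out: dict[tuple[int, str], list] = {}
    by_strand: dict[str, list[tuple[int, list]]] = {}
    for (pos, strand), hits in keys.items():
        by_strand.setdefault(strand, []).append((pos, hits))
    for strand, items in by_strand.items():
        items.sort(key=lambda t: (-len(t[1]), t[0]))
        taken: list[int] = []
        for pos, hits in items:
            home = None
            for t in taken:
                if abs(t - pos) <= tol:
                    home = t
                    break
            if home is None:
                taken.append(pos)
                out[(pos, strand)] = list(hits)
            else:
                out[(home, strand)].extend(hits)
    return out


def annotate_sites(
    calls: list[SiteCall],
    ref: ReferenceModel,
    tolerance: int = 0,
) -> list[SiteCall]:
    """Label calls with canonical site names (same strand, within
    tolerance; nearest canonical site wins, leftmost on a distance tie);
    everything else is 'novel'."""
    out = []
    for c in calls:
        best_label = "novel"
        best_dist = tolerance + 1
        for s in sorted(ref.canonical_sites, key=lambda s: s.position):
            if s.strand != c.strand:
                continue
            d = abs(s.position - c.position)
            if d <= tolerance and d < best_dist:
                best_label, best_dist = s.label, d
        out.append(replace_label(c, best_label))
    return out


def replace_label(call: SiteCall, label: str) -> SiteCall:
    return replace(call, label=label)


def calls_table_rows(calls: list[SiteCall]):
    for c in calls:
        yield {
            "position": c.position,
            "strand": c.strand,
            "label": c.label,
            "counts": ",".join(map(str, c.raw_counts_by_replicate)),
            "rp10m_mean": c.rp10m_mean,
            "lambda": c.background_lambda,
            "enrichment": c.enrichment,
            "p": c.p_value,
            "q": c.q_value,
            "n_reps": c.n_replicates_detected,
        }
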