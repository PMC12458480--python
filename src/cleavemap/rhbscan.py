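"""Antisense complementarity search between lncRNAs and a target RNA.

A seed is an exact (or bounded-mismatch) Watson-Crick reverse-complement
match of k consecutive lncRNA bases to a target window; GU wobbles do not
count as matches inside the seed.  Seeds are extended in both directions
counting Watson-Crick matches (+1) and GU wobbles (+0.5) against included
mismatches (-1), stopping at two consecutive non-pairing positions, at a
mismatch budget, or at a sequence end, then trimming back to the last
pairing position.  Both orientations of each lncRNA are scanned.

This is a defined seed-and-extend procedure, not a thermodynamic
interaction model: scores are dimensionless counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._util import revcomp, to_dna

# Watson-Crick and GU pairing in DNA space (T stands for U)
_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "T"), ("T", "G")}

DEFAULT_SEED_LEN = 14
DEFAULT_MIN_SCORE = 18.0


@dataclass(frozen=True)
class SeedMatch:
    lncrna_id: str
    orientation: str  # '+': lncRNA as given; '-': its reverse complement
    query_start: int  # on the oriented query sequence
    target_start: int
    k: int
    mismatches: int


@dataclass(frozen=True)
class RhbHit:
    lncrna_id: str
    orientation: str
    query_interval: tuple[int, int]  # on the original lncRNA, 0-based half-open
    target_interval: tuple[int, int]
    seed_len: int
    seed_mismatches: int
    duplex_len: int
    matches: int
    gu_pairs: int
    mismatches: int
    score: float


def _oriented(seq: str, orientation: str) -> str:
    return seq if orientation == "+" else revcomp(seq)


def _to_original_interval(start: int, end: int, orientation: str, length: int) -> tuple[int, int]:
    if orientation == "+":
        return start, end
    return length - end, length - start


def seed_scan(
    catalog: Sequence[tuple[str, str]],
    target: str,
    k: int = DEFAULT_SEED_LEN,
    max_seed_mismatches: int = 0,
    orientations: str = "both",
) -> list[SeedMatch]:
    """All length-k lncRNA windows whose reverse complement matches a
    target window with at most max_seed_mismatches mismatches.

    Records shorter than k are skipped with a warning.  Hits are sorted by
    (lncrna_id, orientation, query_start, target_start).
    """
    if k < 6:
        raise ValueError("seed length k must be >= 6")
    target = to_dna(target)
    if len(target) < k:
        raise ValueError("target shorter than the seed length")
    oris = ("+", "-") if orientations == "both" else (orientations,)

    hits: list[SeedMatch] = []
    if max_seed_mismatches == 0:
        index: dict[str, list[int]] = {}
        for t in range(len(target) - k + 1):
            index.setdefault(target[t : t + k], []).append(t)
    else:
        t_arr = np.frombuffer(target.encode(), dtype=np.uint8)
        t_windows = np.lib.stride_tricks.sliding_window_view(t_arr, k)

    for rid, raw in catalog:
        seq = to_dna(raw)
        if len(seq) < k:
            warnings.warn(f"record {rid} shorter than seed length {k}; skipped")
            continue
        for ori in oris:
            q = _oriented(seq, ori)
            for qs in range(len(q) - k + 1):
                probe = revcomp(q[qs : qs + k])
                if max_seed_mismatches == 0:
                    for t in index.get(probe, ()):
                        hits.append(SeedMatch(rid, ori, qs, t, k, 0))
                else:
                    p_arr = np.frombuffer(probe.encode(), dtype=np.uint8)
                    mm = (t_windows != p_arr).sum(axis=1)
                    for t in np.nonzero(mm <= max_seed_mismatches)[0]:
                        hits.append(SeedMatch(rid, ori, qs, int(t), k, int(mm[t])))
    return sorted(hits, key=lambda h: (h.lncrna_id, h.orientation, h.query_start, h.target_start))


def _pair_kind(qb: str, tb: str, allow_gu: bool) -> str:
    if (qb, tb) in _WC:
        return "wc"
    if allow_gu and (qb, tb) in _GU:
        return "gu"
    return "mm"


def extend_duplex(
    hit: SeedMatch,
    lncrna_seq: str,
    target_seq: str,
    allow_gu: bool = True,
    max_extension_mismatches: int = 2,
    stop_after: int = 2,
) -> RhbHit:
    """Extend a seed match into a full duplex and score it.

    Within the antisense geometry, oriented-query position qs+i pairs
    target position te-1-i; extension therefore walks the query leftwards
    while walking the target rightwards, and vice versa.  score =
    matches + 0.5*gu_pairs - mismatches over the final (trimmed) duplex.
    """
    lnc = to_dna(lncrna_seq)
    tgt = to_dna(target_seq)
    q = _oriented(lnc, hit.orientation)
    qs, qe = hit.query_start, hit.query_start + hit.k
    ts, te = hit.target_start, hit.target_start + hit.k

    # pairing states of the seed itself
    states = [_pair_kind(q[qs + i], tgt[te - 1 - i], allow_gu=False) for i in range(hit.k)]
    # seed positions are WC-or-mismatch by definition (GU not credited in the seed)

    def _extend(step_q: int):
        nonlocal qs, qe, ts, te, states
        added: list[str] = []
        consec_mm = 0
        total_mm = 0
        while True:
            if step_q < 0:
                nq, nt = qs - 1, te
                if nq < 0 or nt >= len(tgt):
                    break
            else:
                nq, nt = qe, ts - 1
                if nq >= len(q) or nt < 0:
                    break
            kind = _pair_kind(q[nq], tgt[nt], allow_gu)
            if kind == "mm":
                consec_mm += 1
                total_mm += 1
                if consec_mm >= stop_after or total_mm > max_extension_mismatches:
                    break
            else:
                consec_mm = 0
            added.append(kind)
            if step_q < 0:
                qs, te = nq, nt + 1
            else:
                qe, ts = nq + 1, nt
        # trim trailing mismatches at the freshly extended edge
        while added and added[-1] == "mm":
            added.pop()
            if step_q < 0:
                qs, te = qs + 1, te - 1
            else:
                qe, ts = qe - 1, ts + 1
        if step_q < 0:
            states = added[::-1] + states
        else:
            states = states + added

    _extend(-1)
    _extend(+1)

    matches = states.count("wc")
    gu = states.count("gu")
    mm = states.count("mm")
    qlo, qhi = _to_original_interval(qs, qe, hit.orientation, len(lnc))
    return RhbHit(
        lncrna_id=hit.lncrna_id,
        orientation=hit.orientation,
        query_interval=(qlo, qhi),
        target_interval=(ts, te),
        seed_len=hit.k,
        seed_mismatches=hit.mismatches,
        duplex_len=qe - qs,
        matches=matches,
        gu_pairs=gu,
        mismatches=mm,
        score=matches + 0.5 * gu - mm,
    )


def rank_hits(hits: Sequence[RhbHit], min_score: float = DEFAULT_MIN_SCORE) -> list[RhbHit]:
    """Filter by score and rank: descending score, longer duplex first,
    then leftmost target position."""
    kept = [h for h in hits if h.score >= min_score]
    return sorted(kept, key=lambda h: (-h.score, -h.duplex_len, h.target_interval[0], h.lncrna_id))


def scan_catalog(
    catalog: Sequence[tuple[str, str]],
    target: str,
    k: int = DEFAULT_SEED_LEN,
    max_seed_mismatches: int = 0,
    min_score: float = DEFAULT_MIN_SCORE,
    allow_gu: bool = True,
) -> list[RhbHit]:
    """seed_scan + extend_duplex + rank_hits in one call."""
    seqs = {rid: seq for rid, seq in catalog}
    seeds = seed_scan(catalog, target, k=k, max_seed_mismatches=max_seed_mismatches)
    hits = [extend_duplex(s, seqs[s.lncrna_id], target, allow_gu=allow_gu) for s in seeds]
    return rank_hits(_dedupe(hits), min_score=min_score)


def _dedupe(hits: list[RhbHit]) -> list[RhbHit]:
    """Collapse overlapping seeds that extended to the identical duplex."""
    seen: set[tuple] = set()
    out = []
    for h in hits:
        key = (h.lncrna_id, h.orientation, h.query_interval, h.target_interval)
        if key not in seen:
            seen.add(key)
            out.append(h)
    return out


def alignment_view(hit: RhbHit, lncrna_seq: str, target_seq: str) -> str:
    """Text rendering of the duplex (query shown 3'->5' under the target)."""
    lnc = to_dna(lncrna_seq)
    tgt = to_dna(target_seq)
    q = _oriented(lnc, hit.orientation)
    qlo, qhi = hit.query_interval
    if hit.orientation == "-":
        qlo, qhi = len(lnc) - hit.query_interval[1], len(lnc) - hit.query_interval[0]
    ts, te = hit.target_interval
    top = tgt[ts:te]
    bottom = q[qlo:qhi][::-1]
    rail = []
    for a, b in zip(top, bottom):
        kind = _pair_kind(b, a, True)
        rail.append("|" if kind == "wc" else (":" if kind == "gu" else " "))
    return (
        f"target 5'-{top}-3'  [{ts},{te})\n"
        f"          {''.join(rail)}\n"
        f"query  3'-{bottom}-5'  {hit.lncrna_id}({hit.orientation}) [{hit.query_interval[0]},{hit.query_interval[1]})"
    )
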