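"""RNA secondary structure and RNase III cut-pair geometry.

RNase III enzymes cleave both strands of an RNA helix, leaving products
whose 3' ends protrude.  With 5'-monophosphate coordinates (a cut lies
between position-1 and position), a sense cut at i across a helix from an
antisense cut at j has overhang offset

    d = j - partner[i] - 1

where partner[i] is the base paired with i.  d = 0 is a blunt cut, d = 1 a
1-nt 3' overhang, and d = 2 the canonical Dicer/RNase III 2-nt 3'
overhang; anything else is non-canonical.

Structures come from the built-in maximum-pairing (Nussinov) folder or
from dot-bracket strings produced by external thermodynamic folders.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .endmap import EndTrack

_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "U"), ("U", "G")}

KLASS_BY_OFFSET = {0: "blunt", 1: "overhang1", 2: "overhang2"}


def _can_pair(a: str, b: str, allow_gu: bool) -> bool:
    return (a, b) in _PAIRS or (allow_gu and (a, b) in _GU)


@dataclass
class PairTable:
    """Nested secondary structure: partner[i] = paired index or -1."""

    sequence: str
    partner: np.ndarray
    min_loop: int = 3

    def __post_init__(self) -> None:
        self.partner = np.asarray(self.partner, dtype=np.int64)
        n = len(self.sequence)
        if self.partner.size != n:
            raise ValueError("partner vector length differs from sequence length")
        for i, j in enumerate(self.partner):
            if j < 0:
                continue
            if self.partner[j] != i:
                raise ValueError(f"partner is not an involution at {i}")
            if abs(i - j) < self.min_loop + 1:
                raise ValueError(f"pair ({i},{j}) violates min_loop {self.min_loop}")
        self._check_nested()

    def _check_nested(self) -> None:
        stack: list[int] = []
        for i, j in enumerate(self.partner):
            if j > i:
                stack.append(int(j))
            elif 0 <= j < i:
                if not stack or stack[-1] != i:
                    raise ValueError(f"crossing pair at {i}")
                stack.pop()

    @property
    def n_pairs(self) -> int:
        return int((self.partner >= 0).sum()) // 2

    def to_dotbracket(self) -> str:
        out = []
        for i, j in enumerate(self.partner):
            out.append("." if j < 0 else ("(" if j > i else ")"))
        return "".join(out)


def parse_dotbracket(sequence: str, structure: str, min_loop: int = 0) -> PairTable:
    """Pair table from a Vienna dot-bracket string.

    Raises ValueError with the offending index for unbalanced input.
    min_loop defaults to 0 here so that externally folded structures are
    accepted verbatim.
    """
    if len(sequence) != len(structure):
        raise ValueError("sequence and structure lengths differ")
    partner = np.full(len(sequence), -1, dtype=np.int64)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at index {i}")
            j = stack.pop()
            partner[i], partner[j] = j, i
        elif ch != ".":
            raise ValueError(f"invalid structure character {ch!r} at index {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at index {stack[0]}")
    return PairTable(sequence, partner, min_loop=min_loop)


def fold_nussinov(sequence: str, min_loop: int = 3, allow_gu: bool = True) -> PairTable:
    """Maximum base-pairing fold (Nussinov dynamic programming).

    Maximizes the number of AU/GC (and optionally GU) pairs subject to
    nesting and a minimum hairpin loop.  Traceback is deterministic: at
    each subinterval the 5' base is paired if any optimal structure pairs
    it, with the smallest admissible partner index.
    """
    seq = sequence.upper()
    if len(seq) == 0:
        raise ValueError("empty sequence")
    if set(seq) - set("ACGU"):
        raise ValueError(f"invalid residues for RNA folding: {sorted(set(seq) - set('ACGU'))}")
    n = len(seq)
    M = np.zeros((n + 1, n + 1), dtype=np.int32)  # M[i][j]: s[i..j] inclusive
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if _can_pair(seq[i], seq[k], allow_gu):
                    cand = 1 + M[i + 1][k - 1] + (M[k + 1][j] if k < j else 0)
                    if cand > best:
                        best = cand
            M[i][j] = best
    partner = np.full(n, -1, dtype=np.int64)
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        if M[i][j] == 0:
            continue
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            if _can_pair(seq[i], seq[k], allow_gu):
                cand = 1 + M[i + 1][k - 1] + (M[k + 1][j] if k < j else 0)
                if cand == M[i][j]:
                    partner[i], partner[k] = k, i
                    stack.append((i + 1, k - 1))
                    if k < j:
                        stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return PairTable(seq, partner, min_loop=min_loop)


@dataclass(frozen=True)
class DuplexSignature:
    sense_cut: int  # 5'P position of the sense-strand cut
    antisense_cut: int  # 5'P position of the antisense-strand cut
    offset: int  # d = antisense_cut - partner[sense_cut] - 1
    klass: str
    sense_count: int = 0
    antisense_count: int = 0
    region: tuple[int, int] | None = None


def classify_cut_pair(pt: PairTable, i: int, j: int) -> DuplexSignature:
    """Classify the 3'-overhang geometry of a sense/antisense cut pair.

    i and j are 5'P positions (cuts between position-1 and position) in
    the pair table's coordinates.  Raises ValueError when the sense cut
    does not sit on a helix (i unpaired).
    """
    n = len(pt.sequence)
    if not (0 < i <= n) or not (0 < j <= n):
        raise ValueError(f"cut positions must be in (0, {n}]")
    if i >= n or pt.partner[i] < 0:
        raise ValueError(f"no helix at sense cut {i}")
    d = int(j - pt.partner[i] - 1)
    return DuplexSignature(i, j, d, KLASS_BY_OFFSET.get(d, "noncanonical"))


OFFSET_WINDOW = (-2, 4)


def scan_signatures(
    plus_track: EndTrack,
    minus_track: EndTrack,
    pt_by_region: Mapping[tuple[int, int], PairTable],
    min_count: int = 10,
    offset_window: tuple[int, int] = OFFSET_WINDOW,
) -> list[DuplexSignature]:
    """Pair sense and antisense 5'-end peaks across annotated helices.

    For every sense peak (plus-strand count >= min_count) that lies on a
    helix of a region's structure, antisense peaks are searched within the
    offset window; the pair with the highest joint count is reported (ties:
    smaller |d|, then smaller antisense position).  Coordinates in the
    result are reference coordinates.
    """
    lo_d, hi_d = offset_window
    out: list[DuplexSignature] = []
    for (start, end), pt in sorted(pt_by_region.items()):
        if len(pt.sequence) != end - start:
            raise ValueError(f"pair table length mismatch for region ({start},{end})")
        sense = [p for p in np.nonzero(plus_track.counts[start:end] >= min_count)[0]]
        anti = [q for q in np.nonzero(minus_track.counts[start:end] >= min_count)[0]]
        for li in sense:
            if pt.partner[li] < 0:
                continue
            best = None
            for lj in anti:
                d = int(lj - pt.partner[li] - 1)
                if not (lo_d <= d <= hi_d):
                    continue
                joint = int(plus_track.counts[start + li] + minus_track.counts[start + lj])
                key = (-joint, abs(d), lj)
                if best is None or key < best[0]:
                    best = (key, lj, d)
            if best is not None:
                _, lj, d = best
                out.append(
                    DuplexSignature(
                        sense_cut=start + int(li),
                        antisense_cut=start + int(lj),
                        offset=d,
                        klass=KLASS_BY_OFFSET.get(d, "noncanonical"),
                        sense_count=int(plus_track.counts[start + li]),
                        antisense_count=int(minus_track.counts[start + lj]),
                        region=(start, end),
                    )
                )
    return sorted(out, key=lambda s: (s.sense_cut, s.antisense_cut))


@dataclass(frozen=True)
class SmallRnaSignature:
    signature: DuplexSignature
    sense_matches_site: bool
    antisense_matches_site: bool


def smallrna_duplex_signature(
    smallrna_plus: EndTrack,
    smallrna_minus: EndTrack,
    pt_by_region: Mapping[tuple[int, int], PairTable],
    read_lengths: Sequence[int] | None = None,
    min_count: int = 1,
    site_positions: Iterable[tuple[int, str]] = (),
) -> list[SmallRnaSignature]:
    """Duplex geometry of Ago-loaded small-RNA 5' ends.

    Applies the scan_signatures geometry to small-RNA 5'-end tracks and
    reports, per signature, whether each small-RNA 5' end coincides (same
    nucleotide, same strand) with a degradome 5'P site from
    `site_positions` [(position, strand), ...].  read_lengths is accepted
    for interface symmetry with the library design; the 5'-end geometry
    alone determines the overhang class.
    """
    del read_lengths
    sigs = scan_signatures(smallrna_plus, smallrna_minus, pt_by_region, min_count=min_count)
    sites = set(site_positions)
    return [
        SmallRnaSignature(
            s,
            sense_matches_site=(s.sense_cut, "+") in sites,
            antisense_matches_site=(s.antisense_cut, "-") in sites,
        )
        for s in sigs
    ]


def signatures_table_rows(sigs: Iterable[DuplexSignature]):
    for s in sigs:
        yield {
            "sense_cut": s.sense_cut,
            "antisense_cut": s.antisense_cut,
            "offset": s.offset,
            "klass": s.klass,
            "sense_count": s.sense_count,
            "antisense_count": s.antisense_count,
            "region": "NA" if s.region is None else f"{s.region[0]}-{s.region[1]}",
        }
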