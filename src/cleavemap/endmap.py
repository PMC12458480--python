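"""Read alignment and strand-aware per-base 5'-end count tracks.

The aligner is a deliberate desk-scale stand-in: ungapped exact (or
bounded-mismatch) search of each read against both strands of a single
short reference.  Placement policy for multi-mapping reads: the plus
strand is preferred over the minus strand, and within a strand the
leftmost position wins; multi-mapping reads are flagged.

Track conventions: a plus-strand read contributes one 5'-end event at its
alignment start; a minus-strand read's biological 5' end sits at
start + read_length - 1 on the reference.  Normalization is RP10M (reads
per ten million aligned 5'-end events, both strands pooled), so the two
normalized strand tracks of a library always sum to 1e7.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from ._util import revcomp, to_dna
from .reference import ReferenceModel
from .simulate import ReadLibrary

RP10M = 10_000_000.0


@dataclass(frozen=True)
class Alignment:
    read_id: str
    ref_name: str
    start: int  # leftmost reference coordinate, 0-based
    strand: str  # '+' or '-'
    matched: bool
    read_len: int
    multimapped: bool = False


@dataclass
class EndTrack:
    """Per-base 5'-end counts on one strand of the reference.

    total_aligned counts aligned reads over *both* strands of the library
    this track came from, so RP10M values of the strand pair are jointly
    normalized.
    """

    ref_name: str
    strand: str
    counts: np.ndarray
    total_aligned: int
    normalized: np.ndarray | None = None

    @property
    def length(self) -> int:
        return int(self.counts.size)


def _count_occurrences(ref_seq: str, sub: str) -> tuple[int, int]:
    """(first occurrence or -1, number of occurrences capped at 2)."""
    first = ref_seq.find(sub)
    if first < 0:
        return -1, 0
    second = ref_seq.find(sub, first + 1)
    return first, 1 if second < 0 else 2


def _mismatch_scan(ref_arr: np.ndarray, read: str, max_mm: int) -> list[int]:
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    L = r.size
    if L > ref_arr.size:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(ref_arr, L)
    mm = (windows != r).sum(axis=1)
    return np.nonzero(mm <= max_mm)[0].tolist()


def align_reads(
    ref: ReferenceModel,
    library: ReadLibrary | list[tuple[str, str]],
    max_mismatches: int = 0,
) -> list[Alignment]:
    """Align every read of a library (or [(id, seq), ...]) to the reference.

    U residues are treated as T.  Unalignable reads are reported with
    matched=False.  Raises ValueError on an empty reference.
    """
    if len(ref.sequence) == 0:
        raise ValueError("empty reference")
    if isinstance(library, ReadLibrary):
        items = list(zip(library.read_ids(), library.sequences(ref)))
    else:
        items = [(rid, seq) for rid, seq in library]

    ref_seq = ref.sequence
    ref_arr = np.frombuffer(ref_seq.encode(), dtype=np.uint8) if max_mismatches > 0 else None
    out: list[Alignment] = []
    for rid, raw in items:
        read = to_dna(raw)
        if not read or set(read) - set("ACGT"):
            raise ValueError(f"read {rid}: invalid sequence {raw!r}")
        if max_mismatches == 0:
            p_pos, p_n = _count_occurrences(ref_seq, read)
            m_pos, m_n = _count_occurrences(ref_seq, revcomp(read))
        else:
            plus = _mismatch_scan(ref_arr, read, max_mismatches)
            minus = _mismatch_scan(ref_arr, revcomp(read), max_mismatches)
            p_pos, p_n = (plus[0], len(plus)) if plus else (-1, 0)
            m_pos, m_n = (minus[0], len(minus)) if minus else (-1, 0)
        n_hits = p_n + m_n
        if p_pos >= 0:
            out.append(Alignment(rid, ref.name, p_pos, "+", True, len(read), n_hits > 1))
        elif m_pos >= 0:
            out.append(Alignment(rid, ref.name, m_pos, "-", True, len(read), n_hits > 1))
        else:
            out.append(Alignment(rid, ref.name, -1, ".", False, len(read)))
    return out


def build_end_track(alignments: list[Alignment], ref: ReferenceModel) -> tuple[EndTrack, EndTrack]:
    """(plus, minus) 5'-end count tracks from alignments.

    Unmatched reads are excluded; the shared total_aligned is the number of
    matched reads.  Empty input yields zero tracks.
    """
    L = ref.length
    plus = np.zeros(L, dtype=np.int64)
    minus = np.zeros(L, dtype=np.int64)
    total = 0
    for a in alignments:
        if not a.matched:
            continue
        if a.ref_name != ref.name:
            raise ValueError(f"alignment {a.read_id} references {a.ref_name}, not {ref.name}")
        total += 1
        if a.strand == "+":
            plus[a.start] += 1
        else:
            minus[min(a.start + a.read_len - 1, L - 1)] += 1
    return (
        EndTrack(ref.name, "+", plus, total),
        EndTrack(ref.name, "-", minus, total),
    )


def end_track_from_origins(library: ReadLibrary, ref: ReferenceModel) -> tuple[EndTrack, EndTrack]:
    """Exact 5'-end tracks straight from simulated ground-truth origins.

    Equivalent to align_reads + build_end_track for error-free reads (the
    aligner-oracle tests verify that identity); used where alignment cost
    is not the point.
    """
    L = ref.length
    is_minus = library.strands == "-"
    plus = np.bincount(library.origins[~is_minus], minlength=L).astype(np.int64)
    minus = np.bincount(library.origins[is_minus], minlength=L).astype(np.int64)
    total = library.n_reads
    return EndTrack(ref.name, "+", plus, total), EndTrack(ref.name, "-", minus, total)


def normalize_track(track: EndTrack) -> EndTrack:
    """Fill RP10M values: counts / total_aligned * 1e7 (zero when empty)."""
    if track.total_aligned > 0:
        norm = track.counts / track.total_aligned * RP10M
    else:
        norm = np.zeros_like(track.counts, dtype=float)
    return replace(track, counts=track.counts.copy(), normalized=norm)


def normalize_pair(pair: tuple[EndTrack, EndTrack]) -> tuple[EndTrack, EndTrack]:
    return normalize_track(pair[0]), normalize_track(pair[1])


# ---------------------------------------------------------------------------
# external interfaces

def write_bedgraph(track: EndTrack, path: str | Path, normalized: bool = False) -> None:
    vec = track.normalized if normalized else track.counts
    if normalized and vec is None:
        raise ValueError("track has no normalized values; call normalize_track first")
    with open(path, "w") as fh:
        for pos in np.nonzero(vec)[0]:
            v = vec[pos]
            val = f"{v:.6g}" if normalized else str(int(v))
            fh.write(f"{track.ref_name}\t{pos}\t{pos + 1}\t{val}\n")


def read_bedgraph(path: str | Path, ref: ReferenceModel, strand: str) -> EndTrack:
    counts = np.zeros(ref.length, dtype=np.int64)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, _end, value = line.split()[:4]
            if chrom != ref.name:
                raise ValueError(f"bedGraph record on {chrom}, expected {ref.name}")
            counts[int(start)] += int(round(float(value)))
    return EndTrack(ref.name, strand, counts, int(counts.sum()))


def tracks_from_bed6(path: str | Path, ref: ReferenceModel) -> tuple[EndTrack, EndTrack]:
    """Real-data ingestion path: BED6 of 5'-end positions.

    Each record contributes `score` events (score 0 or '.' counts as 1) at
    its start coordinate on its strand.
    """
    plus = np.zeros(ref.length, dtype=np.int64)
    minus = np.zeros(ref.length, dtype=np.int64)
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: BED6 requires 6 columns")
            chrom, start, _end, _name, score, strand = parts[:6]
            if chrom != ref.name:
                raise ValueError(f"{path}:{ln}: record on {chrom}, expected {ref.name}")
            n = 1 if score in (".", "0") else int(score)
            pos = int(start)
            if strand == "+":
                plus[pos] += n
            elif strand == "-":
                minus[pos] += n
            else:
                raise ValueError(f"{path}:{ln}: strand must be + or -")
    total = int(plus.sum() + minus.sum())
    return EndTrack(ref.name, "+", plus, total), EndTrack(ref.name, "-", minus, total)


def write_alignment_report(alignments: list[Alignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tref\tstart\tstrand\tmatched\tread_len\tmultimapped\n")
        for a in alignments:
            fh.write(
                f"{a.read_id}\t{a.ref_name}\t{a.start}\t{a.strand}\t"
                f"{int(a.matched)}\t{a.read_len}\t{int(a.multimapped)}\n"
            )
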