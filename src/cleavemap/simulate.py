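"""Synthetic 5'P read libraries, Ago-IP small-RNA duplexes, lncRNA catalog.

simulate_library draws each read's 5'-monophosphate end categorically over
the planted sites plus a uniform background, then takes the read sequence
verbatim from the reference (reverse complement for minus-strand origins),
truncated at the reference ends.  Reads are error-free by default (an
optional uniform substitution rate is available), which keeps the alignment
oracle exact.  Replicates are independent categorical draws: pure
multinomial noise, no overdispersion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._util import revcomp, rng_for
from .profiles import CleavageProfile
from .reference import ReferenceModel

DEFAULT_READ_LENGTH = 30


@dataclass
class ReadLibrary:
    """Simulated 5'P library: per-read ground-truth origins.

    origins[i] is the 5'-end reference coordinate of read i; strands[i] is
    '+' or '-'; site_index[i] indexes the profile site the read came from,
    or -1 for background decay.  Sequences are materialized lazily from the
    reference (plus-strand reads run rightwards from the origin, minus-
    strand reads leftwards, reverse-complemented).
    """

    condition: str
    replicate: int
    read_length: int
    origins: np.ndarray
    strands: np.ndarray  # '<U1'
    site_index: np.ndarray
    lengths: np.ndarray | None = None  # per-read lengths (small RNA); else read_length

    @property
    def n_reads(self) -> int:
        return int(self.origins.size)

    def read_length_of(self, i: int) -> int:
        return int(self.lengths[i]) if self.lengths is not None else self.read_length

    def sequence_of(self, i: int, ref: ReferenceModel) -> str:
        override = getattr(self, "_materialized", None)
        if override is not None:
            return override[i]
        p = int(self.origins[i])
        L = self.read_length_of(i)
        if self.strands[i] == "+":
            return ref.sequence[p : p + L]
        lo = max(0, p - L + 1)
        return revcomp(ref.sequence[lo : p + 1])

    def sequences(self, ref: ReferenceModel) -> list[str]:
        return [self.sequence_of(i, ref) for i in range(self.n_reads)]

    def read_ids(self) -> list[str]:
        return [f"{self.condition}_r{self.replicate}_{i}" for i in range(self.n_reads)]

    def to_fastq(self, path: str | Path, ref: ReferenceModel) -> None:
        with open(path, "w") as fh:
            for i in range(self.n_reads):
                seq = self.sequence_of(i, ref)
                fh.write(f"@{self.condition}_r{self.replicate}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")

    def realized_site_counts(self, profile: CleavageProfile) -> dict[str, int]:
        out = {s.label: 0 for s in profile.sites}
        out["background"] = 0
        for idx in self.site_index:
            if idx < 0:
                out["background"] += 1
            else:
                out[profile.sites[idx].label] += 1
        return out


@dataclass
class RhbPlant:
    """Ground truth of the planted lncRNA:target complementarity."""

    lncrna_id: str
    mutant_id: str
    query_interval: tuple[int, int]  # on the lncRNA, 0-based half-open
    seed_query_interval: tuple[int, int]
    target_interval: tuple[int, int]  # on the target RNA
    seed_target_interval: tuple[int, int]
    n_mismatches: int
    seed_len: int
    duplex_len: int


@dataclass
class GroundTruth:
    profile: CleavageProfile
    realized_counts: dict[str, dict[str, int]] = field(default_factory=dict)  # library key -> site -> n
    rhb_plant: RhbPlant | None = None

    def record(self, library: ReadLibrary) -> None:
        key = f"{library.condition}/rep{library.replicate}"
        counts = library.realized_site_counts(self.profile)
        if sum(counts.values()) != library.n_reads:
            raise AssertionError("realized counts do not sum to library depth")
        self.realized_counts[key] = counts

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "sites": [
                {
                    "label": s.label,
                    "position": s.position,
                    "strand": s.strand,
                    "efficiency_by_condition": s.efficiency_by_condition,
                }
                for s in self.profile.sites
            ],
            "conditions": [
                {"name": c.name, "n_replicates": c.n_replicates, "depth": c.depth}
                for c in self.profile.conditions
            ],
            "realized_counts": self.realized_counts,
            "rhb_plant": None if self.rhb_plant is None else vars(self.rhb_plant),
        }
        text = json.dumps(payload, indent=1, sort_keys=True, default=list)
        if path is not None:
            Path(path).write_text(text)
        return text

    def sites_bed(self, path: str | Path, ref: ReferenceModel, condition: str | None = None) -> None:
        """BED6 of planted sites; score = round(1000 * efficiency)."""
        cond = condition or self.profile.conditions[0].name
        with open(path, "w") as fh:
            for s in self.profile.sites:
                eff = s.efficiency_by_condition.get(cond, 0.0)
                fh.write(
                    f"{ref.name}\t{s.position}\t{s.position + 1}\t{s.label}\t{round(1000 * eff)}\t{s.strand}\n"
                )


def simulate_library(
    ref: ReferenceModel,
    profile: CleavageProfile,
    condition: str,
    replicate: int,
    seed: int = 42,
    read_length: int = DEFAULT_READ_LENGTH,
    substitution_rate: float = 0.0,
) -> ReadLibrary:
    """Draw one replicate library of 5'P reads for a condition.

    Each read's 5' end is a categorical draw over {planted sites} with
    probability equal to the site's efficiency, and a uniform plus-strand
    background taking the remaining mass.  Depth comes from the profile's
    condition design.  Deterministic for a given (seed, condition,
    replicate).
    """
    cond = profile.condition(condition)  # raises KeyError if unknown
    depth = cond.depth
    rng = rng_for(seed, "library", condition, replicate)

    sites, probs, bg_mass = profile.site_probabilities(condition)
    pvec = np.array(probs + [bg_mass], dtype=float)
    pvec = pvec / pvec.sum() if pvec.sum() > 0 else pvec
    if depth == 0:
        empty = np.empty(0, dtype=np.int64)
        return ReadLibrary(condition, replicate, read_length, empty, np.empty(0, dtype="<U1"), empty.copy())

    counts = rng.multinomial(depth, pvec)
    origins = np.empty(depth, dtype=np.int64)
    strands = np.empty(depth, dtype="<U1")
    site_index = np.empty(depth, dtype=np.int64)
    k = 0
    for i, s in enumerate(sites):
        n = counts[i]
        origins[k : k + n] = s.position
        strands[k : k + n] = s.strand
        site_index[k : k + n] = i
        k += n
    nbg = counts[-1]
    # background decay 5' ends: uniform over positions that support a
    # full-length read, so simulated reads stay uniquely alignable
    hi = max(1, ref.length - read_length + 1)
    origins[k:] = rng.integers(0, hi, size=nbg)
    strands[k:] = "+"
    site_index[k:] = -1
    perm = rng.permutation(depth)
    lib = ReadLibrary(condition, replicate, read_length, origins[perm], strands[perm], site_index[perm])
    if substitution_rate > 0:
        lib = _with_substitutions(lib, ref, substitution_rate, rng)
    return lib


def _with_substitutions(lib: ReadLibrary, ref: ReferenceModel, rate: float, rng) -> ReadLibrary:
    # materialized-sequence variant; origins/strands stay the ground truth
    seqs = []
    bases = np.array(list("ACGT"))
    for i in range(lib.n_reads):
        s = list(lib.sequence_of(i, ref))
        hits = np.nonzero(rng.random(len(s)) < rate)[0]
        for h in hits:
            s[h] = rng.choice(bases[bases != s[h]])
        seqs.append("".join(s))
    lib._materialized = seqs  # type: ignore[attr-defined]
    return lib


@dataclass(frozen=True)
class DuplexSpec:
    """A planted small-RNA duplex: sense/antisense 5'P positions and length.

    antisense_5p may be None for single-stranded small RNAs.  Read length
    must be in the Dicer-product range (20-24 nt).  The two reads must lie
    on opposite strands of one overlapping interval.
    """

    sense_5p: int
    antisense_5p: int | None
    length: int = 21

    def __post_init__(self) -> None:
        if not (20 <= self.length <= 24):
            raise ValueError("small-RNA length must be in [20, 24]")
        if self.antisense_5p is not None:
            s_lo, s_hi = self.sense_5p, self.sense_5p + self.length
            a_lo, a_hi = self.antisense_5p - self.length + 1, self.antisense_5p + 1
            if min(s_hi, a_hi) - max(s_lo, a_lo) <= 0:
                raise ValueError(
                    "duplex partners do not overlap: sense "
                    f"[{s_lo},{s_hi}) vs antisense [{a_lo},{a_hi})"
                )


def simulate_smallrna(
    ref: ReferenceModel,
    duplex_spec: Sequence[DuplexSpec],
    depth: int,
    seed: int = 42,
    condition: str = "smallrna",
    replicate: int = 1,
) -> ReadLibrary:
    """Ago-IP-style small-RNA library with 5' ends at the planted positions.

    Reads are split evenly across duplex entries, and within an entry
    across the two strands (all to the sense strand when antisense_5p is
    None).
    """
    origins: list[int] = []
    strands: list[str] = []
    lengths: list[int] = []
    if depth > 0 and duplex_spec:
        rng = rng_for(seed, "smallrna", condition, replicate)
        per_spec = rng.multinomial(depth, np.full(len(duplex_spec), 1.0 / len(duplex_spec)))
        for spec, n in zip(duplex_spec, per_spec):
            if spec.antisense_5p is None:
                n_sense, n_anti = n, 0
            else:
                n_sense = int(rng.binomial(n, 0.5))
                n_anti = n - n_sense
            origins += [spec.sense_5p] * n_sense + ([spec.antisense_5p] * n_anti if n_anti else [])
            strands += ["+"] * n_sense + ["-"] * n_anti
            lengths += [spec.length] * n
    return ReadLibrary(
        condition,
        replicate,
        read_length=21,
        origins=np.array(origins, dtype=np.int64),
        strands=np.array(strands, dtype="<U1"),
        site_index=np.full(len(origins), -1, dtype=np.int64),
        lengths=np.array(lengths, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# lncRNA catalog with a planted complementarity element

_PAIRS_WITH = {"A": {"T"}, "C": {"G"}, "G": {"C", "T"}, "T": {"A", "G"}}  # WC + GU (DNA space)


def _nonpairing_base(target_base: str) -> str:
    """A base that can neither Watson-Crick nor GU pair with target_base."""
    for b in "ACGT":
        if target_base not in _PAIRS_WITH[b]:
            return b
    raise AssertionError("unreachable")


def make_lncrna_catalog(
    ref: ReferenceModel,
    n_decoys: int = 20,
    rhb_target: tuple[int, int] = (20, 45),
    seed_len: int = 14,
    mutant_mismatches: int = 8,
    seed: int = 42,
    duplex_len: int = 25,
    lnc_len: int = 200,
) -> tuple[list[tuple[str, str]], RhbPlant]:
    """Catalog of lncRNAs: one planted antisense element, its seed mutant,
    and shuffled-composition decoys.

    The planted record carries the exact reverse complement of the
    duplex_len-nt target window starting at rhb_target[0]; the seed is the
    first seed_len nt of that window.  Flanking bases of the insert are
    chosen to be unable to pair (WC or GU) with the adjacent target bases,
    so the extendable complementarity is exactly duplex_len by
    construction.  The mutant record carries exactly mutant_mismatches
    substitutions inside the seed.  Returns ([(id, sequence), ...], plant).
    """
    t0, t1 = rhb_target
    if t1 - t0 < seed_len:
        raise ValueError(f"rhb_target length {t1 - t0} < seed_len {seed_len}")
    duplex_len = max(duplex_len, seed_len)
    if t0 + duplex_len > ref.length:
        raise ValueError("rhb_target duplex window exceeds the reference")
    if not (0 <= mutant_mismatches <= seed_len):
        raise ValueError("mutant_mismatches must be in [0, seed_len]")

    rng = rng_for(seed, "lncrna")
    target_window = ref.sequence[t0 : t0 + duplex_len]
    insert = revcomp(target_window)

    backbone = list(rng.choice(list("ACGT"), size=lnc_len))
    ipos = (lnc_len - duplex_len) // 2
    planted = backbone.copy()
    planted[ipos : ipos + duplex_len] = list(insert)
    # hard boundaries: two non-pairing bases on each flank of the insert.
    # Query position ipos-1-m pairs target position t0+duplex_len+m;
    # query position ipos+duplex_len+m pairs target position t0-1-m.
    for m in (0, 1):
        tpos = t0 + duplex_len + m
        if 0 <= tpos < ref.length and ipos - 1 - m >= 0:
            planted[ipos - 1 - m] = _nonpairing_base(ref.sequence[tpos])
        tpos = t0 - 1 - m
        if 0 <= tpos < ref.length and ipos + duplex_len + m < lnc_len:
            planted[ipos + duplex_len + m] = _nonpairing_base(ref.sequence[tpos])
    planted_seq = "".join(planted)

    # seed occupies the *last* seed_len nt of the insert (reverse complement
    # of the first seed_len nt of the target window).
    seed_q0 = ipos + duplex_len - seed_len
    seed_q1 = ipos + duplex_len
    mutant = list(planted_seq)
    # the 5'-most seed position is always mutated so that no exact seed
    # window of the mutant survives; the rest are drawn at random
    if mutant_mismatches >= 1:
        rest = rng.choice(np.arange(seed_q0 + 1, seed_q1), size=mutant_mismatches - 1, replace=False)
        mut_positions = sorted([seed_q0, *rest.tolist()])
    else:
        mut_positions = []
    for p in mut_positions:
        choices = [b for b in "ACGT" if b != mutant[p]]
        mutant[p] = str(rng.choice(choices))
    mutant_seq = "".join(mutant)

    records = [("lnc_rhb", planted_seq), ("lnc_rhb_mut", mutant_seq)]
    comp = np.array([ref.sequence.count(b) for b in "ACGT"], dtype=float)
    comp /= comp.sum()
    for i in range(n_decoys):
        records.append((f"decoy_{i + 1:02d}", "".join(rng.choice(list("ACGT"), size=lnc_len, p=comp))))

    plant = RhbPlant(
        lncrna_id="lnc_rhb",
        mutant_id="lnc_rhb_mut",
        query_interval=(ipos, ipos + duplex_len),
        seed_query_interval=(seed_q0, seed_q1),
        target_interval=(t0, t0 + duplex_len),
        seed_target_interval=(t0, t0 + seed_len),
        n_mismatches=mutant_mismatches,
        seed_len=seed_len,
        duplex_len=duplex_len,
    )
    return records, plant


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
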