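"""Toy collapsed rDNA transcription unit with annotated processing sites.

The reference emulates a single pre-rRNA transcription unit
(5'ETS-18S-ITS1-5.8S-ITS2-28S-3'ETS) at desk scale.  Canonical
endonucleolytic processing sites (TSS, A0, A1, hp3, B0, B', B1, C1) are
planted at fixed coordinates, and sites that biologically sit on double-
stranded hairpins (A0, B0/B', hp3) are embedded inside hairpin-forming
cassettes whose secondary structure is known by construction, so that
duplex-signature geometry can be tested against exact ground truth.

Coordinates are 0-based, half-open throughout.  A cleavage position is the
5'-monophosphate position: the index of the first nucleotide of the
downstream cleavage product (the scissile bond lies between position-1 and
position).  This matches BED conventions and keeps overhang algebra exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from ._util import rng_for

FEATURE_ORDER = ("5'ETS", "18S", "ITS1", "5.8S", "ITS2", "28S", "3'ETS")

DEFAULT_SEGMENT_LENGTHS: dict[str, int] = {
    "5'ETS": 700,
    "18S": 300,
    "ITS1": 150,
    "5.8S": 120,
    "ITS2": 150,
    "28S": 400,
    "3'ETS": 180,
}

#: stem arm / loop geometry of embedded hairpin cassettes (nt)
CASSETTE_ARM = 22
CASSETTE_LOOP = 6


@dataclass(frozen=True)
class Feature:
    label: str
    start: int  # 0-based inclusive
    end: int  # exclusive


@dataclass(frozen=True)
class CanonicalSite:
    label: str
    position: int  # 5'P position
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class HairpinCassette:
    """A planted perfect stem-loop: arm + loop + revcomp(arm).

    Arms are C/G-only and the loop is A-only, so in the cassette no base
    outside the designed stem can form a Watson-Crick or GU pair: the
    designed stem is the unique maximum-pairing structure.
    """

    label: str
    start: int
    arm: int = CASSETTE_ARM
    loop: int = CASSETTE_LOOP

    @property
    def end(self) -> int:
        return self.start + 2 * self.arm + self.loop

    @property
    def length(self) -> int:
        return 2 * self.arm + self.loop

    def partner_of(self, position: int) -> int:
        """Designed pairing partner of an absolute reference position."""
        k = position - self.start
        if not (0 <= k < self.length):
            raise ValueError(f"position {position} outside cassette {self.label}")
        j = self.length - 1 - k
        if k < self.arm or k >= self.arm + self.loop:
            return self.start + j
        return -1  # loop position, unpaired

    def dotbracket(self) -> str:
        return "(" * self.arm + "." * self.loop + ")" * self.arm


@dataclass(frozen=True)
class SiteSpec:
    """Requested site placement: offset within a named feature.

    hairpin_role:
      None    - site in single-stranded context
      'stem'  - site mid-way down the 5' arm of an embedded hairpin
      'tip'   - site near the loop of an embedded hairpin
    """

    label: str
    feature: str
    offset: int
    strand: str = "+"
    hairpin_role: str | None = None


#: offset of a 'stem'-role site within its cassette (on the 5' arm)
STEM_SITE_OFFSET = 10
#: offset of a 'tip'-role site within its cassette (2 nt below the loop)
TIP_SITE_OFFSET = CASSETTE_ARM - 2


@dataclass
class ReferenceModel:
    name: str
    sequence: str
    features: list[Feature]
    canonical_sites: list[CanonicalSite]
    cassettes: list[HairpinCassette] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        n = len(self.sequence)
        if set(self.sequence) - set("ACGT"):
            raise ValueError("reference sequence must be uppercase ACGT")
        labels = [f.label for f in self.features]
        if tuple(labels) != FEATURE_ORDER:
            raise ValueError(f"features must be exactly {FEATURE_ORDER} in order, got {labels}")
        pos = 0
        for f in self.features:
            if f.start != pos or f.end <= f.start:
                raise ValueError(f"features must tile the sequence; bad segment {f.label}")
            pos = f.end
        if pos != n:
            raise ValueError("features do not cover the full sequence")
        seen: set[str] = set()
        for s in self.canonical_sites:
            if s.label in seen:
                raise ValueError(f"duplicate site label {s.label}")
            seen.add(s.label)
            if not (0 <= s.position < n):
                raise ValueError(f"site {s.label} position {s.position} outside [0,{n})")
            if s.strand not in "+-":
                raise ValueError(f"site {s.label} strand must be + or -")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def feature(self, label: str) -> Feature:
        for f in self.features:
            if f.label == label:
                return f
        raise KeyError(label)

    def site(self, label: str) -> CanonicalSite:
        for s in self.canonical_sites:
            if s.label == label:
                return s
        raise KeyError(label)

    def cassette(self, label: str) -> HairpinCassette:
        for c in self.cassettes:
            if c.label == label:
                return c
        raise KeyError(label)

    # ---- serialization -------------------------------------------------

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            for i in range(0, len(self.sequence), width):
                fh.write(self.sequence[i : i + width] + "\n")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "name": self.name,
            "sequence": self.sequence,
            "features": [[f.label, f.start, f.end] for f in self.features],
            "canonical_sites": [[s.label, s.position, s.strand] for s in self.canonical_sites],
            "cassettes": [[c.label, c.start, c.arm, c.loop] for c in self.cassettes],
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ReferenceModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        d = json.loads(text)
        return cls(
            name=d["name"],
            sequence=d["sequence"],
            features=[Feature(*f) for f in d["features"]],
            canonical_sites=[CanonicalSite(*s) for s in d["canonical_sites"]],
            cassettes=[HairpinCassette(*c) for c in d.get("cassettes", [])],
        )


def _cassette_sequence(rng, arm: int = CASSETTE_ARM, loop: int = CASSETTE_LOOP) -> str:
    from ._util import revcomp

    left = "".join(rng.choice(list("CG"), size=arm))
    return left + "A" * loop + revcomp(left)


def make_reference(
    segment_lengths: Mapping[str, int] | None = None,
    site_spec: Sequence[SiteSpec] | None = None,
    seed: int = 42,
    name: str = "rdna_unit",
) -> ReferenceModel:
    """Build the toy rDNA unit with planted sites and hairpin cassettes.

    Deterministic for a given seed (byte-identical sequence).  Sites whose
    spec carries a hairpin_role get a stem-loop cassette embedded so the
    site falls at the role's designed offset inside the stem.

    Raises ValueError naming the offending site when an offset falls
    outside its feature, or when cassettes would overlap each other or a
    feature boundary.
    """
    segment_lengths = dict(segment_lengths or DEFAULT_SEGMENT_LENGTHS)
    if site_spec is None:
        site_spec = default_site_spec()
    missing = [k for k in FEATURE_ORDER if k not in segment_lengths]
    if missing:
        raise ValueError(f"missing segment lengths for {missing}")
    for label, ln in segment_lengths.items():
        if ln < 50:
            raise ValueError(f"segment {label} shorter than 50 nt")

    features: list[Feature] = []
    pos = 0
    for label in FEATURE_ORDER:
        features.append(Feature(label, pos, pos + segment_lengths[label]))
        pos += segment_lengths[label]
    total = pos
    fmap = {f.label: f for f in features}

    rng = rng_for(seed, "reference")
    seq = list(rng.choice(list("ACGT"), size=total))

    sites: list[CanonicalSite] = []
    cassettes: list[HairpinCassette] = []
    for spec in site_spec:
        if spec.feature not in fmap:
            raise ValueError(f"site {spec.label}: unknown feature {spec.feature}")
        f = fmap[spec.feature]
        if not (0 <= spec.offset < f.end - f.start):
            raise ValueError(
                f"site {spec.label}: offset {spec.offset} outside feature "
                f"{spec.feature} (length {f.end - f.start})"
            )
        abspos = f.start + spec.offset
        if spec.hairpin_role is not None:
            anchor = {"stem": STEM_SITE_OFFSET, "tip": TIP_SITE_OFFSET}.get(spec.hairpin_role)
            if anchor is None:
                raise ValueError(f"site {spec.label}: unknown hairpin_role {spec.hairpin_role}")
            cstart = abspos - anchor
            cass = HairpinCassette(spec.label, cstart)
            if cstart < f.start or cass.end > f.end:
                raise ValueError(f"site {spec.label}: hairpin cassette exceeds feature {spec.feature}")
            for other in cassettes:
                if cass.start < other.end and other.start < cass.end:
                    raise ValueError(f"site {spec.label}: cassette overlaps {other.label}")
            cassettes.append(cass)
            cseq = _cassette_sequence(rng_for(seed, "cassette", spec.label))
            seq[cass.start : cass.end] = list(cseq)
        sites.append(CanonicalSite(spec.label, abspos, spec.strand))

    return ReferenceModel(name, "".join(seq), features, sites, cassettes)


def default_site_spec() -> list[SiteSpec]:
    """Canonical processing sites plus six novel 5'ETS sites (14 total).

    TSS is the +1 transcription start; A0/hp3 and six novel sites sit in
    the 5'ETS; A1/B1/C1 are the mature 18S/5.8S/28S 5' ends; B0 and its
    antisense partner B' sit on the 3'ETS hairpin with the canonical 2-nt
    3'-overhang geometry (B' = designed partner of B0, offset +3, minus
    strand, giving d = 2).
    """
    spec = [
        SiteSpec("TSS", "5'ETS", 0),
        SiteSpec("n1", "5'ETS", 100),
        SiteSpec("n2", "5'ETS", 140),
        SiteSpec("n3", "5'ETS", 180),
        SiteSpec("hp3", "5'ETS", 300, hairpin_role="tip"),
        SiteSpec("n4", "5'ETS", 420),
        SiteSpec("n5", "5'ETS", 470),
        SiteSpec("n6", "5'ETS", 520),
        SiteSpec("A0", "5'ETS", 640, hairpin_role="stem"),
        SiteSpec("A1", "18S", 0),
        SiteSpec("B1", "5.8S", 0),
        SiteSpec("C1", "28S", 0),
        SiteSpec("B0", "3'ETS", 60, hairpin_role="stem"),
    ]
    # B' is the antisense cut paired with B0 across the 3'ETS hairpin:
    # 5'P at partner(B0) + 3 so that d = j - partner(i) - 1 = 2.
    b0_abs_offset = 60
    cass_start = b0_abs_offset - STEM_SITE_OFFSET
    partner_off = cass_start + (2 * CASSETTE_ARM + CASSETTE_LOOP - 1) - STEM_SITE_OFFSET - cass_start
    bprime_offset = cass_start + partner_off + 3
    spec.append(SiteSpec("B'", "3'ETS", bprime_offset, strand="-"))
    return spec


def novel13_site_spec() -> list[SiteSpec]:
    """Site layout with thirteen novel 5'ETS sites (21 sites total)."""
    novel = [SiteSpec(f"n{i + 1}", "5'ETS", off) for i, off in enumerate(
        (60, 100, 140, 180, 220, 420, 450, 480, 510, 540, 570, 600, 615)
    )]
    keep = [s for s in default_site_spec() if not s.label.startswith("n")]
    return sorted(keep + novel, key=lambda s: (s.feature != "5'ETS", s.offset))


def default_reference(seed: int = 42) -> ReferenceModel:
    return make_reference(DEFAULT_SEGMENT_LENGTHS, default_site_spec(), seed=seed)
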