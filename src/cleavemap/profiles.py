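"""Planted cleavage models: per-site, per-condition cleavage efficiencies.

A CleavageProfile assigns each planted site a per-condition efficiency,
interpreted directly as the probability that a sequenced 5'-monophosphate
end originates from that site.  The remaining probability mass
(1 - sum of efficiencies) is the background: exonucleolytic-decay 5' ends
spread uniformly over the transcribed (+) strand.  Keeping per-site
probabilities equal to the planted efficiencies across conditions makes
planted between-condition ratios recoverable without bias.

Preset profiles encode the study conditions: a quiescent wild type with a
6.8-fold A0-over-B0 preference, a Dicer-deletion condition with A0 cleavage
reduced to 10% and B0 to 21% of wild type (and all but one novel site
reduced to 10%), a cycling-cell preset with a 3.8-fold B0 preference, and a
four-condition preset in which hp3 cleavage is ordered
dcr1d < wt < ribocop_d = dcr1d_ribocop_d.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .reference import ReferenceModel

DEFAULT_DEPTH = 100_000
DEFAULT_REPLICATES = 3


@dataclass(frozen=True)
class Condition:
    name: str
    n_replicates: int = DEFAULT_REPLICATES
    depth: int = DEFAULT_DEPTH

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


@dataclass(frozen=True)
class SiteEfficiency:
    label: str
    position: int
    strand: str
    efficiency_by_condition: dict[str, float]


@dataclass
class CleavageProfile:
    sites: list[SiteEfficiency]
    conditions: list[Condition]
    background_rate: float | None = None  # nominal check; see background_mass()

    def __post_init__(self) -> None:
        names = [c.name for c in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError("duplicate condition names")
        for s in self.sites:
            for cond, eff in s.efficiency_by_condition.items():
                if not (0.0 <= eff <= 1.0):
                    raise ValueError(f"site {s.label}: efficiency {eff} outside [0,1] ({cond})")
        for c in self.conditions:
            tot = sum(s.efficiency_by_condition.get(c.name, 0.0) for s in self.sites)
            if tot > 1.0 + 1e-9:
                raise ValueError(f"condition {c.name}: site efficiencies sum to {tot} > 1")
            if self.background_rate is not None and tot + self.background_rate > 1.0 + 1e-9:
                raise ValueError(
                    f"condition {c.name}: efficiencies + background_rate exceed 1"
                )

    def condition(self, name: str) -> Condition:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(f"unknown condition {name!r}")

    def condition_names(self) -> list[str]:
        return [c.name for c in self.conditions]

    def background_mass(self, condition: str) -> float:
        """Background probability mass = 1 - sum of site efficiencies."""
        self.condition(condition)
        tot = sum(s.efficiency_by_condition.get(condition, 0.0) for s in self.sites)
        return max(0.0, 1.0 - tot)

    def site_probabilities(self, condition: str) -> tuple[list[SiteEfficiency], list[float], float]:
        """(sites, per-site probabilities, background mass); sums to 1."""
        probs = [s.efficiency_by_condition.get(condition, 0.0) for s in self.sites]
        return self.sites, probs, self.background_mass(condition)

    def efficiency(self, label: str, condition: str) -> float:
        for s in self.sites:
            if s.label == label:
                return s.efficiency_by_condition.get(condition, 0.0)
        raise KeyError(f"unknown site {label!r}")


# ---------------------------------------------------------------------------
# presets

_WT = {
    "TSS": 0.08,
    "A0": 0.068,
    "A1": 0.15,
    "hp3": 0.05,
    "B0": 0.010,
    "B'": 0.008,
    "B1": 0.13,
    "C1": 0.12,
}
_NOVEL_WT = 0.015

_DCR1D_FACTORS = {
    "TSS": 1.0,  # Pol I start, Dicer-independent
    "A0": 0.10,
    "A1": 0.40,
    "hp3": 0.20,
    "B0": 0.21,
    "B'": 0.21,
    "B1": 0.40,
    "C1": 0.40,
}


def _novel_labels(ref: ReferenceModel) -> list[str]:
    return [s.label for s in ref.canonical_sites if s.label.startswith("n")]


def default_profile(
    ref: ReferenceModel,
    n_replicates: int = DEFAULT_REPLICATES,
    depth: int = DEFAULT_DEPTH,
) -> CleavageProfile:
    """Two-condition (wt, dcr1d) profile over the reference's planted sites.

    In wt, sites carry 70% of the read mass (background 30%); all novel
    sites except the last are reduced to 10% in dcr1d, mirroring a
    "downregulated at all but one site" pattern.
    """
    novel = _novel_labels(ref)
    sites: list[SiteEfficiency] = []
    for s in ref.canonical_sites:
        if s.label in _WT:
            wt = _WT[s.label]
            mut = wt * _DCR1D_FACTORS[s.label]
        else:
            wt = _NOVEL_WT
            mut = wt * (1.0 if novel and s.label == novel[-1] else 0.10)
        sites.append(SiteEfficiency(s.label, s.position, s.strand, {"wt": wt, "dcr1d": mut}))
    conds = [Condition("wt", n_replicates, depth), Condition("dcr1d", n_replicates, depth)]
    return CleavageProfile(sites, conds)


def four_condition_profile(
    ref: ReferenceModel,
    n_replicates: int = DEFAULT_REPLICATES,
    depth: int = DEFAULT_DEPTH,
    hp3_efficiencies: dict[str, float] | None = None,
) -> CleavageProfile:
    """wt / dcr1d / ribocop_d / dcr1d_ribocop_d with ordered hp3 cleavage.

    hp3 planted efficiencies default to 0.05 (wt), 0.01 (dcr1d) and 0.15
    (both RiboCop deletions): inhibited without Dicer, up-regulated when
    the occluding lncRNA is gone.
    """
    hp3 = hp3_efficiencies or {"wt": 0.05, "dcr1d": 0.01, "ribocop_d": 0.15, "dcr1d_ribocop_d": 0.15}
    base = default_profile(ref, n_replicates, depth)
    sites: list[SiteEfficiency] = []
    for s in base.sites:
        eff = dict(s.efficiency_by_condition)
        eff["ribocop_d"] = eff["wt"]
        eff["dcr1d_ribocop_d"] = eff["dcr1d"]
        if s.label == "hp3":
            eff.update(hp3)
        sites.append(SiteEfficiency(s.label, s.position, s.strand, eff))
    conds = [Condition(n, n_replicates, depth) for n in ("wt", "dcr1d", "ribocop_d", "dcr1d_ribocop_d")]
    return CleavageProfile(sites, conds)


def cycling_profile(
    ref: ReferenceModel,
    n_replicates: int = DEFAULT_REPLICATES,
    depth: int = DEFAULT_DEPTH,
) -> CleavageProfile:
    """Cycling-cell preset: B0 is the preferred early site (B0/A0 = 3.8),
    and A0 cleavage is Dicer-independent (unchanged in dcr1d)."""
    sites: list[SiteEfficiency] = []
    for s in ref.canonical_sites:
        if s.label == "A0":
            wt = 0.020
            mut = wt
        elif s.label == "B0":
            wt = 0.076
            mut = wt
        elif s.label in _WT:
            wt = _WT[s.label]
            mut = wt
        else:
            wt = _NOVEL_WT
            mut = wt
        sites.append(
            SiteEfficiency(s.label, s.position, s.strand, {"cycling_wt": wt, "cycling_dcr1d": mut})
        )
    conds = [Condition("cycling_wt", n_replicates, depth), Condition("cycling_dcr1d", n_replicates, depth)]
    return CleavageProfile(sites, conds)


def ratio_profile(
    ref: ReferenceModel,
    r: float,
    site: str = "A0",
    n_replicates: int = DEFAULT_REPLICATES,
    depth: int = DEFAULT_DEPTH,
) -> CleavageProfile:
    """Two conditions identical except one site's efficiency scaled by r."""
    if not (0.0 <= r):
        raise ValueError("r must be >= 0")
    base = default_profile(ref, n_replicates, depth)
    sites = []
    for s in base.sites:
        wt = s.efficiency_by_condition["wt"]
        mut = wt * r if s.label == site else wt
        sites.append(SiteEfficiency(s.label, s.position, s.strand, {"wt": wt, "mut": mut}))
    conds = [Condition("wt", n_replicates, depth), Condition("mut", n_replicates, depth)]
    return CleavageProfile(sites, conds)
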