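"""End-to-end orchestration: simulate -> map -> call -> differential ->
duplex signatures -> RHB scan, from one config, with ground-truth scoring.

Every stage result lands in a RunReport; when an output directory is set,
stage outputs are also written as plain-text artifacts (FASTA, bedGraph,
TSV, JSON).  The report hash is a sha256 over a canonical JSON rendering
of the machine-readable results, so two runs with the same config and
seed are bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._util import canonical_json, sha256_of, to_rna
from . import __version__ as _version
from .diffcleave import PreferenceRatio, preference_ratio, site_matrix, test_differential, write_differential_tsv
from .duplexsig import (
    DuplexSignature,
    SmallRnaSignature,
    parse_dotbracket,
    scan_signatures,
    signatures_table_rows,
    smallrna_duplex_signature,
)
from .endmap import align_reads, build_end_track, end_track_from_origins, normalize_pair, write_bedgraph
from .profiles import CleavageProfile, default_profile, four_condition_profile
from .reference import ReferenceModel, default_reference, make_reference, default_site_spec, DEFAULT_SEGMENT_LENGTHS
from .rhbscan import RhbHit, scan_catalog
from .simulate import DuplexSpec, GroundTruth, make_lncrna_catalog, simulate_library, simulate_smallrna, write_fasta
from .sitecall import annotate_sites, call_track_pair, merge_replicates

log = logging.getLogger("cleavemap")


@dataclass
class RunConfig:
    seed: int = 42
    outdir: str | None = None
    segment_lengths: dict[str, int] | None = None
    profile: str = "default"  # 'default' | 'four_condition' preset name
    depth: int = 100_000
    n_replicates: int = 3
    read_length: int = 30
    align: bool = True
    write_reads: bool = False
    reference_condition: str = "wt"
    min_count: int = 10
    alpha_q: float = 0.01
    min_reps: int = 2
    pseudo_rp10m: float = 1.0
    signature_min_count: int = 10
    smallrna_depth: int = 2000
    rhb_n_decoys: int = 20
    rhb_min_score: float = 18.0

    def to_dict(self) -> dict:
        return {k: v for k, v in vars(self).items()}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls().to_dict())
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        return sha256_of(self.to_dict())


@dataclass
class RunReport:
    config: RunConfig
    reference: ReferenceModel
    profile: CleavageProfile
    truth: GroundTruth
    tracks: dict[str, list[tuple]] = field(default_factory=dict)
    merged_calls: dict[str, list] = field(default_factory=dict)
    matrix: pd.DataFrame | None = None
    differential: dict[str, pd.DataFrame] = field(default_factory=dict)
    preferences: list[PreferenceRatio] = field(default_factory=list)
    signatures: list[DuplexSignature] = field(default_factory=list)
    smallrna_signatures: list[SmallRnaSignature] = field(default_factory=list)
    rhb_hits: list[RhbHit] = field(default_factory=list)
    recovery: dict[str, dict] = field(default_factory=dict)
    stage_log: list[dict] = field(default_factory=list)

    def summary(self) -> dict:
        """Machine-readable results (the hashed payload)."""
        return {
            "version": _version,
            "seed": self.config.seed,
            "config_hash": self.config.config_hash,
            "n_sites_planted": len(self.profile.sites),
            "merged_calls": {
                cond: [[c.position, c.strand, c.label, c.raw_counts_by_replicate] for c in calls]
                for cond, calls in self.merged_calls.items()
            },
            "differential": {
                cond: df[["position", "strand", "label", "ratio_percent", "p_value", "q_value", "direction"]]
                .round(6)
                .to_dict("records")
                for cond, df in self.differential.items()
            },
            "preferences": [vars(p) for p in self.preferences],
            "signatures": [list(signatures_table_rows([s]))[0] for s in self.signatures],
            "smallrna_signatures": [
                {
                    **list(signatures_table_rows([s.signature]))[0],
                    "sense_matches_site": s.sense_matches_site,
                    "antisense_matches_site": s.antisense_matches_site,
                }
                for s in self.smallrna_signatures
            ],
            "rhb_hits": [vars(h) for h in self.rhb_hits],
            "recovery": self.recovery,
            "stages": self.stage_log,
        }

    @property
    def report_hash(self) -> str:
        return sha256_of(self.summary())


def _stage(report: RunReport, name: str, **counts) -> None:
    entry = {"stage": name, **counts}
    report.stage_log.append(entry)
    log.info("stage=%s %s", name, " ".join(f"{k}={v}" for k, v in counts.items()))


def _build_profile(config: RunConfig, ref: ReferenceModel) -> CleavageProfile:
    if config.profile == "default":
        return default_profile(ref, config.n_replicates, config.depth)
    if config.profile == "four_condition":
        return four_condition_profile(ref, config.n_replicates, config.depth)
    raise ValueError(f"unknown profile preset {config.profile!r}")


def run_pipeline(config: RunConfig, profile: CleavageProfile | None = None) -> RunReport:
    """Run every stage from one config; see module docstring.

    Any stage failure is re-raised annotated with the stage name.
    """
    stage = "setup"
    try:
        ref = make_reference(
            config.segment_lengths or DEFAULT_SEGMENT_LENGTHS, default_site_spec(), seed=config.seed
        )
        profile = profile or _build_profile(config, ref)
        truth = GroundTruth(profile)
        report = RunReport(config, ref, profile, truth)
        outdir = Path(config.outdir) if config.outdir else None
        if outdir:
            outdir.mkdir(parents=True, exist_ok=True)
            ref.to_fasta(outdir / "reference.fa")
            ref.to_json(outdir / "reference.json")
            config.to_yaml(outdir / "config.yaml")
        _stage(report, "reference", length=ref.length, sites=len(ref.canonical_sites))

        stage = "simulate"
        libraries: dict[str, list] = {}
        for cond in profile.conditions:
            libs = []
            for rep in range(1, cond.n_replicates + 1):
                lib = simulate_library(ref, profile, cond.name, rep, seed=config.seed, read_length=config.read_length)
                truth.record(lib)
                if outdir and config.write_reads:
                    lib.to_fastq(outdir / f"{cond.name}_rep{rep}.fastq", ref)
                libs.append(lib)
            libraries[cond.name] = libs
        if outdir:
            truth.sites_bed(outdir / "planted_sites.bed", ref)
        _stage(report, "simulate", libraries=sum(len(v) for v in libraries.values()))

        stage = "pileup"
        for cond, libs in libraries.items():
            pairs = []
            for lib in libs:
                if config.align:
                    alns = align_reads(ref, lib)
                    pair = build_end_track(alns, ref)
                else:
                    pair = end_track_from_origins(lib, ref)
                pair = normalize_pair(pair)
                if outdir:
                    write_bedgraph(pair[0], outdir / f"{cond}_rep{lib.replicate}_plus.bedgraph")
                    write_bedgraph(pair[1], outdir / f"{cond}_rep{lib.replicate}_minus.bedgraph")
                pairs.append(pair)
            report.tracks[cond] = pairs
        _stage(report, "pileup", conditions=len(report.tracks))

        stage = "call"
        for cond, pairs in report.tracks.items():
            per_rep = [
                call_track_pair(
                    pair, read_length=config.read_length,
                    min_count=config.min_count, alpha_q=config.alpha_q,
                )
                for pair in pairs
            ]
            merged = merge_replicates(per_rep, tracks=pairs, min_reps=min(config.min_reps, len(pairs)))
            report.merged_calls[cond] = annotate_sites(merged, ref)
        _stage(report, "call", **{c: len(v) for c, v in report.merged_calls.items()})

        stage = "recovery"
        for cond in report.merged_calls:
            report.recovery[cond] = score_recovery(report.merged_calls[cond], profile, cond)
        _stage(report, "recovery", **{c: round(v["recall"], 3) for c, v in report.recovery.items()})

        stage = "differential"
        report.matrix = site_matrix(report.merged_calls, report.tracks)
        ref_cond = config.reference_condition
        if ref_cond in report.tracks and not report.matrix.empty:
            for cond in report.tracks:
                if cond == ref_cond:
                    continue
                df = test_differential(report.matrix, ref_cond, cond, config.pseudo_rp10m)
                report.differential[cond] = df
                if outdir:
                    write_differential_tsv(df, outdir / f"differential_{cond}_vs_{ref_cond}.tsv")
            labels = set(report.matrix.index.get_level_values("label"))
            if {"A0", "B0"} <= labels:
                for cond in report.tracks:
                    report.preferences.append(
                        preference_ratio(report.matrix, cond, "A0", "B0", config.pseudo_rp10m)
                    )
        _stage(report, "differential", contrasts=len(report.differential))

        stage = "signature"
        pt_by_region = {
            (c.start, c.end): parse_dotbracket(to_rna(ref.sequence[c.start : c.end]), c.dotbracket())
            for c in ref.cassettes
        }
        pooled = _pooled_tracks(report.tracks.get(ref_cond, []))
        if pooled is not None:
            # restrict the scan to reproducibly called sites: signatures are a
            # property of called cleavage events, not of raw background piles
            masked = _mask_to_calls(pooled, report.merged_calls.get(ref_cond, []))
            report.signatures = scan_signatures(
                masked[0], masked[1], pt_by_region, min_count=config.signature_min_count
            )
        _stage(report, "signature", signatures=len(report.signatures))

        stage = "smallrna"
        if config.smallrna_depth > 0:
            duplexes = _designed_duplexes(ref)
            srna = simulate_smallrna(ref, duplexes, config.smallrna_depth, seed=config.seed)
            sr_pair = end_track_from_origins(srna, ref)
            called = {
                (c.position, c.strand) for calls in report.merged_calls.values() for c in calls
            }
            report.smallrna_signatures = smallrna_duplex_signature(
                sr_pair[0], sr_pair[1], pt_by_region, min_count=1, site_positions=called
            )
        _stage(report, "smallrna", signatures=len(report.smallrna_signatures))

        stage = "rhb_scan"
        catalog, plant = make_lncrna_catalog(ref, n_decoys=config.rhb_n_decoys, seed=config.seed)
        truth.rhb_plant = plant
        report.rhb_hits = scan_catalog(catalog, ref.sequence, min_score=config.rhb_min_score)
        if outdir:
            write_fasta(catalog, outdir / "lncrna_catalog.fa")
            truth.to_json(outdir / "ground_truth.json")
        _stage(report, "rhb_scan", hits=len(report.rhb_hits))

        if outdir:
            _write_tables(report, outdir)
            (outdir / "report.json").write_text(canonical_json(report.summary()))
            (outdir / "report.hash").write_text(report.report_hash + "\n")
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _pooled_tracks(pairs: list[tuple]):
    """Sum replicate tracks (raw counts) into one pooled pair."""
    if not pairs:
        return None
    from dataclasses import replace

    plus = replace(pairs[0][0], counts=sum(p[0].counts for p in pairs), normalized=None)
    minus = replace(pairs[0][1], counts=sum(p[1].counts for p in pairs), normalized=None)
    return plus, minus


def _mask_to_calls(pooled: tuple, merged_calls) -> tuple:
    """Zero every track position that is not a merged called site."""
    import numpy as np
    from dataclasses import replace

    plus, minus = pooled
    keep_plus = np.zeros_like(plus.counts, dtype=bool)
    keep_minus = np.zeros_like(minus.counts, dtype=bool)
    for c in merged_calls:
        (keep_plus if c.strand == "+" else keep_minus)[c.position] = True
    return (
        replace(plus, counts=np.where(keep_plus, plus.counts, 0)),
        replace(minus, counts=np.where(keep_minus, minus.counts, 0)),
    )


def _designed_duplexes(ref: ReferenceModel) -> list[DuplexSpec]:
    """Planted Ago-IP duplexes: the canonical 2-nt overhang at B0/B' and a
    1-nt-offset duplex at A0 (the A0/A1-like geometry)."""
    out = []
    try:
        b0 = ref.site("B0")
        cass = ref.cassette("B0")
        out.append(DuplexSpec(b0.position, cass.partner_of(b0.position) + 3, 21))  # d = 2
    except KeyError:
        pass
    try:
        a0 = ref.site("A0")
        cass = ref.cassette("A0")
        out.append(DuplexSpec(a0.position, cass.partner_of(a0.position) + 2, 21))  # d = 1
    except KeyError:
        pass
    return out


def score_recovery(merged_calls, profile: CleavageProfile, condition: str) -> dict:
    """Exact-position confusion counts of merged calls vs planted sites."""
    planted = {
        (s.position, s.strand)
        for s in profile.sites
        if s.efficiency_by_condition.get(condition, 0.0) > 0
    }
    called = {(c.position, c.strand) for c in merged_calls}
    tp = len(called & planted)
    return {
        "n_planted": len(planted),
        "n_called": len(called),
        "tp": tp,
        "recall": tp / len(planted) if planted else float("nan"),
        "precision": tp / len(called) if called else float("nan"),
    }


def hp3_contrast(
    report: RunReport,
    site: str = "hp3",
    conditions: tuple[str, ...] = ("wt", "dcr1d", "ribocop_d", "dcr1d_ribocop_d"),
) -> dict:
    """Per-condition RP10M at a site and whether the recovered ordering of
    condition means matches the planted efficiency ordering.

    Ties in planted efficiencies are treated as unordered within their
    tie group; with all efficiencies equal the result carries
    ordering=None ('no ordering').  Raises ValueError when a requested
    condition is missing or fewer than two conditions are given.
    """
    if len(conditions) < 2:
        raise ValueError("hp3 contrast needs at least two conditions")
    for cond in conditions:
        if cond not in report.tracks:
            raise ValueError(f"condition {cond!r} missing from the run")
    s = next((x for x in report.profile.sites if x.label == site), None)
    if s is None:
        raise ValueError(f"site {site!r} not planted")
    track_idx = 0 if s.strand == "+" else 1
    means = {}
    for cond in conditions:
        vals = [pair[track_idx].normalized[s.position] for pair in report.tracks[cond]]
        means[cond] = float(sum(vals) / len(vals))
    planted = {c: report.profile.efficiency(site, c) for c in conditions}
    if len(set(planted.values())) == 1:
        return {"site": site, "mean_rp10m": means, "planted": planted, "ordering": None, "matches_planted": None}
    recovered = sorted(conditions, key=lambda c: means[c])
    ok = all(
        planted[a] <= planted[b] for a, b in zip(recovered, recovered[1:])
    )
    return {
        "site": site,
        "mean_rp10m": means,
        "planted": planted,
        "ordering": recovered,
        "matches_planted": ok,
    }


def _write_tables(report: RunReport, outdir: Path) -> None:
    from .sitecall import calls_table_rows

    for cond, calls in report.merged_calls.items():
        pd.DataFrame(list(calls_table_rows(calls))).to_csv(outdir / f"sites_{cond}.tsv", sep="\t", index=False)
        with open(outdir / f"sites_{cond}.bed", "w") as fh:
            for c in calls:
                fh.write(
                    f"{report.reference.name}\t{c.position}\t{c.position + 1}\t{c.label}\t0\t{c.strand}\n"
                )
    if report.signatures:
        pd.DataFrame(list(signatures_table_rows(report.signatures))).to_csv(
            outdir / "signatures.tsv", sep="\t", index=False
        )
    if report.rhb_hits:
        pd.DataFrame([vars(h) for h in report.rhb_hits]).to_csv(outdir / "rhb_hits.tsv", sep="\t", index=False)
    if report.preferences:
        pd.DataFrame([vars(p) for p in report.preferences]).to_csv(
            outdir / "preference_ratios.tsv", sep="\t", index=False
        )
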