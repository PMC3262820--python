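"""End-to-end orchestration: simulate -> align -> filter -> call -> overlap -> RIP.

A *study* mirrors the original two-replicate design: one genome and truth
methylome, two independently sequenced libraries (different fragment sizes
and random streams), per-replicate conversion-rate calibration and binomial
calls, and a final verdict that only accepts methylcytosines found in both
replicates. Every run is a deterministic function of the study seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import filters, methcall, ripstats, simdata
from .bsalign import AlignmentSet, AlignParams, ReferenceSet, build_converted_references
from .methcall import CallerConfig
from .simdata import MethylomeTruth, RepeatTruthSet, SimConfig

log = logging.getLogger("hollowmeth")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Study-level configuration (serializable to/from YAML)."""

    sim: SimConfig = field(default_factory=SimConfig)
    significance_threshold: float = 0.01
    min_depth: int = 10
    correction_mode: str = "per_site"
    q_min: int = 20
    rip_min_len: int = 400
    control_name: str = simdata.CONTROL_NAME

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = SimConfig(**d.pop("sim", {}))
        return cls(sim=sim, **d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class ReplicateResult:
    replicate_id: int
    aln: AlignmentSet
    filter_report: filters.FilterReport
    pile: pd.DataFrame
    calls: pd.DataFrame
    conversion_rate_pct: float
    caller: CallerConfig
    report: dict


@dataclass
class StudyResult:
    config: RunConfig
    ref: ReferenceSet
    methylome: MethylomeTruth
    repeats: RepeatTruthSet
    replicates: list[ReplicateResult]
    overlap: pd.DataFrame
    report: dict


def run_replicate(
    config: RunConfig,
    replicate_id: int,
    ref: ReferenceSet,
    methylome: MethylomeTruth,
) -> ReplicateResult:
    """Sequence, map, filter and call one biological replicate."""
    if config.control_name not in ref.contigs:
        raise ConfigError(f"control contig {config.control_name!r} missing from reference")
    if config.control_name not in ref.control_names:
        raise ConfigError(f"contig {config.control_name!r} is not flagged as control")

    t0 = time.perf_counter()
    rep_sim = simdata.replicate_config(config.sim, replicate_id)
    reads, truth = simdata.simulate_bisulfite_reads(ref, methylome, rep_sim)
    log.info("replicate %d: simulated %d read pairs (%.1fs)", replicate_id, len(reads), time.perf_counter() - t0)

    t1 = time.perf_counter()
    conv = build_converted_references(ref)
    params = AlignParams.from_fragment_model(rep_sim.fragment_mean, rep_sim.fragment_sd, rep_sim.read_length)
    aln = align_reads(reads, conv, params)
    log.info("replicate %d: aligned %d/%d pairs (%.1fs)", replicate_id, len(aln), len(reads), time.perf_counter() - t1)

    filtered, freport = filters.apply_filters(aln, q_min=config.q_min)
    pile = methcall.pileup(filtered, ref)
    conv_rate = methcall.conversion_rate(pile, ref.control_names)
    p = 1.0 - conv_rate / 100.0
    # a perfectly converted control yields p=0; floor at half a count over
    # the control depth so the binomial test stays defined (conservative:
    # a smaller p could only make calls easier)
    control_n = int(pile.loc[pile["contig"].isin(ref.control_names), "depth"].sum())
    p = max(p, 0.5 / control_n)
    caller = CallerConfig(
        false_positive_rate=p,
        significance_threshold=config.significance_threshold,
        min_depth=config.min_depth,
        correction_mode=config.correction_mode,
    )
    genomic = pile[~pile["contig"].isin(ref.control_names)].reset_index(drop=True)
    calls = methcall.call_methylation(genomic, caller)
    summary = methcall.summarize_replicate(calls, pile, ref.control_names)
    report = {
        "replicate_id": replicate_id,
        "fragment_mean": rep_sim.fragment_mean,
        "n_read_pairs": len(reads),
        "n_aligned": len(aln),
        "filter": dataclasses.asdict(freport),
        "conversion_rate_pct": conv_rate,
        "false_positive_rate": p,
        "global_methylation_pct": 100.0 * methcall.global_methylation_level(genomic),
        "summary": summary,
    }
    log.info(
        "replicate %d: conversion %.3f%%, %d methylcytosine calls",
        replicate_id, conv_rate, summary["n_passed"],
    )
    return ReplicateResult(replicate_id, filtered, freport, pile, calls, conv_rate, caller, report)


def align_reads(reads: simdata.ReadPairBatch, conv, params: AlignParams) -> AlignmentSet:
    from .bsalign import align_pairs

    return align_pairs(reads.r1, reads.q1, reads.r2, reads.q2, conv, params, pair_ids=reads.ids)


def run_study(config: RunConfig) -> StudyResult:
    """Run the full two-replicate study from one config."""
    ref, repeats = simdata.simulate_genome(config.sim)
    methylome = simdata.simulate_methylome(ref, config.sim)
    reps = [run_replicate(config, rid, ref, methylome) for rid in (1, 2)]
    overlap = methcall.overlap_replicates(reps[0].calls, reps[1].calls)
    log.info("overlap: %d methylcytosines in both replicates", len(overlap))

    rip_section = _rip_section(ref, repeats, config.rip_min_len)
    report = {
        "config_digest": config.digest(),
        "seed": config.sim.seed,
        "replicates": [r.report for r in reps],
        "verdict": {
            "calls_rep1": int(reps[0].report["summary"]["n_passed"]),
            "calls_rep2": int(reps[1].report["summary"]["n_passed"]),
            "overlap_calls": int(len(overlap)),
            "conversion_rate_pct": [r.conversion_rate_pct for r in reps],
            "global_methylation_pct": [r.report["global_methylation_pct"] for r in reps],
        },
        "rip": rip_section,
    }
    return StudyResult(config, ref, methylome, repeats, reps, overlap, report)


def _rip_section(ref: ReferenceSet, repeats: RepeatTruthSet, min_len: int) -> dict:
    groups: dict[bool, list[ripstats.RepeatInterval]] = {False: [], True: []}
    for iv in repeats.intervals:
        groups[iv.rip_mutated].append(ripstats.RepeatInterval(iv.contig, iv.start, iv.end))
    dists = {
        flag: ripstats.rip_distribution(ref, ivs, min_len=min_len, species_label="rip" if flag else "plain")
        for flag, ivs in groups.items()
    }
    out = {
        "mean_index_unmutated": float(pd.Series(dists[False].indices).mean()) if dists[False].indices else None,
        "mean_index_rip": float(pd.Series(dists[True].indices).mean()) if dists[True].indices else None,
    }
    if len(dists[False].indices) >= 2 and len(dists[True].indices) >= 2:
        t, p = ripstats.rip_ttest(dists[True], dists[False])
        out["welch_t"] = t
        out["welch_p"] = p
    return out


def write_study(result: StudyResult, outdir) -> None:
    """Persist the study artifacts (FASTA/FASTQ/BED/TSV/JSON) to a directory."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.ref.to_fasta(out / "genome.fasta")
    result.repeats.to_bed(out / "repeats.bed")
    result.methylome.to_tsv(out / "truth_methylome.tsv")
    for rep in result.replicates:
        rep.calls.assign(position=rep.calls["position"] + 1).to_csv(
            out / f"calls_rep{rep.replicate_id}.tsv", sep="\t", index=False
        )
    result.overlap.assign(position=result.overlap["position"] + 1).to_csv(
        out / "overlap_calls.tsv", sep="\t", index=False
    )
    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, default=float)
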