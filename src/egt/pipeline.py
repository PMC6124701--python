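"""End-to-end orchestration: simulate -> assemble -> repeats -> transfers -> synteny.

Each stage writes its artifacts into the run directory in standard formats
(FASTA/FASTQ/GFF3/BED/TSV/JSON) and later stages read only those on-disk
artifacts, so any stage can be re-run from its inputs reproducibly.  A
single global seed is propagated to every stochastic stage.  The JSON run
report echoes every parameter and aggregates the headline tables; when a
truth manifest is present the report includes precision/recall of the
transfer calls against it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .assemble import AssemblyParams, assemble_genome
from .core import Genome, Interval, Role, write_bed6, write_fasta, write_gff3
from .homolog import HomologyParams
from .repeats import duplicated_length, find_exact_repeats
from .simulate import (
    GroundTruth,
    ReadSet,
    SimConfig,
    simulate_mitogenome,
    simulate_nuclear,
    simulate_plastome,
    simulate_reads,
    truth_features,
)
from .synteny import find_orfs, ribbon_map, stringent_params
from .transfers import (
    attribute_compartment,
    call_transfers,
    calls_to_bed,
    cluster_large_fragments,
    dedup_repeat_hits,
    summaries_to_table,
    summarize_by_chromosome,
)

REPORT_SCHEMA_VERSION = 1

# thresholds echoed for provenance in every run header
HEADLINE_THRESHOLDS = {
    "repeat_min_len": 100,
    "orf_min_len": 303,
    "cluster_min_large_len": 1000,
    "summary_sub_threshold": 250,
    "word_size": 11,
    "evalue_transfers": 1e-5,
    "evalue_structural": 1e-10,
    "max_hits": 50000,
    "min_depth_qc": 200,
}


class StageError(RuntimeError):
    pass


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "assemble", "repeats", "transfers", "synteny")
    sim: SimConfig = field(default_factory=SimConfig)
    assembly: AssemblyParams = field(default_factory=AssemblyParams)
    homology: HomologyParams = field(default_factory=HomologyParams)


def validate_against_truth(
    calls: Sequence, events: Sequence, reciprocal: float = 0.5
) -> dict[str, float]:
    """Overlap-based scoring of calls against the generator's event log.

    A call matches an event iff their target intervals overlap reciprocally
    by >= ``reciprocal``.  Breakpoint error is the mean absolute endpoint
    offset over matched (call, event) pairs.
    """
    if not events:
        raise ValueError("empty truth: nothing to validate against")
    matched_events = 0
    offsets: list[float] = []
    call_matched = [False] * len(calls)
    for ev in events:
        t = ev.target
        best = None
        for i, c in enumerate(calls):
            ov = c.target.reciprocal_overlap(t)
            if ov >= reciprocal and (best is None or ov > best[0]):
                best = (ov, i)
        if best is not None:
            matched_events += 1
            c = calls[best[1]]
            call_matched[best[1]] = True
            offsets.append((abs(c.target.start - t.start) + abs(c.target.end - t.end)) / 2.0)
    # calls may legitimately match an event other than their best partner
    for i, c in enumerate(calls):
        if not call_matched[i]:
            call_matched[i] = any(c.target.reciprocal_overlap(ev.target) >= reciprocal for ev in events)
    precision = sum(call_matched) / len(calls) if calls else 0.0
    recall = matched_events / len(events)
    return {
        "precision": precision,
        "recall": recall,
        "breakpoint_error_bp": sum(offsets) / len(offsets) if offsets else 0.0,
        "n_calls": len(calls),
        "n_events": len(events),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns (and writes) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.sim
    if cfg.seed != config.seed:
        cfg = SimConfig(**{**asdict_shallow(cfg), "seed": config.seed})
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "egt_version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "thresholds": HEADLINE_THRESHOLDS,
        "results": {},
    }
    try:
        state: dict = {}
        for stage in config.stages:
            fn = _STAGES.get(stage)
            if fn is None:
                raise StageError(f"unknown stage {stage!r}")
            fn(cfg, config, outdir, state, report["results"])
    except Exception as exc:  # partial report + re-raise for nonzero exit
        report["error"] = f"{type(exc).__name__}: {exc}"
        (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
        raise
    (outdir / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def asdict_shallow(dc) -> dict:
    return {k: getattr(dc, k) for k in dc.__dataclass_fields__}


def _stage_simulate(cfg: SimConfig, config: RunConfig, outdir: Path, state: dict, results: dict) -> None:
    plastome, structure = simulate_plastome(cfg)
    mito, mito_truth = simulate_mitogenome(cfg, plastome, structure)
    chroms, nuc_truth = simulate_nuclear(cfg, mito, plastome)
    truth = GroundTruth(events=mito_truth.events + nuc_truth.events)
    # organelle-enriched library for assembly; plastome-overweighted pool for
    # the coverage QC (reproduces the high-depth peaks over MTPT regions)
    reads = simulate_reads([mito], cfg)
    cov_reads = simulate_reads([mito, plastome], cfg, weights={"plastome": 10.0})
    write_fasta([plastome], outdir / "plastome.fasta")
    write_fasta([mito], outdir / "mitogenome.fasta")
    write_fasta(chroms, outdir / "nuclear.fasta")
    reads.write_fastq(outdir / "reads_1.fastq", outdir / "reads_2.fastq")
    cov_reads.write_fastq(outdir / "reads_cov_1.fastq", outdir / "reads_cov_2.fastq")
    truth.to_json(outdir / "truth.json")
    write_gff3(truth_features(truth), outdir / "truth.gff3")
    state.update(
        plastome=plastome,
        structure=structure,
        mito=mito,
        chroms=chroms,
        truth=truth,
        reads=reads,
        cov_reads=cov_reads,
    )
    results["simulate"] = {
        "plastome_len": len(plastome),
        "mito_len": len(mito),
        "n_chromosomes": len(chroms),
        "n_truth_events": len(truth.events),
        "n_read_pairs": len(reads),
    }


def _stage_assemble(cfg: SimConfig, config: RunConfig, outdir: Path, state: dict, results: dict) -> None:
    from .core import read_fasta, canonical_rotation

    mito = state.get("mito") or read_fasta(outdir / "mitogenome.fasta")[0]
    reads = state.get("reads") or ReadSet.read_fastq(outdir / "reads_1.fastq", outdir / "reads_2.fastq")
    genome, closed, contigs = assemble_genome(reads, [mito], config.assembly, genome_id="mito_assembly")
    write_fasta([genome], outdir / "assembly.fasta")
    exact = genome.seq == canonical_rotation(mito.seq)
    state["assembly"] = genome
    results["assemble"] = {
        "closed": closed,
        "length": len(genome),
        "n_contigs": len(contigs),
        "exact_match_to_reference": exact,
    }
    cov_reads = state.get("cov_reads")
    if cov_reads is None and (outdir / "reads_cov_1.fastq").exists():
        cov_reads = ReadSet.read_fastq(outdir / "reads_cov_1.fastq", outdir / "reads_cov_2.fastq")
    if cov_reads is not None:
        from .assemble import coverage_profile

        depth, flags, warns = coverage_profile(mito, cov_reads, config.assembly)
        write_bed6([(iv, label, 0) for iv, label in flags], outdir / "coverage_qc.bed")
        results["assemble"]["coverage"] = {
            "median_depth": float(__import__("numpy").median(depth)),
            "n_low_flags": sum(1 for _, l in flags if l == "low"),
            "n_high_flags": sum(1 for _, l in flags if l == "plastome_like_high_depth"),
            "warnings": warns,
        }


def _stage_repeats(cfg: SimConfig, config: RunConfig, outdir: Path, state: dict, results: dict) -> None:
    from .core import read_fasta

    mito = state.get("mito") or read_fasta(outdir / "mitogenome.fasta")[0]
    pairs = find_exact_repeats(mito, min_len=100)
    stats = duplicated_length(pairs, mito)
    rows = []
    for p in pairs:
        rows.append((p.a, f"repeat:{p.orientation}", p.length))
        rows.append((p.b, f"repeat:{p.orientation}", p.length))
    write_bed6(rows, outdir / "repeats.bed")
    state["repeats"] = pairs
    results["repeats"] = {
        "n_pairs": len(pairs),
        "total_dup_len": stats.total_dup_len,
        "max_dup_len": stats.max_dup_len,
    }


def _stage_transfers(cfg: SimConfig, config: RunConfig, outdir: Path, state: dict, results: dict) -> None:
    from .core import read_fasta

    mito = state.get("mito") or read_fasta(outdir / "mitogenome.fasta")[0]
    plastome = state.get("plastome") or read_fasta(outdir / "plastome.fasta")[0]
    chroms = state.get("chroms") or read_fasta(outdir / "nuclear.fasta")
    structure = state.get("structure")
    truth = state.get("truth")
    if truth is None and (outdir / "truth.json").exists():
        truth = GroundTruth.from_json(outdir / "truth.json")
    p = config.homology
    mito_repeats = state.get("repeats") or find_exact_repeats(mito, min_len=100)
    plast_repeats = find_exact_repeats(plastome, min_len=100)

    mtpt = call_transfers(plastome, [mito], p)
    mtpt, comp_totals = attribute_compartment(mtpt, structure)
    numt = dedup_repeat_hits(call_transfers(mito, chroms, p), mito_repeats)
    nupt = dedup_repeat_hits(call_transfers(plastome, chroms, p), plast_repeats)

    write_bed6(calls_to_bed(mtpt + numt + nupt), outdir / "transfers.bed")
    summaries, rollup = summarize_by_chromosome(numt, chroms)
    summaries_to_table(summaries).to_csv(outdir / "numt_summary.tsv", sep="\t", index=False)
    clusters = cluster_large_fragments(numt + nupt)
    (outdir / "clusters.json").write_text(
        json.dumps(
            [
                {
                    "chrom": cl.chrom_id,
                    "window": [cl.window.start, cl.window.end],
                    "n_members": len(cl.members),
                    "total_bp": cl.total_bp,
                }
                for cl in clusters
            ],
            indent=1,
        )
    )
    results["transfers"] = {
        "n_mtpt": len(mtpt),
        "n_numt": len(numt),
        "n_nupt": len(nupt),
        "mtpt_compartment_bp": comp_totals,
        "numt_rollup": rollup,
        "n_clusters": len(clusters),
    }
    if truth is not None and truth.events:
        numt_truth = truth.of_class("NUMT")
        if numt_truth:
            results["transfers"]["numt_vs_truth"] = validate_against_truth(numt, numt_truth)
        nupt_truth = truth.of_class("NUPT")
        if nupt_truth:
            results["transfers"]["nupt_vs_truth"] = validate_against_truth(nupt, nupt_truth)
    state.update(mtpt=mtpt, numt=numt, nupt=nupt)


def _stage_synteny(cfg: SimConfig, config: RunConfig, outdir: Path, state: dict, results: dict) -> None:
    from .core import read_fasta, write_gff3 as _wg

    mito = state.get("mito") or read_fasta(outdir / "mitogenome.fasta")[0]
    assembly = state.get("assembly")
    other = assembly if assembly is not None else mito
    orfs = find_orfs(mito)
    _wg(orfs, outdir / "orfs.gff3")
    ribbons = ribbon_map(mito, other, stringent_params())
    results["synteny"] = {
        "n_orfs": len(orfs),
        "n_ribbons": len(ribbons),
        "top_bin_count": sum(1 for r in ribbons if r.bin == ">0.75"),
    }


_STAGES = {
    "simulate": _stage_simulate,
    "assemble": _stage_assemble,
    "repeats": _stage_repeats,
    "transfers": _stage_transfers,
    "synteny": _stage_synteny,
}
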