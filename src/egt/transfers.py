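"""Calling and summarizing intracellular DNA transfers.

Transfers among the three DNA-containing compartments of a plant cell are
called as local alignment hits of an organellar genome against a host
genome: plastome -> mitogenome hits are MTPTs, mitogenome -> nucleus hits
are NUMTs, plastome -> nucleus hits are NUPTs.  Because noncoding
mitochondrial sequence gives no directional signal, every shared
mitochondrial/nuclear segment is counted as a NUMT rather than guessing a
direction.

Post-processing mirrors standard practice: multiple hits to one host locus
caused by duplicated regions of the organellar query are collapsed to the
single best hit; plastome-side coverage is partitioned over the LSC/SSC/IR
compartments with the two IR copies projected onto one before totals are
taken; per-chromosome summaries report count/mean/median/max/min both
overall and restricted to calls above a length threshold; and large calls
are clustered along each chromosome to expose the tight multi-kb insertion
clusters characteristic of recent transfers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Genome, Interval, PlastomeStructure, Role, interval_union_length, merge_intervals
from .homolog import HomologyParams, Hsp, find_hsps
from .repeats import RepeatPair

_CLASS_BY_ROLES = {
    (Role.plastome, Role.mitogenome): "MTPT",
    (Role.mitogenome, Role.nuclear_chromosome): "NUMT",
    (Role.plastome, Role.nuclear_chromosome): "NUPT",
}


@dataclass(frozen=True)
class TransferCall:
    """A classified organellar-DNA copy in a host genome."""

    klass: str  # MTPT | NUMT | NUPT
    target: Interval  # host genome locus
    source: Interval  # organellar counterpart
    identity: float
    evalue: float
    length: int
    score: int = 0
    deduped: bool = False
    compartment: str = "NA"  # LSC | SSC | IR | NA


def call_transfers(
    organelle: Genome,
    host: Sequence[Genome],
    params: HomologyParams | None = None,
) -> list[TransferCall]:
    """One TransferCall per retained HSP of organelle (query) vs host genomes.

    The transfer class follows from the role pair: plastome->mitogenome =
    MTPT, mitogenome->nuclear = NUMT, plastome->nuclear = NUPT; any other
    combination is an error.  Defaults are word size 11, E <= 1e-5,
    50,000 max hits.
    """
    p = params or HomologyParams()
    calls: list[TransferCall] = []
    for h in host:
        key = (organelle.role, h.role)
        if key not in _CLASS_BY_ROLES:
            raise ValueError(
                f"no transfer class for query role {organelle.role.value} vs host role {h.role.value}"
            )
        klass = _CLASS_BY_ROLES[key]
        for hsp in find_hsps(organelle, h, p):
            calls.append(
                TransferCall(
                    klass=klass,
                    target=hsp.subject,
                    source=hsp.query,
                    identity=hsp.identity,
                    evalue=hsp.evalue,
                    length=hsp.align_len,
                    score=hsp.score,
                )
            )
    calls.sort(key=lambda c: (c.target.seq_id, c.target.start, -c.score))
    return calls


def dedup_repeat_hits(
    calls: Sequence[TransferCall],
    organelle_repeats: Sequence[RepeatPair],
    reciprocal: float = 0.5,
) -> list[TransferCall]:
    """Collapse multiple hits per host locus caused by organellar repeats.

    Two calls are redundant when their target intervals overlap reciprocally
    by >= ``reciprocal`` and their source intervals lie in different members
    of the same repeat family; only the best-scoring call of such a group
    survives, marked ``deduped``.  Calls not implicated by any repeat pass
    through unchanged.  Idempotent.
    """
    if not organelle_repeats:
        return list(calls)

    def family_members(call: TransferCall) -> set[int]:
        """Indices of repeat pairs owning a member that covers the source."""
        fams = set()
        for i, rp in enumerate(organelle_repeats):
            for member in (rp.a, rp.b):
                iv = Interval(member.seq_id, member.start, member.end)
                src = Interval(call.source.seq_id, call.source.start, call.source.end)
                ov = iv.overlap(src)
                if ov >= 0.8 * len(src):
                    fams.add(i)
        return fams

    order = sorted(
        range(len(calls)),
        key=lambda i: (-calls[i].score, calls[i].target.seq_id, calls[i].target.start),
    )
    fams = [family_members(c) for c in calls]
    kept: list[int] = []
    dropped: set[int] = set()
    dedup_mark: set[int] = set()
    for i in order:
        if i in dropped:
            continue
        for j in kept:
            ci, cj = calls[i], calls[j]
            if (
                ci.target.seq_id == cj.target.seq_id
                and ci.target.reciprocal_overlap(cj.target) >= reciprocal
                and fams[i] & fams[j]
            ):
                dropped.add(i)
                dedup_mark.add(j)
                break
        else:
            kept.append(i)
    out = []
    for i in sorted(kept, key=lambda i: (calls[i].target.seq_id, calls[i].target.start)):
        c = calls[i]
        out.append(replace(c, deduped=True) if i in dedup_mark else c)
    return out


def attribute_compartment(
    calls: Sequence[TransferCall], structure: PlastomeStructure | None
) -> tuple[list[TransferCall], dict[str, int]]:
    """Attribute plastome-sourced calls to LSC/SSC/IR and total the coverage.

    Per-compartment totals are union lengths of the source-side coverage;
    hits to IRb are reflected onto IRa first, so the same segment hitting
    both IR copies is counted once.  Each call is labelled by the
    compartment holding the majority of its source interval.
    """
    if structure is None:
        import warnings

        warnings.warn("plastome structure missing: compartments set to NA")
        return list(calls), {"LSC": 0, "SSC": 0, "IR": 0, "total": 0}

    sid = structure.lsc.seq_id
    comp_ivs: dict[str, list[Interval]] = {"LSC": [], "SSC": [], "IR": []}
    labelled: list[TransferCall] = []
    for c in calls:
        s, e = c.source.start, c.source.end
        pieces: dict[str, int] = {"LSC": 0, "SSC": 0, "IR": 0}
        for name, iv in (("LSC", structure.lsc), ("SSC", structure.ssc)):
            lo, hi = max(s, iv.start), min(e, iv.end)
            if lo < hi:
                comp_ivs[name].append(Interval(sid, lo, hi))
                pieces[name] += hi - lo
        proj = structure.project_onto_ira(s, e)
        if proj is not None:
            comp_ivs["IR"].append(Interval(sid, proj[0], proj[1]))
            pieces["IR"] += proj[1] - proj[0]
        # an interval may touch IRb beyond the projection window returned;
        # handle a call spanning both IR copies by also projecting the IRb part
        lo, hi = max(s, structure.irb.start), min(e, structure.irb.end)
        if lo < hi and proj is not None and (proj[0] != structure.ira.start + (structure.irb.end - hi)):
            ref = (
                structure.ira.start + (structure.irb.end - hi),
                structure.ira.start + (structure.irb.end - lo),
            )
            comp_ivs["IR"].append(Interval(sid, ref[0], ref[1]))
            pieces["IR"] += ref[1] - ref[0]
        label = max(pieces, key=lambda k: pieces[k]) if any(pieces.values()) else "NA"
        labelled.append(replace(c, compartment=label))
    totals = {
        name: (interval_union_length(ivs) if ivs else 0) for name, ivs in comp_ivs.items()
    }
    totals["total"] = totals["LSC"] + totals["SSC"] + totals["IR"]
    return labelled, totals


@dataclass(frozen=True)
class ChromosomeSummary:
    chrom_id: str
    n: int
    n_ge_threshold: int
    mean_len: float
    median_len: float
    max_len: int
    min_len: int
    mean_len_ge: float
    median_len_ge: float
    max_len_ge: int
    min_len_ge: int
    cumulative_bp: int
    pct_of_chromosome: float


def summarize_by_chromosome(
    calls: Sequence[TransferCall],
    host_genomes: Sequence[Genome],
    sub_threshold: int = 250,
) -> tuple[list[ChromosomeSummary], dict]:
    """Per-chromosome transfer statistics plus a genome-level rollup.

    For each chromosome: call count, mean/median/max/min call length, the
    same four restricted to calls longer than ``sub_threshold``, the
    cumulative (union) bp covered by calls, and that union as a percent of
    the chromosome.  The rollup sums counts and per-chromosome unions.
    """
    by_chrom: dict[str, list[TransferCall]] = {g.id: [] for g in host_genomes}
    for c in calls:
        by_chrom.setdefault(c.target.seq_id, []).append(c)
    glen = {g.id: len(g) for g in host_genomes}
    summaries = []
    total_bp = 0
    total_n = 0
    for g in host_genomes:
        cs = by_chrom[g.id]
        lens = np.array([c.length for c in cs], dtype=float)
        big = lens[lens >= sub_threshold]
        cum = (
            interval_union_length([Interval(g.id, c.target.start, c.target.end) for c in cs])
            if cs
            else 0
        )
        total_bp += cum
        total_n += len(cs)
        summaries.append(
            ChromosomeSummary(
                chrom_id=g.id,
                n=len(cs),
                n_ge_threshold=int(big.size),
                mean_len=float(lens.mean()) if lens.size else 0.0,
                median_len=float(np.median(lens)) if lens.size else 0.0,
                max_len=int(lens.max()) if lens.size else 0,
                min_len=int(lens.min()) if lens.size else 0,
                mean_len_ge=float(big.mean()) if big.size else 0.0,
                median_len_ge=float(np.median(big)) if big.size else 0.0,
                max_len_ge=int(big.max()) if big.size else 0,
                min_len_ge=int(big.min()) if big.size else 0,
                cumulative_bp=cum,
                pct_of_chromosome=100.0 * cum / glen[g.id],
            )
        )
    rollup = {
        "n": total_n,
        "cumulative_bp": total_bp,
        "pct_of_genome": 100.0 * total_bp / sum(glen.values()) if glen else 0.0,
    }
    return summaries, rollup


def summaries_to_table(summaries: Sequence[ChromosomeSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


@dataclass(frozen=True)
class FragmentCluster:
    chrom_id: str
    window: Interval
    members: tuple[TransferCall, ...]
    total_bp: int


def cluster_large_fragments(
    calls: Sequence[TransferCall],
    min_large_len: int = 1_000,
    max_gap: int = 100_000,
) -> list[FragmentCluster]:
    """Single-linkage clusters of large calls along each chromosome.

    Calls >= ``min_large_len`` are chained while the gap between consecutive
    calls is <= ``max_gap``; clusters with >= 2 members are reported, sorted
    by total bp (descending).  Singletons are suppressed.
    """
    large = [c for c in calls if c.length >= min_large_len]
    by_chrom: dict[str, list[TransferCall]] = {}
    for c in large:
        by_chrom.setdefault(c.target.seq_id, []).append(c)
    clusters: list[FragmentCluster] = []
    for chrom, cs in by_chrom.items():
        cs.sort(key=lambda c: c.target.start)
        group: list[TransferCall] = []
        for c in cs:
            if group and c.target.start - group[-1].target.end > max_gap:
                if len(group) >= 2:
                    clusters.append(_mk_cluster(chrom, group))
                group = []
            group.append(c)
        if len(group) >= 2:
            clusters.append(_mk_cluster(chrom, group))
    clusters.sort(key=lambda cl: (-cl.total_bp, cl.chrom_id, cl.window.start))
    return clusters


def _mk_cluster(chrom: str, group: list[TransferCall]) -> FragmentCluster:
    return FragmentCluster(
        chrom_id=chrom,
        window=Interval(chrom, min(c.target.start for c in group), max(c.target.end for c in group)),
        members=tuple(group),
        total_bp=sum(c.length for c in group),
    )


@dataclass(frozen=True)
class DotFragment:
    nuclear: Interval
    organelle: Interval
    orientation: str
    identity_pct: float


def dotmatrix_report(
    nuclear_region: Genome,
    organelle: Genome,
    params: HomologyParams | None = None,
    min_large_len: int = 1_000,
    mosaic_span: int = 10_000,
) -> tuple[list[DotFragment], bool]:
    """Dot-matrix fragments between a nuclear region and an organelle genome.

    Reports every HSP >= ``min_large_len`` as (nuclear interval, organelle
    interval, orientation, identity %), plus a mosaic flag: true iff the
    fragments derive from organellar loci more than ``mosaic_span`` apart or
    from mixed orientations -- the signature of a cluster stitched from
    several independent transfer events.
    """
    p = params or HomologyParams()
    hsps = find_hsps(organelle, nuclear_region, p)
    frags = [
        DotFragment(
            nuclear=h.subject,
            organelle=h.query,
            orientation=h.strand,
            identity_pct=round(100.0 * h.identity, 2),
        )
        for h in hsps
        if h.align_len >= min_large_len
    ]
    frags.sort(key=lambda f: (f.nuclear.start, f.organelle.start))
    mosaic = False
    if frags:
        if len({f.orientation for f in frags}) > 1:
            mosaic = True
        merged = merge_intervals(
            [Interval(organelle.id, f.organelle.start, f.organelle.end) for f in frags]
        )
        for a, b in zip(merged, merged[1:]):
            if b.start - a.end > mosaic_span:
                mosaic = True
    return frags, mosaic


def calls_to_bed(calls: Sequence[TransferCall]) -> list[tuple[Interval, str, int]]:
    """BED6 rows: name = class:source-locus, score = identity x 1000."""
    rows = []
    for c in calls:
        name = f"{c.klass}:{c.source.seq_id}:{c.source.start}-{c.source.end}"
        rows.append((c.target, name, int(round(c.identity * 1000))))
    return rows
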