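"""Structural comparison between mitogenomes.

Plant mitogenomes rearrange rapidly while conserving most of their
sequence, so structure is compared through syntenic blocks: stringent local
alignments (E <= 1e-10) chained collinearly, filtered to blocks longer than
1 kb that contain at least one annotated gene.  The module also computes
per-genome conserved-fraction (Venn-class) decompositions for a trio of
genomes, score-ratio ribbon bins for rearrangement maps, and the two small
annotation utilities the comparisons rely on: an ORF finder (>= 303 bp,
ATG start, all six frames, honoring circularity) and a gene
presence/duplication matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Feature, FeatureKind, Genome, Interval, Topology, revcomp
from .homolog import HomologyParams, Hsp, find_hsps

STOP_CODONS = {"TAA", "TAG", "TGA"}


def stringent_params(**kw) -> HomologyParams:
    """The stringent comparison parameterization (E <= 1e-10)."""
    kw.setdefault("evalue_max", 1e-10)
    return HomologyParams(**kw)


@dataclass(frozen=True)
class SyntenyBlock:
    a: Interval
    b: Interval
    orientation: str  # same | inverted
    genes: tuple[str, ...]
    length: int
    score: int = 0


@dataclass(frozen=True)
class RibbonBin:
    hsp: Hsp
    ratio: float
    bin: str  # "<=0.25" | "<=0.50" | "<=0.75" | ">0.75"


def _chain_hsps(hsps: list[Hsp], max_chain_gap: int) -> list[list[Hsp]]:
    """Greedy collinear chaining of same-strand HSPs along the query."""
    chains: list[list[Hsp]] = []
    for strand in ("+", "-"):
        hits = sorted(
            (h for h in hsps if h.strand == strand),
            key=lambda h: (h.query.start, h.subject.start),
        )
        open_chains: list[list[Hsp]] = []
        for h in hits:
            best = None
            for ch in open_chains:
                last = ch[-1]
                qgap = h.query.start - last.query.end
                if strand == "+":
                    sgap = h.subject.start - last.subject.end
                else:
                    sgap = last.subject.start - h.subject.end
                if -50 <= qgap <= max_chain_gap and -50 <= sgap <= max_chain_gap:
                    if best is None or last.query.end > best[-1].query.end:
                        best = ch
            if best is not None:
                best.append(h)
            else:
                ch = [h]
                chains.append(ch)
                open_chains.append(ch)
            open_chains = [c for c in open_chains if c[-1].query.end >= h.query.start - max_chain_gap]
    return chains


def find_synteny_blocks(
    gA: Genome,
    gB: Genome,
    annotA: Sequence[Feature] | None,
    params: HomologyParams | None = None,
    min_block_len: int = 1_000,
    max_chain_gap: int = 500,
    require_gene: bool = True,
) -> list[SyntenyBlock]:
    """Syntenic blocks between two genomes.

    HSPs at the stringent E-value are chained collinearly (same orientation,
    inter-hit gap <= ``max_chain_gap`` on both genomes); chains shorter than
    ``min_block_len`` on gA, or containing no annotated gene of gA when the
    gene filter is on, are discarded.  Surviving blocks are non-overlapping
    on gA (lower-scoring overlaps dropped).
    """
    if require_gene and annotA is None:
        raise ValueError("gene filter enabled but no annotation supplied")
    p = params or stringent_params()
    hsps = find_hsps(gA, gB, p)
    blocks: list[SyntenyBlock] = []
    for chain in _chain_hsps(hsps, max_chain_gap):
        qs = min(h.query.start for h in chain)
        qe = max(h.query.end for h in chain)
        ss = min(h.subject.start for h in chain)
        se = max(h.subject.end for h in chain)
        if qe - qs < min_block_len:
            continue
        genes: tuple[str, ...] = ()
        if annotA is not None:
            genes = tuple(
                sorted(
                    {
                        f.name
                        for f in annotA
                        if f.kind in (FeatureKind.gene, FeatureKind.rRNA, FeatureKind.tRNA)
                        and f.interval.seq_id == gA.id
                        and f.interval.overlap(Interval(gA.id, qs, qe)) > 0
                    }
                )
            )
        if require_gene and not genes:
            continue
        strand = chain[0].strand
        blocks.append(
            SyntenyBlock(
                a=Interval(gA.id, qs, qe),
                b=Interval(gB.id, ss, se, strand),
                orientation="same" if strand == "+" else "inverted",
                genes=genes,
                length=qe - qs,
                score=sum(h.score for h in chain),
            )
        )
    # enforce non-overlap on gA: higher-scoring blocks win; lower ones are
    # trimmed at the edges (alignment ends chance-extend a few bp across a
    # rearrangement breakpoint) and dropped only if nothing usable remains
    blocks.sort(key=lambda b: (-b.score, b.a.start))
    kept: list[SyntenyBlock] = []
    for b in blocks:
        qs, qe = b.a.start, b.a.end
        bs, be = b.b.start, b.b.end
        dead = False
        for k in kept:
            ov_lo, ov_hi = max(qs, k.a.start), min(qe, k.a.end)
            if ov_lo >= ov_hi:
                continue
            if k.a.start <= qs and qe <= k.a.end:
                dead = True
                break
            if ov_lo == qs:  # trim left edge
                cut = ov_hi - qs
                qs += cut
                if b.orientation == "same":
                    bs += cut
                else:
                    be -= cut
            elif ov_hi == qe:  # trim right edge
                cut = qe - ov_lo
                qe -= cut
                if b.orientation == "same":
                    be -= cut
                else:
                    bs += cut
            else:  # a kept block sits strictly inside this one
                dead = True
                break
        if dead or qe - qs < min_block_len or be <= bs:
            continue
        kept.append(
            SyntenyBlock(
                a=Interval(b.a.seq_id, qs, qe),
                b=Interval(b.b.seq_id, bs, be, b.b.strand),
                orientation=b.orientation,
                genes=b.genes,
                length=qe - qs,
                score=b.score,
            )
        )
    kept.sort(key=lambda b: b.a.start)
    return kept


def conserved_fraction(
    genomes: Sequence[Genome], params: HomologyParams | None = None
) -> dict[str, dict[str, int]]:
    """Per-genome Venn-class lengths of conserved sequence among three genomes.

    For each genome, every position is classed by which of the other two
    genomes it is homologous to (stringent E-value), yielding four lengths:
    shared with both, with each one alone, or unique.  Lengths are on each
    genome's own coordinates (duplicated regions make them asymmetric) and
    sum exactly to the genome length.
    """
    if len(genomes) != 3:
        raise ValueError("conserved_fraction expects exactly three genomes")
    p = params or stringent_params()
    out: dict[str, dict[str, int]] = {}
    for a in genomes:
        others = [g for g in genomes if g.id != a.id]
        masks = []
        for b in others:
            m = np.zeros(len(a), dtype=bool)
            for h in find_hsps(a, b, p):
                m[h.query.start : h.query.end] = True
            masks.append(m)
        m1, m2 = masks
        out[a.id] = {
            f"shared_with_both": int(np.count_nonzero(m1 & m2)),
            f"shared_with_{others[0].id}_only": int(np.count_nonzero(m1 & ~m2)),
            f"shared_with_{others[1].id}_only": int(np.count_nonzero(~m1 & m2)),
            "unique": int(np.count_nonzero(~m1 & ~m2)),
        }
    return out


def ribbon_map(gA: Genome, gB: Genome, params: HomologyParams | None = None) -> list[RibbonBin]:
    """Score-ratio ribbon bins for a rearrangement map.

    Every retained HSP gets ratio = score / max score over the comparison
    and a color bin (<=0.25, <=0.50, <=0.75, >0.75); the best HSP always has
    ratio 1 and lands in the top bin.  Sorted by gA coordinate.
    """
    p = params or stringent_params()
    hsps = find_hsps(gA, gB, p)
    if not hsps:
        return []
    max_score = max(h.score for h in hsps)
    out = []
    for h in sorted(hsps, key=lambda h: (h.query.start, h.subject.start)):
        ratio = h.score / max_score
        if ratio <= 0.25:
            b = "<=0.25"
        elif ratio <= 0.50:
            b = "<=0.50"
        elif ratio <= 0.75:
            b = "<=0.75"
        else:
            b = ">0.75"
        out.append(RibbonBin(hsp=h, ratio=ratio, bin=b))
    return out


def find_orfs(genome: Genome, min_len: int = 303, longest_only: bool = True) -> list[Feature]:
    """ATG-initiated, stop-terminated ORFs >= min_len on both strands.

    All six frames are scanned; on circular genomes the scan crosses the
    origin (ORFs are reported at their forward-strand coordinates modulo the
    length, origin-spanning ones split implicitly by the caller if needed).
    Within one stop-to-stop frame segment only the longest ATG start is
    reported unless ``longest_only`` is false.  Lengths include the stop
    codon.
    """
    n = len(genome)
    circular = genome.topology is Topology.circular
    results: list[tuple[int, int, str]] = []  # (fwd_start, length, strand)
    for strand in ("+", "-"):
        seq = genome.seq if strand == "+" else revcomp(genome.seq)
        text = seq + seq if circular else seq
        limit = len(text)
        for frame in range(3):
            starts: list[int] = []
            i = frame
            while i + 3 <= limit:
                codon = text[i : i + 3]
                if codon == "ATG":
                    starts.append(i)
                elif codon in STOP_CODONS:
                    for s in (starts[:1] if longest_only else starts):
                        length = i + 3 - s
                        if min_len <= length <= n and (not circular or s < n):
                            results.append((s, length, strand))
                    starts = []
                i += 3
    feats: list[Feature] = []
    seen: set[tuple[int, int, str]] = set()
    idx = 0
    for s, length, strand in results:
        if strand == "+":
            fwd_start = s % n
        else:
            # position s on the reverse strand maps to forward end n - s
            fwd_start = (n - (s % n) - length) % n
        key = (fwd_start, length, strand)
        if key in seen:
            continue
        seen.add(key)
        end = fwd_start + length
        if end > n:
            if not circular:
                continue
            # origin-spanning ORF: report the wrapped span as the main piece
            end = n
            fwd_start_clip = fwd_start
            length_clip = end - fwd_start_clip
            if length_clip % 3:
                length_clip -= length_clip % 3
            if length_clip < 3:
                continue
            feats.append(
                Feature(
                    interval=Interval(genome.id, fwd_start_clip, fwd_start_clip + length_clip, strand),
                    kind=FeatureKind.ORF,
                    name=f"orf_{fwd_start}_{strand}",
                )
            )
            continue
        feats.append(
            Feature(
                interval=Interval(genome.id, fwd_start, end, strand),
                kind=FeatureKind.ORF,
                name=f"orf_{fwd_start}_{strand}",
            )
        )
        idx += 1
    feats.sort(key=lambda f: (f.interval.start, f.interval.end, f.interval.strand))
    return feats


def gene_presence_matrix(
    annotations: Mapping[str, Sequence[Feature]],
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Gene x genome copy counts, presence classes, and duplicated-gene tallies.

    ``annotations`` maps genome id -> feature list.  Returns (counts,
    classes, duplicated_per_genome): counts holds copy numbers, classes
    holds absent/single/duplicated, and the duplicated tally per genome
    excludes ORFs and tRNAs.
    """
    rows = []
    for gid, feats in annotations.items():
        for f in feats:
            rows.append({"genome": gid, "gene": f.name, "kind": f.kind.value})
    if not rows:
        return pd.DataFrame(), pd.DataFrame(), {gid: 0 for gid in annotations}
    df = pd.DataFrame(rows)
    counts = (
        df.groupby(["gene", "genome"]).size().unstack(fill_value=0).reindex(
            columns=list(annotations.keys()), fill_value=0
        )
    )
    classes = counts.map(lambda c: "absent" if c == 0 else ("single" if c == 1 else "duplicated"))
    kinds = df.drop_duplicates("gene").set_index("gene")["kind"]
    dup_counts = {}
    for gid in annotations:
        dup = 0
        for gene in counts.index:
            if counts.loc[gene, gid] >= 2 and kinds.get(gene) not in ("ORF", "tRNA"):
                dup += 1
        dup_counts[gid] = dup
    return counts, classes, dup_counts


def blocks_to_table(blocks: Sequence[SyntenyBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "block_id": i + 1,
                "a_seq": b.a.seq_id,
                "a_start": b.a.start,
                "a_end": b.a.end,
                "b_seq": b.b.seq_id,
                "b_start": b.b.start,
                "b_end": b.b.end,
                "orientation": b.orientation,
                "length": b.length,
                "n_genes": len(b.genes),
                "genes": ",".join(b.genes),
            }
            for i, b in enumerate(blocks)
        ]
    )
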