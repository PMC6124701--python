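"""Seed-and-extend local alignment with Karlin-Altschul E-values.

The engine follows the classic blastn recipe: exact ``word_size`` seeds on
both strands, ungapped X-drop extension along each seed diagonal, collinear
chaining of nearby segments, and gapped refinement of multi-segment chains
with an affine-gap local alignment restricted to the chain's bounding box.
Every cross-genome comparison in the package (transfer calling, synteny,
conserved fractions, dot matrices) is built on :func:`find_hsps`.

Scoring defaults are blastn-like (+1/-2, gap open -5, extend -2); a gap of
length L costs ``gap_open + L * gap_extend``.  E-values use the
Karlin-Altschul form E = K * m * n * exp(-lambda * S); the default
constants K=0.46, lambda=1.28 are the standard ungapped values for the
+1/-2 nucleotide scheme (at organelle-vs-nuclear search spaces they put
the shortest significant exact hit near 36 bp).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio import Align

from .core import Genome, Interval, interval_union_length, merge_intervals, revcomp


@dataclass
class HomologyParams:
    word_size: int = 11
    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2
    evalue_max: float = 1e-5
    max_hits: int = 50_000
    # ungapped Karlin-Altschul constants for the +1/-2 nucleotide scheme
    karlin_K: float = 0.46
    karlin_lambda: float = 1.28
    xdrop: int = 20
    band: int = 50
    chain_gap: int = 100  # max unaligned bp between chained segments

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")


@dataclass(frozen=True)
class Hsp:
    """A high-scoring segment pair: one local alignment hit.

    ``query``/``subject`` are forward-strand coordinates on either sequence;
    ``strand`` is '-' when the query matches the reverse complement of the
    subject.  ``identity`` counts matches over alignment columns, gap
    columns included.
    """

    query: Interval
    subject: Interval
    strand: str
    score: int
    identity: float
    align_len: int
    evalue: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity outside [0,1]")
        if self.evalue < 0:
            raise ValueError("negative evalue")


def evalue(score: float, m: int, n: int, params: HomologyParams) -> float:
    """Karlin-Altschul expected hit count: E = K * m * n * exp(-lambda * S)."""
    if m <= 0 or n <= 0:
        raise ValueError("sequence lengths must be positive")
    return params.karlin_K * m * n * math.exp(-params.karlin_lambda * score)


# ---------------------------------------------------------------------------
# internals


@dataclass
class _Segment:
    qs: int
    qe: int
    ss: int
    se: int
    score: int
    matches: int

    @property
    def diag(self) -> int:
        return self.qs - self.ss


def _index_words(seq: str, w: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(len(seq) - w + 1):
        word = seq[i : i + w]
        if "N" in word:
            continue
        idx.setdefault(word, []).append(i)
    return idx


def _extend_ungapped(q: str, s: str, qpos: int, spos: int, w: int, p: HomologyParams) -> _Segment:
    """X-drop ungapped extension of an exact w-mer seed on one diagonal."""
    m, mm, xd = p.match, p.mismatch, p.xdrop
    score = w * m
    matches = w
    # right
    best, best_i, cur, cur_m = score, 0, score, 0
    i, j = qpos + w, spos + w
    nq, ns = len(q), len(s)
    while i < nq and j < ns:
        a, b = q[i], s[j]
        if a == b and a != "N":
            cur += m
            cur_m += 1
        else:
            cur += mm
        if cur > best:
            best, best_i, matches_r = cur, i - (qpos + w) + 1, cur_m
        if cur < best - xd:
            break
        i += 1
        j += 1
    if best > score:
        right = best_i
        matches += matches_r
    else:
        right = 0
    score = best
    # left
    best, best_i, cur, cur_m = score, 0, score, 0
    i, j = qpos - 1, spos - 1
    while i >= 0 and j >= 0:
        a, b = q[i], s[j]
        if a == b and a != "N":
            cur += m
            cur_m += 1
        else:
            cur += mm
        if cur > best:
            best, best_i, matches_l = cur, qpos - i, cur_m
        if cur < best - xd:
            break
        i -= 1
        j -= 1
    if best > score:
        left = best_i
        matches += matches_l
    else:
        left = 0
    return _Segment(
        qs=qpos - left,
        qe=qpos + w + right,
        ss=spos - left,
        se=spos + w + right,
        score=best,
        matches=matches,
    )


def _ungapped_segments(q: str, s: str, p: HomologyParams) -> list[_Segment]:
    w = p.word_size
    if len(q) < w or len(s) < w:
        return []
    idx = _index_words(s, w)
    # seeds grouped per diagonal so each repeated region is extended once
    by_diag: dict[int, list[tuple[int, int]]] = {}
    for i in range(len(q) - w + 1):
        word = q[i : i + w]
        if "N" in word:
            continue
        for j in idx.get(word, ()):
            by_diag.setdefault(i - j, []).append((i, j))
    segments: list[_Segment] = []
    for diag in sorted(by_diag):
        covered = -1
        for qpos, spos in sorted(by_diag[diag]):
            if qpos + w <= covered:
                continue
            seg = _extend_ungapped(q, s, qpos, spos, w, p)
            covered = seg.qe
            segments.append(seg)
    return segments


def _chain_segments(segments: list[_Segment], p: HomologyParams) -> list[list[_Segment]]:
    """Greedy collinear chaining of ungapped segments into gapped candidates."""
    segs = sorted(segments, key=lambda t: (t.qs, t.ss))
    chains: list[list[_Segment]] = []
    open_chains: list[list[_Segment]] = []
    for seg in segs:
        best = None
        for ch in open_chains:
            last = ch[-1]
            qgap = seg.qs - last.qe
            sgap = seg.ss - last.se
            if (
                -p.band <= qgap <= p.chain_gap
                and -p.band <= sgap <= p.chain_gap
                and abs(seg.diag - last.diag) <= p.band
                and seg.qe > last.qe
                and seg.se > last.se
            ):
                if best is None or last.qe > best[-1].qe:
                    best = ch
        if best is not None:
            best.append(seg)
        else:
            ch = [seg]
            chains.append(ch)
            open_chains.append(ch)
        open_chains = [c for c in open_chains if c[-1].qe >= seg.qs - p.chain_gap]
    return chains


def _make_aligner(p: HomologyParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = p.match
    aligner.mismatch_score = p.mismatch
    # our convention: gap of length L costs gap_open + L*gap_extend
    aligner.open_gap_score = p.gap_open + p.gap_extend
    aligner.extend_gap_score = p.gap_extend
    return aligner


def _refine_chain(q: str, s: str, chain: list[_Segment], p: HomologyParams, aligner: Align.PairwiseAligner) -> _Segment | None:
    """Gapped local re-alignment over a multi-segment chain's bounding box."""
    pad = p.band
    qs = max(0, min(t.qs for t in chain) - pad)
    qe = min(len(q), max(t.qe for t in chain) + pad)
    ss = max(0, min(t.ss for t in chain) - pad)
    se = min(len(s), max(t.se for t in chain) + pad)
    alns = aligner.align(q[qs:qe], s[ss:se])
    if len(alns) == 0:
        return None
    aln = alns[0]
    qblocks, sblocks = aln.aligned
    if len(qblocks) == 0:
        return None
    counts = aln.counts()
    matches = counts.identities
    columns = counts.identities + counts.mismatches + counts.gaps
    seg = _Segment(
        qs=qs + int(qblocks[0][0]),
        qe=qs + int(qblocks[-1][1]),
        ss=ss + int(sblocks[0][0]),
        se=ss + int(sblocks[-1][1]),
        score=int(aln.score),
        matches=matches,
    )
    seg.columns = columns  # type: ignore[attr-defined]
    return seg


def _segment_to_hsp(
    seg: _Segment, qid: str, sid: str, strand: str, slen: int, m: int, n: int, p: HomologyParams
) -> Hsp:
    columns = getattr(seg, "columns", seg.qe - seg.qs)
    if strand == "+":
        s_iv = Interval(sid, seg.ss, seg.se, "+")
    else:
        # coordinates were computed on revcomp(subject); map back
        s_iv = Interval(sid, slen - seg.se, slen - seg.ss, "-")
    return Hsp(
        query=Interval(qid, seg.qs, seg.qe, "+"),
        subject=s_iv,
        strand=strand,
        score=seg.score,
        identity=seg.matches / columns if columns else 0.0,
        align_len=columns,
        evalue=evalue(seg.score, m, n, p),
    )


def _drop_shadows(hsps: list[Hsp]) -> list[Hsp]:
    """Remove HSPs whose query and subject spans are contained in a better hit."""
    kept: list[Hsp] = []
    for h in sorted(hsps, key=lambda x: (-x.score, x.query.start, x.subject.start)):
        shadowed = False
        for k in kept:
            if (
                k.strand == h.strand
                and k.query.start <= h.query.start
                and h.query.end <= k.query.end
                and k.subject.start <= h.subject.start
                and h.subject.end <= k.subject.end
            ):
                shadowed = True
                break
        if not shadowed:
            kept.append(h)
    return kept


def find_hsps(query: Genome, subject: Genome, params: HomologyParams | None = None) -> list[Hsp]:
    """All local alignment hits between two genomes.

    Returns HSPs filtered to ``evalue <= evalue_max``, truncated to
    ``max_hits`` by descending score, deterministically ordered
    (score desc, then query start, then subject start).
    """
    p = params or HomologyParams()
    if not query.seq or not subject.seq:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(p)
    m, n = len(query.seq), len(subject.seq)
    hsps: list[Hsp] = []
    for strand, sseq in (("+", subject.seq), ("-", revcomp(subject.seq))):
        segments = _ungapped_segments(query.seq, sseq, p)
        for chain in _chain_segments(segments, p):
            if len(chain) == 1:
                seg = chain[0]
            else:
                seg = _refine_chain(query.seq, sseq, chain, p, aligner)
                if seg is None:
                    continue
            hsp = _segment_to_hsp(seg, query.id, subject.id, strand, n, m, n, p)
            if hsp.evalue <= p.evalue_max and hsp.align_len >= p.word_size:
                hsps.append(hsp)
    hsps = _drop_shadows(hsps)
    hsps.sort(key=lambda h: (-h.score, h.query.start, h.subject.start))
    return hsps[: p.max_hits]


def hit_coverage(hsps: Sequence[Hsp], on: str = "query") -> tuple[list[Interval], int]:
    """Merged interval union of HSP footprints on one side, and its length."""
    if on not in ("query", "subject"):
        raise ValueError("on must be 'query' or 'subject'")
    ivs = [getattr(h, on) for h in hsps]
    if not ivs:
        return [], 0
    merged = merge_intervals([Interval(iv.seq_id, iv.start, iv.end) for iv in ivs])
    return merged, sum(len(iv) for iv in merged)


def hsps_to_table(hsps: Sequence[Hsp]):
    """blastn -outfmt 6 style table (1-based inclusive; subject reversed on '-')."""
    import pandas as pd

    rows = []
    for h in hsps:
        if h.strand == "+":
            sstart, send = h.subject.start + 1, h.subject.end
        else:
            sstart, send = h.subject.end, h.subject.start + 1
        mismatches = h.align_len - round(h.identity * h.align_len)
        rows.append(
            {
                "qid": h.query.seq_id,
                "sid": h.subject.seq_id,
                "pident": round(100 * h.identity, 3),
                "length": h.align_len,
                "mismatches": mismatches,
                "qstart": h.query.start + 1,
                "qend": h.query.end,
                "sstart": sstart,
                "send": send,
                "evalue": h.evalue,
                "score": h.score,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "qid", "sid", "pident", "length", "mismatches",
            "qstart", "qend", "sstart", "send", "evalue", "score",
        ],
    )
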