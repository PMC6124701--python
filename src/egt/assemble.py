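"""Bait-and-iterate organelle assembly from short paired-end reads.

The strategy mirrors how organelle genomes are routinely fished out of
whole-genome read pools: (1) *bait* read pairs sharing an exact k-mer with
reference seed sequences; (2) build zero-mismatch contigs as maximal
unbranched paths of a de Bruijn graph of the baited reads; (3) *iterate*:
recruit reads overlapping contig ends by exact bases, extend each end by a
strict per-column consensus, and merge contigs whose ends share an exact
overlap, until a single contig closes on itself; (4) circularize by
trimming the terminal exact overlap and report the canonical rotation;
(5) QC by per-base coverage depth, flagging low-coverage intervals and the
plastome-like high-depth peaks that betray mitochondrial plastid DNA.

"Mapping" throughout means exact k-mer anchoring plus ungapped exact
comparison -- the reproducible reading of a zero-mismatch, zero-gap
assembler.  Consensus extension halts at any position where a second
allele has real support, surfacing repeat-boundary ambiguity instead of
guessing a path.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .core import Genome, Interval, Role, Topology, canonical_rotation, revcomp
from .simulate import ReadSet


class AssemblyError(ValueError):
    pass


class AmbiguityError(AssemblyError):
    """Raised when a circle can be closed in more than one way."""


@dataclass
class AssemblyParams:
    bait_k: int = 31
    assembly_k: int = 63
    min_overlap: int = 50
    max_iterations: int = 40
    min_depth_qc: float = 200.0
    plastome_fold_flag: float = 5.0
    # consensus extension: halt when a second allele reaches this support
    branch_frac: float = 0.25
    branch_min: int = 2
    max_reads_per_column: int = 40
    # QC flags narrower than this are sampling noise at threshold crossings
    min_flag_width: int = 25

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise AssemblyError("max_iterations must be >= 1")


@dataclass
class Contig:
    seq: str
    support: list[int] = field(default_factory=list)
    iteration_born: int = 0

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# baiting


def bait_reads(reads: ReadSet, baits: list[Genome], params: AssemblyParams | None = None) -> ReadSet:
    """Keep read pairs in which at least one mate shares an exact bait k-mer.

    Pairs are kept or dropped as a unit; both strands of the baits are
    indexed, so read orientation does not matter.
    """
    p = params or AssemblyParams()
    if not baits:
        raise AssemblyError("baits must be non-empty")
    k = p.bait_k
    if reads.ids and min(len(s) for s in reads.r1 + reads.r2) < k:
        raise AssemblyError(f"bait_k={k} exceeds read length")
    kmers: set[str] = set()
    for b in baits:
        for seq in (b.seq, revcomp(b.seq)):
            for i in range(len(seq) - k + 1):
                w = seq[i : i + k]
                if "N" not in w:
                    kmers.add(w)

    def _hits(seq: str) -> bool:
        return any(seq[i : i + k] in kmers for i in range(len(seq) - k + 1))

    keep = [i for i in range(len(reads)) if _hits(reads.r1[i]) or _hits(reads.r2[i])]
    ids = [reads.ids[i] for i in keep]
    return ReadSet(
        ids=ids,
        r1=[reads.r1[i] for i in keep],
        r2=[reads.r2[i] for i in keep],
        origins={rid: reads.origins[rid] for rid in ids if rid in reads.origins},
    )


# ---------------------------------------------------------------------------
# de Bruijn contigs


def _kmer_counts(reads: ReadSet, k: int) -> Counter:
    counts: Counter = Counter()
    for seq in reads.r1 + reads.r2:
        if len(seq) < k:
            continue
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if "N" not in w:
                counts[w] += 1
    return counts


def build_contigs(reads: ReadSet, params: AssemblyParams | None = None) -> list[Contig]:
    """Maximal unbranched paths of the assembly_k de Bruijn graph.

    Both strands of every read contribute k-mers; each contig is emitted
    once, in its lexicographically smaller orientation.  Per-base support is
    the count of the k-mer covering the base (forward plus reverse counts).
    """
    p = params or AssemblyParams()
    k = p.assembly_k
    if not reads.ids:
        raise AssemblyError("no reads to assemble")
    fwd = _kmer_counts(reads, k)
    if not fwd:
        raise AssemblyError(f"all reads shorter than assembly_k={k}; use a smaller k")
    counts: Counter = Counter(fwd)
    for w, c in fwd.items():
        counts[revcomp(w)] += c
    kset = set(counts)

    def succ(w: str) -> list[str]:
        return [w[1:] + b for b in "ACGT" if w[1:] + b in kset]

    def pred(w: str) -> list[str]:
        return [b + w[:-1] for b in "ACGT" if b + w[:-1] in kset]

    visited: set[str] = set()
    contigs: list[Contig] = []

    def walk(start: str) -> str:
        """Extend an unbranched path forward from start; returns the sequence."""
        path = [start]
        visited.add(start)
        cur = start
        while True:
            nxt = succ(cur)
            if len(nxt) != 1:
                break
            nx = nxt[0]
            if nx in visited or len(pred(nx)) != 1:
                break
            visited.add(nx)
            path.append(nx)
            cur = nx
        return path[0] + "".join(w[-1] for w in path[1:])

    starts = [w for w in kset if len(pred(w)) != 1 or any(len(succ(q)) != 1 for q in pred(w))]
    for w in sorted(starts):
        if w in visited:
            continue
        seq = walk(w)
        contigs.append(Contig(seq=seq))
    # isolated cycles (a clean circular molecule collapses to one cycle)
    for w in sorted(kset):
        if w not in visited:
            contigs.append(Contig(seq=walk(w)))

    uniq: dict[str, Contig] = {}
    for c in contigs:
        key = min(c.seq, revcomp(c.seq))
        if key not in uniq or len(c.seq) > len(uniq[key].seq):
            c.seq = key
            uniq[key] = c
    out = sorted(uniq.values(), key=lambda c: (-len(c.seq), c.seq))
    for c in out:
        c.support = _support(c.seq, counts, k)
    return out


def _support(seq: str, counts: Counter, k: int) -> list[int]:
    if len(seq) < k:
        return [max(1, counts.get(seq, 1))] * len(seq)
    per_kmer = [counts.get(seq[i : i + k], 1) for i in range(len(seq) - k + 1)]
    return [per_kmer[min(i, len(per_kmer) - 1)] for i in range(len(seq))]


# ---------------------------------------------------------------------------
# iterative extension


class _ReadIndex:
    """Sparse k-mer index over both strands of a read set.

    k-mers are indexed every ``step`` offsets; a query therefore probes the
    ``step`` terminal windows of a contig end, which guarantees any read
    overlapping the end by >= k + step bases is found.
    """

    def __init__(self, reads: ReadSet, k: int, step: int = 8):
        self.k = k
        self.step = step
        self.seqs: list[str] = []
        self.index: dict[str, list[tuple[int, int]]] = {}
        for seq in reads.r1 + reads.r2:
            self._add(seq)
            self._add(revcomp(seq))

    def _add(self, seq: str) -> None:
        sid = len(self.seqs)
        self.seqs.append(seq)
        for off in range(0, max(1, len(seq) - self.k + 1), self.step):
            w = seq[off : off + self.k]
            if len(w) == self.k and "N" not in w:
                self.index.setdefault(w, []).append((sid, off))

    def reads_overlapping_end(self, contig: str, min_overlap: int) -> list[tuple[str, int]]:
        """(read sequence, overlap length) for reads exactly matching the
        contig suffix and extending beyond it."""
        e = len(contig)
        out = []
        seen: set[tuple[int, int]] = set()
        for j in range(self.step):
            qpos = e - self.k - j
            if qpos < 0:
                break
            w = contig[qpos : qpos + self.k]
            for sid, off in self.index.get(w, ()):
                p = qpos - off  # implied read start on the contig
                key = (sid, p)
                if key in seen:
                    continue
                seen.add(key)
                seq = self.seqs[sid]
                ov = e - p
                if ov < min_overlap or ov >= len(seq) or p < 0:
                    continue
                if seq[:ov] == contig[p:]:
                    out.append((seq, ov))
        return out


def _extend_right(contig: str, index: _ReadIndex, p: AssemblyParams, cap: int) -> str:
    """Consensus extension of the right end until ambiguity or no recruits."""
    while len(contig) < cap:
        cands = index.reads_overlapping_end(contig, p.min_overlap)
        overhangs = sorted(
            (seq[ov:] for seq, ov in cands if len(seq) > ov),
            key=len,
            reverse=True,
        )[: p.max_reads_per_column]
        if not overhangs:
            break
        ext: list[str] = []
        col = 0
        max_col = max(len(o) for o in overhangs)
        halted = False
        while col < max_col:
            column = [o[col] for o in overhangs if len(o) > col]
            if not column:
                break
            tally = Counter(column).most_common()
            top, top_n = tally[0]
            second_n = tally[1][1] if len(tally) > 1 else 0
            total = len(column)
            if second_n == top_n or second_n >= max(p.branch_min, int(np.ceil(p.branch_frac * total))):
                halted = True
                break
            ext.append(top)
            col += 1
        if not ext:
            break
        contig = contig + "".join(ext)
        if halted:
            break
    return contig


def _max_suffix_prefix(x: str, y: str, min_overlap: int) -> int:
    """Largest L >= min_overlap with x[-L:] == y[:L]; 0 if none."""
    probe = x[-min_overlap:]
    if len(probe) < min_overlap:
        return 0
    best = 0
    start = 0
    while True:
        q = y.find(probe, start)
        if q == -1:
            break
        L = q + min_overlap
        if L <= len(x) and x[-L:] == y[:L]:
            best = max(best, L)
        start = q + 1
    return best


def _self_closure(seq: str, min_overlap: int) -> list[int]:
    """All L >= min_overlap with seq[:L] == seq[-L:] (candidate closures)."""
    out = []
    probe = seq[:min_overlap]
    start = 0
    while True:
        q = seq.find(probe, max(start, 1))
        if q == -1:
            break
        L = len(seq) - q
        if L >= min_overlap and seq[:L] == seq[q:]:
            out.append(L)
        start = q + 1
    return sorted(set(out), reverse=True)


def extend_iterate(
    contigs: list[Contig], all_reads: ReadSet, params: AssemblyParams | None = None
) -> list[Contig]:
    """Iteratively extend contig ends and merge overlapping contigs.

    Each iteration: (a) every contig end is extended by the strict consensus
    of exactly-overlapping recruited reads (both ends, via reverse
    complement); (b) contigs wholly contained in another are removed;
    (c) the pair of contigs with the longest exact end-to-end overlap
    (>= min_overlap, any orientation) is merged.  Stops when nothing grows,
    when a lone contig closes on itself, or at max_iterations.  The longest
    contig length never decreases across iterations.
    """
    p = params or AssemblyParams()
    if not contigs:
        return []
    index = _ReadIndex(all_reads, p.bait_k) if all_reads.ids else None
    seqs = [c.seq for c in contigs]
    cap = 2 * sum(len(s) for s in seqs) + 10 * p.bait_k
    for iteration in range(1, p.max_iterations + 1):
        if len(seqs) == 1 and _self_closure(seqs[0], p.min_overlap):
            break
        grew = False
        if index is not None:
            new_seqs = []
            for s in seqs:
                s2 = _extend_right(s, index, p, cap)
                s2 = revcomp(_extend_right(revcomp(s2), index, p, cap))
                if len(s2) > len(s):
                    grew = True
                new_seqs.append(s2)
            seqs = new_seqs
        # containment removal (exact substring, either orientation)
        seqs = sorted(seqs, key=len, reverse=True)
        kept: list[str] = []
        for s in seqs:
            if any(s in t or revcomp(s) in t for t in kept):
                continue
            kept.append(s)
        seqs = kept
        merged = _merge_once(seqs, p)
        if merged is not None:
            seqs = merged
            grew = True
        if not grew:
            break
    counts = _kmer_counts(all_reads, p.assembly_k) if all_reads.ids else Counter()
    full: Counter = Counter(counts)
    for w, c in counts.items():
        full[revcomp(w)] += c
    out = []
    for s in sorted(seqs, key=lambda x: (-len(x), x)):
        out.append(Contig(seq=s, support=_support(s, full, p.assembly_k), iteration_born=iteration))
    return out


def _merge_once(seqs: list[str], p: AssemblyParams) -> list[str] | None:
    """Merge the contig pair with the longest exact end overlap, if any."""
    best = None
    for i in range(len(seqs)):
        for j in range(len(seqs)):
            if i == j:
                continue
            for flip in (False, True):
                y = revcomp(seqs[j]) if flip else seqs[j]
                L = _max_suffix_prefix(seqs[i], y, p.min_overlap)
                if L and (best is None or L > best[0]):
                    best = (L, i, j, flip)
    if best is None:
        return None
    L, i, j, flip = best
    y = revcomp(seqs[j]) if flip else seqs[j]
    merged = seqs[i] + y[L:]
    return [merged] + [s for k, s in enumerate(seqs) if k not in (i, j)]


def circularize(contig: Contig, params: AssemblyParams | None = None, genome_id: str = "assembly") -> tuple[Genome, bool]:
    """Close a contig into a circle by trimming its terminal exact overlap.

    Returns (genome, closed).  If the two ends share an exact overlap
    >= min_overlap the duplicate copy is trimmed and the genome is emitted
    circular at its canonical rotation; otherwise the contig is returned
    linear and flagged not-closed.  Genuinely distinct closure overlaps (not
    explained by the periodicity of the longest one) raise AmbiguityError.
    """
    p = params or AssemblyParams()
    seq = contig.seq
    candidates = _self_closure(seq, p.min_overlap)
    if not candidates:
        return Genome(id=genome_id, seq=seq, topology=Topology.linear, role=Role.contig), False
    L = candidates[0]
    for L2 in candidates[1:]:
        # implied by periodicity of the main closure?
        if seq[:L2] != seq[L - L2 : L]:
            raise AmbiguityError(f"multiple distinct closure overlaps: {candidates}")
    closed = canonical_rotation(seq[: len(seq) - L])
    return Genome(id=genome_id, seq=closed, topology=Topology.circular, role=Role.contig), True


# ---------------------------------------------------------------------------
# coverage QC


def coverage_profile(
    genome: Genome, reads: ReadSet, params: AssemblyParams | None = None
) -> tuple[np.ndarray, list[tuple[Interval, str]], list[str]]:
    """Per-base read depth by exact k-mer anchored placement, with QC flags.

    Reads are placed wherever they match the genome exactly (both strands;
    circular genomes wrap); a read matching several loci contributes
    1/n_loci depth to each, so exact repeats keep their true copy depth.
    Intervals with depth < min_depth_qc are flagged ``low``; intervals with
    depth >= plastome_fold_flag x median are flagged
    ``plastome_like_high_depth`` -- the signature of plastome-shared
    (MTPT) regions in an organelle read pool.
    """
    p = params or AssemblyParams()
    n = len(genome)
    depth = np.zeros(n, dtype=float)
    warns: list[str] = []
    circular = genome.topology is Topology.circular
    text = genome.seq + genome.seq[: 2 * p.bait_k] if circular else genome.seq
    k = p.bait_k
    idx: dict[str, list[int]] = {}
    for i in range(len(text) - k + 1):
        if (not circular) or i < n:
            w = text[i : i + k]
            if "N" not in w:
                idx.setdefault(w, []).append(i)
    if not reads.ids:
        warns.append("empty read set: profile is all-low")
    big = genome.seq + genome.seq if circular else genome.seq
    for seq in list(reads.r1) + list(reads.r2):
        placements: set[int] = set()
        for s in (seq, revcomp(seq)):
            if len(s) < k:
                continue
            for pos in idx.get(s[:k], ()):
                if pos + len(s) <= len(big) and big[pos : pos + len(s)] == s:
                    placements.add(pos)
        if placements:
            share = 1.0 / len(placements)
            for pos in placements:
                if pos + len(seq) <= n:
                    depth[pos : pos + len(seq)] += share
                else:  # wraps the origin
                    depth[pos:n] += share
                    depth[: (pos + len(seq)) - n] += share
    flags: list[tuple[Interval, str]] = []
    flags += [
        (iv, "low")
        for iv in _runs(depth < p.min_depth_qc, genome.id)
        if len(iv) >= p.min_flag_width
    ]
    med = float(np.median(depth))
    if med > 0:
        flags += [
            (iv, "plastome_like_high_depth")
            for iv in _runs(depth >= p.plastome_fold_flag * med, genome.id)
            if len(iv) >= p.min_flag_width
        ]
    else:
        warns.append("median depth is zero; high-depth flags suppressed")
    return depth, flags, warns


def _runs(mask: np.ndarray, seq_id: str) -> list[Interval]:
    out = []
    diff = np.diff(np.concatenate(([0], mask.astype(int), [0])))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for s, e in zip(starts, ends):
        out.append(Interval(seq_id, int(s), int(e)))
    return out


def assemble_genome(
    reads: ReadSet, baits: list[Genome], params: AssemblyParams | None = None, genome_id: str = "assembly"
) -> tuple[Genome, bool, list[Contig]]:
    """Bait -> build -> extend -> circularize convenience pipeline."""
    p = params or AssemblyParams()
    baited = bait_reads(reads, baits, p)
    contigs = build_contigs(baited, p)
    contigs = extend_iterate(contigs, baited, p)
    genome, closed = circularize(contigs[0], p, genome_id=genome_id)
    return genome, closed, contigs
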