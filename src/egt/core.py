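"""Domain types, interval arithmetic, and standard-format I/O.

Coordinates are 0-based half-open everywhere inside the package; GFF3
output converts to 1-based inclusive, BED output stays 0-based half-open.
Circular genomes are stored linearized at a canonical rotation (the
lexicographically minimal rotation of the smaller of the sequence and its
reverse complement), so assemblies of the same molecule compare equal
string-wise regardless of where the assembler happened to open the circle.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised for malformed input files or invalid sequence content."""


class Topology(str, enum.Enum):
    circular = "circular"
    linear = "linear"


class Role(str, enum.Enum):
    mitogenome = "mitogenome"
    plastome = "plastome"
    nuclear_chromosome = "nuclear_chromosome"
    contig = "contig"


class FeatureKind(str, enum.Enum):
    gene = "gene"
    rRNA = "rRNA"
    tRNA = "tRNA"
    ORF = "ORF"
    MTPT = "MTPT"
    other = "other"


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution, N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_seq(seq: str, record_id: str = "?") -> str:
    """Upper-case and validate a DNA string; reject U and other non-IUPAC letters.

    Ambiguity codes other than N are rejected: every downstream exact-match
    primitive (baiting, repeat search, seeding) treats the alphabet as
    {A,C,G,T} plus an N that never matches anything.
    """
    seq = seq.upper()
    bad = set(seq) - VALID_ALPHABET
    if bad:
        pos = next(i for i, c in enumerate(seq) if c in bad)
        raise FormatError(
            f"record {record_id!r}: invalid character {seq[pos]!r} at position {pos}"
        )
    return seq


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open interval [start, end) on a named sequence.

    A feature spanning the circular origin is represented as an ordered pair
    of intervals (see :func:`wrap_interval`), never with end < start.
    """

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "Interval") -> float:
        """min(overlap/len(self), overlap/len(other)); 0 across sequences."""
        ov = self.overlap(other)
        if ov == 0:
            return 0.0
        return min(ov / len(self), ov / len(other))

    def contains(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start <= other.start
            and other.end <= self.end
        )


def wrap_interval(seq_id: str, start: int, end: int, n: int, strand: str = "+") -> list[Interval]:
    """Normalize an interval on a circular sequence of length n.

    start may be any integer, end > start, end - start <= n.  Returns one
    interval if the span does not cross the origin, otherwise the ordered
    pair of sub-intervals on either side of it.
    """
    length = end - start
    if length > n:
        raise ValueError("interval longer than the circular sequence")
    start %= n
    end = start + length
    if end <= n:
        return [Interval(seq_id, start, end, strand)]
    return [
        Interval(seq_id, start, n, strand),
        Interval(seq_id, 0, end - n, strand),
    ]


@dataclass(frozen=True)
class Feature:
    interval: Interval
    kind: FeatureKind
    name: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("feature name must be non-empty")
        if self.kind is FeatureKind.ORF and len(self.interval) % 3 != 0:
            raise ValueError("ORF length must be divisible by 3")


@dataclass
class Genome:
    """A sequence with an id, a topology, and a biological role."""

    id: str
    seq: str
    topology: Topology = Topology.linear
    role: Role = Role.contig

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"genome {self.id!r} has empty sequence")
        self.seq = validate_seq(self.seq, self.id)
        self.topology = Topology(self.topology)
        self.role = Role(self.role)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> float:
        """GC fraction over non-N bases."""
        acgt = sum(self.seq.count(b) for b in "ACGT")
        if acgt == 0:
            return 0.0
        return (self.seq.count("G") + self.seq.count("C")) / acgt


@dataclass(frozen=True)
class PlastomeStructure:
    """Quadripartite plastome partition: LSC - IRa - SSC - IRb.

    The four intervals tile the plastome with no gaps or overlaps and the
    IRb sequence is the exact reverse complement of the IRa sequence.
    """

    lsc: Interval
    ira: Interval
    ssc: Interval
    irb: Interval

    def __post_init__(self) -> None:
        parts = [self.lsc, self.ira, self.ssc, self.irb]
        ids = {p.seq_id for p in parts}
        if len(ids) != 1:
            raise ValueError("plastome structure spans multiple sequences")
        ordered = sorted(parts, key=lambda p: p.start)
        if ordered[0].start != 0:
            raise ValueError("structure must start at position 0")
        for a, b in zip(ordered, ordered[1:]):
            if a.end != b.start:
                raise ValueError("structure intervals must tile without gaps/overlaps")

    @property
    def length(self) -> int:
        return max(p.end for p in (self.lsc, self.ira, self.ssc, self.irb))

    def compartment_of(self, pos: int) -> str:
        """Compartment class (LSC/SSC/IR) containing a position."""
        for name, iv in (("LSC", self.lsc), ("SSC", self.ssc), ("IR", self.ira), ("IR", self.irb)):
            if iv.start <= pos < iv.end:
                return name
        raise ValueError(f"position {pos} outside plastome of length {self.length}")

    def project_onto_ira(self, start: int, end: int) -> tuple[int, int] | None:
        """Map the IR part of [start, end) onto IRa coordinates.

        An interval hitting IRb is reflected onto the equivalent IRa
        positions so that identical hits to the two IR copies merge before
        per-compartment totals are taken.  Returns None if the interval does
        not touch either IR copy.
        """
        s = max(start, self.ira.start)
        e = min(end, self.ira.end)
        if s < e:
            return s, e
        s = max(start, self.irb.start)
        e = min(end, self.irb.end)
        if s < e:
            # reflect: position p in IRb pairs with ira.start + (irb.end-1-p)
            return (
                self.ira.start + (self.irb.end - e),
                self.ira.start + (self.irb.end - s),
            )
        return None


# ---------------------------------------------------------------------------
# interval arithmetic


def merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Union of intervals on one sequence, merged and sorted; strand ignored."""
    if not intervals:
        return []
    ids = {iv.seq_id for iv in intervals}
    if len(ids) != 1:
        raise ValueError(f"intervals span multiple sequences: {sorted(ids)}")
    seq_id = ids.pop()
    spans = sorted((iv.start, iv.end) for iv in intervals)
    merged: list[list[int]] = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [Interval(seq_id, s, e) for s, e in merged]


def interval_union_length(intervals: Sequence[Interval]) -> int:
    """Total bp covered by at least one interval; overlap counted once."""
    return sum(len(iv) for iv in merge_intervals(intervals))


def canonical_rotation(seq: str) -> str:
    """Canonical linearization of a circular sequence.

    The lexicographically minimal rotation of min(seq, revcomp(seq)) — a
    deterministic opening point, so two assemblies of the same circle are
    string-equal.  Booth's algorithm, O(n).
    """
    rc = revcomp(seq)
    best = None
    for s in (seq, rc):
        i = _least_rotation(s)
        cand = s[i:] + s[:i]
        if best is None or cand < best:
            best = cand
    return best  # type: ignore[return-value]


def _least_rotation(s: str) -> int:
    """Index of the lexicographically least rotation (Booth's algorithm)."""
    ss = s + s
    n = len(ss)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


# ---------------------------------------------------------------------------
# readers / writers (deterministic: records in input / sorted order)


def read_fasta(
    path: str | Path,
    role: Role | str = Role.contig,
    topology: Topology | str = Topology.linear,
) -> list[Genome]:
    """Read a FASTA file into Genomes.

    role/topology apply to every record unless a record header carries
    ``[role=...]`` / ``[topology=...]`` tags (the dialect our own writer
    emits).  Sequences are upper-cased; U and ambiguity codes other than N
    are format errors naming the record and offending position.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    genomes = []
    for rec in records:
        r, t = Role(role), Topology(topology)
        for tok in rec.description.split():
            if tok.startswith("[role=") and tok.endswith("]"):
                r = Role(tok[6:-1])
            elif tok.startswith("[topology=") and tok.endswith("]"):
                t = Topology(tok[10:-1])
        genomes.append(Genome(id=rec.id, seq=str(rec.seq), topology=t, role=r))
    return genomes


def write_fasta(genomes: Iterable[Genome], path: str | Path, tags: bool = True, width: int = 70) -> None:
    records = []
    for g in genomes:
        desc = f"[role={g.role.value}] [topology={g.topology.value}]" if tags else ""
        records.append(SeqRecord(Seq(g.seq), id=g.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_gff3(features: Iterable[Feature], path: str | Path, source: str = "egt") -> None:
    """Write features as GFF3 (1-based inclusive), sorted by (seq, start, name)."""
    feats = sorted(features, key=lambda f: (f.interval.seq_id, f.interval.start, f.name))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in feats:
            iv = f.interval
            fh.write(
                "\t".join(
                    [
                        iv.seq_id,
                        source,
                        f.kind.value,
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        f"ID={f.name}",
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[Feature]:
    """Read the simple GFF3 dialect written by :func:`write_gff3`."""
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise FormatError(f"{path}: malformed GFF3 line: {line!r}")
            seq_id, _src, kind, start, end, _score, strand, _frame, attrs = cols[:9]
            name = "unknown"
            for kv in attrs.split(";"):
                if kv.startswith("ID=") or kv.startswith("Name="):
                    name = kv.split("=", 1)[1]
                    break
            try:
                k = FeatureKind(kind)
            except ValueError:
                k = FeatureKind.other
            feats.append(
                Feature(
                    interval=Interval(seq_id, int(start) - 1, int(end), strand if strand in "+-" else "+"),
                    kind=k,
                    name=name,
                )
            )
    return feats


def write_bed6(rows: Iterable[tuple[Interval, str, int]], path: str | Path) -> None:
    """Write (interval, name, score) rows as BED6, 0-based half-open, sorted."""
    rows = sorted(rows, key=lambda r: (r[0].seq_id, r[0].start, r[0].end, r[1]))
    with open(path, "w") as fh:
        for iv, name, score in rows:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")
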