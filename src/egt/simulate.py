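"""Synthetic organellar/nuclear genome and read simulator with ground truth.

The generator emulates the statistical structure of a solanaceous genome
trio: a quadripartite circular plastome (LSC-IRa-SSC-IRb, IRb the exact
reverse complement of IRa), a circular mitogenome a few hundred kb long
carrying exact repeat families (0.1-20 kb, direct and inverted) and
verbatim plastome implants (MTPTs), and nuclear chromosomes carrying
organellar implants (NUMTs/NUPTs) -- scattered small fragments plus tightly
clustered large ones -- degraded by substitutions and indels according to a
per-implant "age" (divergence).  Paired-end reads are drawn uniformly with
a normal insert-size distribution, honoring circularity.

Every implanted event is logged in a :class:`GroundTruth` manifest, the
oracle for all recovery tests downstream.  Identical configs (including the
seed) produce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    Feature,
    FeatureKind,
    Genome,
    Interval,
    PlastomeStructure,
    Role,
    Topology,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RepeatSpec:
    """One exact repeat family to implant: copy count includes the original."""

    length: int
    orientation: str = "direct"  # direct | inverted
    copies: int = 2


@dataclass(frozen=True)
class MtptSpec:
    """A verbatim plastome segment to implant into the mitogenome."""

    length: int
    compartment: str = "any"  # LSC | SSC | IR | any
    count: int = 1


@dataclass(frozen=True)
class ImplantSpec:
    """Organellar fragments to implant into nuclear chromosomes."""

    length: int
    count: int = 1
    divergence: float = 0.0
    clustered: bool = False
    chromosome: int | None = None  # 0-based index, None = random

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence <= 0.3):
            raise ConfigError("divergence must lie in [0, 0.3]")


@dataclass
class SimConfig:
    """Generator configuration; defaults mirror a tomato-like genome trio.

    Organellar sizes follow the published tomato values (155 kb plastome
    with 25 kb inverted repeats; ~430 kb mitogenome with tens of kb of
    duplication; 9,598 bp of plastome implants split 2,558/32/7,008 bp over
    LSC/SSC/IR); nuclear chromosomes are kept to a few hundred kb -- real
    chromosomes are three orders larger, but the implant spectrum (many
    scattered ~0.1-0.3 kb copies plus clustered multi-kb copies) is what the
    callers exercise.  Reads default to 200x coverage of 100 bp pairs with
    a 400 +/- 60 bp insert.
    """

    seed: int = 0
    # plastome geometry
    plastome_len: int = 155_000
    ir_len: int = 25_000
    ssc_len: int = 18_000
    # mitogenome
    mito_len: int = 430_000
    repeat_spec: tuple[RepeatSpec, ...] = (
        RepeatSpec(20_000, "direct"),
        RepeatSpec(8_000, "inverted"),
        RepeatSpec(4_000, "direct"),
        RepeatSpec(1_000, "direct"),
        RepeatSpec(300, "inverted"),
        RepeatSpec(100, "direct"),
    )
    mtpt_spec: tuple[MtptSpec, ...] = (
        MtptSpec(2_558, "LSC"),
        MtptSpec(32, "SSC"),
        MtptSpec(7_008, "IR"),
    )
    # nuclear genome
    n_chromosomes: int = 3
    chrom_len: int = 300_000
    numt_spec: tuple[ImplantSpec, ...] = (
        ImplantSpec(150, count=20, divergence=0.02),
        ImplantSpec(400, count=10, divergence=0.01),
        ImplantSpec(3_000, count=4, divergence=0.01, clustered=True),
    )
    nupt_spec: tuple[ImplantSpec, ...] = (
        ImplantSpec(150, count=15, divergence=0.02),
        ImplantSpec(2_000, count=3, divergence=0.005, clustered=True),
    )
    # reads
    read_len: int = 100
    insert_mean: int = 400
    insert_sd: int = 60
    depth: float = 200.0
    error_rate: float = 0.0
    gc: float = 0.45

    def __post_init__(self) -> None:
        if self.ir_len < 1 or 2 * self.ir_len + self.ssc_len >= self.plastome_len:
            raise ConfigError("need 2*ir_len + ssc_len < plastome_len and ir_len >= 1")
        for name in ("plastome_len", "ssc_len", "mito_len", "chrom_len", "read_len"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")
        if not (0.0 <= self.error_rate < 1.0):
            raise ConfigError("error_rate must lie in [0, 1)")


@dataclass(frozen=True)
class Event:
    klass: str  # repeat | MTPT | NUMT | NUPT
    source: Interval
    target: Interval
    divergence_applied: float = 0.0
    indels_applied: int = 0
    orientation: str = "+"


@dataclass
class GroundTruth:
    """Exhaustive log of implanted events plus per-read true origins."""

    events: list[Event] = field(default_factory=list)
    read_origins: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def of_class(self, klass: str) -> list[Event]:
        return [e for e in self.events if e.klass == klass]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "events": [
                {
                    "klass": e.klass,
                    "source": [e.source.seq_id, e.source.start, e.source.end],
                    "target": [e.target.seq_id, e.target.start, e.target.end],
                    "divergence_applied": e.divergence_applied,
                    "indels_applied": e.indels_applied,
                    "orientation": e.orientation,
                }
                for e in self.events
            ]
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        gt = cls()
        for e in payload["events"]:
            gt.events.append(
                Event(
                    klass=e["klass"],
                    source=Interval(*e["source"]),
                    target=Interval(*e["target"]),
                    divergence_applied=e["divergence_applied"],
                    indels_applied=e["indels_applied"],
                    orientation=e.get("orientation", "+"),
                )
            )
        return gt


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p).tobytes().decode()


def _other_base(rng: np.random.Generator, avoid: str) -> str:
    """A base guaranteed to differ from ``avoid``."""
    choices = [b for b in "ACGT" if b != avoid]
    return choices[int(rng.integers(len(choices)))]


def _guard_flanks(
    rng: np.random.Generator,
    seq: list[str],
    start: int,
    end: int,
    left_ctx: str,
    right_ctx: str,
    width: int = 2,
) -> None:
    """Force up to ``width`` bases on each implant flank to mismatch the
    source-adjacent bases, making implant boundaries sharp: alignment
    extension cannot walk past them, so truth intervals and called
    intervals agree at base resolution on undiverged implants.

    ``left_ctx``/``right_ctx`` are the source bases adjacent to the implant
    in implant orientation (left_ctx ends at the base just before it).
    """
    for k in range(1, width + 1):
        pos = start - k
        if pos >= 0 and len(left_ctx) >= k:
            src = left_ctx[-k]
            if seq[pos] == src:
                seq[pos] = _other_base(rng, src)
        pos = end + (k - 1)
        if pos < len(seq) and len(right_ctx) >= k:
            src = right_ctx[k - 1]
            if seq[pos] == src:
                seq[pos] = _other_base(rng, src)


def _oriented_context(source_seq: str, s: int, e: int, orient: str, width: int = 2) -> tuple[str, str]:
    """Source bases flanking [s, e), in implant orientation."""
    left = source_seq[max(0, s - width) : s]
    right = source_seq[e : e + width]
    if orient == "-":
        left, right = revcomp(right), revcomp(left)
    return left, right


def _place(rng: np.random.Generator, occupied: list[tuple[int, int]], length: int, genome_len: int, tries: int = 2000) -> int:
    """Uniform random placement rejected on overlap with prior implants."""
    for _ in range(tries):
        start = int(rng.integers(0, genome_len - length + 1))
        if all(start + length <= s or start >= e for s, e in occupied):
            occupied.append((start, start + length))
            return start
    raise ConfigError("could not place implant: requested implants exceed genome capacity")


def simulate_plastome(cfg: SimConfig) -> tuple[Genome, PlastomeStructure]:
    """Quadripartite circular plastome; IRb is exactly revcomp(IRa)."""
    rng = np.random.default_rng(cfg.seed * 16 + 1)
    lsc_len = cfg.plastome_len - 2 * cfg.ir_len - cfg.ssc_len
    seq = _random_seq(rng, cfg.plastome_len - cfg.ir_len, cfg.gc)
    lsc = seq[:lsc_len]
    ira = seq[lsc_len : lsc_len + cfg.ir_len]
    ssc = seq[lsc_len + cfg.ir_len :]
    full = lsc + ira + ssc + revcomp(ira)
    gid = "plastome"
    structure = PlastomeStructure(
        lsc=Interval(gid, 0, lsc_len),
        ira=Interval(gid, lsc_len, lsc_len + cfg.ir_len),
        ssc=Interval(gid, lsc_len + cfg.ir_len, lsc_len + cfg.ir_len + cfg.ssc_len),
        irb=Interval(gid, cfg.plastome_len - cfg.ir_len, cfg.plastome_len),
    )
    genome = Genome(id=gid, seq=full, topology=Topology.circular, role=Role.plastome)
    return genome, structure


def simulate_mitogenome(
    cfg: SimConfig,
    plastome: Genome | None = None,
    structure: PlastomeStructure | None = None,
) -> tuple[Genome, GroundTruth]:
    """Circular mitogenome with exact repeat families and MTPT implants.

    Repeat families copy a stretch of the background to the other copy
    locations (reverse-complemented for inverted families); MTPTs are copied
    verbatim from the plastome compartment named in the spec.  All implants
    are placed uniformly at random, rejected on overlap, and logged.
    """
    if cfg.mtpt_spec and plastome is None:
        raise ConfigError("mtpt_spec given but no plastome supplied")
    rng = np.random.default_rng(cfg.seed * 16 + 2)
    seq = list(_random_seq(rng, cfg.mito_len, cfg.gc))
    gid = "mitogenome"
    truth = GroundTruth()
    occupied: list[tuple[int, int]] = []

    total = sum(r.length * r.copies for r in cfg.repeat_spec) + sum(
        m.length * m.count for m in cfg.mtpt_spec
    )
    if total >= cfg.mito_len:
        raise ConfigError("requested repeats/implants exceed genome length")

    for spec in cfg.repeat_spec:
        starts = [_place(rng, occupied, spec.length, cfg.mito_len) for _ in range(spec.copies)]
        src = "".join(seq[starts[0] : starts[0] + spec.length])
        source_iv = Interval(gid, starts[0], starts[0] + spec.length)
        src_left = "".join(seq[max(0, starts[0] - 2) : starts[0]])
        src_right = "".join(seq[starts[0] + spec.length : starts[0] + spec.length + 2])
        for s in starts[1:]:
            copy = src if spec.orientation == "direct" else revcomp(src)
            seq[s : s + spec.length] = copy
            if spec.orientation == "direct":
                lctx, rctx = src_left, src_right
            else:
                lctx, rctx = revcomp(src_right), revcomp(src_left)
            _guard_flanks(rng, seq, s, s + spec.length, lctx, rctx)
            truth.events.append(
                Event(
                    klass="repeat",
                    source=source_iv,
                    target=Interval(gid, s, s + spec.length),
                    orientation="+" if spec.orientation == "direct" else "-",
                )
            )

    for spec in cfg.mtpt_spec:
        for _ in range(spec.count):
            src_start = _pick_compartment_start(rng, spec, structure, plastome)
            frag = plastome.seq[src_start : src_start + spec.length]
            s = _place(rng, occupied, spec.length, cfg.mito_len)
            seq[s : s + spec.length] = frag
            lctx, rctx = _oriented_context(plastome.seq, src_start, src_start + spec.length, "+")
            _guard_flanks(rng, seq, s, s + spec.length, lctx, rctx)
            truth.events.append(
                Event(
                    klass="MTPT",
                    source=Interval(plastome.id, src_start, src_start + spec.length),
                    target=Interval(gid, s, s + spec.length),
                )
            )

    genome = Genome(id=gid, seq="".join(seq), topology=Topology.circular, role=Role.mitogenome)
    return genome, truth


def _pick_compartment_start(
    rng: np.random.Generator,
    spec: MtptSpec,
    structure: PlastomeStructure | None,
    plastome: Genome,
) -> int:
    if structure is None or spec.compartment == "any":
        return int(rng.integers(0, len(plastome) - spec.length + 1))
    if spec.compartment == "LSC":
        iv = structure.lsc
    elif spec.compartment == "SSC":
        iv = structure.ssc
    elif spec.compartment == "IR":
        iv = structure.ira
    else:
        raise ConfigError(f"unknown compartment {spec.compartment!r}")
    if spec.length > len(iv):
        raise ConfigError(f"MTPT of {spec.length} bp does not fit in {spec.compartment}")
    return int(rng.integers(iv.start, iv.end - spec.length + 1))


def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> tuple[str, int]:
    """Substitutions at the divergence rate plus indels at divergence/10.

    Substitutions are uniform over the three alternatives; indel lengths are
    Geometric(0.5) capped at 10 bp, insertions and deletions equally likely.
    Returns the mutated sequence and the number of indel events.
    """
    if divergence == 0.0:
        return seq, 0
    out: list[str] = []
    indels = 0
    bases = "ACGT"
    i = 0
    n = len(seq)
    while i < n:
        if rng.random() < divergence / 10.0:
            indels += 1
            ln = min(int(rng.geometric(0.5)), 10)
            if rng.random() < 0.5:
                out.append("".join(bases[rng.integers(4)] for _ in range(ln)))
                continue  # insertion before seq[i]; do not consume
            else:
                i += ln  # deletion
                continue
        c = seq[i]
        if rng.random() < divergence:
            c = bases[(bases.index(c) + 1 + int(rng.integers(3))) % 4] if c in bases else c
        out.append(c)
        i += 1
    mutated = "".join(out)
    if not mutated:
        mutated = seq[:1]
    return mutated, indels


def simulate_nuclear(
    cfg: SimConfig,
    mito: Genome | None = None,
    plastome: Genome | None = None,
) -> tuple[list[Genome], GroundTruth]:
    """Nuclear chromosomes with implanted, age-degraded organellar fragments.

    Implants are inserted into the background (so the pre/post length
    difference equals total implanted bp).  Scattered fragments go to
    uniform random positions; clustered specs place all ``count`` fragments
    of the spec within one window, separated by background spacers of at
    most 500 bp, so the window spans at most 5x the total implant length.
    """
    rng = np.random.default_rng(cfg.seed * 16 + 3)
    truth = GroundTruth()
    genomes: list[Genome] = []

    # (chrom index) -> list of (bg position, mutated seq, event prototype)
    plans: dict[int, list[tuple[int, str, str, Interval, float, int, str]]] = {
        i: [] for i in range(cfg.n_chromosomes)
    }

    for klass, specs, source in (("NUMT", cfg.numt_spec, mito), ("NUPT", cfg.nupt_spec, plastome)):
        for spec in specs:
            if not spec.count:
                continue
            if source is None:
                raise ConfigError(f"{klass} spec given but no source genome supplied")
            if spec.length > cfg.chrom_len:
                raise ConfigError("implant longer than chromosome")
            if spec.clustered:
                chrom = spec.chromosome if spec.chromosome is not None else int(
                    rng.integers(cfg.n_chromosomes)
                )
                span = 500 * spec.count
                anchor = int(rng.integers(0, max(1, cfg.chrom_len - span)))
                pos = anchor
                for _ in range(spec.count):
                    _add_fragment(rng, plans[chrom], pos, spec, source, klass, None)
                    # spacers stay in [150, 500] bp: tight enough to cluster,
                    # wide enough that neighbours are never chained into one call
                    pos += int(rng.integers(150, 501))
            else:
                for _ in range(spec.count):
                    chrom = spec.chromosome if spec.chromosome is not None else int(
                        rng.integers(cfg.n_chromosomes)
                    )
                    # scattered implants keep >= 1 kb of background between
                    # insertion points so distinct events stay distinct calls
                    pos = None
                    for _try in range(200):
                        cand = int(rng.integers(0, cfg.chrom_len))
                        if all(abs(cand - p[0]) >= 1_000 for p in plans[chrom]):
                            pos = cand
                            break
                    if pos is None:
                        raise ConfigError("could not scatter implant with 1 kb separation")
                    _add_fragment(rng, plans[chrom], pos, spec, source, klass, None)

    for i in range(cfg.n_chromosomes):
        cid = f"chr{i + 1:02d}"
        background = _random_seq(rng, cfg.chrom_len, cfg.gc)
        pieces: list[str] = []
        cursor = 0
        offset = 0
        guards: list[tuple[int, int, str, str]] = []
        chrom_events: list[Event] = []
        for pos, frag, klass, src_iv, div, indels, orient, lctx, rctx in sorted(
            plans[i], key=lambda t: t[0]
        ):
            pieces.append(background[cursor:pos])
            offset += pos - cursor
            target = Interval(cid, offset, offset + len(frag))
            chrom_events.append(
                Event(
                    klass=klass,
                    source=src_iv,
                    target=target,
                    divergence_applied=div,
                    indels_applied=indels,
                    orientation=orient,
                )
            )
            guards.append((offset, offset + len(frag), lctx, rctx))
            pieces.append(frag)
            offset += len(frag)
            cursor = pos
        pieces.append(background[cursor:])
        chrom_seq = list("".join(pieces))
        for start, end, lctx, rctx in guards:
            _guard_flanks(rng, chrom_seq, start, end, lctx, rctx)
        truth.events.extend(chrom_events)
        genomes.append(
            Genome(id=cid, seq="".join(chrom_seq), topology=Topology.linear, role=Role.nuclear_chromosome)
        )
    return genomes, truth


def _add_fragment(
    rng: np.random.Generator,
    plan: list,
    pos: int,
    spec: ImplantSpec,
    source: Genome,
    klass: str,
    _unused,
) -> None:
    src_start = int(rng.integers(0, len(source) - spec.length + 1))
    frag = source.seq[src_start : src_start + spec.length]
    orient = "+"
    if rng.random() < 0.5:
        frag = revcomp(frag)
        orient = "-"
    frag, indels = _mutate(rng, frag, spec.divergence)
    src_iv = Interval(source.id, src_start, src_start + spec.length)
    lctx, rctx = _oriented_context(source.seq, src_start, src_start + spec.length, orient)
    plan.append((pos, frag, klass, src_iv, spec.divergence, indels, orient, lctx, rctx))


@dataclass
class ReadSet:
    """Paired-end reads with per-read true origins."""

    ids: list[str]
    r1: list[str]
    r2: list[str]
    origins: dict[str, tuple[str, int, int]]

    def __len__(self) -> int:
        return len(self.ids)

    def write_fastq(self, path1: str | Path, path2: str | Path, qual: str = "I") -> None:
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for rid, a, b in zip(self.ids, self.r1, self.r2):
                f1.write(f"@{rid}/1\n{a}\n+\n{qual * len(a)}\n")
                f2.write(f"@{rid}/2\n{b}\n+\n{qual * len(b)}\n")

    @classmethod
    def read_fastq(cls, path1: str | Path, path2: str | Path) -> "ReadSet":
        def _read(path):
            ids, seqs = [], []
            with open(path) as fh:
                while True:
                    h = fh.readline()
                    if not h:
                        break
                    seqs.append(fh.readline().strip())
                    ids.append(h.strip().lstrip("@").rsplit("/", 1)[0])
                    fh.readline()
                    fh.readline()
            return ids, seqs

        ids1, r1 = _read(path1)
        _ids2, r2 = _read(path2)
        return cls(ids=ids1, r1=r1, r2=r2, origins={})


def simulate_reads(
    genomes: Sequence[Genome],
    cfg: SimConfig,
    weights: dict[str, float] | None = None,
) -> ReadSet:
    """Paired-end reads: uniform starts (wrapping on circular genomes),
    Normal(insert_mean, insert_sd) insert sizes, per-base error at
    ``error_rate``; mate 2 is the reverse complement of the insert's end.

    ``weights`` multiply the per-genome depth, letting plastome reads
    over-represent plastome-shared mitogenome regions the way real organelle
    read pools do.
    """
    rng = np.random.default_rng(cfg.seed * 16 + 4)
    weights = weights or {}
    ids: list[str] = []
    r1: list[str] = []
    r2: list[str] = []
    origins: dict[str, tuple[str, int, int]] = {}
    rl = cfg.read_len
    for g in genomes:
        if rl > len(g):
            raise ConfigError(f"read_len {rl} exceeds genome {g.id} length {len(g)}")
        w = weights.get(g.id, 1.0)
        n_pairs = int(round(cfg.depth * w * len(g) / (2 * rl)))
        circular = g.topology is Topology.circular
        seq2 = g.seq + g.seq if circular else g.seq
        inserts = np.clip(
            np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_pairs)).astype(int),
            rl,
            len(g),
        )
        if circular:
            starts = rng.integers(0, len(g), size=n_pairs)
        else:
            starts = np.array(
                [int(rng.integers(0, max(1, len(g) - ins + 1))) for ins in inserts]
            )
        for i in range(n_pairs):
            s, ins = int(starts[i]), int(inserts[i])
            a = seq2[s : s + rl]
            b = revcomp(seq2[s + ins - rl : s + ins])
            rid = f"{g.id}_{i}"
            ids.append(rid)
            r1.append(a)
            r2.append(b)
            origins[rid] = (g.id, s, s + ins)
    if cfg.error_rate > 0:
        r1 = [_seq_errors(rng, s, cfg.error_rate) for s in r1]
        r2 = [_seq_errors(rng, s, cfg.error_rate) for s in r2]
    return ReadSet(ids=ids, r1=r1, r2=r2, origins=origins)


def _seq_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    bases = "ACGT"
    for i in hits:
        c = arr[i].decode()
        if c in bases:
            arr[i] = bases[(bases.index(c) + 1 + int(rng.integers(3))) % 4].encode()
    return arr.tobytes().decode()


def truth_features(truth: GroundTruth) -> list[Feature]:
    """Truth events as GFF3-writable features (one per implant target)."""
    feats = []
    for i, e in enumerate(truth.events):
        kind = FeatureKind.MTPT if e.klass == "MTPT" else FeatureKind.other
        feats.append(Feature(interval=e.target, kind=kind, name=f"{e.klass}_{i:04d}"))
    return feats
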