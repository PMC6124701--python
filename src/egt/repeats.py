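"""Exact duplicated-region detection within a genome.

Plant mitogenomes expand through exact repeats (from ~100 bp up to tens of
kb) that drive recombination and rearrangement, so the duplication content
of a mitogenome is summarized as the set of maximal exactly-repeated pairs
of length >= 100 bp with zero mismatches, in both direct and inverted
orientation.

The detector anchors on shared ``min_len``-mers (any repeat of length
>= min_len contains one at its left edge) and extends each anchored pair to
maximality; a per-diagonal coverage marker keeps the cost linear in total
repeat length.  Circular genomes are searched on the doubled sequence and
pairs are deduplicated modulo the genome length.  N never matches anything,
itself included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import Genome, Interval, Topology, interval_union_length, revcomp


@dataclass(frozen=True)
class RepeatPair:
    """One maximal exact duplicated region: two intervals plus orientation."""

    a: Interval
    b: Interval
    orientation: str  # "direct" | "inverted"
    length: int

    def __post_init__(self) -> None:
        if self.orientation not in ("direct", "inverted"):
            raise ValueError("orientation must be direct or inverted")
        if self.a == self.b:
            raise ValueError("repeat members must differ")


@dataclass(frozen=True)
class DupStats:
    genome_id: str
    total_len: int
    total_dup_len: int
    max_dup_len: int

    def __post_init__(self) -> None:
        if not (0 <= self.total_dup_len <= self.total_len):
            raise ValueError("total_dup_len outside [0, total_len]")


def _extend_pair(text: str, i: int, j: int, k: int, limit: int) -> tuple[int, int]:
    """Maximal extension of text[i:i+k] == text[j:j+k]; returns (left, right)."""
    n = len(text)
    left = 0
    while i - left - 1 >= 0 and j - left - 1 >= 0:
        a, b = text[i - left - 1], text[j - left - 1]
        if a != b or a == "N":
            break
        left += 1
        if k + left >= limit:
            break
    right = 0
    while i + k + right < n and j + k + right < n:
        a, b = text[i + k + right], text[j + k + right]
        if a != b or a == "N":
            break
        right += 1
        if k + left + right >= limit:
            break
    return left, right


def _anchor_pairs(
    text_a: str, text_b: str, k: int, limit: int, same: bool
) -> list[tuple[int, int, int]]:
    """Maximal matching runs between two texts via k-mer anchors.

    Returns (start_a, start_b, length) triples, maximally extended within
    each text (texts are concatenated for extension when ``same``).  When
    ``same`` is true, only pairs with start_a < start_b are produced.
    """
    idx: dict[str, list[int]] = {}
    for j in range(len(text_b) - k + 1):
        word = text_b[j : j + k]
        if "N" not in word:
            idx.setdefault(word, []).append(j)
    covered: dict[int, int] = {}  # diagonal -> rightmost covered position in a
    out: list[tuple[int, int, int]] = []
    if same:
        combined = text_a
    else:
        combined = text_a + "\x00" + text_b
        off = len(text_a) + 1
    for i in range(len(text_a) - k + 1):
        word = text_a[i : i + k]
        if "N" in word:
            continue
        for j in idx.get(word, ()):
            if same:
                if j <= i:
                    continue
                jj = j
            else:
                jj = j + off
            diag = jj - i
            if covered.get(diag, -1) >= i + k:
                continue
            left, right = _extend_pair(combined, i, jj, k, limit)
            start_a = i - left
            length = k + left + right
            covered[diag] = start_a + length
            out.append((start_a, (jj - (0 if same else off)) - left, length))
    return out


def find_exact_repeats(genome: Genome, min_len: int = 100) -> list[RepeatPair]:
    """All maximal exact repeated pairs >= min_len within one genome.

    Both orientations are searched; circular genomes are handled by doubling
    the sequence and deduplicating pairs modulo the length.  Pairs crossing
    the circular origin are split at the origin (both members cut at the
    same offset) so that every reported interval satisfies start < end.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    n = len(genome.seq)
    if n < min_len:
        return []
    circular = genome.topology is Topology.circular
    text = genome.seq + genome.seq if circular else genome.seq
    limit = n  # a repeat member cannot exceed the genome length

    # (a0, b0, orientation) -> max length: truncated images of one maximal
    # pair (artifacts of the doubled-sequence search) collapse onto it
    raw: dict[tuple[int, int, str], int] = {}

    def _note(a0: int, b0: int, ln: int, orient: str) -> None:
        key = (a0, b0, orient)
        if raw.get(key, 0) < ln:
            raw[key] = ln

    for sa, sb, length in _anchor_pairs(text, text, min_len, limit, same=True):
        if length < min_len:
            continue
        for a0, b0, ln in _canonical_images(sa, sb, length, n, circular, "direct"):
            _note(a0, b0, ln, "direct")

    rc_text = revcomp(text)
    for sa, sb, length in _anchor_pairs(text, rc_text, min_len, limit, same=False):
        if length < min_len:
            continue
        # rc_text[sb : sb+length] is revcomp of text[len(text)-sb-length : len(text)-sb]
        b_start = len(text) - sb - length
        for a0, b0, ln in _canonical_images(sa, b_start, length, n, circular, "inverted"):
            _note(a0, b0, ln, "inverted")

    pairs: list[RepeatPair] = []
    for (a0, b0, orient), ln in sorted(raw.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])):
        for pa, pb, pl in _split_at_origin(a0, b0, ln, n, orient):
            if pl < min_len:
                continue
            ia = Interval(genome.id, pa, pa + pl)
            ib = Interval(genome.id, pb, pb + pl, "+" if orient == "direct" else "-")
            if (ia.start, ia.end) == (ib.start, ib.end):
                continue
            if (ia.start, ia.end) > (ib.start, ib.end):
                ia, ib = Interval(genome.id, ib.start, ib.end), Interval(
                    genome.id, ia.start, ia.end, ib.strand
                )
            pairs.append(RepeatPair(a=ia, b=ib, orientation=orient, length=pl))
    # a maximal pair can be rediscovered pre-split from different doubled images
    uniq = {(p.a.start, p.a.end, p.b.start, p.b.end, p.orientation): p for p in pairs}
    return sorted(uniq.values(), key=lambda p: (p.a.start, p.b.start, -p.length, p.orientation))


def _canonical_images(sa: int, sb: int, length: int, n: int, circular: bool, orient: str):
    """Canonicalize doubled-sequence coordinates modulo the genome length."""
    if not circular:
        yield (sa, sb, length) if (sa, ) <= (sb, ) else (sb, sa, length)
        return
    length = min(length, n)
    a0, b0 = sa % n, sb % n
    if a0 == b0 and orient == "direct":
        return  # the trivial self-image across the doubling
    if orient == "direct" and (sb - sa) % n == 0:
        return
    if (a0,) > (b0,):
        a0, b0 = b0, a0
    yield (a0, b0, length)


def _split_at_origin(a0: int, b0: int, length: int, n: int, orient: str):
    """Split a (possibly origin-crossing) pair at the origin, same offset both members."""
    cuts = {0, length}
    if a0 + length > n:
        cuts.add(n - a0)
    if b0 + length > n:
        cuts.add(n - b0)
    offs = sorted(cuts)
    for lo, hi in zip(offs, offs[1:]):
        pa, pb = (a0 + lo) % n, (b0 + lo) % n
        yield pa, pb, hi - lo


def duplicated_length(pairs: Sequence[RepeatPair], genome: Genome) -> DupStats:
    """Duplication summary: union length of all repeat members, longest pair.

    The cumulative figure counts every genomic position lying in any repeat
    member once (the union convention), which cannot double-count
    overlapping repeat families; the per-pair sum is available from the
    pair list itself when the other convention is wanted.
    """
    ivs = []
    for p in pairs:
        ivs.append(Interval(genome.id, p.a.start, p.a.end))
        ivs.append(Interval(genome.id, p.b.start, p.b.end))
    total = interval_union_length(ivs) if ivs else 0
    return DupStats(
        genome_id=genome.id,
        total_len=len(genome),
        total_dup_len=total,
        max_dup_len=max((p.length for p in pairs), default=0),
    )


def dup_correlations(table) -> dict:
    """Pearson correlations over a DupStats table.

    ``table`` is a DataFrame-like with columns total_len, total_dup_len,
    max_dup_len (one row per genome).  Returns Pearson r, the two-sided p
    from the t transform, and R^2 for (total duplication vs genome length)
    and (total duplication vs maximum repeat length).
    """
    import pandas as pd

    df = pd.DataFrame(table)
    if len(df) < 3:
        raise ValueError("need >= 3 genomes for a correlation")
    for col in ("total_len", "total_dup_len", "max_dup_len"):
        if np.isclose(np.var(df[col].to_numpy(dtype=float)), 0.0):
            raise ValueError(f"zero variance in column {col}: correlation undefined")
    r1, p1 = stats.pearsonr(df["total_dup_len"], df["total_len"])
    r2, p2 = stats.pearsonr(df["total_dup_len"], df["max_dup_len"])
    return {
        "pearson_r_total_vs_genome": float(r1),
        "p_total_vs_genome": float(p1),
        "pearson_r_total_vs_max": float(r2),
        "p_total_vs_max": float(p2),
        "r_squared_total_vs_genome": float(r1**2),
        "r_squared_total_vs_max": float(r2**2),
    }
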