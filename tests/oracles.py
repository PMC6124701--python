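"""Independent brute-force oracles used only by the test suite.

Each oracle deliberately uses a different algorithmic route from the
implementation it checks: full-matrix Smith-Waterman instead of
seed-and-extend, an all-diagonals numpy scan instead of hash-anchored
repeat extension, a regex scan instead of the codon-walking ORF finder,
and bit vectors instead of interval merging.
"""

from __future__ import annotations

import re

import numpy as np
from numba import njit

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@njit(cache=True)
def _sw_kernel(a: np.ndarray, b: np.ndarray, match: int, mismatch: int, gap_open: int, gap_extend: int) -> int:
    """Affine-gap local alignment optimum; a gap of length L costs
    gap_open + L*gap_extend (both negative)."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), -10**9, dtype=np.int64)
    F = np.full((n + 1, m + 1), -10**9, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(E[i, j - 1] + gap_extend, H[i, j - 1] + gap_open + gap_extend)
            F[i, j] = max(F[i - 1, j] + gap_extend, H[i - 1, j] + gap_open + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            h = H[i - 1, j - 1] + s
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
    return best


def smith_waterman_score(
    a: str, b: str, match: int = 1, mismatch: int = -2, gap_open: int = -5, gap_extend: int = -2
) -> int:
    """Full quadratic Smith-Waterman local optimum (affine gaps)."""
    aa = np.frombuffer(a.encode(), dtype=np.uint8).astype(np.int64)
    bb = np.frombuffer(b.encode(), dtype=np.uint8).astype(np.int64)
    return int(_sw_kernel(aa, bb, match, mismatch, gap_open, gap_extend))


def best_local_score_both_strands(a: str, b: str, **kw) -> int:
    return max(smith_waterman_score(a, b, **kw), smith_waterman_score(a, rc(b), **kw))


# ---------------------------------------------------------------------------
# repeats: all-diagonals scan


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    diff = np.diff(np.concatenate(([0], mask.astype(np.int8), [0])))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def exact_repeat_pairs_oracle(seq: str, min_len: int) -> set[tuple[int, int, int, str]]:
    """All maximal exact repeat pairs >= min_len in a linear sequence.

    Scans every diagonal of seq-vs-seq (direct) and seq-vs-revcomp
    (inverted) with numpy equality runs.  Returns canonical tuples
    (a_start, b_start, length, orientation) with (a_start,) <= (b_start,);
    N matches nothing.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    valid = arr != ord("N")
    n = len(seq)
    out: set[tuple[int, int, int, str]] = set()
    # direct: compare seq[i] vs seq[i+d]
    for d in range(1, n):
        eq = (arr[:-d] == arr[d:]) & valid[:-d] & valid[d:]
        for s, e in _runs_of_true(eq):
            if e - s >= min_len:
                out.add((s, s + d, e - s, "direct"))
    # inverted: seq[a:a+L] == rc(seq)[p:p+L] with b = n - p - L
    rarr = np.frombuffer(rc(seq).encode(), dtype=np.uint8)
    rvalid = rarr != ord("N")
    for off in range(-(n - 1), n):
        if off >= 0:
            x, y, base = arr[off:], rarr[: n - off], off
        else:
            x, y, base = arr[: n + off], rarr[-off:], off
        eq = (x == y) & (valid[off:] if off >= 0 else valid[: n + off]) & (
            rvalid[: n - off] if off >= 0 else rvalid[-off:]
        )
        for s, e in _runs_of_true(eq):
            L = e - s
            if L < min_len:
                continue
            if off >= 0:
                a_start, p = off + s, s
            else:
                a_start, p = s, -off + s
            b_start = n - p - L
            a, b = (a_start, b_start) if a_start <= b_start else (b_start, a_start)
            if (a, L) == (b, L) and a == b:
                continue
            if a == b_start and b == a_start and a_start == b_start:
                continue
            out.add((a, b, L, "inverted"))
    # drop exact self-pairs (perfect palindromes aligned onto themselves)
    return {t for t in out if not (t[3] == "inverted" and t[0] == t[1])}


# ---------------------------------------------------------------------------
# ORFs: regex scan


def orf_oracle(seq: str, min_len: int) -> set[tuple[int, int, str]]:
    """(fwd_start, length, strand) of every longest-per-stop ATG ORF >= min_len
    in a LINEAR sequence, via regex over each frame."""
    n = len(seq)
    out: set[tuple[int, int, str]] = set()
    for strand in ("+", "-"):
        s = seq if strand == "+" else rc(seq)
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, n - 2, 3)]
            text = "".join("M" if c == "ATG" else ("*" if c in ("TAA", "TAG", "TGA") else "x") for c in codons)
            for m in re.finditer(r"M[Mx]*\*", text):
                start_codon = m.start()
                end_codon = m.end()  # exclusive, includes the stop
                length = (end_codon - start_codon) * 3
                if length < min_len:
                    continue
                pos = frame + start_codon * 3
                if strand == "+":
                    out.add((pos, length, "+"))
                else:
                    out.add((n - pos - length, length, "-"))
    return out


def bitvector_union_length(intervals: list[tuple[int, int]], n: int) -> int:
    v = np.zeros(n, dtype=bool)
    for s, e in intervals:
        v[s:e] = True
    return int(v.sum())
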