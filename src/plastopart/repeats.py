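"""Dispersed and tandem repeat detection.

Dispersed repeats use an ungapped (Hamming) mismatch model: a hit is a pair
of equal-length blocks, forward or inverted, whose mismatch count does not
exceed ``floor(mismatch_frac * length)``. N never matches anything.

The scan reports every *maximal* valid window on each comparison diagonal:
a window is maximal when extending it by one base on either side (which may
also raise the mismatch budget) would exceed the budget or leave the
sequence/window bounds. This single-step maximality rule is deliberately
simple so that an independent brute-force scan can mirror it exactly.

The key trick: with cumulative mismatch counts ``c`` along a diagonal and
``B[i] = c[i] - frac * i``, a window (l, r] is within budget iff
``B[r] <= B[l]`` (mismatches are integers, so the floor in the budget is
implied). Validity, extension and maximality therefore reduce to O(1)
comparisons on ``B``.

Tandem repeats are perfect arrays of a primitive unit; an array is maximal
when it cannot be extended left or right by even one base of a further unit
copy. Arrays whose span is contained in another reported array's span are
discarded ("hidden" repeats), preferring the smaller unit at equal span.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core_io import Interval, PlastomeRecord, reverse_complement

__all__ = [
    "RepeatHit",
    "TandemRepeat",
    "scan_short_repeats",
    "compare_pair",
    "scan_tandem_repeats",
    "mismatch_budget",
]

_EPS = 1e-9


def mismatch_budget(length: int, mismatch_frac: float) -> int:
    """floor(mismatch_frac * length), robust to float representation."""
    return int(math.floor(mismatch_frac * length + _EPS))


@dataclass(frozen=True)
class RepeatHit:
    seq1: str
    seq2: str
    direction: str  # "forward" | "inverted"
    length: int
    pos1: Interval
    pos2: Interval
    mismatches: int

    def sort_key(self) -> tuple:
        return (self.pos1.start, self.pos2.start, self.length, self.direction)


@dataclass(frozen=True)
class TandemRepeat:
    unit: str
    unit_len: int
    copies: float
    span: Interval
    total_len: int


def compare_pair(seq1: str, seq2: str, direction: str) -> int:
    """Mismatch count between the two blocks of a putative repeat pair.

    For inverted pairs seq2 is reverse-complemented first. N never matches.
    """
    if len(seq1) != len(seq2):
        raise ValueError(
            f"unequal block lengths: {len(seq1)} vs {len(seq2)}"
        )
    if direction not in ("forward", "inverted"):
        raise ValueError(f"direction must be forward|inverted, got {direction!r}")
    a = seq1.upper()
    b = reverse_complement(seq2.upper()) if direction == "inverted" else seq2.upper()
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


# ---------------------------------------------------------------------------
# dispersed repeats


def _as_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _diagonal_windows(
    a: np.ndarray,
    b: np.ndarray,
    d: int,
    min_len: int,
    frac: float,
) -> list[tuple[int, int]]:
    """Maximal valid windows on diagonal ``d`` of the a-vs-b comparison.

    Returns (i, L) pairs: a-window a[i:i+L] pairs with b[i+d:i+d+L].
    """
    n_a, n_b = len(a), len(b)
    lo = max(0, -d)
    hi = min(n_a, n_b - d)
    m = hi - lo
    if m < min_len:
        return []
    av = a[lo:hi]
    bv = b[lo + d : hi + d]
    nmask = (av == ord("N")) | (bv == ord("N"))
    mism = (av != bv) | nmask
    c = np.concatenate(([0], np.cumsum(mism, dtype=np.int64)))
    idx = np.arange(m + 1)
    B = c - frac * idx
    # candidate right ends: exists l <= r-min_len with B[l] >= B[r]-eps
    pm = np.maximum.accumulate(B)
    rs = np.arange(min_len, m + 1)
    cand = rs[pm[rs - min_len] >= B[rs] - _EPS]
    out: list[tuple[int, int]] = []
    for r in cand:
        ls = np.flatnonzero(B[: r - min_len + 1] >= B[r] - _EPS)
        if ls.size == 0:
            continue
        # single-step maximality
        left_blocked = (ls == 0) | (B[r] > B[np.maximum(ls - 1, 0)] + _EPS)
        if r == m:
            right_blocked = np.ones(ls.size, dtype=bool)
        else:
            right_blocked = B[r + 1] > B[ls] + _EPS
        for l in ls[left_blocked & right_blocked]:
            out.append((lo + int(l), int(r - l)))
    return out


def _all_diagonals(n_a: int, n_b: int, min_len: int) -> range:
    return range(-(n_a - min_len), n_b - min_len + 1)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def _scan_pair(
    seq_a: str,
    seq_b: str,
    *,
    direction: str,
    min_len: int,
    frac: float,
    off_a: int,
    off_b: int,
    same: bool,
    genome: str,
    hits: dict,
) -> None:
    """Scan window A against window B (both genome-forward sub-sequences).

    ``off_a``/``off_b`` are 0-based genome offsets of the two windows.
    For inverted scans, B is compared against the reverse complement and
    positions are mapped back to genome-forward coordinates.
    """
    a = _as_array(seq_a)
    b_seq = reverse_complement(seq_b) if direction == "inverted" else seq_b
    b = _as_array(b_seq)
    n_b = len(b)
    if same and direction == "forward":
        diagonals: Iterable[int] = range(1, n_b - min_len + 1)
    else:
        diagonals = _all_diagonals(len(a), n_b, min_len)
    for d in diagonals:
        for i, L in _diagonal_windows(a, b, d, min_len, frac):
            p = i + d  # window start within b_seq
            g1 = off_a + i  # 0-based genome start of block 1
            if direction == "forward":
                g2 = off_b + p
            else:
                g2 = off_b + (n_b - p - L)
            if g1 == g2:
                continue  # self pair / fully-overlapping placement
            if g2 < g1:
                g1, g2 = g2, g1
            s1 = genome[g1 : g1 + L]
            s2 = genome[g2 : g2 + L]
            mism = _hamming(s1, reverse_complement(s2) if direction == "inverted" else s2)
            key = (direction, g1, g2, L)
            if key not in hits:
                hits[key] = RepeatHit(
                    seq1=s1,
                    seq2=s2,
                    direction=direction,
                    length=L,
                    pos1=Interval(g1 + 1, g1 + L),
                    pos2=Interval(g2 + 1, g2 + L),
                    mismatches=mism,
                )


def scan_short_repeats(
    record: PlastomeRecord | str,
    windows: Sequence[Interval] | None = None,
    min_len: int = 16,
    mismatch_frac: float = 0.10,
    directions: Sequence[str] = ("forward", "inverted"),
) -> list[RepeatHit]:
    """Scan for dispersed forward/inverted repeat pairs.

    With ``windows`` given, only pairs whose two copies both lie inside the
    listed windows are reported (any window combination), and maximality is
    assessed within the window bounds. Each unordered pair is reported once
    with ``pos1 < pos2``.
    """
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    genome = record.seq if isinstance(record, PlastomeRecord) else str(record).upper()
    hits: dict = {}
    if windows is None:
        spans = [Interval(1, len(genome))]
    else:
        spans = list(windows)
        for w in spans:
            if w.wraps:
                raise ValueError("wrapping scan windows are not supported")
            w.validate(len(genome))
    subs = [(genome[w.start - 1 : w.end], w.start - 1) for w in spans]
    for i, (sa, oa) in enumerate(subs):
        for j in range(i, len(subs)):
            sb, ob = subs[j]
            for direction in directions:
                _scan_pair(
                    sa,
                    sb,
                    direction=direction,
                    min_len=min_len,
                    frac=mismatch_frac,
                    off_a=oa,
                    off_b=ob,
                    same=(i == j),
                    genome=genome,
                    hits=hits,
                )
    return sorted(hits.values(), key=RepeatHit.sort_key)


# ---------------------------------------------------------------------------
# tandem repeats


def _primitive(unit: str) -> bool:
    p = len(unit)
    for d in range(1, p):
        if p % d == 0 and unit == unit[:d] * (p // d):
            return False
    return True


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) inclusive indices."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def scan_tandem_repeats(
    record: PlastomeRecord | str,
    unit_min: int = 2,
    unit_max: int = 1000,
    min_copies: int = 2,
) -> tuple[list[TandemRepeat], dict]:
    """Detect maximal perfect tandem arrays with primitive units.

    Returns the arrays plus a summary dict with ``count``, ``total_bp`` and
    ``percent_of_genome``. Partial trailing unit copies extend the span;
    ``copies`` is fractional. The scan is linear in the deposited-origin
    frame; arrays crossing the origin are not joined.
    """
    seq = record.seq if isinstance(record, PlastomeRecord) else str(record).upper()
    n = len(seq)
    arr = _as_array(seq)
    is_n = arr == ord("N")
    found: list[TandemRepeat] = []
    for p in range(unit_min, min(unit_max, n // 2) + 1):
        eq = (arr[p:] == arr[:-p]) & ~is_n[p:] & ~is_n[:-p]
        for a, b in _runs(eq):
            run_len = b - a + 1
            if run_len < p * (min_copies - 1):
                continue
            start0 = a  # genome 0-based start of the array (= a, since eq[i] compares seq[i+p] with seq[i])
            span_len = run_len + p
            unit = seq[start0 : start0 + p]
            if not _primitive(unit):
                continue
            found.append(
                TandemRepeat(
                    unit=unit,
                    unit_len=p,
                    copies=round(span_len / p, 2),
                    span=Interval(start0 + 1, start0 + span_len),
                    total_len=span_len,
                )
            )
    # hidden-repeat removal: drop arrays span-contained in another's span,
    # preferring the smaller unit at exactly equal span.
    found.sort(key=lambda t: (t.span.start, -t.span.end, t.unit_len))
    kept: list[TandemRepeat] = []
    max_end = 0
    for t in found:
        if t.span.end > max_end:
            kept.append(t)
            max_end = t.span.end
    kept.sort(key=lambda t: (t.span.start, t.span.end, t.unit_len))
    total = sum(t.total_len for t in kept)
    summary = {
        "count": len(kept),
        "total_bp": total,
        "percent_of_genome": round(100.0 * total / n, 2) if n else 0.0,
    }
    return kept, summary
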