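"""Quadripartite partitioning of circular plastomes.

Detects the large inverted repeat as the longest pair of disjoint exact
inverted-repeat copies on the circle (seed-and-extend over shared k-mers
between the sequence and its reverse complement), labels the two
single-copy gaps LSC (longer) and SSC (shorter), and derives the four
junctions:

    J_LB  LSC|IRb      J_SB  IRb|SSC      J_SA  SSC|IRa      J_LA  IRa|LSC

Junction positions are reported as the IR-side base at each boundary, which
is well defined whatever the orientation of the deposited linearisation.
The canonical traversal order is LSC -> IRb -> SSC -> IRa with the 5' end
of *ycf1* (when annotated) inside IRa; :func:`canonicalize` rotates and
flips a record into that frame, which downstream analyses use internally so
that all summaries are rotation- and strand-invariant.

Detection is exact-match: the IR copies of hand-finished plastome
assemblies are identical by construction. If a record carries slightly
divergent copies, the largest identical core is reported rather than being
silently extended across mismatches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_io import (
    GeneFeature,
    Interval,
    PlastomeRecord,
    flip_record,
    reverse_complement,
    rotate_record,
)

__all__ = ["QuadripartiteMap", "JunctionProfile", "detect_quadripartite",
           "junction_profiles", "canonicalize"]

JUNCTIONS = ("J_LB", "J_SB", "J_SA", "J_LA")


@dataclass
class QuadripartiteMap:
    """Region coordinates (record frame) and canonical region lengths."""

    lsc: Interval
    irb: Interval
    ssc: Interval
    ira: Interval
    junctions: dict[str, int]
    lsc_len: int
    ssc_len: int
    ir_len: int
    genome_len: int
    flipped: bool = False  # deposited orientation is the flip of canonical

    def conservation_holds(self) -> bool:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len == self.genome_len


@dataclass
class JunctionProfile:
    junction: str
    overlapping_gene: str | None
    bp_in_ir: int
    bp_in_sc: int
    gene_length: int | None
    genes_fully_in_ir_adjacent: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# detection


def _inverted_blocks(seq: str, min_len: int, k: int = 21) -> list[tuple[int, int, int]]:
    """Maximal exact inverted-repeat block pairs on the circle.

    Works on the doubled sequence so pairs spanning the origin are found.
    Returns (start1, start2, length) with 0-based starts modulo genome
    length and start1 < start2.
    """
    n = len(seq)
    if n < 2 * min_len:
        return []
    s2 = seq + seq
    t2 = reverse_complement(s2)
    n2 = 2 * n
    if min_len < k:
        k = max(8, min_len)
    kmers: dict[str, list[int]] = {}
    for i in range(n):  # representatives in the first copy suffice
        kmers.setdefault(s2[i : i + k], []).append(i)
    diagonals: set[int] = set()
    for p in range(n2 - k + 1):
        for i in kmers.get(t2[p : p + k], ()):
            diagonals.add(p - i)
    a = np.frombuffer(s2.encode(), dtype=np.uint8)
    b = np.frombuffer(t2.encode(), dtype=np.uint8)
    pairs: dict[tuple[int, int, int], None] = {}
    for d in diagonals:
        lo = max(0, -d)
        hi = min(n2, n2 - d)
        if hi - lo < min_len:
            continue
        eq = (a[lo:hi] == b[lo + d : hi + d]) & (a[lo:hi] != ord("N"))
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1) + lo
        ends = np.flatnonzero(diff == -1) + lo  # exclusive
        for st, en in zip(starts.tolist(), ends.tolist()):
            L = min(en - st, n)
            if L < min_len:
                continue
            p0 = st + d
            b1 = st % n
            b2 = (n2 - p0 - L) % n
            if b1 == b2:
                continue  # palindrome paired with itself
            if b2 < b1:
                b1, b2 = b2, b1
            pairs[(b1, b2, L)] = None
    return list(pairs)


def _circular_gap(end0: int, start0: int, n: int) -> int:
    """Gap walking forward from 0-based position end0 (exclusive) to start0."""
    return (start0 - end0 - 1) % n


def _interval_from0(start0: int, length: int, n: int) -> Interval:
    end0 = (start0 + length - 1) % n
    return Interval(start0 + 1, end0 + 1, wraps=start0 + length - 1 >= n)


def detect_quadripartite(
    record: PlastomeRecord, min_ir_len: int = 1000
) -> QuadripartiteMap | None:
    """Partition a circular plastome into LSC / IRb / SSC / IRa.

    Returns ``None`` when no inverted repeat of at least ``min_ir_len``
    exists (the explicit no-IR result). Ties between equally long maximal
    pairs break deterministically to the smallest start coordinate, with a
    warning.
    """
    n = record.length
    candidates = []
    for b1, b2, L in _inverted_blocks(record.seq, min_ir_len):
        gap12 = _circular_gap((b1 + L - 1) % n, b2, n)
        gap21 = _circular_gap((b2 + L - 1) % n, b1, n)
        if gap12 + gap21 + 2 * L != n:
            continue  # overlapping copies cannot partition the circle
        candidates.append((L, b1, b2, gap12, gap21))
    if not candidates:
        return None
    best_len = max(c[0] for c in candidates)
    top = sorted(c for c in candidates if c[0] == best_len)
    if len(top) > 1:
        warnings.warn(
            f"{record.id}: {len(top)} maximal inverted-repeat pairs of "
            f"{best_len} bp; using the smallest start coordinate"
        )
    L, b1, b2, gap12, gap21 = top[0]

    if gap12 >= gap21:
        lsc_start, lsc_len = (b1 + L) % n, gap12
        ssc_start, ssc_len = (b2 + L) % n, gap21
        after_lsc, after_ssc = b2, b1  # traversal: LSC, b2, SSC, b1
    else:
        lsc_start, lsc_len = (b2 + L) % n, gap21
        ssc_start, ssc_len = (b1 + L) % n, gap12
        after_lsc, after_ssc = b1, b2
    irb0, ira0 = after_lsc, after_ssc
    flipped = False
    ycf1 = record.features_named("ycf1")
    if ycf1:
        five = ycf1[0].five_prime(n)
        if _interval_from0(irb0, L, n).contains(five, n):
            # ycf1's 5' end sits in the copy after the LSC: the deposited
            # orientation is the flip of canonical, so swap the IR labels.
            irb0, ira0 = ira0, irb0
            flipped = True

    irb = _interval_from0(irb0, L, n)
    ira = _interval_from0(ira0, L, n)
    lsc = _interval_from0(lsc_start, lsc_len, n)
    ssc = _interval_from0(ssc_start, ssc_len, n)

    def ir_side_base(ir_iv: Interval, sc_iv: Interval) -> int:
        nxt = sc_iv.end % n + 1  # base just after the single-copy region
        return ir_iv.start if ir_iv.start == nxt else ir_iv.end

    junctions = {
        "J_LB": ir_side_base(irb, lsc),
        "J_SB": ir_side_base(irb, ssc),
        "J_SA": ir_side_base(ira, ssc),
        "J_LA": ir_side_base(ira, lsc),
    }
    return QuadripartiteMap(
        lsc=lsc, irb=irb, ssc=ssc, ira=ira, junctions=junctions,
        lsc_len=lsc_len, ssc_len=ssc_len, ir_len=L, genome_len=n,
        flipped=flipped,
    )


# ---------------------------------------------------------------------------
# canonical frame


def canonical_map(lsc_len: int, ir_len: int, ssc_len: int) -> QuadripartiteMap:
    """The map of a genome already laid out as LSC+IRb+SSC+IRa from base 1."""
    L = lsc_len + ssc_len + 2 * ir_len
    lsc = Interval(1, lsc_len)
    irb = Interval(lsc_len + 1, lsc_len + ir_len)
    ssc = Interval(lsc_len + ir_len + 1, lsc_len + ir_len + ssc_len)
    ira = Interval(lsc_len + ir_len + ssc_len + 1, L)
    junctions = {
        "J_LB": irb.start, "J_SB": irb.end, "J_SA": ira.start, "J_LA": ira.end,
    }
    return QuadripartiteMap(
        lsc=lsc, irb=irb, ssc=ssc, ira=ira, junctions=junctions,
        lsc_len=lsc_len, ssc_len=ssc_len, ir_len=ir_len, genome_len=L,
    )


def canonicalize(
    record: PlastomeRecord,
    qmap: QuadripartiteMap | None = None,
    min_ir_len: int = 1000,
) -> tuple[PlastomeRecord, QuadripartiteMap]:
    """Rotate/flip a partitioned record into the canonical frame.

    In the canonical frame the LSC starts at position 1, traversal order is
    LSC -> IRb -> SSC -> IRa, and ycf1's 5' end (when annotated) is in IRa.
    """
    if qmap is None:
        qmap = detect_quadripartite(record, min_ir_len)
        if qmap is None:
            raise ValueError(f"{record.id}: no inverted repeat found")
    rec = record
    L = qmap.genome_len
    if qmap.flipped:
        rec = flip_record(rec)
        lsc_start = L - qmap.lsc.end + 1
    else:
        lsc_start = qmap.lsc.start
    rec = rotate_record(rec, lsc_start)
    return rec, canonical_map(qmap.lsc_len, qmap.ir_len, qmap.ssc_len)


# ---------------------------------------------------------------------------
# junction profiling


def junction_profiles(
    qmap: QuadripartiteMap, record: PlastomeRecord
) -> list[JunctionProfile]:
    """Per-junction gene overlap decomposition.

    For each junction, identifies the annotated gene spanning it (if any),
    splits that gene's spliced length into IR-side and single-copy-side
    parts, and lists the genes lying wholly inside the adjacent IR copy,
    ordered by distance from the junction. Computed in the canonical frame,
    so the decomposition is rotation- and strand-invariant.
    """
    rec, m = canonicalize(record, qmap)
    n = m.genome_len
    # boundary: (last base of upstream region, first base of downstream one)
    bounds = {
        "J_LB": (m.lsc.end, m.irb.start, m.irb),
        "J_SB": (m.irb.end, m.ssc.start, m.irb),
        "J_SA": (m.ssc.end, m.ira.start, m.ira),
        "J_LA": (m.ira.end, 1, m.ira),
    }
    genes = [f for f in rec.features if f.kind in ("CDS", "tRNA", "rRNA")]
    spans = [(f, f.span_positions(n)) for f in genes]
    ir_bp = {
        "IRb": set(m.irb.positions(n)),
        "IRa": set(m.ira.positions(n)),
    }
    profiles = []
    for junc in JUNCTIONS:
        up_pos, down_pos, ir_iv = bounds[junc]
        ir_pos = ir_bp["IRb" if ir_iv is m.irb else "IRa"]
        spanning = None
        for f, span in spans:
            if up_pos in span and down_pos in span:
                if spanning is None or f.spliced_length(n) > spanning.spliced_length(n):
                    spanning = f
        if spanning is not None:
            bp_ir = len(spanning.span_positions(n) & ir_pos)
            gene_name: str | None = spanning.name
            gene_len: int | None = spanning.spliced_length(n)
            bp_sc = gene_len - bp_ir
        else:
            bp_ir = bp_sc = 0
            gene_name = gene_len = None
        inside = []
        for f, span in spans:
            if span <= ir_pos:
                lo, hi = min(span), max(span)
                if junc in ("J_LB", "J_SA"):  # junction at the IR's low end
                    dist = lo - ir_iv.start
                else:  # junction at the IR's high end
                    dist = ir_iv.end - hi
                inside.append((dist, f.name))
        inside.sort()
        profiles.append(
            JunctionProfile(
                junction=junc,
                overlapping_gene=gene_name,
                bp_in_ir=bp_ir,
                bp_in_sc=bp_sc,
                gene_length=gene_len,
                genes_fully_in_ir_adjacent=[name for _, name in inside],
            )
        )
    return profiles
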