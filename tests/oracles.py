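"""Independent reference implementations used to check the library.

Everything here is deliberately naive: direct transliterations of the
definitions, sharing no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}

# plastid/bacterial genetic code, written out codon by codon
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def translate_by_table(seq: str, codon_start: int = 1) -> str:
    s = seq[codon_start - 1 :]
    out = []
    for i in range(0, len(s) - len(s) % 3, 3):
        codon = s[i : i + 3]
        out.append("X" if "N" in codon else CODON_TABLE[codon])
    return "".join(out)


def hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def budget(length: int, frac: float) -> int:
    return int(math.floor(frac * length + 1e-9))


def brute_force_repeats(seq, min_len=16, frac=0.10, directions=("forward", "inverted")):
    """O(n^3)-ish literal enumeration of maximal valid repeat windows.

    A window is valid when its Hamming mismatches fit floor(frac*len);
    it is reported when neither one-base extension (which may raise the
    budget) stays valid and in bounds. Pairs are canonical: pos1 < pos2,
    identical placements excluded. Returns {(direction, g1, g2, length)}
    with 0-based starts.
    """
    n = len(seq)
    hits = set()

    def valid(m, L):
        return m <= budget(L, frac)

    def mism_char(a, b):
        return 0 if (a == b and a != "N") else 1

    for direction in directions:
        other = revcomp(seq) if direction == "inverted" else seq
        for i in range(n):
            for p in range(n):
                if direction == "forward" and p <= i:
                    continue
                m = 0
                for L in range(1, n + 1):
                    if i + L > n or p + L > n:
                        break
                    m += mism_char(seq[i + L - 1], other[p + L - 1])
                    if L < min_len or not valid(m, L):
                        continue
                    if (
                        i > 0
                        and p > 0
                        and valid(m + mism_char(seq[i - 1], other[p - 1]), L + 1)
                    ):
                        continue
                    if (
                        i + L < n
                        and p + L < n
                        and valid(m + mism_char(seq[i + L], other[p + L]), L + 1)
                    ):
                        continue
                    if direction == "forward":
                        g1, g2 = i, p
                    else:
                        g1, g2 = i, n - p - L
                        if g1 == g2:
                            continue
                        if g2 < g1:
                            g1, g2 = g2, g1
                    hits.add((direction, g1, g2, L))
    return hits


def matrix_repeat_oracle(seq, min_len=16, frac=0.10, directions=("forward", "inverted")):
    """Exhaustive per-diagonal window enumeration with dense numpy masks.

    Mathematically identical to :func:`brute_force_repeats` but tractable
    for sequences of a few hundred bp; still independent of the package's
    candidate-pruning scan.
    """
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    eps = 1e-9
    hits = set()
    for direction in directions:
        b_str = revcomp(seq) if direction == "inverted" else seq
        b = np.frombuffer(b_str.encode(), dtype=np.uint8)
        diags = (
            range(1, n - min_len + 1)
            if direction == "forward"
            else range(-(n - min_len), n - min_len + 1)
        )
        for d in diags:
            lo = max(0, -d)
            hi = min(n, n - d)
            m = hi - lo
            if m < min_len:
                continue
            av, bv = arr[lo:hi], b[lo + d : hi + d]
            mism = (av != bv) | (av == ord("N")) | (bv == ord("N"))
            c = np.concatenate(([0], np.cumsum(mism)))
            B = c - frac * np.arange(m + 1)
            l_idx = np.arange(m + 1)[:, None]
            r_idx = np.arange(m + 1)[None, :]
            V = (B[None, :] <= B[:, None] + eps) & (r_idx - l_idx >= min_len)
            Bl1 = np.concatenate(([np.inf], B[:-1]))  # B[l-1], l>=1
            Br1 = np.concatenate((B[1:], [-np.inf]))  # B[r+1], r<m
            Lext = B[None, :] <= Bl1[:, None] + eps
            Rext = Br1[None, :] <= B[:, None] + eps
            Rext[:, m] = False
            Lext[0, :] = False
            for l, r in zip(*np.nonzero(V & ~Lext & ~Rext)):
                L = int(r - l)
                i = lo + int(l)
                p = lo + d + int(l)
                if direction == "forward":
                    g1, g2 = i, p
                else:
                    g1, g2 = i, n - p - L
                    if g1 == g2:
                        continue
                    if g2 < g1:
                        g1, g2 = g2, g1
                hits.add((direction, g1, g2, L))
    return hits


def brute_longest_inverted_pair(seq: str, min_len: int) -> int:
    """Length of the longest exact inverted-repeat pair (disjoint copies)
    on the circular sequence, by doubled-sequence dynamic programming."""
    n = len(seq)
    s2 = seq + seq
    t2 = revcomp(s2)
    best = 0
    n2 = 2 * n
    prev = [0] * (n2 + 1)
    for i in range(1, n2 + 1):
        cur = [0] * (n2 + 1)
        for j in range(1, n2 + 1):
            if s2[i - 1] == t2[j - 1] != "N":
                cur[j] = prev[j - 1] + 1
                L = min(cur[j], n)
                if L > best:
                    b1 = (i - L) % n
                    b2 = (n2 - (j - L) - L) % n
                    if b1 != b2:
                        g12 = (b2 - (b1 + L)) % n
                        g21 = (b1 - (b2 + L)) % n
                        if g12 + g21 + 2 * L == n:
                            best = L
        prev = cur
    return best if best >= min_len else 0
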