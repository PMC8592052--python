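"""Dispersed repeat scanning and perfect tandem-repeat detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import brute_force_repeats, hamming, matrix_repeat_oracle, revcomp
from plastopart.core_io import Interval, PlastomeRecord
from plastopart.repeats import (
    compare_pair,
    mismatch_budget,
    scan_short_repeats,
    scan_tandem_repeats,
)
from plastopart.synthetic_data import PlantedTandem, SynthSpec, build_plastome

# published junction repeat pairs of P. maritimum and Na. poeticus
PMAR_INV = ("TCATTATTAGGTTTATA", "TATAAACCCAATAATGA")  # 17 bp, 1 mismatch
PMAR_FWD = ("TTCATTTTTCTCTTCTTT", "TTCATTTTCCTCTTCTTT")  # 18 bp, 1 mismatch
NPOE_INV = ("TCATTATTAGGTTTATA", "TATAAACCCAATAATTA")  # 17 bp, 2 mismatches


def as_keys(hits):
    return {(h.direction, h.pos1.start - 1, h.pos2.start - 1, h.length) for h in hits}


class TestComparePair:
    @pytest.mark.parametrize(
        "pair,direction,expected",
        [
            (PMAR_INV, "inverted", 1),
            (PMAR_FWD, "forward", 1),
            (NPOE_INV, "inverted", 2),
            (("ACGTACGTACGTACGTA",) * 2, "forward", 0),
        ],
    )
    def test_printed_pairs(self, pair, direction, expected):
        assert compare_pair(pair[0], pair[1], direction) == expected

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_pair("ACGT", "ACG", "forward")

    def test_n_never_matches(self):
        assert compare_pair("ACNT", "ACNT", "forward") == 1

    @settings(derandomize=True, max_examples=100)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=40))
    def test_self_forward_distance(self, s):
        assert compare_pair(s, s, "forward") == s.count("N")


class TestThreshold:
    def test_budget_floor(self):
        assert mismatch_budget(17, 0.10) == 1
        assert mismatch_budget(18, 0.10) == 1
        assert mismatch_budget(20, 0.10) == 2
        assert mismatch_budget(30, 0.10) == 3  # not a float-representation 2

    def test_two_mismatch_17mer_rejected_at_ten_percent(self):
        """A 17 bp inverted pair with 2 mismatches exceeds floor(1.7)=1 and
        must not be reported, while the 1-mismatch homolog is."""
        rng = np.random.default_rng(77)
        bg = "".join(rng.choice(list("ACGT"), size=400))
        ok1, ok2 = PMAR_INV
        bad1, bad2 = NPOE_INV
        seq = bg[:50] + ok1 + bg[50:150] + ok2 + bg[150:250] + bad1 + bg[250:330] + bad2 + bg[330:]
        w_all = [Interval(1, len(seq))]
        hits = scan_short_repeats(seq, w_all, min_len=16, mismatch_frac=0.10)
        cover = lambda h, a, b: h.pos1.start <= a and h.pos1.end >= b
        ok_hits = [h for h in hits if h.direction == "inverted" and cover(h, 51, 67)]
        bad_hits = [
            h for h in hits if h.direction == "inverted" and cover(h, 251, 267)
        ]
        assert ok_hits and all(h.mismatches <= mismatch_budget(h.length, 0.10) for h in hits)
        assert not bad_hits


class TestOracleEquivalence:
    def test_tiny_sequences_match_literal_brute_force(self):
        rng = np.random.default_rng(101)
        for trial in range(6):
            n = int(rng.integers(60, 110))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            if trial % 2 == 0:  # plant a pair so hits exist
                core = "".join(rng.choice(list("ACGT"), size=14))
                seq = seq[:4] + core + seq[18 : n - 22] + revcomp(core) + seq[n - 8 :]
            got = as_keys(scan_short_repeats(seq, min_len=12))
            assert got == brute_force_repeats(seq, min_len=12)

    def test_seeded_sequences_match_matrix_oracle(self):
        rng = np.random.default_rng(202)
        for trial in range(25):
            n = int(rng.integers(100, 300))
            seq = list(rng.choice(list("ACGT"), size=n))
            if trial % 2 == 0:
                core = "".join(rng.choice(list("ACGT"), size=17))
                other = list(core if trial % 4 == 0 else revcomp(core))
                other[int(rng.integers(17))] = "A"
                a, b = 10, n - 40
                seq[a : a + 17] = core
                seq[b : b + 17] = other
            s = "".join(seq)
            assert as_keys(scan_short_repeats(s)) == matrix_repeat_oracle(s)


class TestScanProperties:
    def test_windowed_exact_pair_reported_exactly(self):
        """A 16/16 exact inverted pair straddling two windows whose bounds
        coincide with the repeat is reported as exactly that hit."""
        rng = np.random.default_rng(55)
        bg = "".join(rng.choice(list("ACGT"), size=400))
        core = "ACGGTTCAAGGATCCA"
        seq = bg[:100] + core + bg[100:300] + revcomp(core) + bg[300:]
        w1, w2 = Interval(101, 116), Interval(317, 332)
        hits = scan_short_repeats(seq, [w1, w2], min_len=16)
        inv = [h for h in hits if h.direction == "inverted"]
        assert [(h.pos1.start, h.pos1.end, h.pos2.start, h.pos2.end, h.mismatches) for h in inv] == [
            (101, 116, 317, 332, 0)
        ]

    def test_hit_invariants(self):
        rng = np.random.default_rng(66)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        core = "".join(rng.choice(list("ACGT"), size=25))
        seq = seq[:50] + core + seq[75:500] + revcomp(core) + seq[525:]
        for h in scan_short_repeats(seq, min_len=14):
            assert h.pos1.end - h.pos1.start + 1 == h.length
            assert h.pos2.end - h.pos2.start + 1 == h.length
            assert h.mismatches <= mismatch_budget(h.length, 0.10)
            other = revcomp(h.seq2) if h.direction == "inverted" else h.seq2
            assert hamming(h.seq1, other) == h.mismatches
            assert (h.pos1.start, h.pos1.end) != (h.pos2.start, h.pos2.end)

    def test_inverted_scan_invariant_under_genome_revcomp(self):
        rng = np.random.default_rng(88)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        core = "".join(rng.choice(list("ACGT"), size=18))
        seq = seq[:60] + core + seq[78:400] + revcomp(core) + seq[418:]
        n = len(seq)
        fwd = {
            (h.length, h.mismatches, n - h.pos2.end + 1, n - h.pos1.start + 1)
            for h in scan_short_repeats(seq, directions=("inverted",))
        }
        flipped = {
            (h.length, h.mismatches, h.pos1.start, h.pos2.end)
            for h in scan_short_repeats(revcomp(seq), directions=("inverted",))
        }
        assert fwd == flipped


class TestTandem:
    def test_dinucleotide_array(self):
        arrays, summary = scan_tandem_repeats("GGACACACAGG")
        assert [(t.unit, t.span.start, t.span.end) for t in arrays] == [("AC", 3, 9)]
        assert arrays[0].copies == 3.5 and summary["count"] == 1

    def test_homopolymer_excluded_at_unit_min_2(self):
        arrays, _ = scan_tandem_repeats("AAAAAA")
        assert arrays == []

    def test_primitive_units_only(self):
        arrays, _ = scan_tandem_repeats("TTATATATATT")  # AT array, not ATAT
        assert {t.unit_len for t in arrays} == {2}

    def test_span_revalidates_and_no_nesting(self, type_a):
        rec, _ = type_a
        arrays, summary = scan_tandem_repeats(rec)
        spans = []
        for t in arrays:
            span_seq = rec.seq[t.span.start - 1 : t.span.end]
            full = int(t.copies)
            assert span_seq.startswith(t.unit * full)
            rem = t.total_len - full * t.unit_len
            assert span_seq[full * t.unit_len :] == t.unit[:rem]
            spans.append((t.span.start, t.span.end))
        for i, (a1, b1) in enumerate(spans):
            for a2, b2 in spans[i + 1 :]:
                assert not (a1 <= a2 and b2 <= b1) and not (a2 <= a1 and b1 <= b2)
        assert summary["total_bp"] == sum(t.total_len for t in arrays)

    def test_planted_arrays_recovered(self):
        rng = np.random.default_rng(31)
        planted = [
            PlantedTandem(int(rng.integers(2, 31)), int(rng.integers(2, 7)))
            for _ in range(50)
        ]
        rec, truth = build_plastome(SynthSpec.type_a(31, planted_tandem=planted))
        arrays, _ = scan_tandem_repeats(rec)
        got = {(t.unit_len, t.span.start, t.span.end) for t in arrays}
        for t in truth.tandems:
            assert (t["unit_len"], t["span"][0], t["span"][1]) in got
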