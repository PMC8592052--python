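"""J_SA typing, expansion-event reconstruction and origin tracing."""

import numpy as np
import pytest

from plastopart.core_io import Interval, PlastomeRecord, reverse_complement
from plastopart.junction_typing import (
    classify_jsa,
    diff_junctions,
    find_mediating_repeats,
    map_segment_origin,
)
from plastopart.quadripartite import detect_quadripartite
from plastopart.synthetic_data import (
    SynthSpec,
    build_plastome,
    scenario_single_expansion,
    scenario_two_event_expansion,
    strumaria_like_spec,
)


def jsa_of(rec):
    m = detect_quadripartite(rec)
    return classify_jsa(None, m, rec), m


class TestClassifyJsa:
    def test_type_a_at_1000bp(self):
        rec, truth = build_plastome(SynthSpec.type_a(71))
        jsa, _ = jsa_of(rec)
        assert jsa.type == "A" and jsa.ycf1_bp_in_ira == 1000
        assert not jsa.ycf1_fully_in_ir

    def test_type_b_at_2737bp(self):
        spec = SynthSpec(
            seed=71, jsa_type="B", ycf1_len=3600, ycf1_bp_in_ira=2737,
            ir_len=8900, ssc_len=6200,
        )
        rec, _ = build_plastome(spec)
        jsa, _ = jsa_of(rec)
        assert jsa.type == "B" and jsa.ycf1_bp_in_ira == 2737

    def test_type_c_with_extra_ir_genes(self):
        rec, truth = build_plastome(strumaria_like_spec(71))
        jsa, _ = jsa_of(rec)
        assert jsa.type == "C" and jsa.ycf1_fully_in_ir
        assert jsa.extra_ir_genes == ["ndhH", "rps15"]
        assert jsa.ycf1_bp_in_ira == truth.ycf1_bp_in_ira

    def test_monotone_in_ycf1_portion(self):
        """Raising ycf1's IRa portion can only move the label A -> B -> C."""
        order = {"A": 0, "B": 1, "C": 2}
        last = -1
        for bp in (600, 1500, 2100, 2900):
            spec = SynthSpec(
                seed=73, jsa_type="B", ycf1_len=3600, ycf1_bp_in_ira=bp,
                ir_len=6500 + bp, ssc_len=8900 - bp,
            )
            rec, _ = build_plastome(spec)
            jsa, _ = jsa_of(rec)
            assert order[jsa.type] >= last
            last = order[jsa.type]
        rec, _ = build_plastome(SynthSpec.type_c(73))
        jsa, _ = jsa_of(rec)
        assert order[jsa.type] >= last

    def test_missing_ycf1_unclassifiable(self):
        rec, _ = build_plastome(SynthSpec.type_a(79))
        stripped = PlastomeRecord(
            rec.id, rec.seq, True, [f for f in rec.features if f.name != "ycf1"]
        )
        m = detect_quadripartite(stripped)
        jsa = classify_jsa(None, m, stripped)
        assert jsa.type == "unclassifiable"
        assert jsa.diagnostic


class TestDiffJunctions:
    def test_identical_genomes_give_no_events(self, type_a):
        rec, _ = type_a
        assert diff_junctions((rec, None), (rec, None)) == []

    def test_single_expansion_recovered(self):
        anc, der, truth = scenario_single_expansion(83)
        events = diff_junctions((der, None), (anc, None))
        assert len(events) == 1
        ev = events[0]
        assert ev.size == truth[0]["size"]
        assert ev.genes_incorporated == truth[0]["genes"]
        assert ev.mechanism_hypothesis == "dsb_or_other"
        assert not ev.mediating_repeats and not ev.flagged

    def test_repeat_mediated_expansion_labelled(self):
        anc, der, truth = scenario_single_expansion(83, with_repeat=True)
        events = diff_junctions((der, None), (anc, None))
        assert len(events) == 1
        assert events[0].mechanism_hypothesis == "repeat_mediated"
        assert events[0].mediating_repeats
        assert events[0].size == truth[0]["size"]

    def test_two_event_history_recovered_in_order(self):
        anc, der, truth = scenario_two_event_expansion(83)
        events = diff_junctions((der, None), (anc, None))
        assert [e.size for e in events] == [t["size"] for t in truth]
        assert events[0].genes_incorporated == []  # 45 bp from a spacer
        assert events[1].genes_incorporated == ["rps15", "ycf1"]
        assert events[0].segment.start < events[1].segment.start

    def test_mechanism_invariant_repeats_imply_label(self):
        for seed, with_rep in ((91, True), (91, False)):
            anc, der, _ = scenario_single_expansion(seed, with_repeat=with_rep)
            for ev in diff_junctions((der, None), (anc, None)):
                assert (ev.mechanism_hypothesis == "repeat_mediated") == bool(
                    ev.mediating_repeats
                )


class TestMediatingRepeats:
    def test_cross_window_restriction(self):
        rng = np.random.default_rng(7)
        bg = "".join(rng.choice(list("ACGT"), size=900))
        core = "".join(rng.choice(list("ACGT"), size=20))
        seq = bg[:100] + core + bg[100:300] + core + bg[300:500] + reverse_complement(core) + bg[500:]
        rec = PlastomeRecord("W", seq, True)
        w1 = Interval(80, 160)
        w2 = Interval(480, 600)
        hits = find_mediating_repeats(rec, w1, w2)
        # only the copy pair straddling the two windows qualifies
        assert hits and all(
            (w1.start <= h.pos1.start <= w1.end) and (w2.start <= h.pos2.start <= w2.end)
            for h in hits
        )


class TestSegmentOrigin:
    def test_verbatim_segment_places_exactly(self, type_a):
        rec, _ = type_a
        seg = rec.seq[5000:5045]
        pl = map_segment_origin(seg, rec)
        assert (pl.interval.start, pl.interval.end) == (5001, 5045)
        assert pl.identity == 1.0 and pl.strand == "+"

    def test_two_substitutions_still_place(self, type_a):
        rec, _ = type_a
        seg = list(rec.seq[5000:5045])
        seg[10] = "A" if seg[10] != "A" else "C"
        seg[30] = "T" if seg[30] != "T" else "G"
        pl = map_segment_origin("".join(seg), rec)
        assert (pl.interval.start, pl.interval.end) == (5001, 5045)
        assert pl.identity == pytest.approx(43 / 45, abs=0.01)

    def test_spacer_context_naming(self, type_a):
        rec, truth = type_a
        # the widest SSC spacer, safely between two named genes
        spacer = max(truth.spacers["ssc"], key=lambda iv: iv.end - iv.start)
        mid = (spacer.start + spacer.end) // 2
        seg = rec.seq[mid - 15 : mid + 15]
        pl = map_segment_origin(seg, rec)
        assert pl is not None and pl.context.endswith("spacer")

    def test_unrelated_segment_unplaced(self, type_a):
        rec, _ = type_a
        rng = np.random.default_rng(17)
        seg = "".join(rng.choice(list("ACGT"), size=60))
        assert map_segment_origin(seg, rec) is None

    def test_short_segment_rejected(self, type_a):
        rec, _ = type_a
        with pytest.raises(ValueError):
            map_segment_origin("ACGTACGT", rec)

    def test_reverse_strand_placement(self, type_a):
        rec, _ = type_a
        seg = reverse_complement(rec.seq[12000:12050])
        pl = map_segment_origin(seg, rec)
        assert pl.strand == "-"
        assert (pl.interval.start, pl.interval.end) == (12001, 12050)
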