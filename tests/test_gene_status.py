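"""Reference panels, presence assessment and gene classification."""

import numpy as np
import pytest

from conftest import make_single_gene_record
from plastopart.core_io import rotate_record
from plastopart.gene_status import (
    assess_presence,
    build_reference_panel,
    classify_gene,
    status_matrix,
)
from plastopart.synthetic_data import SynthSpec, build_plastome, strumaria_like_spec

from oracles import CODON_TABLE


def random_cds(rng, n_codons):
    sense = [c for c in CODON_TABLE if CODON_TABLE[c] != "*"]
    body = "".join(rng.choice(sense, size=n_codons))
    return "ATG" + body + "TAA"


class TestReferencePanel:
    def test_modal_length_with_tie_to_longest(self):
        rng = np.random.default_rng(1)
        cds900 = random_cds(rng, 298)  # 900 bp
        cds903 = random_cds(rng, 299)  # 903 bp
        records = [
            make_single_gene_record("s1", cds900),
            make_single_gene_record("s2", cds900),
            make_single_gene_record("s3", cds903),
        ]
        panel = build_reference_panel(records)
        assert panel.length("geneX") == 900
        tie = build_reference_panel(records[1:])  # {900, 903}: tie -> longest
        assert tie.length("geneX") == 903

    def test_single_record_panel_is_verbatim(self, type_a, intact_panel):
        rec, truth = type_a
        for gene, length in truth.gene_lengths.items():
            assert intact_panel.length(gene) == length
        assert all(intact_panel.length(g) % 3 == 0 for g in intact_panel.names())

    def test_gene_with_no_intact_copy_is_omitted_with_warning(self):
        rng = np.random.default_rng(2)
        cds = random_cds(rng, 60)
        broken = cds[:90] + "TAA" + cds[93:]  # internal stop everywhere
        with pytest.warns(UserWarning, match="no intact copy"):
            panel = build_reference_panel([make_single_gene_record("s1", broken)])
        assert "geneX" not in panel


class TestPresence:
    def test_verbatim_gene_has_full_coverage(self, type_a, intact_panel):
        rec, _ = type_a
        cov, loci = assess_presence(intact_panel.sequence("rbcL"), rec)
        assert cov == 1.0
        assert len(loci) == 1

    def test_ir_duplicated_gene_has_two_loci(self, type_a, intact_panel):
        rec, _ = type_a
        cov, loci = assess_presence(intact_panel.sequence("ndhB"), rec)
        assert cov == 1.0
        assert len(loci) == 2
        assert {l["strand"] for l in loci} == {"+", "-"}

    def test_truncation_coverage_matches_planted_fraction(self, intact_panel):
        rec, truth = build_plastome(
            SynthSpec.type_a(41, planted_status={"clpP": ("truncate", 0.25)})
        )
        panel = build_reference_panel([build_plastome(SynthSpec.type_a(41))[0]])
        cov, _ = assess_presence(panel.sequence("clpP"), rec)
        assert cov == pytest.approx(truth.lesions["clpP"][-1]["realized_fraction"], abs=1e-9)

    def test_diverged_copy_rescued_by_alignment(self):
        rng = np.random.default_rng(3)
        cds = random_cds(rng, 200)  # 606 bp
        mutated = list(cds)
        for pos in rng.choice(len(cds), size=24, replace=False):  # ~96% identity
            mutated[pos] = str(rng.choice([b for b in "ACGT" if b != mutated[pos]]))
        rec = make_single_gene_record("div", "".join(mutated), strand="-")
        cov, _ = assess_presence(cds, rec)
        assert cov > 0.9


class TestClassification:
    def test_planted_internal_stop_with_genome_position(self, intact_panel):
        rec, truth = build_plastome(
            SynthSpec.type_a(43, planted_status={"ndhJ": ("internal_stop",)})
        )
        st = classify_gene("ndhJ", rec, intact_panel_for(43))
        assert st.status == "pseudogene" and st.has("internal_stop")
        f = next(e for e in st.evidence if e.kind == "internal_stop")
        offset = truth.lesions["ndhJ"][-1]["cds_offset"]
        feat = rec.features_named("ndhJ")[0]
        from plastopart.core_io import feature_genome_position

        assert f.position == feature_genome_position(rec, feat, offset)

    def test_half_length_copy_without_stop(self, type_a):
        """A gene at 50% of reference length missing its stop codon is a
        pseudogene with missing_stop evidence (the IR-duplicated case)."""
        rec, truth = build_plastome(strumaria_like_spec(11))
        panel = intact_panel_for(11)
        st = classify_gene("ndhH", rec, panel)
        assert st.status == "pseudogene"
        assert st.has("missing_stop")
        assert st.copy_count == 2

    def test_planted_intact_gene_clean(self, type_a, intact_panel):
        rec, _ = type_a
        st = classify_gene("rbcL", rec, intact_panel)
        assert st.status == "intact"
        assert not any(
            e.kind in ("internal_stop", "missing_stop", "frameshift") for e in st.evidence
        )

    def test_deleted_gene_is_lost(self):
        rec, _ = build_plastome(
            SynthSpec.type_a(47, planted_status={"ndhE": ("delete",)})
        )
        st = classify_gene("ndhE", rec, intact_panel_for(47))
        assert st.status == "lost"
        cov = next(e for e in st.evidence if e.kind == "coverage_fraction")
        assert cov.value == 0.0

    def test_frameshift_detected(self):
        rec, _ = build_plastome(
            SynthSpec.type_a(53, planted_status={"cemA": ("frameshift",)})
        )
        st = classify_gene("cemA", rec, intact_panel_for(53))
        assert st.status == "pseudogene" and st.has("frameshift")

    def test_n_patch_gives_uncertain(self):
        rec, _ = build_plastome(
            SynthSpec.type_a(59, planted_status={"ndhC": ("n_patch",)})
        )
        st = classify_gene("ndhC", rec, intact_panel_for(59))
        assert st.status == "uncertain" and st.has("contains_N")

    @pytest.mark.parametrize("frac,expected", [(0.30, "pseudogene"), (0.29, "lost")])
    def test_strict_30_percent_boundary(self, frac, expected):
        """rbcL is 720 bp, so 0.30 lands exactly on the boundary: coverage
        0.30 is not lost (strict <); just below, it is."""
        rec, truth = build_plastome(
            SynthSpec.type_a(61, planted_status={"rbcL": ("truncate", frac)})
        )
        panel = intact_panel_for(61)
        st = classify_gene("rbcL", rec, panel)
        assert truth.statuses["rbcL"] == expected
        assert st.status == expected


class TestStatusMatrix:
    def test_all_intact_panel_has_zero_degradation(self, type_a, intact_panel):
        rec, truth = type_a
        matrix, counts = status_matrix([rec], intact_panel)
        row = counts.iloc[0]
        assert row.pseudogene == 0 and row.lost == 0 and row.uncertain == 0
        assert row.intact_unique == len(intact_panel.names())
        dup = matrix[matrix.copy_count == 2].gene.tolist()
        assert "ndhB" in dup and "rps7" in dup

    @pytest.mark.parametrize("seed", range(8))
    def test_planted_statuses_recovered(self, seed):
        spec = SynthSpec.type_a(
            seed,
            planted_status={
                "ndhJ": ("internal_stop",),
                "ndhD": ("frameshift",),
                "cemA": ("missing_stop",),
                "ndhE": ("delete",),
                "ndhG": ("truncate", 0.6),
                "psaC": ("truncate", 0.15),
                "ndhC": ("n_patch",),
            },
        )
        rec, truth = build_plastome(spec)
        panel = intact_panel_for(seed)
        matrix, _ = status_matrix([rec], panel)
        got = dict(zip(matrix.gene, matrix.status))
        for gene, status in truth.statuses.items():
            assert got[gene] == status, gene

    def test_status_invariant_under_rotation(self, intact_panel):
        rec, truth = build_plastome(
            SynthSpec.type_a(11, planted_status={"ndhJ": ("internal_stop",)})
        )
        base = {
            g: classify_gene(g, rec, intact_panel).status
            for g in ("ndhJ", "rbcL", "ndhB")
        }
        rot = rotate_record(rec, 33000)
        for g, status in base.items():
            assert classify_gene(g, rot, intact_panel).status == status

    def test_coverage_always_in_unit_interval(self, type_a, intact_panel):
        rec, _ = type_a
        matrix, _ = status_matrix([rec], intact_panel)
        assert ((matrix.coverage >= 0) & (matrix.coverage <= 1)).all()
        lost = matrix[matrix.status == "lost"]
        assert (lost.coverage < 0.30).all()
        rest = matrix[matrix.status.isin(["pseudogene", "intact"])]
        assert (rest.coverage >= 0.30).all()


def intact_panel_for(seed: int):
    rec, _ = build_plastome(SynthSpec.type_a(seed))
    return build_reference_panel([rec])
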