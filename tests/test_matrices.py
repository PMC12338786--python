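"""SAS matrix construction, thresholds, combination and comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slimtriage.matrices import (
    DDG_THRESHOLDS,
    NON_TOLERATED,
    TOLERATED,
    UNKNOWN,
    DdGRecord,
    SASMatrix,
    average_ddg,
    build_clinical_matrix,
    compare_ddg_matrices,
    ddg_confidence_score,
    final_matrix,
    final_verdicts,
    matrix_variant_agreement,
    parse_positionscan,
    tolerance_from_ddg,
)
from slimtriage.motifs import AMINO_ACIDS, compile_motif_pattern
from slimtriage.variants import VariantCall, VariantEvidence


def make_call(pos_alt, label, confidence, ref="N", pid="P1", position=10):
    ev = VariantEvidence(
        pid, position, ref, pos_alt, "clinvar",
        clinical_class="Pathogenic" if label == "pathogenic" else "Benign",
        stars=1,
    ) if label != "unresolved" else VariantEvidence(
        pid, position, ref, pos_alt, "gnomad", allele_frequency=1e-9
    )
    return VariantCall(ev, label, confidence)


class TestParsePositionScan:
    def test_native_dialect_mutation_label(self, tmp_path):
        f = tmp_path / "ps.txt"
        f.write_text("NA825D\t3.42\nNA825N\t0.01\n")
        records = parse_positionscan(f, structure_id="s1", motif_start=825)
        assert records[0] == DdGRecord(1, "N", "D", 3.42, "s1")
        self_sub = records[1]
        assert self_sub.ref_aa == self_sub.alt_aa == "N"
        assert self_sub.ddg == pytest.approx(0.01)

    def test_simplified_tsv_round_trip(self, tmp_path):
        f = tmp_path / "ps.tsv"
        f.write_text("position\tref_aa\talt_aa\tddg\n2\tP\tG\t4.20\n")
        (r,) = parse_positionscan(f, structure_id="s2")
        assert (r.position, r.ref_aa, r.alt_aa, r.ddg) == (2, "P", "G", 4.2)

    def test_malformed_label_names_line(self, tmp_path):
        f = tmp_path / "bad.txt"
        f.write_text("NA825D\t3.42\n???\t1.0\n")
        with pytest.raises(ValueError, match="line 2"):
            parse_positionscan(f, motif_start=825)

    def test_empty_file(self, tmp_path):
        f = tmp_path / "empty.txt"
        f.write_text("")
        assert parse_positionscan(f, motif_start=1) == []

    def test_native_dialect_requires_motif_start(self, tmp_path):
        f = tmp_path / "ps.txt"
        f.write_text("NA825D\t3.42\n")
        with pytest.raises(ValueError, match="motif_start"):
            parse_positionscan(f)


class TestAverage:
    def test_mean_of_two_structures(self):
        recs = {
            "a": [DdGRecord(1, "N", "D", 1.0, "a")],
            "b": [DdGRecord(1, "N", "D", 3.0, "b")],
        }
        m = average_ddg(recs, "cls", 4)
        assert m.cell(1, "D") == pytest.approx(2.0)
        assert m.n_structures == 2
        assert pd.isna(m.cell(2, "D"))

    def test_single_structure_identity(self):
        recs = {"a": [DdGRecord(2, "P", "G", 4.2, "a")]}
        m = average_ddg(recs, "cls", 4)
        assert m.cell(2, "G") == pytest.approx(4.2)

    def test_structure_order_irrelevant(self):
        a = [DdGRecord(1, "N", "D", 1.0), DdGRecord(3, "A", "W", -0.5)]
        b = [DdGRecord(1, "N", "D", 2.5)]
        m1 = average_ddg({"a": a, "b": b}, "cls", 4)
        m2 = average_ddg({"b": b, "a": a}, "cls", 4)
        pd.testing.assert_frame_equal(m1.values, m2.values)

    @settings(max_examples=50, deadline=None)
    @given(
        data=st.lists(
            st.tuples(
                st.integers(0, 2),  # structure
                st.integers(1, 3),  # position
                st.sampled_from("DGW"),
                st.floats(-2, 8, allow_nan=False),
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_matches_brute_force_cell_means(self, data):
        by_structure = {}
        seen = set()
        for sid, pos, alt, ddg in data:
            if (sid, pos, alt) in seen:
                continue
            seen.add((sid, pos, alt))
            by_structure.setdefault(str(sid), []).append(
                DdGRecord(pos, "N", alt, ddg, str(sid))
            )
        m = average_ddg(by_structure, "cls", 3)
        for pos in (1, 2, 3):
            for alt in "DGW":
                vals = [
                    r.ddg
                    for recs in by_structure.values()
                    for r in recs
                    if r.position == pos and r.alt_aa == alt
                ]
                if vals:
                    assert m.cell(pos, alt) == pytest.approx(sum(vals) / len(vals))
                else:
                    assert pd.isna(m.cell(pos, alt))


class TestTolerance:
    def build(self, cells, source="pdb", length=2):
        recs = {"s": [DdGRecord(p, "N", a, v, "s") for (p, a), v in cells.items()]}
        return tolerance_from_ddg(average_ddg(recs, "cls", length, source=source))

    def test_below_pdb_threshold_tolerated(self):
        t = self.build({(1, "D"): 1.0})
        assert t.cell(1, "D") == TOLERATED

    def test_source_specific_thresholds(self):
        assert self.build({(1, "D"): 1.8}, "af2").cell(1, "D") == NON_TOLERATED
        assert self.build({(1, "D"): 1.8}, "pdb").cell(1, "D") == TOLERATED

    @pytest.mark.parametrize("source", ["pdb", "af2"])
    def test_boundary_is_non_tolerated(self, source):
        thr = DDG_THRESHOLDS[source]
        assert self.build({(1, "D"): thr}, source).cell(1, "D") == NON_TOLERATED

    def test_missing_cells_unknown(self):
        assert self.build({(1, "D"): 0.0}).cell(2, "D") == UNKNOWN

    @settings(max_examples=50, deadline=None)
    @given(
        ddg=st.floats(-2, 8, allow_nan=False),
        delta=st.floats(0.0, 5.0, allow_nan=False),
    )
    def test_monotone_lowering_never_detolerates(self, ddg, delta):
        hi = self.build({(1, "D"): ddg})
        lo = self.build({(1, "D"): ddg - delta})
        if hi.cell(1, "D") == TOLERATED:
            assert lo.cell(1, "D") == TOLERATED


class TestClinicalMatrix:
    MOTIF = compile_motif_pattern("NP.[YF]", identifier="cls")

    def test_single_pathogenic_cell(self):
        m = build_clinical_matrix([(1, make_call("D", "pathogenic", 2.3))], self.MOTIF)
        assert m.cell(1, "D") == pytest.approx(2.3)

    def test_opposing_evidence_sums(self):
        calls = [
            (1, make_call("D", "pathogenic", 2.3)),
            (1, make_call("D", "benign", -1.1)),
        ]
        m = build_clinical_matrix(calls, self.MOTIF)
        assert m.cell(1, "D") == pytest.approx(1.2)

    def test_no_calls_all_empty(self):
        m = build_clinical_matrix([], self.MOTIF)
        assert m.values.isna().all().all()

    def test_call_outside_motif_rejected(self):
        with pytest.raises(ValueError):
            build_clinical_matrix([(5, make_call("D", "pathogenic", 1.0))], self.MOTIF)

    def test_order_independence(self):
        calls = [
            (1, make_call("D", "pathogenic", 2.3)),
            (2, make_call("G", "benign", -1.0)),
            (1, make_call("D", "benign", -0.5)),
        ]
        m1 = build_clinical_matrix(calls, self.MOTIF)
        m2 = build_clinical_matrix(list(reversed(calls)), self.MOTIF)
        pd.testing.assert_frame_equal(m1.values, m2.values)


class TestDdgConfidence:
    @pytest.mark.parametrize("source", ["pdb", "af2"])
    def test_zero_at_threshold(self, source):
        assert ddg_confidence_score(DDG_THRESHOLDS[source], source) == 0.0

    def test_saturates_at_twice_threshold(self):
        assert ddg_confidence_score(2 * 2.1, "pdb") == pytest.approx(1.0)
        assert ddg_confidence_score(10.0, "pdb") == pytest.approx(1.0)

    def test_zero_ddg_scores_minus_one(self):
        assert ddg_confidence_score(0.0, "pdb") == pytest.approx(-1.0)
        assert ddg_confidence_score(0.0, "af2") == pytest.approx(-1.0)


class TestFinalMatrix:
    MOTIF = compile_motif_pattern("NP.[YF]", identifier="cls")

    def ddg_matrix(self, cells, source="pdb"):
        recs = {"s": [DdGRecord(p, "N", a, v, "s") for (p, a), v in cells.items()]}
        return average_ddg(recs, "cls", 4, source=source)

    def test_both_layers_sum(self):
        clinical = build_clinical_matrix(
            [(1, make_call("D", "pathogenic", 2.3))], self.MOTIF
        )
        # ddg 2.94 kcal/mol on pdb -> confidence (2.94-2.1)/2.1 = +0.4
        ddg = self.ddg_matrix({(1, "D"): 2.94})
        f = final_matrix(clinical, ddg)
        assert f.cell(1, "D") == pytest.approx(2.7)
        assert final_verdicts(f).cell(1, "D") == NON_TOLERATED

    def test_ddg_alone_passes_through(self):
        f = final_matrix(None, self.ddg_matrix({(2, "G"): 0.0}))
        assert f.cell(2, "G") == pytest.approx(-1.0)
        assert final_verdicts(f).cell(2, "G") == TOLERATED

    def test_cancellation_is_uncertain(self):
        clinical = build_clinical_matrix(
            [(1, make_call("D", "pathogenic", 0.3))], self.MOTIF
        )
        ddg = self.ddg_matrix({(1, "D"): 2.1 * (1 - 0.3)})  # score -0.3
        f = final_matrix(clinical, ddg)
        assert f.cell(1, "D") == pytest.approx(0.0)
        assert final_verdicts(f).cell(1, "D") == "uncertain"

    def test_clinical_only_reduces_to_tau_rule(self):
        calls = [
            (1, make_call("D", "pathogenic", 2.3)),
            (2, make_call("G", "benign", -1.0)),
            (3, make_call("W", "pathogenic", 0.2)),
        ]
        clinical = build_clinical_matrix(calls, self.MOTIF)
        v = final_verdicts(final_matrix(clinical, None))
        assert v.cell(1, "D") == NON_TOLERATED
        assert v.cell(2, "G") == TOLERATED
        assert v.cell(3, "W") == "uncertain"

    def test_shape_mismatch_rejected(self):
        other = compile_motif_pattern("NP.", identifier="cls")
        clinical = build_clinical_matrix([], other)
        with pytest.raises(ValueError):
            final_matrix(clinical, self.ddg_matrix({(1, "D"): 1.0}))


class TestCompare:
    def dense(self, rng_seed=0, length=3, source="pdb"):
        rng = np.random.default_rng(rng_seed)
        recs = {
            "s": [
                DdGRecord(p, "N", a, float(rng.uniform(-1, 6)), "s")
                for p in range(1, length + 1)
                for a in AMINO_ACIDS
                if a != "N"
            ]
        }
        return average_ddg(recs, "cls", length, source=source)

    def test_identity(self):
        m = self.dense()
        rho, acc = compare_ddg_matrices(m, m)
        assert rho == pytest.approx(1.0)
        assert acc == pytest.approx(1.0)

    def test_constant_shift_preserves_ranks(self):
        a = self.dense()
        b = SASMatrix("cls", "ddg", a.values + 0.1, source="pdb", n_structures=1)
        # guard: the shift must not cross the threshold anywhere
        crosses = ((a.values < 2.1) & (b.values >= 2.1)).any().any()
        rho, acc = compare_ddg_matrices(a, b)
        assert rho == pytest.approx(1.0)
        if not crosses:
            assert acc == pytest.approx(1.0)

    def test_negation_reverses_ranks(self):
        a = self.dense()
        b = SASMatrix("cls", "ddg", -a.values, source="pdb", n_structures=1)
        rho, _ = compare_ddg_matrices(a, b)
        assert rho == pytest.approx(-1.0)

    def test_too_few_shared_cells(self):
        recs = {"s": [DdGRecord(1, "N", "D", 1.0, "s"), DdGRecord(1, "N", "G", 2.0, "s")]}
        m = average_ddg(recs, "cls", 2)
        with pytest.raises(ValueError, match="shared cells"):
            compare_ddg_matrices(m, m)


class TestAgreement:
    def test_six_of_eight_concordant(self):
        """Tolerance matrix vs eight observed variants: 6/8 concordance."""
        cells = {
            (1, "D"): 4.0, (1, "K"): 4.2, (2, "S"): 3.9, (2, "T"): 4.1,  # non-tol
            (3, "I"): 0.3, (4, "S"): 4.5, (4, "C"): 4.4, (4, "H"): 4.6,
        }
        recs = {"s": [DdGRecord(p, "X" if False else "N", a, v, "s") for (p, a), v in cells.items()]}
        tol = tolerance_from_ddg(average_ddg(recs, "cls", 4, source="af2"))
        calls = [
            (1, make_call("D", "pathogenic", 2.0)),  # agree
            (1, make_call("K", "pathogenic", 1.0)),  # agree
            (2, make_call("S", "pathogenic", 1.0)),  # agree
            (2, make_call("T", "pathogenic", 1.0)),  # agree
            (3, make_call("I", "benign", -2.0)),     # agree
            (4, make_call("S", "pathogenic", 1.0)),  # agree
            (4, make_call("C", "benign", -1.0)),     # disagree
            (4, make_call("H", "benign", -1.0)),     # disagree
        ]
        n_agree, n_tested, acc = matrix_variant_agreement(tol, calls)
        assert (n_agree, n_tested) == (6, 8)
        assert acc == pytest.approx(0.75)

    def test_no_testable_calls(self):
        tol = tolerance_from_ddg(average_ddg({}, "cls", 4, source="pdb"))
        assert matrix_variant_agreement(tol, []) == (0, 0, None)

    def test_unknown_cells_not_tested(self):
        tol = tolerance_from_ddg(average_ddg({}, "cls", 4, source="pdb"))
        calls = [(1, make_call("D", "pathogenic", 1.0))]
        assert matrix_variant_agreement(tol, calls) == (0, 0, None)


class TestSerialization:
    def test_tsv_round_trip(self, tmp_path):
        recs = {"s": [DdGRecord(1, "N", "D", 1.25, "s"), DdGRecord(3, "A", "W", -0.5, "s")]}
        m = average_ddg(recs, "cls", 4, source="af2")
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        back = SASMatrix.from_tsv(path, "cls", "ddg", source="af2")
        pd.testing.assert_frame_equal(m.values, back.values)
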