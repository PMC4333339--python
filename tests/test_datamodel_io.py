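"""File formats, container invariants, and cohort alignment."""

import numpy as np
import pandas as pd
import pytest

from mirsense import (
    ExpressionMatrix,
    PatientRecord,
    ResponseSignature,
    ScoreSet,
    SubtypeProfile,
    ValidationError,
    align,
    chop_signature,
    read_clinical_table,
    read_expression_matrix,
    read_gi50_table,
    read_signature,
    write_clinical_table,
    write_expression_matrix,
    write_gi50_table,
    write_signature,
)
from mirsense.datamodel import DrugResponsePanel


def _write(path, text):
    path.write_text(text)
    return path


class TestExpressionMatrixIO:
    def test_well_formed_tsv_preserves_shape_and_order(self, tmp_path):
        p = _write(
            tmp_path / "m.tsv",
            "feature_id\tS1\tS2\nmiR-b\t1\t2\nmiR-a\t3\t4\nmiR-c\t5\t6\n",
        )
        m = read_expression_matrix(p)
        assert m.feature_ids == ["miR-b", "miR-a", "miR-c"]
        assert m.sample_ids == ["S1", "S2"]
        assert m.values.loc["miR-a", "S2"] == 4

    def test_duplicate_feature_id_error_names_it(self, tmp_path):
        p = _write(
            tmp_path / "m.tsv", "feature_id\tS1\nmiR-a\t1\nmiR-a\t2\n"
        )
        with pytest.raises(ValidationError, match="miR-a"):
            read_expression_matrix(p)

    def test_na_is_missing_not_zero(self, tmp_path):
        p = _write(tmp_path / "m.tsv", "feature_id\tS1\tS2\nmiR-a\tNA\t2\n")
        m = read_expression_matrix(p)
        assert np.isnan(m.values.loc["miR-a", "S1"])
        assert m.values.loc["miR-a", "S2"] == 2

    def test_non_numeric_cell_error_gives_location(self, tmp_path):
        p = _write(tmp_path / "m.tsv", "feature_id\tS1\nmiR-a\t1\nmiR-b\toops\n")
        with pytest.raises(ValidationError, match="miR-b.*S1"):
            read_expression_matrix(p)

    def test_round_trip(self, tmp_path, small_expression):
        path = tmp_path / "out.tsv"
        write_expression_matrix(small_expression, path)
        back = read_expression_matrix(path)
        pd.testing.assert_frame_equal(back.values, small_expression.values)


class TestGI50IO:
    def test_molar_scale_transformed(self, tmp_path):
        p = _write(
            tmp_path / "g.tsv",
            "drug\tCL1\tCL2\tCL3\nvin\t1e-6\t1e-7\t1e-5\n",
        )
        panel = read_gi50_table(p, scale="gi50_molar")
        assert panel.values.loc["vin", "CL1"] == pytest.approx(6.0)
        assert panel.values.loc["vin", "CL2"] == pytest.approx(7.0)

    def test_neg_log10_passthrough(self, tmp_path):
        p = _write(tmp_path / "g.tsv", "drug\tCL1\tCL2\tCL3\nvin\t6.0\t5.5\t4\n")
        panel = read_gi50_table(p, scale="neg_log10")
        assert panel.values.loc["vin", "CL1"] == 6.0

    def test_zero_molar_gi50_is_error(self, tmp_path):
        p = _write(tmp_path / "g.tsv", "drug\tCL1\tCL2\tCL3\nvin\t0\t1e-6\t1e-6\n")
        with pytest.raises(ValidationError, match="log undefined"):
            read_gi50_table(p, scale="gi50_molar")

    def test_equivalent_inputs_give_identical_panels(self, tmp_path):
        molar = _write(
            tmp_path / "a.tsv", "drug\tC1\tC2\tC3\nd\t1e-6\t1e-5\t1e-7\n"
        )
        neglog = _write(tmp_path / "b.tsv", "drug\tC1\tC2\tC3\nd\t6\t5\t7\n")
        a = read_gi50_table(molar, scale="gi50_molar")
        b = read_gi50_table(neglog, scale="neg_log10")
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_round_trip(self, tmp_path, tiny_panel):
        path = tmp_path / "p.tsv"
        write_gi50_table(tiny_panel, path)
        back = read_gi50_table(path, scale="neg_log10")
        pd.testing.assert_frame_equal(back.values, tiny_panel.values)

    def test_drug_with_too_few_measurements_rejected(self):
        df = pd.DataFrame(
            {"C1": [1.0], "C2": [np.nan], "C3": [np.nan], "C4": [2.0]}, index=["d"]
        )
        with pytest.raises(ValidationError, match="fewer than 3"):
            DrugResponsePanel(df)


_CLINICAL_HEADER = (
    "patient_id,ipi,treatment,response,os_days,os_event,pfs_days,"
    "pfs_event,relapse,relapse_regimens\n"
)


class TestClinicalIO:
    def test_valid_row_case_insensitive_response(self, tmp_path):
        p = _write(
            tmp_path / "c.csv",
            _CLINICAL_HEADER + "P1,3,R-CHOP,cru,400,0,400,0,0,\n",
        )
        (rec,) = read_clinical_table(p)
        assert rec.response == "CRu"
        assert rec.ipi == 3

    def test_ipi_out_of_range_is_error(self, tmp_path):
        p = _write(
            tmp_path / "c.csv", _CLINICAL_HEADER + "P1,6,R-CHOP,CR,400,0,400,0,0,\n"
        )
        with pytest.raises(ValidationError, match="IPI"):
            read_clinical_table(p)

    def test_pfs_after_os_with_both_events_is_error(self, tmp_path):
        p = _write(
            tmp_path / "c.csv", _CLINICAL_HEADER + "P1,2,R-CHOP,PD,300,1,500,1,1,DHAP\n"
        )
        with pytest.raises(ValidationError, match="pfs_days"):
            read_clinical_table(p)

    def test_unknown_response_label_lists_allowed(self, tmp_path):
        p = _write(
            tmp_path / "c.csv", _CLINICAL_HEADER + "P1,2,R-CHOP,XYZ,300,1,200,1,0,\n"
        )
        with pytest.raises(ValidationError, match="CR, CRu, PR, SD, PD"):
            read_clinical_table(p)

    def test_round_trip_with_regimens(self, tmp_path):
        rec = PatientRecord(
            patient_id="P9",
            ipi=4,
            treatment="R-CHOEP",
            response="PR",
            os_days=812.5,
            os_event=True,
            pfs_days=300.25,
            pfs_event=True,
            relapse=True,
            relapse_regimens=("DHAP", "ICE"),
        )
        path = tmp_path / "c.csv"
        write_clinical_table([rec], path)
        (back,) = read_clinical_table(path)
        assert back == rec


class TestSignatureIO:
    def test_packaged_chop_signature_has_20_probes(self):
        sig = chop_signature()
        assert len(sig) == 20
        assert sig.treatment_name == "CHOP"
        assert sig.threshold == 0.25
        assert "hsa-miR-93_st" in sig.feature_ids
        assert "ACA48_x_st" in sig.feature_ids  # snoRNA probe kept verbatim

    def test_round_trip_is_identity(self, tmp_path):
        sig = ResponseSignature(
            "CHOEP", (("miR-a", 0.3333333333333333), ("miR-b", 0.5)), threshold=0.25
        )
        path = tmp_path / "s.sig.tsv"
        write_signature(sig, path)
        back = read_signature(path)
        assert back.treatment_name == sig.treatment_name
        assert back.threshold == sig.threshold
        assert back.entries == sig.entries

    def test_entry_below_threshold_is_corrupt(self, tmp_path):
        p = _write(
            tmp_path / "bad.sig.tsv",
            "# treatment=X\n# threshold=0.25\n"
            "feature_id\tselection_correlation\nmiR-a\t0.10\n",
        )
        with pytest.raises(ValidationError, match="threshold"):
            read_signature(p)


class TestAlign:
    def _expr(self, samples):
        return ExpressionMatrix(
            pd.DataFrame(
                np.ones((2, len(samples))), index=["f1", "f2"], columns=samples
            )
        )

    def _cohort(self, ids):
        return [
            PatientRecord(i, 1, "R-CHOP", "CR", 100, False, 100, False)
            for i in ids
        ]

    def test_partial_overlap_in_cohort_order(self):
        res = align(self._expr(["A", "B", "C"]), self._cohort(["C", "B", "D"]))
        assert res.expression.sample_ids == ["C", "B"]
        assert [r.patient_id for r in res.records] == ["C", "B"]
        assert res.dropped_samples == ("A",)
        assert res.dropped_patients == ("D",)

    def test_identical_sets_drop_nothing(self):
        res = align(self._expr(["A", "B"]), self._cohort(["A", "B"]))
        assert res.dropped_samples == ()
        assert res.dropped_patients == ()

    def test_disjoint_sets_error(self):
        with pytest.raises(ValidationError, match="no overlap"):
            align(self._expr(["A"]), self._cohort(["B"]))


class TestContainerInvariants:
    def test_scoreset_rejects_inconsistent_calls(self):
        with pytest.raises(ValidationError, match="calls"):
            ScoreSet(
                patient_ids=("a", "b"),
                raw_scores=(1.0, 2.0),
                normalized_scores=(0.0, 100.0),
                combined_scores=(0.0, 100.0),
                calls=("resistant", "resistant"),
                cutoff=50.0,
            )

    def test_scoreset_requires_full_0_100_span(self):
        with pytest.raises(ValidationError, match="0 and 100"):
            ScoreSet(
                patient_ids=("a", "b"),
                raw_scores=(1.0, 2.0),
                normalized_scores=(10.0, 90.0),
                combined_scores=(10.0, 90.0),
                calls=("resistant", "sensitive"),
            )

    def test_subtype_profile_lists_must_be_disjoint(self):
        with pytest.raises(ValidationError, match="overlap"):
            SubtypeProfile(gcb_features=("a", "b"), abc_features=("b", "c"))

    def test_signature_rejects_duplicates_and_empty(self):
        with pytest.raises(ValidationError):
            ResponseSignature("X", ())
        with pytest.raises(ValidationError, match="duplicate"):
            ResponseSignature("X", (("a", 0.5), ("a", 0.6)))
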