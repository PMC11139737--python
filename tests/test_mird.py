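"""MIRD dose sums, S-value tables, effective dose and summary statistics."""

import numpy as np
import pandas as pd
import pytest

from rb82dose import paper_tables
from rb82dose.mird import (
    DoseReport,
    OrganMappingError,
    SValueTable,
    TissueWeights,
    dose_range_summary,
    effective_dose,
    load_svalues,
    load_tissue_weights,
    organ_doses,
    resolve_organ_name,
    rest_stress_relative_difference,
    synthetic_svalue_table,
)
from pathlib import Path

import rb82dose

TOY_CSV = Path(rb82dose.__file__).parent / "data" / "svalues_toy.csv"


class TestSValueTable:
    def test_toy_table_loads_and_resolves(self):
        table = load_svalues(TOY_CSV)
        assert table.get("Liver", "liver") == 3.0
        assert table.get("liver", "Spleen") == 0.5
        assert table.get("Total body (remainder)", "liver") == 0.1

    def test_duplicate_pair_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(
            "phantom,source,target,s_mGy_per_MBq_h\n"
            "toy,liver,liver,1.0\ntoy,liver,liver,2.0\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            load_svalues(p)

    def test_negative_svalue_rejected(self, tmp_path):
        p = tmp_path / "neg.csv"
        p.write_text("phantom,source,target,s_mGy_per_MBq_h\ntoy,liver,liver,-1.0\n")
        with pytest.raises(ValueError, match="negative"):
            load_svalues(p)

    def test_alias_resolution(self):
        assert (
            resolve_organ_name("Urinary bladder content")
            == "urinary_bladder_contents"
        )
        assert resolve_organ_name("Heart content") == "heart_contents"

    def test_cross_dose_above_self_dose_warns(self):
        with pytest.warns(UserWarning, match="cross-dose"):
            SValueTable("odd", {("a", "a"): 1.0, ("b", "a"): 2.0, ("b", "b"): 3.0})


class TestOrganDoses:
    def test_diagonal_table(self):
        s = SValueTable("toy", {("liver", "liver"): 1.0})
        report = organ_doses(pd.Series({"liver": 0.002}), s)
        assert report.get("liver") == pytest.approx(2.0)  # uGy/MBq

    def test_two_source_hand_value(self):
        # 0.001*3 + 0.002*0.5 = 0.004 mGy/MBq = 4.0 uGy/MBq
        s = SValueTable(
            "toy",
            {("a", "a"): 3.0, ("b", "a"): 0.5, ("a", "b"): 0.0, ("b", "b"): 1.0},
        )
        report = organ_doses(pd.Series({"a": 0.001, "b": 0.002}), s)
        assert report.get("a") == pytest.approx(4.0)

    def test_zero_tia_gives_zero_doses(self):
        s = load_svalues(TOY_CSV)
        report = organ_doses(pd.Series({"liver": 0.0, "spleen": 0.0}), s)
        assert (report.doses == 0).all()

    def test_linearity(self):
        s = load_svalues(TOY_CSV)
        tia = pd.Series({"liver": 0.001, "spleen": 0.002, "total_body": 0.02})
        d1 = organ_doses(tia, s).doses
        d3 = organ_doses(3.0 * tia, s).doses
        np.testing.assert_allclose(d3, 3.0 * d1, rtol=1e-12)

    def test_unresolved_source_raises(self):
        s = load_svalues(TOY_CSV)
        with pytest.raises(OrganMappingError):
            organ_doses(pd.Series({"pancreas": 0.001}), s)

    def test_missing_remainder_row_is_explicit(self):
        s = SValueTable("toy", {("liver", "liver"): 1.0})
        with pytest.raises(ValueError, match="remainder"):
            organ_doses(pd.Series({"liver": 0.001, "Total body (remainder)": 0.02}), s)

    def test_synthetic_table_doses_are_nonnegative_and_bounded(self):
        # any non-negative S-table applied to the published TIA fixture
        # yields non-negative doses with E inside the organ-dose range
        tia = paper_tables.tia_column("p1_rest")
        masses = {organ: 100.0 for organ in tia.index if not organ.startswith("Total")}
        s = synthetic_svalue_table(masses, 1.41, body_mass_g=70000.0)
        report = organ_doses(tia, s)
        assert (report.doses >= 0).all()
        w = TissueWeights({"lungs": 0.5, "liver": 0.3, "remainder": 0.2})
        e = effective_dose(report, w)
        organ_vals = [report.get(o) for o in ("lungs", "liver", "spleen", "kidneys")]
        assert min(organ_vals) <= e <= max(report.doses)


class TestEffectiveDose:
    def test_single_organ_unit_weight(self):
        report = DoseReport(pd.Series({"liver": 1.0}))
        w = TissueWeights({"liver": 1.0})
        assert effective_dose(report, w) == pytest.approx(1.0)

    def test_equal_doses_give_that_dose(self):
        # every weighted tissue present at dose d -> E = d since sum(w) = 1
        from rb82dose.mird import _REMAINDER_CANDIDATES, _WEIGHT_CANDIDATES

        d = 0.73
        organs = {cands[0]: d for cands in _WEIGHT_CANDIDATES.values()}
        organs.update({cands[0]: d for cands in _REMAINDER_CANDIDATES})
        report = DoseReport(pd.Series(organs))
        assert effective_dose(report, load_tissue_weights()) == pytest.approx(d)

    def test_linearity(self):
        report = paper_tables.mird_dose_reports()[0]
        w = load_tissue_weights()
        doubled = DoseReport(2.0 * report.doses)
        with pytest.warns(UserWarning):
            e1 = effective_dose(report, w)
        with pytest.warns(UserWarning):
            e2 = effective_dose(doubled, w)
        assert e2 == pytest.approx(2.0 * e1, rel=1e-12)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            TissueWeights({"liver": 0.5})

    def test_bundled_weights_load(self):
        w = load_tissue_weights()
        assert sum(w.weights.values()) == pytest.approx(1.0, abs=1e-12)


class TestSummaryStatistics:
    def test_rest_stress_difference_published_values(self):
        # effective-dose pairs of two of the three subjects
        assert rest_stress_relative_difference(0.502, 0.553) == -9.2
        assert rest_stress_relative_difference(0.757, 0.745) == 1.6

    def test_equal_inputs_give_zero(self):
        assert rest_stress_relative_difference(1.0, 1.0) == 0.0

    def test_nonpositive_stress_rejected(self):
        with pytest.raises(ValueError):
            rest_stress_relative_difference(1.0, 0.0)

    def test_heart_wall_range_from_mird_table(self):
        reports = paper_tables.mird_dose_reports()
        assert dose_range_summary(reports, "Heart wall") == (1.84, 2.78)

    def test_kidneys_range_from_voxel_table(self):
        reports = paper_tables.voxel_dose_reports()
        assert dose_range_summary(reports, "Kidneys") == (3.22, 5.37)

    def test_single_report_min_equals_max(self):
        report = DoseReport(pd.Series({"liver": 1.5}))
        assert dose_range_summary([report], "liver") == (1.5, 1.5)

    def test_absent_organ_raises(self):
        report = DoseReport(pd.Series({"liver": 1.5}))
        with pytest.raises(OrganMappingError):
            dose_range_summary([report], "pancreas")

    def test_sex_specific_na_cells_are_skipped(self):
        reports = paper_tables.mird_dose_reports()
        # uterus exists only in the female subject's reports
        lo, hi = dose_range_summary(reports, "Uterus")
        assert (lo, hi) == (0.446, 0.446)
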