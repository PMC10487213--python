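"""Fatty-acid classification, class sums, component totals, yield, validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greensolv.errors import (
    FattyAcidCodeError,
    InvalidInputError,
    UndefinedRatioError,
)
from greensolv.quality import (
    MUFA,
    PUFA,
    SFA,
    STEROL,
    TOCOPHEROL,
    ComponentTable,
    FattyAcidProfile,
    class_sums,
    classify_fatty_acid,
    compare_totals,
    component_totals,
    extraction_yield,
    profiles_from_wide,
    read_composition_csv,
    read_composition_long_csv,
    summary_table,
    truncate,
    validate_profile,
)


class TestClassification:
    @pytest.mark.parametrize(
        "code, label",
        [
            ("C16:0", SFA),
            ("C18:1", MUFA),
            ("C18:2", PUFA),
            ("C18:3", PUFA),
            ("C20:1", MUFA),
        ],
    )
    def test_double_bond_count_decides_class(self, code, label):
        assert classify_fatty_acid(code) == label

    @pytest.mark.parametrize("bad", ["18:2", "C18", "C18:2:1", "Cx:y", "C1:0", ""])
    def test_malformed_codes_rejected(self, bad):
        with pytest.raises(FattyAcidCodeError):
            classify_fatty_acid(bad)


class TestClassSums:
    def test_reference_hexane_profile(self, fatty_acid_profiles):
        hexane = next(p for p in fatty_acid_profiles if p.sample == "n-Hexane")
        summary = class_sums(hexane)
        assert summary.sfa == pytest.approx(14.57)
        assert summary.mufa == pytest.approx(42.94)
        assert summary.pufa == pytest.approx(44.32)
        assert summary.ratio() == pytest.approx(44.32 / 14.57)

    def test_empty_profile_sums_to_zero(self):
        summary = class_sums(FattyAcidProfile("empty", {}))
        assert (summary.sfa, summary.mufa, summary.pufa) == (0.0, 0.0, 0.0)
        assert summary.pufa_sfa_ratio is None

    def test_all_pufa_profile_has_undefined_ratio(self):
        summary = class_sums(FattyAcidProfile("x", {"C18:3": 100.0}))
        assert summary.pufa == 100.0
        assert summary.sfa == 0.0
        with pytest.raises(UndefinedRatioError):
            summary.ratio()

    @given(
        st.dictionaries(
            keys=st.sampled_from(
                ["C8:0", "C14:0", "C16:0", "C16:1", "C18:1", "C18:2", "C18:3", "C20:0"]
            ),
            values=st.floats(0, 50),
            max_size=8,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_classes_partition_the_total(self, entries):
        summary = class_sums(FattyAcidProfile("p", entries))
        assert summary.sfa + summary.mufa + summary.pufa == pytest.approx(
            sum(entries.values()), abs=1e-9
        )

    def test_permutation_invariant(self, fatty_acid_profiles):
        hexane = next(p for p in fatty_acid_profiles if p.sample == "n-Hexane")
        reversed_entries = dict(reversed(list(hexane.entries.items())))
        assert class_sums(FattyAcidProfile("r", reversed_entries)) == class_sums(
            FattyAcidProfile("r", hexane.entries)
        )


class TestSummaryDisplay:
    def test_truncation_convention_for_ratio(self):
        # the display ratio is truncated at 2 decimals, sums are rounded
        assert truncate(2.70911) == 2.70
        assert truncate(3.04187) == 3.04
        assert truncate(-1.239) == -1.23

    def test_summary_table_layout(self, fatty_acid_profiles):
        table = summary_table([class_sums(p) for p in fatty_acid_profiles])
        assert list(table.index) == [SFA, MUFA, PUFA, "PUFA/SFA"]
        assert table.loc[SFA, "CPME"] == pytest.approx(12.59)
        assert table.loc["PUFA/SFA", "CPME"] == pytest.approx(3.46)


class TestComponentTotals:
    def test_cpme_sterol_sum(self):
        from greensolv.datasets import load_component_table

        totals = component_totals(load_component_table(STEROL))
        assert totals["CPME"] == pytest.approx(785.91)

    def test_family_mismatch_rejected(self):
        from greensolv.datasets import load_component_table

        with pytest.raises(InvalidInputError):
            component_totals(load_component_table(STEROL), family=TOCOPHEROL)

    def test_all_zero_column_totals_zero(self):
        table = ComponentTable(
            family=STEROL,
            data=pd.DataFrame({"s1": [0.0, 0.0], "s2": [1.0, 2.0]}, index=["a", "b"]),
        )
        totals = component_totals(table)
        assert totals["s1"] == 0.0 and totals["s2"] == 3.0

    def test_totals_are_additive_over_concatenation(self, rng):
        data1 = pd.DataFrame(rng.uniform(0, 100, (3, 4)), index=["a", "b", "c"])
        data2 = pd.DataFrame(rng.uniform(0, 100, (2, 4)), index=["d", "e"])
        t1 = component_totals(ComponentTable(STEROL, data1))
        t2 = component_totals(ComponentTable(STEROL, data2))
        combined = component_totals(ComponentTable(STEROL, pd.concat([data1, data2])))
        np.testing.assert_allclose(combined, t1 + t2)

    def test_negative_contents_rejected(self):
        with pytest.raises(InvalidInputError):
            ComponentTable(STEROL, pd.DataFrame({"s": [-1.0]}))

    def test_unknown_family_rejected(self):
        with pytest.raises(InvalidInputError):
            ComponentTable("lignan", pd.DataFrame({"s": [1.0]}))

    def test_printed_totals_compared_not_overwritten(self):
        table = ComponentTable(
            family=TOCOPHEROL,
            data=pd.DataFrame({"s": [1.0, 2.0]}, index=["a", "b"]),
            printed_totals=pd.Series({"s": 10.0}),
        )
        check = compare_totals(table)
        assert check.loc["s", "recomputed"] == 3.0
        assert check.loc["s", "printed"] == 10.0
        assert bool(check.loc["s", "flagged"])


class TestExtractionYield:
    @pytest.mark.parametrize(
        "oil, seeds, expected", [(0.0, 10.0, 0.0), (5.0, 10.0, 50.0), (58.82, 100.0, 58.82)]
    )
    def test_percent_of_dry_mass(self, oil, seeds, expected):
        assert extraction_yield(oil, seeds) == pytest.approx(expected)

    @pytest.mark.parametrize("seeds", [0.0, -1.0])
    def test_nonpositive_seed_mass_rejected(self, seeds):
        with pytest.raises(InvalidInputError):
            extraction_yield(1.0, seeds)


class TestValidation:
    def test_reference_hexane_column_is_valid(self, fatty_acid_profiles):
        hexane = next(p for p in fatty_acid_profiles if p.sample == "n-Hexane")
        report = validate_profile(hexane)
        assert report.valid
        assert report.total == pytest.approx(101.83)

    def test_syntax_violation_listed(self):
        report = validate_profile(FattyAcidProfile("x", {"18:2": 50.0, "C16:0": 50.0}))
        assert not report.valid
        assert any("18:2" in issue for issue in report.issues)

    def test_negative_percentage_listed(self):
        report = validate_profile(FattyAcidProfile("x", {"C16:0": -0.1, "C18:1": 100.0}))
        assert not report.valid
        assert any("negative" in issue for issue in report.issues)


class TestIO:
    def test_wide_and_long_readers_agree(self, tmp_path):
        wide = pd.DataFrame(
            {"A": [1.0, 2.0], "B": [3.0, 4.0]}, index=pd.Index(["C16:0", "C18:1"], name="code")
        )
        wide_path = tmp_path / "wide.csv"
        wide.to_csv(wide_path)
        long = wide.reset_index().melt(id_vars="code", var_name="sample", value_name="value")
        long = long.rename(columns={"code": "analyte"})
        long_path = tmp_path / "long.csv"
        long.to_csv(long_path, index=False)
        from_wide = read_composition_csv(wide_path)
        from_long = read_composition_long_csv(long_path)
        pd.testing.assert_frame_equal(
            from_wide.sort_index(), from_long.sort_index(), check_names=False
        )
        profiles = profiles_from_wide(from_wide)
        assert [p.sample for p in profiles] == ["A", "B"]
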