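"""ddCT arithmetic, fold-regulation conventions and volcano classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_ct_table
from mirvalid.core import ValidationError
from mirvalid.qpcrquant import (
    CtTable,
    PanelConfig,
    classify_volcano,
    ddct_quantify,
    delta_ct,
    fold_change_from_regulation,
    fold_regulation,
)


def two_group_ct(case_targets, ctrl_targets, ref_case=20.0, ref_ctrl=20.0,
                 target="miR-t", ref="miR-r"):
    rows = []
    for i, ct in enumerate(case_targets):
        rows.append((f"c{i}", "case", target, ct, False))
        rows.append((f"c{i}", "case", ref, ref_case, False))
    for i, ct in enumerate(ctrl_targets):
        rows.append((f"k{i}", "control", target, ct, False))
        rows.append((f"k{i}", "control", ref, ref_ctrl, False))
    return make_ct_table(rows)


PANEL = PanelConfig(target_assays=["miR-t"], reference_assays=["miR-r"])


class TestDeltaCt:
    def test_mean_of_two_references(self):
        ct = make_ct_table([
            ("s1", "case", "miR-t", 25.0, False),
            ("s1", "case", "ref1", 20.0, False),
            ("s1", "case", "ref2", 22.0, False),
            ("s2", "control", "miR-t", 25.0, False),
            ("s2", "control", "ref1", 20.0, False),
            ("s2", "control", "ref2", 22.0, False),
        ])
        panel = PanelConfig(target_assays=["miR-t"],
                            reference_assays=["ref1", "ref2"])
        dct = delta_ct(ct, panel)
        assert dct.loc[dct.sample_id == "s1", "dct"].item() == pytest.approx(4.0)

    def test_single_reference_degenerate_mean(self):
        ct = two_group_ct([24.0], [26.0])
        dct = delta_ct(ct, PANEL)
        assert set(dct["dct"]) == {4.0, 6.0}

    def test_undetermined_reference_uses_remaining(self):
        ct = make_ct_table([
            ("s1", "case", "miR-t", 25.0, False),
            ("s1", "case", "ref1", 21.0, False),
            ("s1", "case", "ref2", np.nan, True),
        ])
        panel = PanelConfig(target_assays=["miR-t"],
                            reference_assays=["ref1", "ref2"])
        dct = delta_ct(ct, panel)
        assert dct["dct"].item() == pytest.approx(4.0)

    def test_sample_without_reference_dropped_with_name(self):
        ct = make_ct_table([
            ("good", "case", "miR-t", 25.0, False),
            ("good", "case", "miR-r", 20.0, False),
            ("bad", "case", "miR-t", 25.0, False),
            ("bad", "case", "miR-r", np.nan, True),
        ])
        with pytest.warns(UserWarning, match="bad"):
            dct = delta_ct(ct, PANEL)
        assert set(dct["sample_id"]) == {"good"}

    def test_replicates_averaged_before_dct(self):
        ct = make_ct_table([
            ("s1", "case", "miR-t", 24.0, False),
            ("s1", "case", "miR-t", 26.0, False),
            ("s1", "case", "miR-r", 20.0, False),
        ])
        dct = delta_ct(ct, PANEL)
        assert dct["dct"].item() == pytest.approx(5.0)


class TestDdctQuantify:
    def test_known_formula(self):
        # case dCT mean 3, control 5 -> ddCT -2, FC 4, FR 4
        ct = two_group_ct([23.0, 23.0], [25.0, 25.0])
        res = ddct_quantify(delta_ct(ct, PANEL))
        row = res.loc["miR-t"]
        assert row["ddct"] == pytest.approx(-2.0)
        assert row["fold_change"] == pytest.approx(4.0)
        assert row["fold_regulation"] == pytest.approx(4.0)

    def test_equal_means_identity(self):
        ct = two_group_ct([24.0, 25.0], [25.0, 24.0])
        row = ddct_quantify(delta_ct(ct, PANEL)).loc["miR-t"]
        assert row["ddct"] == pytest.approx(0.0)
        assert row["fold_change"] == pytest.approx(1.0)
        assert row["fold_regulation"] == pytest.approx(1.0)

    def test_downregulation_sign_convention(self):
        fc = 0.3774
        assert fold_regulation(fc) == pytest.approx(-2.65, abs=0.005)

    def test_underpowered_target_flagged(self):
        ct = make_ct_table([
            ("c0", "case", "miR-t", 24.0, False),
            ("c0", "case", "miR-r", 20.0, False),
            ("k0", "control", "miR-t", 25.0, False),
            ("k0", "control", "miR-r", 20.0, False),
            ("k1", "control", "miR-t", 25.5, False),
            ("k1", "control", "miR-r", 20.0, False),
        ])
        row = ddct_quantify(delta_ct(ct, PANEL)).loc["miR-t"]
        assert bool(row["flagged"]) and np.isnan(row["p"])

    def test_label_swap_negates_ddct(self):
        ct = two_group_ct([22.0, 23.0, 21.5], [25.0, 26.0, 24.5])
        swapped_rows = ct.records.copy()
        swapped_rows["group"] = swapped_rows["group"].map(
            {"case": "control", "control": "case"}
        )
        r1 = ddct_quantify(delta_ct(ct, PANEL)).loc["miR-t"]
        r2 = ddct_quantify(delta_ct(CtTable(swapped_rows), PANEL)).loc["miR-t"]
        assert r2["ddct"] == pytest.approx(-r1["ddct"])
        assert r2["fold_regulation"] == pytest.approx(-r1["fold_regulation"])
        assert r2["p"] == pytest.approx(r1["p"])

    def test_permutation_p_close_to_welch(self):
        ct = two_group_ct([22.0, 23.0, 21.5, 22.5], [25.0, 26.0, 24.5, 25.5])
        dct = delta_ct(ct, PANEL)
        welch = ddct_quantify(dct).loc["miR-t", "p"]
        perm = ddct_quantify(
            dct, p_on="permutation", n_permutations=2000,
            rng=np.random.default_rng(0),
        ).loc["miR-t", "p"]
        # a complete-separation toy: both should call it significant
        assert welch < 0.05 and perm < 0.05


class TestFoldRegulation:
    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.floats(0.01, 100.0))
    def test_round_trip_identity(self, fc):
        fr = fold_regulation(fc)
        assert abs(fr) >= 1.0
        assert fold_change_from_regulation(fr) == pytest.approx(fc, rel=1e-12)
        assert fold_regulation(fold_change_from_regulation(fr)) == pytest.approx(
            fr, rel=1e-12
        )

    def test_round_trip_exact(self):
        for fc in (0.25, 0.5, 1.0, 2.0, 7.5):
            fr = fold_regulation(fc)
            back = fr if fr >= 1 else -1.0 / fr
            assert back == pytest.approx(fc)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            fold_regulation(0.0)


class TestClassifyVolcano:
    def _frame(self, fr, p):
        return pd.DataFrame({"fold_regulation": fr, "p": p})

    @pytest.mark.parametrize(
        "fr,p,expected",
        [
            (2.24, 0.007977, "up"),
            (-4.54, 0.000001, "down"),
            (1.5, 0.01, "ns"),
            (2.0, 0.05, "ns"),     # p cut is strict <
            (2.0, 0.049, "up"),    # fr cut is inclusive >=
            (-2.0, 0.049, "down"),
        ],
    )
    def test_threshold_cases(self, fr, p, expected):
        out = classify_volcano(self._frame([fr], [p]))
        assert out["class"].iloc[0] == expected

    def test_missing_p_is_ns(self):
        out = classify_volcano(self._frame([5.0], [np.nan]))
        assert out["class"].iloc[0] == "ns"


class TestPanelConfig:
    def test_overlapping_roles_rejected(self):
        with pytest.raises(ValidationError, match="both"):
            PanelConfig(target_assays=["a"], reference_assays=["a"])

    def test_requires_reference(self):
        with pytest.raises(ValidationError, match="reference"):
            PanelConfig(target_assays=["a"], reference_assays=[])
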