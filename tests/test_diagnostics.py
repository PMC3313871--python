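"""Box-plot summaries, shifted-center detection, corrections, plausibility."""

import logging

import numpy as np
import pandas as pd
import pytest

import iccwatch as iw
from iccwatch.diagnostics import MAD_SCALE
from iccwatch.exceptions import (
    InsufficientClustersError,
    NoMatchingRowsError,
    RuleAlreadyAppliedError,
    ValidationError,
    VariableNotFoundError,
)
from helpers import make_table, seed_for


def summaries_from_medians(medians):
    """Minimal CenterSummary list carrying only the medians that matter."""
    return [
        iw.CenterSummary(
            center_id=f"C{i:02d}", n=10, mean=m, median=m, q1=m, q3=m,
            iqr=0.0, whisker_low=m, whisker_high=m,
        )
        for i, m in enumerate(medians)
    ]


class TestCenterBoxplotStats:
    def test_hand_tukey_summary_with_outlier(self):
        tab = make_table({"A": [1, 2, 3, 4, 100]})
        (s,) = iw.center_boxplot_stats(tab, "y")
        assert (s.q1, s.median, s.q3) == (2.0, 3.0, 4.0)
        assert s.iqr == 2.0
        assert s.outlier_values == (100.0,)
        assert (s.whisker_low, s.whisker_high) == (1.0, 4.0)

    def test_single_value_center(self):
        tab = make_table({"A": [7]})
        (s,) = iw.center_boxplot_stats(tab, "y")
        assert s.q1 == s.median == s.q3 == 7.0
        assert s.outlier_values == ()

    def test_identical_centers_identical_summaries(self):
        tab = make_table({"A": [1, 2, 3], "B": [1, 2, 3], "C": [1, 2, 3]})
        a, b, c = iw.center_boxplot_stats(tab, "y")
        for field in ("median", "q1", "q3", "whisker_low", "whisker_high"):
            assert getattr(a, field) == getattr(b, field) == getattr(c, field)

    def test_order_stable_by_center_id(self):
        tab = make_table({"B": [1], "A": [2], "AB": [3]})
        ids = [s.center_id for s in iw.center_boxplot_stats(tab, "y")]
        assert ids == sorted(ids)

    def test_unknown_variable_errors(self):
        with pytest.raises(VariableNotFoundError, match="variable not found"):
            iw.center_boxplot_stats(make_table({"A": [1]}), "nope")


class TestShiftDetection:
    def test_two_grossly_shifted_centers_flagged(self):
        found = iw.detect_shifted_centers(
            summaries_from_medians([70, 71, 69, 120, 121]), min_offset=20
        )
        assert {f.center_id for f in found} == {"C03", "C04"}
        offsets = sorted(f.estimated_offset for f in found)
        assert offsets == [49.0, 50.0]

    def test_no_shift_no_flags(self):
        assert (
            iw.detect_shifted_centers(
                summaries_from_medians([70, 71, 69]), min_offset=20
            )
            == []
        )

    def test_negative_offset_detected(self):
        found = iw.detect_shifted_centers(
            summaries_from_medians([-10, 69, 70, 71]), min_offset=20
        )
        assert [f.center_id for f in found] == ["C00"]
        assert found[0].estimated_offset == pytest.approx(-79.5)

    def test_requires_three_centers(self):
        with pytest.raises(InsufficientClustersError):
            iw.detect_shifted_centers(summaries_from_medians([1, 2]))

    def test_invariant_to_common_constant(self):
        meds = [70.0, 71.0, 69.0, 120.0, 121.0]
        base = iw.detect_shifted_centers(summaries_from_medians(meds), 20)
        shifted = iw.detect_shifted_centers(
            summaries_from_medians([m + 500 for m in meds]), 20
        )
        assert [(f.center_id, f.estimated_offset) for f in base] == [
            (f.center_id, f.estimated_offset) for f in shifted
        ]

    def test_robust_z_rule_uses_scaled_mad(self):
        meds = [70, 71, 69, 120, 121]
        ref = np.median(meds)
        mad = np.median(np.abs(np.array(meds) - ref)) * MAD_SCALE
        found = iw.detect_shifted_centers(summaries_from_medians(meds),
                                          min_offset=None, robust_z=3.0)
        assert {f.center_id for f in found} == {"C03", "C04"}
        for f in found:
            assert f.robust_z == pytest.approx(abs(f.estimated_offset) / mad)

    def test_offset_estimate_converges_with_center_size(self):
        base = seed_for("offset-convergence")
        d, sw, k = 13.0, 4.0, 10
        mean_abs_err = {}
        for n in (100, 1600):
            errs = []
            for i in range(20):
                cfg = iw.SimulationConfig(
                    k=k, center_sizes=n, mu=70.0, sigma_b=0.0, sigma_w=sw,
                    offsets={"C": d}, seed=(base + i) % 2**31,
                )
                tab = iw.simulate_multicenter(cfg)
                found = iw.detect_shifted_centers(
                    iw.center_boxplot_stats(tab, "sitting_height"), min_offset=5
                )
                (hit,) = [f for f in found if f.center_id == "C"]
                errs.append(abs(hit.estimated_offset - d))
            mean_abs_err[n] = float(np.mean(errs))
        se_median = 1.2533 * sw / np.sqrt(1600)
        assert mean_abs_err[1600] <= 2 * se_median
        assert mean_abs_err[1600] < mean_abs_err[100]

    def test_gross_offset_drives_icc_to_one(self):
        rng = np.random.default_rng(seed_for("gross-offset"))
        groups = {f"C{i}": list(rng.uniform(0, 10, 30)) for i in range(6)}
        tab = make_table(groups)
        data_range = tab["value"].max() - tab["value"].min()
        rule = iw.CorrectionRule(
            center_id="C0", variable="y", offset=1e6 * data_range,
            reason="synthetic gross equipment error",
        )
        corrupted, _ = iw.apply_correction(tab, rule)
        assert iw.icc_estimate(corrupted).rho > 0.99


class TestApplyCorrection:
    def test_offset_applied_to_values(self):
        tab = make_table({"B": [20.0, 21.0], "A": [70.0, 71.0], "C": [69.0]})
        rule = iw.CorrectionRule("B", "y", 50.0, reason="wrong ruler")
        fixed, log = iw.apply_correction(tab, rule)
        assert sorted(fixed.loc[fixed.center_id == "B", "value"]) == [70.0, 71.0]
        assert len(log) == 2
        assert set(log.columns) >= {"subject_id", "old_value", "new_value"}

    def test_only_target_center_changes(self):
        tab = make_table({"AB": [60.0, 61.0], "A": [70.0], "B": [71.0]})
        fixed, _ = iw.apply_correction(tab, iw.CorrectionRule("AB", "y", 10.0))
        untouched = fixed[fixed.center_id != "AB"]
        assert untouched["value"].tolist() == tab[tab.center_id != "AB"]["value"].tolist()
        assert fixed.loc[fixed.center_id == "AB", "value"].tolist() == [70.0, 71.0]
        assert len(fixed) == len(tab)

    def test_download_window_and_subject_scope(self):
        tab = pd.concat(
            [make_table({"B": [1.0, 2.0]}, download_index=1),
             make_table({"B": [3.0, 4.0]}, download_index=2)],
            ignore_index=True,
        )
        tab["subject_id"] = [f"s{i}" for i in range(len(tab))]
        rule = iw.CorrectionRule("B", "y", 10.0, download_min=2, download_max=2)
        fixed, log = iw.apply_correction(tab, rule)
        assert fixed.loc[fixed.download_index == 1, "value"].tolist() == [1.0, 2.0]
        assert fixed.loc[fixed.download_index == 2, "value"].tolist() == [13.0, 14.0]
        subj = tuple(log["subject_id"][:1])
        rule2 = iw.CorrectionRule("B", "y", 5.0, subject_ids=subj)
        fixed2, log2 = iw.apply_correction(fixed, rule2)
        assert len(log2) == 1

    def test_reapplication_raises(self):
        tab = make_table({"A": [1.0], "B": [2.0]})
        rule = iw.CorrectionRule("A", "y", 5.0)
        fixed, _ = iw.apply_correction(tab, rule)
        with pytest.raises(RuleAlreadyAppliedError, match="already applied"):
            iw.apply_correction(fixed, rule)

    def test_absent_center_raises(self):
        with pytest.raises(NoMatchingRowsError, match="no matching rows"):
            iw.apply_correction(
                make_table({"A": [1.0]}), iw.CorrectionRule("ZZ", "y", 5.0)
            )

    def test_inverse_rule_restores_exactly(self):
        tab = make_table({"A": [10.0, 12.0], "B": [20.0, 24.0]})
        rule = iw.CorrectionRule("B", "y", -50.0)
        fixed, _ = iw.apply_correction(tab, rule)
        restored, _ = iw.apply_correction(fixed, rule.inverse())
        assert restored["value"].tolist() == tab["value"].tolist()

    def test_revert_from_change_log_is_bit_exact(self):
        rng = np.random.default_rng(seed_for("revert-log"))
        tab = make_table({"A": list(rng.normal(70.3, 1, 5)),
                          "B": list(rng.normal(70.3, 1, 5))})
        rule = iw.CorrectionRule("A", "y", 0.1, reason="fp-hostile offset")
        fixed, log = iw.apply_correction(tab, rule)
        restored = iw.revert_correction(fixed, log)
        assert np.array_equal(
            restored["value"].to_numpy(), tab["value"].to_numpy()
        )

    def test_correction_then_icc_recompute(self, hand_table):
        # shifting B:{4,5,6} down by 3 aligns the centers: no clustering left
        fixed, _ = iw.apply_correction(
            hand_table, iw.CorrectionRule("B", "y", -3.0)
        )
        est = iw.icc_estimate(fixed)
        assert est.rho_raw == pytest.approx(-0.5, abs=1e-12)
        assert est.rho == 0.0

    def test_zero_offset_rule_invalid(self):
        with pytest.raises(ValidationError):
            iw.CorrectionRule("A", "y", 0.0)


class TestImplausibleValueScan:
    RANGES = [iw.PlausibleRange("y", 40.0, 120.0)]

    def test_out_of_range_value_flagged(self):
        tab = make_table({"A": [0.0, 80.0]})
        flags = iw.implausible_value_scan(tab, self.RANGES)
        assert len(flags) == 1
        assert flags[0].flag_type is iw.FlagType.IMPLAUSIBLE_VALUE
        assert flags[0].details["value"] == 0.0

    def test_boundary_value_is_plausible(self):
        tab = make_table({"A": [120.0, 40.0]})
        assert iw.implausible_value_scan(tab, self.RANGES) == []

    def test_empty_table_empty_report(self):
        assert iw.implausible_value_scan(make_table({}), self.RANGES) == []

    def test_variable_without_range_skipped_with_warning(self, caplog):
        tab = make_table({"A": [999.0]}, variable="unranged")
        with caplog.at_level(logging.WARNING, logger="iccwatch.diagnostics"):
            flags = iw.implausible_value_scan(tab, self.RANGES)
        assert flags == []
        assert "no plausible range" in caplog.text

    def test_invalid_range_rejected(self):
        with pytest.raises(ValidationError):
            iw.PlausibleRange("y", 10.0, 10.0)
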