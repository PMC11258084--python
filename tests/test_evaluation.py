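"""RMS statistics, detection rules and diagnostic metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cacsim.evaluation import (
    DetectionThresholds,
    build_report,
    classify_fn_fp,
    diagnostic_metrics,
    rms,
    rmse_rmsd,
    summary_table,
)


def make_table(rows):
    defaults = {
        "method": "volume_fraction", "group": "low", "patient_size": "medium",
        "kind": "insert", "roi_name": "r", "insert_name": "i", "diameter_mm": 5.0,
        "density_mgha": 52.0, "slice": 0, "score": np.nan, "mass_mg": 0.0,
        "ground_truth_mg": 0.5, "matched_negative": False,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestRMS:
    def test_zero_for_identical(self):
        assert rms([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_examples(self):
        assert rms([3.0, 4.0], [0.0, 0.0]) == pytest.approx(np.sqrt(25 / 2))
        assert rms([1, 1, 1, 1], [0, 0, 0, 0]) == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            rms([1.0], [1.0, 2.0])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force(self, values):
        y = np.asarray(values)
        yhat = np.zeros_like(y)
        brute = np.sqrt(sum(abs(a - b) ** 2 for a, b in zip(y, yhat)) / len(y))
        assert rms(y, yhat) == pytest.approx(brute, rel=1e-12, abs=1e-12)


class TestDetectionRules:
    def bkg_rows(self, masses, **kw):
        return [
            {"kind": "background", "roi_name": f"b{i}", "insert_name": None,
             "mass_mg": m, "ground_truth_mg": 0.0, "matched_negative": True, **kw}
            for i, m in enumerate(masses)
        ]

    def test_threshold_is_mean_plus_1p5_sd(self):
        table = make_table(self.bkg_rows([0.0, 1.0, 2.0, 3.0]))
        thr = DetectionThresholds.from_background(table)
        mean, sd, t = thr.stats[("volume_fraction", "medium", 5.0)]
        assert mean == pytest.approx(1.5)
        assert sd == pytest.approx(np.std([0, 1, 2, 3], ddof=1))
        assert t == pytest.approx(mean + 1.5 * sd)

    def test_mass_at_threshold_is_fn_inclusive(self):
        bkg = self.bkg_rows([0.0, 1.0, 2.0, 3.0])
        thr_val = 1.5 + 1.5 * np.std([0, 1, 2, 3], ddof=1)
        table = make_table(bkg + [
            {"mass_mg": thr_val},              # exactly at threshold -> FN
            {"mass_mg": thr_val + 1e-9},       # just above -> detected
        ])
        thresholds = DetectionThresholds.from_background(table)
        labeled = classify_fn_fp(table, thresholds)
        ins = labeled[labeled["kind"] == "insert"]["label"].tolist()
        assert ins == ["fn", "tp"]

    def test_agatston_zero_score_rule(self):
        bkg = self.bkg_rows([0.0, 0.0, 0.0], method="agatston")
        table = make_table(bkg + [
            {"method": "agatston", "score": 0.0, "mass_mg": 0.0},
            {"method": "agatston", "score": 2.5, "mass_mg": 0.1},
        ])
        thresholds = DetectionThresholds.from_background(table)
        labeled = classify_fn_fp(table, thresholds)
        ins = labeled[labeled["kind"] == "insert"]["label"].tolist()
        assert ins == ["fn", "tp"]

    def test_background_fp_rule(self):
        bkg = self.bkg_rows([0.0, 0.1, -0.1, 0.05, 5.0])
        table = make_table(bkg)
        thresholds = DetectionThresholds.from_background(table)
        labeled = classify_fn_fp(table, thresholds)
        assert (labeled["label"] == "fp").sum() == 1  # only the 5.0 outlier

    def test_missing_background_stats_is_error(self):
        table = make_table([{"kind": "insert", "mass_mg": 1.0}])
        with pytest.raises(ValueError, match="background"):
            DetectionThresholds.from_background(table)


class TestDiagnostics:
    def labeled(self, tp, fn, fp, tn):
        rows = (
            [{"kind": "insert", "label": "tp"}] * tp
            + [{"kind": "insert", "label": "fn"}] * fn
            + [{"kind": "background", "label": "fp"}] * fp
            + [{"kind": "background", "label": "tn"}] * tn
        )
        return pd.DataFrame(rows)

    def test_perfect_classifier(self):
        d = diagnostic_metrics(self.labeled(10, 0, 0, 10))
        assert (d["sensitivity"], d["specificity"], d["ppv"], d["npv"]) == (100.0, 100.0, 100.0, 100.0)

    def test_printed_sensitivity_arithmetic(self):
        # 85 misses out of 162 positives (68 + 17 across both groups), no FPs
        d = diagnostic_metrics(self.labeled(162 - 85, 85, 0, 162))
        assert d["sensitivity"] == pytest.approx(47.53, abs=0.005)
        assert d["specificity"] == 100.0

    def test_all_negatives_below_threshold(self):
        d = diagnostic_metrics(self.labeled(5, 5, 0, 20))
        assert d["specificity"] == 100.0

    def test_sensitivity_monotone_in_fn(self):
        vals = [diagnostic_metrics(self.labeled(20 - fn, fn, 1, 19))["sensitivity"] for fn in range(5)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        npvs = [diagnostic_metrics(self.labeled(20 - fn, fn, 1, 19))["npv"] for fn in range(5)]
        assert all(a >= b for a, b in zip(npvs, npvs[1:]))

    def test_empty_class_is_error(self):
        with pytest.raises(ValueError):
            diagnostic_metrics(self.labeled(0, 0, 1, 1))
        with pytest.raises(ValueError):
            diagnostic_metrics(self.labeled(1, 1, 0, 0))


class TestAccuracyAndSummary:
    def test_rmse_and_rmsd(self):
        truth = np.array([1.0, 2.0, 3.0, 4.0])
        measured = 2.0 * truth  # perfectly linear -> RMSD 0, RMSE > 0
        table = make_table(
            [{"mass_mg": m, "ground_truth_mg": t, "insert_name": f"i{i}"}
             for i, (m, t) in enumerate(zip(measured, truth))]
        )
        acc = rmse_rmsd(table)
        assert acc["rmsd_mg"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert acc["rmse_mg"].iloc[0] == pytest.approx(rms(truth, measured))
        assert acc["slope"].iloc[0] == pytest.approx(2.0)

    def test_summary_cv(self):
        rows = []
        for i, m in enumerate((10.0, 20.0, 30.0)):
            rows.append({"insert_name": f"i{i}", "mass_mg": m, "ground_truth_mg": 15.0})
        table = make_table(rows)
        summ = summary_table(table)
        assert summ["mean_mg"].iloc[0] == pytest.approx(20.0)
        assert summ["sd_mg"].iloc[0] == pytest.approx(10.0)
        assert summ["cv_pct"].iloc[0] == pytest.approx(50.0)

    def test_constant_masses_zero_cv(self):
        table = make_table(
            [{"insert_name": f"i{i}", "mass_mg": 5.0} for i in range(4)]
        )
        assert summary_table(table)["cv_pct"].iloc[0] == 0.0

    def test_zero_mean_cv_undefined(self):
        table = make_table(
            [{"insert_name": f"i{i}", "mass_mg": m} for i, m in enumerate((-1.0, 1.0))]
        )
        assert np.isnan(summary_table(table)["cv_pct"].iloc[0])

    def test_report_fn_percentages(self):
        bkg = [
            {"kind": "background", "roi_name": f"b{i}", "mass_mg": 0.0,
             "ground_truth_mg": 0.0, "matched_negative": True}
            for i in range(5)
        ]
        ins = [{"mass_mg": 1.0, "insert_name": f"i{i}"} for i in range(3)]
        ins += [{"mass_mg": -1.0, "insert_name": "i3"}]
        table = make_table(bkg + ins)
        thresholds = DetectionThresholds.from_background(table)
        labeled = classify_fn_fp(table, thresholds)
        report = build_report(labeled, thresholds)
        assert report.fn_percent("volume_fraction", "low") == pytest.approx(25.0)
        assert "False negatives" in report.render_text()
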