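"""Detectability and accuracy statistics for the scoring methods.

Inputs arrive as a tidy score table (one row per scored ROI and slice).
False negatives follow the study rule: an Agatston measurement on a
known-calcium ROI is a false negative iff its score is exactly zero, while
for the mass methods (which can return signed masses) a measurement is a
false negative iff its mass is less than or equal to the mean background
mass plus 1.5 standard deviations, with background statistics estimated
from insert-free ROIs measured by the same method under the same protocol.
False positives are the mirror rule on background ROIs.  Accuracy is
root-mean-square error against analytic ground truth (RMSE) and against
ordinary-least-squares fitted values (RMSD, the precision measure).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "rms",
    "DetectionThresholds",
    "classify_fn_fp",
    "diagnostic_metrics",
    "summary_table",
    "rmse_rmsd",
    "EvaluationReport",
]

#: Columns of the tidy score table produced by the experiment driver.
SCORE_COLUMNS = [
    "method", "group", "patient_size", "kind", "roi_name", "insert_name",
    "diameter_mm", "density_mgha", "slice", "score", "mass_mg", "ground_truth_mg",
]


def rms(y, yhat) -> float:
    """Root-mean-square difference sqrt(sum |y - yhat|^2 / N)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("length mismatch between y and yhat")
    if y.size < 1:
        raise ValueError("need at least one data point")
    return float(np.sqrt(np.mean(np.abs(y - yhat) ** 2)))


@dataclass
class DetectionThresholds:
    """Mean + 1.5 SD background-mass thresholds, stratified by protocol.

    ``stats`` maps a stratum key (method, patient_size, diameter_mm) to
    (mean, sd, threshold).  ``by`` records the stratification columns.
    """

    stats: dict[tuple, tuple[float, float, float]]
    by: tuple[str, ...] = ("method", "patient_size", "diameter_mm")
    n_sd: float = 1.5

    @classmethod
    def from_background(
        cls,
        table: pd.DataFrame,
        by: tuple[str, ...] = ("method", "patient_size", "diameter_mm"),
        n_sd: float = 1.5,
    ) -> "DetectionThresholds":
        bkg = table[table["kind"] == "background"]
        if bkg.empty:
            raise ValueError("no background rows to estimate thresholds from")
        stats = {}
        for key, sub in bkg.groupby(list(by)):
            m = float(sub["mass_mg"].mean())
            sd = float(sub["mass_mg"].std(ddof=1)) if len(sub) > 1 else 0.0
            stats[key if isinstance(key, tuple) else (key,)] = (m, sd, m + n_sd * sd)
        return cls(stats=stats, by=tuple(by), n_sd=n_sd)

    def threshold_for(self, row: pd.Series) -> float:
        key = tuple(row[c] for c in self.by)
        if key not in self.stats:
            raise KeyError(f"no background statistics for stratum {key}")
        return self.stats[key][2]


def classify_fn_fp(table: pd.DataFrame, thresholds: DetectionThresholds) -> pd.DataFrame:
    """Label each score-table row.

    Insert rows: ``fn`` (missed) or ``tp`` (detected); background rows:
    ``fp`` or ``tn``.  Agatston uses score == 0 as the miss rule; mass
    methods compare against mean background + 1.5 SD (inclusive).
    """
    out = table.copy()
    labels = []
    for _, row in out.iterrows():
        is_insert = row["kind"] == "insert"
        if row["method"] == "agatston":
            positive = row["score"] > 0
        else:
            positive = row["mass_mg"] > thresholds.threshold_for(row)
        if is_insert:
            labels.append("tp" if positive else "fn")
        else:
            labels.append("fp" if positive else "tn")
    out["label"] = labels
    return out


def diagnostic_metrics(labeled: pd.DataFrame) -> dict[str, float]:
    """Sensitivity, specificity, PPV, NPV (percent) from labelled rows."""
    counts = labeled["label"].value_counts()
    tp = int(counts.get("tp", 0))
    fn = int(counts.get("fn", 0))
    fp = int(counts.get("fp", 0))
    tn = int(counts.get("tn", 0))
    if tp + fn == 0:
        raise ValueError("no positive (insert) measurements present")
    if fp + tn == 0:
        raise ValueError("no negative (background) measurements present")
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    ppv = 100.0 * tp / (tp + fp) if tp + fp else float("nan")
    npv = 100.0 * tn / (tn + fn) if tn + fn else float("nan")
    return {"sensitivity": sens, "specificity": spec, "ppv": ppv, "npv": npv,
            "tp": tp, "fn": fn, "fp": fp, "tn": tn}


def rmse_rmsd(table: pd.DataFrame, zero_intercept: bool = False) -> pd.DataFrame:
    """Per (method, group): RMSE vs ground truth and RMSD vs OLS-fitted values.

    RMSD regresses measured mass on ground truth (ordinary least squares,
    intercept included by default) and measures scatter about the fit.
    """
    rows = []
    ins = table[(table["kind"] == "insert")]
    for (method, group), sub in ins.groupby(["method", "group"]):
        y_true = sub["ground_truth_mg"].to_numpy(float)
        y_meas = sub["mass_mg"].to_numpy(float)
        rmse = rms(y_true, y_meas)
        if zero_intercept:
            X = y_true[:, None]
        else:
            X = np.column_stack([np.ones_like(y_true), y_true])
        coef, *_ = np.linalg.lstsq(X, y_meas, rcond=None)
        fitted = X @ coef
        rmsd = rms(fitted, y_meas)
        rows.append({"method": method, "group": group, "rmse_mg": rmse, "rmsd_mg": rmsd,
                     "slope": coef[-1], "intercept": 0.0 if zero_intercept else coef[0], "n": len(sub)})
    return pd.DataFrame(rows)


def summary_table(table: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD/CV of per-insert mass by method, diameter class and patient size.

    Per-slice measurements are first summed to whole-insert masses; the
    mean is reported per patient size and pooled statistics (mean, SD,
    CV = 100 SD / mean) across sizes and densities, next to the analytic
    ground truth.  A zero pooled mean leaves the CV undefined (NaN).
    """
    ins = table[table["kind"] == "insert"]
    per_insert = (
        ins.groupby(["method", "group", "patient_size", "diameter_mm", "insert_name"])
        .agg(mass_mg=("mass_mg", "sum"), ground_truth_mg=("ground_truth_mg", "sum"))
        .reset_index()
    )
    rows = []
    for (method, dia), sub in per_insert.groupby(["method", "diameter_mm"]):
        by_size = {s: float(g["mass_mg"].mean()) for s, g in sub.groupby("patient_size")}
        mean = float(sub["mass_mg"].mean())
        sd = float(sub["mass_mg"].std(ddof=1)) if len(sub) > 1 else 0.0
        cv = 100.0 * sd / mean if mean != 0 else float("nan")
        rows.append(
            {
                "method": method,
                "diameter_mm": dia,
                **{f"mean_{s}_mg": v for s, v in sorted(by_size.items())},
                "ground_truth_mg": float(sub["ground_truth_mg"].mean()),
                "mean_mg": mean,
                "sd_mg": sd,
                "cv_pct": cv,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Aggregated detectability and accuracy results for one experiment."""

    fn_table: pd.DataFrame          # per (method, group): FN count, total, percent
    accuracy: pd.DataFrame          # rmse/rmsd per (method, group)
    diagnostics: dict[str, dict]    # per method: sensitivity/specificity/ppv/npv
    summary: pd.DataFrame           # Table-2-style mean/SD/CV
    thresholds: DetectionThresholds | None = None
    config_digest: str = ""

    def fn_percent(self, method: str, group: str) -> float:
        sel = self.fn_table[(self.fn_table["method"] == method) & (self.fn_table["group"] == group)]
        if sel.empty:
            raise KeyError((method, group))
        return float(sel["fn_pct"].iloc[0])

    def to_json(self) -> str:
        doc = {
            "false_negatives": self.fn_table.to_dict(orient="records"),
            "accuracy": self.accuracy.to_dict(orient="records"),
            "diagnostics": self.diagnostics,
            "summary": self.summary.to_dict(orient="records"),
            "config_digest": self.config_digest,
        }
        return json.dumps(doc, indent=2, default=float)

    def render_text(self) -> str:
        lines = ["False negatives (CAC = 0) per method and density group:"]
        for _, r in self.fn_table.iterrows():
            lines.append(
                f"  {r['method']:<22s} {r['group']:<5s} {int(r['fn'])}/{int(r['total'])}"
                f" = {r['fn_pct']:6.2f} %"
            )
        lines.append("")
        lines.append("Accuracy (mg):")
        for _, r in self.accuracy.iterrows():
            lines.append(
                f"  {r['method']:<22s} {r['group']:<5s} RMSE {r['rmse_mg']:7.3f}   RMSD {r['rmsd_mg']:7.3f}"
            )
        lines.append("")
        lines.append("Diagnostics (%, both groups pooled):")
        for m, d in self.diagnostics.items():
            lines.append(
                f"  {m:<22s} sens {d['sensitivity']:6.2f}  spec {d['specificity']:6.2f}"
                f"  ppv {d['ppv']:6.2f}  npv {d['npv']:6.2f}"
            )
        lines.append("")
        lines.append("Per-insert mass summary (pooled over densities):")
        lines.append(self.summary.to_string(index=False, float_format=lambda v: f"{v:0.2f}"))
        return "\n".join(lines)


def build_report(labeled: pd.DataFrame, thresholds: DetectionThresholds | None = None) -> EvaluationReport:
    """Assemble the full report from a labelled score table."""
    ins = labeled[labeled["kind"] == "insert"]
    rows = []
    for (method, group), sub in ins.groupby(["method", "group"]):
        fn = int((sub["label"] == "fn").sum())
        total = len(sub)
        rows.append({"method": method, "group": group, "fn": fn, "total": total,
                     "fn_pct": 100.0 * fn / total})
    fn_table = pd.DataFrame(rows)
    diagnostics = {m: diagnostic_metrics(sub) for m, sub in labeled.groupby("method")}
    return EvaluationReport(
        fn_table=fn_table,
        accuracy=rmse_rmsd(labeled),
        diagnostics=diagnostics,
        summary=summary_table(labeled),
        thresholds=thresholds,
    )
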