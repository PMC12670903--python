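"""Model/Results surface for the stress-adequacy evaluation.

`StressAdequacyModel` is built from a cohort (simulated or user-supplied
measurements) and `fit()` produces a `StressAdequacyResults` carrying, per
stress-adequacy marker, the confusion table against the FFR-based reference,
diagnostic summaries under both conditioning conventions, ROC/Youden
analyses and cross-validated AUCs, plus the visual-read agreement (kappa).

The evaluation question mirrors clinical use: among *negative* perfusion
studies, does the marker (splenic switch-off, a splenic SI ratio below its
cutoff, or an adequate hemodynamic response) distinguish true negatives from
potentially false negatives, with invasive FFR as the reference?
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import DegenerateEnhancementError, measure_patient
from .rules import Thresholds, adjudicate_reference, classify_negative_study, \
    hemodynamic_adequacy, predict_sso
from .simulate import PatientRecord
from .stats import Confusion2x2, CrossValAUC, DiagnosticSummary, ROCResult, \
    UndefinedMetricError, cohens_kappa, cv_auc, diagnostic_summary, roc_points

__all__ = ["StressAdequacyModel", "StressAdequacyResults"]

REPORT_SCHEMA_VERSION = 1

#: markers evaluated on negative CMR studies, in report order
NEGATIVE_STUDY_MARKERS = ("sso", "sso_stress", "si_stress_rest",
                          "si_spleen_myo", "hr", "sbp")

#: continuous scores swept in ROC analyses (all: lower value = positive call)
RATIO_SCORES = ("si_stress_rest_spleen", "si_spleen_myocardium_stress",
                "upslope_stress", "ttp_stress_s")


class StressAdequacyModel:
    """Diagnostic-accuracy evaluation of splenic stress-adequacy markers.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per analyzable patient with columns ``patient_id``,
        ``cad_ffr_positive``, ``cmr_read``, ``sso_visual``,
        ``sso_stress_visual``, ``hr_rest``, ``hr_stress``, ``sbp_rest``,
        ``sbp_stress``, ``si_stress_rest_spleen``,
        ``si_spleen_myocardium_stress``, ``ttp_stress_s``,
        ``upslope_stress`` (plus any extra columns, which are kept).
    thresholds : Thresholds
        Decision cutoffs for the markers.
    excluded : list of (patient_id, reason)
        Patients dropped during measurement (degenerate enhancement).
    """

    def __init__(self, data: pd.DataFrame,
                 thresholds: Thresholds = Thresholds(),
                 excluded: Sequence[tuple[str, str]] = ()):
        required = {"patient_id", "cad_ffr_positive", "cmr_read", "sso_visual",
                    "sso_stress_visual", "hr_rest", "hr_stress", "sbp_rest",
                    "sbp_stress", "si_stress_rest_spleen",
                    "si_spleen_myocardium_stress", "ttp_stress_s",
                    "upslope_stress"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data is missing columns {sorted(missing)}")
        self.data = data.reset_index(drop=True)
        self.thresholds = thresholds
        self.excluded = list(excluded)

    @classmethod
    def from_cohort(cls, cohort: Sequence[PatientRecord],
                    thresholds: Thresholds = Thresholds(),
                    rest_anchor: str = "independent_peak") -> "StressAdequacyModel":
        """Measure every patient's curves and assemble the analysis table.

        Patients whose curves show degenerate enhancement are excluded with a
        recorded reason rather than silently dropped.
        """
        rows, excluded = [], []
        for rec in cohort:
            try:
                m = measure_patient(rec, rest_anchor=rest_anchor)
            except DegenerateEnhancementError as err:
                excluded.append((rec.patient_id, str(err)))
                continue
            rows.append({
                "patient_id": rec.patient_id,
                "cad_ffr_positive": rec.cad_ffr_positive,
                "adequacy_truth": rec.adequacy_truth,
                "gamma_splenic": rec.gamma_splenic,
                "cmr_read": rec.cmr_read,
                "sso_visual": rec.sso_visual,
                "sso_stress_visual": rec.sso_stress_visual,
                "hr_rest": rec.hr_rest, "hr_stress": rec.hr_stress,
                "sbp_rest": rec.sbp_rest, "sbp_stress": rec.sbp_stress,
                "peak_frame_stress": m.peak_frame_stress,
                "peak_frame_rest": m.peak_frame_rest,
                "si_stress_rest_spleen": m.si_stress_rest_spleen,
                "si_spleen_myocardium_stress": m.si_spleen_myocardium_stress,
                "ttp_stress_s": m.ttp_stress_s,
                "upslope_stress": m.upslope_stress,
            })
        return cls(pd.DataFrame(rows), thresholds, excluded)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame,
                       thresholds: Thresholds = Thresholds()) -> "StressAdequacyModel":
        """Build directly from already-measured per-patient values."""
        return cls(data, thresholds)

    # -- marker calls -------------------------------------------------------

    def marker_calls(self) -> pd.DataFrame:
        """Adjudication and per-marker adequate-stress calls per patient."""
        df = self.data
        thr = self.thresholds
        out = pd.DataFrame({"patient_id": df["patient_id"]})
        out["reference_label"] = [
            adjudicate_reference(r, bool(c))
            for r, c in zip(df["cmr_read"], df["cad_ffr_positive"])
        ]
        out["sso_visual"] = df["sso_visual"].astype(bool)
        out["sso_stress_visual"] = df["sso_stress_visual"].astype(bool)
        out["call_si_stress_rest"] = [
            predict_sso(v, thr.tn_stress_rest) for v in df["si_stress_rest_spleen"]]
        out["call_si_spleen_myo"] = [
            predict_sso(v, thr.tn_spleen_myo) for v in df["si_spleen_myocardium_stress"]]
        hemo = [hemodynamic_adequacy(hr_r, hr_s, sb_r, sb_s, thr)
                for hr_r, hr_s, sb_r, sb_s in zip(df["hr_rest"], df["hr_stress"],
                                                  df["sbp_rest"], df["sbp_stress"])]
        out["hr_adequate"] = [h["hr_adequate"] for h in hemo]
        out["sbp_adequate"] = [h["sbp_adequate"] for h in hemo]
        return out

    # -- fitting ------------------------------------------------------------

    def fit(self, k_folds: int = 5, seed: int = 0,
            convention: str = "marker_conditional") -> "StressAdequacyResults":
        """Evaluate every marker against the FFR-based reference.

        ``convention`` selects the sensitivity/specificity conditioning used
        in :meth:`StressAdequacyResults.summary`; both conventions are always
        computed and kept.
        """
        calls = self.marker_calls()
        df = self.data
        negative = calls["reference_label"].isin(["true_negative", "false_negative"])
        ref_tn = (calls["reference_label"] == "true_negative").to_numpy()

        marker_cols = {
            "sso": "sso_visual",
            "sso_stress": "sso_stress_visual",
            "si_stress_rest": "call_si_stress_rest",
            "si_spleen_myo": "call_si_spleen_myo",
            "hr": "hr_adequate",
            "sbp": "sbp_adequate",
        }
        tables: dict[str, Confusion2x2] = {}
        summaries: dict[str, dict[str, DiagnosticSummary]] = {}
        neg = negative.to_numpy()
        for name, col in marker_cols.items():
            try:
                tab = Confusion2x2.from_calls(calls[col].to_numpy()[neg], ref_tn[neg])
                tables[name] = tab
                summaries[name] = {}
                for conv in ("marker_conditional", "outcome_conditional"):
                    try:
                        summaries[name][conv] = diagnostic_summary(tab, conv)
                    except UndefinedMetricError:
                        pass
            except (UndefinedMetricError, ValueError):
                continue

        # ROC / cvAUC: ratios predicting visual switch-off (full cohort) and
        # true-negative status (negative studies only).
        roc: dict[str, dict[str, ROCResult]] = {}
        cv: dict[str, dict[str, CrossValAUC]] = {}
        tasks = {
            "predict_sso_visual": (np.ones(len(df), dtype=bool),
                                   df["sso_visual"].to_numpy(dtype=bool)),
            "predict_true_negative": (neg, ref_tn),
        }
        if "adequacy_truth" in df.columns:
            # simulated cohorts carry the generative adequacy label
            tasks["predict_adequacy"] = (np.ones(len(df), dtype=bool),
                                         df["adequacy_truth"].to_numpy(dtype=bool))
        for task, (mask, labels) in tasks.items():
            roc[task], cv[task] = {}, {}
            for score_col in RATIO_SCORES:
                scores = df[score_col].to_numpy(dtype=float)[mask]
                lab = labels[mask]
                try:
                    roc[task][score_col] = roc_points(scores, lab, "lower_is_positive")
                    cv[task][score_col] = cv_auc(scores, lab, k=k_folds,
                                                 seed=seed, direction="lower_is_positive")
                except UndefinedMetricError:
                    continue

        try:
            kappa = cohens_kappa(df["sso_visual"].to_numpy(dtype=bool),
                                 df["sso_stress_visual"].to_numpy(dtype=bool))
        except UndefinedMetricError:
            kappa = None

        return StressAdequacyResults(
            model=self, calls=calls, tables=tables, summaries=summaries,
            roc=roc, cv=cv, kappa_visual=kappa, k_folds=k_folds, seed=seed,
            convention=convention,
        )


@dataclass
class StressAdequacyResults:
    """Fitted marker-performance estimates with uncertainties and diagnostics."""

    model: StressAdequacyModel
    calls: pd.DataFrame
    tables: dict[str, Confusion2x2]
    summaries: dict[str, dict[str, DiagnosticSummary]]
    roc: dict[str, dict[str, ROCResult]]
    cv: dict[str, dict[str, CrossValAUC]]
    kappa_visual: float | None
    k_folds: int
    seed: int
    convention: str

    @property
    def n_patients(self) -> int:
        return len(self.model.data)

    @property
    def n_negative(self) -> int:
        return int(self.calls["reference_label"].isin(
            ["true_negative", "false_negative"]).sum())

    def marker_table(self, convention: str | None = None) -> pd.DataFrame:
        """Per-marker sensitivity/specificity/accuracy/LR table (percent)."""
        conv = convention or self.convention
        rows = []
        for name in NEGATIVE_STUDY_MARKERS:
            if name not in self.summaries or conv not in self.summaries[name]:
                continue
            rep = self.summaries[name][conv].report()
            tab = self.tables[name]
            rows.append({
                "marker": name,
                "sensitivity_pct": rep["sensitivity_pct"],
                "specificity_pct": rep["specificity_pct"],
                "accuracy_pct": rep["accuracy_pct"],
                "lr_pos": rep["lr_pos"],
                "lr_neg": rep["lr_neg"],
                "a": tab.a, "b": tab.b, "c": tab.c, "d": tab.d,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = [
            "Stress-adequacy marker evaluation (reference: FFR-based adjudication)",
            f"  patients analyzed: {self.n_patients}   negative CMR studies: {self.n_negative}",
            f"  excluded: {len(self.model.excluded)}   "
            f"convention: {self.convention}   k-folds: {self.k_folds}   seed: {self.seed}",
            "",
            "Marker performance among negative CMR studies:",
        ]
        table = self.marker_table()
        if not table.empty:
            lines.append(table.to_string(index=False))
        lines.append("")
        lines.append("Cross-validated AUC (lower ratio = adequate stress):")
        for task, entry in self.cv.items():
            for score, res in entry.items():
                lines.append(
                    f"  {task:24s} {score:30s} cvAUC {res.cv_auc:.3f} "
                    f"(95% CI {res.ci_low:.3f}-{res.ci_high:.3f})")
        youden = self.youden_cutoffs()
        if youden:
            lines.append("")
            lines.append("Youden-optimal cutoffs:")
            for (task, score), cut in youden.items():
                lines.append(f"  {task:24s} {score:30s} <= {cut:.3f}")
        if self.kappa_visual is not None:
            lines.append("")
            lines.append(f"Visual read agreement (stress-rest vs stress-only): "
                         f"kappa = {self.kappa_visual:.2f}")
        return "\n".join(lines)

    def youden_cutoffs(self) -> dict[tuple[str, str], float]:
        return {(task, score): res.youden_cutoff
                for task, entry in self.roc.items()
                for score, res in entry.items()}

    def to_report(self) -> dict:
        """JSON-serializable report (both conventions, full precision)."""
        report: dict = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "n_patients": self.n_patients,
            "n_negative_studies": self.n_negative,
            "excluded": [{"patient_id": p, "reason": r}
                         for p, r in self.model.excluded],
            "k_folds": self.k_folds,
            "seed": self.seed,
            "convention": self.convention,
            "markers": {},
            "roc": {},
            "cv_auc": {},
            "agreement": {"kappa_visual_vs_stress_only": self.kappa_visual},
        }
        for name, convs in self.summaries.items():
            tab = self.tables[name]
            report["markers"][name] = {
                "counts": {"a": tab.a, "b": tab.b, "c": tab.c, "d": tab.d},
                **{conv: s.report() for conv, s in convs.items()},
            }
        for task, entry in self.roc.items():
            report["roc"][task] = {
                score: {"auc": res.auc, "youden_cutoff": res.youden_cutoff,
                        "direction": res.direction}
                for score, res in entry.items()
            }
        for task, entry in self.cv.items():
            report["cv_auc"][task] = {
                score: {"cv_auc": res.cv_auc, "ci_low": res.ci_low,
                        "ci_high": res.ci_high, "k": res.k,
                        "fold_aucs": list(res.fold_aucs),
                        "ci_method": res.ci_method, "seed": res.seed}
                for score, res in entry.items()
            }
        return report
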