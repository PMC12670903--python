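"""Decision thresholds for stress adequacy and study adjudication.

Three families of rules:

* FFR-referenced adjudication of the per-patient CMR read into
  true/false-positive/negative (FFR < 0.8 in any vessel defines significant
  CAD; the simulator pre-applies the per-vessel reduction to one flag);
* splenic-ratio cutoffs — low ratios indicate adequate vasodilator stress,
  so a ratio at or below the cutoff (inclusive, matching the published
  "<=" thresholds) supports a true-negative reading of a negative study,
  while a higher ratio flags it as potentially false-negative;
* hemodynamic adequacy markers: heart-rate rise >= 10 bpm and systolic
  blood-pressure drop >= 10 mmHg under adenosine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "Thresholds",
    "adjudicate_reference",
    "predict_sso",
    "classify_negative_study",
    "hemodynamic_adequacy",
]


@dataclass(frozen=True)
class Thresholds:
    """Published cutoffs, all inclusive.

    ``sso_pred_*`` cutoffs predict visual splenic switch-off from the ratios;
    ``tn_*`` cutoffs classify negative CMR studies as true- vs potentially
    false-negative.
    """

    sso_pred_stress_rest: float = 0.25
    sso_pred_spleen_myo: float = 0.28
    tn_stress_rest: float = 0.32
    tn_spleen_myo: float = 0.38
    hr_delta_bpm: float = 10.0
    sbp_delta_mmhg: float = 10.0
    ffr_cutoff: float = 0.8

    def __post_init__(self) -> None:
        ratio_cuts = (self.sso_pred_stress_rest, self.sso_pred_spleen_myo,
                      self.tn_stress_rest, self.tn_spleen_myo)
        if any(c <= 0 for c in ratio_cuts + (self.hr_delta_bpm,
                                             self.sbp_delta_mmhg,
                                             self.ffr_cutoff)):
            raise ValueError("all cutoffs must be > 0")
        if any(c >= 2 for c in ratio_cuts):
            raise ValueError("ratio cutoffs must be < 2")


def adjudicate_reference(cmr_read: str, cad_ffr_positive: bool) -> str:
    """Label a CMR study against the FFR reference.

    Returns one of ``true_negative``, ``false_negative``, ``true_positive``,
    ``false_positive``.
    """
    if cmr_read not in ("positive", "negative"):
        raise ValueError(f"cmr_read must be positive|negative, got {cmr_read!r}")
    if cmr_read == "negative":
        return "false_negative" if cad_ffr_positive else "true_negative"
    return "true_positive" if cad_ffr_positive else "false_positive"


def predict_sso(ratio: float, cutoff: float) -> bool:
    """True iff the ratio is at or below the cutoff (inclusive)."""
    if math.isnan(ratio):
        raise ValueError("ratio is NaN")
    return ratio <= cutoff


def classify_negative_study(metrics, thresholds: Thresholds = Thresholds(),
                            cmr_read: str = "negative") -> dict[str, bool]:
    """Per-marker adequate-stress calls for a negative CMR study.

    ``True`` means the marker supports a true-negative reading (adequate
    stress); ``False`` flags the study as potentially false-negative.  Only
    defined for negative reads — switch-off carries clinical meaning when the
    perfusion study itself found nothing.
    """
    if cmr_read != "negative":
        raise ValueError("classify_negative_study applies only to negative CMR reads")
    return {
        "si_stress_rest": predict_sso(metrics.si_stress_rest_spleen,
                                      thresholds.tn_stress_rest),
        "si_spleen_myo": predict_sso(metrics.si_spleen_myocardium_stress,
                                     thresholds.tn_spleen_myo),
    }


def hemodynamic_adequacy(hr_rest: float, hr_stress: float,
                         sbp_rest: float, sbp_stress: float,
                         thresholds: Thresholds = Thresholds()) -> dict[str, bool]:
    """Heart-rate and blood-pressure response markers (inclusive cutoffs)."""
    if min(hr_rest, hr_stress, sbp_rest, sbp_stress) <= 0:
        raise ValueError("vitals must be positive")
    return {
        "hr_adequate": hr_stress - hr_rest >= thresholds.hr_delta_bpm,
        "sbp_adequate": sbp_rest - sbp_stress >= thresholds.sbp_delta_mmhg,
    }
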