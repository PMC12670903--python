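"""Splenic and myocardial signal-intensity measurements.

Implements the measurement procedure for the simple quantitative ratios:
all enhancements are baseline-normalized (mean of the pre-contrast frames
subtracted) and read off at the time frame of peak myocardial SI during
first-pass perfusion.  Two ratios are produced per patient:

* ``si_stress_rest_spleen`` — splenic stress enhancement over splenic rest
  enhancement, each at the peak myocardial frame of its own condition
  (or of the stress condition, with ``rest_anchor="same_frame_index"``);
* ``si_spleen_myocardium_stress`` — splenic over myocardial enhancement on
  the stress acquisition, both at the stress peak myocardial frame.

The advanced curve parameters are time-to-peak (time from series start to
maximum SI) and "upslope", defined — as in the source measurement protocol —
as the range between minimum and maximum SI, not a literal slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import PerfusionSeries
from .simulate import PatientRecord

__all__ = [
    "SplenicMetrics",
    "DegenerateEnhancementError",
    "baseline_si",
    "peak_myocardial_frame",
    "si_stress_rest_ratio",
    "si_spleen_myocardium_ratio",
    "time_to_peak",
    "upslope",
    "measure_patient",
]

#: denominators with absolute enhancement at or below this are unusable
EPSILON_AU = 1e-6


class DegenerateEnhancementError(ValueError):
    """A ratio denominator shows no usable contrast enhancement."""

    def __init__(self, message: str, patient_id: str | None = None):
        self.patient_id = patient_id
        if patient_id is not None:
            message = f"patient {patient_id}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class SplenicMetrics:
    """Per-patient stress-adequacy biomarkers."""

    peak_frame_stress: int
    peak_frame_rest: int
    si_stress_rest_spleen: float
    si_spleen_myocardium_stress: float
    ttp_stress_s: float
    upslope_stress: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.si_stress_rest_spleen)
                and np.isfinite(self.si_spleen_myocardium_stress)):
            raise ValueError("ratios must be finite")
        if self.ttp_stress_s < 0:
            raise ValueError("ttp_stress_s must be >= 0")
        if self.upslope_stress < 0:
            raise ValueError("upslope_stress must be >= 0")


def baseline_si(series: PerfusionSeries) -> float:
    """Mean SI over the pre-contrast frames at the start of the series."""
    return float(np.mean(series.si[: series.n_baseline_frames]))


def peak_myocardial_frame(series: PerfusionSeries) -> int:
    """Index of the maximum myocardial SI; ties go to the earliest frame."""
    if series.tissue != "myocardium":
        raise ValueError(
            f"peak_myocardial_frame requires a myocardium series, got {series.tissue!r}")
    return int(np.argmax(series.si))


def _enhancement_at(series: PerfusionSeries, frame: int) -> float:
    return float(series.si[frame]) - baseline_si(series)


def si_stress_rest_ratio(spleen_stress: PerfusionSeries,
                         spleen_rest: PerfusionSeries,
                         myo_stress: PerfusionSeries,
                         myo_rest: PerfusionSeries,
                         rest_anchor: str = "independent_peak",
                         epsilon: float = EPSILON_AU) -> float:
    """Splenic stress/rest SI ratio at peak myocardial first-pass.

    ``rest_anchor`` selects the rest time frame: ``"independent_peak"``
    anchors it at the rest acquisition's own peak myocardial frame;
    ``"same_frame_index"`` reuses the stress peak frame index.
    """
    stress_frame = peak_myocardial_frame(myo_stress)
    if rest_anchor == "independent_peak":
        rest_frame = peak_myocardial_frame(myo_rest)
    elif rest_anchor == "same_frame_index":
        rest_frame = stress_frame
    else:
        raise ValueError(f"unknown rest_anchor {rest_anchor!r}")

    num = _enhancement_at(spleen_stress, stress_frame)
    den = _enhancement_at(spleen_rest, rest_frame)
    if abs(den) <= epsilon:
        raise DegenerateEnhancementError(
            f"rest splenic enhancement {den:.3g} a.u. is below {epsilon:g} "
            "(unusable rest study)")
    return num / den


def si_spleen_myocardium_ratio(spleen_stress: PerfusionSeries,
                               myo_stress: PerfusionSeries,
                               epsilon: float = EPSILON_AU) -> float:
    """Splenic over myocardial enhancement at the stress peak myocardial frame."""
    frame = peak_myocardial_frame(myo_stress)
    num = _enhancement_at(spleen_stress, frame)
    den = _enhancement_at(myo_stress, frame)
    if abs(den) <= epsilon:
        raise DegenerateEnhancementError(
            f"myocardial stress enhancement {den:.3g} a.u. is below {epsilon:g} "
            "(failed contrast arrival)")
    return num / den


def time_to_peak(series: PerfusionSeries) -> float:
    """Seconds from series start to the (earliest) maximum SI."""
    return float(series.times[int(np.argmax(series.si))] - series.times[0])


def upslope(series: PerfusionSeries) -> float:
    """SI range, max minus min, of the series (a.u.)."""
    return float(np.max(series.si) - np.min(series.si))


def measure_patient(record: PatientRecord,
                    rest_anchor: str = "independent_peak") -> SplenicMetrics:
    """Compute all splenic stress-adequacy biomarkers for one patient.

    Degenerate-enhancement errors are re-raised tagged with the patient id so
    callers can exclude the patient with a logged reason.
    """
    sp_st = record.series("stress", "spleen")
    sp_re = record.series("rest", "spleen")
    my_st = record.series("stress", "myocardium")
    my_re = record.series("rest", "myocardium")
    try:
        ratio_sr = si_stress_rest_ratio(sp_st, sp_re, my_st, my_re,
                                        rest_anchor=rest_anchor)
        ratio_sm = si_spleen_myocardium_ratio(sp_st, my_st)
    except DegenerateEnhancementError as err:
        raise DegenerateEnhancementError(str(err), patient_id=record.patient_id) from err
    return SplenicMetrics(
        peak_frame_stress=peak_myocardial_frame(my_st),
        peak_frame_rest=peak_myocardial_frame(my_re),
        si_stress_rest_spleen=ratio_sr,
        si_spleen_myocardium_stress=ratio_sm,
        ttp_stress_s=time_to_peak(sp_st),
        upslope_stress=upslope(sp_st),
    )
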