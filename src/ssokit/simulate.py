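"""Synthetic cohort generator for splenic switch-off analysis.

Generates per-patient first-pass enhancement curves (spleen, remote
myocardium, LV blood pool; stress and rest), hemodynamics, visual reads and
ground-truth labels with the statistical structure the downstream analysis
assumes:

* under adequate vasodilator stress the splenic stress amplitude is a small
  fraction (``gamma_splenic``) of the rest amplitude — the switch-off;
* CAD prevalence and stress-adequacy prevalence are configurable, with
  defaults anchored to a multicenter FFR-referenced cohort (58% pathological
  FFR, 73% switch-off prevalence);
* false-negative CMR reads are enriched under inadequate stress.

Within a patient, the stress and rest curves of each tissue share bolus
timing and shape and differ only in amplitude, so with zero noise the
measured splenic stress/rest SI ratio recovers ``gamma_splenic`` exactly.
Each patient draws from an independent substream spawned from the root seed
by patient counter, making cohort content independent of iteration order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .curves import GammaVariateParams, PerfusionSeries, gamma_variate_curve

__all__ = [
    "SimulationConfig",
    "PatientRecord",
    "simulate_patient",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "CohortFormatError",
]

_FLOAT_FMT = "%.17g"  # round-trippable for float64


class CohortFormatError(ValueError):
    """Raised when cohort files violate the CSV/JSON schemas."""


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Prevalences and hemodynamic normals default to the printed cohort
    statistics of the reference study population (pathological FFR in 58%,
    switch-off in 73%, rest HR 66+/-12 bpm rising to 82+/-15 bpm under
    adenosine).  Splenic amplitude fractions, reader error rates and noise
    have no published distributions and are calibration choices; all are
    exposed here.
    """

    n_patients: int = 179
    cad_prevalence: float = 0.58
    adequacy_prevalence: float = 0.73
    gamma_adequate_range: tuple[float, float] = (0.05, 0.30)
    gamma_inadequate_range: tuple[float, float] = (0.50, 1.10)
    reader_miss_prob: float = 0.05
    reader_miss_prob_inadequate: float = 0.50
    false_positive_prob: float = 0.0
    visual_sso_error_prob: float = 0.05
    visual_sso_stress_error_prob: float = 0.15
    noise_sd: float = 2.0
    n_frames: int = 40
    frame_interval_s: float = 1.0
    n_baseline_frames: int = 3
    hr_rest_mean_sd: tuple[float, float] = (66.0, 12.0)
    hr_stress_delta_adequate_mean_sd: tuple[float, float] = (16.0, 8.0)
    hr_stress_delta_inadequate_mean_sd: tuple[float, float] = (4.0, 4.0)
    sbp_rest_mean_sd: tuple[float, float] = (129.0, 21.0)
    sbp_stress_delta_adequate_mean_sd: tuple[float, float] = (-4.0, 10.0)
    sbp_stress_delta_inadequate_mean_sd: tuple[float, float] = (3.0, 8.0)
    dbp_rest_mean_sd: tuple[float, float] = (73.0, 10.0)
    dbp_stress_delta_mean_sd: tuple[float, float] = (-2.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("cad_prevalence", "adequacy_prevalence", "reader_miss_prob",
                     "reader_miss_prob_inadequate", "false_positive_prob",
                     "visual_sso_error_prob", "visual_sso_stress_error_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("gamma_adequate_range", "gamma_inadequate_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi):
                raise ValueError(f"{name} must satisfy 0 <= lower <= upper")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (1 <= self.n_baseline_frames < self.n_frames):
            raise ValueError("need 1 <= n_baseline_frames < n_frames")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")

    def to_json(self) -> str:
        d = asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        d = json.loads(text)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise CohortFormatError(f"unknown config keys: {sorted(unknown)}")
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


@dataclass(frozen=True)
class PatientRecord:
    """Ground truth, hemodynamics, reads and ROI curves for one patient."""

    patient_id: str
    cad_ffr_positive: bool
    adequacy_truth: bool
    gamma_splenic: float
    hr_rest: float
    hr_stress: float
    sbp_rest: float
    sbp_stress: float
    dbp_rest: float
    dbp_stress: float
    cmr_read: str  # "positive" | "negative"
    sso_visual: bool
    sso_stress_visual: bool
    curves: Mapping[tuple[str, str], PerfusionSeries] = field(repr=False)

    def __post_init__(self) -> None:
        if self.cmr_read not in ("positive", "negative"):
            raise ValueError(f"cmr_read must be positive|negative, got {self.cmr_read!r}")
        expected = {(c, t) for c in PerfusionSeries.CONDITIONS
                    for t in PerfusionSeries.TISSUES}
        if set(self.curves) != expected:
            raise ValueError(
                f"patient {self.patient_id}: expected six series "
                f"(2 conditions x 3 tissues), got {sorted(self.curves)}"
            )

    def series(self, condition: str, tissue: str) -> PerfusionSeries:
        return self.curves[(condition, tissue)]


def _visual_threshold(config: SimulationConfig) -> float:
    """Midpoint between the upper ends of the two gamma ranges."""
    return 0.5 * (config.gamma_adequate_range[1] + config.gamma_inadequate_range[1])


def _patient_rng(config: SimulationConfig, index: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence([config.seed, index])))


def simulate_patient(config: SimulationConfig, index: int = 0,
                     rng: np.random.Generator | None = None) -> PatientRecord:
    """Draw one synthetic patient.

    ``rng`` defaults to the per-patient substream spawned from
    ``(config.seed, index)``; passing it explicitly allows deterministic
    replay of a single patient.
    """
    if rng is None:
        rng = _patient_rng(config, index)

    cad = bool(rng.random() < config.cad_prevalence)
    adequate = bool(rng.random() < config.adequacy_prevalence)
    lo, hi = (config.gamma_adequate_range if adequate
              else config.gamma_inadequate_range)
    gamma = float(rng.uniform(lo, hi)) if hi > lo else float(lo)

    # Hemodynamics.
    hr_rest = float(rng.normal(*config.hr_rest_mean_sd))
    hr_delta = float(rng.normal(*(config.hr_stress_delta_adequate_mean_sd if adequate
                                  else config.hr_stress_delta_inadequate_mean_sd)))
    sbp_rest = float(rng.normal(*config.sbp_rest_mean_sd))
    sbp_delta = float(rng.normal(*(config.sbp_stress_delta_adequate_mean_sd if adequate
                                   else config.sbp_stress_delta_inadequate_mean_sd)))
    dbp_rest = float(rng.normal(*config.dbp_rest_mean_sd))
    dbp_delta = float(rng.normal(*config.dbp_stress_delta_mean_sd))

    # CMR read: no false positives unless configured; misses enriched under
    # inadequate stress.
    if cad:
        miss_p = config.reader_miss_prob if adequate else config.reader_miss_prob_inadequate
        cmr_read = "negative" if rng.random() < miss_p else "positive"
    else:
        cmr_read = "positive" if rng.random() < config.false_positive_prob else "negative"

    # Visual reads: switch-off is seen when the generated splenic fraction is
    # clearly on the adequate side; each read flips with its own error rate.
    thr = _visual_threshold(config)
    sso_true = gamma <= thr
    sso_visual = sso_true ^ (rng.random() < config.visual_sso_error_prob)
    sso_stress_visual = sso_true ^ (rng.random() < config.visual_sso_stress_error_prob)

    # Bolus kinetics: blood pool arrives first, then spleen, then myocardium.
    # Stress and rest share timing within a tissue; only amplitudes differ.
    times = np.arange(config.n_frames, dtype=float) * config.frame_interval_s
    bp_onset = float(rng.uniform(4.0, 7.0))

    def draw_tissue(onset_extra_lo, onset_extra_hi, scale_lo=1.5, scale_hi=2.5):
        return (bp_onset + float(rng.uniform(onset_extra_lo, onset_extra_hi)),
                float(rng.uniform(2.0, 4.0)),
                float(rng.uniform(scale_lo, scale_hi)))

    spleen_onset, spleen_shape, spleen_scale = draw_tissue(1.0, 3.0)
    myo_onset, myo_shape, myo_scale = draw_tissue(2.0, 4.0)

    spleen_baseline = float(rng.uniform(80.0, 120.0))
    spleen_rest_amp = float(rng.uniform(50.0, 90.0))
    myo_baseline = float(rng.uniform(60.0, 100.0))
    myo_rest_amp = float(rng.uniform(25.0, 45.0))
    myo_hyperemia = float(rng.uniform(1.3, 2.0))
    bpool_baseline = float(rng.uniform(60.0, 100.0))
    bpool_amp = float(rng.uniform(150.0, 250.0))
    bpool_shape = float(rng.uniform(2.0, 4.0))
    bpool_scale = float(rng.uniform(1.0, 2.0))

    kinetics = {
        ("rest", "spleen"): GammaVariateParams(spleen_baseline, spleen_rest_amp,
                                               spleen_onset, spleen_shape, spleen_scale),
        ("stress", "spleen"): GammaVariateParams(spleen_baseline, gamma * spleen_rest_amp,
                                                 spleen_onset, spleen_shape, spleen_scale),
        ("rest", "myocardium"): GammaVariateParams(myo_baseline, myo_rest_amp,
                                                   myo_onset, myo_shape, myo_scale),
        ("stress", "myocardium"): GammaVariateParams(myo_baseline, myo_rest_amp * myo_hyperemia,
                                                     myo_onset, myo_shape, myo_scale),
        ("rest", "blood_pool"): GammaVariateParams(bpool_baseline, bpool_amp,
                                                   bp_onset, bpool_shape, bpool_scale),
        ("stress", "blood_pool"): GammaVariateParams(bpool_baseline, bpool_amp,
                                                     bp_onset, bpool_shape, bpool_scale),
    }
    curves = {}
    for key, params in kinetics.items():
        si = gamma_variate_curve(params, times)
        if config.noise_sd > 0:
            si = si + rng.normal(0.0, config.noise_sd, size=si.shape)
        curves[key] = PerfusionSeries(key[1], key[0], times, si,
                                      config.n_baseline_frames)

    return PatientRecord(
        patient_id=f"P{index:04d}",
        cad_ffr_positive=cad,
        adequacy_truth=adequate,
        gamma_splenic=gamma,
        hr_rest=hr_rest,
        hr_stress=hr_rest + hr_delta,
        sbp_rest=sbp_rest,
        sbp_stress=sbp_rest + sbp_delta,
        dbp_rest=dbp_rest,
        dbp_stress=dbp_rest + dbp_delta,
        cmr_read=cmr_read,
        sso_visual=bool(sso_visual),
        sso_stress_visual=bool(sso_stress_visual),
        curves=curves,
    )


def simulate_cohort(config: SimulationConfig) -> list[PatientRecord]:
    """Draw ``config.n_patients`` independent patients."""
    return [simulate_patient(config, i) for i in range(config.n_patients)]


# ---------------------------------------------------------------------------
# Cohort I/O: patients.csv + curves.csv + config.json


_PATIENT_COLUMNS = [
    "patient_id", "cad_ffr_positive", "adequacy_truth", "gamma_splenic",
    "hr_rest", "hr_stress", "sbp_rest", "sbp_stress", "dbp_rest", "dbp_stress",
    "cmr_read", "sso_visual", "sso_stress_visual",
]
_CURVE_COLUMNS = ["patient_id", "condition", "tissue", "frame_index", "time_s", "si"]


def write_cohort(cohort: list[PatientRecord], directory: str | Path,
                 config: SimulationConfig | None = None) -> dict[str, Path]:
    """Write patients.csv, curves.csv and (if given) config.json.

    Floats are serialized with 17 significant digits so the round trip is
    exact; output is deterministic byte-for-byte for a fixed cohort.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    patients = pd.DataFrame([
        {
            "patient_id": r.patient_id,
            "cad_ffr_positive": int(r.cad_ffr_positive),
            "adequacy_truth": int(r.adequacy_truth),
            "gamma_splenic": r.gamma_splenic,
            "hr_rest": r.hr_rest, "hr_stress": r.hr_stress,
            "sbp_rest": r.sbp_rest, "sbp_stress": r.sbp_stress,
            "dbp_rest": r.dbp_rest, "dbp_stress": r.dbp_stress,
            "cmr_read": r.cmr_read,
            "sso_visual": int(r.sso_visual),
            "sso_stress_visual": int(r.sso_stress_visual),
        }
        for r in cohort
    ], columns=_PATIENT_COLUMNS)

    curve_rows = []
    for r in cohort:
        for (condition, tissue), s in sorted(r.curves.items()):
            for i, (t, v) in enumerate(zip(s.times, s.si)):
                curve_rows.append((r.patient_id, condition, tissue, i, t, v))
    curves = pd.DataFrame(curve_rows, columns=_CURVE_COLUMNS)

    paths = {"patients": directory / "patients.csv",
             "curves": directory / "curves.csv"}
    patients.to_csv(paths["patients"], index=False, float_format=_FLOAT_FMT)
    curves.to_csv(paths["curves"], index=False, float_format=_FLOAT_FMT)
    if config is not None:
        paths["config"] = directory / "config.json"
        paths["config"].write_text(config.to_json() + "\n")
    return paths


def _require_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{name}: missing columns {missing}")


def read_cohort(directory: str | Path,
                n_baseline_frames: int | None = None
                ) -> tuple[list[PatientRecord], SimulationConfig | None]:
    """Read a cohort written by :func:`write_cohort`.

    Returns ``(cohort, config)``; ``config`` is None when no config.json is
    present, in which case ``n_baseline_frames`` must be supplied (it is not
    part of the CSV schemas).
    """
    directory = Path(directory)
    ppath = directory / "patients.csv"
    cpath = directory / "curves.csv"
    if not ppath.exists() or not cpath.exists():
        raise CohortFormatError(f"no cohort found in {directory}")

    config = None
    cfg_path = directory / "config.json"
    if cfg_path.exists():
        config = SimulationConfig.from_json(cfg_path.read_text())
    if n_baseline_frames is None:
        if config is None:
            raise CohortFormatError(
                "no config.json in directory; pass n_baseline_frames explicitly")
        n_baseline_frames = config.n_baseline_frames

    patients = pd.read_csv(ppath, dtype={"patient_id": str},
                           float_precision="round_trip")
    _require_columns(patients, _PATIENT_COLUMNS, "patients.csv")
    dup = patients["patient_id"][patients["patient_id"].duplicated()]
    if not dup.empty:
        raise CohortFormatError(f"patients.csv: duplicate patient_id {dup.iloc[0]!r}")

    curves = pd.read_csv(cpath, dtype={"patient_id": str},
                         float_precision="round_trip")
    _require_columns(curves, _CURVE_COLUMNS, "curves.csv")

    cohort = []
    curve_groups = dict(tuple(curves.groupby("patient_id", sort=False)))
    for _, row in patients.iterrows():
        pid = row["patient_id"]
        if pid not in curve_groups:
            raise CohortFormatError(f"curves.csv: no curves for patient {pid}")
        series = {}
        for (condition, tissue), g in curve_groups[pid].groupby(
                ["condition", "tissue"], sort=False):
            g = g.sort_values("frame_index")
            idx = g["frame_index"].to_numpy()
            if not np.array_equal(idx, np.arange(len(idx))):
                raise CohortFormatError(
                    f"curves.csv: non-contiguous frame_index for patient {pid}, "
                    f"{condition}/{tissue}")
            t = g["time_s"].to_numpy(dtype=float)
            if t.size > 1 and np.any(np.diff(t) <= 0):
                raise CohortFormatError(
                    f"curves.csv: non-monotone time_s for patient {pid}, "
                    f"{condition}/{tissue}")
            series[(condition, tissue)] = PerfusionSeries(
                tissue, condition, t, g["si"].to_numpy(dtype=float),
                n_baseline_frames)
        cohort.append(PatientRecord(
            patient_id=pid,
            cad_ffr_positive=bool(row["cad_ffr_positive"]),
            adequacy_truth=bool(row["adequacy_truth"]),
            gamma_splenic=float(row["gamma_splenic"]),
            hr_rest=float(row["hr_rest"]), hr_stress=float(row["hr_stress"]),
            sbp_rest=float(row["sbp_rest"]), sbp_stress=float(row["sbp_stress"]),
            dbp_rest=float(row["dbp_rest"]), dbp_stress=float(row["dbp_stress"]),
            cmr_read=str(row["cmr_read"]),
            sso_visual=bool(row["sso_visual"]),
            sso_stress_visual=bool(row["sso_stress_visual"]),
            curves=series,
        ))
    return cohort, config
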