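"""First-pass contrast enhancement curves.

A normalized gamma-variate describes the signal-intensity (SI) time course
of a contrast bolus transiting a tissue of interest: flat at the pre-contrast
baseline until bolus arrival, then a skewed enhancement peak that decays back
toward baseline.  The parameterisation used here is normalized so that the
maximum enhancement above baseline equals ``amplitude`` exactly, which makes
peak amplitude an explicit, recoverable quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GammaVariateParams:
    """Parameters of a normalized gamma-variate enhancement curve.

    Attributes
    ----------
    baseline_si : float
        Pre-contrast signal intensity (a.u.), >= 0.
    amplitude : float
        Peak enhancement above baseline (a.u.), >= 0.
    onset_s : float
        Bolus arrival time (s), >= 0.
    shape : float
        Dimensionless shape exponent, > 0.
    scale_s : float
        Decay time scale (s), > 0.  The peak sits at
        ``onset_s + shape * scale_s``.
    """

    baseline_si: float
    amplitude: float
    onset_s: float
    shape: float
    scale_s: float

    def __post_init__(self) -> None:
        vals = (self.baseline_si, self.amplitude, self.onset_s,
                self.shape, self.scale_s)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite gamma-variate parameter in {vals}")
        if self.baseline_si < 0:
            raise ValueError(f"baseline_si must be >= 0, got {self.baseline_si}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if self.onset_s < 0:
            raise ValueError(f"onset_s must be >= 0, got {self.onset_s}")
        if self.shape <= 0:
            raise ValueError(f"shape must be > 0, got {self.shape}")
        if self.scale_s <= 0:
            raise ValueError(f"scale_s must be > 0, got {self.scale_s}")

    @property
    def peak_time_s(self) -> float:
        """Time of maximum SI: ``onset_s + shape * scale_s``."""
        return self.onset_s + self.shape * self.scale_s


def gamma_variate_curve(params: GammaVariateParams, times: np.ndarray) -> np.ndarray:
    """Evaluate a normalized gamma-variate enhancement curve.

    For t <= onset the curve sits at ``baseline_si``.  For t > onset,

        SI(t) = baseline + amplitude * (dt/tp)**shape * exp(shape * (1 - dt/tp))

    with ``dt = t - onset_s`` and ``tp = shape * scale_s`` (the peak offset),
    so the maximum above baseline equals ``amplitude`` exactly, attained at
    ``onset_s + shape * scale_s``.

    Parameters
    ----------
    params : GammaVariateParams
    times : array of float
        Sample times (s); nonnegative and strictly increasing.

    Returns
    -------
    numpy.ndarray of SI values (a.u.), same length as `times`.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a nonempty 1-D array")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    dt = t - params.onset_s
    tp = params.shape * params.scale_s
    si = np.full_like(t, params.baseline_si)
    rising = dt > 0
    x = dt[rising] / tp
    si[rising] = params.baseline_si + params.amplitude * (
        x**params.shape * np.exp(params.shape * (1.0 - x))
    )
    return si


@dataclass(frozen=True)
class PerfusionSeries:
    """One tissue's SI time course for one condition (stress or rest).

    The first ``n_baseline_frames`` frames are pre-contrast dynamics; their
    mean defines the baseline SI subtracted during normalization.
    """

    tissue: str
    condition: str
    times: np.ndarray
    si: np.ndarray
    n_baseline_frames: int

    TISSUES = ("spleen", "myocardium", "blood_pool")
    CONDITIONS = ("stress", "rest")

    def __post_init__(self) -> None:
        if self.tissue not in self.TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.condition not in self.CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        times = np.asarray(self.times, dtype=float)
        si = np.asarray(self.si, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "si", si)
        if times.ndim != 1 or si.shape != times.shape:
            raise ValueError("times and si must be 1-D arrays of equal length")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (1 <= self.n_baseline_frames < times.size):
            raise ValueError(
                f"n_baseline_frames must be in [1, {times.size - 1}], "
                f"got {self.n_baseline_frames}"
            )

    def __len__(self) -> int:
        return int(self.times.size)

    def shifted(self, c: float) -> "PerfusionSeries":
        """Return a copy with a constant added to every frame."""
        return PerfusionSeries(self.tissue, self.condition, self.times,
                               self.si + c, self.n_baseline_frames)

    def scaled(self, k: float) -> "PerfusionSeries":
        """Return a copy with every frame multiplied by ``k``."""
        return PerfusionSeries(self.tissue, self.condition, self.times,
                               self.si * k, self.n_baseline_frames)
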