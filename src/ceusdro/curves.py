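"""Operational definitions of the perfusion parameters on an enhancement curve.

The same routine measures both the imposed ground-truth curve of the virtual
phantom and the fitted curve recovered from a measured time-intensity curve
(TIC), so that relative errors between the two isolate the acquisition chain
rather than differences in the parameter definitions.

Conventions (all on the baseline-subtracted enhancement curve):

* **MI** — maximum intensity: peak value above baseline.
* **TTP** — time to peak, measured from acquisition start.
* **MTT** — full width at half maximum (FWHM) of the enhancement peak, the
  operational mean-transit-time surrogate used across perfusion modalities.
* **AUC** — trapezoidal integral from bolus onset to the end of washout, where
  washout ends when the post-peak slope magnitude falls to (numerically) zero.
* **upslope** = MI / (TTP − onset), **downslope** = MI / (washout_end − TTP),
  **perfusion index** = AUC / MTT.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import InputError

__all__ = ["CurveRules", "PerfusionResult", "curve_parameters", "robust_noise_sd"]


@dataclass(frozen=True)
class CurveRules:
    """Numerical tolerances for the operational parameter definitions.

    onset_frac
        Bolus onset on a noiseless model curve: first time the enhancement
        exceeds this fraction of MI.
    slope_tol_frac
        Washout end: first post-peak time (after the curve has dropped below
        half maximum) where |d(enhancement)/dt| < slope_tol_frac * MI per
        second.  A strict slope of zero is only reached asymptotically.
    smooth_window
        Moving-average window (samples) applied to raw TICs before slope and
        onset detection.  1 disables smoothing.
    onset_noise_k
        Onset threshold on raw TICs: baseline + k * (robust noise SD).
    """

    onset_frac: float = 0.01
    slope_tol_frac: float = 0.005
    smooth_window: int = 5
    onset_noise_k: float = 3.0


@dataclass(frozen=True)
class PerfusionResult:
    """Perfusion parameters extracted from an enhancement curve.

    Intensities are in whatever units the curve carries (normalized echo power
    for linearised analysis, grey levels for compressed-scale analysis); times
    are in seconds from acquisition start.
    """

    mtt: float
    auc: float
    mi: float
    ttp: float
    upslope: float
    downslope: float
    perfusion_index: float
    onset_time: float
    washout_end: float
    flags: tuple[str, ...] = ()
    notes: dict[str, Any] = field(default_factory=dict)

    def as_dict(self) -> dict[str, Any]:
        return {
            "mtt_s": self.mtt,
            "auc": self.auc,
            "mi": self.mi,
            "ttp_s": self.ttp,
            "upslope_per_s": self.upslope,
            "downslope_per_s": self.downslope,
            "perfusion_index_per_s": self.perfusion_index,
            "onset_time_s": self.onset_time,
            "washout_end_s": self.washout_end,
            "flags": list(self.flags),
        }


def robust_noise_sd(values: np.ndarray) -> float:
    """Noise SD estimate from first differences, insensitive to the bolus trend.

    For white Gaussian noise, median(|diff|) = 2 * Phi^-1(3/4) * sigma / sqrt(2)
    up to the factor sqrt(2) from differencing.
    """
    d = np.diff(np.asarray(values, dtype=float))
    if d.size == 0:
        return 0.0
    return float(np.median(np.abs(d)) / (0.6744897501960817 * np.sqrt(2.0)))


def _interp_crossing(t0, y0, t1, y1, level):
    """Time where the segment (t0,y0)-(t1,y1) crosses ``level``."""
    if y1 == y0:
        return t0
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def curve_parameters(
    times: np.ndarray,
    values: np.ndarray,
    baseline: float,
    rules: CurveRules | None = None,
    *,
    peak_time: float | None = None,
    peak_value: float | None = None,
) -> PerfusionResult:
    """Measure MTT, AUC, MI, TTP (and slopes) on a sampled enhancement curve.

    ``values`` includes the baseline; all parameters are computed on
    ``values - baseline``.  ``peak_time``/``peak_value`` may supply an exact
    (e.g. closed-form) peak to remove grid-resolution error from TTP and MI.
    """
    rules = rules or CurveRules()
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != y.shape or t.size < 5:
        raise InputError("curve must be 1-D with at least 5 samples")
    if np.any(np.diff(t) <= 0):
        raise InputError("times must be strictly increasing")

    work = y - float(baseline)
    flags: list[str] = []

    ipk = int(np.argmax(work))
    mi = float(work[ipk]) if peak_value is None else float(peak_value)
    ttp = float(t[ipk]) if peak_time is None else float(peak_time)
    if mi <= 0:
        raise InputError("curve has no enhancement above baseline")
    if ipk in (0, t.size - 1):
        flags.append("truncated")

    # --- onset: last upward crossing of onset_frac * MI before the peak
    thr = rules.onset_frac * mi
    pre = np.nonzero(work[:ipk] < thr)[0]
    if pre.size:
        i = int(pre[-1])
        onset = _interp_crossing(t[i], work[i], t[i + 1], work[i + 1], thr)
    else:
        onset = float(t[0])
        flags.append("onset-at-start")

    # --- FWHM (MTT): half-maximum crossings on each side of the peak
    half = 0.5 * mi
    left = np.nonzero(work[: ipk + 1] < half)[0]
    right = np.nonzero(work[ipk:] < half)[0]
    if left.size:
        i = int(left[-1])
        t_left = _interp_crossing(t[i], work[i], t[i + 1], work[i + 1], half)
    else:
        t_left = float(t[0])
        flags.append("fwhm-left-missing")
    if right.size:
        j = ipk + int(right[0])
        t_right = _interp_crossing(t[j - 1], work[j - 1], t[j], work[j], half)
    else:
        t_right = float(t[-1])
        flags.append("fwhm-right-missing")
    mtt = t_right - t_left

    # --- washout end: post-half-max point where the slope flattens out
    slope = np.gradient(work, t)
    tol = rules.slope_tol_frac * mi
    past_half = np.nonzero(work[ipk:] < half)[0]
    j0 = ipk + int(past_half[0]) if past_half.size else min(ipk + 1, t.size - 1)
    flat = np.nonzero(np.abs(slope[j0:]) < tol)[0]
    if flat.size:
        washout_end = float(t[j0 + int(flat[0])])
    else:
        washout_end = float(t[-1])
        flags.append("truncated")

    # --- AUC: trapezoid of the enhancement from onset to washout end
    lo, hi = onset, washout_end
    inner = (t > lo) & (t < hi)
    tt = np.concatenate(([lo], t[inner], [hi]))
    yy = np.concatenate(([np.interp(lo, t, work)], work[inner], [np.interp(hi, t, work)]))
    auc = float(np.trapezoid(yy, tt))

    upslope = mi / (ttp - onset) if ttp > onset else float("nan")
    downslope = mi / (washout_end - ttp) if washout_end > ttp else float("nan")
    pi = auc / mtt if mtt > 0 else float("nan")

    return PerfusionResult(
        mtt=float(mtt),
        auc=auc,
        mi=mi,
        ttp=ttp,
        upslope=float(upslope),
        downslope=float(downslope),
        perfusion_index=float(pi),
        onset_time=float(onset),
        washout_end=washout_end,
        flags=tuple(flags),
    )
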