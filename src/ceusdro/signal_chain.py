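"""Echo-signal model, receive gain, log-compression and linearisation.

The measurement chain of a conventional scanner is modelled in three stages:

1. **A-line echo model** — the received voltage envelope is the magnitude of
   the depth integral of reflectivity, weighted by the round-trip pulse
   envelope, frequency-dependent attenuation and the carrier phase:

       v(t) = | k * integral R(z) a(t - 2z/c) e^{-2 z alpha(f0)}
                e^{i w0 (t - 2z/c)} dz |

   This full 1-D integral is the validation path; frame synthesis uses the
   factorised per-depth weight of :func:`depth_gain_profile` (same attenuation
   and frequency physics, desk-scale runtime).

2. **Log-compression** to 8-bit grey levels over a dynamic-range window of
   ``lc_dr`` dB below the maximum amplitude ``v_max`` (= 2**15 - 1, the
   largest positive signed 16-bit value):

       QL(V) = clip round( 255 * (20/lc_dr) * log10( (V/v_max) * 10^{lc_dr/20} ) )

   Amplitudes below v_max * 10^{-lc_dr/20} map to 0 and amplitudes above
   v_max saturate at 255 — the mechanism by which a poor dynamic-range choice
   destroys time-intensity-curve information.

3. **Linearisation** back to echo power, the exact inverse of (2) before
   quantization:

       EP(QL) = ( v_max * 10^{(QL/255 - 1) * lc_dr/20} )**2

Receive gain acts multiplicatively on echo amplitude before compression
(``V -> V * 10^{gain_db/20}``).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, ParameterDomainError

__all__ = [
    "SignalModelConfig",
    "CompressionConfig",
    "aline_voltage",
    "depth_gain_profile",
    "apply_gain",
    "log_compress",
    "quantize_grey",
    "linearize",
    "attenuation_neper_per_m",
]

#: dB per neper (20 / ln 10)
DB_PER_NEPER = 20.0 / np.log(10.0)

#: reference transmit frequency at which the simulator chain is calibrated (MHz)
REFERENCE_FREQUENCY_MHZ = 1.5


@dataclass(frozen=True)
class SignalModelConfig:
    """Physical configuration of the transmit/receive model.

    Defaults are standard soft-tissue values: c = 1540 m/s, attenuation slope
    0.5 dB/cm/MHz, Gaussian pulse with 60% fractional bandwidth.  The
    transmit pressure scales as mechanical_index * sqrt(f0), reflecting the
    mechanical index's inverse-square-root frequency definition.
    """

    k: float = 1.0
    c: float = 1540.0
    f0_mhz: float = 1.5
    alpha0_db_cm_mhz: float = 0.5
    fractional_bandwidth: float = 0.6
    focus_depth_m: float = 0.045
    beam_sigma_m: float = 0.02
    mechanical_index: float = 0.08

    def __post_init__(self):
        if self.c <= 0 or self.f0_mhz <= 0:
            raise ParameterDomainError("c and f0 must be > 0")
        if self.alpha0_db_cm_mhz < 0 or self.mechanical_index < 0:
            raise ParameterDomainError("alpha0 and mechanical index must be >= 0")

    @property
    def w0(self) -> float:
        """Angular carrier frequency (rad/s)."""
        return 2.0 * np.pi * self.f0_mhz * 1e6

    @property
    def transmit_pressure(self) -> float:
        """Relative transmit pressure p = MI * sqrt(f0)."""
        return self.mechanical_index * np.sqrt(self.f0_mhz)


@dataclass(frozen=True)
class CompressionConfig:
    """Log-compression window: dynamic range (dB), max amplitude, receive gain."""

    lc_dr_db: float = 60.0
    v_max: float = float(2**15 - 1)
    gain_db: float = 0.0

    def __post_init__(self):
        if self.lc_dr_db <= 0 or self.v_max <= 0:
            raise ParameterDomainError("dynamic range and v_max must be > 0")


def attenuation_neper_per_m(cfg: SignalModelConfig) -> float:
    """Amplitude attenuation coefficient alpha(f0) in nepers per metre."""
    db_per_m = cfg.alpha0_db_cm_mhz * cfg.f0_mhz * 100.0
    return db_per_m / DB_PER_NEPER


def _pulse_envelope(tau: np.ndarray, cfg: SignalModelConfig) -> np.ndarray:
    # Gaussian pulse whose -6 dB spectral full width equals
    # fractional_bandwidth * f0:  sigma_t = sqrt(2 ln 2) / (pi * bw * f0)
    f0 = cfg.f0_mhz * 1e6
    sigma_t = np.sqrt(2.0 * np.log(2.0)) / (np.pi * cfg.fractional_bandwidth * f0)
    return np.exp(-0.5 * (tau / sigma_t) ** 2)


def aline_voltage(t, depths: np.ndarray, reflectivity: np.ndarray, cfg: SignalModelConfig):
    """Discretised A-line echo envelope at times ``t`` (trapezoidal in depth).

    ``reflectivity`` R(z) is sampled on the uniform ``depths`` grid (metres).
    Returns the non-negative complex-magnitude envelope; linear in R and in k.
    """
    z = np.asarray(depths, dtype=float)
    r = np.asarray(reflectivity, dtype=float)
    if z.size == 0 or r.size == 0:
        raise InputError("reflectivity profile must be non-empty")
    if z.shape != r.shape:
        raise InputError("depths and reflectivity must have matching shapes")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    alpha = attenuation_neper_per_m(cfg)
    tau = t_arr[:, None] - 2.0 * z[None, :] / cfg.c  # (nt, nz)
    integrand = (
        r[None, :]
        * _pulse_envelope(tau, cfg)
        * np.exp(-2.0 * z[None, :] * alpha)
        * np.exp(1j * cfg.w0 * tau)
    )
    v = np.abs(cfg.k * np.trapezoid(integrand, z, axis=1))
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(v[0])
    return v


def depth_gain_profile(depths, cfg: SignalModelConfig, include_focus: bool = True):
    """Per-depth amplitude factor e^{-2 z alpha(f0)} * beam(z).

    ``beam(z)`` is a Gaussian axial focus profile centred at the focus depth
    (disabled with ``include_focus=False``, leaving the pure attenuation term,
    monotone decreasing in depth).  Values lie in (0, 1].
    """
    z = np.asarray(depths, dtype=float)
    if np.any(z < 0):
        raise InputError("depths must be >= 0")
    alpha = attenuation_neper_per_m(cfg)
    factor = np.exp(-2.0 * z * alpha)
    if include_focus:
        factor = factor * np.exp(-0.5 * ((z - cfg.focus_depth_m) / cfg.beam_sigma_m) ** 2)
    return factor if z.ndim else float(factor)


def apply_gain(v, gain_db: float):
    """Receive gain: multiply echo amplitude by 10^{gain_db/20}."""
    return np.asarray(v, dtype=float) * 10.0 ** (gain_db / 20.0) if np.ndim(v) else float(v) * 10.0 ** (gain_db / 20.0)


def _grey_continuous(v: np.ndarray, cfg: CompressionConfig) -> np.ndarray:
    with np.errstate(divide="ignore"):
        rel = np.log10(np.asarray(v, dtype=float) / cfg.v_max)
    return 255.0 * (1.0 + (20.0 / cfg.lc_dr_db) * rel)


def quantize_grey(grey) -> np.ndarray:
    """Saturating 8-bit quantization: round half up, clip to [0, 255]."""
    g = np.floor(np.asarray(grey, dtype=float) + 0.5)
    return np.clip(g, 0.0, 255.0).astype(np.uint8)


def log_compress(v, cfg: CompressionConfig, quantize: bool = True):
    """Log-compress echo amplitude to grey level(s).

    With ``quantize=False`` the continuous (un-rounded, un-clipped) grey value
    is returned, which the phantom uses to inject grey-domain noise before a
    single final quantization.
    """
    v_arr = np.asarray(v, dtype=float)
    if np.any(v_arr < 0):
        raise InputError("echo amplitude must be >= 0")
    grey = _grey_continuous(v_arr, cfg)
    if not quantize:
        return grey if np.ndim(v) else float(grey)
    q = quantize_grey(grey)
    if np.isscalar(v) or np.ndim(v) == 0:
        return int(q)
    return q


def linearize(ql, cfg: CompressionConfig):
    """Invert log-compression: grey level -> echo power (v_max^2 at grey 255)."""
    q = np.asarray(ql, dtype=float)
    if np.any(q < 0) or np.any(q > 255):
        raise InputError("grey level must lie in [0, 255]")
    ep = (cfg.v_max * 10.0 ** ((q / 255.0 - 1.0) * cfg.lc_dr_db / 20.0)) ** 2
    if np.isscalar(ql) or np.ndim(ql) == 0:
        return float(ep)
    return ep
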