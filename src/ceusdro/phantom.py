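"""Digital reference object: a synthetic perfusion video with known truth.

The phantom is a timestamped 8-bit greyscale frame sequence showing a
microbubble bolus transiting a straight horizontal vessel embedded in uniform
tissue.  The imposed (ground-truth) perfusion parameters are computed from the
bolus kinetics alone, upstream of the measurement chain, so they are
independent of the acquisition settings — exactly what a sensitivity sweep
needs.

Signal model per pixel (row = depth z, column = lateral position):

* echo **power** = tissue_power + contrast_scale * C(t - delay(rho)) inside
  the vessel, tissue_power outside.  Linearity of intensity (linearised echo
  power) in contrast concentration is the core assumption of TIC-based
  quantification.
* a parabolic (Poiseuille) velocity profile v(rho) = v_peak (1 - (rho/r)^2)
  disperses arrival times across the lumen:
  delay(rho) = transit_time * (1/v_norm(rho) - 1), with the normalised
  velocity floored to keep the wall delay finite.
* echo amplitude = sqrt(power), weighted by the depth/frequency/focus factor
  of the signal chain, normalised to 1 at the vessel depth for the reference
  1.5 MHz acquisition (the simulator's calibration point).
* receive gain is applied, the amplitude is log-compressed, Gaussian noise is
  injected (grey-level domain by default, amplitude domain optionally) and the
  frame is quantized to 8 bits.

Everything is deterministic given the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .curves import CurveRules, PerfusionResult
from .errors import InputError, ParameterDomainError
from .ldrw import LDRWParams, ldrw_concentration, ldrw_truth_parameters
from .signal_chain import (
    REFERENCE_FREQUENCY_MHZ,
    CompressionConfig,
    SignalModelConfig,
    apply_gain,
    depth_gain_profile,
    log_compress,
    quantize_grey,
)

__all__ = [
    "VesselGeometry",
    "PhantomSpec",
    "AcquisitionSettings",
    "FrameStack",
    "synthesize",
    "make_fixture",
    "vessel_roi_mask",
]


@dataclass(frozen=True)
class AcquisitionSettings:
    """The scanner knobs varied in the sensitivity experiments."""

    gain_db: float = 15.0
    dynamic_range_db: float = 60.0
    frequency_mhz: float = 1.5
    mechanical_index: float = 0.08
    focus_depth_m: float = 0.045
    frame_rate_hz: float | None = None  # None: use the phantom's frame rate

    def compression(self) -> CompressionConfig:
        return CompressionConfig(lc_dr_db=self.dynamic_range_db, gain_db=self.gain_db)

    def signal_model(self) -> SignalModelConfig:
        return SignalModelConfig(
            f0_mhz=self.frequency_mhz,
            mechanical_index=self.mechanical_index,
            focus_depth_m=self.focus_depth_m,
        )

    def as_dict(self) -> dict[str, Any]:
        return {
            "gain_db": self.gain_db,
            "dynamic_range_db": self.dynamic_range_db,
            "frequency_mhz": self.frequency_mhz,
            "mechanical_index": self.mechanical_index,
            "focus_depth_m": self.focus_depth_m,
            "frame_rate_hz": self.frame_rate_hz,
        }


@dataclass(frozen=True)
class VesselGeometry:
    """Single straight horizontal vessel (rows map to depth).

    ``transit_time_s`` is the centre-streamline travel time from the vessel
    inlet used to convert the parabolic velocity deficit into an arrival
    delay; ``velocity_floor`` bounds the near-wall slowdown.
    """

    center_depth_m: float = 0.029
    radius_m: float = 0.002
    transit_time_s: float = 0.5
    velocity_floor: float = 0.1


@dataclass(frozen=True)
class PhantomSpec:
    """Phantom geometry, bolus kinetics and noise model.

    Defaults: 200 frames of 512 x 512 pixels at 1 frame/s (covering arterial
    ~35 s and portal ~120 s phases), zero-mean Gaussian noise of variance 0.3
    on the 8-bit grey-level scale, tissue echo power 4e-4 (of v_max^2) and a
    bolus whose peak adds ~50x the tissue power.
    """

    width: int = 512
    height: int = 512
    n_frames: int = 200
    frame_rate_hz: float = 1.0
    pixel_size_m: float = 1e-4
    noise_mean: float = 0.0
    noise_var: float = 0.3
    noise_domain: str = "grey"  # "grey" (8-bit scale) or "amplitude" ([0,1] scale)
    tissue_power: float = 4e-4
    contrast_scale: float = 1.0
    vessel: VesselGeometry = field(default_factory=VesselGeometry)
    bolus: LDRWParams = field(default_factory=LDRWParams)

    def __post_init__(self):
        if self.n_frames < 2:
            raise ParameterDomainError("n_frames must be >= 2")
        if self.noise_var < 0:
            raise ParameterDomainError("noise_var must be >= 0")
        if self.noise_domain not in ("grey", "amplitude"):
            raise ParameterDomainError("noise_domain must be 'grey' or 'amplitude'")
        if self.tissue_power <= 0 or self.contrast_scale < 0:
            raise ParameterDomainError("tissue_power must be > 0 and contrast_scale >= 0")
        depth_span = self.height * self.pixel_size_m
        v = self.vessel
        if v.center_depth_m - v.radius_m <= 0 or v.center_depth_m + v.radius_m >= depth_span:
            raise InputError("vessel does not fit inside the frame")

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass
class FrameStack:
    """Timestamped 8-bit greyscale frame sequence with acquisition provenance."""

    frames: np.ndarray  # (T, H, W) uint8
    timestamps: np.ndarray  # (T,) seconds, strictly increasing
    settings: AcquisitionSettings

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3 or self.frames.dtype != np.uint8:
            raise InputError("frames must be a (T, H, W) uint8 array")
        if len(self.frames) != len(self.timestamps):
            raise InputError("frames and timestamps must have equal length")
        if len(self.timestamps) and np.any(np.diff(self.timestamps) <= 0):
            raise InputError("timestamps must be strictly increasing")

    @property
    def shape(self):
        return self.frames.shape


def _row_depths(spec: PhantomSpec) -> np.ndarray:
    return (np.arange(spec.height) + 0.5) * spec.pixel_size_m


def _depth_weights(spec: PhantomSpec, acq: AcquisitionSettings) -> np.ndarray:
    """Normalised amplitude weight per row: W(z, f) / W(z_vessel, f_ref)."""
    z = _row_depths(spec)
    cfg = acq.signal_model()
    ref = SignalModelConfig(
        f0_mhz=REFERENCE_FREQUENCY_MHZ,
        mechanical_index=acq.mechanical_index,
        focus_depth_m=acq.focus_depth_m,
    )
    w = cfg.transmit_pressure * depth_gain_profile(z, cfg)
    w_ref = ref.transmit_pressure * depth_gain_profile(
        np.array([spec.vessel.center_depth_m]), ref
    )[0]
    return w / w_ref


def _row_delays(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """(vessel row mask, arrival delay per row) from the parabolic profile."""
    z = _row_depths(spec)
    v = spec.vessel
    rho = z - v.center_depth_m
    inside = np.abs(rho) <= v.radius_m
    v_norm = np.clip(1.0 - (rho / v.radius_m) ** 2, v.velocity_floor, 1.0)
    delay = np.where(inside, v.transit_time_s * (1.0 / v_norm - 1.0), 0.0)
    return inside, delay


def ground_truth(spec: PhantomSpec, rules: CurveRules | None = None) -> PerfusionResult | None:
    """Imposed perfusion parameters (centre streamline, normalized power units).

    ``None`` for a bolus-free phantom (``contrast_scale == 0``), which has no
    perfusion parameters to impose.
    """
    if spec.contrast_scale == 0:
        return None
    return ldrw_truth_parameters(spec.bolus, spec.tissue_power, spec.contrast_scale, rules)


def synthesize(
    spec: PhantomSpec,
    acq: AcquisitionSettings | None = None,
    seed: int = 0,
) -> tuple[FrameStack, PerfusionResult]:
    """Render the phantom under given acquisition settings.

    Returns the 8-bit frame stack and the imposed ground truth (which does not
    depend on ``acq`` or ``seed``).  Identical inputs give bit-identical
    stacks.
    """
    acq = acq or AcquisitionSettings()
    frame_rate = acq.frame_rate_hz or spec.frame_rate_hz
    times = np.arange(spec.n_frames) / frame_rate
    inside, delay = _row_delays(spec)
    weights = _depth_weights(spec, acq)
    cfg = acq.compression()

    # (T, H) concentration for vessel rows, zero elsewhere
    conc = np.zeros((spec.n_frames, spec.height))
    rows = np.nonzero(inside)[0]
    if rows.size and spec.contrast_scale > 0:
        tau = np.clip(times[:, None] - delay[rows][None, :], 0.0, None)
        conc[:, rows] = ldrw_concentration(tau.ravel(), spec.bolus).reshape(tau.shape)

    power = spec.tissue_power + spec.contrast_scale * conc  # (T, H)
    amp_rows = np.sqrt(power) * weights[None, :]  # normalized amplitude per row

    rng = np.random.default_rng(seed)
    sd = float(np.sqrt(spec.noise_var))
    frames = np.empty((spec.n_frames, spec.height, spec.width), dtype=np.uint8)
    for i in range(spec.n_frames):
        amp = np.broadcast_to(amp_rows[i][:, None], (spec.height, spec.width))
        if spec.noise_domain == "amplitude" and sd > 0:
            amp = np.clip(amp + rng.normal(spec.noise_mean, sd, amp.shape), 0.0, None)
        v = apply_gain(amp * cfg.v_max, acq.gain_db)
        grey = log_compress(v, cfg, quantize=False)
        if spec.noise_domain == "grey" and sd > 0:
            grey = grey + rng.normal(spec.noise_mean, sd, grey.shape)
        frames[i] = quantize_grey(grey)

    stack = FrameStack(frames=frames, timestamps=times, settings=acq)
    return stack, ground_truth(spec)


_FIXTURE_SCALES = {
    # (width, height, n_frames, frame_rate_hz) — physical extent fixed at 5.12 cm
    "small": (64, 64, 50, 0.25),
    "medium": (128, 128, 200, 1.0),
    "full": (512, 512, 200, 1.0),
}


def fixture_spec(scale: str = "small", **overrides) -> PhantomSpec:
    """PhantomSpec for a named fixture size; bolus timing is size-independent."""
    try:
        w, h, n, fps = _FIXTURE_SCALES[scale]
    except KeyError:
        raise InputError(f"unknown fixture scale {scale!r}; choose from {sorted(_FIXTURE_SCALES)}")
    pixel = 0.0512 / h
    return PhantomSpec(width=w, height=h, n_frames=n, frame_rate_hz=fps,
                       pixel_size_m=pixel, **overrides)


def make_fixture(
    scale: str = "small", seed: int = 0, acq: AcquisitionSettings | None = None, **overrides
) -> tuple[FrameStack, PerfusionResult]:
    """Synthesize a named-size phantom (same pipeline and invariants at any size)."""
    return synthesize(fixture_spec(scale, **overrides), acq, seed)


def vessel_roi_mask(
    spec: PhantomSpec, row_halfwidth_frac: float = 0.5, col_margin_frac: float = 0.1
) -> np.ndarray:
    """Boolean ROI over the central portion of the vessel lumen.

    Rows within ``row_halfwidth_frac`` of the vessel radius around the axis
    (where the parabolic arrival-time dispersion is smallest), columns with a
    lateral margin.
    """
    z = _row_depths(spec)
    rows = np.abs(z - spec.vessel.center_depth_m) <= row_halfwidth_frac * spec.vessel.radius_m
    if not rows.any():
        rows = np.abs(z - spec.vessel.center_depth_m) == np.min(
            np.abs(z - spec.vessel.center_depth_m)
        )
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    c0 = int(spec.width * col_margin_frac)
    c1 = spec.width - c0
    mask[np.nonzero(rows)[0][:, None], np.arange(c0, c1)[None, :]] = True
    return mask


def background_roi_mask(spec: PhantomSpec, size: int = 10) -> np.ndarray:
    """Small tissue-only ROI far from the vessel (top-left corner)."""
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    mask[1 : 1 + size, 1 : 1 + size] = True
    return mask


def with_settings(spec: PhantomSpec, **overrides) -> PhantomSpec:
    """Return a copy of ``spec`` with fields replaced."""
    return replace(spec, **overrides)
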