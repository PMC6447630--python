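"""File I/O: frame stacks (TIFF/AVI), ROI masks (PNG/JSON polygon), configs, results.

Lossless multi-page TIFF is the canonical interchange format; uncompressed
AVI is supported for compatibility with clinical export workflows.  Every
stack written carries a JSON sidecar with the acquisition settings, seed and
(for phantoms) the imposed ground truth, so any artefact can be regenerated.

Coordinates are pixel (row, col), 0-based, origin top-left; rows map to depth.
"""
from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import tifffile
import yaml
from PIL import Image

from . import __version__
from ._avi import read_avi, write_avi
from .curves import PerfusionResult
from .errors import InputError
from .ldrw import LDRWParams
from .phantom import AcquisitionSettings, FrameStack, PhantomSpec, VesselGeometry

__all__ = [
    "read_stack",
    "write_stack",
    "read_roi",
    "write_roi_png",
    "polygon_to_mask",
    "write_results",
    "validate_results",
    "read_results",
    "load_phantom_config",
    "load_acquisition_config",
]

_LUMA = np.array([0.299, 0.587, 0.114])


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(
    stack: FrameStack,
    path,
    *,
    seed: int | None = None,
    truth: PerfusionResult | None = None,
    sidecar: bool = True,
) -> Path:
    """Write a frame stack as multi-page TIFF (.tif/.tiff) or AVI (.avi).

    The JSON sidecar (``<path>.json``) records tool version, settings, seed,
    timestamps and optionally the ground truth.
    """
    path = Path(path)
    fps = 1.0 / float(np.median(np.diff(stack.timestamps))) if len(stack.timestamps) > 1 else 1.0
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, stack.frames, photometric="minisblack")
    elif path.suffix.lower() == ".avi":
        write_avi(path, stack.frames, fps)
    else:
        raise InputError(f"unsupported stack format {path.suffix!r} (use .tif/.tiff/.avi)")
    if sidecar:
        meta: dict[str, Any] = {
            "tool": "ceusdro",
            "version": __version__,
            "settings": stack.settings.as_dict(),
            "seed": seed,
            "frame_rate_hz": fps,
            "timestamps_s": [float(t) for t in stack.timestamps],
        }
        if truth is not None:
            meta["ground_truth"] = truth.as_dict()
        _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_stack(path, frame_rate: float | None = None) -> FrameStack:
    """Read a TIFF or AVI frame stack.

    Timestamps come from the sidecar if present, else from the container
    frame rate; ``frame_rate`` overrides both.  Colour input is converted to
    luminance with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"stack file not found: {path}")
    if path.stat().st_size == 0:
        raise InputError(f"stack file is empty: {path}")
    container_fps = None
    if path.suffix.lower() in (".tif", ".tiff"):
        try:
            frames = tifffile.imread(path)
        except Exception as err:
            raise InputError(f"could not decode TIFF {path}: {err}") from None
    elif path.suffix.lower() == ".avi":
        frames, container_fps = read_avi(path)
    else:
        raise InputError(f"unsupported stack format {path.suffix!r}")
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4 and frames.shape[-1] in (3, 4):
        warnings.warn("colour stack converted to luminance", stacklevel=2)
        frames = np.tensordot(frames[..., :3].astype(float), _LUMA, axes=1)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise InputError(f"{path}: expected a (T, H, W) stack, got shape {frames.shape}")
    if frames.dtype != np.uint8:
        if frames.min() < 0 or frames.max() > 255:
            raise InputError(f"{path}: pixel values outside the 8-bit range")
        frames = np.round(frames).astype(np.uint8)

    settings = AcquisitionSettings()
    timestamps = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "settings" in meta:
            settings = AcquisitionSettings(**meta["settings"])
        if "timestamps_s" in meta:
            timestamps = np.asarray(meta["timestamps_s"], dtype=float)
        container_fps = meta.get("frame_rate_hz", container_fps)
    if frame_rate is not None:
        timestamps = np.arange(len(frames)) / frame_rate
    if timestamps is None or len(timestamps) != len(frames):
        fps = container_fps or 1.0
        timestamps = np.arange(len(frames)) / fps
    return FrameStack(frames=frames, timestamps=timestamps, settings=settings)


def polygon_to_mask(vertices, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise a polygon given as [[row, col], ...] onto a boolean mask.

    A pixel belongs to the mask when its centre lies inside or on the
    boundary of the polygon.
    """
    from matplotlib.path import Path as MplPath

    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise InputError("polygon must be a list of at least 3 [row, col] vertices")
    path = MplPath(verts[:, ::-1])  # (col, row) = (x, y)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    pts = np.column_stack([cc.ravel(), rr.ravel()])
    # test both inflation signs: matplotlib's radius sign depends on orientation
    inside = path.contains_points(pts, radius=0.49) | path.contains_points(pts, radius=-0.49)
    return inside.reshape(shape)


def read_roi(path, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read an ROI mask from PNG (non-zero = inside) or JSON polygon.

    JSON polygons need the target frame ``shape`` to rasterise against.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"ROI file not found: {path}")
    if path.suffix.lower() == ".png":
        arr = np.asarray(Image.open(path).convert("L"))
        return arr > 0
    if path.suffix.lower() == ".json":
        obj = json.loads(path.read_text())
        verts = obj["polygon"] if isinstance(obj, dict) else obj
        if shape is None:
            raise InputError("frame shape required to rasterise a polygon ROI")
        return polygon_to_mask(verts, shape)
    raise InputError(f"unsupported ROI format {path.suffix!r} (use .png or .json)")


def write_roi_png(mask: np.ndarray, path) -> Path:
    path = Path(path)
    Image.fromarray((np.asarray(mask, dtype=bool) * 255).astype(np.uint8), mode="L").save(path)
    return path


_RESULT_REQUIRED = {
    "tool": str,
    "version": str,
    "result": dict,
}
_RESULT_FIELDS = (
    "mtt_s", "auc", "mi", "ttp_s", "upslope_per_s", "downslope_per_s",
    "perfusion_index_per_s", "onset_time_s", "washout_end_s", "flags",
)


def validate_results(obj: dict) -> None:
    """Check a results document against the published schema; raise InputError."""
    problems = []
    for key, typ in _RESULT_REQUIRED.items():
        if key not in obj:
            problems.append(f"missing field {key!r}")
        elif not isinstance(obj[key], typ):
            problems.append(f"field {key!r} must be {typ.__name__}")
    if isinstance(obj.get("result"), dict):
        for f in _RESULT_FIELDS:
            if f not in obj["result"]:
                problems.append(f"missing result field {f!r}")
    if problems:
        raise InputError("invalid results document: " + "; ".join(problems))


def write_results(
    result: PerfusionResult,
    path,
    *,
    settings: AcquisitionSettings | None = None,
    seed: int | None = None,
    csv_path=None,
) -> dict:
    """Write a PerfusionResult as JSON (and optionally a one-row CSV)."""
    doc = {
        "tool": "ceusdro",
        "version": __version__,
        "seed": seed,
        "settings": settings.as_dict() if settings is not None else None,
        "result": result.as_dict(),
    }
    validate_results(doc)
    Path(path).write_text(json.dumps(doc, indent=2))
    if csv_path is not None:
        import pandas as pd

        row = {k: v for k, v in result.as_dict().items() if k != "flags"}
        row["flags"] = ";".join(result.flags)
        pd.DataFrame([row]).to_csv(csv_path, index=False)
    return doc


def read_results(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise InputError(f"results file not found: {path}")
    obj = json.loads(path.read_text())
    validate_results(obj)
    return obj


def load_acquisition_config(cfg: dict) -> AcquisitionSettings:
    known = {k: v for k, v in cfg.items() if v is not None}
    try:
        return AcquisitionSettings(**known)
    except TypeError as err:
        raise InputError(f"bad acquisition config: {err}") from None


def load_phantom_config(cfg: dict) -> PhantomSpec:
    cfg = dict(cfg)
    vessel = VesselGeometry(**cfg.pop("vessel", {}))
    bolus = LDRWParams(**cfg.pop("bolus", {}))
    try:
        return PhantomSpec(vessel=vessel, bolus=bolus, **cfg)
    except TypeError as err:
        raise InputError(f"bad phantom config: {err}") from None


def load_yaml_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    obj = yaml.safe_load(path.read_text())
    if not isinstance(obj, dict):
        raise InputError(f"config {path} must be a mapping")
    return obj
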