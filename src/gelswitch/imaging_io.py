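"""Reading, writing, calibrating and temperature-aligning image sequences.

Frame timing precedence: sidecar CSV (``frames.csv`` with columns
``frame_index,time_s[,temperature_C]``) > constant default acquisition rate
(0.9 frames/s, the camera rate used for the switching videos).
"""
from __future__ import annotations

import glob as _glob
import json
import os
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .datatypes import AlignedSeries, CalibrationResult, FrameSeries, TemperatureProfile
from .errors import AlignmentError, DetectionFailureError, InvalidParameterError

__all__ = [
    "DEFAULT_FPS",
    "load_frames",
    "save_frames",
    "calibrate",
    "align_temperature",
    "read_temperature_log",
    "write_temperature_log",
]

DEFAULT_FPS = 0.9  # frames/s, camera acquisition rate

# ITU-R BT.601 luma weights for grayscale conversion of color input.
_LUMA = np.array([0.299, 0.587, 0.114])


def _to_gray(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        img = img[..., :3] @ _LUMA
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _resolve_sources(source: str) -> list[str]:
    if os.path.isdir(source):
        names = sorted(
            f for f in os.listdir(source)
            if f.lower().endswith((".png", ".tif", ".tiff", ".jpg", ".jpeg"))
        )
        return [os.path.join(source, f) for f in names]
    if any(ch in source for ch in "*?["):
        return sorted(_glob.glob(source))
    return [source]


def load_frames(
    source: str,
    roi: Optional[tuple[int, int, int, int]] = None,
    brightness_offset: float = 0.0,
    fps: float = DEFAULT_FPS,
    pixel_size: float = 1.0,
) -> FrameSeries:
    """Load a frame directory, glob, single image or multi-page TIFF.

    Frames are converted to 8-bit grayscale, cropped to ``roi``
    (``row0, col0, height, width``) and offset in brightness with clipping.
    Times come from a sidecar ``frames.csv`` when present, else from ``fps``.
    """
    paths = _resolve_sources(source)
    if not paths:
        raise IOError(f"no readable images at {source!r}")
    frames: list[np.ndarray] = []
    for p in paths:
        if not os.path.exists(p):
            raise IOError(f"cannot read image file {p!r}")
        if p.lower().endswith((".tif", ".tiff")):
            data = tifffile.imread(p)
            if data.ndim == 2 or (data.ndim == 3 and data.shape[-1] in (3, 4)):
                pages = data[None]  # single frame (possibly color)
            else:
                pages = data  # multi-page stack
            for page in pages:
                frames.append(_to_gray(np.asarray(page, dtype=float)))
        else:
            frames.append(_to_gray(np.asarray(iio.imread(p), dtype=float)))
    shape0 = frames[0].shape
    if any(f.shape != shape0 for f in frames):
        raise InvalidParameterError("all frames must share one shape")
    stack = np.stack(frames)

    if roi is not None:
        r0, c0, hh, ww = roi
        h, w = shape0
        if r0 < 0 or c0 < 0 or hh <= 0 or ww <= 0 or r0 + hh > h or c0 + ww > w:
            raise InvalidParameterError(f"roi {roi} outside frame bounds {shape0}")
        stack = stack[:, r0:r0 + hh, c0:c0 + ww]
    if brightness_offset:
        stack = np.clip(stack.astype(float) + brightness_offset, 0, 255).astype(np.uint8)

    n = len(stack)
    times = np.arange(n) / fps
    meta: dict = {"source": source, "timing": f"constant {fps:g} fps"}
    sidecar = None
    if os.path.isdir(source):
        cand = os.path.join(source, "frames.csv")
        if os.path.exists(cand):
            sidecar = cand
    if sidecar:
        tab = pd.read_csv(sidecar)
        if len(tab) == n and "time_s" in tab.columns:
            times = tab["time_s"].to_numpy(dtype=float)
            meta["timing"] = "sidecar frames.csv"
            if "temperature_C" in tab.columns:
                meta["temperature_C"] = tab["temperature_C"].to_numpy(dtype=float)
        meta_path = os.path.join(source, "meta.json")
        if os.path.exists(meta_path):
            with open(meta_path) as fh:
                extra = json.load(fh)
            meta.update(extra)
            pixel_size = extra.get("pixel_size", pixel_size)
    return FrameSeries(frames=stack, times=times, pixel_size=pixel_size, meta=meta)


def save_frames(
    outdir: str,
    series: FrameSeries,
    temps: Optional[Sequence[float]] = None,
    meta_extra: Optional[dict] = None,
) -> list[str]:
    """Write a series as numbered 8-bit PNGs plus sidecar CSV and metadata JSON."""
    os.makedirs(outdir, exist_ok=True)
    written = []
    for i, frame in enumerate(series.frames):
        p = os.path.join(outdir, f"frame_{i:05d}.png")
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        written.append(p)
    tab = pd.DataFrame({"frame_index": np.arange(len(series)), "time_s": series.times})
    if temps is not None:
        tab["temperature_C"] = np.asarray(temps, dtype=float)
    csv_path = os.path.join(outdir, "frames.csv")
    tab.to_csv(csv_path, index=False)
    meta = {"pixel_size": series.pixel_size}
    meta.update({k: v for k, v in series.meta.items() if _json_safe(v)})
    if meta_extra:
        meta.update(meta_extra)
    meta_path = os.path.join(outdir, "meta.json")
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=_jsonify)
    return written + [csv_path, meta_path]


def _json_safe(v) -> bool:
    return isinstance(v, (int, float, str, bool, type(None), list, dict))


def _jsonify(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    raise TypeError(type(v))


def _auto_locate_square(frame: np.ndarray) -> tuple[int, int, int, int]:
    """Find a dark, filled, roughly square connected component."""
    from scipy import ndimage as ndi

    img = np.asarray(frame, dtype=float)
    dark = img <= img.min() + 0.1 * (img.max() - img.min() + 1e-12)
    labels, n = ndi.label(dark)
    best = None
    for sl in ndi.find_objects(labels):
        if sl is None:
            continue
        hh = sl[0].stop - sl[0].start
        ww = sl[1].stop - sl[1].start
        if hh < 4 or ww < 4 or hh * ww > 0.5 * img.size:
            continue
        region = labels[sl] > 0
        fill = region.mean()
        aspect = min(hh, ww) / max(hh, ww)
        if fill > 0.9 and aspect > 0.85:
            area = hh * ww
            if best is None or area > best[0]:
                best = (area, (sl[0].start, sl[1].start, hh, ww))
    if best is None:
        raise DetectionFailureError("no candidate reference square found")
    return best[1]


def calibrate(
    frame: np.ndarray,
    reference_extent_physical: float,
    locator: str = "auto",
    bbox: Optional[tuple[int, int, int, int]] = None,
) -> CalibrationResult:
    """Pixel-size calibration from a reference object of known physical size.

    ``locator='manual'`` uses the supplied ``bbox`` (row0, col0, height,
    width); ``'auto'`` searches for a dark filled square.  The pixel extent
    is the mean of the bbox sides; the area factor is ``pixel_size**2``.
    """
    if reference_extent_physical <= 0:
        raise InvalidParameterError("reference extent must be positive")
    if locator == "manual":
        if bbox is None:
            raise InvalidParameterError("manual locator requires a bbox")
        r0, c0, hh, ww = bbox
    elif locator == "auto":
        r0, c0, hh, ww = _auto_locate_square(frame)
    else:
        raise InvalidParameterError(f"unknown locator {locator!r}")
    if hh <= 0 or ww <= 0:
        raise InvalidParameterError("reference bbox must have positive extent")
    px = 0.5 * (hh + ww)
    return CalibrationResult(
        pixel_size=reference_extent_physical / px,
        reference_object_px=px,
        reference_object_physical=reference_extent_physical,
    )


def align_temperature(frames: FrameSeries, profile: TemperatureProfile) -> AlignedSeries:
    """Assign one stage temperature per frame by linear interpolation.

    The profile must cover the frame time span (tolerance: one profile
    sampling interval).
    """
    dt = np.median(np.diff(profile.times)) if len(profile.times) > 1 else 0.0
    t0, t1 = profile.times[0], profile.times[-1]
    if frames.times[0] < t0 - dt or frames.times[-1] > t1 + dt:
        raise AlignmentError(
            f"frame span [{frames.times[0]:g}, {frames.times[-1]:g}] s outside "
            f"profile span [{t0:g}, {t1:g}] s"
        )
    temps = profile.temperature_at(frames.times)
    return AlignedSeries(frames=frames, frame_temps=temps)


def read_temperature_log(path: str) -> TemperatureProfile:
    """Read a ``time_s,temperature_C`` CSV into a TemperatureProfile."""
    tab = pd.read_csv(path)
    if "time_s" not in tab.columns or "temperature_C" not in tab.columns:
        raise InvalidParameterError(f"{path!r} lacks time_s/temperature_C columns")
    return TemperatureProfile(
        times=tab["time_s"].to_numpy(dtype=float),
        temps=tab["temperature_C"].to_numpy(dtype=float),
        protocol_label=os.path.basename(path),
    )


def write_temperature_log(path: str, profile: TemperatureProfile) -> str:
    pd.DataFrame({"time_s": profile.times, "temperature_C": profile.temps}).to_csv(
        path, index=False
    )
    return path
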