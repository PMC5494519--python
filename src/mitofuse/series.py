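"""Two-channel time-lapse container and TIFF + JSON-sidecar I/O.

The whole package works on one in-memory currency: an :class:`ImageSeries`
holding a ``(T, 2, H, W)`` unsigned-integer pixel array (channel 0 = mtPA-GFP,
channel 1 = mtDsRed) plus the physical calibration and photoactivation
metadata every analysis stage needs (pixel size, frame interval, activation
frame index, activation ROIs, optional cell mask).

Frame-index convention: frames ``0 .. t_act - 1`` are pre-activation; the
activation pulse falls between frames ``t_act - 1`` and ``t_act``, so
``t_act`` is the first post-activation frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

#: channel indices
CH_GFP = 0
CH_RED = 1

#: rectangular ROI in pixel coordinates: (row0, col0, height, width), half-open
PixelRoi = tuple[int, int, int, int]


@dataclass
class ImageSeries:
    """A two-channel (GFP, DsRed) time-lapse with calibration metadata.

    Parameters
    ----------
    pixels : ndarray, shape (T, 2, H, W), unsigned integer
        Raw pixel data; channel 0 is mtPA-GFP, channel 1 is mtDsRed.
    pixel_um : float
        Pixel side length in micrometres.
    frame_interval_s : float
        Acquisition interval in seconds (0.25 frames/s -> 4 s).
    t_act : int
        Index of the first post-activation frame.
    act_rois : list of (row0, col0, height, width)
        Photoactivation squares in pixel coordinates (0-based, half-open).
    bit_depth : int
        8 or 16.
    cell_roi : ndarray (H, W) of bool, optional
        Mask of the cell; ``None`` means the whole field is in-cell.
    """

    pixels: np.ndarray
    pixel_um: float
    frame_interval_s: float
    t_act: int
    act_rois: list[PixelRoi] = field(default_factory=list)
    bit_depth: int = 8
    cell_roi: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4 or self.pixels.shape[1] != 2:
            raise ValueError(
                f"pixels must have shape (T, 2, H, W); got {self.pixels.shape}"
            )
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if not np.issubdtype(self.pixels.dtype, np.unsignedinteger):
            raise ValueError(f"pixels must be unsigned integer, got {self.pixels.dtype}")
        if self.pixels.size and int(self.pixels.max()) >= 2 ** self.bit_depth:
            raise ValueError("pixel values exceed bit depth")
        if self.pixel_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_um and frame_interval_s must be positive")
        if not (0 <= self.t_act < self.n_frames):
            raise ValueError(f"t_act {self.t_act} outside [0, {self.n_frames})")
        h, w = self.frame_shape
        self.act_rois = [tuple(int(v) for v in r) for r in self.act_rois]
        for r0, c0, hh, ww in self.act_rois:
            if r0 < 0 or c0 < 0 or hh <= 0 or ww <= 0 or r0 + hh > h or c0 + ww > w:
                raise ValueError(f"ROI {(r0, c0, hh, ww)} not inside {h}x{w} frame")
        if self.cell_roi is not None:
            self.cell_roi = np.asarray(self.cell_roi, dtype=bool)
            if self.cell_roi.shape != self.frame_shape:
                raise ValueError("cell_roi shape must match frame shape")

    # -- conveniences -----------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    @property
    def post_frames(self) -> range:
        """Indices of the post-activation frames (``t_act`` inclusive)."""
        return range(self.t_act, self.n_frames)

    @property
    def pre_frames(self) -> range:
        return range(self.t_act)

    def times_s(self, frames=None) -> np.ndarray:
        """Seconds since the first post-activation frame."""
        if frames is None:
            frames = np.arange(self.n_frames)
        return (np.asarray(frames) - self.t_act) * self.frame_interval_s

    def roi_mask(self) -> np.ndarray:
        """Boolean union of all activation ROIs."""
        m = np.zeros(self.frame_shape, dtype=bool)
        for r0, c0, h, w in self.act_rois:
            m[r0 : r0 + h, c0 : c0 + w] = True
        return m

    def cell_mask(self) -> np.ndarray:
        if self.cell_roi is not None:
            return self.cell_roi
        return np.ones(self.frame_shape, dtype=bool)

    def channel(self, ch: int) -> np.ndarray:
        """(T, H, W) view of one channel."""
        return self.pixels[:, ch]

    def copy(self) -> "ImageSeries":
        return replace(
            self,
            pixels=self.pixels.copy(),
            act_rois=list(self.act_rois),
            cell_roi=None if self.cell_roi is None else self.cell_roi.copy(),
        )


# -- I/O -------------------------------------------------------------------

_SIDECAR_REQUIRED = ("pixel_um", "frame_interval_s", "t_act")


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def write_series(series: ImageSeries, path: str | Path) -> Path:
    """Write a series as a TCYX multi-page TIFF plus a JSON sidecar.

    The sidecar carries everything :func:`read_series` needs to rebuild the
    :class:`ImageSeries` losslessly (``cell_roi`` is stored as a bounding
    rectangle if present).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, series.pixels, metadata={"axes": "TCYX"})
    meta: dict = {
        "pixel_um": series.pixel_um,
        "frame_interval_s": series.frame_interval_s,
        "t_act": series.t_act,
        "act_rois": [list(r) for r in series.act_rois],
        "bit_depth": series.bit_depth,
    }
    if series.cell_roi is not None:
        rows = np.any(series.cell_roi, axis=1).nonzero()[0]
        cols = np.any(series.cell_roi, axis=0).nonzero()[0]
        meta["cell_roi_rect"] = [
            int(rows[0]),
            int(cols[0]),
            int(rows[-1] - rows[0] + 1),
            int(cols[-1] - cols[0] + 1),
        ]
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_series(path: str | Path, sidecar: str | Path | None = None) -> ImageSeries:
    """Read a TIFF stack + sidecar back into an :class:`ImageSeries`.

    Axis resolution: a 4-D array is taken as TCYX; a 3-D array as TYX only if
    the sidecar says ``n_channels: 1`` (not produced by this package), else
    the call fails listing the candidate interpretations.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in _SIDECAR_REQUIRED:
        if key not in meta:
            raise KeyError(f"sidecar missing required field {key!r}")
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        axes = tf.series[0].axes if tf.series else ""
    if arr.ndim == 4:
        if axes and axes not in ("TCYX", "QQYX", "ZCYX", "CTYX"):
            raise ValueError(f"ambiguous TIFF axes {axes!r}; candidates: TCYX, CTYX")
        if axes == "CTYX":
            arr = np.swapaxes(arr, 0, 1)
    elif arr.ndim == 3 and arr.shape[0] == 2:
        # single-frame two-channel stack
        arr = arr[None]
    else:
        raise ValueError(
            f"cannot resolve axes of shape {arr.shape} (axes={axes!r}); "
            "expected (T, 2, H, W)"
        )
    cell_roi = None
    if "cell_roi_rect" in meta and meta["cell_roi_rect"] is not None:
        r0, c0, h, w = meta["cell_roi_rect"]
        cell_roi = np.zeros(arr.shape[2:], dtype=bool)
        cell_roi[r0 : r0 + h, c0 : c0 + w] = True
    return ImageSeries(
        pixels=arr,
        pixel_um=float(meta["pixel_um"]),
        frame_interval_s=float(meta["frame_interval_s"]),
        t_act=int(meta["t_act"]),
        act_rois=[tuple(r) for r in meta.get("act_rois", [])],
        bit_depth=int(meta.get("bit_depth", 8 if arr.dtype == np.uint8 else 16)),
        cell_roi=cell_roi,
    )
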