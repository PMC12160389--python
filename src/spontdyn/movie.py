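"""In-memory container for wide-field imaging movies.

A :class:`PixelMovie` holds one processing stage of a recording as a
``(rows, cols, frames)`` array together with the binary region-of-interest
mask and the acquisition metadata (pixel pitch in micrometres, frame
interval in milliseconds).  Stages follow the standard wide-field pipeline:

``raw`` (camera counts F) -> ``baseline`` (running percentile F0)
-> ``dff`` (relative change r = (F - F0)/F0) -> ``deconvolved``
(prior-frame subtraction y_t = r_t - gamma * r_{t-1}).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Allowed stage tags, in pipeline order.
STAGES = ("raw", "baseline", "dff", "deconvolved")

#: Legal stage transitions (from -> allowed to).
_TRANSITIONS = {
    "raw": {"baseline", "dff"},
    "dff": {"deconvolved"},
}


@dataclass
class PixelMovie:
    """One stage of a recording: pixels x frames plus acquisition metadata.

    Parameters
    ----------
    data:
        ``(rows, cols, frames)`` float array.
    roi:
        ``(rows, cols)`` boolean mask; analyses are restricted to ROI pixels.
    pixel_pitch_um:
        Centre-to-centre pixel spacing in micrometres.
    frame_interval_ms:
        Time between consecutive frames in milliseconds.
    stage:
        One of :data:`STAGES`.
    """

    data: np.ndarray
    roi: np.ndarray
    pixel_pitch_um: float = 46.9
    frame_interval_ms: float = 20.0
    stage: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.roi = np.asarray(self.roi, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"data must be (rows, cols, frames), got shape {self.data.shape}")
        if self.data.shape[2] < 1:
            raise ValueError("movie must contain at least one frame")
        if self.roi.shape != self.data.shape[:2]:
            raise ValueError(
                f"ROI shape {self.roi.shape} does not match movie grid {self.data.shape[:2]}"
            )
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.pixel_pitch_um <= 0 or self.frame_interval_ms <= 0:
            raise ValueError("pixel_pitch_um and frame_interval_ms must be positive")

    # -- geometry ----------------------------------------------------------

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def pixel_area_mm2(self) -> float:
        """Area of one pixel in mm^2 (0.0022 mm^2 at 46.9 um pitch)."""
        return (self.pixel_pitch_um / 1000.0) ** 2

    @property
    def roi_area_mm2(self) -> float:
        return float(self.roi.sum()) * self.pixel_area_mm2

    @property
    def duration_ms(self) -> float:
        return self.n_frames * self.frame_interval_ms

    def frame_times_ms(self) -> np.ndarray:
        """Start time of each frame in ms from recording start."""
        return np.arange(self.n_frames) * self.frame_interval_ms

    # -- stage bookkeeping -------------------------------------------------

    def with_stage(self, data: np.ndarray, stage: str) -> "PixelMovie":
        """Return a sibling movie holding `data` at a downstream `stage`."""
        allowed = _TRANSITIONS.get(self.stage, set())
        if stage not in allowed:
            raise ValueError(f"illegal stage transition {self.stage!r} -> {stage!r}")
        return replace(self, data=data, stage=stage)


def disk_roi(grid_shape: tuple[int, int], diameter_mm: float, pixel_pitch_um: float) -> np.ndarray:
    """Centred circular ROI of the given physical diameter.

    Mimics the roughly circular cranial-window field of view; pixels whose
    centre lies within the disk are included.
    """
    h, w = grid_shape
    r_px = (diameter_mm * 1000.0 / pixel_pitch_um) / 2.0
    rows = np.arange(h) - (h - 1) / 2.0
    cols = np.arange(w) - (w - 1) / 2.0
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return rr**2 + cc**2 <= r_px**2


def roi_centroid(roi: np.ndarray) -> tuple[float, float]:
    """(row, col) centroid of the ROI mask."""
    rr, cc = np.nonzero(roi)
    if rr.size == 0:
        raise ValueError("empty ROI")
    return float(rr.mean()), float(cc.mean())


def pixel_coords_mm(roi: np.ndarray, pixel_pitch_um: float) -> np.ndarray:
    """(n_roi, 2) array of (x, y) pixel-centre coordinates in mm.

    Origin at the ROI centroid; x increases with column index (rightward),
    y increases with row index (downward).  Propagation angles are measured
    from +x toward +y.
    """
    r0, c0 = roi_centroid(roi)
    rr, cc = np.nonzero(roi)
    pitch_mm = pixel_pitch_um / 1000.0
    x = (cc - c0) * pitch_mm
    y = (rr - r0) * pitch_mm
    return np.column_stack([x, y])
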