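"""Active-pixel detection, mask cleaning, and event segmentation.

A pixel is active when its deconvolved signal exceeds its own mean by
``k_sd`` standard deviations (computed over the whole recording, ROI
pixels only).  Per-frame masks are cleaned by binary opening (3x3
structuring element) followed by removal of connected components below a
minimum contiguous area (0.028 mm^2).  An event is a maximal run of frames
each containing at least one active pixel, bounded by fully inactive
frames; only events activating at least 1 mm^2 across their duration are
analysed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .movie import PixelMovie

logger = logging.getLogger(__name__)

#: 3x3 all-ones structuring element (8-connectivity), used throughout.
STRUCT_3X3 = np.ones((3, 3), dtype=bool)

DEFAULT_K_SD = 4.0
DEFAULT_MIN_COMPONENT_MM2 = 0.028
DEFAULT_MIN_EVENT_MM2 = 1.0


@dataclass
class Event:
    """A contiguous run of active frames.

    ``masks`` and ``activity`` are ``(rows, cols, n_frames)`` slices of the
    cleaned active mask and the deconvolved movie over the event's inclusive
    frame range ``[t_start, t_end]``.
    """

    t_start: int
    t_end: int
    masks: np.ndarray
    activity: np.ndarray
    frame_interval_ms: float
    touches_boundary: bool = False
    event_id: int = -1
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.t_end - self.t_start + 1

    @property
    def duration_ms(self) -> float:
        return self.n_frames * self.frame_interval_ms

    @property
    def onset_mask(self) -> np.ndarray:
        """Pixels active on the event's first frame."""
        return self.masks[..., 0]

    @property
    def ever_active(self) -> np.ndarray:
        """Pixels active on any frame of the event."""
        return self.masks.any(axis=-1)

    def onset_frames(self) -> np.ndarray:
        """Per-pixel first-active frame (relative to t_start), -1 if never active."""
        ever = self.ever_active
        first = np.argmax(self.masks, axis=-1)
        return np.where(ever, first, -1)

    def onset_times_ms(self) -> np.ndarray:
        """Per-pixel onset time in ms from event start; NaN where never active."""
        f = self.onset_frames()
        return np.where(f >= 0, f * self.frame_interval_ms, np.nan)


def active_mask(movie: PixelMovie, k_sd: float = DEFAULT_K_SD) -> np.ndarray:
    """Per-pixel threshold at ``mean + k_sd * sd`` of the deconvolved trace.

    Statistics are computed per pixel over all frames.  Pixels outside the
    ROI, and zero-variance pixels, are never active.
    """
    if movie.stage != "deconvolved":
        raise ValueError(f"active_mask expects a deconvolved movie, got {movie.stage!r}")
    y = movie.data
    # moment formula avoids the full-size float64 temporary of ndarray.std
    mean = y.mean(axis=-1, dtype=np.float64)
    sq = np.einsum("ijt,ijt->ij", y, y, dtype=np.float64) / y.shape[-1]
    sd = np.sqrt(np.maximum(sq - mean**2, 0.0))
    n_flat = int((movie.roi & (sd == 0)).sum())
    if n_flat:
        logger.warning("%d zero-variance ROI pixels are never active", n_flat)
    thr = np.where(sd > 0, mean + k_sd * sd, np.inf).astype(y.dtype)
    return (y > thr[..., None]) & movie.roi[..., None]


def min_component_px(pixel_area_mm2: float, min_area_mm2: float = DEFAULT_MIN_COMPONENT_MM2) -> int:
    """Smallest pixel count whose area reaches ``min_area_mm2`` (ceil)."""
    return int(np.ceil(min_area_mm2 / pixel_area_mm2))


def clean_mask(
    mask: np.ndarray,
    pixel_area_mm2: float,
    min_area_mm2: float = DEFAULT_MIN_COMPONENT_MM2,
) -> np.ndarray:
    """Binary opening (3x3) then removal of small connected components.

    Opening deletes isolated pixels and thin protrusions; the explicit area
    rule then enforces the contiguous-area criterion exactly (8-connected
    components smaller than ``min_area_mm2`` are removed).  Idempotent.
    """
    min_px = min_component_px(pixel_area_mm2, min_area_mm2)
    out = np.empty_like(mask)
    for t in range(mask.shape[-1]):
        frame = ndimage.binary_opening(mask[..., t], structure=STRUCT_3X3)
        if frame.any():
            labels, n = ndimage.label(frame, structure=STRUCT_3X3)
            if n:
                sizes = np.bincount(labels.ravel())
                small = np.flatnonzero(sizes < min_px)
                small = small[small > 0]
                if small.size:
                    frame &= ~np.isin(labels, small)
        out[..., t] = frame
    return out


def segment_events(mask: np.ndarray, movie: PixelMovie) -> list[Event]:
    """Split the recording into events: maximal runs of non-empty frames.

    Runs touching the first or last frame are kept but flagged
    ``touches_boundary`` (their durations are truncated by the recording).
    """
    frame_active = mask.any(axis=(0, 1))
    n = frame_active.size
    events: list[Event] = []
    t = 0
    while t < n:
        if not frame_active[t]:
            t += 1
            continue
        t0 = t
        while t < n and frame_active[t]:
            t += 1
        t1 = t - 1
        events.append(
            Event(
                t_start=t0,
                t_end=t1,
                masks=mask[..., t0 : t1 + 1],
                activity=movie.data[..., t0 : t1 + 1],
                frame_interval_ms=movie.frame_interval_ms,
                touches_boundary=(t0 == 0 or t1 == n - 1),
                event_id=len(events),
            )
        )
    return events


def filter_events(
    events: list[Event],
    pixel_area_mm2: float,
    min_total_area_mm2: float = DEFAULT_MIN_EVENT_MM2,
) -> list[Event]:
    """Keep events whose union-across-frames active area reaches the minimum."""
    kept = [
        ev
        for ev in events
        if ev.ever_active.sum() * pixel_area_mm2 >= min_total_area_mm2
    ]
    logger.info("filter_events: kept %d of %d events", len(kept), len(events))
    return kept


def max_active_frame(event: Event) -> int:
    """Frame (relative to event start) with the largest summed activity.

    Activity is summed over that frame's active pixels; ties resolve to the
    earliest frame.
    """
    if event.n_frames < 1:
        raise ValueError("empty event")
    sums = (event.activity * event.masks).sum(axis=(0, 1))
    return int(np.argmax(sums))
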