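"""Raw fluorescence -> baseline-corrected dF/F -> deconvolved activity.

The baseline F0 is a per-pixel running rank-order filter (36th percentile
over a 28.5 s centred window by default).  dF/F is ``r = (F - F0) / F0``.
Deconvolution is prior-frame subtraction, ``y_t = r_t - gamma * r_{t-1}``
with gamma the per-frame indicator decay (0.89 for GCaMP8m at 20 ms);
it is the exact left-inverse of the indicator recursion at zero noise.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.ndimage import rank_filter

from .movie import PixelMovie

logger = logging.getLogger(__name__)

DEFAULT_GAMMA = 0.89
DEFAULT_RANK = 0.36
DEFAULT_WINDOW_S = 28.5


def _nearest_rank_index(rank: float, m: int) -> int:
    """0-based nearest-rank (ceil) order-statistic index for window size m."""
    return max(0, min(m - 1, math.ceil(rank * m) - 1))


def compute_baseline(
    raw: PixelMovie,
    rank: float = DEFAULT_RANK,
    window_s: float | None = DEFAULT_WINDOW_S,
) -> PixelMovie:
    """Per-pixel running rank-order baseline.

    Uses nearest-rank (ceil) indexing.  At the trace edges the window is
    truncated rather than padded, so edge baselines are order statistics of
    the data actually observed there.  ``window_s=None``, or a window longer
    than the recording, falls back to a whole-trace percentile (constant in
    time), which is exact for drift-free recordings.
    """
    if raw.stage != "raw":
        raise ValueError(f"compute_baseline expects a raw movie, got stage {raw.stage!r}")
    if not 0.0 < rank < 1.0:
        raise ValueError("rank must lie in (0, 1)")
    data = raw.data
    n = raw.n_frames

    if window_s is not None:
        w = int(round(window_s * 1000.0 / raw.frame_interval_ms))
        if w % 2 == 0:
            w += 1  # force odd for centring
        if w < 3:
            raise ValueError("baseline window must span at least 3 frames")
    else:
        w = None

    if w is None or w >= n:
        if w is not None:
            logger.warning(
                "baseline window (%d frames) exceeds recording (%d frames); "
                "falling back to whole-trace percentile",
                w,
                n,
            )
        k = _nearest_rank_index(rank, n)
        base = np.partition(data, k, axis=-1)[..., k : k + 1]
        # broadcast view: constant over time, no full-size copy
        base = np.broadcast_to(base, data.shape)
        return raw.with_stage(base, "baseline")

    half = w // 2
    k = _nearest_rank_index(rank, w)
    base = rank_filter(data, rank=k, size=(1, 1, w), mode="nearest")
    # recompute truncated-window edges (rank_filter pads; we do not)
    for t in range(half):
        seg = data[..., : t + half + 1]
        kk = _nearest_rank_index(rank, seg.shape[-1])
        base[..., t] = np.partition(seg, kk, axis=-1)[..., kk]
        seg = data[..., n - 1 - t - half :]
        kk = _nearest_rank_index(rank, seg.shape[-1])
        base[..., n - 1 - t] = np.partition(seg, kk, axis=-1)[..., kk]
    return raw.with_stage(base, "baseline")


def dff(raw: PixelMovie, baseline: PixelMovie) -> PixelMovie:
    """Relative fluorescence change ``r = (F - F0) / F0``."""
    if raw.stage != "raw" or baseline.stage != "baseline":
        raise ValueError("dff expects a raw movie and a baseline movie")
    bad = raw.roi & (baseline.data <= 0).any(axis=-1)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"non-positive baseline inside ROI, e.g. at pixel (row={r}, col={c})")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = raw.data - baseline.data
        r /= baseline.data
    np.nan_to_num(r, copy=False, nan=0.0, posinf=0.0, neginf=0.0)
    return raw.with_stage(r, "dff")


def deconvolve(dff_movie: PixelMovie, gamma: float = DEFAULT_GAMMA) -> PixelMovie:
    """Prior-frame subtraction ``y_t = r_t - gamma * r_{t-1}``.

    The first frame is passed through unchanged (``y_0 = r_0``, i.e. the
    pre-recording dF/F is taken as zero).
    """
    if dff_movie.stage != "dff":
        raise ValueError(f"deconvolve expects a dff movie, got stage {dff_movie.stage!r}")
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie in (0, 1)")
    r = dff_movie.data
    y = np.empty_like(r)
    y[..., 0] = r[..., 0]
    y[..., 1:] = r[..., 1:] - gamma * r[..., :-1]
    return dff_movie.with_stage(y, "deconvolved")


def preprocess(
    raw: PixelMovie,
    gamma: float = DEFAULT_GAMMA,
    rank: float = DEFAULT_RANK,
    window_s: float | None = DEFAULT_WINDOW_S,
) -> PixelMovie:
    """Full raw -> deconvolved chain."""
    base = compute_baseline(raw, rank=rank, window_s=window_s)
    return deconvolve(dff(raw, base), gamma=gamma)
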