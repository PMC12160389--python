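"""Within-event propagation: geometry, linear wavefront fits, direction stats.

The propagation area PA is the ever-active area lying beyond a ~420 um
exclusion zone around the onset-frame footprint (nine 3x3 binary dilations);
PA = 0 defines a static event.  Dynamic events are fit with a planar
travelling wavefront ``t_on = x . [cos theta, sin theta] / v + t_shift`` by
minimising the mean squared error of onset times; fit significance is
assessed against frame-order permutations, and direction statistics use the
Rayleigh test on doubled axial angles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize_scalar
from scipy.stats import binomtest

from .events import STRUCT_3X3, Event
from .movie import PixelMovie, pixel_coords_mm

logger = logging.getLogger(__name__)

DEFAULT_N_DILATIONS = 9
DEFAULT_MIN_FRAMES = 5
DEFAULT_N_PERM = 100
DEFAULT_ALPHA_PERCENTILE = 95.0
V_BOUNDS_MM_S = (1.0, 300.0)


@dataclass
class EventGeometry:
    """Active/onset/propagation areas of one event (areas in mm^2)."""

    p_sum: int
    a_active_mm2: float
    a_total_mm2: float
    ra: float
    a_on_mm2: float
    pa_mm2: float
    is_static: bool


@dataclass
class WaveFit:
    """Planar wavefront parameters for one event."""

    v_mm_s: float | None
    theta_deg: float | None          # direction of propagation, [0, 360)
    t_shift_ms: float | None
    mse_ms2: float | None
    degenerate: bool = False         # all onsets identical: simultaneous activation
    significant: bool | None = None  # None until / unless the permutation test runs

    @property
    def theta_axial_deg(self) -> float | None:
        return None if self.theta_deg is None else self.theta_deg % 180.0


def event_geometry(
    event: Event,
    roi: np.ndarray,
    pixel_area_mm2: float,
    n_dilations: int = DEFAULT_N_DILATIONS,
) -> EventGeometry:
    """Areas and the static/dynamic classification for one event.

    The onset mask is dilated ``n_dilations`` times with the 3x3 all-ones
    element (Chebyshev radius ``n_dilations`` pixels, ~420 um at 46.9 um
    pitch); ever-active pixels outside the dilated mask count toward PA.
    """
    ever = event.ever_active & roi
    onset = event.onset_mask & roi
    p_sum = int(ever.sum())
    a_active = p_sum * pixel_area_mm2
    a_total = float(roi.sum()) * pixel_area_mm2
    dil = ndimage.binary_dilation(onset, structure=STRUCT_3X3, iterations=n_dilations)
    pa_px = int((ever & ~dil).sum())
    return EventGeometry(
        p_sum=p_sum,
        a_active_mm2=a_active,
        a_total_mm2=a_total,
        ra=a_active / a_total if a_total > 0 else 0.0,
        a_on_mm2=float(onset.sum()) * pixel_area_mm2,
        pa_mm2=pa_px * pixel_area_mm2,
        is_static=pa_px == 0,
    )


def onset_times(event: Event, roi: np.ndarray, pixel_pitch_um: float):
    """Onset time (ms from event start) and mm coordinates of active pixels.

    Returns ``(t_on, coords)`` with coordinates relative to the ROI centroid
    (x = columns increasing rightward, y = rows increasing downward).
    """
    frames = event.onset_frames()
    coords_all = pixel_coords_mm(roi, pixel_pitch_um)
    f_roi = frames[roi]
    active = f_roi >= 0
    t_on = f_roi[active] * event.frame_interval_ms
    return t_on.astype(float), coords_all[active]


def _profile_fit(t_on: np.ndarray, s: np.ndarray) -> tuple[float, float, float]:
    """Least-squares (slope, intercept, mse) of t_on against projection s."""
    sm, tm = s.mean(), t_on.mean()
    var_s = ((s - sm) ** 2).mean()
    if var_s == 0:
        resid = t_on - tm
        return 0.0, tm, float((resid**2).mean())
    b = float(((s - sm) * (t_on - tm)).mean() / var_s)
    c = tm - b * sm
    resid = t_on - (b * s + c)
    return b, float(c), float((resid**2).mean())


def fit_linear_wave(
    t_on: np.ndarray,
    coords_mm: np.ndarray,
    theta_step_deg: float = 10.0,
    v_bounds: tuple[float, float] = V_BOUNDS_MM_S,
) -> WaveFit:
    """Fit the planar wavefront model by MSE minimisation.

    The direction theta is scanned on a grid (default 10 degree steps); for
    each direction the optimal slope 1/v and intercept t_shift are the exact
    linear least-squares solution, so the scan profiles out v and t_shift.
    The best direction is then refined continuously.  Only directions with a
    positive slope (wave travelling along +u) are admissible; the opposite
    direction appears at theta + 180.
    """
    t_on = np.asarray(t_on, dtype=float)
    coords = np.asarray(coords_mm, dtype=float)
    if t_on.size < 3:
        return WaveFit(None, None, None, None, degenerate=True)
    if np.ptp(t_on) == 0:
        # simultaneous activation: velocity undefined
        return WaveFit(None, None, None, None, degenerate=True)

    def mse_at(theta_deg: float) -> tuple[float, float, float]:
        th = np.deg2rad(theta_deg)
        s = coords[:, 0] * np.cos(th) + coords[:, 1] * np.sin(th)
        b, c, mse = _profile_fit(t_on, s)
        if b <= 0:
            return np.inf, 0.0, 0.0
        return mse, b, c

    grid = np.arange(0.0, 360.0, theta_step_deg)
    mses = np.array([mse_at(th)[0] for th in grid])
    i = int(np.argmin(mses))
    if not np.isfinite(mses[i]):
        return WaveFit(None, None, None, None, degenerate=True)

    res = minimize_scalar(
        lambda th: mse_at(th)[0],
        bounds=(grid[i] - theta_step_deg, grid[i] + theta_step_deg),
        method="bounded",
        options={"xatol": 1e-3},
    )
    theta = float(res.x) % 360.0
    mse, b, c = mse_at(theta)
    if not np.isfinite(mse):
        theta = float(grid[i])
        mse, b, c = mse_at(theta)
    v = 1000.0 / b  # t in ms, s in mm -> v in mm/s
    v = float(np.clip(v, *v_bounds))
    return WaveFit(v_mm_s=v, theta_deg=theta, t_shift_ms=float(c), mse_ms2=float(mse))


def wave_significance(
    event: Event,
    roi: np.ndarray,
    pixel_pitch_um: float,
    fit: WaveFit | None = None,
    n_perm: int = DEFAULT_N_PERM,
    alpha_percentile: float = DEFAULT_ALPHA_PERCENTILE,
    min_frames: int = DEFAULT_MIN_FRAMES,
    rng: np.random.Generator | int | None = None,
) -> WaveFit | None:
    """Frame-permutation test of the linear fit.

    The event's frame order is permuted (``n_perm`` draws, without enforcing
    derangements), onset times recomputed, and the model refit.  Fit quality
    is -MSE, so the real fit is significant when its MSE lies below the
    ``100 - alpha_percentile`` percentile of permuted MSEs.  Events shorter
    than ``min_frames`` frames are excluded (returns None), not failed.
    """
    if event.n_frames < min_frames:
        return None
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if fit is None:
        t_on, coords = onset_times(event, roi, pixel_pitch_um)
        fit = fit_linear_wave(t_on, coords)
    if fit.degenerate or fit.mse_ms2 is None:
        return fit

    coords_all = pixel_coords_mm(roi, pixel_pitch_um)
    masks_roi = event.masks[roi]          # (n_roi, n_frames)
    perm_mses = []
    for _ in range(n_perm):
        order = rng.permutation(event.n_frames)
        pm = masks_roi[:, order]
        ever = pm.any(axis=1)
        first = np.argmax(pm, axis=1)
        t_on_p = first[ever] * event.frame_interval_ms
        pf = fit_linear_wave(t_on_p.astype(float), coords_all[ever])
        perm_mses.append(np.inf if pf.mse_ms2 is None else pf.mse_ms2)
    perm_mses = np.asarray(perm_mses)
    cutoff = np.percentile(perm_mses[np.isfinite(perm_mses)], 100.0 - alpha_percentile)
    fit.significant = bool(fit.mse_ms2 < cutoff)
    return fit


def velocity_ceiling(fov_diameter_mm: float, frame_interval_ms: float) -> float:
    """Fastest detectable propagation: FOV diameter per frame interval (mm/s)."""
    if fov_diameter_mm <= 0 or frame_interval_ms <= 0:
        raise ValueError("inputs must be positive")
    return fov_diameter_mm / (frame_interval_ms / 1000.0)


def axial_direction_stats(theta_deg: np.ndarray, alpha: float = 0.05) -> dict:
    """Axial bias of propagation directions.

    Angles are folded to axial space (mod 180), doubled, and tested with the
    Rayleigh test.  If the axis is significant, a binomial test compares the
    counts of events travelling either way along the mean axis (+-90 degree
    bins) against 0.5.
    """
    import pingouin as pg

    theta = np.asarray(theta_deg, dtype=float)
    if theta.size < 10:
        logger.warning("axial_direction_stats called with fewer than 10 fits")
    doubled = np.deg2rad(2.0 * (theta % 180.0))
    z, p = pg.circ_rayleigh(doubled)
    mean_axis = float(np.rad2deg(np.angle(np.exp(1j * doubled).mean())) / 2.0) % 180.0

    binom_p = None
    n_forward = n_backward = None
    if p < alpha:
        # direction along the axis: sign of cos(theta - mean_axis)
        delta = np.deg2rad(theta - mean_axis)
        forward = np.cos(delta) > 0
        n_forward = int(forward.sum())
        n_backward = int(theta.size - n_forward)
        binom_p = float(binomtest(n_forward, theta.size, 0.5).pvalue)
    return {
        "rayleigh_z": float(z),
        "rayleigh_p": float(p),
        "mean_axis_deg": mean_axis,
        "n_forward": n_forward,
        "n_backward": n_backward,
        "binomial_p": binom_p,
    }


def classify_events(
    events: list[Event],
    movie: PixelMovie,
    n_dilations: int = DEFAULT_N_DILATIONS,
) -> list[EventGeometry]:
    """Geometry (and static/dynamic label) for every event."""
    return [
        event_geometry(ev, movie.roi, movie.pixel_area_mm2, n_dilations=n_dilations)
        for ev in events
    ]
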