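"""Parameter-recovery runs under the package's reference study conditions.

Each function generates synthetic data at the generator defaults (modular
wavelength 0.69 mm, 6.9% static events, 32 mm/s waves on a 3 mm field of
view at 50 Hz), runs the corresponding analysis stage from scratch, and
returns the recovered quantity.  The test suite and the reproduction
script both call these, so the numbers they report come from the identical
computation.
"""

from __future__ import annotations

import numpy as np

from . import events as ev_mod
from . import preprocess as pp
from .movie import pixel_coords_mm
from .propagation import classify_events, fit_linear_wave
from .spatial import wavelength
from .synthetic import SimConfig, make_event, make_modular_pattern, synthesize_session


def wavelength_recovery(
    seed: int,
    n_frames: int = 50,
    grid_shape: tuple[int, int] = (64, 64),
    wavelength_mm: float = 0.69,
    pixel_pitch_um: float = 46.9,
) -> dict:
    """Median wavelength estimate over modular frames at a known period."""
    rng = np.random.default_rng(seed)
    roi = np.ones(grid_shape, dtype=bool)
    estimates = []
    for _ in range(n_frames):
        pat = make_modular_pattern(grid_shape, wavelength_mm, pixel_pitch_um, rng)
        lam = wavelength(pat, roi, pixel_pitch_um)
        if lam is not None:
            estimates.append(lam)
    estimates = np.asarray(estimates)
    return {
        "median_wavelength_mm": float(np.median(estimates)),
        "estimates": estimates,
        "n": int(estimates.size),
        "true_wavelength_mm": wavelength_mm,
    }


def static_fraction_recovery(seed: int, n_events: int = 1000) -> dict:
    """Percentage of events classified static on a planted session.

    Simulates ``n_events`` events of which 6.9% are static (all activity
    inside the onset footprint) and the rest planar waves propagating well
    beyond the 420 um exclusion radius, then runs the full
    segmentation/classification chain: baseline, dF/F, deconvolution,
    4-SD activity threshold, morphological cleaning, event segmentation,
    the 1 mm^2 size filter, and the PA = 0 rule.
    """
    config = SimConfig(
        n_events=n_events,
        static_fraction=0.069,
        wave_fraction=1.0 - 0.069,
        seed=int(seed),
    )
    movie, truth = synthesize_session(config)

    # drift-free session: whole-trace rank percentile is the exact baseline
    base = pp.compute_baseline(movie, window_s=None)
    r = pp.dff(movie, base)
    del movie, base
    y = pp.deconvolve(r, gamma=config.gamma)
    del r

    mask = ev_mod.active_mask(y)
    mask = ev_mod.clean_mask(mask, y.pixel_area_mm2)
    events = ev_mod.segment_events(mask, y)
    events = ev_mod.filter_events(events, y.pixel_area_mm2)
    geos = classify_events(events, y)
    n_static = sum(g.is_static for g in geos)
    return {
        "static_percent": 100.0 * n_static / len(events) if events else float("nan"),
        "n_events_detected": len(events),
        "n_events_planted": len(truth),
        "n_static_planted": truth.counts()["static"],
    }


def wave_velocity_recovery(
    seed: int,
    n_events: int = 100,
    v_mm_s: float = 32.0,
    onset_jitter_ms: float = 10.0,
) -> dict:
    """Median fitted wavefront speed over planted planar-wave events.

    Waves travel at ``v_mm_s`` in uniformly random directions across the
    3 mm field of view; onsets follow the planar model with Gaussian jitter
    (SD half a frame by default) and are quantised to the 20 ms frame grid
    before fitting.
    """
    config = SimConfig(
        wave_speed_mm_s=v_mm_s, onset_jitter_ms=onset_jitter_ms, seed=int(seed)
    )
    rng = np.random.default_rng(seed)
    roi = config.roi
    coords_all = pixel_coords_mm(roi, config.pixel_pitch_um)
    fitted_v, fitted_theta, planted_theta = [], [], []
    for _ in range(n_events):
        _, rec = make_event("wave", config, rng)
        f_roi = rec.onset_frames[roi]
        active = f_roi >= 0
        t_on = f_roi[active].astype(float) * config.frame_interval_ms
        fit = fit_linear_wave(t_on, coords_all[active])
        if fit.v_mm_s is not None:
            fitted_v.append(fit.v_mm_s)
            fitted_theta.append(fit.theta_deg)
            planted_theta.append(rec.planted_theta)
    fitted_v = np.asarray(fitted_v)
    return {
        "median_v_mm_s": float(np.median(fitted_v)),
        "fitted_v": fitted_v,
        "fitted_theta": np.asarray(fitted_theta),
        "planted_theta": np.asarray(planted_theta),
        "n": int(fitted_v.size),
        "true_v_mm_s": v_mm_s,
    }
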