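"""Shared fixtures: small synthetic sessions reused across test modules."""

import numpy as np
import pytest

from spontdyn import events as evm
from spontdyn import preprocess as pp
from spontdyn.propagation import classify_events
from spontdyn.synthetic import SimConfig, synthesize_session


def run_segmentation(movie):
    """Raw movie -> (deconvolved movie, filtered events, geometries)."""
    base = pp.compute_baseline(movie, window_s=None)
    y = pp.deconvolve(pp.dff(movie, base))
    mask = evm.clean_mask(evm.active_mask(y), y.pixel_area_mm2)
    events = evm.filter_events(evm.segment_events(mask, y), y.pixel_area_mm2)
    geos = classify_events(events, y)
    return y, events, geos


@pytest.fixture(scope="session")
def mixed_session():
    """30 events: static, waves, and motifs, with ground truth."""
    config = SimConfig(
        n_events=30, static_fraction=0.2, wave_fraction=0.5, seed=5,
        quiet_range_s=(0.2, 1.0),
    )
    movie, truth = synthesize_session(config)
    return config, movie, truth


@pytest.fixture(scope="session")
def mixed_segmented(mixed_session):
    config, movie, truth = mixed_session
    y, events, geos = run_segmentation(movie)
    return config, truth, y, events, geos


@pytest.fixture(scope="session")
def motif_session():
    """Motif-only session: three 5-frame motifs, ~20 instances each."""
    config = SimConfig(
        n_events=60, static_fraction=0.0, wave_fraction=0.0,
        motif_library_size=3, quiet_range_s=(0.3, 0.8), seed=21,
    )
    movie, truth = synthesize_session(config)
    return config, movie, truth


@pytest.fixture(scope="session")
def motif_segmented(motif_session):
    config, movie, truth = motif_session
    y, events, geos = run_segmentation(movie)
    # planted motif id per detected event, matched by frame-range overlap
    motif_ids = {}
    for ev in events:
        rec = next(
            (r for r in truth.records if r.t_start <= ev.t_end and r.t_end >= ev.t_start),
            None,
        )
        motif_ids[ev.event_id] = rec.motif_id if rec is not None else -1
    return config, truth, y, events, geos, motif_ids


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
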