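"""Motif selection, null threshold, greedy clustering, and coverage tests."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from spontdyn.motifs import (
    MotifSubset,
    _derangement,
    clustering_quality,
    concatenate_vectors,
    correlation_matrix,
    denoise_positions,
    frame_shuffle_control,
    greedy_cluster,
    repeats_and_frequency,
    select_fixed_duration,
    temporal_coverage,
    within_timestep_null,
)


@pytest.fixture(scope="module")
def planted_motifs():
    """Synthetic 5-frame event library: 6 motifs x 20 noisy instances."""
    rng = np.random.default_rng(9)
    n_motifs, n_inst, n_pos, n_px = 6, 20, 5, 300
    lib = rng.standard_normal((n_motifs, n_pos, n_px))
    frames, labels = [], []
    for m in range(n_motifs):
        for _ in range(n_inst):
            frames.append(lib[m] + 0.45 * rng.standard_normal((n_pos, n_px)))
            labels.append(m)
    order = rng.permutation(len(frames))
    frames = np.stack(frames)[order]
    labels = np.asarray(labels)[order]
    den = denoise_positions(frames)
    corr = correlation_matrix(concatenate_vectors(den))
    thr = within_timestep_null(den, n_perm=150, rng=4)
    return frames, labels, den, corr, thr


class TestSelection:
    def test_duration_and_dynamic_filters(self, mixed_segmented):
        _, _, y, events, geos = mixed_segmented
        subset = select_fixed_duration(events, geos, y.roi, y.pixel_pitch_um, n_frames=5)
        ids = set(subset.event_ids)
        for ev, geo in zip(events, geos):
            if ev.event_id in ids:
                assert ev.n_frames == 5 and not geo.is_static
                assert ev.duration_ms == 100.0
            elif ev.n_frames == 5:
                assert geo.is_static  # 5-frame but static: excluded


class TestDenoise:
    def test_low_rank_data_reconstructed_exactly(self, rng):
        basis = rng.standard_normal((20, 100))
        coef = rng.standard_normal((40, 5, 20))
        frames = coef @ basis
        den = denoise_positions(frames, n_components=20)
        np.testing.assert_allclose(den, frames, atol=1e-8)

    def test_identical_events_have_unit_correlation(self, rng):
        one = rng.standard_normal((5, 80))
        frames = np.stack([one, one, rng.standard_normal((5, 80))])
        corr = correlation_matrix(concatenate_vectors(denoise_positions(frames)))
        assert corr[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_correlations_match_brute_force(self, rng):
        frames = rng.standard_normal((12, 5, 60))
        den = denoise_positions(frames, n_components=8)
        vec = concatenate_vectors(den)
        corr = correlation_matrix(vec)
        expect = np.corrcoef(vec)
        np.testing.assert_allclose(corr, expect, atol=1e-10)


class TestNullThreshold:
    def test_deterministic_for_fixed_seed(self, rng):
        frames = rng.standard_normal((15, 5, 50))
        den = denoise_positions(frames)
        t1 = within_timestep_null(den, n_perm=20, rng=7)
        t2 = within_timestep_null(den, n_perm=20, rng=7)
        assert t1 == t2

    def test_single_permutation_runs(self, rng):
        den = denoise_positions(rng.standard_normal((10, 5, 30)))
        assert np.isfinite(within_timestep_null(den, n_perm=1, rng=0))

    def test_calibration_on_structureless_events(self):
        """Events that are per-position means plus noise: about 1% of real
        pairs exceed the 99th-percentile permutation threshold."""
        rng = np.random.default_rng(5)
        means = 2.0 * rng.standard_normal((5, 400))
        frames = means[None] + rng.standard_normal((60, 5, 400))
        den = denoise_positions(frames)
        corr = correlation_matrix(concatenate_vectors(den))
        thr = within_timestep_null(den, n_perm=200, rng=1)
        iu = np.triu_indices(60, k=1)
        frac = float((corr[iu] > thr).mean())
        assert 0.001 < frac < 0.04


class TestRepeats:
    def test_threshold_above_all_gives_zero(self, rng):
        corr = correlation_matrix(rng.standard_normal((8, 40)))
        reps, freq = repeats_and_frequency(corr, threshold=1.1)
        assert (reps == 0).all() and (freq == 0).all()

    def test_three_identical_events(self, rng):
        v = rng.standard_normal(30)
        vecs = np.stack([v, v, v, rng.standard_normal(30)])
        corr = correlation_matrix(vecs)
        reps, freq = repeats_and_frequency(corr, threshold=0.99)
        assert list(reps[:3]) == [2, 2, 2]
        np.testing.assert_allclose(freq[:3], 2 / 4)

    def test_planted_frequency(self, planted_motifs):
        _, _, _, corr, thr = planted_motifs
        reps, freq = repeats_and_frequency(corr, thr)
        # 20 instances per motif -> ~19 repeats of 120 events
        assert np.median(freq) == pytest.approx(19 / 120, abs=0.03)


class TestGreedyCluster:
    def _block_matrix(self, sizes):
        n = sum(sizes)
        corr = np.zeros((n, n))
        start = 0
        for s in sizes:
            corr[start : start + s, start : start + s] = 0.9
            start += s
        np.fill_diagonal(corr, 1.0)
        return corr

    def test_stop_rule_on_blocks(self):
        clusters = greedy_cluster(self._block_matrix([30, 20, 5]), threshold=0.5)
        assert [len(c) for c in clusters] == [30, 20]
        assert clusters[0] == list(range(30))

    def test_no_pairs_above_threshold(self, rng):
        corr = correlation_matrix(rng.standard_normal((20, 50)))
        assert greedy_cluster(corr, threshold=1.0) == []

    def test_clusters_disjoint(self, planted_motifs):
        _, _, _, corr, thr = planted_motifs
        clusters = greedy_cluster(corr, thr)
        flat = [i for c in clusters for i in c]
        assert len(flat) == len(set(flat))

    def test_recovers_planted_labels(self, planted_motifs):
        _, labels, _, corr, thr = planted_motifs
        clusters = greedy_cluster(corr, thr)
        assert len(clusters) >= 6
        pred = -np.ones(len(labels), int)
        for ci, members in enumerate(clusters):
            pred[members] = ci
        sel = pred >= 0
        assert adjusted_rand_score(labels[sel], pred[sel]) > 0.8


class TestTemporalCoverage:
    def test_hand_computed_example(self):
        out = temporal_coverage(np.array([5.0, 25.0, 95.0]), t_total_min=100.0)
        assert out["Fr"] == pytest.approx(0.9)
        assert out["Fb"] == pytest.approx(3 / 10)

    def test_single_bin(self):
        out = temporal_coverage(np.array([12.0, 13.0, 14.0]), t_total_min=100.0)
        assert out["Fb"] == pytest.approx(1 / 10)
        assert out["Fr"] == pytest.approx(0.02)

    def test_full_span(self):
        out = temporal_coverage(np.array([0.0, 100.0]), t_total_min=100.0)
        assert out["Fr"] == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            temporal_coverage(np.array([]), 10.0)
        with pytest.raises(ValueError):
            temporal_coverage(np.array([1.0]), 0.0)


class TestClusteringQuality:
    def test_well_separated_blobs_near_one(self, rng):
        a = rng.normal(0, 0.01, (20, 10))
        b = rng.normal(5, 0.01, (20, 10))
        vectors = np.vstack([a, b])
        out = clustering_quality(vectors, [list(range(20)), list(range(20, 40))], rng=0)
        assert out["silhouette_greedy"] > 0.95
        assert out["silhouette_difference_kmeans_pct"] == pytest.approx(0.0, abs=1e-6)

    def test_matches_brute_force_silhouette(self, rng):
        vectors = rng.standard_normal((12, 4))
        clusters = [[0, 1, 2, 3], [4, 5, 6], [7, 8, 9, 10, 11]]
        out = clustering_quality(vectors, clusters, alternatives=())
        # brute-force a_i, b_i
        labels = np.empty(12, int)
        for ci, m in enumerate(clusters):
            labels[m] = ci
        d = np.linalg.norm(vectors[:, None] - vectors[None, :], axis=-1)
        svals = []
        for i in range(12):
            same = (labels == labels[i]) & (np.arange(12) != i)
            a_i = d[i, same].mean()
            b_i = min(d[i, labels == c].mean() for c in range(3) if c != labels[i])
            svals.append((b_i - a_i) / max(a_i, b_i))
        assert out["silhouette_greedy"] == pytest.approx(np.mean(svals), abs=1e-10)

    def test_single_cluster_flagged(self, rng):
        out = clustering_quality(rng.standard_normal((10, 3)), [[0, 1, 2]])
        assert out["silhouette_greedy"] is None


class TestFrameShuffleControl:
    def test_derangement_has_no_fixed_points(self, rng):
        for _ in range(50):
            p = _derangement(5, rng)
            assert not np.any(p == np.arange(5))

    def test_time_symmetric_events_fully_retained(self, rng):
        one = rng.standard_normal(60)
        frames = np.stack([np.stack([one + 0.01 * rng.standard_normal(60)] * 5) for _ in range(12)])
        den = denoise_positions(frames, n_components=5)
        retained = frame_shuffle_control(den, [list(range(12))], threshold=0.5, rng=rng)
        assert retained[0] == pytest.approx(1.0)

    def test_temporally_ordered_motifs_lose_membership(self, planted_motifs):
        _, _, den, corr, thr = planted_motifs
        clusters = greedy_cluster(corr, thr)
        retained = frame_shuffle_control(den, clusters, thr, rng=3)
        assert np.mean(list(retained.values())) <= 0.2

    def test_reproducible(self, planted_motifs):
        _, _, den, corr, thr = planted_motifs
        clusters = greedy_cluster(corr, thr)
        r1 = frame_shuffle_control(den, clusters, thr, rng=11)
        r2 = frame_shuffle_control(den, clusters, thr, rng=11)
        assert r1 == r2


def test_full_motif_pipeline_on_session(motif_segmented):
    """End to end on a planted session: clusters recover motif identity."""
    from spontdyn.motifs import analyze_motifs

    config, truth, y, events, geos, motif_ids = motif_segmented
    mc = analyze_motifs(
        events, geos, y.roi, y.pixel_pitch_um,
        t_total_min=y.duration_ms / 60000.0, n_perm=100, min_cluster=5, rng=2,
    )
    assert mc.corr_matrix.shape[0] == mc.subset.n_events
    assert len(mc.clusters) >= config.motif_library_size
    true_l, pred_l = [], []
    for ci, members in enumerate(mc.clusters):
        for i in members:
            true_l.append(motif_ids[mc.subset.event_ids[i]])
            pred_l.append(ci)
    assert adjusted_rand_score(true_l, pred_l) > 0.8
    for cov in mc.coverage:
        assert 0.0 <= cov["Fr"] <= 1.0 and 0.0 <= cov["Fb"] <= 1.0
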