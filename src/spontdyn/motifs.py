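"""Repeated spatiotemporal motifs among fixed-duration events.

Dynamic events of exactly five frames (100 ms at 50 Hz) are band-passed,
PCA-denoised per frame position (20 components), concatenated into one
vector per event, and correlated pairwise.  A within-timestep permutation
null (frames shuffled across events independently at each position, 99th
percentile of pooled permuted correlations) calibrates the repeat
threshold; a greedy algorithm then extracts clusters of mutually repeated
events, whose temporal coverage is summarised by the fractional range Fr
and the fraction of represented 10-minute bins Fb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .events import Event
from .propagation import EventGeometry
from .spatial import FilterSpec, bandpass

logger = logging.getLogger(__name__)

DEFAULT_MOTIF_FRAMES = 5
DEFAULT_N_COMPONENTS = 20
DEFAULT_N_PERM = 1000
DEFAULT_PERCENTILE = 99.0
DEFAULT_MIN_CLUSTER = 10
DEFAULT_BIN_MIN = 10.0


@dataclass
class MotifSubset:
    """Band-passed fixed-duration events ready for comparison.

    ``frames`` is ``(n_events, n_positions, n_roi_pixels)``: each event's
    filtered frames restricted to the ROI, in temporal order.
    """

    frames: np.ndarray
    event_ids: list[int]
    start_times_min: np.ndarray

    @property
    def n_events(self) -> int:
        return self.frames.shape[0]

    @property
    def n_positions(self) -> int:
        return self.frames.shape[1]


@dataclass
class MotifClustering:
    """Result bundle of the motif analysis."""

    subset: MotifSubset
    vectors: np.ndarray
    corr_matrix: np.ndarray
    threshold: float
    repeats: np.ndarray
    frequency: np.ndarray
    clusters: list[list[int]] = field(default_factory=list)   # indices into subset
    coverage: list[dict] = field(default_factory=list)


def select_fixed_duration(
    events: list[Event],
    geometries: list[EventGeometry],
    roi: np.ndarray,
    pixel_pitch_um: float,
    n_frames: int = DEFAULT_MOTIF_FRAMES,
    dynamic_only: bool = True,
    spec: FilterSpec | None = None,
) -> MotifSubset:
    """Band-passed ROI frames of the exactly-``n_frames`` (dynamic) events."""
    spec = spec or FilterSpec()
    keep = []
    for ev, geo in zip(events, geometries):
        if ev.n_frames != n_frames:
            continue
        if dynamic_only and geo.is_static:
            continue
        keep.append(ev)
    frames = np.zeros((len(keep), n_frames, int(roi.sum())), dtype=np.float32)
    for i, ev in enumerate(keep):
        for j in range(n_frames):
            frames[i, j] = bandpass(ev.activity[..., j], roi, spec, pixel_pitch_um)[roi]
    starts = np.array([ev.t_start * ev.frame_interval_ms / 60000.0 for ev in keep])
    return MotifSubset(
        frames=frames,
        event_ids=[ev.event_id for ev in keep],
        start_times_min=starts,
    )


def denoise_positions(
    subset_frames: np.ndarray,
    n_components: int = DEFAULT_N_COMPONENTS,
) -> np.ndarray:
    """PCA-denoise each frame position independently across events.

    For each temporal position the (events x pixels) matrix is projected
    onto its leading ``min(n_components, n_events - 1)`` principal
    components and reconstructed.  Keeping the basis per position matches
    the within-timestep structure of the permutation null.
    """
    n_ev, n_pos, n_px = subset_frames.shape
    k = min(n_components, max(1, n_ev - 1), n_px)
    if k < n_components:
        logger.warning("retaining %d PCA components (requested %d)", k, n_components)
    out = np.empty_like(subset_frames, dtype=np.float64)
    for j in range(n_pos):
        x = subset_frames[:, j, :].astype(np.float64)
        pca = PCA(n_components=k, svd_solver="full")
        out[:, j, :] = pca.inverse_transform(pca.fit_transform(x))
    return out


def concatenate_vectors(denoised: np.ndarray) -> np.ndarray:
    """Concatenate an event's frames into one spatiotemporal vector."""
    n_ev = denoised.shape[0]
    return denoised.reshape(n_ev, -1)


def denoise_and_vectorize(
    subset: MotifSubset, n_components: int = DEFAULT_N_COMPONENTS
) -> np.ndarray:
    return concatenate_vectors(denoise_positions(subset.frames, n_components))


def _rowwise_corr(x: np.ndarray) -> np.ndarray:
    z = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(z, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    z /= norm
    r = z @ z.T
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def correlation_matrix(vectors: np.ndarray) -> np.ndarray:
    """Event-by-event Pearson correlation of concatenated vectors."""
    return _rowwise_corr(np.asarray(vectors, dtype=np.float64))


def within_timestep_null(
    denoised: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    percentile: float = DEFAULT_PERCENTILE,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Permutation threshold for significant event-event correlation.

    Each permutation shuffles frame identity independently at every temporal
    position across events (preserving the shared rise-and-fall envelope),
    recomputes all pairwise correlations of the re-concatenated vectors, and
    pools the off-diagonal values; the threshold is the ``percentile`` of
    the pooled distribution.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_ev, n_pos, _ = denoised.shape
    iu = np.triu_indices(n_ev, k=1)
    pooled = []
    for _ in range(n_perm):
        perm = np.stack(
            [denoised[rng.permutation(n_ev), j, :] for j in range(n_pos)], axis=1
        )
        r = _rowwise_corr(perm.reshape(n_ev, -1))
        pooled.append(r[iu])
    return float(np.percentile(np.concatenate(pooled), percentile))


def repeats_and_frequency(
    corr_matrix: np.ndarray, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-event repeat counts and repeat frequency.

    ``repeats[i]`` counts the other events whose correlation with event i
    exceeds the threshold; frequency divides by the total event count.
    """
    above = corr_matrix > threshold
    np.fill_diagonal(above, False)
    repeats = above.sum(axis=1)
    n = corr_matrix.shape[0]
    return repeats, repeats / n if n else repeats.astype(float)


def greedy_cluster(
    corr_matrix: np.ndarray,
    threshold: float,
    min_cluster: int = DEFAULT_MIN_CLUSTER,
) -> list[list[int]]:
    """Iterative extraction of repeat clusters.

    The remaining event with the most above-threshold partners (ties to the
    lowest index) seeds a cluster consisting of itself and those partners;
    members are removed and the procedure repeats until the next cluster
    would have fewer than ``min_cluster`` events.
    """
    above = corr_matrix > threshold
    np.fill_diagonal(above, False)
    n = corr_matrix.shape[0]
    remaining = np.ones(n, dtype=bool)
    clusters: list[list[int]] = []
    while remaining.any():
        counts = (above & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        seed = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(above[seed] & remaining)
        cluster = sorted([seed, *members.tolist()])
        if len(cluster) < min_cluster:
            break
        clusters.append(cluster)
        remaining[cluster] = False
    return clusters


def temporal_coverage(
    times_min: np.ndarray,
    t_total_min: float,
    bin_min: float = DEFAULT_BIN_MIN,
) -> dict:
    """Fractional range Fr and fraction of represented bins Fb of a cluster.

    ``Fr = (max(t) - min(t)) / t_total``; ``Fb`` is the fraction of
    ``bin_min``-minute session bins containing at least one cluster event.
    """
    t = np.asarray(times_min, dtype=float)
    if t.size == 0:
        raise ValueError("cluster has no events")
    if t_total_min <= 0:
        raise ValueError("t_total_min must be positive")
    fr = float((t.max() - t.min()) / t_total_min)
    n_bins = int(np.ceil(t_total_min / bin_min))
    occupied = np.unique(np.clip((t / bin_min).astype(int), 0, n_bins - 1))
    return {"Fr": fr, "Fb": float(occupied.size / n_bins)}


def clustering_quality(
    vectors: np.ndarray,
    clusters: list[list[int]],
    alternatives: tuple[str, ...] = ("hierarchical", "kmeans"),
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Silhouette of the greedy clustering and percentage difference vs alternatives.

    The greedy silhouette is computed over clustered events only (events in
    no cluster are excluded).  Alternative clusterings (hierarchical,
    k-means) are run on the same vectors with a matched cluster count.
    """
    if len(clusters) < 2:
        return {"silhouette_greedy": None, "flagged": "fewer than 2 clusters"}
    seed = rng if isinstance(rng, (int, np.integer)) else 0
    labels = -np.ones(vectors.shape[0], dtype=int)
    for ci, members in enumerate(clusters):
        labels[members] = ci
    mask = labels >= 0
    s_greedy = float(silhouette_score(vectors[mask], labels[mask]))
    out = {"silhouette_greedy": s_greedy}
    k = len(clusters)
    for name in alternatives:
        if name == "hierarchical":
            alt = AgglomerativeClustering(n_clusters=k).fit_predict(vectors[mask])
        elif name == "kmeans":
            alt = KMeans(n_clusters=k, n_init=10, random_state=int(seed)).fit_predict(
                vectors[mask]
            )
        else:
            raise ValueError(f"unknown clustering method {name!r}")
        s_alt = float(silhouette_score(vectors[mask], alt))
        out[f"silhouette_{name}"] = s_alt
        out[f"silhouette_difference_{name}_pct"] = (
            (s_greedy - s_alt) / s_greedy * 100.0 if s_greedy != 0 else None
        )
    return out


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Permutation of range(n) with no fixed point, by rejection sampling."""
    if n < 2:
        raise ValueError("derangement needs n >= 2")
    while True:
        p = rng.permutation(n)
        if not np.any(p == np.arange(n)):
            return p


def frame_shuffle_control(
    denoised: np.ndarray,
    clusters: list[list[int]],
    threshold: float,
    rng: np.random.Generator | int | None = None,
) -> dict[int, float]:
    """Temporal-order control: deranged frames vs cluster mean vectors.

    Each clustered event's frames are deranged (every frame moves), the
    permuted vector is correlated with each cluster's mean vector, and the
    event is assigned to the best cluster if that correlation beats the
    repeat threshold (else to a null cluster).  Returns the fraction of
    events per cluster that retain their original membership; low retention
    indicates the clustering is driven by temporal order, not just spatial
    pattern.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    vectors = concatenate_vectors(denoised)
    means = np.stack([vectors[m].mean(axis=0) for m in clusters])
    means_z = means - means.mean(axis=1, keepdims=True)
    means_z /= np.linalg.norm(means_z, axis=1, keepdims=True)

    retained: dict[int, float] = {}
    for ci, members in enumerate(clusters):
        hits = 0
        for i in members:
            perm = _derangement(denoised.shape[1], rng)
            vec = denoised[i, perm, :].reshape(-1)
            vz = vec - vec.mean()
            nz = np.linalg.norm(vz)
            if nz == 0:
                continue
            r = means_z @ (vz / nz)
            best = int(np.argmax(r))
            if r[best] > threshold and best == ci:
                hits += 1
        retained[ci] = hits / len(members)
    return retained


def analyze_motifs(
    events: list[Event],
    geometries: list[EventGeometry],
    roi: np.ndarray,
    pixel_pitch_um: float,
    t_total_min: float,
    n_frames: int = DEFAULT_MOTIF_FRAMES,
    n_components: int = DEFAULT_N_COMPONENTS,
    n_perm: int = DEFAULT_N_PERM,
    percentile: float = DEFAULT_PERCENTILE,
    min_cluster: int = DEFAULT_MIN_CLUSTER,
    bin_min: float = DEFAULT_BIN_MIN,
    rng: np.random.Generator | int | None = None,
) -> MotifClustering:
    """Full motif pipeline: selection through coverage metrics."""
    subset = select_fixed_duration(events, geometries, roi, pixel_pitch_um, n_frames)
    denoised = denoise_positions(subset.frames, n_components)
    vectors = concatenate_vectors(denoised)
    corr = correlation_matrix(vectors)
    threshold = within_timestep_null(denoised, n_perm=n_perm, percentile=percentile, rng=rng)
    repeats, freq = repeats_and_frequency(corr, threshold)
    clusters = greedy_cluster(corr, threshold, min_cluster=min_cluster)
    coverage = [
        temporal_coverage(subset.start_times_min[m], t_total_min, bin_min) for m in clusters
    ]
    return MotifClustering(
        subset=subset,
        vectors=vectors,
        corr_matrix=corr,
        threshold=threshold,
        repeats=repeats,
        frequency=freq,
        clusters=clusters,
        coverage=coverage,
    )
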