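"""Template spatial motifs and trajectory decoding.

Frames from short events (<= 200 ms) are each fit with a 2-D multi-Gaussian
(one component per connected active region) to form template patterns.  A
per-template membership threshold is the worst correlation between the
template and copies of itself translated up to one SD.  A greedy pass
groups events by their best-matching template (one frame per event), and an
SVM decoder quantifies for how long before/after the template frame the
group identity remains separable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .events import STRUCT_3X3, Event
from .movie import PixelMovie

logger = logging.getLogger(__name__)

DEFAULT_MAX_DURATION_MS = 200.0
DEFAULT_TOP_K = 7
DEFAULT_MIN_MEMBERS = 15
DEFAULT_N_PC = 8
DEFAULT_N_SUBSAMPLE = 100
DEFAULT_N_SHUFFLE = 100
DEFAULT_OFFSET_MAX_MS = 2000.0
MAX_GAUSSIANS = 10


@dataclass
class FramePool:
    """All frames of qualifying short events."""

    frames: np.ndarray           # (n, rows, cols) deconvolved activity
    masks: np.ndarray            # (n, rows, cols) active-pixel masks
    event_ids: np.ndarray        # event id per frame
    frame_times_ms: np.ndarray   # absolute frame start time per frame

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass
class TemplateFit:
    """Multi-Gaussian fit of one frame."""

    pattern: np.ndarray
    params: np.ndarray            # (K, 5): amplitude, row0, col0, sd_row, sd_col
    converged: bool
    sd_px: float                  # geometric-mean SD of the sharpest component
    threshold_sds: tuple[float, float] | None = None  # (sd_row, sd_col) of that component

    @property
    def n_components(self) -> int:
        return self.params.shape[0]


@dataclass
class TemplateGroup:
    template_index: int
    threshold: float
    members: list[tuple[int, int, float]]   # (event_id, pool frame index, r)
    group_rank: int = 0

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class AccuracyCurve:
    """Per-offset decoding accuracy of template-group identity."""

    offsets_ms: np.ndarray
    accuracy: np.ndarray            # (n_offsets, n_subsample), NaN where invalid
    mean_accuracy: np.ndarray
    significant: np.ndarray         # bool per offset
    valid: np.ndarray               # bool per offset (enough frames in range)


def collect_frames(
    events: list[Event],
    movie: PixelMovie,
    max_duration_ms: float = DEFAULT_MAX_DURATION_MS,
) -> FramePool:
    """All frames of events no longer than ``max_duration_ms`` (inclusive)."""
    frames, masks, ids, times = [], [], [], []
    for ev in events:
        if ev.duration_ms > max_duration_ms:
            continue
        for j in range(ev.n_frames):
            frames.append(ev.activity[..., j])
            masks.append(ev.masks[..., j])
            ids.append(ev.event_id)
            times.append((ev.t_start + j) * movie.frame_interval_ms)
    if not frames:
        h, w = movie.grid_shape
        return FramePool(
            frames=np.zeros((0, h, w), dtype=np.float32),
            masks=np.zeros((0, h, w), dtype=bool),
            event_ids=np.zeros(0, dtype=int),
            frame_times_ms=np.zeros(0),
        )
    return FramePool(
        frames=np.stack(frames),
        masks=np.stack(masks),
        event_ids=np.asarray(ids),
        frame_times_ms=np.asarray(times, dtype=float),
    )


def _gaussian_sum(params: np.ndarray, rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
    out = np.zeros(rr.shape, dtype=float)
    for amp, r0, c0, sr, sc in params:
        out += amp * np.exp(
            -((rr - r0) ** 2) / (2.0 * sr**2) - ((cc - c0) ** 2) / (2.0 * sc**2)
        )
    return out


def _moment_init(
    frame: np.ndarray,
    mask: np.ndarray,
    cap: int = MAX_GAUSSIANS,
    peak_min_distance: int = 4,
) -> np.ndarray:
    """One elliptical Gaussian per local activity peak.

    Peaks of the masked frame (minimum separation ``peak_min_distance``
    pixels, strongest first, capped at ``cap``) seed the components;
    each SD comes from activity-weighted moments in the peak's local
    neighbourhood.  Seeding per peak rather than per connected component
    keeps one Gaussian per module even when adjacent active modules merge
    into a single component.
    """
    from skimage.feature import peak_local_max

    vals = np.where(mask, np.clip(frame, 0.0, None), 0.0)
    if not (vals > 0).any():
        raise ValueError("frame has no active component")
    peaks = peak_local_max(
        vals, min_distance=peak_min_distance, num_peaks=cap, exclude_border=False
    )
    if len(peaks) == 0:
        peaks = np.array([np.unravel_index(np.argmax(vals), vals.shape)])
    win = 2 * peak_min_distance  # moment window half-width
    params = []
    h, w = frame.shape
    for r0i, c0i in peaks:
        r_lo, r_hi = max(0, r0i - win), min(h, r0i + win + 1)
        c_lo, c_hi = max(0, c0i - win), min(w, c0i + win + 1)
        local = vals[r_lo:r_hi, c_lo:c_hi]
        tot = local.sum()
        rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        wv = local / tot
        r0 = float((rr * wv).sum())
        c0 = float((cc * wv).sum())
        sr = float(np.sqrt((((rr - r0) ** 2) * wv).sum()))
        sc = float(np.sqrt((((cc - c0) ** 2) * wv).sum()))
        amp = float(frame[r0i, c0i])
        params.append([amp, r0, c0, max(sr, 0.5), max(sc, 0.5)])
    return np.asarray(params)


def _gaussian_jac(params: np.ndarray, rr: np.ndarray, cc: np.ndarray) -> np.ndarray:
    n = rr.size
    k = params.shape[0]
    jac = np.empty((n, 5 * k))
    for i, (amp, r0, c0, sr, sc) in enumerate(params):
        dr = rr - r0
        dc = cc - c0
        g = np.exp(-(dr**2) / (2.0 * sr**2) - (dc**2) / (2.0 * sc**2))
        jac[:, 5 * i] = g
        jac[:, 5 * i + 1] = amp * g * dr / sr**2
        jac[:, 5 * i + 2] = amp * g * dc / sc**2
        jac[:, 5 * i + 3] = amp * g * dr**2 / sr**3
        jac[:, 5 * i + 4] = amp * g * dc**2 / sc**3
    return jac


def fit_template(
    frame: np.ndarray,
    mask: np.ndarray,
    roi: np.ndarray,
    max_nfev: int = 60,
) -> TemplateFit:
    """Least-squares multi-Gaussian fit of one frame.

    One elliptical component per connected active region (8-connectivity,
    capped at 10), initialised from component moments, with an analytic
    Jacobian.  On optimiser failure (non-finite residuals) the moment-based
    template is returned, flagged unconverged.
    """
    init = _moment_init(frame, mask & roi if (mask & roi).any() else mask)
    rr, cc = np.nonzero(roi)
    target = frame[rr, cc].astype(float)
    k = init.shape[0]

    def resid(p):
        return _gaussian_sum(p.reshape(k, 5), rr, cc) - target

    def jac(p):
        return _gaussian_jac(p.reshape(k, 5), rr, cc)

    x0 = init.ravel()
    lo = np.tile([0.0, -np.inf, -np.inf, 0.3, 0.3], k)
    hi = np.tile([np.inf, np.inf, np.inf, max(frame.shape), max(frame.shape)], k)
    converged = True
    try:
        sol = least_squares(resid, x0, jac=jac, bounds=(lo, hi), max_nfev=max_nfev)
        params = sol.x.reshape(k, 5)
        converged = bool(sol.status > 0)
    except Exception:  # fall back to the moment template
        logger.warning("template fit diverged; using moment-based Gaussians")
        params = init
        converged = False
    pattern = np.zeros(frame.shape)
    pattern[rr, cc] = _gaussian_sum(params, rr, cc)
    # translation scale for the membership threshold: the sharpest component
    # (smallest geometric-mean SD).  Using the widest component instead lets
    # multi-modular templates shift by most of a module period, which
    # collapses the threshold toward zero and yields catch-all groups.
    k_sharp = int(np.argmin(np.sqrt(params[:, 3] * params[:, 4])))
    sd_px = float(np.sqrt(params[k_sharp, 3] * params[k_sharp, 4]))
    return TemplateFit(
        pattern=pattern, params=params, converged=converged, sd_px=sd_px,
        threshold_sds=(float(params[k_sharp, 3]), float(params[k_sharp, 4])),
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    az = a - a.mean()
    bz = b - b.mean()
    na, nb = np.linalg.norm(az), np.linalg.norm(bz)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(az, bz) / (na * nb))


def template_threshold(fit: TemplateFit, roi: np.ndarray) -> float:
    """Membership threshold: worst self-correlation under small translations.

    The template is translated on the integer-pixel grid by every offset
    inside the one-SD ellipse of its sharpest fitted component (for an
    isotropic single Gaussian this is the disk of radius SD) and correlated
    with itself over the ROI; the minimum of these correlations (zero shift
    included, so the threshold never exceeds 1) is returned.
    """
    if fit.threshold_sds is not None:
        sr, sc = fit.threshold_sds
    else:
        sr = sc = fit.sd_px
    base = fit.pattern[roi]
    thr = 1.0
    for dr in range(-int(np.floor(sr)), int(np.floor(sr)) + 1):
        for dc in range(-int(np.floor(sc)), int(np.floor(sc)) + 1):
            if (dr / sr) ** 2 + (dc / sc) ** 2 > 1.0:
                continue
            shifted = np.roll(np.roll(fit.pattern, dr, axis=0), dc, axis=1)
            thr = min(thr, _pearson(base, shifted[roi]))
    return thr


def fit_all_templates(pool: FramePool, roi: np.ndarray) -> tuple[list[TemplateFit], np.ndarray]:
    """Fit every pool frame; returns fits and their membership thresholds."""
    fits, thresholds = [], []
    for i in range(len(pool)):
        if not pool.masks[i].any():
            fits.append(None)
            thresholds.append(np.inf)
            continue
        f = fit_template(pool.frames[i], pool.masks[i], roi)
        fits.append(f)
        thresholds.append(template_threshold(f, roi))
    return fits, np.asarray(thresholds)


def greedy_group(
    pool: FramePool,
    roi: np.ndarray,
    fits: list[TemplateFit] | None = None,
    thresholds: np.ndarray | None = None,
    top_k: int = DEFAULT_TOP_K,
    min_members: int = DEFAULT_MIN_MEMBERS,
) -> list[TemplateGroup]:
    """Group events by their most common single-frame patterns.

    Iteratively selects the template with the most above-threshold matched
    events among those not yet grouped; a matched event contributes its
    single best-correlated frame.  Stops after ``top_k`` groups; groups
    smaller than ``min_members`` are dropped (with a warning if fewer than
    ``top_k`` valid groups exist).
    """
    if fits is None or thresholds is None:
        fits, thresholds = fit_all_templates(pool, roi)
    n = len(pool)
    frames_roi = np.stack([pool.frames[i][roi] for i in range(n)]) if n else np.zeros((0, 0))
    fz = frames_roi - frames_roi.mean(axis=1, keepdims=True)
    fn = np.linalg.norm(fz, axis=1, keepdims=True)
    fn[fn == 0] = 1.0
    fz = fz / fn

    corr = np.full((n, n), -np.inf)
    for ti in range(n):
        if fits[ti] is None:
            continue
        tz = fits[ti].pattern[roi]
        tz = tz - tz.mean()
        ntz = np.linalg.norm(tz)
        if ntz == 0:
            continue
        corr[ti] = fz @ (tz / ntz)

    event_of = pool.event_ids
    remaining = np.ones(n, dtype=bool)      # frame-level availability
    groups: list[TemplateGroup] = []
    for _ in range(top_k):
        best_t, best_events = -1, {}
        for ti in range(n):
            if fits[ti] is None:
                continue
            ok = remaining & (corr[ti] > thresholds[ti])
            ev_best: dict[int, tuple[int, float]] = {}
            for fi in np.flatnonzero(ok):
                ev = int(event_of[fi])
                r = float(corr[ti, fi])
                if ev not in ev_best or r > ev_best[ev][1]:
                    ev_best[ev] = (fi, r)
            if len(ev_best) > len(best_events):
                best_t, best_events = ti, ev_best
        if best_t < 0 or not best_events:
            break
        members = [(ev, fi, r) for ev, (fi, r) in sorted(best_events.items())]
        groups.append(
            TemplateGroup(
                template_index=best_t,
                threshold=float(thresholds[best_t]),
                members=members,
                group_rank=len(groups) + 1,
            )
        )
        grouped_events = set(best_events)
        for fi in range(n):
            if int(event_of[fi]) in grouped_events:
                remaining[fi] = False
    kept = [g for g in groups if len(g) >= min_members]
    if len(kept) < top_k:
        logger.warning("only %d template groups with >= %d members", len(kept), min_members)
    for rank, g in enumerate(kept, start=1):
        g.group_rank = rank
    return kept


def trajectory_decoding(
    groups: list[TemplateGroup],
    pool: FramePool,
    movie: PixelMovie,
    offset_max_ms: float = DEFAULT_OFFSET_MAX_MS,
    offset_step_ms: float | None = None,
    n_pc: int = DEFAULT_N_PC,
    n_subsample: int = DEFAULT_N_SUBSAMPLE,
    n_shuffle: int = DEFAULT_N_SHUFFLE,
    rng: np.random.Generator | int | None = None,
    svm_c: float = 1.0,
) -> AccuracyCurve:
    """How long group identity stays decodable around the template frame.

    For each time offset, the session frame at (template frame time +
    offset) of every member event is projected onto the first ``n_pc``
    principal components fit at that offset only; groups are size-matched by
    subsampling (``n_subsample`` draws) and decoded with an RBF-kernel SVM
    under stratified 5-fold cross-validation.  An offset is significant when
    at least 95% of subsamples beat the 95th percentile of their own
    label-shuffle accuracies.
    """
    if len(groups) < 2:
        raise ValueError("trajectory decoding needs at least two groups")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    dt = movie.frame_interval_ms
    if offset_step_ms is None:
        offset_step_ms = dt
    offsets = np.arange(-offset_max_ms, offset_max_ms + 0.5 * offset_step_ms, offset_step_ms)

    t0 = []     # template-frame time per member
    labels = []
    for gi, g in enumerate(groups):
        for _, fi, _ in g.members:
            t0.append(pool.frame_times_ms[fi])
            labels.append(gi)
    t0 = np.asarray(t0)
    labels = np.asarray(labels)
    n_frames = movie.n_frames
    roi = movie.roi

    n_off = offsets.size
    acc = np.full((n_off, n_subsample), np.nan)
    signif = np.zeros(n_off, dtype=bool)
    valid = np.zeros(n_off, dtype=bool)
    m_match = min(np.bincount(labels))

    for oi, off in enumerate(offsets):
        idx = np.rint((t0 + off) / dt).astype(int)
        ok = (idx >= 0) & (idx < n_frames)
        per_group = np.array([np.sum(ok & (labels == gi)) for gi in range(len(groups))])
        if (per_group < 5).any():
            continue  # a group exhausted at this offset: flagged, not failed
        valid[oi] = True
        x_full = movie.data[..., idx[ok]][roi].T        # (n_samples, n_roi)
        y_full = labels[ok]
        k = min(n_pc, x_full.shape[0] - 1, x_full.shape[1])
        z = PCA(n_components=k, svd_solver="full").fit_transform(x_full.astype(np.float64))

        m = min(per_group.min(), m_match)
        sig_count = 0
        for si in range(n_subsample):
            take = np.concatenate(
                [
                    rng.choice(np.flatnonzero(y_full == gi), size=m, replace=False)
                    for gi in range(len(groups))
                ]
            )
            zs, ys = z[take], y_full[take]
            cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=int(rng.integers(2**31)))
            clf = SVC(kernel="rbf", C=svm_c, gamma="scale")
            a = cross_val_score(clf, zs, ys, cv=cv).mean()
            acc[oi, si] = a
            shuff = np.empty(n_shuffle)
            for hi in range(n_shuffle):
                yp = rng.permutation(ys)
                shuff[hi] = cross_val_score(clf, zs, yp, cv=cv).mean()
            if a > np.percentile(shuff, 95):
                sig_count += 1
        signif[oi] = sig_count >= 0.95 * n_subsample
    return AccuracyCurve(
        offsets_ms=offsets,
        accuracy=acc,
        mean_accuracy=np.nanmean(acc, axis=1),
        significant=signif,
        valid=valid,
    )
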