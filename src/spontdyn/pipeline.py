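"""Configuration and the end-to-end pipeline driver.

``PipelineConfig`` aggregates every stage parameter at its reference
default; ``run_pipeline`` executes preprocess -> events -> spatial ->
propagation -> motifs -> templates on a loaded or simulated session,
writing each stage's outputs plus a manifest (config hash, seed, stage
files) under an output directory.  Stages whose outputs already exist
under the same config hash are skipped, making runs resumable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import events as ev_mod
from . import io as io_mod
from . import motifs as motif_mod
from . import preprocess as pp
from . import templates as tpl_mod
from .movie import PixelMovie
from .propagation import (
    axial_direction_stats,
    classify_events,
    fit_linear_wave,
    onset_times,
    velocity_ceiling,
    wave_significance,
)
from .spatial import FilterSpec, bandpass, wavelength
from .synthetic import SimConfig, synthesize_session

logger = logging.getLogger(__name__)

STAGE_ORDER = ("preprocess", "events", "spatial", "propagation", "motifs", "templates")


@dataclass
class PipelineConfig:
    """All stage parameters, at the pipeline's reference defaults."""

    # preprocess
    gamma: float = 0.89
    baseline_rank: float = 0.36
    baseline_window_s: float | None = 28.5
    # events
    k_sd: float = 4.0
    min_component_mm2: float = 0.028
    min_event_mm2: float = 1.0
    # spatial
    s_low_um: float = 23.0
    s_high_um: float = 194.0
    n_surrogates: int = 100
    rotation_step_deg: float = 10.0
    band_mm: tuple[float, float] = (1.3, 1.7)
    min_peak_sep_um: float = 800.0
    # propagation
    n_dilations: int = 9
    min_wave_frames: int = 5
    n_perm_wave: int = 100
    fov_diameter_mm: float = 3.0
    # motifs
    motif_frames: int = 5
    n_pca_motif: int = 20
    n_perm_motif: int = 1000
    motif_percentile: float = 99.0
    min_cluster: int = 10
    bin_min: float = 10.0
    # templates
    template_max_ms: float = 200.0
    top_k: int = 7
    min_members: int = 15
    n_pc: int = 8
    offset_max_ms: float = 2000.0
    n_subsample: int = 100
    n_shuffle: int = 100
    # global
    seed: int = 0
    simulate: SimConfig | None = None

    def filter_spec(self) -> FilterSpec:
        return FilterSpec(self.s_low_um, self.s_high_um)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if d.get("simulate") is not None:
            sim = d["simulate"]
            for key in ("grid_shape", "static_area_px", "quiet_range_s"):
                if sim.get(key) is not None:
                    sim[key] = tuple(sim[key])
            d["simulate"] = SimConfig(**sim)
        if d.get("band_mm") is not None:
            d["band_mm"] = tuple(d["band_mm"])
        return cls(**d)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    out_dir: Path
    manifest: dict
    movie: PixelMovie | None = None
    events: list = field(default_factory=list)
    geometries: list = field(default_factory=list)
    fits: list = field(default_factory=list)
    wavelengths: np.ndarray | None = None
    motifs: motif_mod.MotifClustering | None = None
    groups: list = field(default_factory=list)


def _load_manifest(out_dir: Path) -> dict:
    p = out_dir / "manifest.json"
    if p.exists():
        return json.loads(p.read_text())
    return {"stages": {}}


def _save_manifest(out_dir: Path, manifest: dict) -> None:
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_pipeline(
    config: PipelineConfig,
    movie: PixelMovie | None = None,
    out_dir="spontdyn_out",
    stages: tuple[str, ...] = STAGE_ORDER,
) -> PipelineResult:
    """Run the analysis end to end.

    ``movie`` may be a raw :class:`PixelMovie`; with ``config.simulate``
    set, a synthetic session is generated instead.  Outputs land under
    ``out_dir``; a stage is recomputed only if its outputs are missing or
    the config hash changed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(out_dir)
    cfg_hash = config.hash()
    if manifest.get("config_hash") not in (None, cfg_hash):
        logger.info("config changed; recomputing all stages")
        manifest = {"stages": {}}
    manifest.update(
        {"config_hash": cfg_hash, "seed": config.seed, "version": __version__}
    )
    config.to_yaml(out_dir / "config.yaml")
    rng = np.random.default_rng(config.seed)

    if movie is None:
        if config.simulate is None:
            raise ValueError("provide a movie or set config.simulate")
        movie, truth = synthesize_session(config.simulate)
        from .synthetic import ground_truth_to_json

        ground_truth_to_json(truth, out_dir / "ground_truth.json")
        manifest["stages"]["simulate"] = {"outputs": ["ground_truth.json"]}

    result = PipelineResult(out_dir=out_dir, manifest=manifest)
    apix = movie.pixel_area_mm2

    def done(stage: str) -> bool:
        info = manifest["stages"].get(stage)
        return bool(info) and all((out_dir / f).exists() for f in info["outputs"])

    # -- preprocess --------------------------------------------------------
    y_path = out_dir / "deconvolved.h5"
    if "preprocess" in stages and not done("preprocess"):
        y = pp.preprocess(
            movie,
            gamma=config.gamma,
            rank=config.baseline_rank,
            window_s=config.baseline_window_s,
        )
        io_mod.write_movie(y_path, y)
        manifest["stages"]["preprocess"] = {"outputs": ["deconvolved.h5"]}
        _save_manifest(out_dir, manifest)
    else:
        y = io_mod.read_movie(y_path) if y_path.exists() else None
    result.movie = y
    if y is None:
        return result

    # -- events ------------------------------------------------------------
    mask = ev_mod.clean_mask(
        ev_mod.active_mask(y, k_sd=config.k_sd), apix, config.min_component_mm2
    )
    events = ev_mod.filter_events(
        ev_mod.segment_events(mask, y), apix, config.min_event_mm2
    )
    geos = classify_events(events, y, n_dilations=config.n_dilations)
    result.events, result.geometries = events, geos
    if "events" in stages:
        io_mod.write_event_table(out_dir / "events.csv", events, geos)
        manifest["stages"]["events"] = {
            "outputs": ["events.csv"],
            "n_events": len(events),
            "n_static": int(sum(g.is_static for g in geos)),
        }
        _save_manifest(out_dir, manifest)

    spec = config.filter_spec()

    # -- spatial -----------------------------------------------------------
    if "spatial" in stages and events:
        lams = []
        for ev in events:
            t = ev_mod.max_active_frame(ev)
            lam = wavelength(ev.activity[..., t], y.roi, y.pixel_pitch_um, spec)
            lams.append(np.nan if lam is None else lam)
        result.wavelengths = np.asarray(lams)
        np.savetxt(out_dir / "wavelengths_mm.csv", result.wavelengths, header="wavelength_mm")
        manifest["stages"]["spatial"] = {
            "outputs": ["wavelengths_mm.csv"],
            "median_wavelength_mm": float(np.nanmedian(result.wavelengths)),
        }
        _save_manifest(out_dir, manifest)

    # -- propagation -------------------------------------------------------
    if "propagation" in stages and events:
        fits = []
        for ev, geo in zip(events, geos):
            if geo.is_static or ev.touches_boundary:
                fits.append(None)
                continue
            t_on, coords = onset_times(ev, y.roi, y.pixel_pitch_um)
            fit = fit_linear_wave(t_on, coords)
            fit = (
                wave_significance(
                    ev,
                    y.roi,
                    y.pixel_pitch_um,
                    fit=fit,
                    n_perm=config.n_perm_wave,
                    min_frames=config.min_wave_frames,
                    rng=rng,
                )
                or fit
            )
            fits.append(fit)
        result.fits = fits
        io_mod.write_event_table(out_dir / "wave_fits.csv", events, geos, fits)
        ceiling = velocity_ceiling(config.fov_diameter_mm, y.frame_interval_ms)
        sig = [
            f
            for f in fits
            if f is not None and f.significant and f.v_mm_s is not None and f.v_mm_s <= ceiling
        ]
        stats = (
            axial_direction_stats(np.array([f.theta_deg for f in sig]))
            if len(sig) >= 10
            else {"note": "fewer than 10 significant fits"}
        )
        (out_dir / "direction_stats.json").write_text(json.dumps(stats, indent=2))
        manifest["stages"]["propagation"] = {
            "outputs": ["wave_fits.csv", "direction_stats.json"],
            "n_significant_linear": len(sig),
            "velocity_ceiling_mm_s": ceiling,
        }
        _save_manifest(out_dir, manifest)

    # -- motifs ------------------------------------------------------------
    if "motifs" in stages and events:
        mc = motif_mod.analyze_motifs(
            events,
            geos,
            y.roi,
            y.pixel_pitch_um,
            t_total_min=y.duration_ms / 60000.0,
            n_frames=config.motif_frames,
            n_components=config.n_pca_motif,
            n_perm=config.n_perm_motif,
            percentile=config.motif_percentile,
            min_cluster=config.min_cluster,
            bin_min=config.bin_min,
            rng=rng,
        )
        result.motifs = mc
        payload = {
            "threshold": mc.threshold,
            "clusters": [
                {
                    "event_ids": [mc.subset.event_ids[i] for i in members],
                    **mc.coverage[ci],
                }
                for ci, members in enumerate(mc.clusters)
            ],
        }
        (out_dir / "motif_clusters.json").write_text(json.dumps(payload, indent=2))
        manifest["stages"]["motifs"] = {
            "outputs": ["motif_clusters.json"],
            "n_clusters": len(mc.clusters),
        }
        _save_manifest(out_dir, manifest)

    # -- templates ---------------------------------------------------------
    if "templates" in stages and events:
        pool = tpl_mod.collect_frames(events, y, config.template_max_ms)
        groups = []
        if len(pool):
            groups = tpl_mod.greedy_group(
                pool, y.roi, top_k=config.top_k, min_members=config.min_members
            )
        result.groups = groups
        payload = [
            {
                "rank": g.group_rank,
                "threshold": g.threshold,
                "members": [
                    {"event_id": int(e), "frame": int(f), "r": float(r)}
                    for e, f, r in g.members
                ],
            }
            for g in groups
        ]
        (out_dir / "template_groups.json").write_text(json.dumps(payload, indent=2))
        outputs = ["template_groups.json"]
        if len(groups) >= 2:
            curve = tpl_mod.trajectory_decoding(
                groups,
                pool,
                y,
                offset_max_ms=config.offset_max_ms,
                n_pc=config.n_pc,
                n_subsample=config.n_subsample,
                n_shuffle=config.n_shuffle,
                rng=rng,
            )
            np.savetxt(
                out_dir / "accuracy_curve.csv",
                np.column_stack([curve.offsets_ms, curve.mean_accuracy, curve.significant]),
                header="offset_ms,mean_accuracy,significant",
                delimiter=",",
            )
            outputs.append("accuracy_curve.csv")
        manifest["stages"]["templates"] = {"outputs": outputs, "n_groups": len(groups)}
        _save_manifest(out_dir, manifest)

    return result
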