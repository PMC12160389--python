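"""Reading and writing movies, ROIs, ground truth, and result tables.

Movies travel as multi-page TIFF (uint16, scaled, or float32) or HDF5
(float32 with metadata attributes); ROIs as PNG masks or run-length JSON;
tables as CSV via pandas.  All spatial outputs carry the pixel pitch and
the frame interval so downstream stages stay unit-consistent.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .movie import PixelMovie

_H5_DATASET = "movie"


def write_movie(path, movie: PixelMovie, dtype: str = "float32") -> None:
    """Write a movie as multi-page TIFF (.tif) or HDF5 (.h5/.hdf5).

    TIFF pages are frames.  ``dtype='uint16'`` scales the data to the full
    uint16 range and stores the scale in the metadata; ``float32`` stores
    values verbatim.
    """
    path = Path(path)
    meta = {
        "pixel_pitch_um": movie.pixel_pitch_um,
        "frame_interval_ms": movie.frame_interval_ms,
        "stage": movie.stage,
    }
    frames_first = np.moveaxis(movie.data, -1, 0)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset(_H5_DATASET, data=movie.data.astype(np.float32))
            for k, v in meta.items():
                ds.attrs[k] = v
            fh.create_dataset("roi", data=movie.roi.astype(np.uint8))
        return
    if dtype == "uint16":
        lo = float(frames_first.min())
        hi = float(frames_first.max())
        scale = (hi - lo) / 65535.0 if hi > lo else 1.0
        arr = np.round((frames_first - lo) / scale).astype(np.uint16)
        meta.update({"scale": scale, "offset": lo})
    else:
        arr = frames_first.astype(np.float32)
    tifffile.imwrite(path, arr, metadata=meta)


def read_movie(path, roi: np.ndarray | None = None) -> PixelMovie:
    """Read a movie written by :func:`write_movie`."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            ds = fh[_H5_DATASET]
            data = ds[...]
            meta = dict(ds.attrs)
            roi_file = fh["roi"][...].astype(bool) if "roi" in fh else None
        roi = roi if roi is not None else roi_file
    else:
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        data = np.moveaxis(arr, 0, -1).astype(np.float32)
        if "scale" in meta:
            data = data * float(meta["scale"]) + float(meta["offset"])
    if roi is None:
        roi = np.ones(data.shape[:2], dtype=bool)
    if roi.shape != data.shape[:2]:
        raise ValueError(
            f"ROI shape {roi.shape} does not match movie grid {data.shape[:2]}"
        )
    return PixelMovie(
        data=np.ascontiguousarray(np.moveaxis(np.moveaxis(data, -1, 0), 0, -1)),
        roi=np.asarray(roi, dtype=bool),
        pixel_pitch_um=float(meta.get("pixel_pitch_um", 46.9)),
        frame_interval_ms=float(meta.get("frame_interval_ms", 20.0)),
        stage=str(meta.get("stage", "raw")),
    )


def write_roi(path, roi: np.ndarray) -> None:
    """ROI as PNG mask (.png) or run-length JSON (.json)."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        Image.fromarray((roi.astype(np.uint8)) * 255).save(path)
        return
    flat = roi.ravel().astype(np.int8)
    edges = np.flatnonzero(np.diff(flat)) + 1
    runs = np.diff(np.concatenate([[0], edges, [flat.size]])).tolist()
    payload = {"shape": list(roi.shape), "first": int(flat[0]), "runs": runs}
    path.write_text(json.dumps(payload))


def read_roi(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        return np.asarray(Image.open(path)) > 0
    payload = json.loads(path.read_text())
    vals = []
    v = payload["first"]
    for run in payload["runs"]:
        vals.append(np.full(run, v, dtype=bool))
        v = 1 - v
    return np.concatenate(vals).reshape(payload["shape"])


def write_event_table(path, events, geometries=None, fits=None) -> pd.DataFrame:
    """Per-event CSV: frame range, duration, areas, wave-fit parameters."""
    rows = []
    for i, ev in enumerate(events):
        row = {
            "event_id": ev.event_id,
            "t_start": ev.t_start,
            "t_end": ev.t_end,
            "duration_ms": ev.duration_ms,
            "touches_boundary": ev.touches_boundary,
        }
        if geometries is not None:
            g = geometries[i]
            row.update(
                {
                    "area_mm2": g.a_active_mm2,
                    "ra": g.ra,
                    "pa_mm2": g.pa_mm2,
                    "is_static": g.is_static,
                }
            )
        if fits is not None and fits[i] is not None:
            f = fits[i]
            row.update(
                {
                    "v_mm_s": f.v_mm_s,
                    "theta_deg": f.theta_deg,
                    "mse_ms2": f.mse_ms2,
                    "significant": f.significant,
                }
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
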