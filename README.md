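# spontdyn

Spatiotemporal analysis of millimetre-scale spontaneous activity in
wide-field calcium imaging of the developing cortex.

Early visual cortex produces spontaneous events — brief (tens to hundreds
of milliseconds) episodes in which spatially segregated *modules* of
coactive neurons, spaced roughly 0.7 mm apart, light up across several
millimetres of cortical surface. Characterising how these patterns move
and repeat requires imaging fast (50 Hz) and undoing the calcium
indicator's decay. `spontdyn` implements the full analysis chain for such
recordings, plus a ground-truth synthetic movie generator so that every
stage can be validated by parameter recovery without any animal data:

1. **Preprocessing** — running 36th-percentile baseline F0 over a 28.5 s
   window; ΔF/F `r_pt = (F_pt − F0_pt)/F0_pt`; prior-frame-subtraction
   deconvolution `y_pt = r_pt − γ·r_{p,t−1}` with γ = 0.89 per 20 ms frame
   (GCaMP8m).
2. **Event segmentation** — per-pixel threshold at mean + 4 SD, binary
   opening plus a 0.028 mm² contiguous-area rule, events as maximal runs of
   active frames bounded by inactive frames, and a 1 mm² total-area filter.
3. **Correlation networks** — seed-point Pearson correlation maps across
   the maximally active frame of each event (23/194 µm difference-of-
   Gaussians band-pass), with significance of long-range (1.3–1.7 mm)
   correlations against an ensemble of randomly rotated/reflected surrogate
   frames.
4. **Wavelength** — twice the radius of the first minimum of the radially
   averaged spatial autocorrelation.
5. **Propagation** — the propagation area PA (ever-active area beyond a
   ~420 µm exclusion zone around the onset frame, nine 3×3 dilations);
   PA = 0 defines *static* events, PA > 0 *dynamic* ones.
6. **Linear wavefronts** — fit of per-pixel onset times to the planar model
   `t̂_ON = x_p·[cos θ, sin θ]/v + t_SHIFT` by MSE minimisation, a
   frame-permutation significance test, the 150 mm/s detectability ceiling
   for a 3 mm window at 50 Hz, and Rayleigh/binomial statistics of the
   propagation axis.
7. **Repeated motifs** — event–event correlation of PCA-denoised,
   frame-concatenated 100 ms events, a within-timestep permutation null
   (99th percentile), greedy clustering (≥ 10 events per cluster), and the
   temporal-coverage metrics `Fr = (max t − min t)/t_TOTAL` and `Fb` =
   fraction of occupied 10-min bins.
8. **Template trajectories** — multi-Gaussian template patterns fit to
   frames of short events, translation-derived membership thresholds,
   greedy grouping, and an SVM decoder measuring for how long (±2 s) group
   identity stays above chance.

## Worked example

```python
import numpy as np
from spontdyn import SimConfig, synthesize_session, preprocess_movie
from spontdyn import events as ev
from spontdyn.propagation import classify_events, fit_linear_wave, onset_times, velocity_ceiling
from spontdyn.spatial import wavelength
from spontdyn.events import max_active_frame

config = SimConfig(n_events=100, seed=0)          # 46.9 µm pixels, 50 Hz, 3 mm FOV
movie, truth = synthesize_session(config)
y = preprocess_movie(movie, window_s=None)        # baseline, ΔF/F, deconvolution
mask = ev.clean_mask(ev.active_mask(y), y.pixel_area_mm2)
events = ev.filter_events(ev.segment_events(mask, y), y.pixel_area_mm2)
geos = classify_events(events, y)

n_static = sum(g.is_static for g in geos)
print(f"{len(events)} events detected ({len(truth)} planted); "
      f"{n_static} static ({100*n_static/len(events):.1f}%)")

lams = [wavelength(e.activity[..., max_active_frame(e)], y.roi, y.pixel_pitch_um)
        for e in events]
print(f"median wavelength: {np.nanmedian([l for l in lams if l]):.2f} mm")

fits = []
for e, g in zip(events, geos):
    if g.is_static or e.touches_boundary:
        continue
    t_on, coords = onset_times(e, y.roi, y.pixel_pitch_um)
    fits.append(fit_linear_wave(t_on, coords))
ceiling = velocity_ceiling(config.fov_diameter_mm, config.frame_interval_ms)
v = [f.v_mm_s for f in fits if f.v_mm_s and f.v_mm_s <= ceiling]
print(f"{len(v)} wavefront fits below the {ceiling:.0f} mm/s ceiling; "
      f"median speed {np.median(v):.1f} mm/s")
```

Output:

```
100 events detected (100 planted); 7 static (7.0%)
median wavelength: 0.65 mm
93 wavefront fits below the 150 mm/s ceiling; median speed 34.4 mm/s
```

The session plants 6.9% static events (7 of 100 — all recovered by the
PA = 0 rule), modular patterns at 0.69 mm wavelength, and planar waves at
32 mm/s; the wavefront-speed median here also includes the complex
(non-planar) motif events, so it sits a little above the planted wave
speed.

## Command line

A thin CLI wraps the library:

```bash
spontdyn simulate --n-events 100 --seed 0 --out-dir run/
spontdyn events   --movie run/raw.h5 --out-dir run/
spontdyn run      --simulate --n-events 100 --out-dir run/   # full pipeline
```

Each stage writes CSV/JSON/HDF5 outputs plus a `manifest.json` (config
hash, seed, stage outputs); re-running skips completed stages.

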