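# colomap

Quantitative assessment of colonic motility from two simultaneously acquired
modalities — cine-MRI of the descending colon and multi-channel intraluminal
manometry — plus a coupled synthetic peristalsis phantom that makes the whole
pipeline testable without clinical data.

## Who this is for

Researchers comparing image-based and pressure-based measures of colonic
motor activity: paediatric gastroenterology groups evaluating cine-MRI as a
non-invasive alternative to colonic manometry, and methods developers who
need a ground-truthed test bed for spatiotemporal motility analysis.

## What it computes

**Imaging arm** (`colomap.motility_map`). Given a cine image series (one
sagittal slice, ~1 frame/s), a user-drawn midline and a wall corridor, the
software casts lines perpendicular to the midline every Δs (default 2 mm)
and measures the luminal diameter d(s, t) along each line in every frame by
sub-pixel half-maximum edge detection. Motility is summarised two ways:

- frame-to-frame activity Δd(s, t) = d(s, t+1) − d(s, t);
- the **spatiotemporal residual map**: per position s, an ordinary
  least-squares line a_s + b_s·t is fitted to the diameter time series and

  r(s, t) = d(s, t) − (a_s + b_s·t).

  Negative residuals mean a lumen narrower than its trend — a contraction. A
  propagating contraction appears as a sloped band in the (t, s) plane whose
  slope is its velocity. The rendered plot maps deep troughs to red,
  intermediate narrowing to yellow and no change to blue.

**Manometry arm** (`colomap.manometry`). Pressure traces from a
water-perfused catheter (recording sites every 10 cm) are baselined with a
centred rolling median, thresholded into per-channel contraction events, and
chained across adjacent channels. A chain is a **high-amplitude propagating
contraction (HAPC)** iff it propagates antegradely over at least three
adjacent recording sites with every participating contraction reaching
60 mmHg above baseline. The propagation velocity is the least-squares slope
of sensor position versus onset time.

**Concordance** (`colomap.concordance`). Both arms are put on a common clock,
restricted to the manometry channels visible in the imaged segment, and each
HAPC window is labelled *high* / *minimal* / *absent* by the depth of the
residual trough near the included channels (windows outside the acquisition
are *not recorded*). Counts, round-half-up integer percentages and
image-only activity episodes make up the agreement summary.

**Phantom** (`colomap.phantom`). One ground-truth diameter field
D(s, t) = clamp(D₀ · Π_k [1 − A_k exp(−(s − s0_k − v_k(t − t0_k))² / 2σ_k²)], floor, D₀)
drives both simulated modalities: rendered bright-lumen frames (with
breathing displacement and noise) and pressure traces
P_i(t) = baseline + P_max · max(0, 1 − D(s_i, t)/D₀)^γ, emulating port
occlusion of a water-perfused catheter. Event windows and per-sensor arrival
times are known in closed form, so both arms can be scored exactly.

## Worked example

```python
import numpy as np
import colomap as cm

# a 30-min coupled phantom session with three antegrade contraction waves
cfg, _ = cm.phantom.reference_session_config(seed=0)
truth = cm.simulate_diameter_field(cfg)
frames = cm.render_frames(truth, cfg)
pressure = cm.simulate_manometry(truth, cfg)

# manometry arm: contraction events -> HAPCs
events = cm.detect_contractions(pressure, min_amplitude_mmhg=20.0)
hapcs = cm.detect_hapcs(events, pressure)
print(f"{len(hapcs)} HAPCs detected from {len(events)} contraction events")
for h in hapcs:
    print(f"  sites {h.channels}, weakest peak {h.min_amplitude_mmhg:.0f} mmHg, "
          f"velocity {h.velocity_mm_s:.2f} mm/s, window {h.window_s[0]:.0f}-{h.window_s[1]:.0f} s")

# imaging arm: diameters -> residual motility map
curve = cm.MidlineCurve(points_mm=cfg.midline_points_mm)
diams = cm.measure_diameters(frames, curve, cm.phantom.wall_corridor(cfg), spacing_mm=2.0)
rmap = cm.residual_map(diams)
print(f"deepest residual trough: {-np.min(rmap.residuals_mm[rmap.valid]):.1f} mm")

# concordance: label imaged activity during each HAPC window
session = cm.AlignedSession(
    rmap=rmap, hapcs=hapcs, clock_offset_s=0.0,
    channel_positions_mm=np.asarray(cfg.sensor_positions_mm),
    imaged_segment_mm=(0.0, cfg.midline_arclength_mm))
cls = [cm.classify_mri_activity(session, h) for h in hapcs]
summary = cm.concordance_summary(cls)
print("labels during HAPC windows:", [c.label for c in cls])
print("percentages:", {k: v for k, v in summary.percentages.items() if v})
```

prints

```
3 HAPCs detected from 12 contraction events
  sites [0, 1, 2, 3], weakest peak 80 mmHg, velocity 10.00 mm/s, window 302-339 s
  sites [0, 1, 2, 3], weakest peak 70 mmHg, velocity 7.93 mm/s, window 801-849 s
  sites [0, 1, 2, 3], weakest peak 85 mmHg, velocity 11.90 mm/s, window 1302-1332 s
deepest residual trough: 18.0 mm
labels during HAPC windows: ['high', 'high', 'high']
percentages: {'high': 100}
```

All three simulated waves (true velocities 10, 8 and 12 mm/s) are recovered
by the manometry arm within 1 % and independently labelled as high activity
by the imaging arm.

## Command line

```sh
colomap simulate  --config cfg.yaml --out session/ --seed 1
colomap map       --frames session/frames.nii.gz --midline session/midline.csv \
                  --walls session/wall_a.csv session/wall_b.csv --spacing-mm 2 --out map/
colomap manometry --traces session/pressure.csv --meta session/pressure.yaml --out mano/
colomap compare   --rmap map/residuals.csv --hapcs mano/hapcs.json \
                  --align session/align.yaml --out cmp/
colomap run       --config cfg.yaml --out all/      # the four stages chained
```

Outputs are NIfTI/TIFF image series, CSV matrices (times in the first row,
positions in the first column), JSON event lists and PNG plots; exit code 2
signals a validation problem (e.g. an unknown configuration key).

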