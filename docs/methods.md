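# Methods

## The measurement problem

Colonic manometry senses motility as intraluminal pressure: a contraction of
the colonic wall occludes the ports of a water-perfused catheter, raising
the recorded pressure at that site. Cine-MRI senses the same physiology as a
geometric change: the luminal diameter at a position narrows and relaxes.
The two observables are physically distinct and neither is a simple function
of the other; this package implements each measurement arm explicitly and a
concordance layer that compares their event calls, rather than attempting to
convert one signal into the other.

## Phantom model

The phantom exists so that both arms can be validated against an exact
ground truth. Its core is a lumen-diameter field on an arc-length × time
grid:

```
D(s, t) = clamp( D0 · Π_k [ 1 − A_k · exp(−(s − s0_k − v_k (t − t0_k))² / (2 σ_k²)) · 1{t0_k ≤ t ≤ t_end_k} ],
                 floor, D0 )
```

Each propagating wave is a Gaussian trough in arc-length translating at a
constant velocity. This waveform is a modelling choice, not a measured one:
it is the simplest shape that gives closed-form trough positions, sensor
arrival times `t0 + (s_i − s0)/v` and event windows, which is what a
validation phantom needs. Multiplicative superposition keeps concurrent
waves bounded; the clamp enforces `floor ≤ D ≤ D0` (a lumen never occludes
beyond a residual channel, and the relaxed diameter is the baseline, i.e.
waves only contract).

Background (non-propagating) contractions are drawn from a seeded Poisson
process in time with uniform positions: Gaussian in space (σ = `width_mm`)
with a Hann temporal envelope over `duration_s`, superposed multiplicatively
like the waves. They emulate low-amplitude segmental activity that should
*not* be called an HAPC.

### Image rendering

Frames show a bright-lumen tube of local full width `D(s, t)` centred on the
midline over a dark background — the bright-lumen/dark-wall appearance of a
heavily T2-weighted single-shot acquisition. The tube edge is anti-aliased
over one pixel so the half-maximum intensity crossing sits at the true wall
position; this makes the rendered image a *fair* target for the sub-pixel
edge detector without leaking the detector's own model into the phantom
(the detector is still validated on noisy, breathing-displaced frames).
Breathing is a whole-frame rigid vertical sinusoid (the dominant respiratory
confound in supine free-breathing imaging of the descending colon); image
noise is additive Gaussian. Rician noise statistics and out-of-plane motion
are deliberately not modelled — see Limitations.

### Pressure coupling

Per channel at arc-length `s_i`:

```
P_i(t) = baseline + Pmax · max(0, 1 − D(s_i, t)/D0)^γ + noise,   γ = 1 by default
```

a monotone function of fractional occlusion. The exponent γ is exposed
because the true occlusion–pressure relation of a perfused port is unknown;
γ = 1 makes amplitude arithmetic transparent (occlusion fraction A couples
to a peak excess of A·Pmax).

### Default study conditions

| parameter | default | rationale |
|---|---|---|
| duration | 1800 s | ~30 min of simultaneous recording after stimulant infusion |
| frame interval | 1 s | protocol temporal resolution; a 6 s mode is just a config value (the interval is metadata, never assumed) |
| pixel spacing | 1.5 mm | in-plane resolution typical of a 300–400 mm FOV single-shot sequence |
| baseline diameter D0 | 20 mm | relaxed descending-colon lumen after clean-out |
| occlusion floor | 1 mm | a lumen never vanishes completely on imaging |
| sensor spacing | 100 mm | water-perfused catheter with recording sites every 10 cm |
| sensors in segment | 4 at 50–350 mm | matches a session in which four catheter channels were visible on imaging |
| pressure baseline / gain | 10 / 100 mmHg | resting intraluminal pressure; full occlusion ≈ 110 mmHg, so occlusion fractions ≥ 0.6 clear the 60 mmHg HAPC criterion |
| reference waves | v = 10, 8, 12 mm/s; A = 0.8, 0.7, 0.9; σ = 20, 25, 18 mm | stimulant-induced propagating contractions of the order of 1 cm/s with near-total occlusion |
| breathing | 0–5 mm amplitude, 4 s period | quiet respiration in an adolescent |

All randomness (background events, image noise, pressure noise) flows from a
single config seed through independent named streams, so identical configs
reproduce bit-identical outputs.

## Imaging arm

**Geometry.** The midline is a user input, as in practice; the package never
segments the colon. It is resampled at Δs = 2 mm (default, chosen well below
the spatial width of plausible waves), with centred-difference tangents and
normals by +90° rotation. Endpoint tangents are one-sided, so the two
terminal samples carry a small angular bias of order Δs/(2R) on a curve of
radius R.

**Edge detection.** The user's wall delineation is interpreted as a *search
corridor*: the delineation is drawn once but line lengths change over time,
so the wall must be re-found per frame; searching a corridor (distance to
the drawn wall + margin, default 10 mm) within the perpendicular line is the
reading that reconciles both facts. Intensity is sampled bilinearly at
half-pixel steps; the background level per ray is the median of its
outermost valid quartile; the wall on each side is the first outward
crossing of the half-maximum between midline (lumen) intensity and
background, localised with sub-step linear interpolation. The diameter is
the sum of the two side extents. A cell where either side finds no crossing
— the ray leaves the field of view, the midline sits outside the lumen, the
edge escapes the corridor — is masked invalid and propagated as such, never
imputed and never recorded as 0 mm: an imputed dropout would be
indistinguishable from a contraction.

**Residual map.** One ordinary least-squares line per position over the whole
recording (a windowed alternative exists but is off by default); positions
with fewer than 3 valid frames are masked. Residuals at each fitted position
satisfy the normal equations (Σ r = 0, Σ t·r = 0) to numerical tolerance,
which the tests assert. The plot convention maps strongly negative residuals
to red (contraction), intermediate negative to yellow (minimal activity) and
near-zero to blue, with symmetric colour limits at a configurable quantile
of |r|.

**Velocity from the map.** For a window containing a single band, the trough
position argmin_s r(s, t) is tracked over the frames whose depth reaches 80 %
of the window maximum (where the band is fully developed and unclipped by
the segment ends) and regressed on time. The 80 % gate trades a few frames
of data for robustness against entry/exit truncation bias.

## Manometry arm

**Baseline.** Water-perfused systems drift; the per-channel baseline is a
centred rolling median over 120 s. A median resists contamination by the
contractions themselves, which occupy seconds, not minutes.

**Events.** Candidate events are maximal intervals of excess pressure above
half the detection amplitude (default 20 mmHg), retained when the peak
excess reaches the full amplitude. The onset is the last upward crossing of
20 % of the peak excess before the peak — a level-fraction rule robust to
residual drift — and the end the first downward crossing after it. Onsets
therefore *lead* the trough arrival at a sensor by roughly 1.8 temporal
sigma of the pulse; peaks, not onsets, coincide with arrivals.

**HAPC chaining.** From each unused event in onset order, the chain extends
to the adjacent distal channel's earliest unused event with a strictly later
onset, a lag of at most 60 s and an implied velocity of at most 50 mm/s
(generous gates whose only job is to stop unrelated events chaining). A
chain qualifies iff it spans ≥ 3 adjacent sites and every member reaches
60 mmHg — the per-site reading of the amplitude criterion; a mean-amplitude
mode is provided since the original wording admits both. Events join at most
one HAPC; rejected chains release their events. Because candidate starts are
processed in onset order, the detected set is independent of input order.

**Velocity.** Least-squares slope of sensor position versus onset time;
positive is antegrade. Equal onsets leave the velocity undefined (NaN,
flagged) rather than raising, so batch pipelines survive degenerate chains.

## Concordance

The clock offset between modalities is a required input (it cannot be
inferred from the data and the acquisition protocol does not synchronise the
clocks); shifting both clocks by a common constant changes nothing, which is
asserted as a property. Only channels inside the imaged segment
(half-open interval) participate; zero shared channels is a hard error. Each
HAPC window, padded ±15 s for alignment slack, is scored by the deepest
valid residual trough within half a channel spacing of an included channel:
high ≥ θ_high, minimal ≥ θ_min, else absent. Windows entirely outside the
acquisition are *not recorded* — kept distinct from *absent*, with a merged
view for comparison against reports that fold the two together. Percentages
are integers, rounded half up.

θ_high = 4 mm and θ_min = 1 mm of trough depth are **phantom-calibrated
defaults**: on the reference phantom a near-occlusive wave leaves a trough of
~A·D0 ≈ 14–18 mm and measurement noise stays well under 1 mm, so the
thresholds separate the regimes by an order of magnitude. They are not
clinically validated values; on real data they are mandatory, explicit
parameters.

## What passing tests do and do not show

The phantom validates the *mechanics* of both arms — geometry, edge
localisation, detrending, event chaining, alignment arithmetic — against
exact ground truth, at the full 30 min × 1 frame/s problem size. It does not
establish clinical performance: real recordings add Rician noise,
out-of-plane motion that mimics contraction, haustral texture, catheter
artefacts and genuinely ambiguous low-amplitude activity, none of which the
phantom generates. Agreement results on the phantom are therefore upper
bounds, useful for regression testing and for verifying that a pipeline
change has not broken a measurement, not for claiming sensitivity on
patients.

## Numerical choices and degenerate inputs

- Units: millimetres, seconds, mmHg; all intervals half-open [start, end);
  image origin at the first pixel centre; arc-length origin at the proximal
  midline end; antegrade = increasing arc-length.
- Diameter measurement uses float32 images and half-pixel sampling steps;
  the phantom-recovery requirement (RMSE ≤ 1 pixel spacing) is met with
  ~0.2 mm RMSE at 1.5 mm pixels.
- Least-squares fits use `numpy.polyfit` on valid cells only; positions or
  chains with degenerate spread are masked or flagged, not extrapolated.
- A wave that never enters the imaged segment is a warning with a flag in
  the ground truth, not an error (a session configuration may legitimately
  include it for the manometry arm alone).
- The event-free, noise-free phantom yields activity and residual maps that
  are zero to < 1e-6 mm and zero detected events; this null path is tested.

## Known limitations

- 2-D single-slice geometry only; no out-of-plane motion, no 3-D colon.
- Gaussian image noise (not Rician), rigid vertical breathing only.
- The phantom's pressure coupling is phenomenological; γ is a free knob, not
  a fitted physical constant.
- No low-amplitude motor-pattern taxonomy (cyclic/retrograde patterns) and
  no statistical agreement coefficients — the concordance layer reports raw
  counts and percentages only.
- The imaging-activity thresholds have no normative basis; they are phantom
  calibrations by construction.
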