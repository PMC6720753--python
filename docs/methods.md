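# Methods

This document records the modelling assumptions, parameter choices and
numerical conventions behind `handtherm`. Everything here is testable; the
test suite asserts the stated behaviour and the acceptance script
recomputes the headline numbers end to end.

## 1. Rewarming model

Each finger follows a mono-exponential rewarming law after the cold
challenge is removed:

```
T(t) = T_C + A · (1 − e^(−t/τ)),   0 ≤ t ≤ D
```

with `T_C` the post-cooling temperature (°C), `A` the rewarming amplitude
(°C), `τ` the time constant (s) and `D = 180 s` the observation window.
The area of the rewarming elevation has the closed form

```
S_R = A · (D − τ·(1 − e^(−D/τ)))
```

(`synthetic.closed_form_area`), and `synthetic.solve_tau` inverts it for
`τ` by bracketed root search (`scipy.optimize.brentq`, relative tolerance
1e−6; valid for target areas strictly inside `(0, A·D)`). Cooling is
modelled as a linear drop of `ΔT_C` over the 5 s provocation. The cooling
frames stand in for a phase that a clinical camera cannot observe (the
hand is inside the cooling device); the sequence manifest flags them as
simulated.

Assumptions: no spatial temperature gradient along a finger (each finger
is isothermal at every instant, offset per finger by a fixed ±0.2 °C
spread), a constant palm temperature, a constant ambient background, and
no hand motion during the acquisition.

## 2. Synthetic scene

The default phantom is a 160×160 px scene: a palm ellipse (semi-axes
40×30 px) centred at (112, 78) and five finger capsules radiating fan-like
from that same hub at angles 154°, 122°, 90°, 58°, 26° (thumb→little) with
lengths 70, 93, 102, 96, 78 px and half-width 5 px. The fan layout
guarantees the properties the pipeline relies on: a single connected
silhouette, five skeleton endpoint branches (one per fingertip) plus at
least one palm endpoint, and — because the capsules meet only at the hub —
finger midlines that stay inside their own capsule.

Rendering precedence is finger-over-palm, so a capsule pixel always
carries its finger's temperature even where the finger base overlaps the
palm ellipse. In the narrow wedge where two adjacent capsules overlap, the
earlier (more lateral) finger wins; this can place a single midline pixel
on a neighbour's ±0.1 °C offset, biasing absolute per-finger temperatures
by a few mK. Temperature *changes* and areas are unaffected because every
finger shares the subject's `ΔT_C`, `A` and `τ`.

Default acquisition: 1 Hz (desk-scale; 188 frames = 1 static + 6 cooling
+ 181 rewarming), optional Gaussian sensor noise (default SD 0), ambient
23 °C, emissivity 0.98 recorded in the manifest.

### Thermal presets

| preset   | T_init base (°C) | ΔT_C (°C) | A (°C) | τ (s)   | S_R (°C·s) |
|----------|------------------|-----------|--------|---------|------------|
| WE-MD    | 31.9             | 6.2       | 6.2    | 59.62*  | 764.4      |
| WE-HD    | 31.8             | 4.6       | 1.1    | 10.64*  | 186.3      |
| high     | 31.8             | 7.2       | 2.6    | 38.6    | 368.6      |
| moderate | 31.8             | 7.6       | 3.65   | 30.5    | 546.0      |
| healthy  | 33.0             | 7.1       | 4.5    | 22.5    | 708.8      |

\* recovered by `solve_tau` from the published areas. Group presets were
calibrated so the hand-mean `S_R` lands inside each group's published
range (high 316.7–422.3, moderate 511.6–580.9, healthy 688.1–731.9 °C·s).

### Cohorts

Group sizes default to 50 high / 16 moderate / 42 healthy. Covariates are
sampled from per-group normals **without truncation** to the DAS28 bands:
the group label is assigned by design, and band membership holds in
expectation, not per draw. Within a subject, DAS28 and the joint counts
share one latent normal score and RF/anti-CCP share another, so the
designed couplings are strictly monotone across the whole coupled block:

- `A = A_preset · exp(−0.15·z_severity)` — higher DAS28 ⇒ smaller
  rewarming amplitude (strictly decreasing);
- `T_init = base + 0.8·tanh(z_serology/2)` — higher RF ⇒ warmer
  post-cooling temperature (strictly increasing, bounded ±0.8 °C).

DAS28, ESR, CRP and joint-count means/SDs follow the published cohort
table. RF (IU/mL) and anti-CCP (U/mL) were **not** tabulated in the
source; the defaults (high 120±40 / 150±60, moderate 80±30 / 90±40,
healthy 10±5 / 7±3) are clinically typical per-group values chosen only to
give the serology coupling a realistic scale — the correlation targets
depend on ranks, not on these magnitudes.

### Realism limits

The generator is a validation phantom, not a simulator of clinical
thermograms: no perfusion physiology, no spatial gradients along fingers,
no motion, no optical blur or emissivity variation, an exactly uniform
background, and capsule-and-ellipse geometry rather than anatomical hand
shapes. Conclusions about the pipeline's behaviour on clinical data are
limited accordingly.

## 3. Preprocessing

- Greyscale: `g = round(255·(clamp(T, 20, 40) − 20)/20)` with round-half-up;
  the 20–40 °C window covers ambient and skin temperatures.
- 3×3 mean and median filters with edge replication (`scipy.ndimage`,
  `mode="nearest"`), matched bit-for-bit by brute-force loop oracles in the
  tests.
- Gamma correction via a 256-entry LUT, default γ = 0.8. The source gives
  no value, only the verification criterion that the background histogram
  peak becomes higher/narrower; `background_peak_stats` makes that
  testable and γ = 0.8 satisfies it on the default scene.
- Steps apply in configured order; each `GreyImage` records its window and
  step provenance.

## 4. Segmentation

**Balanced histogram thresholding (BHT).** The heavier end of the
histogram support is trimmed bin by bin, shifting the midpoint as the
support shrinks; the surviving midpoint is the threshold. Two additions
over the textbook loop: (a) the procedure refuses to run when the
smoothed histogram has fewer than two substantive modes
(`NoClearBorderError` — "no clear border" between object and background),
and (b) trimming stops once both pans are empty, since further support
trimming would only drift the midpoint without evidence (a symmetric
two-spike histogram then yields the exact midpoint, 128 for spikes at 100
and 156). Foreground is `grey > level` (the hand is warmer than the
background).

**Frame-difference fallback.** When no valley exists (e.g. ambient near
skin temperature), the pipeline thresholds `|static − first rewarming|`:
the hand changes temperature between thermal states while the background
does not. Identical frames produce an empty mask plus a warning.

**Cleanup.** Iterated 3×3 opening-then-closing to a fixed point with a
10-iteration budget; non-convergence signals a restart (up to 2 per
route). The largest connected component is kept. On the default scene the
cleaned mask is a strict superset of the ground-truth silhouette confined
to a ≤2 px band (smoothing bleeds warmth into a 1 px halo; closing fills
the finger-junction notches).

**Skeleton and ROIs.** Zhang–Suen-style thinning
(`skimage.morphology.skeletonize`) gives a one-pixel 8-connected skeleton.
Endpoints (degree-1 pixels of the pixel graph) are walked depth-first to
the nearest branch point; the five longest branches of length ≥ 10 are the
finger midlines, labelled thumb→little by fingertip angle around the
skeleton centroid (branch cut straight down so a lateral thumb dipping
below the centroid does not wrap).

**Junction clearance (deviation from "full midline").** The last 4 pixels
before the branch point are dropped from each ROI. Near the junction the
skeleton bends off the finger's axis toward the point where neighbouring
capsules merge, which lies at distance `h/cos(γ/2) > h` from both axes
(`h` half-width, `γ` the inter-finger gap angle) — those pixels are
geometrically outside the finger proper. The trim never reduces a branch
below the minimum length, and the fingertip end is always kept.

## 5. Metrics

Keyframe conventions: `T_init` = last static frame; `T_C` = **first
rewarming frame** (the moment of cooling removal — the cooling phase's own
last frame is the same temperature by construction); `T_R` = last
rewarming frame. Derived: `ΔT_C = T_init − T_C`, `ΔT_R = T_R − T_C`.

Sign convention for the cooling area: `S_C = ∫(T_init − T(t)) dt` over the
cooling window, i.e. the **cooling deficit is positive** when the fingers
cooled. `S_R = ∫(T(t) − T_C) dt` over the rewarming window is positive for
any rewarming. `contrast = S_R − S_C`.

Numerics: trapezoidal rule (`np.trapezoid`) on the per-frame samples —
second-order accurate, confirmed by the convergence test; at 1 Hz the
sampled `S_R` sits within 0.1 °C·s of the closed form. ROI means are
arithmetic means over the midline pixels in float64; the hand mean is the
**unweighted** mean over the five fingers (equal weight per finger, not
per pixel, so long and short fingers count equally). Frames are float32,
which bounds temperature-difference precision at ~1e−5 °C.

The static-frame ROIs are reused for all frames: the scene does not move,
and a fixed ROI keeps the extracted curves strictly comparable.

## 6. Statistics

- Shapiro–Wilk for normality screening (3 ≤ n ≤ 5000, non-constant).
- Mann–Whitney U, two-sided: exact null enumeration when
  `n_a·n_b ≤ 400` and the pooled sample is tie-free, otherwise the normal
  approximation with tie and continuity corrections. The exact path is
  verified against brute-force enumeration, and its type-I error at
  α = 0.05 is calibrated to 5 % ± 2 % over 1000 null replicates.
- Spearman rank correlation with mid-ranks for ties; p from the
  t-approximation, with optional exact permutation enumeration for
  n ≤ 10. Zero rank variance returns NaN with a warning.
- `%CV = 100·σ/μ` with the population σ (ddof = 0).
- `run_study` reports group summaries, pairwise Mann–Whitney comparisons
  of all eight thermal outcomes (uncorrected by default; Holm adjustment
  optional) and Spearman correlations of `ΔT_R`, `T_R`, `T_C` against
  DAS28, tender joints, RF and anti-CCP within the patient groups
  (healthy controls are excluded — covariate–outcome coupling is a
  patient-group question and several healthy covariates are constant).

## 7. Interchange format

A sequence is a directory: `manifest.json` (units `degC`, frame rate,
phase boundaries, per-frame timestamps, emissivity, ambient) plus one
single-channel float32 TIFF per frame. The reader validates units, total
and per-phase frame counts, file presence and per-phase timestamp
monotonicity. ROIs and metrics export as CSV, masks/skeletons as PNG, and
every CLI artifact carries the tool version, seed and a 12-hex-digit
configuration hash.
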