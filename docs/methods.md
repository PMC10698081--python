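# Methods

This note documents the models, conventions and numerical choices behind
`respcine`, in the spirit of a package reference rather than a study
report. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and binning conventions

**Respiratory surrogate.** The per-frame surrogate is the median intensity
of a diaphragm ROI. With the default geometry (dark lung descending into
the ROI during inspiration) intensity falls as the diaphragm descends, so
the sign rule "first derivative ≤ 0 ⇒ inspiration" holds; the
`invert_signal` flag flips both the rule and the depth normalization for
ROIs with opposite polarity. Smoothing is a centered moving median over the
previous and subsequent 10 frames (window 21 ≈ 0.7 s at 33 ms frames —
short against a 3–5 s breath, long against cardiac flicker). Windows are
truncated at the series edges rather than padded: no samples are invented.
Ties (derivative exactly 0, common on moving-median plateaus) label as
inspiration by the ≤ rule; one consequence is that end-inspiratory plateau
frames tend to land in inspiration classes, which makes deep *expiration*
classes the first to go sparse on short acquisitions.

**Rescaling and gating.** The [5th, 95th] percentile range of the smoothed
trace maps to a depth in [0, 1] (0 = end-expiration, 1 = deepest gated
inspiration). Frames outside the range — sighs toward inspiratory reserve,
dips toward functional residual capacity — are flagged invalid and excluded
from binning. The percentiles are configurable; 5/95 keeps ≥ 90% of frames
on quiet phantom breathing while rejecting a 3× sigh (tested). Fewer than
five complete gated cycles in a slice raises a warning state, not an error.

**Bins.** 8 respiratory classes (4 equal-width depth bands × inspiration/
expiration; the top band is closed so depth 1.0 is included) × 25 cardiac
phases, phase = ⌊t_trig/(RR/25)⌋ + 1 from the scanner-provided trigger
time. Equal-width bands (rather than quantiles) keep the classes equally
spaced in estimated tidal volume, which is what the downstream regressions
assume. Indices are 1-based in all reports, 0-based internally.

**Overfilled bins.** All pairwise subpixel phase-correlation shifts among
the candidates are computed (`skimage` phase correlation; the package
convention is that `subpixel_shift(a, roll(a, s)) == s`). A candidate whose
mean shift magnitude against the others deviates from the group mean by
more than one group SD is excluded; if that excludes everyone the
unfiltered set is used. Among survivors the frame whose depth is closest to
the class median depth is the representative; ties break to the earliest
acquisition time. This "closest to class median" rule is also what makes
the per-class volumes concentrate at the band center, which the regression
on band-midpoint tidal volumes relies on.

**Empty bins.** An empty bin borrows the same cardiac phase's
representative from the nearest respiratory class, searching the same
respiratory phase side first (crossing the inspiration/expiration boundary
only when the whole side is empty), and is flagged BORROWED. Borrowed bins
exist to keep exported cine stacks complete; they never contribute to any
reported volume. A cardiac phase empty across all eight classes is an
error — the acquisition is too short for binning. A caveat on one edge
case: when RR is nearly commensurate with the 33 ms frame spacing, a fixed
RR samples only a subset of cardiac phases (stroboscopic aliasing). The
phantom therefore supports per-beat RR jitter, which the cohort simulations
enable (8 ms SD); real scanners get this decorrelation for free from
physiological heart-rate variability, and per-beat RR metadata is used
per frame when present.

**ED/ES selection.** Per respiratory class, volumes are computed for all 25
phases, but end-diastole and end-systole are selected as the volume
max/min **among phases whose bins are genuinely filled in every slice**.
Additionally, a class only yields an entry if its clean phases sample both
the ED and the ES neighborhood (±1 phase, cyclic), with the reference
ED/ES phases located on the subject's best-covered class. Without this
gate a sparsely covered deep band can report its "end-systole" near
end-diastole and corrupt the Frank–Starling fit with a physically
impossible stroke volume; with it, undersampled classes simply drop out
and the per-phase regressions run on the remaining ≥ 3 classes.

## Tidal-volume calibration

Absolute tidal volumes are not measurable from the images alone. The
package accepts any displacement→volume calibration table (CSV; OLS line,
diagnostics stored) such as one obtained by MR-compatible spirometry in
volunteers. The subject's normalized depth is converted to millimetres via
the *gated range*: the diaphragm edge (first crossing of the lung/liver
midpoint intensity in the median row profile — navigator-style subpixel
localization) is localized in the shallowest and deepest valid frames and
the displacement extrapolated to the full unit depth range. Phase
correlation is deliberately *not* used here: the diaphragm band is a
smooth, essentially one-dimensional edge with static crop borders, on
which FFT correlation locks to the wrong structure, while profile crossing
is exact to a fraction of a pixel (tested against planted displacements).
Without a table, a built-in quiet-breathing fallback maps the full gated
range to 2.7 ml per cm of body height. Class tidal volumes are evaluated
at the band midpoints (0.125, 0.375, 0.625, 0.875); TTVi is the mean of
per-breath gated peak depths converted to ml and divided by height. TVi
and TTVi are height-indexed (ml/cm); ventricular volumes are BSA-indexed
(DuBois) — two different normalizations, deliberately.

## Phantom

The phantom is an intensity model, not an MR physics simulation (no
k-space, coils or banding). Per frame it renders: background 0.15; a dark
lung band (0.05) over a bright liver band (0.75) with a 3 px sigmoid
boundary that descends with diaphragm displacement; two bright cavities
(1.0) with a 2.5 px myocardial rim (0.45), the LV circular, the RV a wider
ellipse (aspect 1.7), both translating at half the diaphragm excursion;
Gaussian noise (SD 0.02 by default). Cavity areas follow an elliptical
base-to-apex taper across the stack and are anti-aliased so that
half-coverage thresholding reproduces the analytic area; voxelized volumes
agree with the requested analytic volumes to well within 5% for volumes
≥ 30 ml at the default 1.6 mm / 8 mm resolution (tested).

Dynamics: each breath is a raised-cosine excursion with its own depth drawn
from a truncated normal (mean 400 ml, CV 0.25 by default, truncated to
[0.2, 2]×mean); diaphragm displacement = tidal volume / 40 ml·mm⁻¹ exactly
(the planted calibration); the cardiac waveform is a raised-cosine
contraction/relaxation with systole fraction 0.35 (the literature gives
only the ED/ES extremes; any smooth unimodal waveform serves); and preload
coupling EDV = EDV₀ + g·TV with SV = SV₀ + slope·(EDV − EDV₀), g positive
for the RV (+0.05 ml/ml) and negative for the LV (−0.02 ml/ml), matching
the opposite respiratory phases in which the two ventricles fill. Default
vitals (HR 85 bpm, 18 breaths/min) sit in the pediatric range; heart and
breath periods are incommensurate so bins fill over a full series. A
single integer seed drives all randomness.

What the phantom does *not* emulate — and hence what passing tests do not
demonstrate about patient data: through-plane motion and slice
misregistration, trabeculation and papillary muscles, contouring ambiguity
at the base, arrhythmia/ectopy, flow artifacts, and receiver-coil shading.
Parameter recovery on the phantom validates the *pipeline machinery*, not
segmentation of real anatomy (real series are expected to arrive with
externally produced masks).

## Cohorts, scales and the Monte-Carlo check

Synthetic cohorts sample demographics around the two study groups (RV
volume overload: age 9±2 y, height 133±12 cm, weight 30±8 kg, HR 86±7,
RR 21±4, baseline RV-EDVi 123±30 ml/m²; controls: 15±2 y, 165±9 cm,
56±14 kg, HR 84±12, RR 17±3, RV-EDVi 77±6 ml/m²), with per-subject RV
Frank–Starling slopes N(0.75, 0.11) vs N(0.92, 0.02) and tidal volume
scaling with weight (7 ml/kg).

Scales: full scale is 10–12 slices × 900 frames (29.7 s per slice). The
desk-scale default used by the demo pipeline, the recovery tests and the
acceptance script is 6 slices × 600 frames (19.8 s, ≈ 6 breaths): the
shortest acquisition at which the per-slice fill rate reaches ≈ 90% and
all four inspiration depth bands populate reliably; at 300 frames
(≈ 3 breaths) the deep classes are too sparse for 4-point regressions.
The Monte-Carlo cohort check runs 100 replicates of a 6-vs-6 comparison in
"signal" mode — the identical binning/volumetry/statistics code path, but
with the surrogate synthesized from ground-truth displacement and per-phase
volumes read from ground-truth frame volumes instead of rendered and
segmented images — at 4 slices × 600 frames per subject, so each replicate
is a real reduced-scale pipeline run rather than a draw from an assumed
estimator distribution.

## Numerical details and edge cases

- Moving median: truncated edge windows; length must exceed 2·halfwidth.
- First frame inherits the second frame's phase label.
- Zero percentile range (flat signal) is a degenerate-signal error.
- `cardiac_phase_index` guards floating-point spill into phase 26;
  trigger time ≥ RR is a metadata error.
- Negative class tidal-volume estimates (possible with a fitted intercept)
  clip to zero with a flag.
- Regression preconditions: ≥ 3 points and positive predictor variance;
  exact collinear input reproduces the slope to machine precision (scipy
  OLS; verified against closed-form sums).
- Group comparison: equal-variance t-test by default (Welch behind a
  flag); normality diagnostics are reported, not enforced; no
  multiple-testing correction is applied.
- Determinism: identical configuration and seed reproduce a bitwise
  identical report; the run seed fans out to per-subject phantom seeds.

## Known limitations

- The expiration-side Frank–Starling fit may be unavailable on short
  acquisitions (see the tie-rule note above); inspiration fits are the
  primary endpoint.
- The gated-range estimator assumes the diaphragm edge stays inside its
  search band; extreme displacements outside ±15 mm would need a wider
  band.
- `classify_rv_overload` requires a user-supplied age-resolved 90th
  percentile table; the built-in single-row table is a synthetic stand-in
  for demonstrations only.
- TTVi is defined here as the mean gated breath depth per cm height; other
  definitions (e.g. per BSA) exist and are not interchangeable.
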