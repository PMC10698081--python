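# respcine

Respiratory binning and Frank–Starling analysis of free-breathing real-time
cardiac cine MRI.

## The problem

Conventional cardiac MRI is acquired in breath-hold, which freezes — and
distorts — the interaction between breathing and the heart. Real-time
imaging acquires hundreds of short-axis frames per slice during free
breathing, so the respiratory modulation of ventricular filling becomes
measurable: inspiration increases venous return and right-ventricular (RV)
preload, expiration favors left-ventricular (LV) filling. The
Frank–Starling mechanism converts that preload change into a stroke-volume
change, and its *slope* ΔSVi/ΔEDVi (stroke volume vs end-diastolic volume,
both indexed to body surface area) is a dynamic marker of ventricular
function — flattened, for instance, in chronic RV volume overload after
tetralogy-of-Fallot repair or with atrial shunts.

`respcine` implements the complete retrospective analysis chain for such
free-breathing series, for imaging scientists and pediatric-cardiology
researchers:

1. **Respiratory surrogate** (`resp_signal`) — median signal intensity of a
   diaphragm ROI per frame; centered moving median over ±10 frames;
   inspiration = first derivative ≤ 0, expiration = derivative > 0; robust
   5th–95th percentile rescaling to a [0, 1] depth with outlier-breath
   gating and respiratory-cycle counting.
2. **Binning** (`binning`) — each valid frame is assigned to one of
   8 respiratory classes (4 tidal-volume depth bands × inspiration/
   expiration) × 25 cardiac phases from the ECG trigger time
   (phase = ⌊t_trig/(RR/25)⌋ + 1). Overfilled bins are resolved by subpixel
   FFT phase correlation: candidates whose mean pairwise shift deviates
   from the group mean by more than one SD are excluded, then the frame
   with depth closest to the class median is kept. Empty bins borrow from
   the nearest class (same respiratory phase first) but are flagged and
   never enter quantitative results.
3. **Tidal-volume calibration** (`tidal`) — a linear displacement→volume
   calibration (ml per mm of diaphragm excursion) converts the gated depth
   range to estimated class tidal volumes, indexed to body height
   (TVi, ml/cm); the typical tidal volume per height (TTVi) is the mean
   gated breath depth per cm.
4. **Volumetry** (`volumetry`) — disc summation over the short-axis stack
   (8 mm slices, no gap) per respiratory class and cardiac phase;
   ED/ES = volume max/min over genuinely filled phases; SV = EDV − ESV,
   EF = 100·SV/EDV; indexing by DuBois BSA
   (0.007184·weight^0.425·height^0.725).
5. **Statistics** (`starling`) — per subject and respiratory phase, OLS of
   each metric on class TVi and of SVi on EDVi (the Frank–Starling slope);
   Table-style change summaries per TTVi; Kolmogorov–Smirnov/Shapiro–Wilk
   residual checks and independent-samples t-tests between groups
   (significance at P < 0.05).

Because no raw patient series are distributable, the package ships a
**synthetic cardiorespiratory phantom** (`phantom`) that renders b-SSFP-like
short-axis frames (200×200 px, 1.6 mm pixels, 33 ms per frame, 900 frames
per slice at full scale) with known ground truth: breath-to-breath variable
respiration, a diaphragm whose displacement is exactly proportional to
tidal volume, and a planted linear preload coupling
EDV = EDV₀ + g·TV, SV = SV₀ + slope·(EDV − EDV₀). Every stage of the
pipeline is validated by recovering those planted parameters.

## Worked example

One phantom subject with a planted RV Frank–Starling slope of 0.75,
processed end to end through the image-based pipeline (6 slices × 600
frames, ~25 s on one CPU):

```python
from respcine import PhantomConfig, RunConfig, run_phantom_subject, SubjectRecord

pcfg = PhantomConfig(n_slices=6, frames_per_slice=600, starling_slope_rv=0.75, seed=3)
rec = SubjectRecord(id="demo", age_years=10, sex="F", weight_kg=35.0,
                    height_cm=140.0, group="rv_overload")
res = run_phantom_subject(pcfg, rec, RunConfig(n_slices=6, frames_per_slice=600))
print(f"bins filled: {res.fill_stats['filled_pct']}%   "
      f"gated diaphragm range: {res.gated_range_mm:.1f} mm   "
      f"TTVi: {res.ttvi:.2f} ml/cm")
for f in res.fits:
    print(f"{f.ventricle} {f.resp_phase:<11}  slope {f.slope:.3f}  R^2 {f.r2:.3f}  n {f.n_points}")
```

prints

```
bins filled: 90.6%   gated diaphragm range: 11.6 mm   TTVi: 2.02 ml/cm
LV inspiration  slope 1.078  R^2 1.000  n 3
LV expiration   slope 1.087  R^2 1.000  n 3
RV inspiration  slope 0.738  R^2 1.000  n 3
RV expiration   slope 0.726  R^2 0.990  n 3
```

90.6% of the 1200 bins fill without borrowing; the navigator-measured
diaphragm excursion of 11.6 mm corresponds to a typical tidal volume of
2.02 ml per cm body height; and the fitted RV slopes (0.738/0.726) recover
the planted 0.75 while the LV slopes sit near their planted 1.05. A
two-cohort comparison (6 phantoms with RV slope ≈ 0.75 vs 6 with ≈ 0.92) is
run by `respcine run-all --out results --seed 0`, which writes per-class
volumes, per-subject fits, group t-tests and a JSON report.

## Command line

`respcine` exposes `simulate`, `extract-signal`, `bin`, `calibrate`,
`volumetry`, `starling` and `run-all` subcommands (`--config`, `--out`,
`--seed`, `--invert-signal`, `--paper-scale`). Configuration is YAML,
tabular outputs CSV, structured outputs JSON, image series NIfTI with JSON
timing sidecars (DICOM with per-frame trigger times is also read).

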