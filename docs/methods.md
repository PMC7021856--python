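# Methods

## Dead-time model

The detector is modelled as paralysable: every incoming event extends the
dead period, so a true event rate R_t is observed as
R_o = R_t·exp(−R_t·τ). The observed rate is unimodal with maximum
1/(e·τ) at R_t = 1/τ; an observed rate below the maximum corresponds to
two true rates, and only the below-saturation branch (R_t·τ < 1) is
physical. Inversion uses the principal branch of the Lambert W function,
R_t = −W₀(−R_o·τ)/τ, with a bracketed bisection implementation as an
independent fallback (tolerance 1e−12 on R_t·τ, both absolute and
relative). Observed rates within 1e−9 (relative) of the apex are rejected
as saturated rather than inverted, because the two branches meet there
and the inversion is numerically ambiguous.

The correction applied to the primary (scatter-corrected photopeak) rate
R_Po is *driven by the wide-spectrum observed rate* R_Wo, not by R_Po
itself: the correction factor f = R_Pt/R_Po solves
1 = f·exp(−f·R_Wo·τ). This is deliberate: photons of any energy paralyse
the camera, and R_Wo — summed over contiguous windows covering most of
the recordable spectrum — tracks that total burden in a way that is
insensitive to how much scattering medium surrounds the source. The τ
fitted this way predicts the losses of *primary* counts from R_Wo; it is
not the τ of R_Wo's own losses, and is expected to be larger, because
pulse pile-up displaces primary events out of the photopeak and amplifies
primary losses relative to whole-spectrum losses.

## Energy windows and scatter correction

The bundled window scheme is the six-window Lu-177 configuration: a 20%
photopeak window at 208 keV (PP), flanking lower/upper scatter windows
(LS, US) each as wide as 10% of the photopeak centre, and three general
scatter windows covering 18–55, 55–166 and 250–680 keV. The stored limits
are the vendor-printed integer values (e.g. G2 is stored as [55–166]
although 111 keV ± 50% gives [55.5–166.5]); exact real limits are used
whenever a window is built from centre and width, and integer rounding
(half-up) is presentation-only. Wide-spectrum combinations: 3W
(PP+LS+G2, 55–229 keV), 4W (PP+LS+US+G2, 55–250 keV), 6W (all six,
18–680 keV).

TEW scatter correction subtracts LS+US counts from PP; DEW subtracts LS
only. Both are plain count subtractions: since LS and US are each half
the photopeak width, the standard trapezoid TEW estimate reduces exactly
to the plain sum, and no width weighting is applied by default (a
width-weighted variant is available behind a flag). A negative net after
subtraction — possible in low-count frames — is clipped to zero with a
warning by default; a keep-negative policy is available for fitting
studies where clipping would bias low-rate points.

## Calibration

Samples are serial acquisitions with known activity A, observed primary
rate R_Po and per-combination wide rates R_Wo. The model is
R_Wo = CF·X_W·exp(−CF·X_W·τ) with X_W = A·R_Wo/R_Po; its functional form
forces the curve through the origin.

* **Method B (joint)** fits CF and τ in a single non-linear least-squares
  pass over the full activity range. τ is parameterized as log τ for
  positivity and conditioning; initial CF is the through-origin slope of
  the lowest-decile X_W points, initial τ is 0.5 μs. Standard errors come
  from the Jacobian-based covariance at the optimum.
* **Method A (two-step)** first estimates CF as the slope of a
  through-origin linear fit of R_Po vs A over dead-time-free samples,
  then fits τ with CF fixed. "Dead-time-free" means a correction factor
  below 1.01 under a provisional τ, obtained from one Method B pass
  (a fixed activity cut-off can override this). Because the retained
  samples still carry up to 1% loss — and a through-origin fit inherits
  that bias, which the fixed-CF τ stage then amplifies several-fold —
  the CF stage divides each retained R_Po by its provisional correction
  factor first. CF is defined as R_Pt/A, so this is the estimator the
  definition asks for; with it, Methods A and B coincide to machine
  precision on data generated exactly from the model.

Fits are unweighted by default. Optional Poisson-variance weighting
(σ per rate from its counts and acquisition time, with `absolute_sigma`)
is available; it matters when the reported standard errors are used in
agreement tests, because under heteroscedastic counting noise the
unweighted covariance underestimates them by roughly a factor of three
for the default scenario.

### Usable range

A calibration series deliberately extends past the camera's operating
range — that is how the range is measured. The system leaves its
paralysable regime with a sharp sensitivity drop followed by divergent
per-detector behaviour; `detect_usable_range` flags, in order of
increasing X_W, the first sample whose R_Wo falls more than a tolerance
(default 5%; the drop is not given a sharper published criterion) below
the fitted curve, or where per-detector primary rates diverge by more
than the same tolerance. `calibrate_with_range` grows the fit forward:
the lower half of the series is fitted first and samples are appended in
X_W order while they stay within tolerance of the extrapolated curve.
Forward growth is used because a joint fit that includes even one
post-saturation sample can bend τ enough to hide the drop from a
fit-then-detect loop. Quantification beyond the detected range is
refused: past saturation the observed wide rate falls back down, so an
out-of-range observation is indistinguishable from a valid low-rate one
without the range bound (accuracy summaries therefore also check known
activity against the range's maximum activity where available).

## Segmentation and volumes

Reconstructed SPECT volumes hold projection-number-scaled counts; the
observed primary rate is the (masked) voxel sum divided by
n_projections·t_projection. Two masks suppress the spurious diffuse
background that scatter correction leaves in dense non-radioactive
regions: per-slice circular ROIs (voxel included when its centre lies in
the disc — matching clinical ROI tools and reproducible, no area
weighting) and a threshold at a fraction (default 1%) of the maximum
voxel, inclusive at the boundary so the maximum voxel is always kept.
Voxel arrays are indexed (x, y, z), slices along z; physical mm are
measured from the volume corner with voxel centres at
(index + 0.5)·voxel_size. Volumes are exchanged as NIfTI with a JSON
sidecar carrying n_projections and t_projection.

## Quantification

Recovered activity is A = R_Po·f(R_Wo, τ)/CF. Accuracy is
(recovered − known)/known·100; summaries report the mean and sample SD
over in-range results, with out-of-range results listed separately
rather than averaged (they can be pooled on request). The rescale slope
f/(CF·t·v)·1e6 maps voxel counts to Bq/mL, folding the correction
factor, calibration factor, total acquisition time t and voxel volume v
into one factor, as used when exporting SPECT volumes as PET-like DICOM.
Known activities are decay-corrected to scan time with the standard
Lu-177 half-life of 6.6443 d; decay is bookkeeping, not part of the
camera model.

## Simulator

The synthetic camera mirrors the calibration model exactly in its
noise-free core: X = CF·A·k, R_Wo = X·exp(−X·τ), R_Po = R_Wo/k, with a
constant spectral ratio k = R_Wo/R_Po per phantom. This choice makes
Method B recovery exact in the noise-free limit, separating
model-fidelity tests from robustness tests; the distortions below are
layered on top individually.

* **Window split.** The non-primary rate is distributed over the five
  non-photopeak windows by per-phantom fractions, and the photopeak
  additionally receives a local-scatter share equal to the LS+US shares
  — exactly what TEW removes — so TEW returns R_Po in expectation.
* **Counting noise** is Poisson on counts (never Gaussian on rates),
  seeded; a fixed seed gives bit-identical output.
* **Truth values** default to CF = 9.36 cps/MBq and τ = 0.550 μs per
  detector, with saturation at 350 kcps wide-spectrum, so simulated
  magnitudes match the activity and count-rate ranges of a real Lu-177
  characterisation (~20 MBq–19 GBq; photopeak ~0.1–98 kcps, wide
  ~0.5–380 kcps).
* **Spectral ratios** k default to 4.0 for sources in air (planar), 5.5,
  6.0 and 6.5 for the 10/16/32-cm attenuating cylinders, and 7.0 for the
  Jaszczak phantom — increasing with the volume of scattering medium and
  bracketing realistic photopeak-to-wide-spectrum rate ratios.
* **Saturation divergence.** Beyond the saturation rate each detector's
  sensitivity decays exponentially in the relative excess rate, detector
  2 faster than detector 1 (the system prioritizes detector 1 at high
  rate). The exponential form is an implementation choice; only the
  sharp-drop-then-divergence shape matters to the detection code.
* **Pile-up (optional).** A fraction 1 − exp(−X·τ_pileup) of surviving
  primary events is displaced from PP into US and G1, conserving the 6W
  total. This reproduces the expected ordering: the τ that predicts
  primary losses from R_Wo exceeds the τ of R_Wo's own losses.
* **Volume artefacts.** Synthetic volumes place source spheres (weighted
  by concentration; the default Jaszczak fill is 6:1 spheres:cylinder)
  and add diffuse spurious counts in dense non-source regions at a
  constant rate equal to background_level × CF × 100 MBq, so the
  relative contamination grows as activity falls — the direction of the
  real reconstruction artefact.

What the simulator does **not** emulate: photon transport, collimator
and crystal physics, reconstruction noise texture and resolution
recovery, attenuation-map errors, energy-resolution effects at
sub-window scale, and the detailed mechanism of the low-activity
sensitivity tailing (the constant background rate is a phenomenological
stand-in). Passing recovery tests therefore demonstrates correctness of
the estimation pipeline under the stated statistical model, not accuracy
on any particular physical camera, which must still be characterised by
measurement.

## Problem sizes and defaults

The default planar plan uses 17 activities spaced geometrically over
19 MBq–15.1 GBq at 60-s frames — the span a serial capillary-addition
experiment covers, reaching past saturation so the usable range is
measurable. Recovery studies in the test suite use 20 seeded replicates
of that plan; segmentation studies use 8 tomographic activities on
40×40×20 volumes of 4.8-mm voxels (96 projections), sizes chosen so the
whole suite runs in seconds while keeping per-sample counts in the
10⁴–10⁷ range of real acquisitions. Tolerances asserted in the tests:
Method B noise-free recovery to 0.1%, A/B agreement to 0.5%, Poisson
replicate recovery medians of 1% (CF) and 3% (τ), inversion vs oracle to
1e−9 relative.

## Known limitations

* Dead time is modelled as a single time-invariant constant; hybrid or
  non-paralysable models and per-projection (angle-dependent) dead time
  are out of scope.
* Method A's residual-dead-time correction relies on the provisional
  Method B fit; with the fixed activity cut-off override the raw
  uncorrected estimator is used.
* Usable-range detection needs the series to actually cross the drop;
  otherwise the range is reported open-ended at the last sample.
* The DEW subtraction applies no scaling to the lower-scatter counts.
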