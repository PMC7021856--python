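# qspectcal

Camera calibration, dead-time correction and activity quantification for
Lu-177 quantitative SPECT (QSPECT).

## The problem

Dosimetry for Lu-177 radionuclide therapy needs SPECT images whose voxel
values are calibrated to absolute activity. That requires two system
constants, measured over the camera's full operating range:

* the **calibration factor** *CF* (cps/MBq) — the dead-time-free primary
  (scatter-corrected photopeak) count rate per unit activity;
* the **dead-time constant** τ (μs) of the paralysable detector model,
  which predicts the losses of primary counts as a function of the
  observed count rate.

The paralysable model says an incoming true rate *R*<sub>t</sub> is
observed as *R*<sub>o</sub> = *R*<sub>t</sub>·e^(−*R*<sub>t</sub>·τ),
which peaks at 1/(e·τ). Because photons of *any* energy paralyse the
detector, and the spectral shape depends on how much scattering medium
surrounds the source, the dead-time driver used here is the
**wide-spectrum** observed rate *R*<sub>Wo</sub> — the summed rate over a
set of contiguous energy windows (18–680 keV for the full "6W"
combination) — rather than the photopeak rate, which makes the fitted τ
geometry-independent. The calibration model fitted to a serial
acquisition of known activities *A* is

  *R*<sub>Wo</sub> = *CF*·*X*<sub>W</sub>·e^(−*CF*·*X*<sub>W</sub>·τ),
  *X*<sub>W</sub> = *A*·*R*<sub>Wo</sub>/*R*<sub>Po</sub>,

fitted either in two steps (Method A: *CF* from a through-origin linear
fit of low-activity data, then τ) or jointly (Method B). The correction
factor applied to an observed primary rate is *f* = *R*<sub>Pt</sub>/
*R*<sub>Po</sub> solving 1 = *f*·e^(−*f*·*R*<sub>Wo</sub>·τ), computed in
closed form with the Lambert W function, and recovered activity is
*A* = *R*<sub>Po</sub>·*f*/*CF*.

The package provides: the energy-window schema with TEW/DEW scatter
correction, the paralysable model and its inversion, Method A/B fitting
with usable-range detection, volume segmentation (per-slice circular ROIs
and 1%-of-max thresholding), activity quantification with accuracy
scoring, and a synthetic camera/phantom simulator with known ground
truth for validation and recovery studies. It is aimed at medical
physicists commissioning quantitative Lu-177 imaging and at anyone who
needs a tested reference implementation of wide-spectrum-driven dead-time
correction.

## Worked example

Simulate a serial planar acquisition (17 activities, 19 MBq–15.1 GBq,
60-s frames, Poisson noise; the simulator truth is CF = 9.36 cps/MBq,
τ = 0.550 μs with saturation at 350 kcps), calibrate, and quantify:

```sh
$ qspectcal sim planar --seed 7 --out records.csv
wrote 34 rows to records.csv
$ qspectcal calibrate records.csv --method B --combination 6W --out calib.json
CF = 9.353 +/- 0.002 cps/MBq   tau = 0.5478 +/- 0.0006 us   (method B, 6W, n=16)
usable range: up to 9962 MBq / 304 kcps wide-spectrum
$ qspectcal quantify records.csv --calibration calib.json --out quant.csv --summary summary.json
accuracy: +0.07 +/- 0.32% (n=16, 1 beyond usable range)
```

Reading the output: the joint fit (Method B) recovers the calibration
factor within 0.1% and the dead-time constant within 0.5% of the
simulator truth from 16 usable samples; the top acquisition sits past the
saturation point and is excluded automatically. Dead-time-corrected
quantification of the same series then recovers the known activities to
+0.07% on average with a 0.32% spread; the sample beyond the usable range
is reported separately because quantification there is not possible.

The same workflow is available as a library:

```python
import qspectcal as q

camera = q.CameraTruth()                      # CF=9.36, tau=0.550 us
series = q.generate_series(camera, q.air_2d(),
                           q.default_planar_plan(seed=7))
fit, usable = q.calibrate_with_range(series, method="B", combination="6W")
result = q.quantify_sample(series[3], fit)
```

## Layout

* `qspectcal.windows` — energy-window schema, combined rates, TEW/DEW.
* `qspectcal.deadtime` — paralysable model, Lambert-W inversion,
  correction factor.
* `qspectcal.calibration` — Methods A/B, dead-time-free subset selection,
  usable-range detection, sensitivity tables.
* `qspectcal.segmentation` — volume rates, threshold and ROI masks,
  NIfTI I/O.
* `qspectcal.quantify` — activity recovery, accuracy summaries, rescale
  slope.
* `qspectcal.simulate` — synthetic camera/phantoms (spectral ratios,
  saturation divergence, pile-up, Poisson noise, Lu-177 decay).
* `qspectcal.cli` — the `qspectcal` command (`sim`, `calibrate`,
  `quantify`).

See `docs/methods.md` for the model details, simulator assumptions and
numerical choices.
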