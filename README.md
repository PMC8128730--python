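# lgequant

Simulation and analysis of **myocardial scar quantification under tunable
MRI noise reduction**.

Late gadolinium enhancement (LGE) cardiac MR is the reference technique for
imaging myocardial fibrosis: scar retains contrast agent and appears bright
against the "nulled" (suppressed) normal myocardium. Scar burden is usually
quantified semi-automatically as the fraction of left-ventricular (LV)
myocardium above a signal-intensity threshold:

* **kSD method** — `T = mean(remote ROI) + k · SD(remote ROI)` with
  k = 2, 4 or 6, where the remote ROI lies in visibly normal myocardium;
* **FWHM method** — `T = ½ · max(SI within the scar ROI)` (full width at
  half maximum).

Modern reconstruction pipelines ship tunable denoisers: the user requests a
noise-reduction (NR) level between 0 and 100%, and the reconstruction
removes that fraction of the predicted image noise. Because the kSD
threshold depends directly on the noise SD of the remote ROI, denoising
silently *lowers* the threshold and inflates the measured scar burden — a
clinically consequential artifact, since LGE extent feeds prognostic models
and ICD decisions. The FWHM threshold depends on signal amplitude, not
noise SD, and is comparatively immune.

`lgequant` makes this mechanism reproducible without patient data or a
proprietary reconstruction network. It provides:

* `lgequant.synthetic` — generators for a static SNR phantom and for
  short-axis LGE cohorts (ischemic subendocardial wedges, non-ischemic
  patchy mid-wall lesions) with partial-volume blur, tissue texture, coil
  shading and exact ground truth;
* `lgequant.denoise` — NEX averaging and an *exact* NR emulator that
  subtracts a known fraction of a stored noise realization
  (`residual = (1 − nr) · noise` by default, or `√(1 − nr) · noise`);
* `lgequant.metrics` — ROI statistics, `SNR = mean(SI)/SD(air)`,
  `CNR = (SI_scar − SI_remote)/(1.5 · SD(air))`, and 20–80% edge sharpness
  (1/cm) from interpolated line profiles;
* `lgequant.quantify` — contour rasterization, kSD/FWHM thresholds, scar
  masks and % LV burden;
* `lgequant.pipeline` — the two experiments (phantom SNR-vs-NEX study and
  cohort NR sweep) with paired Friedman / Wilcoxon signed-rank statistics at
  Bonferroni-corrected α = 0.0125, plus CSV/JSON/plot reports.

A thin CLI (`lgequant simulate|denoise|metrics|quantify|phantom-study|cohort-study`)
wraps these functions.

## Worked example

```python
from lgequant import make_cohort, run_cohort_study, run_phantom_study

# Phantom: which NEX (signal averages) matches each NR level?
curve = run_phantom_study(seed=1, n_reps=20, nr_levels=(0.5, 0.75))
print(curve.effective_nex.round(2).to_string(index=False))

# Cohort: 30 scar-positive cases, NR sweep, all quantification methods
cohort = make_cohort(n_cases=30, ischemic_fraction=0.27, seed=7)
sweep, summary = run_cohort_study(cohort, sigma=12.0, seed=11)
top = summary.summary[summary.summary.nr_level == 1.0]
print(top[["method", "mean_scar_percent", "mean_rel_change",
           "median_rel_change"]].round(1).to_string(index=False))
print(summary.tests.to_string(index=False))
```

prints

```
 nr_level   snr  effective_nex  effective_nex_continuous
     0.50 42.77              4                       4.0
     0.75 85.81             16                      16.1

method  mean_scar_percent  mean_rel_change  median_rel_change
  fwhm                7.5              2.9                2.4
manual                5.9              0.0                0.0
   sd2               20.1             25.8               24.8
   sd4               16.1            105.3               92.8
   sd6               12.1            133.6              115.0

method   friedman_p
  fwhm 2.996043e-01
manual 1.000000e+00
   sd2 6.846785e-24
   sd4 5.875203e-25
   sd6 5.875203e-25
```

Reading this: denoising a single-average phantom image at NR 50% (75%)
yields the SNR of 4 (16) averages — the square-root law in action. On the
cohort, the `mean_rel_change` column is the inflation of measured scar
burden at NR 100% relative to the un-denoised image: the SD-threshold
methods inflate severely and in order (2SD < 4SD < 6SD, here +26%, +105%,
+134%), with Friedman p-values far below the 0.0125 significance bar, while
FWHM moves ~3% (p = 0.30) and the manual reference is constant by
construction.

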