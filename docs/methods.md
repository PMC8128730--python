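# Methods

## What is being modeled

The package studies how a tunable denoising reconstruction changes
threshold-based myocardial scar quantification on late gadolinium
enhancement (LGE) cardiac MR. Nothing is fitted to data; both experiments
are forward simulations with exact ground truth:

1. **Static phantom experiment.** A uniform doped disk in air. SNR is
   measured as the signal-ROI mean divided by the average SD of three
   background (air) ROIs, following the phantom convention of using several
   background regions. (Phantom protocols are sometimes described with both
   mean and SD taken outside the phantom, which would make SNR a pure
   background statistic; this implementation measures the mean inside the
   phantom and the SD outside, the IEC-consistent reading.) Sweeping the number of signal averages (NEX) without
   denoising establishes the square-root SNR law; applying the
   noise-reduction (NR) emulator to single-average images expresses each NR
   level as an *effective NEX*.

2. **Cohort experiment.** A cohort of synthetic short-axis LGE cases, each
   reconstructed (emulated) at NR levels 0, 25, 50, 75 and 100% from the
   same noise realization — the within-case pairing that justifies paired
   statistics. Scar burden (% of LV myocardium) is quantified at every
   level with 2SD/4SD/6SD thresholds above remote myocardium, the FWHM
   half-maximum threshold, and the generator's ground-truth mask standing
   in for a manual reader. Per method, a Friedman test across levels is
   followed (when significant at 0.05) by Wilcoxon signed-rank tests of
   each level against baseline, with significance at Bonferroni-corrected
   α = 0.05/4 = 0.0125.

## The noise-reduction emulator

The emulator is *oracle-based*: the generator stores the exact Gaussian
noise field added to each clean image, and denoising at level `nr`
subtracts a known fraction of precisely that field. Clean structure is
never altered — no smoothing, sharpening or de-ringing — which isolates the
one mechanism under study: the dependence of SD-based thresholds on
residual noise. Two semantics are implemented because "noise variance
reduced by the requested NR level" is ambiguous:

* `amplitude_linear` (default): residual SD = (1 − nr)·σ, so SNR grows as
  1/(1 − nr). NR 50% ≡ NEX 4 and NR 75% ≡ NEX 16.
* `variance_linear`: residual SD = √(1 − nr)·σ; NR 50% ≡ NEX 2 only.

The amplitude-linear default is the one consistent with the phantom
behavior of such reconstructions (NR 50%/75% matching 4/16 averages);
the variance-linear reading is kept selectable for sensitivity analyses.
At nr = 1 both return the clean image bit-for-bit.

Noise is additive zero-mean Gaussian on magnitude images, clipped at zero.
At the tissue SNRs involved the Rician correction is negligible inside the
body; in air the clipped field scales linearly with the residual factor, so
every SNR *ratio* (the quantity all conclusions rest on) is unaffected by
clipping. A Rician option is deliberately out of scope.

## Synthetic image model

A case is a stack of parallel short-axis slices (default 256 × 256 pixels
at 1.5 mm, 8 mm slices with 2 mm gap) containing a circular LV: bright
blood pool inside the endocardial contour, nulled remote myocardium in the
ring, and hyperenhanced scar in one of two patterns:

* *ischemic wedge* — subendocardial angular sector with a transmurality
  fraction, emulating a coronary-territory infarct;
* *non-ischemic patchy* — circular mid-wall foci scattered inside an
  angular window, emulating multifocal fibrosis.

The clean tissue image is piecewise constant, then modulated and degraded
in order: (a) smooth multiplicative tissue texture (SD 2% of tissue SI,
correlation ≈ 8 px); (b) additional intra-scar heterogeneity (SD 8%,
correlation ≈ 4 px) representing core/gray-zone structure; (c) a low-order
multiplicative shading field (±6% across the LV radius, random direction)
representing coil-sensitivity and nulling gradients; (d) Gaussian
partial-volume blur (σ = 1 px), matching an acquisition matrix slightly
coarser than the reconstructed grid. Ground truth records the pre-blur,
pre-texture scar mask and its exact % of LV.

Intensity calibration (arbitrary units): remote myocardium 60, scar 220,
blood pool 190, noise σ = 12 in the cohort study. This puts nulled remote
myocardium at SNR 5, scar at SNR ≈ 18 and scar-remote CNR ≈ 9 — a typical
clinical LGE operating point. The remote-SNR choice matters: suppressed
myocardium sits close to the noise floor in practice, and the SD-threshold
inflation mechanism is quantitatively strong only in that regime. At much
higher remote SNR (e.g. 15) the same code produces the same qualitative
ordering but with inflation of only a few percent.

Three ingredients deserve explicit rationale because the mechanism's
statistics depend on them:

* **Why tissue texture exists at all** — with perfectly uniform tissue, the
  remote-ROI SD collapses to zero at NR 100% and the kSD threshold
  degenerates to the remote mean (the code flags this case rather than
  failing).
* **Why the texture is spatially coarse** — a small remote ROI drawn in
  locally homogeneous myocardium underestimates ring-wide intensity
  variation, exactly as real ROIs do; this makes the fully denoised kSD
  threshold cut into genuine tissue heterogeneity, which is a large part of
  why 2SD inflates in practice.
* **Why the scar is heterogeneous** — if the scar were uniform, the
  scar-ROI maximum would be noise-dominated and the FWHM threshold would
  fall deterministically with NR in every case, making the paired Friedman
  test on FWHM spuriously significant. With core/gray-zone heterogeneity
  the maximum is signal-dominated and the per-case FWHM trend has random
  sign, reproducing the observed pattern (kSD methods strongly significant,
  FWHM not).

## Cohort composition

Default cohorts have 30 scar-positive cases with an ischemic fraction of
0.27 (8 wedge cases, 22 patchy). Per-case parameters are drawn uniformly
from documented ranges (4–8 slices, scar on 35–75% of slices, wedge extent
45–95° with transmurality 0.35–0.85, 3–6 patches of radius 1.8–3.5 px per
slice). The ranges are calibrated so the default cohort's median true scar
burden is ≈ 6% of LV (measured 5.9%, IQR 4.7–7.0 at the default seed),
the burden typical of a mixed ischemic/non-ischemic scar-positive
population. Per-case seeds are `seed + index`; every generator output is a
pure function of (spec, seed).

## Quantification conventions

* Contours and ROIs are defined once per case on the clean image and reused
  unchanged at every NR level, mirroring contour copying between
  reconstructions of the same acquisition.
* A pixel belongs to a polygonal region iff its center is strictly inside
  the polygon; the myocardium mask is epicardial minus endocardial
  interior.
* Sample SD uses the n − 1 denominator everywhere.
* Threshold comparison is `>=` (pixels exactly at threshold count as scar),
  fixed so results are bit-exact.
* FWHM uses half the maximum within the scar ROI only, not all myocardium.
* Sharpness: thresholds at 20% and 80% of the profile's total intensity
  range; crossings are located by linear interpolation on the monotone run
  with the largest intensity span covering both thresholds (ties toward the
  first run), so a noisy profile with wiggles still measures its dominant
  edge. Positions are in cm via the pixel spacing.
* Degenerate inputs: zero remote SD flags the result instead of failing;
  zero noise SD raises an undefined-SNR error; flat profiles raise an
  undefined-sharpness error.

## Problem sizes and determinism

The test suite runs small grids (96 × 96, 3–4 slices) for unit tests and
the full default conditions (256 × 256, 30 cases, 5 NR levels, 5 methods)
for the acceptance checks; the phantom study uses 20 noise replicates with
≈ 11,500 background pixels, enough to estimate SDs to well under 5%. The
whole suite completes in well under a minute. All stochastic tests fix
their seeds; `scripts/acceptance.py` derives every random stream from its
`--seed` argument.

## Known limitations

* The emulator is idealized: it cannot over- or under-estimate noise, and
  it does not emulate resolution enhancement, de-ringing or the artifact
  amplification of a learned reconstruction. Empirical SNR gain factors of
  a real network (which bundle those effects) are therefore outside the
  model; the emulator's gains follow the exact closed forms above.
* One clause one might expect from threshold monotonicity — scar burden
  non-decreasing in NR *in every single case* — does not hold exactly:
  lowering the threshold and attenuating the noise happen simultaneously,
  so supra-threshold noise pixels drain away while blur-shell pixels are
  gained, and a few cases per cohort show sub-percentage-point dips between
  adjacent NR levels (the trend holds in the mean and in the large
  majority of cases). Mask nesting is exact only at a fixed image.
* Geometry is stylized: circular contours, no papillary muscles or
  trabeculation, no motion/wrapping/ghosting artifacts, no long-axis views,
  no inversion-recovery signal physics. Passing tests demonstrate the
  statistical mechanism, not segmentation performance on anatomical images.
* "Manual" quantification is the generator's ground truth; statements about
  agreement with manual reading are relative to this stand-in.
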