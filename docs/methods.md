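# Methods

## The assay being modelled

In a surface nucleation assay, γ-tubulin ring complexes (γTuRCs) are
immobilised on a passivated glass surface and fluorescent tubulin is added.
Individual microtubules nucleate from individual surface templates and are
followed in real time by TIRF microscopy over a 164 × 164 μm field at
1 frame / 5 s. The observables are the cumulative number of filaments per
field over time, kymographs of single filaments from which end growth
speeds are read, and the number of fluorescent template spots per field.
`mtnuc` implements a stochastic forward model of this experiment plus the
full quantification chain, so that every headline kinetic quantity can be
recovered end-to-end from synthetic data and the chain can equally be
applied to user-supplied tables or images in the same schemas.

## Kinetic model

**Templated nucleation.** Each surface template fires at most once, after an
exponential waiting time with rate

    k(c) = f_MAP · k_ref · (c / c_ref)^n_coop ,

with tubulin concentration `c` in μM. The memoryless waiting time encodes a
constant nucleation probability per template per unit time, which is what a
linear filament-count curve implies. Defaults: `c_ref` = 20 μM,
`k_ref` = −ln(1 − 0.005)/540 s ≈ 9.28 × 10⁻⁶ s⁻¹ (0.5% of templates fire
within 9 min at the reference concentration; the exponential rather than
linear survival form is used — at this magnitude the two agree to < 0.3%
relative), `n_coop` = 6.7. The exponent makes templated nucleation highly
cooperative: halving tubulin reduces the rate ~104-fold.

**Growth.** Plus ends elongate linearly above a critical concentration:
`v₊(c) = g_MAP · v_slope · max(0, c − c_elong)` with `v_slope` = 26.8/13
nm s⁻¹ μM⁻¹ and `c_elong` = 2 μM, so the seed-assay line passes through
(15 μM, 26.8 nm/s). γTuRC-nucleated plus ends use the same line scaled by
26.3/26.8, pinning the slightly lower speed measured for templated
filaments. γTuRC minus ends are capped (speed identically 0); seed-assay
minus ends follow a shallower line through (2 μM, 0) and (15 μM, 7.0 nm/s).
Between-filament speed dispersion is a truncated normal with SD 4.2 nm/s
(plus) and 2.2 nm/s (minus), reconstructed as SEM × √n from the reported
SEM (0.4 and 0.2 nm/s) and sample sizes (n = 110 and 123). There are no
catastrophes or rescues by default — 20-min acquisitions show persistent
growth — though a hook exists in the trajectory model to add them.

**Spontaneous (solution) nucleation.** A field-level Poisson stream with
rate `k_spont(c) = k_spont_ref · (c/c_ref)^n_spont`, `n_spont` = 8 (within
the 6–15 range reported for solution nucleation cooperativity). Only the
detection threshold of spontaneous nucleation (~15 μM) is measured, not the
law itself, so the amplitude is calibrated: the expected number of visible
filaments per field per 20 min is set to 2.0 at 15 μM
(`k_spont_ref` ≈ 0.0166 field⁻¹ s⁻¹). With the ×4.3 rate step from 12.5 to
15 μM this makes 15 μM the modal first-passing grid point of the empirical
criterion. Filaments from this stream "land" on the surface at an
exponential initial length (mean 3 μm) with two dynamic ends, and are
flagged `origin="landed"` in the ground truth.

**Template density.** The surface density of templates is likewise not
printed; the default `n_templates` = 130,000 per field is calibrated the
same way, so the templated detection criterion first passes at 7.5 μM
(expected 2.0 visible filaments/field/20 min there, 0.45 at 6 μM).

**MAP dose-response.** chTOG and TPX2 multiply the nucleation rate by the
hyperbolic saturation `1 + (f_max − 1) · d/(d + K½)`. chTOG: `f_max` = 21,
`K½` = 5 nM (≥95% saturated at 100 nM, within the physiological range), and
a moderate speed multiplier (asymptote 1.35 — the speed effect's magnitude
is not printed; this value is an assumption and is excluded from the
recovered-quantity checks). TPX2: `f_max` = 3, `K½` = 200 nM ("rather high
concentrations"; also an assumption excluded from checks), no speed effect.
EB3 is an identity modifier at any dose.

## Imaging forward model and measurement

Kymographs are rendered by integrating a Gaussian PSF (FWHM 0.30 μm) over
the segment [minus end, plus end] each frame, at 0.107 μm/px (typical 60×
TIRF camera sampling; neither optics parameter is printed, and the
measurement tolerances absorb the choice), plus additive Gaussian read
noise (SD 0.1 of the filament plateau). The PSF integral gives each end an
error-function edge whose half-plateau crossing falls exactly on the true
end position; the measurement stage exploits this by locating, per frame,
the outermost half-level crossings (two consecutive above-level pixels
required, linear subpixel interpolation) and fitting a Theil–Sen line to
each edge trace. Frames where the filament is still shorter than roughly
the PSF are skipped; a kymograph with more than half of its frames blank,
or without contrast 4× above the background noise, is rejected. On
noiseless input the recovered speed is exact to ≪1%; at default noise the
Monte-Carlo bias is ≪2% with per-kymograph scatter ~0.02 nm/s. The end
with the larger |speed| is labelled plus; the minus end is "capped" below
2 nm/s; ends whose |speeds| agree within that threshold are flagged
ambiguous rather than guessed. Only filaments observed ≥ 2 min are
measured, mirroring the minimum-lifetime rule of the manual analysis.

Spot counting smooths the image (σ = 1 px) and takes local maxima above a
robust noise floor (median + 6 MAD) with a 1-px exclusion radius. Landed
filaments are excluded from nucleation counts when first detected longer
than 1 μm or when both ends exceed the static threshold.

## Quantification chain

Counts are accumulated at 10 equally spaced time points per movie
(mirroring the manual protocol); the nucleation rate `r_nuc` is the OLS
slope with intercept, per field. The concentration dependence is fitted by
unweighted nonlinear least squares on `r = A·cⁿ` initialised from the
log-log regression (the fit is unweighted because no weighting scheme is
specified for the original analysis; the log-log estimate is reported
alongside). The critical-nucleus range is (round(n), round(2n)) with
round-half-up. The detection threshold is the lowest tested concentration
whose replicate-mean count at the 20-min window end is ≥ 1; the elongation
threshold is the x-intercept of the speed-vs-concentration line; fold
stimulation is the ratio of fitted rates to the zero-dose rate.

## Problem sizes and replication in the reproduction runs

The packaged reproduction (`mtnuc reproduce-paper`, `scripts/acceptance.py`)
uses: 6 concentrations × 12 replicate fields for the dilution series (the
rate and exponent estimators are unbiased; pooling 12 fields keeps the
Monte-Carlo error of the exponent at ~0.06 so that the *rounded*
critical-nucleus bound is stable — the source data likewise pool at least
three independent experiments per condition); 100 rendered kymographs per
speed condition; 100 filaments per concentration for the speed line;
10⁵ templates for the efficiency estimate; 2 × 10⁶ templates × 3 replicate
fields per chTOG dose (the zero-dose denominator at 10 μM tubulin is the
noise bottleneck of the fold estimate); and 12 replicate fields per grid
point for both detection thresholds (the replicate-mean ≥ 1 criterion sits
on a discrete grid, so extra fields reduce misclassification from Poisson
noise). A full run takes well under a minute on one CPU.

## What the synthetic data do and do not emulate

Emulated: exponential waiting times with concentration-dependent rates,
linear cumulative counts, between-filament speed dispersion, capped vs
growing minus ends, rare landed filaments, saturating/null MAP modifiers,
field geometry and frame timing, PSF blur and read noise. Not emulated:
photobleaching, filament bending and lateral fluctuation, filament
crossings and overcrowding-induced miscounting, surface crowding, TPX2
condensates, catastrophes/rescues, and camera gain specifics (intensities
are arbitrary units). Passing recovery checks therefore demonstrates that
the quantification chain is correct and unbiased under the stated noise
model, not that it is robust to every artefact of real TIRF data.

## Numerical and design notes

* Degenerate inputs raise rather than guess: negative concentrations,
  unknown assay kinds, blank kymographs, flat speed lines, < 3 rate points,
  nonpositive reference rates.
* Nonpositive rates are excluded from the power-law fit with a warning.
* Per-run seeds are derived from a base seed via SHA-256 of the
  (seed, index...) tuple, recorded in output metadata; identical configs
  give byte-identical CSVs.
* Truncation of speed draws at zero is by redraw; at the default mean/SD
  ratios the truncated mass is negligible (< 10⁻⁹).
* Filament positions and orientations are uniform over the field and
  circle; neither is stated in the source protocol and nothing downstream
  depends on them except rendering geometry.
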