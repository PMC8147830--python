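# Methods

This note documents the models, defaults and numerical choices behind
`earoct`, and what the synthetic validation does and does not demonstrate.

## Phantom model

Simulation happens directly in the reconstructed A-scan domain — linear
backscatter magnitude versus optical depth — rather than in the spectral
(interferogram) domain, because every downstream consumer (features,
classifier, thickness) operates on reconstructed A-scans. Spectral-domain
effects (k-resampling, dispersion, sensitivity roll-off) are out of scope.

**Depth axis.** `n_depth_px = 1024` samples over `depth_range_um = 2900`,
i.e. ≈ 2.83 µm of optical path per pixel — the one-sided FFT of a
2048-pixel spectrometer with a ~2.9 mm imaging range. Pixel 0 is the zero
optical delay. Depths are micrometres of optical path unless a name says
`physical`; physical = optical / refractive index (1.44 for the TM, also
applied to the biofilm layer, for which no separate index is modelled).

**Structure.** The TM is rendered as two specular surface reflections
(relative magnitudes 1.0 and 0.8) plus a diffuse interior band (0.45),
each interface spread by a Gaussian axial point-spread function of 4.9 µm
FWHM (configurable up to 19.2 µm to emulate the coarsest resolution the
classifier tolerates). Subpixel positions are exact: peaks are evaluated
analytically on the pixel grid and bands use the error-function form of a
box convolved with the PSF. A biofilm adds an interior band (0.35) and a
far-boundary reflection (0.55). An effusion fills the cavity with

* a continuous backscatter envelope `0.3 · exp(−2µ(z − z₀))`, multiplied
  per pixel by unit-mean Rayleigh speckle (fully developed speckle), and
* discrete scatterer particles as a Poisson process (`effusion_density_mm1`
  per mm of cavity, default cavity extent 1.5 mm), with amplitudes
  `0.7 · U(0.7, 1.3)` scaled by the same decay envelope.

**Noise.** The noise floor is additive Rayleigh-distributed magnitude noise
(the magnitude of complex circular Gaussian noise), scaled so that the peak
SNR — 20·log₁₀(clean peak / noise σ) — equals `snr_db`. Measured SNR of
generated A-scans is within ±0.4 dB of target on 100-seed averages
(tolerance ±1.5 dB). `snr_db=None` disables both the floor and the speckle
for idealised noiseless phantoms.

**Motion.** Hand motion is a rigid per-A-scan axial shift, uniform on
±`jitter_um`. No lateral structure is modelled: the target device acquires
M-mode (time) data without lateral scanning.

**Determinism.** An A-scan is a pure function of (spec, seed). M-mode
column *k* draws from `SeedSequence(entropy=seed, spawn_key=(k,))`, whose
first variate is the jitter offset, so any column is reproducible in
isolation; dataset A-scan *j* of ear *i* uses `spawn_key=(i, j)`. Every
A-scan carries a truth record (interface depths, scatterer positions, µ,
noise σ, offset) recoverable exactly.

## Feature extraction

**Validity.** An A-scan has signal iff its maximum rises
`signal_threshold_mult = 6` noise deviations *above the noise-floor mean*
(floor statistics from the deepest 10% of the profile). Measuring the
excursion above the mean rather than from zero matters for heavy-tailed
Rayleigh noise: the max of ~1000 floor samples alone exceeds 6σ in about a
third of draws, while the mean-referenced rule keeps the false-signal rate
near 1%. Invalid A-scans carry no features and are excluded from every
percentage readout.

**Peaks.** Rules applied in a fixed, fully specified order: (1) candidates
are interior local maxima, a flat plateau counting once at its first
sample; (2) candidates with prominence below `min_prominence_rel = 0.1` ×
the global maximum are dropped; (3) of any two survivors closer than
`min_separation_um = 9.8` (2× the 4.9 µm axial resolution) the taller wins,
equal heights resolving toward the shallower. The defaults separate TM
surfaces down to 50 µm physical thickness while suppressing speckle maxima.
The detector is property-tested for exact agreement with an independent
brute-force scan of the same rules.

**TM thickness.** The two tallest peaks (ties toward the shallower) are the
TM surfaces; thickness is their optical separation, divided by 1.44 for
physical micrometres. "Predominant" is interpreted as tallest, not
shallowest — in an effusion-filled ear a bright scatterer can occasionally
displace the true inner surface, which adds benign variance to a feature
the classifier treats as one signal among three. Mean recovery error on
phantoms is below one pixel-equivalent (≈ 2 µm physical) across the 50–120
µm physiological band.

**Attenuation.** Single-scattering round-trip model I(z) ∝ exp(−2µz); µ is
−slope/2 of an ordinary least-squares fit of ln I against depth in mm
(depth measured along the optical axis, matching how the generator plants
the decay). The default window:

* starts two resolution-widths behind the *adherent layer complex* — the
  deepest detected peak within `layer_complex_um = 150` of the TM inner
  peak — so a biofilm's own reflections never contaminate the cavity fit;
* ends at the last depth where the 5-px-smoothed profile exceeds the noise
  floor (mean + 5·σ/√5), trimmed by two resolution-widths so the
  high-leverage tail avoids boundary roll-off;
* subtracts the noise-floor mean before the logarithm, which removes the
  slope-flattening bias of the additive floor at depth.

Each of these choices was adopted after quantifying its bias: without them,
recovery errors reach +14% (layer contamination, µ = 0.5) and −9% (floor
flattening, µ ≥ 4); with them, the median over 100 A-scans at 80 dB is
within 1% for µ ∈ {0.5, 1, 2, 4, 8} mm⁻¹. An explicit `fit_region` is
fitted exactly as given on raw intensities (so a constant region returns
µ = 0 exactly); windows with fewer than 10 positive samples return NaN,
which the classifier interprets as "no measurable decay" (0 mm⁻¹).

**Quality gate.** An acquisition is trusted when SNR ≥ 80 dB and axial
resolution ≤ 19.2 µm, both inclusive. The pipeline gates on the *achieved*
SNR — the best per-column peak SNR — since transiently degraded columns are
expected and handled by per-A-scan exclusion; a mean or median would flap
for scans acquired at exactly the threshold.

## Classification

Features are exactly the three A-scan quantities above (manifest
`tm_thickness_physical_um`, `peak_count`, `attenuation_mm1`); SNR and
validity are plumbing, not model inputs. The model is a bagged ensemble of
100 CART trees (bootstrap on, √p features per split, unlimited depth,
unweighted classes by default; per-class weighting available). Prediction
averages per-tree class frequencies; ties resolve by the fixed order
NORMAL < BIOFILM < EFFUSION_BIOFILM. Hard labels are the primary output;
`predict_proba` exposes the ensemble posterior.

Models persist as JSON bundles of flattened tree arrays plus the feature
manifest, class list, seed and a SHA-256 fingerprint of the training
matrix. Prediction always runs from those arrays, so a saved-and-reloaded
model is predictive bit-for-bit identical; agreement with the scikit-learn
ensemble it was exported from is covered by a dual-route test.

**Real-time window.** The displayed readout derives from the most recent
250 A-scans at or after the trigger (`window` configurable). A stream with
fewer than 250 post-trigger A-scans yields all of them plus a shortfall
flag; the window is never extended to compensate for invalid A-scans,
which are excluded from the percentages but counted.

**Line classification.** Percentage of valid A-scans per class; INVALID
labels leave the denominator. With no valid A-scans the result is flagged
empty rather than emitting percentages. The whole-image entry point
reports both the windowed (real-time) and full-scan (post-hoc) readouts.

**Verdict.** A scan is called ABNORMAL when the windowed abnormal
percentage (biofilm + effusion-with-biofilm) exceeds 50% — the package's
own cutoff, exposed as `verdict_threshold_pct` — with the dominant abnormal
subtype attached and a flag when the two abnormal subtypes are within 10
percentage points.

**Cross-validation.** Leave-one-ear-out: one fold per distinct ear, trained
on all other ears' valid A-scans, evaluated on the held-out ear; overall
accuracy pools all folds. The fold partition is checked structurally
(disjoint, exhaustive, no leakage).

## TM thickness from images

Median filter (3×3) → global Otsu threshold (fixed-value override
available) → largest 8-connected component → per-column thickness as the
longest run of band pixels, converted by pixel pitch / 1.44. A
foreground/background mean-contrast guard (3×) returns an empty result on
structure-free images, where Otsu would otherwise bisect the noise
distribution. Columns failing the has-signal rule can be excluded from
summaries.

Because interface reflections are PSF-spread, a thresholded band is
systematically wider than the membrane (~2.5 px for a 1.0-amplitude edge
peak over a ~0.2 threshold). `thickness_stats(..., psf_fwhm_um=...)`
subtracts the expected super-threshold half-width `σ·√(2·ln(A/t))` of each
edge, which removes the bias to sub-pixel level; it is off by default so
that sharp synthetic masks measure their literal pixel extent. Group
comparisons emit descriptive statistics only (n, mean, sd, 2.5–97.5%
range); inferential testing is left to the user's statistics environment.

## Synthetic study conditions

The canonical study is 10 ears per class × 100 A-scans at 80 dB SNR, with
per-ear anatomy drawn once: TM thickness U(50, 120) µm, surface depth
U(400, 700) µm, biofilm (when present) U(30, 60) µm, effusion scatterer
density 8 mm⁻¹ and µ U(1, 4) mm⁻¹. These ranges span the physiological TM
band and give the three classes their expected signatures (2 peaks / 3
peaks / ≥6 peaks with measurable attenuation). Leave-one-ear-out accuracy
on this design exceeds 90% (typically 94–100% depending on seed), which
stands in qualitatively for the >90% accuracies reported for real-ear
classifiers of this kind; it is *not* evidence about clinical performance,
since the phantoms lack real anatomical variability, probe-angle effects,
mirror/flip artifacts and inter-device differences.

A known departure from the idealised expectation that accuracy degrades
monotonically with SNR: between 80 and 40 dB accuracy sits at ceiling and
40 dB occasionally edges ahead by ~1% — at 80 dB the within-ear feature
variance is so small that trees can overfit individual training ears'
thickness values, a regularisation-by-noise effect. The degradation test
therefore asserts equivalence within a noise band at the top of the range
and the unambiguous collapse at 20 dB (where speckle maxima cross the
peak-prominence threshold and the class signatures dissolve).

## Problem sizes

Validation sizes were chosen so the whole suite and the acceptance script
each run in well under a minute on one CPU while keeping estimator noise
far from the tolerances: 100 seeds per SNR/µ/thickness recovery point,
1000 random profiles for detector-oracle equivalence, 58 ears × 5 A-scans
for the fold-structure check, and the full 10 × 3 × 100 study for
end-to-end accuracy.

## Known limitations

* Speckle statistics and probe-motion spectra are surrogates (unit-mean
  Rayleigh; uniform rigid jitter), not fits to measured data.
* The biofilm shares the TM's refractive index; effusion attenuation is
  the only attenuation modelled (the TM itself does not attenuate).
* Attenuation is reported per mm of optical depth; converting to per-mm of
  geometric path in a medium of known index is a constant factor left to
  the user.
* The classifier is only as good as the three features; image-texture or
  surface-otoscopy information is intentionally out of scope.
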