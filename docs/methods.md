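# Methods

## Forward optical model

Tissue is modeled as a single homogeneous absorbing layer observed in
diffuse reflection under narrow-band laser illumination at 445 nm and
473 nm. Reflectance follows a modified Beer–Lambert law

    R(λ) = R₀ · exp(−μₐ(λ) · DPF · d),

with μₐ(λ) = ln(10)·[s·ε_HbO₂(λ) + (1−s)·ε_Hb(λ)]·c. Assumptions, and why
they were chosen:

- **Hemoglobin is the only chromophore.** In the 440–480 nm window
  hemoglobin dominates mucosal absorption; melanin, bilirubin and water are
  neglected.
- **Wavelength-independent baseline R₀ and DPF.** Scattering varies slowly
  over the 28 nm separating the two lasers; folding it into a constant
  baseline keeps the model invertible with a single lookup table. Any
  common-mode error cancels in the inter-frame ratio anyway.
- **Monochrome effective channel per laser.** The real sensor is an RGB CCD
  whose channel sensitivities are not publicly tabulated, so each laser
  frame is modeled as one effective intensity channel rather than a
  spectral integral over the sensor response. This is a documented
  limitation, not an approximation that can be checked here.
- **No radiative transport.** Monte-Carlo photon migration, layered mucosa
  and phase functions are out of scope; the package is a pipeline
  reference, not a tissue-optics simulator.

### Extinction data

`data/hb_extinction_synthetic.csv` holds decadic molar extinction of
oxy/deoxy-hemoglobin on a 400–600 nm, 2 nm grid, per tetramer
(64,500 g/mol). It is a **synthetic reconstruction**: a monotone (PCHIP)
interpolation through approximate anchor values recalled from the standard
compiled whole-blood tabulations. The qualitative features that the method
depends on are correct — Soret and Q bands, isosbestic crossings near
421/500/547/570/583 nm, deoxy exceeding oxy extinction at both 445 and
473 nm with *different* contrast — but individual coefficients should not
be used for quantitative spectroscopy. All simulation and estimation use
the same table, so none of the package's results depend on its metrological
accuracy.

## Inversion

The estimator inverts the log-ratio r = ln(I₄₇₃/I₄₄₅) through a table of r
versus StO₂ computed from the forward model at a reference state. The
log-ratio (rather than the plain ratio) makes illumination-scale invariance
exact and linearizes pathlength effects. Defaults:

| parameter | default | unit | rationale |
|---|---|---|---|
| wavelength pair | 445, 473 | nm | the device's OSI lasers |
| reference c(Hb) | 15 | g/L | effective mucosal hemoglobin giving optical depths ~0.25–2.2 across the saturation range |
| reference pathlength | 0.15 | mm | blue-light penetration depth scale in mucosa |
| DPF | 1.0 | – | absorbed into the pathlength; no independent information available |
| baseline R₀ | 0.5 | – | cancels in the ratio; sets simulated exposure only |
| LUT grid step | 0.5 | % StO₂ | below display quantization (1 %) at negligible cost |
| validity floor / ceiling | 1 % / 98 % | of full scale | rejects dark pixels and specular saturation |

The LUT reference state equals the phantom defaults, so the noiseless
round-trip is exact to the grid step. Out-of-range ratios clip to 0/100 %
and stay *valid* with a separate clip flag, so ROI means are not biased by
silently dropping extremes.

**Concentration sensitivity (measured, not assumed).** The intensity
log-ratio is proportional to c·d, so a concentration (or pathlength)
mismatch k between tissue and LUT reference maps the estimate to
s′ ≈ k·s + (1−k)·s₀ with s₀ ≈ 129 % for the default wavelengths and
extinction table. Measured on noiseless flat phantoms, a +10 %
concentration error shifts a 50 % StO₂ pixel to ≈42 % — about 0.8 % StO₂
per 1 % concentration error. Two-wavelength intensity-ratio oximetry
without an attenuation normalization is therefore *not*
concentration-invariant; the real device's proprietary calibration
presumably addresses this, and this package makes the sensitivity explicit
(it is verified against the closed form in the test suite) instead of
claiming device equivalence. The phantom generator accordingly keeps
hemoglobin heterogeneity mild (1 % relative SD).

## Video stream model

Frames alternate 445, 473, 445, … starting at 445 nm (the phase is the
package's choice; it makes white-light extraction the even subsequence).
Pairing is disjoint — frames (0,1), (2,3), … — because 30 fps capture is
stated to produce 15 fps output; a sliding window would produce 29 maps
per second. A trailing unpaired frame is dropped and logged. The sensor is
16-bit linear; exposure is set so the brightest clean pixel sits at ~60 %
of full scale. Noise is Poisson shot noise on the counts plus additive
Gaussian read noise (default SD 10 counts). Consecutive frames are assumed
co-registered; motion compensation is a non-goal.

## Display rendering

StO₂ maps to RGB in 1 % bins: 0 % dark blue (25,35,110), 50 % yellowish
green (170,210,40), 100 % red (220,30,30), interpolated in HSV so the hue
descends monotonically blue → cyan → green → yellow → red. The exact anchor
triples and the interpolation path are cosmetic choices (only the hue names
are constrained); all 101 entries are pairwise distinct. Invalid pixels
render mid-gray.

## Synthetic phantoms and the ischemia experiment

`make_scene` draws the StO₂ field as a smooth Gaussian random field
(Gaussian-filtered white noise, correlation length 12 px, standardized to
the requested mean and SD before clipping to [0,100] %), with mildly
heterogeneous hemoglobin (1 % relative SD) and baseline (5 %), and ~0.5 %
specular pixels that saturate the sensor.

`simulate_experiment` reproduces the study design: n = 3 subjects × four
time points (before/after anastomosis, 1 and 30 min after arterial
ligation) with target means (52.6, 52.0, 15.9, 12.1) % and between-subject
SDs (2.0, 2.6, 6.0, 5.3) %. Subject-level means are drawn
Normal(target, SD), clipped to [0,100]; post-ligation scenes embed a
demarcated hypoxic disk (sigmoid edge, default 8 px) at the drawn mean
inside a perfused surround at 52 %, covering the three ROI sites with a
wide margin. Time points are independent draws; no temporal decay model is
implied by the source data (1 min vs 30 min are statistically
indistinguishable there). All randomness flows from one protocol seed
through spawned generators, so every acquisition is independently
reproducible. Within-scene spatial SD defaults to 3 % StO₂ — a visible but
moderate texture chosen by the package; the source reports no pixel-level
statistics.

What the phantoms deliberately do **not** emulate: real mucosal geometry
and folds, peristaltic motion and blur, inter-frame motion, RGB sensor
spectral integration, wavelength-dependent scattering, and any device
calibration. Passing tests therefore demonstrate the correctness and
statistical behavior of the *pipeline* under its own forward model, not
clinical accuracy on tissue.

## Quantification protocol

Three square ROIs (default 21 px side on 256×256 scenes — the source gives
no ROI size) at fixed relative positions; arithmetic mean of valid pixels
per ROI, requiring ≥ 50 % valid; per-subject value = mean of that subject's
three ROI means (pooling to one value per subject preserves the pairing
unit for n = 3; a pooled per-ROI mode is selectable); group summaries as
mean ± sample SD (n−1); two-sided paired t-tests at α = 0.05 with no
multiple-testing correction, matching the study's analysis. Zero-variance
differences return p = 1 with a degeneracy flag rather than an error.

## Numerical choices and problem sizes

- LUT inversion by linear interpolation on the 0.5 % grid; monotonicity of
  the tabulated ratio is asserted at construction (a non-monotone ratio
  indicates a degenerate wavelength pair and is refused).
- Scene statistics are evaluated on 256×256 phantoms; the experiment-level
  statistical suite uses 200 independently seeded replicates of the default
  protocol and the acceptance script 101 replicates — sizes chosen to make
  Monte-Carlo fractions and biases stable to well under the tested margins.
- Invalid pixels carry NaN (never 0) so true anoxia is not aliased;
  serialized masks pack validity and clip flags into one uint8 TIFF.
- Isosbestic wavelengths are located by bisection on the piecewise-linear
  extinction difference, so "absorption independent of saturation" holds to
  machine precision exactly at those roots.

## Known limitations

- Not device-equivalent: the commercial calibration, RGB spectral
  integration and specular handling are undisclosed; thresholds here are
  engineering defaults.
- Concentration/pathlength sensitivity of the two-wavelength log-ratio (see
  above) is inherent to the inversion variable.
- The porcine in-vivo measurements themselves are not reproducible at desk
  scale; the synthetic experiment tests the protocol's statistical
  behavior, not animal physiology.
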