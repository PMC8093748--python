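# Methods

This note documents the models, parameter choices, and numerical decisions
behind `cscolor`, and what the synthetic experiments do and do not show
about real photographic data.

## Colorimetric chain

Spectra are stored as piecewise-linear reflectance curves on strictly
increasing wavelength grids (nm).  Tristimulus integration uses a common
1-nm grid over the intersection of the spectrum, illuminant, and observer
supports, with the trapezoidal rule; the normalization `k = 1/Σ I·ȳ Δλ`
makes a perfect white reflector map exactly to the illuminant white point.
The illuminant and observer are CIE D65 and the CIE 1931 2° observer,
shipped as 5-nm CSV resources and interpolated linearly — the default
assumption of standard spectral-processing toolkits when none is specified.
Conversions require joint support down to 380 nm and up to 760 nm; plant
spectrometers that measure to 2500 nm lose nothing because the observer
curves vanish above 780 nm.

sRGB uses the IEC 61966-2-1 matrix (7-decimal constants) and transfer curve
(linear toe below 0.0031308, exponent 1/2.4 above).  Out-of-gamut and
over-range linear values are clipped to [0, 1] and flagged rather than
gamut-mapped: that is what a consumer camera pipeline does to the data this
package is about.  Reflectance above 1 (gloss/specular artifacts) is
accepted, integrated as-is, and flagged.  CIE-LAB uses the D65 reference
white `(0.95047, 1, 1.08883)` and the cube-root function with the 6/29
linear segment.  HSV follows the hexcone convention with hue in degrees and
the sentinel H = 0 for achromatic colors.  Hue is circular; aggregation
defaults to the circular mean (arithmetic averaging is available because
legacy point-measurement tools averaged degrees naively, and comparing the
two is itself informative).

## Avian visual model

Cone spectral sensitivities are log-normal pigment templates
`R(λ) ∝ exp(−ln²(λ/λmax)/(2w²))` with `w = 0.06` and λmax values typical of
average UVS and VS eyes: u = 370 (U-type) or 410 nm (V-type), s = 445,
m = 508, l = 565, double cone 565 nm.  Curves are normalized to unit area so
a flat spectrum under a flat illuminant stimulates all cones equally;
measured sensitivities can be substituted from CSV.  Quantum catches use an
ideal equal-energy illuminant because museum spectrometry is
illumination-standardized, and the downstream statistic (R²) is scale-free;
receptor-noise weighting is deliberately omitted for the same reason.

Relative single-cone catches embed into a regular tetrahedron of
circumradius 0.75.  The orientation places the u vertex on the +x axis, so
`x = q_u − ¼` is exactly the relative UV/violet stimulation; y and z span
the remaining (camera-visible) chromatic plane.  Orientation matters here:
per-axis regressions are not rotation-invariant, and the UV-blindness
analysis requires an axis that isolates the UV cone.  The achromatic signal
is `DL = ln(Q_d)`, a monotone log channel; intensity scaling of a spectrum
leaves (x, y, z) unchanged and shifts DL by the log of the scale.

## Photo measurement model

A photograph is measured as k = 3 random points inside one region of
interest, averaged to a photo value, then to a unit (species/treatment)
value; HSV and Lab are converted per point and then averaged, mirroring how
per-point measurement tools are used in practice.  Patterned patches are
sampled over the whole ROI without separating pattern elements.

The synthetic camera acts in linear RGB: truth × lognormal exposure gain
(per photo) × per-channel lognormal white balance, plus additive per-photo
sensor noise and per-point within-ROI scatter, then clipping to [0, 1] and
sRGB encoding.  Putting all noise upstream of the transfer curve is
physically right and has a useful consequence: saturated photos condense
exactly at 255, which is what makes ceiling-detection workable.  Saturation
screening flags a unit × channel when more than 25% of values sit at or
above `level − 1` (the threshold is configurable; the 25%/254 defaults are
this package's operationalization of a judgement the original workflow made
by eye).  With gamma disabled the model degenerates to `truth + noise` on
the 8-bit scale — the configuration used for all variance-components
arithmetic, since closed-form R² predictions hold only for additive noise
in the measured scale.

Bird-study defaults (chosen once as representative of uncurated wildlife
photography, and to land individual-photo agreement in the R² ≈ 0.5–0.8
regime observed with real citizen-science data): exposure log-SD 0.35,
white-balance log-SD 0.12, sensor SD 10/255, ROI scatter 8/255, 1–25 photos
per species (uniform), star ratings skewed toward 4–5.

## Synthetic species and the UV contrast

Species truths are family-templated reflectance spectra on 300–800 nm:
sigmoids for red/yellow/pink, a blue peak plus red shoulder for purple,
plateaus for white/black/gray-brown, with jittered parameters; the mix is
weighted toward gray/brown plumage.  Every species also receives a small
multiplicative UV perturbation (`×(1 + U(0, 0.15)·gauss(355, 12))`), and a
dedicated UV-contrast family carries a larger additive UV bump — UV
variation that is deliberately (a) invisible to sRGB and (b) small relative
to visible-range variation, since UV reflectance largely tracks visible
reflectance in real plumage.  Under these conditions two structural
properties hold and are asserted in tests: the x axis is the least variable
chromatic axis, and x for the U-type eye is the worst-predicted avian
dimension from Lab a + b.

The museum generator draws 1 + Binomial(4, 0.405) specimens per species
(mean 2.62), small replicate noise (SD 3/255), uniform ages 0–80 years, and
an optional planted age drift per channel for recovery tests.

## Plant control ladder

Seven treatments run from spectrometry to citizen science with
monotonically increasing gain/white-balance/sensor/ROI noise, plus small
systematic exposure biases per camera method (flash brightens, ambient
dims) so treatments differ in location as well as spread.  Two synthetic
species mimic a dark purple-red and a bright yellow flower; the bright
species gets a 2.2× exposure multiplier in one treatment, driving its R and
G channels into saturation so the screening-and-exclusion path is exercised
end to end.  Sample sizes (15–48 photos per treatment) match the scale of a
realistic field comparison.

## Precision curve and the plateau rule

The empirical curve follows the original procedure exactly: one regression
of species means on spectrometry means, absolute residuals grouped by each
species' own photo count.  This confounds species identity with photo
count, so a bootstrap mode subsamples k photos per species from the same
well-sampled species at every k (residuals against the full-data regression
line by default; per-k refitting behind a flag).  Under pure Gaussian photo
noise of SD σ the curve is σ√(2/(πk)), which the bootstrap reproduces
within a few percent and the tests assert at 5%.

"Plateau" has no standard quantitative definition; the rule here is the
smallest k at which the remaining achievable gain
`(c(k) − c(K)) / (c(1) − c(K))` falls below a threshold (default 0.10,
i.e. 90% of the possible precision improvement realized), after 3-point
moving-average smoothing of the curve interior (endpoints unsmoothed, so
the gain normalization is anchored on the measured extremes).  For the
ideal 1/√k decay with K = 25 this recommends k = 13, and k stays within
12–15 for thresholds 0.08–0.12.  A per-step relative-improvement rule was
considered and rejected: for 1/√k decay the step ratio only drops below 2%
at k ≈ 25, making the recommendation degenerate at the curve's end.  A flat
curve plateaus at k = 1; a non-decreasing curve returns K with a
`plateaued=False` flag.

## Statistical tests

Bartlett's T (with the standard correction factor C) and the tie-corrected
Kruskal–Wallis H are implemented directly from their formulas — they are
part of the analysis contract — with χ² reference distributions; the test
suite proves equivalence to the scipy implementations at 1e-10 and
calibrates both to a 4–6% rejection band under a true null at α = 0.05.
Zero-variance groups make Bartlett's log-variance undefined and raise with
the offending group named; all-identical pooled values likewise for H.
The patterned-vs-plain contrast uses Welch's t per channel with Bonferroni
correction across the three channels capped at 1 (Holm available); a
Bonferroni-style cap is what produces the reported "p = 1" for an exactly
null contrast.

## What the synthetic experiments do and do not show

Passing tests demonstrate that the pipeline's statistics behave as theory
predicts under a known generative model: agreement R² matches
variance-components arithmetic, precision curves match the √k law, test
sizes are calibrated, the UV mechanism produces the expected blind spot,
and the control ladder's variance ordering emerges rather than being
asserted.  They do not certify real photographs: the generator has no
background contamination, misidentified ROIs, inter-observer point-picking
variation, JPEG compression, or species-correlated lighting, all of which
push real individual-level agreement below the synthetic values.  Problem
sizes in the test suite and acceptance script (e.g. 537 synthetic species,
100 calibration replicates, 2,000 null replicates) were chosen to keep
Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- The plain tetrahedral model omits receptor noise, ocular media
  transmission, and von Kries adaptation; only rank/variance structure of
  the avian coordinates should be interpreted, not discriminability.
- The illuminant/observer behind any particular legacy conversion may
  differ from D65/2°; both are injectable if a different convention is
  needed.
- Hue regressions treat degrees linearly by default (matching the legacy
  analysis); the circular-statistics alternative exists but then R² is not
  comparable across modes.
- The empirical precision curve inherits the species-confounding of the
  original procedure by design; use the resampled mode for inference.
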