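# Methods

## Speckle model and simulated phantom

The simulator renders an envelope-detected B-mode display image directly:
each background pixel at depth $d$ mm is drawn as
$\mathrm{Rayleigh}(\sigma_s)\cdot(1-\lambda)^d$, clipped to the 8-bit
display range. The Rayleigh envelope is the canonical fully developed
speckle model (many random sub-resolution scatterers per resolution cell),
and it makes the simulator's truth closed-form: the point SNR
(mean/standard deviation) is $\sqrt{\pi/(4-\pi)} \approx 1.913$ at every
depth, independent of the scale. A simple display-style log-compression is
available as an option but off by default: the metrics operate on whatever
display mapping the device exported, and the linear-envelope default keeps
the closed forms exact.

Defaults, with units and rationale:

| parameter | default | meaning |
|---|---|---|
| image field | 450 × 760 px at 0.1 mm/px (45 × 76 mm) | deep enough for the 3 cm wire group plus margin; wide enough for six 8 mm discs in two rows with a free SNR strip |
| `speckle_scale` σ_s | 40 display units | background mean ≈ 50 of 255: a mid-grey gelatin background with negligible ceiling clipping |
| `decay_per_mm` λ | 0.01/mm | ≈ 0.9 dB/cm amplitude loss, a soft-tissue-phantom-like attenuation visible over 45 mm without flattening the deep rows |
| contrast targets | 8 mm discs at −9, −6, −3, +3, +6 dB and hyperechoic | the graded-contrast group of a CIRS 040GSE-style phantom |
| hyperechoic disc | +12 dB | the datasheet grades this target only qualitatively; any value above +6 dB preserves the grading order |
| wires | 1, 2, 3 cm deep at 8 mm lateral | the vertical wire group used for PSF estimation |
| PSF sigmas (σ_h, σ_v, σ_e) | 0.3, 0.2, 0.6 mm | sub-millimetre lateral/axial resolution and a broader out-of-plane beam, typical of linear POCUS probes |

A contrast disc multiplies the local speckle amplitude by $10^{\,c/20}$,
so foreground and background are Rayleigh with scales in ratio
$k = 10^{c/20}$ and the true gCNR is the overlap integral of the two
Rayleigh densities, computed by numerical integration
(`analytic_gcnr_rayleigh`). This oracle ignores 8-bit clipping and the
small within-ROI depth decay; both effects are below the estimator's
finite-sample noise for the default geometry, and the cross-check against a
$10^6$-sample histogram agrees to better than 0.01.

A wire renders as an anisotropic Gaussian blob. Its amplitude is set to
(display ceiling − mean local speckle), so the echo saturates the display
at its centre *on top of* the speckle pedestal; with an additive pedestal
the peak-above-baseline of the observed profile then equals the Gaussian
coefficient and the FWHM of the rendered wire is exactly
$2\sqrt{2\ln 2}\,\sigma$ per axis, which is what the ground truth records.
Elevational resolution is simulated the way it is measured physically:
when the acquisition is marked as 45°-oriented, the wire's lateral blur is
σ_e instead of σ_h, so the out-of-plane beam width appears along the image
row axis and is read with the ordinary horizontal profile machinery.

The gain sweep is emulated as amplitude scaling followed by clipping, with
0–100 % gain spanning a ×12 (≈ 21.6 dB) swing, a realistic receive-gain
range. Two genuine failure modes emerge: zero gain blanks the image (all
targets indistinguishable, gCNR 0), and at high gain the speckle is driven
deep into the display ceiling. Clipping alone degrades gCNR only once the
clip level falls *below* the point where the foreground and background
densities cross — above that point the min-overlap is provably unchanged
because the piled-up ceiling mass equals the tail overlap it replaces —
which is why the full swing is sized to push the deep targets past that
regime; the optimum gain then sits at an interior setting.

## Metric estimators and numerical choices

**gCNR.** Histogram densities on shared bin edges; each histogram is
normalised to unit mass and the overlap is the binwise min-sum. Default 64
equal-width bins over the pooled min–max (a bias/variance compromise for
8-bit data); explicit edges, an explicit range, or pooled-quantile bins
are options. Quantile binning makes the estimator exactly invariant to
monotone intensity remaps. A degenerate range (all values equal) is one
bin: identical occupancy gives 0. Values are clamped to [0, 1]. The
definitional bounds are exact, not asymptotic: identical arrays give
exactly 0, sets with no shared bin exactly 1.

**Depth SNR.** Noise is the population (ddof 0) standard deviation: the
row is the entire population of interest, and the convention is fixed for
determinism. Zero-variance rows are flagged NaN rather than dropped so
depth indexing is preserved. Window averaging uses non-overlapping windows
anchored at the curve's first depth, each output sample at the window
centre, NaNs excluded from the mean, empty windows omitted. Note the
row estimator mean/std has a finite-width positive bias
(≈ +4 % at 30 columns for Rayleigh data, from Jensen's inequality applied
to 1/std); the recovery tests measure against the analytic constant with a
5 % tolerance that absorbs it. The estimator is reported as defined rather
than debiased, because on real images the bias depends on the unknown
intensity distribution.

**PSF.** Line profiles are nearest-pixel lookups at native spacing
(`round(length/2/spacing)` samples per side, default 3 mm lines); the wire
centroid is the arithmetic mean of the labelled pixel coordinates.
Replicates are aligned at their highest prominent peak
(`scipy.signal.find_peaks`, prominence ≥ 10 % of the profile's dynamic
range, guarding against speckle maxima), linearly resampled onto a common
uniform grid at the finest native spacing with 0 kept on the grid, and
averaged over the common support. Width is the FWHM above a baseline
estimated as the median of the outer 25 % of samples, with crossings
located by linear interpolation; this makes the width invariant to
amplitude scaling and additive offsets. A flat replicate or a profile that
never re-crosses its half-maximum is an error, not a guess.

**Pad conversion.** mm→pixel pads round half away from zero per axis, with
each axis's own spacing; boxes are half-open and clipped to image bounds.

## Study-table generator and statistics

Survey ranks: per rater and category, device scores are latent quality
values plus independent Gaussian noise (sd 1.0 ≈ one rank step of
disagreement), ranked descending — each rater necessarily emits a valid
permutation. The default latent scores are the negated published mean
ranks per category, so the synthetic survey reproduces the reported
preference structure in expectation. Blind-scan annotations: per
operator × phantom × device, the pass count is Poisson at the instructed
pacing (30 s video × 0.125 passes/s, minimum 1), successes are binomial at
the per-device rate, and the manual ONSD measurement is the phantom's
caliper mean plus the per-device bias plus Gaussian noise (sd 0.3 mm).
Defaults use the published per-device success rates and bias coefficients
as the injected effects; 15 raters, 9 operators, 3 phantoms per device.

Rank ANOVA is computed with rater as a blocking factor (repeated-measures
layout). This matters: within a rater, ranks are a constrained permutation
whose groups are negatively correlated, and a one-way layout on pooled
ranks roughly doubles the nominal type-I error (≈ 10 % at α = 5 % in a
2000-replicate null simulation), while the blocked form — equivalently the
Iman–Davenport F transform of the Friedman statistic — holds ≈ 5 %. With
zero residual variance (perfect rater agreement) the test reports p = 0.

The paired Wilcoxon uses scipy with Pratt zero handling, the exact null
when the data admit it (no zeros, n ≤ 25) and the tie-corrected normal
approximation with continuity correction otherwise; its null rejection
rate is ≈ 4–5 % in the same simulation. All rank differences zero yields
p = 1 with a warning rather than an exception.

The ONSD bias regression is OLS of (measurement − caliper mean) on device
indicator columns with no intercept, so each coefficient is directly that
device's expected bias in mm with conventional standard errors and 95 %
CIs. One coefficient per device (including all devices) is only estimable
without an intercept, which fixes the design. Phantoms are pooled as
independent observations. Summary tables use the sample (n−1) standard
deviation, configurable.

Latin squares are cyclic squares with independently seeded row, column and
symbol permutations — every symbol once per row and column by construction.

## What the simulator does and does not emulate

It emulates: Rayleigh speckle with depth decay, graded-contrast discs,
saturating wire echoes with anisotropic Gaussian blur, gain-induced
blanking and saturation, replicate-to-replicate speckle variation with
fixed geometry, and the effect structure of the two human studies.

It does not emulate: acoustic propagation (no diffraction, reverberation,
shadowing or refraction artifacts), log-compressed vendor post-processing
(edge enhancement, speckle reduction), spatially varying PSFs or focal
zones, rater covariance beyond independent noise, operator learning
effects, or phantom-to-phantom manufacturing variability. Passing recovery
tests therefore demonstrates the correctness of the estimators under the
stated speckle model, not device performance on real tissue; on real
exports the metrics inherit whatever display processing the vendor
applied.

## Problem sizes

The packaged test and reproduction runs use 450 × 760 px phantoms (0.1 mm
spacing; 900 × 1520 at 0.05 mm for fine PSF sampling), triplicate
replicates as in standard QA practice (10 for the contrast-ordering
check), 2000-replicate null simulations for test-size calibration and 200
replicates for bias-recovery coverage — sizes chosen so each check's
Monte-Carlo error is several times smaller than the tolerance it is judged
against.

## Known limitations

* The analytic gCNR oracle ignores quantisation and ceiling clipping;
  for the hyperechoic disc (+12 dB) a visible fraction of the foreground
  saturates and the measured value sits a few thousandths below the
  oracle. The grading order is unaffected.
* The FWHM-above-baseline width is only meaningful for unimodal profiles;
  side-lobed PSFs would need a different scalarisation.
* The row-SNR estimator's finite-width bias (above) is inherent to the
  mean/std definition at narrow boxes.
* Nearest-pixel line sampling quantises the centroid to the pixel grid; at
  native spacings ≥ σ/2 this contributes a sub-sample width jitter that
  replicate averaging suppresses but does not remove.
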