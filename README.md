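# pocusqa

Quantitative image-quality QA for B-mode ultrasound calibration phantoms,
plus the statistics used to compare point-of-care ultrasound (POCUS)
devices for optic nerve sheath diameter (ONSD) measurement.

Portable POCUS probes differ widely in contrast, depth penetration and
resolution, and those differences propagate into clinical measurements such
as ONSD (a sonographic surrogate for intracranial pressure). `pocusqa`
implements the laboratory metrics used to characterise such devices on a
multi-purpose calibration phantom (CIRS 040GSE-style wire and
graded-contrast targets), a synthetic phantom simulator with closed-form
ground truth so every metric can be verified without physical hardware, and
the statistical layer for device-comparison studies.

## The metrics

**Generalized contrast-to-noise ratio.** For foreground (contrast-target)
and background intensity densities $p_f$ and $p_b$,

$$\mathrm{gCNR} = 1 - \int \min\{p_f(x),\, p_b(x)\}\,dx .$$

gCNR is the complement of the overlap of the two densities: 0 when they
are identical, 1 when an ideal classifier separates them perfectly, and
invariant to monotone display remaps. Densities are estimated by
histograms on shared bins (64 equal-width bins by default; quantile bins
optional). The ROI protocol takes the labelled target as foreground and
the remainder of a 1.7 mm-padded bounding box as background.

**Depth-resolved SNR.** Inside a structure-free box, each image row gives
signal = mean intensity, noise = population standard deviation, and
SNR = signal/noise as a function of depth, optionally block-averaged in
5 mm windows. Fully developed Rayleigh speckle has the constant point SNR
$\sqrt{\pi/(4-\pi)} \approx 1.913$, which the simulator recovery tests use
as truth.

**PSF width.** Intensity profiles across 100 µm wire targets (3 mm lines
through the wire centroid, horizontal and vertical; lateral-at-45° for the
elevational direction) are peak-aligned over replicate images, averaged,
and scalarised as the full width at half maximum above an outer-quartile
baseline. A Gaussian beam of width $\sigma$ has
$\mathrm{FWHM} = 2\sqrt{2\ln 2}\,\sigma$.

**Study statistics.** Per-category tests for a device effect on clinician
preference ranks (rater-blocked ANOVA on ranks, i.e. the Iman–Davenport
form of the Friedman test), paired Wilcoxon signed-rank between two
devices, blind-scan pass-success summaries, a per-device ONSD
measurement-bias OLS regression (device indicators, no intercept, so each
coefficient is that device's expected bias in mm), and a seeded
Latin-square generator for counterbalancing.

## Worked example

```python
import numpy as np
import pocusqa as pq

spec = pq.default_spec(seed=1)                      # CIRS-040GSE-like layout
images, mask, truth = pq.generate_triplicate(spec)  # 3 replicate acquisitions

for tid in mask.ids_of_kind("contrast_target"):
    entry = mask.legend[tid]
    vals = [pq.gcnr_for_target(img, mask, tid).value for img in images]
    print(f"{entry.contrast_db:+5.0f} dB: measured gCNR {np.mean(vals):.3f}  "
          f"(analytic truth {truth.gcnr[tid]:.3f})")

box = pq.padded_bbox(mask, 1, 0.0, images[0])       # structure-free SNR strip
_, _, snr = pq.snr_curve(images[0], box, mask=mask)
smooth = pq.window_average(snr, window_mm=5)
print("windowed SNR at 2.5/22.5/42.5 mm:",
      " ".join(f"{v:.2f}" for v in smooth.value[[0, 4, 8]]),
      f"(speckle model constant {truth.snr_constant:.3f})")

wid = mask.ids_of_kind("wire")[0]
centroid = pq.centroid_of_label(mask, wid)
profiles = [pq.extract_line_profile(img, centroid, "horizontal", 3.0) for img in images]
mean_psf = pq.align_and_average_psf(profiles, direction="horizontal", depth_cm=1.0)
print(f"1 cm wire, horizontal FWHM: {pq.psf_width(mean_psf):.3f} mm "
      f"(true {truth.psf_width_mm[wid]['horizontal']:.3f} mm)")
```

prints

```
   -9 dB: measured gCNR 0.651  (analytic truth 0.649)
   -6 dB: measured gCNR 0.467  (analytic truth 0.471)
   -3 dB: measured gCNR 0.253  (analytic truth 0.249)
   +3 dB: measured gCNR 0.247  (analytic truth 0.249)
   +6 dB: measured gCNR 0.473  (analytic truth 0.471)
  +12 dB: measured gCNR 0.772  (analytic truth 0.778)
windowed SNR at 2.5/22.5/42.5 mm: 2.03 1.96 2.05 (speckle model constant 1.913)
1 cm wire, horizontal FWHM: 0.748 mm (true 0.706 mm)
```

The measured gCNR tracks the Rayleigh-overlap truth per target and shows
the expected U shape over signed contrast: the ±3 dB targets are hardest to
tell from background. The depth-SNR hovers at the speckle constant (the
small upward offset is the finite-width row estimator's known bias), and
the wire's lateral FWHM recovers the simulated beam width.

## Command line

```sh
pocusqa simulate phantom --seed 3 --out sim/        # PNGs + mask + truth.json
pocusqa simulate study --seed 3 --out study/        # survey.csv, annotations.csv
pocusqa qa gcnr --image sim/phantom_rep0.png --image sim/phantom_rep1.png \
    --mask sim/mask.png --out gcnr.csv
pocusqa qa snr --image sim/phantom_rep0.png --mask sim/mask.png --out snr.csv
pocusqa qa psf --image sim/phantom_rep0.png --mask sim/mask.png \
    --direction horizontal --out psf.csv
pocusqa stats survey --in study/survey.csv --out tables/ \
    --pair butterfly_iq clarius_l7hd
pocusqa stats onsd-bias --in study/annotations.csv --out bias.csv
pocusqa run --seed 1 --out demo/                    # end-to-end bundle
```

`pocusqa run` is deterministic: the same seed reproduces every CSV byte for
byte.

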