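"""Synthetic calibration-phantom simulator with recoverable ground truth.

Emulates the structures of a CIRS 040GSE-style multi-purpose phantom on
which B-mode image quality is conventionally assessed: thin (100 µm) wire
targets at 1, 2 and 3 cm depth and 8 mm diameter graded-contrast discs
(−9, −6, −3, +3, +6 dB and a hyperechoic disc), embedded in fully developed
speckle.  The speckle envelope is Rayleigh — the canonical model for the
amplitude of many random sub-resolution scatterers — which gives the
simulator closed-form truth:

* the point SNR (mean/std) of Rayleigh speckle is ``sqrt(pi/(4-pi)) ≈ 1.913``;
* a disc of contrast c dB scales the local Rayleigh scale by ``10**(c/20)``,
  so its true gCNR is the overlap integral of two Rayleigh densities;
* a wire renders as an anisotropic Gaussian blob whose FWHM per axis is
  ``2*sqrt(2*ln 2) * sigma``.

Depth-dependent signal loss is modelled as a fractional amplitude decay per
mm.  Elevational (out-of-plane) resolution is probed the way it is measured
physically: with the transducer at 45° to the wires, out-of-plane blur
appears along the lateral axis of the image, so the simulator renders wires
with the elevational sigma as their lateral width in that orientation.

The study-table generator stands in for the two human studies: clinician
preference ranks arise from per-device latent quality scores plus rater
noise, rank-transformed per rater and category; blind-scan annotations draw
per-pass successes from a per-device Bernoulli rate and ONSD measurements
from the phantom's caliper mean plus a per-device bias and Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .phantom_io import (
    AnnotationRecord,
    LabelEntry,
    LabelMask,
    PhantomImage,
    SurveyRecord,
    SURVEY_CATEGORIES,
)

__all__ = [
    "HYPERECHOIC_DB",
    "INSTRUCTED_SECONDS_PER_SWEEP",
    "RAYLEIGH_SNR",
    "ContrastTargetSpec",
    "PhantomSpec",
    "GroundTruth",
    "StudyEffects",
    "default_spec",
    "default_study_effects",
    "analytic_gcnr_rayleigh",
    "gaussian_fwhm",
    "instructed_pass_rate",
    "simulate_speckle",
    "render_contrast_target",
    "render_wire",
    "generate_phantom",
    "generate_triplicate",
    "generate_study_tables",
]

#: Rendered amplitude ratio for the "hyperechoic" disc, which the phantom's
#: datasheet grades only qualitatively; any value above +6 dB is faithful.
HYPERECHOIC_DB = 12.0

#: The blind-scan instructions pace one sweep per count of eight, i.e.
#: 1/8 = 0.125 passes per second.
INSTRUCTED_SECONDS_PER_SWEEP = 8.0

#: Point SNR (mean/std) of a Rayleigh envelope: sqrt(pi/(4-pi)).
RAYLEIGH_SNR = math.sqrt(math.pi / (4.0 - math.pi))

DISPLAY_MAX = 255.0


def instructed_pass_rate() -> float:
    """Pass rate implied by the written blind-scan instructions (passes/s)."""
    return 1.0 / INSTRUCTED_SECONDS_PER_SWEEP


def gaussian_fwhm(sigma_mm: float) -> float:
    """Full width at half maximum of a Gaussian: 2*sqrt(2 ln 2)*sigma."""
    return 2.0 * math.sqrt(2.0 * math.log(2.0)) * sigma_mm


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContrastTargetSpec:
    """An 8 mm graded-contrast disc: centre in mm, diameter, contrast."""

    center_row_mm: float
    center_col_mm: float
    diameter_mm: float = 8.0
    contrast_db: float | None = None
    hyperechoic: bool = False

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("diameter must be > 0")
        if self.contrast_db is None and not self.hyperechoic:
            raise ValueError("target needs a contrast_db or hyperechoic=True")

    @property
    def effective_db(self) -> float:
        return HYPERECHOIC_DB if self.hyperechoic else float(self.contrast_db)


@dataclass
class PhantomSpec:
    """Ground-truth recipe for one simulated phantom acquisition.

    ``wires`` are (depth_cm, lateral_mm) pairs.  PSF sigmas are in mm:
    horizontal (lateral, in-plane), vertical (axial) and elevational
    (out-of-plane).  ``scan_orientation`` selects whether wires are imaged
    head-on or at 45°, in which case the elevational sigma becomes the
    lateral blur.
    """

    shape: tuple[int, int] = (450, 760)
    spacing_mm: float = 0.1
    speckle_scale: float = 40.0
    decay_per_mm: float = 0.01
    wires: Sequence[tuple[float, float]] = field(
        default_factory=lambda: [(1.0, 8.0), (2.0, 8.0), (3.0, 8.0)]
    )
    contrast_targets: Sequence[ContrastTargetSpec] = field(default_factory=list)
    psf_sigma_h: float = 0.3
    psf_sigma_v: float = 0.2
    psf_sigma_e: float = 0.6
    seed: int = 0
    scan_orientation: Literal["standard", "elevational_45"] = "standard"
    snr_box_col_mm: tuple[float, float] = (66.0, 69.0)
    log_compress: bool = False

    def __post_init__(self) -> None:
        if min(self.psf_sigma_h, self.psf_sigma_v, self.psf_sigma_e) <= 0:
            raise ValueError("PSF sigmas must be > 0")
        if self.spacing_mm <= 0 or self.speckle_scale <= 0:
            raise ValueError("spacing and speckle scale must be > 0")
        if self.decay_per_mm < 0 or self.decay_per_mm >= 1:
            raise ValueError("decay_per_mm must be in [0, 1)")
        rows, cols = self.shape
        h_mm, w_mm = rows * self.spacing_mm, cols * self.spacing_mm
        for t in self.contrast_targets:
            r = t.diameter_mm / 2
            if not (
                r <= t.center_row_mm <= h_mm - r and r <= t.center_col_mm <= w_mm - r
            ):
                raise ValueError(f"contrast target {t} outside image bounds")
        for depth_cm, lat in self.wires:
            if not (0 <= depth_cm * 10 < h_mm and 0 <= lat < w_mm):
                raise ValueError(f"wire at ({depth_cm} cm, {lat} mm) out of bounds")

    @property
    def lateral_wire_sigma(self) -> float:
        return self.psf_sigma_e if self.scan_orientation == "elevational_45" else self.psf_sigma_h


def default_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """The packaged CIRS-040GSE-like layout.

    45 × 76 mm field at 0.1 mm/pixel: a vertical wire group at 8 mm lateral
    (1/2/3 cm deep), six 8 mm contrast discs in two rows
    (−9/−6/−3 dB at 14 mm depth, +3/+6 dB and hyperechoic at 32 mm), and a
    3 mm wide structure-free strip at the right edge for depth-SNR.
    """
    targets = [
        ContrastTargetSpec(14.0, 24.0, contrast_db=-9.0),
        ContrastTargetSpec(14.0, 40.0, contrast_db=-6.0),
        ContrastTargetSpec(14.0, 56.0, contrast_db=-3.0),
        ContrastTargetSpec(32.0, 24.0, contrast_db=3.0),
        ContrastTargetSpec(32.0, 40.0, contrast_db=6.0),
        ContrastTargetSpec(32.0, 56.0, hyperechoic=True),
    ]
    return PhantomSpec(contrast_targets=targets, seed=seed, **overrides)


@dataclass
class GroundTruth:
    """Analytic truth for one simulated phantom.

    ``gcnr`` maps contrast-target label id → the Rayleigh-overlap gCNR;
    ``psf_width_mm`` maps wire label id → direction → true FWHM;
    ``snr_constant`` is the point SNR of the speckle model.
    """

    gcnr: dict[int, float]
    psf_width_mm: dict[int, dict[str, float]]
    snr_constant: float
    mask: LabelMask


# ---------------------------------------------------------------------------
# Analytic oracle
# ---------------------------------------------------------------------------


def analytic_gcnr_rayleigh(contrast_db: float, n_grid: int = 20001) -> float:
    """gCNR between Rayleigh speckle and speckle scaled by ``contrast_db``.

    Numerically integrates ``1 - ∫ min(p_fg, p_bg)`` for Rayleigh densities
    with scales ``k*sigma`` and ``sigma`` where ``k = 10**(dB/20)``; the
    result depends only on ``k``, not on sigma.
    """
    k = 10.0 ** (contrast_db / 20.0)
    hi = 9.0 * max(1.0, k)
    x = np.linspace(0.0, hi, n_grid)
    p_bg = stats.rayleigh.pdf(x, scale=1.0)
    p_fg = stats.rayleigh.pdf(x, scale=k)
    overlap = np.trapezoid(np.minimum(p_fg, p_bg), x)
    return float(np.clip(1.0 - overlap, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Image synthesis
# ---------------------------------------------------------------------------


def _depth_gain(spec: PhantomSpec) -> np.ndarray:
    depth = np.arange(spec.shape[0]) * spec.spacing_mm
    return (1.0 - spec.decay_per_mm) ** depth


def _log_compress(amplitude: np.ndarray) -> np.ndarray:
    # simple display-style compression mapping [0, 255] onto [0, 255]
    return DISPLAY_MAX * np.log1p(amplitude) / np.log1p(DISPLAY_MAX)


def simulate_speckle(spec: PhantomSpec, seed: int | None = None) -> PhantomImage:
    """Rayleigh speckle with depth decay, clipped to the 8-bit display range.

    Pixel at depth d (mm) is ``Rayleigh(speckle_scale) * (1-decay)**d``.
    Fully reproducible for a fixed seed (defaults to ``spec.seed``).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    env = rng.rayleigh(scale=spec.speckle_scale, size=spec.shape)
    env *= _depth_gain(spec)[:, None]
    if spec.log_compress:
        env = _log_compress(env)
    return PhantomImage(
        np.clip(env, 0.0, DISPLAY_MAX),
        spacing_row=spec.spacing_mm,
        spacing_col=spec.spacing_mm,
    )


def _disc_mask(image: PhantomImage, center_mm: tuple[float, float], diameter_mm: float) -> np.ndarray:
    rr = np.arange(image.shape[0]) * image.spacing_row
    cc = np.arange(image.shape[1]) * image.spacing_col
    dr = rr[:, None] - center_mm[0]
    dc = cc[None, :] - center_mm[1]
    return dr * dr + dc * dc <= (diameter_mm / 2.0) ** 2


def render_contrast_target(
    image: PhantomImage,
    center_mm: tuple[float, float],
    diameter_mm: float,
    contrast_db: float,
) -> PhantomImage:
    """Scale the speckle amplitude inside a disc by ``10**(dB/20)``.

    Returns a new image; the input is not modified.  A 0 dB target is the
    identity inside clipping.
    """
    r = diameter_mm / 2.0
    h = image.shape[0] * image.spacing_row
    w = image.shape[1] * image.spacing_col
    if not (r <= center_mm[0] <= h - r and r <= center_mm[1] <= w - r):
        raise ValueError("contrast disc extends outside the image")
    disc = _disc_mask(image, center_mm, diameter_mm)
    out = image.pixels.copy()
    out[disc] = np.clip(out[disc] * 10.0 ** (contrast_db / 20.0), 0.0, DISPLAY_MAX)
    return replace(image, pixels=out)


def render_wire(
    image: PhantomImage,
    position_mm: tuple[float, float],
    sigma_row_mm: float,
    sigma_col_mm: float,
    peak: float = DISPLAY_MAX,
) -> PhantomImage:
    """Add a wire echo: an anisotropic Gaussian blob saturating at ``peak``.

    Sigmas are the axial (row) and lateral (col) PSF widths in mm.  The blob
    is added to the speckle and clipped, so the centre sits at the display
    ceiling, as a strong specular reflector does on a real phantom.
    """
    h = image.shape[0] * image.spacing_row
    w = image.shape[1] * image.spacing_col
    if not (0 <= position_mm[0] < h and 0 <= position_mm[1] < w):
        raise ValueError("wire position outside the image")
    if sigma_row_mm <= 0 or sigma_col_mm <= 0:
        raise ValueError("wire sigmas must be > 0")
    rr = np.arange(image.shape[0]) * image.spacing_row - position_mm[0]
    cc = np.arange(image.shape[1]) * image.spacing_col - position_mm[1]
    blob = peak * np.exp(
        -0.5 * ((rr[:, None] / sigma_row_mm) ** 2 + (cc[None, :] / sigma_col_mm) ** 2)
    )
    return replace(image, pixels=np.clip(image.pixels + blob, 0.0, DISPLAY_MAX))


def apply_gain(
    image: PhantomImage, gain_fraction: float, max_multiplier: float = 12.0
) -> PhantomImage:
    """Emulate a display gain sweep: scale amplitude, then clip.

    ``gain_fraction`` in [0, 1] maps linearly onto an amplitude multiplier
    in ``[0, max_multiplier]`` (the default full swing is ~21.6 dB, a
    realistic receive-gain range).  Gain 0 blanks the image, so targets are
    indistinguishable from background; at high gain the speckle itself is
    driven deep into the display ceiling — once the clip level falls below
    the point where the foreground and background densities cross, the
    piled-up mass at the ceiling genuinely overlaps and separability
    degrades.  These are the two failure modes a sweep is run to bracket.
    """
    if not (0.0 <= gain_fraction <= 1.0):
        raise ValueError("gain_fraction must lie in [0, 1]")
    scaled = np.clip(image.pixels * (gain_fraction * max_multiplier), 0.0, DISPLAY_MAX)
    return replace(image, pixels=scaled)


def _wire_label_mask(
    image: PhantomImage, position_mm: tuple[float, float], sigma_row: float, sigma_col: float
) -> np.ndarray:
    """Pixels inside the blob's half-maximum ellipse (at least the centre)."""
    rr = np.arange(image.shape[0]) * image.spacing_row - position_mm[0]
    cc = np.arange(image.shape[1]) * image.spacing_col - position_mm[1]
    q = (rr[:, None] / sigma_row) ** 2 + (cc[None, :] / sigma_col) ** 2
    mask = q <= 2.0 * math.log(2.0)
    if not mask.any():
        i = int(round(position_mm[0] / image.spacing_row))
        j = int(round(position_mm[1] / image.spacing_col))
        mask[i, j] = True
    return mask


WIRE_LABEL_BASE = 30
TARGET_LABEL_BASE = 10
SNR_BOX_LABEL = 1


def generate_phantom(
    spec: PhantomSpec, seed: int | None = None
) -> tuple[PhantomImage, LabelMask, GroundTruth]:
    """Compose speckle, contrast discs and wires; return image, mask, truth.

    The mask labels every disc (ids 10+), every wire's half-maximum ellipse
    (ids 30+) and a structure-free SNR strip (id 1).  Structures may not
    overlap each other or the SNR strip.  The ground truth carries each
    disc's analytic Rayleigh-overlap gCNR and each wire's true FWHM per
    direction.
    """
    image = simulate_speckle(spec, seed=seed)

    structures: list[tuple[int, np.ndarray, LabelEntry]] = []
    for i, t in enumerate(spec.contrast_targets):
        disc = _disc_mask(image, (t.center_row_mm, t.center_col_mm), t.diameter_mm)
        structures.append(
            (
                TARGET_LABEL_BASE + i,
                disc,
                LabelEntry(
                    kind="contrast_target",
                    contrast_db=t.effective_db,
                    hyperechoic=t.hyperechoic,
                ),
            )
        )
    sigma_lat = spec.lateral_wire_sigma
    for i, (depth_cm, lat_mm) in enumerate(spec.wires):
        pos = (depth_cm * 10.0, lat_mm)
        wmask = _wire_label_mask(image, pos, spec.psf_sigma_v, sigma_lat)
        structures.append(
            (WIRE_LABEL_BASE + i, wmask, LabelEntry(kind="wire", depth_cm=depth_cm))
        )

    c0, c1 = spec.snr_box_col_mm
    j0, j1 = int(round(c0 / spec.spacing_mm)), int(round(c1 / spec.spacing_mm))
    snr_strip = np.zeros(spec.shape, dtype=bool)
    snr_strip[:, j0:j1] = True

    occupied = np.zeros(spec.shape, dtype=bool)
    for lid, m, _ in structures:
        if (occupied & m).any() or (snr_strip & m).any():
            raise ValueError(f"structure with label {lid} overlaps another structure")
        occupied |= m

    for t in spec.contrast_targets:
        image = render_contrast_target(
            image, (t.center_row_mm, t.center_col_mm), t.diameter_mm, t.effective_db
        )
    for depth_cm, lat_mm in spec.wires:
        # the echo saturates the display at its centre *on top of* the local
        # speckle pedestal, so the blob amplitude is ceiling minus the mean
        # background amplitude at that depth
        pedestal = (
            spec.speckle_scale
            * math.sqrt(math.pi / 2.0)
            * (1.0 - spec.decay_per_mm) ** (depth_cm * 10.0)
        )
        image = render_wire(
            image,
            (depth_cm * 10.0, lat_mm),
            spec.psf_sigma_v,
            sigma_lat,
            peak=max(1.0, DISPLAY_MAX - pedestal),
        )

    labels = np.zeros(spec.shape, dtype=np.int32)
    legend: dict[int, LabelEntry] = {SNR_BOX_LABEL: LabelEntry(kind="snr_box")}
    labels[snr_strip] = SNR_BOX_LABEL
    for lid, m, entry in structures:
        labels[m] = lid
        legend[lid] = entry
    mask = LabelMask(labels, legend)

    gcnr_truth = {
        TARGET_LABEL_BASE + i: analytic_gcnr_rayleigh(t.effective_db)
        for i, t in enumerate(spec.contrast_targets)
    }
    psf_truth = {
        WIRE_LABEL_BASE + i: {
            "horizontal": gaussian_fwhm(spec.psf_sigma_h),
            "vertical": gaussian_fwhm(spec.psf_sigma_v),
            "elevational": gaussian_fwhm(spec.psf_sigma_e),
        }
        for i in range(len(spec.wires))
    }
    truth = GroundTruth(
        gcnr=gcnr_truth, psf_width_mm=psf_truth, snr_constant=RAYLEIGH_SNR, mask=mask
    )
    return image, mask, truth


def generate_triplicate(
    spec: PhantomSpec, n_replicates: int = 3
) -> tuple[list[PhantomImage], LabelMask, GroundTruth]:
    """Replicate acquisitions: seeds ``spec.seed + i`` over fixed geometry.

    Mirrors re-positioning the probe on a physical phantom: independent
    speckle realisations, identical structures, one shared mask/truth.
    """
    images = []
    mask = truth = None
    for i in range(n_replicates):
        img, mask, truth = generate_phantom(spec, seed=spec.seed + i)
        images.append(img)
    return images, mask, truth


# ---------------------------------------------------------------------------
# Study-table synthesis
# ---------------------------------------------------------------------------


@dataclass
class StudyEffects:
    """Effect sizes driving the synthetic preference survey and blind-scan
    annotation tables.

    ``latent_scores[category][device]`` is the latent quality (higher is
    better) from which each rater's ranks are drawn; ``pass_success_prob``
    and ``onsd_bias_mm`` are per scan device; ``phantom_caliper_mm`` maps
    phantom id → (caliper_min, caliper_max) physical ONSD measurements.
    """

    latent_scores: dict[str, dict[str, float]]
    rank_noise_sd: float = 1.0
    n_raters: int = 15
    pass_success_prob: dict[str, float] = field(default_factory=dict)
    onsd_bias_mm: dict[str, float] = field(default_factory=dict)
    onsd_noise_sd_mm: float = 0.3
    n_operators: int = 9
    phantom_caliper_mm: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"ph1": (4.3, 4.5), "ph2": (5.1, 5.3), "ph3": (6.0, 6.2)}
    )
    video_seconds: float = 30.0

    def __post_init__(self) -> None:
        for d, p in self.pass_success_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"success probability for {d!r} outside [0, 1]")
        if self.rank_noise_sd < 0 or self.onsd_noise_sd_mm < 0:
            raise ValueError("noise standard deviations must be >= 0")
        for cat, scores in self.latent_scores.items():
            if len(scores) < 1:
                raise ValueError(f"category {cat!r} has no devices")


def default_study_effects() -> StudyEffects:
    """Study conditions mirroring the published device comparison.

    Six survey devices with latent scores set to the negated mean survey
    ranks per category; five scan devices with the reported pass-success
    rates and per-device ONSD biases (mm).
    """
    mean_ranks = {
        "image_quality": {
            "butterfly_iq": 3.3, "clarius_l7hd": 2.3, "interson_spl01": 4.5,
            "zonare_zone": 2.1, "sonivate_soniceye": 5.1, "sonoque_l5c": 3.2,
        },
        "acquisition_ease": {
            "butterfly_iq": 3.1, "clarius_l7hd": 2.8, "interson_spl01": 3.7,
            "zonare_zone": 2.7, "sonivate_soniceye": 4.8, "sonoque_l5c": 3.5,
        },
        "software": {
            "butterfly_iq": 2.0, "clarius_l7hd": 3.5, "interson_spl01": 3.9,
            "zonare_zone": 3.5, "sonivate_soniceye": 4.9, "sonoque_l5c": 3.5,
        },
        "tactile_feel": {
            "butterfly_iq": 3.4, "clarius_l7hd": 3.6, "interson_spl01": 3.4,
            "zonare_zone": 3.0, "sonivate_soniceye": 4.5, "sonoque_l5c": 3.0,
        },
        "overall_onsd": {
            "butterfly_iq": 2.7, "clarius_l7hd": 2.6, "interson_spl01": 4.0,
            "zonare_zone": 3.1, "sonivate_soniceye": 5.2, "sonoque_l5c": 3.3,
        },
    }
    latent = {
        cat: {dev: -rank for dev, rank in scores.items()}
        for cat, scores in mean_ranks.items()
    }
    return StudyEffects(
        latent_scores=latent,
        pass_success_prob={
            "butterfly_iq": 0.922, "clarius_l7hd": 0.917, "interson_spl01": 0.832,
            "sonivate_soniceye": 0.517, "sonoque_l5c": 0.923,
        },
        onsd_bias_mm={
            "butterfly_iq": -0.5203, "clarius_l7hd": 0.1415, "interson_spl01": -0.358,
            "sonivate_soniceye": -0.4586, "sonoque_l5c": -0.5604,
        },
    )


def generate_study_tables(
    effects: StudyEffects, seed: int = 0
) -> tuple[list[SurveyRecord], list[AnnotationRecord]]:
    """Draw one synthetic survey and one blind-scan annotation table.

    Survey: per rater and category, device scores = latent + N(0, noise),
    ranked descending (rank 1 = best), so each rater emits a permutation.
    Annotations: per operator × phantom × device, pass count ~ Poisson at
    the instructed 0.125 passes/s pacing (minimum 1), successes binomial
    at the device rate, ONSD = caliper mean + device bias + N(0, noise).
    """
    rng = np.random.default_rng(seed)
    surveys: list[SurveyRecord] = []
    for cat, scores in effects.latent_scores.items():
        if cat not in SURVEY_CATEGORIES:
            raise ValueError(f"unknown survey category {cat!r}")
        devices = sorted(scores)
        for r in range(effects.n_raters):
            noisy = np.array([scores[d] for d in devices])
            noisy = noisy + rng.normal(0.0, effects.rank_noise_sd, size=len(devices))
            order = stats.rankdata(-noisy, method="ordinal")
            for dev, rank in zip(devices, order):
                surveys.append(
                    SurveyRecord(rater_id=f"rater{r:02d}", device_id=dev,
                                 category=cat, rank=int(rank))
                )

    annotations: list[AnnotationRecord] = []
    mean_passes = effects.video_seconds * instructed_pass_rate()
    for dev in sorted(effects.pass_success_prob):
        p = effects.pass_success_prob[dev]
        bias = effects.onsd_bias_mm.get(dev, 0.0)
        for op in range(effects.n_operators):
            for ph, (cmin, cmax) in sorted(effects.phantom_caliper_mm.items()):
                n_passes = max(1, int(rng.poisson(mean_passes)))
                n_success = int(rng.binomial(n_passes, p))
                onsd = 0.5 * (cmin + cmax) + bias + rng.normal(0.0, effects.onsd_noise_sd_mm)
                annotations.append(
                    AnnotationRecord(
                        video_id=f"{dev}-op{op:02d}-{ph}",
                        device_id=dev,
                        phantom_id=ph,
                        n_passes=n_passes,
                        n_success=n_success,
                        onsd_measured=round(float(onsd), 3),
                        caliper_min=cmin,
                        caliper_max=cmax,
                    )
                )
    return surveys, annotations
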