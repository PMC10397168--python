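"""B-mode image-quality metrics: gCNR, depth-resolved SNR, PSF width.

The three laboratory metrics computed from labelled calibration-phantom
images:

**gCNR** — the generalized contrast-to-noise ratio, ``1 - ∫ min(p_f, p_b)``,
where ``p_f`` and ``p_b`` are the foreground (contrast target) and
background intensity densities.  It is the Bayes error complement of an
ideal pixel classifier: 0 when the distributions are identical, 1 when they
are perfectly separable, and invariant to any monotone intensity remap that
is applied to both regions (with quantile binning this holds exactly).
Densities are estimated by histograms on shared bins; the estimator is the
discrete min-sum of bin masses.

**Depth SNR** — per image row inside a structure-free box: mean intensity
(signal), population standard deviation (noise) and their ratio, as a
function of depth, optionally block-averaged in non-overlapping depth
windows.  For fully developed Rayleigh speckle the true ratio is the
constant ``sqrt(pi/(4-pi)) ≈ 1.913`` at every depth, which is the
simulator-recovery oracle.

**PSF width** — intensity profiles across a thin wire target along the
horizontal/vertical image axes (or lateral-at-45° for the elevational
direction), peak-aligned over replicates, averaged, and scalarised as the
full width at half maximum above an outer-quartile baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .phantom_io import LabelMask, PhantomImage, RoiBox, padded_bbox

__all__ = [
    "GcnrResult",
    "DepthCurve",
    "PsfProfile",
    "gcnr",
    "gcnr_for_target",
    "gain_sweep_summary",
    "snr_curve",
    "window_average",
    "centroid_of_label",
    "extract_line_profile",
    "align_and_average_psf",
    "psf_width",
]

Direction = Literal["horizontal", "vertical", "elevational"]


@dataclass(frozen=True)
class GcnrResult:
    """One gCNR measurement for one contrast target in one image."""

    value: float
    target_contrast_db: float | None = None
    replicate_id: int | None = None
    gain_setting: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValueError("gCNR must lie in [0, 1]")


@dataclass
class DepthCurve:
    """Ordered (depth mm, value) samples; NaN marks undefined rows."""

    depth_mm: np.ndarray
    value: np.ndarray
    kind: Literal["signal", "noise", "snr"]

    def __post_init__(self) -> None:
        self.depth_mm = np.asarray(self.depth_mm, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.depth_mm.shape != self.value.shape or self.depth_mm.ndim != 1:
            raise ValueError("depth_mm and value must be matching 1-D arrays")
        if self.depth_mm.size and np.any(np.diff(self.depth_mm) <= 0):
            raise ValueError("depths must be strictly increasing")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.value)


@dataclass
class PsfProfile:
    """Peak-centred offset-vs-intensity curve for one wire and direction."""

    offsets_mm: np.ndarray
    intensities: np.ndarray
    direction: Direction
    depth_cm: float | None = None
    width_mm: float | None = None
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.offsets_mm = np.asarray(self.offsets_mm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.offsets_mm.shape != self.intensities.shape:
            raise ValueError("offsets and intensities must have the same shape")
        if self.width_mm is not None and self.width_mm <= 0:
            raise ValueError("width must be > 0")


# ---------------------------------------------------------------------------
# gCNR
# ---------------------------------------------------------------------------


def _shared_edges(
    pooled: np.ndarray,
    bins: int | Sequence[float],
    value_range: tuple[float, float] | None,
    binning: Literal["width", "quantile"],
) -> np.ndarray:
    if not np.isscalar(bins) and not isinstance(bins, int):
        edges = np.asarray(bins, dtype=float)
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError("explicit bin edges must be 1-D and increasing")
        return edges
    n_bins = int(bins)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if binning == "quantile":
        qs = np.linspace(0.0, 1.0, n_bins + 1)
        edges = np.quantile(pooled, qs)
        edges = np.unique(edges)
        if edges.size < 2:
            edges = np.array([edges[0], edges[0]])
        return edges
    lo, hi = (
        (float(pooled.min()), float(pooled.max())) if value_range is None else map(float, value_range)
    )
    if hi < lo:
        raise ValueError("range must satisfy max >= min")
    if hi == lo:
        # degenerate range: a single bin
        return np.array([lo, lo])
    return np.linspace(lo, hi, n_bins + 1)


def gcnr(
    fg_pixels: np.ndarray,
    bg_pixels: np.ndarray,
    n_bins: int | Sequence[float] = 64,
    value_range: tuple[float, float] | None = None,
    binning: Literal["width", "quantile"] = "width",
) -> float:
    """Histogram-overlap gCNR between two pixel sets.

    Both sets are binned on shared edges (``n_bins`` equal-width bins over
    ``value_range`` — pooled min–max when omitted — or pooled-quantile bins,
    or explicit edges).  Each histogram is normalised to unit mass and the
    overlap is the binwise min-sum, so

        gcnr = 1 - sum_bins min(mass_f, mass_b),

    clamped to [0, 1].  Identical sets give exactly 0; sets with no shared
    bin give exactly 1.  A degenerate range (min == max) is one bin: 0 when
    both sets occupy it.
    """
    fg = np.asarray(fg_pixels, dtype=float).ravel()
    bg = np.asarray(bg_pixels, dtype=float).ravel()
    if fg.size == 0 or bg.size == 0:
        raise ValueError("foreground and background pixel sets must be non-empty")
    pooled = np.concatenate([fg, bg])
    edges = _shared_edges(pooled, n_bins, value_range, binning)
    if edges[0] == edges[-1]:
        in_fg = np.mean(fg == edges[0])
        in_bg = np.mean(bg == edges[0])
        return float(np.clip(1.0 - min(in_fg, in_bg), 0.0, 1.0))
    mass_f = np.histogram(fg, bins=edges)[0] / fg.size
    mass_b = np.histogram(bg, bins=edges)[0] / bg.size
    return float(np.clip(1.0 - np.minimum(mass_f, mass_b).sum(), 0.0, 1.0))


def gcnr_for_target(
    image: PhantomImage,
    mask: LabelMask,
    target_id: int,
    pad_mm: float = 1.7,
    n_bins: int = 64,
    value_range: tuple[float, float] | None = None,
    binning: Literal["width", "quantile"] = "width",
    replicate_id: int | None = None,
    gain_setting: float | None = None,
) -> GcnrResult:
    """gCNR of one labelled contrast target against its local background.

    The ROI protocol: a bounding box around the labelled target padded by
    ``pad_mm`` (default 1.7 mm) per side; foreground = the labelled pixels,
    background = the remaining pixels of the box.
    """
    box = padded_bbox(mask, target_id, pad_mm, image)
    sub_img = image.pixels[box.slices]
    sub_lab = mask.labels[box.slices]
    fg = sub_img[sub_lab == target_id]
    bg = sub_img[sub_lab != target_id]
    if bg.size == 0:
        raise ValueError(
            f"target {target_id}: background empty after subtracting the label "
            f"from its padded box; increase pad_mm"
        )
    value = gcnr(fg, bg, n_bins=n_bins, value_range=value_range, binning=binning)
    entry = mask.legend[target_id]
    return GcnrResult(
        value=value,
        target_contrast_db=entry.contrast_db,
        replicate_id=replicate_id,
        gain_setting=gain_setting,
    )


def gain_sweep_summary(
    results: Iterable[GcnrResult] | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate-mean gCNR per (gain, contrast) and the best gain per target.

    Returns ``(mean_table, best_gain)``: the first has one row per
    (gain_setting, target_contrast_db) with the mean over replicates; the
    second the gain achieving the maximum mean gCNR per contrast — the
    operating point a sweep is run to find.
    """
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "value": r.value,
                    "target_contrast_db": r.target_contrast_db,
                    "replicate_id": r.replicate_id,
                    "gain_setting": r.gain_setting,
                }
                for r in results
            ]
        )
    if df.empty:
        raise ValueError("no gCNR results to summarise")
    mean_table = (
        df.groupby(["gain_setting", "target_contrast_db"], dropna=False)["value"]
        .mean()
        .reset_index()
        .rename(columns={"value": "mean_gcnr"})
    )
    idx = mean_table.groupby("target_contrast_db", dropna=False)["mean_gcnr"].idxmax()
    best = mean_table.loc[idx].reset_index(drop=True)
    best = best.rename(columns={"gain_setting": "best_gain", "mean_gcnr": "best_mean_gcnr"})
    return mean_table, best


# ---------------------------------------------------------------------------
# Depth SNR
# ---------------------------------------------------------------------------


def snr_curve(
    image: PhantomImage,
    snr_box: RoiBox,
    mask: LabelMask | None = None,
) -> tuple[DepthCurve, DepthCurve, DepthCurve]:
    """Row-wise signal, noise and SNR inside a structure-free box.

    Per row: signal = mean intensity, noise = population (n) standard
    deviation, snr = signal/noise.  Zero-noise rows are flagged undefined
    (NaN), not dropped.  If a mask is given, the box must contain only
    unlabeled or snr_box pixels.
    """
    if snr_box.n_cols < 2:
        raise ValueError("SNR box must span at least 2 columns")
    if snr_box.row_max > image.shape[0] or snr_box.col_max > image.shape[1]:
        raise ValueError("SNR box exceeds image bounds")
    if mask is not None:
        sub = mask.labels[snr_box.slices]
        allowed = {0} | set(mask.ids_of_kind("snr_box"))
        present = set(np.unique(sub))
        if not present <= allowed:
            raise ValueError(
                f"SNR box contains labelled structures: ids {sorted(present - allowed)}"
            )
    block = image.pixels[snr_box.slices]
    signal = block.mean(axis=1)
    noise = block.std(axis=1)  # population std (ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(noise > 0, signal / noise, np.nan)
    depth = image.depth_origin + (snr_box.row_min + np.arange(block.shape[0])) * image.spacing_row
    return (
        DepthCurve(depth, signal, "signal"),
        DepthCurve(depth, noise, "noise"),
        DepthCurve(depth, snr, "snr"),
    )


def window_average(
    curve: DepthCurve, window_mm: float = 5.0, stride_mm: float = 5.0
) -> DepthCurve:
    """Block-average a depth curve in fixed windows.

    Windows of ``window_mm`` start every ``stride_mm`` from the curve's
    first depth; each output sample sits at the window centre and averages
    the defined samples inside; windows with none are omitted.
    """
    if window_mm <= 0 or stride_mm <= 0:
        raise ValueError("window and stride must be > 0")
    if curve.depth_mm.size == 0:
        return DepthCurve(curve.depth_mm, curve.value, curve.kind)
    start = curve.depth_mm[0]
    end = curve.depth_mm[-1]
    centers, means = [], []
    w0 = start
    while w0 <= end:
        sel = (curve.depth_mm >= w0) & (curve.depth_mm < w0 + window_mm)
        vals = curve.value[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            centers.append(w0 + window_mm / 2.0)
            means.append(vals.mean())
        w0 += stride_mm
    return DepthCurve(np.array(centers), np.array(means), curve.kind)


# ---------------------------------------------------------------------------
# PSF
# ---------------------------------------------------------------------------


def centroid_of_label(mask: LabelMask, label_id: int) -> tuple[float, float]:
    """Arithmetic-mean (row, col) pixel coordinate of a label's pixels."""
    rows, cols = np.nonzero(mask.labels == label_id)
    if rows.size == 0:
        raise KeyError(f"label id {label_id} has no pixels")
    return float(rows.mean()), float(cols.mean())


def extract_line_profile(
    image: PhantomImage,
    centroid: tuple[float, float],
    direction: Literal["horizontal", "vertical"],
    length_mm: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a centred line profile through a point at native spacing.

    ``centroid`` is a (row, col) pixel coordinate (fractional allowed).
    Samples are nearest-pixel lookups every native pixel along the chosen
    axis, ``round(length/2/spacing)`` either side of the centroid; samples
    falling outside the image are clipped away.  Offsets are mm relative to
    the centroid.
    """
    r0, c0 = centroid
    n_rows, n_cols = image.shape
    if not (0 <= r0 < n_rows and 0 <= c0 < n_cols):
        raise ValueError(f"centroid {centroid} outside image")
    spacing = image.spacing_col if direction == "horizontal" else image.spacing_row
    n_half = int(round(length_mm / 2.0 / spacing))
    steps = np.arange(-n_half, n_half + 1)
    if direction == "horizontal":
        jj = np.rint(c0).astype(int) + steps
        keep = (jj >= 0) & (jj < n_cols)
        ii = np.full(keep.sum(), int(round(r0)))
        jj = jj[keep]
    else:
        ii = np.rint(r0).astype(int) + steps
        keep = (ii >= 0) & (ii < n_rows)
        jj = np.full(keep.sum(), int(round(c0)))
        ii = ii[keep]
    offsets = steps[keep] * spacing
    return offsets.astype(float), image.pixels[ii, jj].astype(float)


def _find_main_peak(intensities: np.ndarray, min_prominence_frac: float = 0.10) -> int:
    """Index of the highest sufficiently prominent local maximum."""
    dyn = float(intensities.max() - intensities.min())
    if dyn <= 0:
        raise ValueError("flat profile: no peak")
    peaks, props = find_peaks(intensities, prominence=min_prominence_frac * dyn)
    if peaks.size == 0:
        # a maximum at the first/last sample is not a local max for find_peaks
        idx = int(np.argmax(intensities))
        if idx in (0, intensities.size - 1):
            raise ValueError("no interior peak found in profile")
        raise ValueError("no sufficiently prominent peak found in profile")
    return int(peaks[np.argmax(intensities[peaks])])


def align_and_average_psf(
    profiles: Sequence[tuple[np.ndarray, np.ndarray]] | Sequence[PsfProfile],
    direction: Direction = "horizontal",
    depth_cm: float | None = None,
) -> PsfProfile:
    """Peak-align replicate wire profiles and average them.

    Each replicate is shifted so its highest prominent peak sits at offset
    0, all are linearly resampled onto a common uniform grid at the finest
    native spacing, and the pointwise mean is taken over the common
    support.  A flat replicate raises an error naming its index.
    """
    if len(profiles) == 0:
        raise ValueError("need at least one profile")
    aligned: list[tuple[np.ndarray, np.ndarray]] = []
    for i, p in enumerate(profiles):
        offs, ints = (p.offsets_mm, p.intensities) if isinstance(p, PsfProfile) else p
        offs = np.asarray(offs, dtype=float)
        ints = np.asarray(ints, dtype=float)
        try:
            k = _find_main_peak(ints)
        except ValueError as exc:
            raise ValueError(f"replicate {i}: {exc}") from exc
        aligned.append((offs - offs[k], ints))

    spacing = min(float(np.min(np.diff(o))) for o, _ in aligned if o.size > 1)
    lo = max(float(o[0]) for o, _ in aligned)
    hi = min(float(o[-1]) for o, _ in aligned)
    if hi <= lo:
        raise ValueError("aligned profiles share no common support")
    # integer multiples of the finest spacing keep 0 on the grid, so the
    # averaged peak stays centred
    i0 = int(np.ceil(lo / spacing - 1e-9))
    i1 = int(np.floor(hi / spacing + 1e-9))
    grid = np.arange(i0, i1 + 1) * spacing
    mean = np.mean([np.interp(grid, o, v) for o, v in aligned], axis=0)
    return PsfProfile(
        offsets_mm=grid,
        intensities=mean,
        direction=direction,
        depth_cm=depth_cm,
        n_replicates=len(aligned),
    )


def psf_width(profile: PsfProfile | tuple[np.ndarray, np.ndarray]) -> float:
    """Full width at half maximum above an outer-quartile baseline, in mm.

    Baseline = median of the outer 25% of samples (the tails of the
    profile); half-maximum = baseline + (peak − baseline)/2; the two
    crossings nearest the peak are located by linear interpolation.  The
    result is invariant to amplitude scaling and to an added constant.
    """
    if isinstance(profile, PsfProfile):
        offs, ints = profile.offsets_mm, profile.intensities
    else:
        offs, ints = map(np.asarray, profile)
    if offs.size < 3:
        raise ValueError("profile too short")
    n_tail = max(1, offs.size // 8)
    baseline = float(np.median(np.concatenate([ints[:n_tail], ints[-n_tail:]])))
    k = int(np.argmax(ints))
    peak = float(ints[k])
    if peak <= baseline:
        raise ValueError("profile has no peak above baseline")
    half = baseline + 0.5 * (peak - baseline)

    def _cross(side: int) -> float:
        idx = np.arange(k, -1, -1) if side < 0 else np.arange(k, offs.size)
        for a, b in zip(idx[:-1], idx[1:]):
            if ints[b] <= half <= ints[a] or ints[a] <= half <= ints[b]:
                if ints[b] == ints[a]:
                    return float(offs[b])
                t = (half - ints[a]) / (ints[b] - ints[a])
                return float(offs[a] + t * (offs[b] - offs[a]))
        raise ValueError(
            f"half-maximum never crossed on the {'left' if side < 0 else 'right'}; "
            "profile too short"
        )

    left = _cross(-1)
    right = _cross(+1)
    width = right - left
    if width <= 0:
        raise ValueError("degenerate width")
    return float(width)
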