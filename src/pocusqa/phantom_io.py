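"""Reading and writing phantom images, label masks and study tables.

B-mode exports from point-of-care probes arrive as plain 8-bit grayscale
rasters (PNG/TIFF) that carry no physical calibration, so pixel spacing is
supplied either explicitly, through a YAML sidecar (``<image>.yaml`` with
``spacing_row``/``spacing_col`` keys, mm per pixel), or — for metafile
formats such as NRRD/MHA — from the embedded header, which takes precedence.

Conventions used throughout the package:

* arrays are row-major and 0-based; depth increases with row index;
* boxes are half-open ``[min, max)`` on both axes;
* mm→pixel pad conversion rounds half away from zero, per axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PhantomImage",
    "LabelEntry",
    "LabelMask",
    "RoiBox",
    "AnnotationRecord",
    "SurveyRecord",
    "ValidationError",
    "FormatError",
    "SURVEY_CATEGORIES",
    "read_phantom_image",
    "write_phantom_image",
    "read_label_mask",
    "write_label_mask",
    "padded_bbox",
    "load_annotations",
    "load_survey",
    "write_annotations",
    "write_survey",
]

SURVEY_CATEGORIES = (
    "image_quality",
    "acquisition_ease",
    "software",
    "tactile_feel",
    "overall_onsd",
)

ANNOTATION_COLUMNS = [
    "video_id",
    "device_id",
    "phantom_id",
    "n_passes",
    "n_success",
    "onsd_measured",
    "caliper_min",
    "caliper_max",
]

SURVEY_COLUMNS = ["rater_id", "device_id", "category", "rank"]


class FormatError(ValueError):
    """Raised for unreadable or ambiguous raster input."""


class ValidationError(ValueError):
    """Raised when tabular records violate their invariants.

    ``rows`` holds the offending 0-based data-row indices when applicable.
    """

    def __init__(self, message: str, rows: Sequence[int] = ()):
        super().__init__(message)
        self.rows = list(rows)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class PhantomImage:
    """A 2-D B-mode intensity raster with physical pixel spacing.

    Parameters
    ----------
    pixels : ndarray
        Non-negative intensities in display units (0–255 expected).
    spacing_row, spacing_col : float
        Pixel spacing in mm/pixel; strictly positive.
    depth_origin : float
        Depth (mm) of the first row; 0 at the transducer face by default.
    """

    pixels: np.ndarray
    spacing_row: float
    spacing_col: float
    depth_origin: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not (self.spacing_row > 0 and self.spacing_col > 0):
            raise ValueError("pixel spacing must be strictly positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def depth_mm(self) -> np.ndarray:
        """Depth of each row centre, in mm from the transducer face."""
        return self.depth_origin + np.arange(self.shape[0]) * self.spacing_row


@dataclass
class LabelEntry:
    """Legend entry describing one labelled structure."""

    kind: Literal["wire", "contrast_target", "snr_box", "background"]
    depth_cm: float | None = None
    contrast_db: float | None = None
    hyperechoic: bool = False


@dataclass
class LabelMask:
    """Integer label raster aligned to a :class:`PhantomImage`.

    Label 0 is reserved for unlabeled pixels; every nonzero id present in
    ``labels`` must appear in ``legend``.
    """

    labels: np.ndarray
    legend: dict[int, LabelEntry] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 2-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"label ids missing from legend: {sorted(missing)}")

    def ids_of_kind(self, kind: str) -> list[int]:
        return sorted(i for i, e in self.legend.items() if e.kind == kind)

    def pixels_for(self, image: PhantomImage, label_id: int) -> np.ndarray:
        if label_id not in self.legend:
            raise KeyError(f"label id {label_id} not in legend")
        if self.labels.shape != image.shape:
            raise ValueError("mask shape does not match image shape")
        return image.pixels[self.labels == label_id]


@dataclass(frozen=True)
class RoiBox:
    """Half-open pixel box ``[row_min, row_max) × [col_min, col_max)``."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if not (self.row_max > self.row_min and self.col_max > self.col_min):
            raise ValueError("RoiBox must satisfy max > min on both axes")
        if self.row_min < 0 or self.col_min < 0:
            raise ValueError("RoiBox indices must be non-negative")

    @property
    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_min, self.row_max), slice(self.col_min, self.col_max)

    @property
    def n_rows(self) -> int:
        return self.row_max - self.row_min

    @property
    def n_cols(self) -> int:
        return self.col_max - self.col_min

    @property
    def area(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class AnnotationRecord:
    """One blind-scan video's annotation (passes, successes, ONSD)."""

    video_id: str
    device_id: str
    phantom_id: str
    n_passes: int
    n_success: int
    onsd_measured: float | None
    caliper_min: float
    caliper_max: float

    def __post_init__(self) -> None:
        if self.n_passes < 0:
            raise ValueError("n_passes must be >= 0")
        if not (0 <= self.n_success <= self.n_passes):
            raise ValueError("n_success must satisfy 0 <= n_success <= n_passes")
        if self.caliper_min > self.caliper_max:
            raise ValueError("caliper_min must be <= caliper_max")

    @property
    def caliper_mean(self) -> float:
        return 0.5 * (self.caliper_min + self.caliper_max)


@dataclass
class SurveyRecord:
    """One rank (1 = best) given by one rater to one device in a category."""

    rater_id: str
    device_id: str
    category: str
    rank: int

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------

_METAFILE_SUFFIXES = {".nrrd", ".mha", ".mhd", ".nii", ".gz"}


def _to_grayscale(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3]
        if np.all(rgb[..., 0] == rgb[..., 1]) and np.all(rgb[..., 0] == rgb[..., 2]):
            return rgb[..., 0]
        raise FormatError(
            f"{path}: color image has no pure-gray reduction; convert to grayscale first"
        )
    raise FormatError(f"{path}: unsupported raster shape {arr.shape}")


def _sidecar_spacing(path: Path) -> tuple[float, float] | None:
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if not sidecar.exists():
        sidecar = path.with_suffix(".yaml")
    if not sidecar.exists():
        return None
    meta = yaml.safe_load(sidecar.read_text())
    return float(meta["spacing_row"]), float(meta["spacing_col"])


def read_phantom_image(
    path: str | Path,
    spacing_row: float | None = None,
    spacing_col: float | None = None,
    depth_origin: float = 0.0,
) -> PhantomImage:
    """Read a grayscale raster as a :class:`PhantomImage`.

    Spacing resolution order: embedded header (NRRD/MHA via SimpleITK) >
    explicit arguments > YAML sidecar.  8-bit input round-trips bit-exact.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _METAFILE_SUFFIXES:
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img)
        arr = np.squeeze(arr)
        if arr.ndim != 2:
            raise FormatError(f"{path}: expected a 2-D image, got shape {arr.shape}")
        # SimpleITK spacing order is (x, y) = (col, row)
        sc, sr = img.GetSpacing()[:2]
        return PhantomImage(arr, spacing_row=sr, spacing_col=sc, depth_origin=depth_origin)

    arr = _to_grayscale(np.asarray(iio.imread(path)), path)
    if spacing_row is None or spacing_col is None:
        spacing = _sidecar_spacing(path)
        if spacing is None:
            raise ValueError(
                f"{path}: no pixel spacing given and no YAML sidecar found"
            )
        spacing_row, spacing_col = spacing
    return PhantomImage(arr, spacing_row, spacing_col, depth_origin=depth_origin)


def write_phantom_image(path: str | Path, image: PhantomImage) -> None:
    """Write an image as 8-bit PNG/TIFF plus a YAML spacing sidecar.

    Intensities are rounded and clipped to 0–255; integer-valued input in
    range is therefore preserved bit-exact.
    """
    path = Path(path)
    arr = np.clip(np.rint(image.pixels), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)
    sidecar = path.with_suffix(path.suffix + ".yaml")
    sidecar.write_text(
        yaml.safe_dump(
            {
                "spacing_row": float(image.spacing_row),
                "spacing_col": float(image.spacing_col),
                "depth_origin": float(image.depth_origin),
            }
        )
    )


def _legend_to_dict(legend: Mapping[int, LabelEntry]) -> dict:
    out = {}
    for lid, e in legend.items():
        d: dict = {"kind": e.kind}
        if e.depth_cm is not None:
            d["depth_cm"] = float(e.depth_cm)
        if e.contrast_db is not None:
            d["contrast_db"] = float(e.contrast_db)
        if e.hyperechoic:
            d["hyperechoic"] = True
        out[int(lid)] = d
    return out


def write_label_mask(path: str | Path, mask: LabelMask) -> None:
    """Write a label raster (16-bit PNG) with a YAML legend sidecar."""
    path = Path(path)
    labels = mask.labels
    if labels.min() < 0 or labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label ids must fit in uint16 for PNG masks")
    iio.imwrite(path, labels.astype(np.uint16))
    sidecar = path.with_suffix(path.suffix + ".yaml")
    sidecar.write_text(yaml.safe_dump({"labels": _legend_to_dict(mask.legend)}))


def read_label_mask(path: str | Path, legend_path: str | Path | None = None) -> LabelMask:
    """Read a label raster and its legend sidecar."""
    path = Path(path)
    if path.suffix.lower() in _METAFILE_SUFFIXES:
        import SimpleITK as sitk

        arr = np.squeeze(sitk.GetArrayFromImage(sitk.ReadImage(str(path))))
    else:
        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            arr = _to_grayscale(arr, path)
    sidecar = Path(legend_path) if legend_path else path.with_suffix(path.suffix + ".yaml")
    legend: dict[int, LabelEntry] = {}
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
        for lid, d in (meta.get("labels") or {}).items():
            legend[int(lid)] = LabelEntry(
                kind=d["kind"],
                depth_cm=d.get("depth_cm"),
                contrast_db=d.get("contrast_db"),
                hyperechoic=bool(d.get("hyperechoic", False)),
            )
    return LabelMask(arr.astype(np.int64), legend)


# ---------------------------------------------------------------------------
# ROI geometry
# ---------------------------------------------------------------------------


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def padded_bbox(
    mask: LabelMask, label_id: int, pad_mm: float, image: PhantomImage
) -> RoiBox:
    """Tight bounding box of a label, padded by ``pad_mm`` per side and
    clipped to the image bounds.

    The mm→pixel conversion uses each axis's own spacing, rounding half away
    from zero, so the pad is symmetric before clipping.
    """
    if label_id not in mask.legend:
        raise KeyError(f"label id {label_id} not in legend")
    rows, cols = np.nonzero(mask.labels == label_id)
    if rows.size == 0:
        raise KeyError(f"label id {label_id} has no pixels in the mask")
    pad_r = _round_half_away(pad_mm / image.spacing_row)
    pad_c = _round_half_away(pad_mm / image.spacing_col)
    n_rows, n_cols = image.shape
    return RoiBox(
        row_min=max(0, int(rows.min()) - pad_r),
        row_max=min(n_rows, int(rows.max()) + 1 + pad_r),
        col_min=max(0, int(cols.min()) - pad_c),
        col_max=min(n_cols, int(cols.max()) + 1 + pad_c),
    )


# ---------------------------------------------------------------------------
# Tabular study records
# ---------------------------------------------------------------------------


def load_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Load blind-scan annotation records from CSV, validating each row.

    Rows violating the count or caliper invariants are collected and
    reported together with their 0-based row numbers.
    """
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"annotation CSV missing columns: {sorted(missing)}")
    records: list[AnnotationRecord] = []
    bad: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        try:
            onsd = row["onsd_measured"]
            records.append(
                AnnotationRecord(
                    video_id=str(row["video_id"]),
                    device_id=str(row["device_id"]),
                    phantom_id=str(row["phantom_id"]),
                    n_passes=int(row["n_passes"]),
                    n_success=int(row["n_success"]),
                    onsd_measured=None if pd.isna(onsd) else float(onsd),
                    caliper_min=float(row["caliper_min"]),
                    caliper_max=float(row["caliper_max"]),
                )
            )
        except (ValueError, TypeError) as exc:
            bad.append((int(i), str(exc)))
    if bad:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad)
        raise ValidationError(f"invalid annotation rows: {detail}", rows=[i for i, _ in bad])
    return records


def load_survey(path: str | Path) -> list[SurveyRecord]:
    """Load survey rank records from CSV.

    Within each (rater, category) group the device ranks must form a
    permutation of 1..n_devices; offending groups are rejected with their
    row numbers.
    """
    df = pd.read_csv(path)
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"survey CSV missing columns: {sorted(missing)}")
    records: list[SurveyRecord] = []
    bad: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        try:
            records.append(
                SurveyRecord(
                    rater_id=str(row["rater_id"]),
                    device_id=str(row["device_id"]),
                    category=str(row["category"]),
                    rank=int(row["rank"]),
                )
            )
        except (ValueError, TypeError) as exc:
            bad.append((int(i), str(exc)))
    if bad:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad)
        raise ValidationError(f"invalid survey rows: {detail}", rows=[i for i, _ in bad])

    df = df.reset_index(drop=True)
    for (rater, cat), grp in df.groupby(["rater_id", "category"]):
        ranks = sorted(int(r) for r in grp["rank"])
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValidationError(
                f"rater {rater!r}, category {cat!r}: ranks {ranks} are not a "
                f"permutation of 1..{len(ranks)}",
                rows=list(grp.index),
            )
    return records


def write_annotations(path: str | Path, records: Sequence[AnnotationRecord]) -> None:
    pd.DataFrame(
        [
            {
                "video_id": r.video_id,
                "device_id": r.device_id,
                "phantom_id": r.phantom_id,
                "n_passes": r.n_passes,
                "n_success": r.n_success,
                "onsd_measured": r.onsd_measured,
                "caliper_min": r.caliper_min,
                "caliper_max": r.caliper_max,
            }
            for r in records
        ],
        columns=ANNOTATION_COLUMNS,
    ).to_csv(path, index=False)


def write_survey(path: str | Path, records: Sequence[SurveyRecord]) -> None:
    pd.DataFrame(
        [
            {
                "rater_id": r.rater_id,
                "device_id": r.device_id,
                "category": r.category,
                "rank": r.rank,
            }
            for r in records
        ],
        columns=SURVEY_COLUMNS,
    ).to_csv(path, index=False)
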