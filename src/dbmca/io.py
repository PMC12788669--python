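"""Reading and writing of on-disk artifacts and the dataset folder layout.

All pixel coordinates in the package are row-major, 0-based, in (row, col)
order.  Image intensities are min-max normalized floats in [0, 1]; masks are
{0, 1} integer grids congruent with their image.  A dataset on disk is::

    <dir>/
      images/0000.npy, 0001.npy, ...
      masks/0000.npy,  0001.npy, ...
      labels.csv                    # columns: index, label
      truth.csv                     # per-nodule generating parameters
      manifest.json                 # spacing, sizes, config hash

NPY round-trips are lossless; PNG export quantizes to 8 bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .features import NoduleFeatures
    from .phantom import PhantomDataset


class MetadataError(ValueError):
    """A required metadata field (e.g. DICOM pixel spacing) is absent."""


class DatasetIntegrityError(ValueError):
    """On-disk dataset is incomplete or internally inconsistent."""


@dataclass(frozen=True)
class PixelSpacing:
    """Physical pixel size in mm along the row and column axes."""

    row_mm: float
    col_mm: float

    def __post_init__(self) -> None:
        if not (self.row_mm > 0 and self.col_mm > 0):
            raise ValueError(f"pixel spacing must be strictly positive, got {self}")

    @property
    def mm_per_pixel(self) -> float:
        """Isotropic mm/pixel scale: geometric mean of the two axes."""
        return float(np.sqrt(self.row_mm * self.col_mm))

    def as_tuple(self) -> tuple[float, float]:
        return (self.row_mm, self.col_mm)


@dataclass
class CTImage:
    """A 2D grayscale CT slice with physical pixel spacing."""

    pixels: np.ndarray
    spacing: PixelSpacing

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"CTImage expects a 2D grid, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("CTImage intensities must be finite")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class NoduleMask:
    """Binary nodule indicator grid congruent with its CTImage."""

    pixels: np.ndarray
    spacing: PixelSpacing

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"NoduleMask expects a 2D grid, got shape {arr.shape}")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("NoduleMask values must be 0/1")
        self.pixels = arr.astype(np.uint8)

    @property
    def background_fraction(self) -> float:
        return float(1.0 - self.pixels.mean())


def normalize_minmax(arr: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant grid maps to all zeros."""
    arr = np.asarray(arr, dtype=np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def read_dicom_slice(path: str | Path) -> CTImage:
    """Read a single-frame DICOM slice into a normalized :class:`CTImage`.

    Raises ``FileNotFoundError`` for a missing file and :class:`MetadataError`
    if the PixelSpacing tag is absent — physical spacing drives the 3 mm
    nodule gate, so a silent default would corrupt downstream sizes.
    """
    import pydicom

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ds = pydicom.dcmread(path)
    if "PixelSpacing" not in ds:
        raise MetadataError(f"{path}: DICOM PixelSpacing tag missing")
    row_mm, col_mm = (float(v) for v in ds.PixelSpacing)
    pixels = normalize_minmax(ds.pixel_array.astype(np.float64))
    return CTImage(pixels=pixels, spacing=PixelSpacing(row_mm, col_mm))


def write_png(image: CTImage, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG (lossy quantization to 256 levels)."""
    from PIL import Image

    arr = np.clip(image.pixels, 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8), mode="L").save(str(path))


def read_png(path: str | Path, spacing: PixelSpacing) -> CTImage:
    from PIL import Image

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = np.asarray(Image.open(str(path)).convert("L"), dtype=np.float64) / 255.0
    return CTImage(pixels=arr, spacing=spacing)


def _config_hash(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_dataset(dataset: "PhantomDataset", out_dir: str | Path) -> dict:
    """Serialize a dataset to the folder layout; returns the manifest dict."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    n = len(dataset.images)
    for i in range(n):
        np.save(out / "images" / f"{i:04d}.npy", dataset.images[i].pixels)
        np.save(out / "masks" / f"{i:04d}.npy", dataset.masks[i].pixels)
    pd.DataFrame({"index": range(n), "label": dataset.labels}).to_csv(
        out / "labels.csv", index=False
    )
    truth_rows = []
    for i, nodules in enumerate(dataset.truth):
        for nod in nodules:
            truth_rows.append(
                {
                    "index": i,
                    "center_row": nod.center[0],
                    "center_col": nod.center[1],
                    "semi_axis_major_px": nod.semi_axes[0],
                    "semi_axis_minor_px": nod.semi_axes[1],
                    "orientation_rad": nod.orientation,
                    "diameter_mm": nod.diameter_mm,
                    "intensity": nod.intensity,
                }
            )
    pd.DataFrame(
        truth_rows,
        columns=[
            "index",
            "center_row",
            "center_col",
            "semi_axis_major_px",
            "semi_axis_minor_px",
            "orientation_rad",
            "diameter_mm",
            "intensity",
        ],
    ).to_csv(out / "truth.csv", index=False)
    spacing = dataset.images[0].spacing if n else PixelSpacing(1.0, 1.0)
    manifest = {
        "n_samples": n,
        "image_shape": list(dataset.images[0].pixels.shape) if n else None,
        "spacing_mm": list(spacing.as_tuple()),
        "config_hash": _config_hash(dataset.config_summary),
        "config": dataset.config_summary,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_dataset(in_dir: str | Path) -> "PhantomDataset":
    """Read a dataset folder back; validates shapes and manifest consistency."""
    from .phantom import NoduleTruth, PhantomDataset

    src = Path(in_dir)
    manifest_path = src / "manifest.json"
    if not manifest_path.exists():
        raise DatasetIntegrityError(f"{src}: manifest.json missing")
    manifest = json.loads(manifest_path.read_text())
    spacing = PixelSpacing(*manifest["spacing_mm"])
    n = int(manifest["n_samples"])

    images, masks = [], []
    for i in range(n):
        img_path = src / "images" / f"{i:04d}.npy"
        mask_path = src / "masks" / f"{i:04d}.npy"
        if not img_path.exists():
            raise DatasetIntegrityError(f"missing image file {img_path}")
        if not mask_path.exists():
            raise DatasetIntegrityError(f"missing mask file {mask_path}")
        img = np.load(img_path)
        mask = np.load(mask_path)
        if img.shape != mask.shape:
            raise DatasetIntegrityError(
                f"sample {i}: image shape {img.shape} != mask shape {mask.shape}"
            )
        if manifest["image_shape"] is not None and list(img.shape) != manifest["image_shape"]:
            raise DatasetIntegrityError(
                f"sample {i}: shape {img.shape} disagrees with manifest "
                f"{manifest['image_shape']}"
            )
        images.append(CTImage(pixels=img, spacing=spacing))
        masks.append(NoduleMask(pixels=mask, spacing=spacing))

    labels_df = pd.read_csv(src / "labels.csv")
    if len(labels_df) != n:
        raise DatasetIntegrityError("labels.csv row count disagrees with manifest")
    labels = [int(v) for v in labels_df["label"]]

    truth: list[list[NoduleTruth]] = [[] for _ in range(n)]
    truth_df = pd.read_csv(src / "truth.csv")
    for _, row in truth_df.iterrows():
        truth[int(row["index"])].append(
            NoduleTruth(
                center=(float(row["center_row"]), float(row["center_col"])),
                semi_axes=(float(row["semi_axis_major_px"]), float(row["semi_axis_minor_px"])),
                orientation=float(row["orientation_rad"]),
                diameter_mm=float(row["diameter_mm"]),
                intensity=float(row["intensity"]),
            )
        )
    return PhantomDataset(
        images=images,
        masks=masks,
        labels=labels,
        truth=truth,
        config_summary=manifest.get("config", {}),
    )


FEATURE_CSV_COLUMNS = [
    "centroid_row",
    "centroid_col",
    "diameter_mm",
    "perimeter_mm",
    "mean_intensity",
    "eccentricity",
    "label",
]


def write_features_csv(
    features: Iterable["NoduleFeatures"], path: str | Path, labels: Iterable[int] | None = None
) -> None:
    """Write one row per region; an empty list yields a header-only CSV."""
    feats = list(features)
    labels = list(labels) if labels is not None else [-1] * len(feats)
    rows = [
        {
            "centroid_row": f.centroid[0],
            "centroid_col": f.centroid[1],
            "diameter_mm": f.equivalent_diameter_mm,
            "perimeter_mm": f.perimeter_mm,
            "mean_intensity": f.mean_intensity,
            "eccentricity": f.eccentricity,
            "label": lab,
        }
        for f, lab in zip(feats, labels, strict=True)
    ]
    pd.DataFrame(rows, columns=FEATURE_CSV_COLUMNS).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_features_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
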