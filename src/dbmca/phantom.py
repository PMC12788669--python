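"""Synthetic CT phantom generator.

Emulates the statistical structure the classification pipeline assumes from
lung-CT slices with nodule annotations: square grayscale slices with physical
pixel spacing, sparse binary nodule masks (background-dominated), and integer
severity labels 0-5 where 0 means "no nodule / non-cancerous" and 1-5 grade
severity monotonically in nodule size.

Nodules are rasterized ellipses with additive Gaussian texture noise on a
smoothed low-frequency background (a lung-parenchyma stand-in).  Ellipses
make ground truth analytic: the extracted morphometry (eccentricity,
equivalent diameter, perimeter, mean intensity) is exactly the set of
ellipse-controllable quantities.  A nodule's size is parameterized by its
area-equivalent diameter d = 2·sqrt(a·b)·spacing in mm.

Severity is graded by total nodule burden: the area-equivalent diameter of
all nodules combined, d_eq = sqrt(sum_i d_i^2) in mm, cut into equal-width
grade bins.  This is monotone non-decreasing in every single nodule's
diameter and reduces to plain diameter grading for a solitary nodule, while
keeping the severity signal proportional to total lesion area — the
structure that makes the sparse mask modality genuinely informative.

Each image is built label-first: a grade is drawn uniformly from the
configured class set, a burden d_eq is drawn inside that grade's bin, and
the burden is split over 1-3 non-overlapping component nodules (Dirichlet
split of the squared diameter, each component at least 3 mm so every
generated nodule is relevant to the downstream size gate).  Masks of
nodule-bearing slices are sparse by construction: the burden range is sized
so foreground stays below 15% per mask and the mean background fraction over
nodule-bearing masks falls inside ``background_fraction_range`` under the
default configuration; class-0 slices have empty masks.

A single :class:`numpy.random.Generator` seeded from the config drives every
draw, so a fixed seed reproduces the dataset byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .io import CTImage, NoduleMask, PixelSpacing

#: pixels kept clear between an ellipse and the image border
_BORDER_MARGIN = 4
#: minimum clearance in pixels between two nodule boundaries
_MIN_SEPARATION = 12


class ConfigurationError(ValueError):
    """Phantom configuration is infeasible (e.g. nodule larger than image)."""


@dataclass(frozen=True)
class DiameterLabelRule:
    """Map nodule equivalent diameter (mm) to a severity grade 1-5.

    The diameter axis is cut at ``cutpoints`` (ascending); a diameter equal to
    a cut-point is assigned to the upper grade.  Grades are clipped to 5.
    An absent nodule is always grade 0 (handled by the caller).
    """

    cutpoints: tuple[float, ...]

    @staticmethod
    def equal_bins(d_min: float, d_max: float, n_grades: int = 5) -> "DiameterLabelRule":
        """Equal-width diameter bins over [d_min, d_max], one per grade."""
        edges = np.linspace(d_min, d_max, n_grades + 1)[1:-1]
        return DiameterLabelRule(cutpoints=tuple(float(e) for e in edges))

    def grade(self, diameter_mm: float) -> int:
        return min(5, 1 + int(sum(diameter_mm >= c for c in self.cutpoints)))

    def bin_interval(self, grade: int, d_min: float, d_max: float) -> tuple[float, float]:
        """Diameter interval mapped to ``grade`` (for label-first sampling)."""
        edges = [d_min, *self.cutpoints, d_max]
        if not 1 <= grade <= len(edges) - 1:
            raise ValueError(f"grade {grade} outside rule range")
        return edges[grade - 1], edges[grade]


@dataclass(frozen=True)
class NoduleTruth:
    """Generating parameters of one nodule."""

    center: tuple[float, float]  # (row, col) pixels
    semi_axes: tuple[float, float]  # (major, minor) pixels
    orientation: float  # radians
    diameter_mm: float  # area-equivalent diameter
    intensity: float  # pre-noise nodule intensity


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom study conditions.

    ``diameter_mm_range`` bounds the per-image total-burden equivalent
    diameter (equal to the single nodule's diameter when there is one);
    component nodules in a multi-nodule split never fall below 3 mm.
    ``background_fraction_range`` is the sparsity band of nodule-bearing
    masks: its lower edge is a hard per-mask cap on foreground and the band
    holds in the mean under the default configuration (class-0 masks are
    empty by definition and sit at background fraction 1).
    """

    n_samples: int = 100
    image_size: int = 128
    pixel_spacing_mm: float = 0.7
    nodules_per_image: tuple[int, int] = (1, 3)
    diameter_mm_range: tuple[float, float] = (8.0, 38.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.6)
    intensity_contrast: float = 0.5
    noise_sd: float = 0.02
    background_fraction_range: tuple[float, float] = (0.85, 0.95)
    classes: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    label_rule: DiameterLabelRule | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.background_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError("background_fraction_range must lie in [0, 1]")
        if self.diameter_mm_range[0] <= 0:
            raise ConfigurationError("minimum nodule diameter must be positive")
        if self.diameter_mm_range[0] > self.diameter_mm_range[1]:
            raise ConfigurationError("diameter_mm_range must be ordered (min, max)")
        if not (0.0 <= self.eccentricity_range[0] <= self.eccentricity_range[1] < 1.0):
            raise ConfigurationError("eccentricity_range must lie in [0, 1)")
        if self.pixel_spacing_mm <= 0:
            raise ConfigurationError("pixel spacing must be positive")
        if any(c not in range(6) for c in self.classes) or not self.classes:
            raise ConfigurationError("classes must be a non-empty subset of {0..5}")
        if self.nodules_per_image[0] > self.nodules_per_image[1] or self.nodules_per_image[0] < 0:
            raise ConfigurationError("nodules_per_image must be an ordered non-negative range")
        # worst-case major semi-axis must fit inside the grid
        a_max = self._major_semi_axis_px(self.diameter_mm_range[1], self.eccentricity_range[1])
        if 2 * (a_max + _BORDER_MARGIN) >= self.image_size:
            raise ConfigurationError(
                f"largest nodule (semi-axis {a_max:.1f} px) does not fit in a "
                f"{self.image_size} px image"
            )

    def _major_semi_axis_px(self, diameter_mm: float, eccentricity: float) -> float:
        d_px = diameter_mm / self.pixel_spacing_mm
        axis_ratio = np.sqrt(1.0 - eccentricity**2)  # minor/major
        return (d_px / 2.0) / np.sqrt(axis_ratio)

    @property
    def rule(self) -> DiameterLabelRule:
        if self.label_rule is not None:
            return self.label_rule
        return DiameterLabelRule.equal_bins(*self.diameter_mm_range)

    @property
    def spacing(self) -> PixelSpacing:
        return PixelSpacing(self.pixel_spacing_mm, self.pixel_spacing_mm)

    def summary(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "image_size": self.image_size,
            "pixel_spacing_mm": self.pixel_spacing_mm,
            "nodules_per_image": list(self.nodules_per_image),
            "diameter_mm_range": list(self.diameter_mm_range),
            "eccentricity_range": list(self.eccentricity_range),
            "intensity_contrast": self.intensity_contrast,
            "noise_sd": self.noise_sd,
            "background_fraction_range": list(self.background_fraction_range),
            "classes": list(self.classes),
            "label_cutpoints": list(self.rule.cutpoints),
            "seed": self.seed,
        }


@dataclass
class PhantomDataset:
    images: list[CTImage]
    masks: list[NoduleMask]
    labels: list[int]
    truth: list[list[NoduleTruth]]
    config_summary: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.images)
        if not (len(self.masks) == len(self.labels) == len(self.truth) == n):
            raise ValueError("images, masks, labels and truth must have equal lengths")
        for img, mask in zip(self.images, self.masks):
            if img.pixels.shape != mask.pixels.shape:
                raise ValueError("each mask must be congruent with its image")
        if any(lab not in range(6) for lab in self.labels):
            raise ValueError("labels must lie in 0..5")

    def __len__(self) -> int:
        return len(self.images)

    def image_array(self) -> np.ndarray:
        """(n, H, W) float array of image intensities."""
        return np.stack([img.pixels for img in self.images])

    def mask_array(self) -> np.ndarray:
        """(n, H, W) float array of mask indicators."""
        return np.stack([m.pixels.astype(np.float64) for m in self.masks])

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=np.int64)


def render_nodule(
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    orientation: float,
    grid_size: int,
) -> np.ndarray:
    """Rasterize a filled ellipse as a {0,1} grid (pixel-center membership).

    ``center`` is (row, col); ``semi_axes`` is (a, b) in pixels with the major
    axis along ``orientation`` radians (measured from the row axis).
    """
    a, b = semi_axes
    if a <= 0 or b <= 0:
        raise ValueError(f"semi-axes must be positive, got {semi_axes}")
    r0, c0 = center
    if not (0 <= r0 < grid_size and 0 <= c0 < grid_size):
        raise ValueError(f"center {center} lies outside the {grid_size} px grid")
    rows, cols = np.mgrid[0:grid_size, 0:grid_size]
    dr, dc = rows - r0, cols - c0
    cos_t, sin_t = np.cos(orientation), np.sin(orientation)
    u = dr * cos_t + dc * sin_t  # along major axis
    v = -dr * sin_t + dc * cos_t
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.uint8)


def burden_diameter(truth: Sequence[NoduleTruth]) -> float:
    """Total-burden equivalent diameter: sqrt(sum of squared diameters), the
    diameter of the circle whose area equals the combined nodule area."""
    return float(np.sqrt(sum(n.diameter_mm**2 for n in truth)))


def label_from_nodule(
    truth: NoduleTruth | Sequence[NoduleTruth] | None, rule: DiameterLabelRule
) -> int:
    """Severity label of a nodule (or nodule list): 0 when absent, else the
    grade of the total-burden equivalent diameter under ``rule``.  For a
    single nodule this is simply the grade of its own diameter."""
    if truth is None:
        return 0
    if isinstance(truth, NoduleTruth):
        truth = [truth]
    if len(truth) == 0:
        return 0
    return rule.grade(burden_diameter(truth))


#: smallest component nodule in a multi-nodule split, mm (the clinical size
#: gate: smaller lesions are not tracked as nodules)
_MIN_COMPONENT_MM = 3.0


def _split_burden(rng: np.random.Generator, d_eq: float, k: int) -> list[float]:
    """Split a total burden into k component diameters with sum d_i^2 = d_eq^2.

    Squared diameters follow a symmetric Dirichlet split, resampled until
    every component clears the 3 mm floor; falls back to fewer components
    (k = 1 always succeeds).  Components are returned largest first.
    """
    while k > 1:
        for _ in range(20):
            w = rng.dirichlet(np.ones(k))
            ds = d_eq * np.sqrt(np.sort(w)[::-1])
            if ds[-1] >= _MIN_COMPONENT_MM:
                return [float(d) for d in ds]
        k -= 1
    return [float(d_eq)]


def _sample_axes(
    rng: np.random.Generator, config: PhantomConfig, diameter_mm: float
) -> tuple[float, float, float]:
    ecc = rng.uniform(*config.eccentricity_range)
    axis_ratio = float(np.sqrt(1.0 - ecc**2))
    d_px = diameter_mm / config.pixel_spacing_mm
    a = (d_px / 2.0) / np.sqrt(axis_ratio)
    b = (d_px / 2.0) * np.sqrt(axis_ratio)
    theta = rng.uniform(0.0, np.pi)
    return a, b, theta


def _place_center(
    rng: np.random.Generator,
    size: int,
    semi_major: float,
    placed: list[tuple[float, float, float]],
    n_tries: int = 80,
) -> tuple[float, float] | None:
    lo = semi_major + _BORDER_MARGIN
    hi = size - 1 - semi_major - _BORDER_MARGIN
    if hi <= lo:
        return None
    for _ in range(n_tries):
        r0, c0 = rng.uniform(lo, hi), rng.uniform(lo, hi)
        ok = all(
            np.hypot(r0 - pr, c0 - pc) >= semi_major + pa + _MIN_SEPARATION
            for pr, pc, pa in placed
        )
        if ok:
            return r0, c0
    return None


def generate_phantom(config: PhantomConfig) -> PhantomDataset:
    """Generate a :class:`PhantomDataset` under ``config``.

    Labels are balanced over ``config.classes``; masks of nodule-bearing
    images are sparse (foreground below ``1 - background_fraction_range[0]``
    under the default configuration); class-0 images have empty masks.
    """
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    total_px = size * size
    rule = config.rule
    fg_hi = 1.0 - config.background_fraction_range[0]
    n_min, n_max = config.nodules_per_image

    images: list[CTImage] = []
    masks: list[NoduleMask] = []
    labels: list[int] = []
    truth: list[list[NoduleTruth]] = []

    for _ in range(config.n_samples):
        grade = 0 if n_max == 0 else int(rng.choice(config.classes))
        nodules: list[NoduleTruth] = []
        mask = np.zeros((size, size), dtype=np.uint8)

        if grade > 0:
            placed: list[tuple[float, float, float]] = []
            d_lo, d_hi = rule.bin_interval(grade, *config.diameter_mm_range)
            d_eq = rng.uniform(d_lo, d_hi)
            component_ds = _split_burden(
                rng, d_eq, int(rng.integers(max(n_min, 1), n_max + 1))
            )
            for d in component_ds:
                a, b, theta = _sample_axes(rng, config, d)
                center = _place_center(rng, size, a, placed)
                if center is None:
                    break  # crowded slice: carry the reduced burden honestly
                ell = render_nodule(center, (a, b), theta, size)
                if nodules and (mask | ell).mean() > fg_hi:
                    break  # keep the per-mask sparsity cap
                mask |= ell
                intensity = 0.25 + config.intensity_contrast + rng.uniform(-0.03, 0.03)
                nodules.append(
                    NoduleTruth(
                        center=center,
                        semi_axes=(a, b),
                        orientation=theta,
                        diameter_mm=d,
                        intensity=intensity,
                    )
                )
                placed.append((center[0], center[1], a))
            if not nodules:
                raise ConfigurationError(
                    "could not place the primary nodule; image too small for "
                    "the configured diameter range"
                )

        # smooth low-frequency parenchyma stand-in in ~[0.1, 0.3]
        bg_field = gaussian_filter(rng.standard_normal((size, size)), sigma=size / 16.0)
        sd = bg_field.std()
        if sd > 0:
            bg_field = np.clip((bg_field - bg_field.mean()) / (3.0 * sd), -1.0, 1.0)
        img = 0.2 + 0.1 * bg_field
        for nod in nodules:
            ell = render_nodule(nod.center, nod.semi_axes, nod.orientation, size)
            img = np.where(ell > 0, nod.intensity, img)
        img = np.clip(img + rng.normal(0.0, config.noise_sd, (size, size)), 0.0, 1.0)

        # recompute from what was actually placed (a crowded slice may have
        # dropped a component, reducing the burden)
        label = label_from_nodule(nodules, rule)
        images.append(CTImage(pixels=img, spacing=config.spacing))
        masks.append(NoduleMask(pixels=mask, spacing=config.spacing))
        labels.append(label)
        truth.append(nodules)

    return PhantomDataset(
        images=images,
        masks=masks,
        labels=labels,
        truth=truth,
        config_summary=config.summary(),
    )


def scaled_config(n_samples: int, seed: int = 0, classes: tuple[int, ...] = (0, 1, 2, 3, 4, 5)) -> PhantomConfig:
    """Desk-scale configuration: 64 px slices at 1 mm/px with the same sparse
    structure as the default, sized so training stays CPU-friendly."""
    return PhantomConfig(
        n_samples=n_samples,
        image_size=64,
        pixel_spacing_mm=1.0,
        nodules_per_image=(1, 3),
        diameter_mm_range=(6.0, 26.0),
        classes=classes,
        seed=seed,
    )


def separable_config(n_samples: int, seed: int = 0) -> PhantomConfig:
    """Two widely separated severity grades (1 vs 5) on 64 px slices — a
    linearly learnable task for model sanity checks."""
    return PhantomConfig(
        n_samples=n_samples,
        image_size=64,
        pixel_spacing_mm=1.0,
        nodules_per_image=(1, 1),
        diameter_mm_range=(6.0, 26.0),
        eccentricity_range=(0.0, 0.4),
        background_fraction_range=(0.80, 0.999),
        classes=(1, 5),
        seed=seed,
    )
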