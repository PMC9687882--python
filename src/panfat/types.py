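"""Core container types shared across the pipeline.

All images are 2-D ``numpy`` arrays in row-major (row, col) = (y, x) order with
0-based pixel indices. Masks are boolean arrays with pixel-set semantics.
Physical units: pixel spacing in mm/pixel, slice thickness in mm, volumes in
mm^3, fat fractions in percent (0-100).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import InvalidInputError

Phase = Literal["water", "fat"]


@dataclass
class GraySlice:
    """One 2-D single-channel MR slice.

    Parameters
    ----------
    data : ndarray of float, shape (H, W)
        Pixel intensities in arbitrary scanner units.
    spacing : float
        In-plane pixel spacing, mm/pixel (isotropic).
    thickness : float
        Slice thickness in mm.
    phase : {"water", "fat"}
        Acquisition phase this slice belongs to.
    """

    data: np.ndarray
    spacing: float = 1.0
    thickness: float = 3.0
    phase: Phase = "water"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise InvalidInputError(f"slice data must be 2-D, got {self.data.ndim}-D")
        if self.spacing <= 0 or self.thickness <= 0:
            raise InvalidInputError("spacing and thickness must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class SuperpixelMap:
    """Per-pixel superpixel label field plus per-superpixel summaries.

    Invariants (checked by :meth:`validate`): labels form a partition of the
    pixel grid into ``K_actual`` nonempty clusters labelled 0..K_actual-1;
    each stored center pixel carries its own superpixel's label; sizes sum to
    the pixel count.
    """

    labels: np.ndarray
    K_actual: int
    centers: np.ndarray  # (K_actual, 2) int, (row, col)
    sizes: np.ndarray  # (K_actual,) int

    def validate(self) -> None:
        labs = np.unique(self.labels)
        if labs.min() != 0 or labs.max() != self.K_actual - 1 or len(labs) != self.K_actual:
            raise InvalidInputError("labels must cover 0..K_actual-1 with no gaps")
        if int(self.sizes.sum()) != self.labels.size:
            raise InvalidInputError("sizes must sum to the pixel count")
        rows, cols = self.centers[:, 0], self.centers[:, 1]
        if not np.array_equal(self.labels[rows, cols], np.arange(self.K_actual)):
            raise InvalidInputError("each center must lie inside its own superpixel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]


@dataclass
class SuperpixelQuality:
    """Quality metrics of one superpixel map against a ground-truth mask.

    UE
        Undersegmentation error in [0, 1] (lower is better).
    BR
        Boundary recall in [0, 1] (higher is better).
    ASA
        Achievable segmentation accuracy as an area-agreement percentage.
    CP
        Compactness: size-weighted isoperimetric quotient in (0, 1].
    I
        Balance index ``1 - BR/CP``; its minimum positive value marks the
        operating point where boundary recall and compactness are balanced.
    """

    UE: float
    BR: float
    ASA: float
    CP: float
    I: float


@dataclass
class SchematicImage:
    """Superpixel-averaged (visual summary) image.

    ``values`` is constant within each superpixel of ``source_map`` and each
    constant equals the arithmetic mean of the source gray values over that
    superpixel.
    """

    values: np.ndarray
    source_map: SuperpixelMap


@dataclass
class PhantomSeries:
    """Emulsion phantom series: known fat fractions with observed intensities.

    ``samples`` is a list of (true_fat_fraction %, mean_intensity) pairs with
    strictly increasing fractions in [0, 100].
    """

    samples: list[tuple[float, float]]
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if len(self.samples) < 2:
            raise InvalidInputError("a phantom series needs at least 2 samples")
        fracs = np.array([s[0] for s in self.samples], dtype=float)
        intens = np.array([s[1] for s in self.samples], dtype=float)
        if np.any(np.diff(fracs) <= 0):
            raise InvalidInputError("phantom fractions must be strictly increasing")
        if fracs.min() < 0 or fracs.max() > 100:
            raise InvalidInputError("phantom fractions must lie in [0, 100]")
        if not np.all(np.isfinite(intens)) or np.any(intens < 0):
            raise InvalidInputError("phantom intensities must be finite and non-negative")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([s[0] for s in self.samples], dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([s[1] for s in self.samples], dtype=float)


@dataclass
class SyntheticSlicePair:
    """A matched water/fat slice pair with ground truth.

    ``true_fat_fraction_map`` holds per-pixel fat percentages and is zero
    outside intra-organ fat speckles; ``organ_area_mm2`` is the mask area in
    physical units.
    """

    water: GraySlice
    fat: GraySlice
    gt_mask: np.ndarray
    true_fat_fraction_map: np.ndarray
    organ_area_mm2: float

    def __post_init__(self) -> None:
        shapes = {self.water.shape, self.fat.shape, self.gt_mask.shape,
                  self.true_fat_fraction_map.shape}
        if len(shapes) != 1:
            raise InvalidInputError("water/fat/mask/fraction-map shapes must match")
        if self.water.spacing != self.fat.spacing:
            raise InvalidInputError("water and fat spacing must match")


@dataclass
class SyntheticStack:
    """An ordered stack of synthetic slice pairs with known volumes."""

    slices: list[SyntheticSlicePair]
    thickness: float
    true_volume_mm3: float
    true_fat_volume_mm3: float

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise InvalidInputError("thickness must be positive")


@dataclass
class CalibrationCurve:
    """Affine map from fat-image pixel intensity to fat fraction (%).

    ``fraction = clip(slope * intensity + intercept, 0, 100)``. The curve also
    records its fit quality (R^2) and the intensity range it was fitted on.
    """

    slope: float
    intercept: float
    r_squared: float
    valid_range: tuple[float, float]

    def __call__(self, intensity: np.ndarray) -> np.ndarray:
        return np.clip(self.slope * np.asarray(intensity, dtype=float) + self.intercept,
                       0.0, 100.0)


@dataclass
class FatFractionMap:
    """Per-pixel fat percentages defined on a region of interest."""

    values: np.ndarray
    mask: np.ndarray
    n_out_of_range: int = 0

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise InvalidInputError("fraction map and mask shapes must match")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise InvalidInputError("fat fractions must be finite inside the mask")


@dataclass
class SliceQuant:
    """Per-slice quantification breakdown."""

    index: int
    area_mm2: float
    eroded_area_mm2: float
    kept_pixels: int
    fat_volume_mm3: float


@dataclass
class QuantResult:
    """Pancreas volume, intra-pancreatic fat volume and fat fraction.

    ``fat_fraction_pct`` is ``100 * fat_volume / pancreas_volume`` when the
    pancreas volume is positive; the denominator uses the un-eroded pancreas
    volume unless the caller configured otherwise.
    """

    pancreas_volume_mm3: float
    fat_volume_mm3: float
    fat_fraction_pct: float
    per_slice: list[SliceQuant] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pancreas_volume_mm3": self.pancreas_volume_mm3,
            "pancreas_volume_ml": self.pancreas_volume_mm3 / 1000.0,
            "fat_volume_mm3": self.fat_volume_mm3,
            "fat_volume_ml": self.fat_volume_mm3 / 1000.0,
            "fat_fraction_pct": self.fat_fraction_pct,
            "per_slice": [
                {
                    "slice": s.index,
                    "area_mm2": s.area_mm2,
                    "eroded_area_mm2": s.eroded_area_mm2,
                    "kept_pixels": s.kept_pixels,
                    "fat_volume_mm3": s.fat_volume_mm3,
                }
                for s in self.per_slice
            ],
        }


@dataclass
class TrainHistory:
    """Per-epoch training and validation Dice scores."""

    train_dice: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_dice)


@dataclass
class PredictionMask:
    """A binary segmentation prediction.

    In ``centered`` mode the mask is by construction a union of whole
    superpixels of ``source_map`` (each superpixel takes the class of its
    center pixel).
    """

    mask: np.ndarray
    mode: Literal["dense", "centered"]
    source_map: SuperpixelMap | None = None


def as_bool_mask(mask: "np.ndarray | Sequence") -> np.ndarray:
    """Coerce an array-like to a 2-D boolean mask."""
    m = np.asarray(mask)
    if m.ndim != 2:
        raise InvalidInputError("mask must be 2-D")
    return m.astype(bool)
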