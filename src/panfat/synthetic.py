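"""Synthetic water/fat MR data with analytically known ground truth.

The generators emulate the inputs of the quantification pipeline without any
acquisition step: an emulsion-phantom calibration series (known fat fraction
vs. mean intensity), single water/fat slice pairs containing a soft elongated
organ with intra-organ fat speckle at a requested area-weighted fraction, and
multi-slice stacks whose total volume and fat volume are known exactly by
construction.

Intensity convention
--------------------
Both the phantom series and the fat-phase slices share one affine intensity
model: ``intensity = FAT_SLOPE * fat_fraction_pct + FAT_INTERCEPT (+ noise)``.
This keeps phantom calibration and per-pixel fat mapping on a single scale, so
a calibration curve fitted on a generated phantom series inverts the fat-slice
intensities of generated images up to noise.

Geometry: the organ is a union of two or three overlapping ellipses with a
sinusoidal boundary perturbation, which yields the elongated, lobulated,
soft-boundary shape typical of the pancreas on axial slices. Optional
confounder blobs with near-organ water intensity touch the organ boundary,
mimicking the small intestine and visceral tissue that make the true boundary
ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import InvalidInputError
from .types import GraySlice, PhantomSeries, SyntheticSlicePair, SyntheticStack

# Shared affine intensity<->fat-fraction convention (arbitrary units / %).
FAT_SLOPE = 1.5
FAT_INTERCEPT = 5.0

# Water-phase intensities (arbitrary units).
WATER_BACKGROUND = 40.0
WATER_ORGAN = 125.0
WATER_CONFOUNDER = 118.0

#: Default per-pixel Gaussian noise (intensity units) on the fat phase.
DEFAULT_NOISE_SD = 1.5

#: Default per-pixel noise on the water phase. Abdominal MR magnitude images
#: are noisy relative to soft-tissue contrast; together with partial-volume
#: blur this keeps the organ/confounder boundary genuinely low-contrast.
DEFAULT_WATER_NOISE_SD = 6.0

#: Partial-volume blur (px) applied to the water phase before noise.
WATER_BLUR_SIGMA = 1.1

#: Background-tissue and confounder (visceral-fat) fat fractions, %.
BACKGROUND_FAT_PCT = 2.0
CONFOUNDER_FAT_PCT = 40.0

#: Intra-organ speckle values are confined to [LOW, HIGH] %, comfortably
#: inside the MR-opsy inclusion band [1, 20] so that acquisition noise does
#: not push genuine in-band fat across the exclusion thresholds.
SPECKLE_LOW_PCT = 1.5
SPECKLE_HIGH_PCT = 18.0


@dataclass
class OrganSpec:
    """Geometry of the synthetic organ.

    ``center`` is fractional (row, col); ``radius_frac`` the base semi-major
    axis as a fraction of the smaller image dimension; ``aspect`` the
    minor/major axis ratio; the boundary is perturbed radially by
    ``1 + boundary_amp * sin(n_lobes * theta + phase)``.
    """

    center: tuple[float, float] = (0.50, 0.52)
    radius_frac: float = 0.26
    aspect: float = 0.55
    n_ellipses: int = 3
    boundary_amp: float = 0.10
    n_lobes: int = 7
    angle_deg: float = -18.0
    scale: float = 1.0


def _ellipse_mask(shape, center_rc, a, b, angle_rad, boundary_amp, n_lobes, phase):
    """Pixel mask of one ellipse with sinusoidally perturbed radius."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    dy = rr - center_rc[0]
    dx = cc - center_rc[1]
    # rotate into the ellipse frame
    u = np.cos(angle_rad) * dx + np.sin(angle_rad) * dy
    v = -np.sin(angle_rad) * dx + np.cos(angle_rad) * dy
    theta = np.arctan2(v, u)
    radius = 1.0 + boundary_amp * np.sin(n_lobes * theta + phase)
    return (u / a) ** 2 + (v / b) ** 2 <= radius**2


def _organ_mask(shape, spec: OrganSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    base = spec.radius_frac * spec.scale * min(h, w)
    if base < 2.0:
        return np.zeros(shape, dtype=bool)
    if base * (1.0 + spec.boundary_amp) >= 0.5 * min(h, w):
        raise InvalidInputError("organ does not fit inside the image")
    angle = np.deg2rad(spec.angle_deg)
    c0 = np.array([spec.center[0] * h, spec.center[1] * w])
    mask = np.zeros(shape, dtype=bool)
    n = max(1, spec.n_ellipses)
    # lay the lobes out along the major axis to elongate the shape
    offsets = np.linspace(-0.55, 0.55, n) * base
    for i, off in enumerate(offsets):
        center = c0 + off * np.array([np.sin(angle), np.cos(angle)])
        a = base * (0.72 + 0.18 * rng.random())
        b = a * spec.aspect * (0.85 + 0.3 * rng.random())
        phase = rng.uniform(0, 2 * np.pi)
        mask |= _ellipse_mask(shape, center, a, b,
                              angle + rng.normal(0, 0.12),
                              spec.boundary_amp, spec.n_lobes, phase)
    return mask


def _speckle_field(mask: np.ndarray, target_pct: float, rng: np.random.Generator,
                   sigma: float = 1.2) -> np.ndarray:
    """Intra-organ fat speckle map (%), area-weighted mean ~= target_pct.

    Gaussian blobs are stamped at random intra-organ sites and blurred; values
    below 1.5% are cut to 0 (clean parenchyma) and values are capped at 18%,
    so every nonzero speckle value lies strictly inside the MR-opsy band. Blob
    amplitudes are rescaled iteratively until the area-weighted mean matches
    the requested fraction.
    """
    field = np.zeros(mask.shape, dtype=float)
    n_organ = int(mask.sum())
    if target_pct <= 0 or n_organ == 0:
        return field
    coords = np.argwhere(mask)
    blob_mass = 12.0 * 2.0 * np.pi * sigma**2  # mean peak 12% times blur mass
    n_blobs = max(3, int(round(target_pct * n_organ / blob_mass)))
    idx = rng.integers(0, len(coords), size=n_blobs)
    peaks = rng.uniform(8.0, 16.0, size=n_blobs)
    impulse = np.zeros(mask.shape, dtype=float)
    np.add.at(impulse, (coords[idx, 0], coords[idx, 1]), peaks * 2 * np.pi * sigma**2)
    base = gaussian_filter(impulse, sigma)
    base[~mask] = 0.0

    scale = 1.0
    for _ in range(15):
        f = base * scale
        f[f < SPECKLE_LOW_PCT] = 0.0
        np.clip(f, 0.0, SPECKLE_HIGH_PCT, out=f)
        mean = f[mask].mean()
        if abs(mean - target_pct) <= 0.2:
            break
        scale *= target_pct / mean if mean > 0 else 2.0
    return f


def generate_phantom_series(fractions=None, slope: float = FAT_SLOPE,
                            intercept: float = FAT_INTERCEPT,
                            noise_sd: float = 0.5, seed: int = 0) -> PhantomSeries:
    """Generate an emulsion-phantom calibration series.

    Each sample pairs a known fat volume fraction (%) with the mean image
    intensity it produces under the affine intensity model, plus Gaussian
    measurement noise. Defaults span 0-100% in 10% steps.

    Raises
    ------
    InvalidInputError
        For fewer than 2 fractions, non-increasing or out-of-range fractions,
        or negative noise_sd.
    """
    if fractions is None:
        fractions = list(range(0, 101, 10))
    fractions = [float(f) for f in fractions]
    if len(fractions) < 2:
        raise InvalidInputError("need at least 2 phantom fractions")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be non-negative")
    arr = np.asarray(fractions)
    if np.any(np.diff(arr) <= 0):
        raise InvalidInputError("fractions must be strictly increasing")
    if arr.min() < 0 or arr.max() > 100:
        raise InvalidInputError("fractions must lie in [0, 100]")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(fractions)) if noise_sd > 0 else np.zeros(len(fractions))
    intensities = slope * arr + intercept + noise
    intensities = np.maximum(intensities, 0.0)  # intensities are non-negative
    samples = [(float(f), float(i)) for f, i in zip(arr, intensities)]
    return PhantomSeries(samples=samples, noise_sd=noise_sd, seed=seed)


def generate_slice_pair(shape=(512, 512), spacing: float = 1.0,
                        organ_spec: OrganSpec | None = None,
                        fat_fraction: float = 8.0,
                        confounders: bool = True,
                        noise_sd: float = DEFAULT_NOISE_SD,
                        water_noise_sd: float = DEFAULT_WATER_NOISE_SD,
                        thickness: float = 3.0,
                        seed: int = 0) -> SyntheticSlicePair:
    """Generate one matched water/fat slice pair with ground truth.

    The water image shows the organ brighter than background, softened by
    partial-volume blur, with a smooth bias field and pixel noise
    (``water_noise_sd``); when ``confounders`` is set, one or two blobs of
    near-organ intensity touch the organ boundary, so the clinically relevant
    part of the boundary is genuinely low-contrast. The fat image renders
    per-pixel fat fractions through the shared affine intensity model with
    its own noise level (``noise_sd``); the organ's speckle map is returned
    as ``true_fat_fraction_map`` and its area-weighted mean matches
    ``fat_fraction`` to within half a percentage point for organs of at
    least ~500 pixels.
    """
    if not (0.0 <= fat_fraction <= 100.0):
        raise InvalidInputError("fat_fraction must be in [0, 100]")
    h, w = shape
    if h < 32 or w < 32:
        raise InvalidInputError("shape must be at least 32x32")
    spec = organ_spec or OrganSpec()
    rng = np.random.default_rng(seed)

    gt_mask = _organ_mask((h, w), spec, rng)
    frac_map = _speckle_field(gt_mask, fat_fraction, rng)

    # --- water phase ---
    water = np.full((h, w), WATER_BACKGROUND, dtype=float)
    water[gt_mask] = WATER_ORGAN
    conf_mask = np.zeros((h, w), dtype=bool)
    if confounders and gt_mask.any():
        conf_mask = _confounder_blobs(gt_mask, spec, rng)
        water[conf_mask & ~gt_mask] = WATER_CONFOUNDER
    # smooth bias field plus pixel noise, both typical of MR magnitude images
    bias = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=max(h, w) / 8.0)
    if bias.std() > 0:
        bias = bias / bias.std() * 4.0
    water = gaussian_filter(water, WATER_BLUR_SIGMA) + bias
    if water_noise_sd > 0:
        water = water + rng.normal(0.0, water_noise_sd, (h, w))

    # --- fat phase: affine render of the full-scene fat fraction ---
    scene_frac = np.full((h, w), BACKGROUND_FAT_PCT, dtype=float)
    scene_frac[gt_mask] = frac_map[gt_mask]
    scene_frac[conf_mask & ~gt_mask] = CONFOUNDER_FAT_PCT
    fat = FAT_SLOPE * scene_frac + FAT_INTERCEPT
    if noise_sd > 0:
        fat = fat + rng.normal(0.0, noise_sd, (h, w))

    area = float(gt_mask.sum()) * spacing**2
    return SyntheticSlicePair(
        water=GraySlice(water, spacing=spacing, thickness=thickness, phase="water"),
        fat=GraySlice(fat, spacing=spacing, thickness=thickness, phase="fat"),
        gt_mask=gt_mask,
        true_fat_fraction_map=frac_map,
        organ_area_mm2=area,
    )


def _confounder_blobs(gt_mask: np.ndarray, spec: OrganSpec,
                      rng: np.random.Generator) -> np.ndarray:
    """One or two elliptical blobs abutting the organ boundary."""
    h, w = gt_mask.shape
    boundary = gt_mask & ~_erode1(gt_mask)
    pts = np.argwhere(boundary)
    conf = np.zeros_like(gt_mask)
    if len(pts) == 0:
        return conf
    centroid = np.argwhere(gt_mask).mean(axis=0)
    n = rng.integers(1, 3)
    for _ in range(n):
        p = pts[rng.integers(0, len(pts))]
        out = p - centroid
        norm = np.linalg.norm(out)
        if norm == 0:
            continue
        out = out / norm
        r = spec.radius_frac * spec.scale * min(h, w) * rng.uniform(0.35, 0.55)
        center = p + out * r * 0.8
        conf |= _ellipse_mask((h, w), center, r, r * rng.uniform(0.6, 1.0),
                              rng.uniform(0, np.pi), 0.08, 5, rng.uniform(0, 2 * np.pi))
    return conf


def _erode1(mask: np.ndarray) -> np.ndarray:
    from scipy.ndimage import binary_erosion

    return binary_erosion(mask, np.ones((3, 3), dtype=bool), border_value=0)


def generate_stack(n_slices: int | None = None, thickness: float = 3.0,
                   shape=(512, 512), spacing: float = 1.0,
                   fat_fraction: float = 8.0,
                   organ_spec: OrganSpec | None = None,
                   profile: str = "ellipsoid",
                   confounders: bool = True,
                   noise_sd: float = DEFAULT_NOISE_SD,
                   water_noise_sd: float = DEFAULT_WATER_NOISE_SD,
                   seed: int = 0) -> SyntheticStack:
    """Generate an ordered multi-slice stack with known total volumes.

    ``n_slices`` defaults to a draw from 6-9, the typical number of axial
    slices covering the pancreas at 3 mm thickness. With the ``ellipsoid``
    profile the per-slice organ scale follows ``sqrt(1 - z^2/c^2)`` so the
    organ waxes and wanes through the stack; ``constant`` keeps every slice
    at full scale. ``true_volume_mm3`` and ``true_fat_volume_mm3`` are
    recomputed from the generated masks and fraction maps, so they match a
    pixel-count recomputation exactly.
    """
    rng = np.random.default_rng(seed)
    if n_slices is None:
        n_slices = int(rng.integers(6, 10))
    if n_slices < 1:
        raise InvalidInputError("n_slices must be >= 1")
    if thickness <= 0:
        raise InvalidInputError("thickness must be positive")
    spec = organ_spec or OrganSpec()

    if profile == "ellipsoid":
        z = (np.arange(n_slices) + 0.5 - n_slices / 2.0) / (n_slices / 2.0)
        scales = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
        scales = np.maximum(scales, 0.25)  # keep every slice non-degenerate
    elif profile == "constant":
        scales = np.ones(n_slices)
    else:
        raise InvalidInputError(f"unknown profile {profile!r}")

    slices = []
    for i in range(n_slices):
        pair = generate_slice_pair(
            shape=shape, spacing=spacing,
            organ_spec=replace(spec, scale=spec.scale * float(scales[i])),
            fat_fraction=fat_fraction, confounders=confounders,
            noise_sd=noise_sd, water_noise_sd=water_noise_sd, thickness=thickness,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        slices.append(pair)

    vol = sum(p.organ_area_mm2 for p in slices) * thickness
    fat_vol = sum(p.true_fat_fraction_map.sum() / 100.0 * p.water.spacing**2
                  for p in slices) * thickness
    return SyntheticStack(slices=slices, thickness=thickness,
                          true_volume_mm3=float(vol),
                          true_fat_volume_mm3=float(fat_vol))


def generate_ellipsoid_stack(semi_axes_mm=(30.0, 20.0, 12.0), spacing: float = 1.0,
                             thickness: float = 3.0, shape=(192, 192),
                             fat_fraction: float = 0.0, noise_sd: float = DEFAULT_NOISE_SD,
                             water_noise_sd: float = DEFAULT_WATER_NOISE_SD,
                             seed: int = 0) -> tuple[SyntheticStack, float]:
    """Stack whose organ is an exact ellipsoid; returns (stack, analytic volume).

    Slices sample the ellipsoid at slice-center depths (Cavalieri midpoint
    sampling); the analytic volume is ``4/3 * pi * a * b * c``. Used to check
    convergence of the slice-sum volume estimator against a closed form.
    """
    a, b, c = (float(v) for v in semi_axes_mm)
    n_slices = int(np.ceil(2 * c / thickness))
    h, w = shape
    rng = np.random.default_rng(seed)
    slices = []
    for i in range(n_slices):
        zc = (i + 0.5) * thickness - c
        s2 = 1.0 - (zc / c) ** 2
        mask = np.zeros((h, w), dtype=bool)
        if s2 > 0:
            ai = a * np.sqrt(s2) / spacing  # pixels
            bi = b * np.sqrt(s2) / spacing
            rr, cc = np.mgrid[0:h, 0:w].astype(float)
            mask = (((cc - w / 2) / ai) ** 2 + ((rr - h / 2) / bi) ** 2) <= 1.0
        frac = _speckle_field(mask, fat_fraction, rng) if fat_fraction > 0 else np.zeros((h, w))
        water = np.full((h, w), WATER_BACKGROUND)
        water[mask] = WATER_ORGAN
        fat = FAT_SLOPE * np.where(mask, frac, BACKGROUND_FAT_PCT) + FAT_INTERCEPT
        if water_noise_sd > 0:
            water = water + rng.normal(0, water_noise_sd, (h, w))
        if noise_sd > 0:
            fat = fat + rng.normal(0, noise_sd, (h, w))
        slices.append(SyntheticSlicePair(
            water=GraySlice(water, spacing=spacing, thickness=thickness, phase="water"),
            fat=GraySlice(fat, spacing=spacing, thickness=thickness, phase="fat"),
            gt_mask=mask, true_fat_fraction_map=frac,
            organ_area_mm2=float(mask.sum()) * spacing**2,
        ))
    vol = sum(p.organ_area_mm2 for p in slices) * thickness
    fat_vol = sum(p.true_fat_fraction_map.sum() / 100.0 * spacing**2 for p in slices) * thickness
    stack = SyntheticStack(slices=slices, thickness=thickness,
                           true_volume_mm3=float(vol), true_fat_volume_mm3=float(fat_vol))
    return stack, 4.0 / 3.0 * np.pi * a * b * c
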