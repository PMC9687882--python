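"""Superpixel and segmentation quality metrics.

Implements undersegmentation error (UE), boundary recall (BR), achievable
segmentation accuracy (ASA), compactness (CP), the BR/CP balance index
``I = 1 - BR/CP`` and the Dice similarity coefficient (DSC).

Boundary convention: a pixel is a boundary pixel when any of its 4-neighbors
(within the image) carries a different label / mask value. Boundary matching
for BR uses the Chebyshev (chessboard) distance.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import distance_transform_cdt

from .errors import UndefinedMetricError
from .types import SuperpixelMap, SuperpixelQuality, as_bool_mask


def _boundary(field: np.ndarray) -> np.ndarray:
    """Pixels whose 4-neighborhood (in-image) contains a different value."""
    b = np.zeros(field.shape, dtype=bool)
    b[:-1, :] |= field[:-1, :] != field[1:, :]
    b[1:, :] |= field[1:, :] != field[:-1, :]
    b[:, :-1] |= field[:, :-1] != field[:, 1:]
    b[:, 1:] |= field[:, 1:] != field[:, :-1]
    return b


def mask_boundary(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels of a binary mask (inside the mask)."""
    m = as_bool_mask(mask)
    return _boundary(m) & m


def label_boundary(labels: np.ndarray) -> np.ndarray:
    """Boundary pixels of an integer label field."""
    return _boundary(np.asarray(labels))


def object_region(superpixels: SuperpixelMap, gt_mask: np.ndarray,
                  majority: float = 0.5) -> np.ndarray:
    """Union of superpixels assigned to the object by majority overlap.

    A superpixel belongs to the object when strictly more than ``majority``
    of its pixels overlap the ground-truth mask.
    """
    gt = as_bool_mask(gt_mask)
    labels = superpixels.labels
    k = superpixels.K_actual
    overlap = np.bincount(labels.ravel(), weights=gt.ravel().astype(float), minlength=k)
    frac = overlap / superpixels.sizes
    return np.isin(labels, np.nonzero(frac > majority)[0])


def compute_ue(superpixels: SuperpixelMap, gt_mask: np.ndarray) -> float:
    """Undersegmentation error ``U_S / (R_S + O_S)``.

    The superpixel-derived object region is the majority-overlap union; O_S
    counts region pixels outside the ground truth (present but should not
    be), U_S ground-truth pixels missing from the region, R_S the
    ground-truth pixel count.
    """
    gt = as_bool_mask(gt_mask)
    if not gt.any():
        raise UndefinedMetricError("UE is undefined for an empty ground-truth mask")
    region = object_region(superpixels, gt)
    o_s = int(np.count_nonzero(region & ~gt))
    u_s = int(np.count_nonzero(gt & ~region))
    r_s = int(np.count_nonzero(gt))
    return u_s / (r_s + o_s)


def compute_br(superpixels: SuperpixelMap, gt_mask: np.ndarray, d: int = 2) -> float:
    """Boundary recall ``TP / (TP + FN)`` at Chebyshev tolerance ``d``.

    TP counts ground-truth boundary pixels lying within chessboard distance
    ``d`` of some superpixel boundary pixel; FN the rest.
    """
    gt = as_bool_mask(gt_mask)
    if d < 0:
        raise UndefinedMetricError("boundary tolerance d must be >= 0")
    gb = mask_boundary(gt)
    if not gb.any():
        raise UndefinedMetricError("ground truth has no boundary")
    sb = label_boundary(superpixels.labels)
    if not sb.any():
        return 0.0
    # chessboard distance from every pixel to the nearest superpixel boundary
    dist = distance_transform_cdt(~sb, metric="chessboard")
    tp = int(np.count_nonzero(gb & (dist <= d)))
    fn = int(np.count_nonzero(gb)) - tp
    return tp / (tp + fn)


def compute_asa(region_pred: float, region_ref: float) -> float:
    """Achievable segmentation accuracy ``(1 - |R_s - T_s| / R_s) * 100``.

    Area agreement between a predicted region ``T_s`` and the reference
    region ``R_s`` (same units, pixels or mm^2), floored at 0%.
    """
    if region_ref <= 0:
        raise UndefinedMetricError("ASA is undefined for an empty reference region")
    return max(0.0, (1.0 - abs(region_ref - region_pred) / region_ref) * 100.0)


def _perimeters(labels: np.ndarray, k: int) -> np.ndarray:
    """Exposed 4-neighborhood edge count per label (image border is exposed)."""
    per = np.zeros(k, dtype=np.int64)
    h, w = labels.shape
    for axis, side in ((0, 0), (0, -1), (1, 0), (1, -1)):
        edge = labels[side, :] if axis == 0 else labels[:, side]
        per += np.bincount(edge, minlength=k)
    for shift_axis in (0, 1):
        a = labels.take(range(0, labels.shape[shift_axis] - 1), axis=shift_axis)
        b = labels.take(range(1, labels.shape[shift_axis]), axis=shift_axis)
        diff = a != b
        per += np.bincount(a[diff], minlength=k)
        per += np.bincount(b[diff], minlength=k)
    return per


def compute_cp(superpixels: SuperpixelMap) -> float:
    """Compactness: size-weighted mean isoperimetric quotient, in (0, 1].

    ``CP = sum_k (|S_k|/N) * (4 pi A_k / P_k^2)`` with A_k the pixel count of
    superpixel k and P_k its exposed edge count (image border included).
    Values above 1 (possible on the pixel grid for tiny regions) are clipped.
    """
    labels = superpixels.labels
    k = superpixels.K_actual
    n = labels.size
    areas = superpixels.sizes.astype(float)
    per = _perimeters(labels, k).astype(float)
    q = 4.0 * np.pi * areas / per**2
    cp = float(np.sum(areas / n * q))
    return min(cp, 1.0)


def balance_index(br: float, cp: float) -> float:
    """Balance index ``I = 1 - BR/CP`` between boundary recall and compactness.

    The operating point of interest is the minimum *positive* I: high BR and
    high CP together. Negative values (BR exceeding CP) rank after positive
    ones in the search.
    """
    if cp <= 0:
        raise UndefinedMetricError("balance index undefined for CP <= 0")
    return 1.0 - br / cp


def evaluate_map(superpixels: SuperpixelMap, gt_mask: np.ndarray,
                 d: int = 2) -> SuperpixelQuality:
    """All quality metrics of one superpixel map against a ground-truth mask."""
    gt = as_bool_mask(gt_mask)
    ue = compute_ue(superpixels, gt)
    br = compute_br(superpixels, gt, d=d)
    region = object_region(superpixels, gt)
    asa = compute_asa(float(region.sum()), float(gt.sum()))
    cp = compute_cp(superpixels)
    return SuperpixelQuality(UE=ue, BR=br, ASA=asa, CP=cp, I=balance_index(br, cp))


def dice_coefficient(x: np.ndarray, y: np.ndarray) -> float:
    """Dice similarity coefficient ``2|X ∩ Y| / (|X| + |Y|)``.

    Undefined (raises) when both masks are empty.
    """
    xm = as_bool_mask(x)
    ym = as_bool_mask(y)
    if xm.shape != ym.shape:
        raise UndefinedMetricError("mask shapes must match")
    denom = int(xm.sum()) + int(ym.sum())
    if denom == 0:
        raise UndefinedMetricError("DSC undefined when both masks are empty")
    return 2.0 * int(np.count_nonzero(xm & ym)) / denom
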