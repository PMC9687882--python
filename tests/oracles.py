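"""Independent brute-force pixel-level oracles.

Everything here is written as plain loops over pixels, deliberately sharing
no code with the package implementation, so metric and morphology results
can be cross-checked exactly on small fields.
"""

from __future__ import annotations

import math

import numpy as np


def boundary_pixels_of_mask(mask: np.ndarray) -> set[tuple[int, int]]:
    h, w = mask.shape
    out = set()
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if 0 <= ni < h and 0 <= nj < w and not mask[ni, nj]:
                    out.add((i, j))
    return out


def boundary_pixels_of_labels(labels: np.ndarray) -> set[tuple[int, int]]:
    h, w = labels.shape
    out = set()
    for i in range(h):
        for j in range(w):
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if 0 <= ni < h and 0 <= nj < w and labels[ni, nj] != labels[i, j]:
                    out.add((i, j))
    return out


def ue_oracle(labels: np.ndarray, gt: np.ndarray) -> float:
    """Undersegmentation error with the >50% majority-overlap object rule."""
    region = np.zeros_like(gt, dtype=bool)
    for lab in np.unique(labels):
        members = labels == lab
        if gt[members].sum() / members.sum() > 0.5:
            region |= members
    o_s = int(np.sum(region & ~gt))
    u_s = int(np.sum(gt & ~region))
    r_s = int(np.sum(gt))
    return u_s / (r_s + o_s)


def br_oracle(labels: np.ndarray, gt: np.ndarray, d: int) -> float:
    gb = boundary_pixels_of_mask(gt)
    sb = boundary_pixels_of_labels(labels)
    tp = 0
    for (i, j) in gb:
        if any(max(abs(i - a), abs(j - b)) <= d for (a, b) in sb):
            tp += 1
    return tp / len(gb)


def asa_oracle(pred_area: float, ref_area: float) -> float:
    return max(0.0, (1.0 - abs(ref_area - pred_area) / ref_area) * 100.0)


def cp_oracle(labels: np.ndarray) -> float:
    h, w = labels.shape
    n = h * w
    total = 0.0
    for lab in np.unique(labels):
        area = 0
        per = 0
        for i in range(h):
            for j in range(w):
                if labels[i, j] != lab:
                    continue
                area += 1
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    ni, nj = i + di, j + dj
                    if not (0 <= ni < h and 0 <= nj < w) or labels[ni, nj] != lab:
                        per += 1
        total += (area / n) * (4.0 * math.pi * area / per**2)
    return min(total, 1.0)


def dice_oracle(x: np.ndarray, y: np.ndarray) -> float:
    inter = int(np.sum(x & y))
    return 2.0 * inter / (int(x.sum()) + int(y.sum()))


def erosion_oracle(mask: np.ndarray, k: int) -> np.ndarray:
    """{z : (B + z) subset of X} for a k x k square B, background outside."""
    h, w = mask.shape
    r = k // 2
    out = np.zeros_like(mask, dtype=bool)
    for i in range(h):
        for j in range(w):
            ok = True
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    ni, nj = i + di, j + dj
                    if not (0 <= ni < h and 0 <= nj < w) or not mask[ni, nj]:
                        ok = False
                        break
                if not ok:
                    break
            out[i, j] = ok
    return out


def pixel_similarity_oracle(p, q, c_s, c_c) -> float:
    """Direct evaluation of the similarity kernel."""
    return (c_s**2 * (math.cos(math.pi / 2 * (p[0] - q[0]))
                      + math.cos(math.pi / 2 * (p[1] - q[1])))
            + c_c**2 * math.cos(math.pi / 2 * (p[2] - q[2])))


def random_label_field(rng: np.random.Generator, h: int, w: int,
                       k: int) -> np.ndarray:
    """A random partition into <= k labels with every label nonempty."""
    labels = rng.integers(0, k, size=(h, w))
    _, labels = np.unique(labels, return_inverse=True)
    return labels.reshape(h, w).astype(np.int32)
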