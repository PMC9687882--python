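"""Grayscale linear spectral clustering (LSC) superpixels.

The similarity between two pixels p, q with normalized coordinates and gray
value (x, y, g) in [0, 1] is

    D(p, q) = c_s^2 (cos(pi/2 (x_p - x_q)) + cos(pi/2 (y_p - y_q)))
              + c_c^2 cos(pi/2 (g_p - g_q))

which is maximal (= 2 c_s^2 + c_c^2) for identical pixels, i.e. it is a
similarity kernel. The kernel factorizes exactly through a 6-dimensional
cosine/sine feature embedding, so Euclidean k-means in the embedded space
maximizes within-cluster similarity — the standard LSC construction, here
adapted from three-channel Lab color to a single gray channel. Only the
ratio ``r = c_s / c_c`` matters: large r weighs spatial proximity more and
yields compact superpixels with weaker boundary adherence; small r the
reverse. The balance index ``I = 1 - BR/CP`` is minimized (over positive
values) to pick r, via simulated annealing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import measure
from sklearn.base import BaseEstimator

from .errors import InvalidInputError
from .metrics import balance_index, compute_br, compute_cp, evaluate_map
from .types import GraySlice, SchematicImage, SuperpixelMap


@dataclass
class LSCParams:
    """Parameters of the grayscale LSC segmentation.

    ``r`` is the spatial/similarity weight ratio ``c_s / c_c``; ``c_c`` is
    fixed and ``c_s = r * c_c``. ``min_region_fraction`` controls the
    connectivity cleanup: connected fragments smaller than this fraction of
    the mean superpixel size are merged into a neighbor.
    """

    n_superpixels: int = 2500
    r: float = 0.25
    c_c: float = 1.0
    max_iter: int = 10
    min_region_fraction: float = 0.05
    smooth_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_superpixels < 2:
            raise InvalidInputError("n_superpixels must be >= 2")
        if self.r <= 0:
            raise InvalidInputError("r must be positive")
        if self.max_iter < 1:
            raise InvalidInputError("max_iter must be >= 1")


def _check_normalized(*values: float) -> None:
    for v in values:
        if not (0.0 <= v <= 1.0):
            raise InvalidInputError(f"normalized component {v} outside [0, 1]")


def pixel_similarity(p, q, c_s: float, c_c: float) -> float:
    """Similarity between two pixels ``(x, y, g)`` normalized to [0, 1].

    Symmetric in p and q; maximal, equal to ``2 c_s^2 + c_c^2``, iff p == q.
    """
    xp, yp, gp = p
    xq, yq, gq = q
    _check_normalized(xp, yp, gp, xq, yq, gq)
    h = math.pi / 2.0
    return (c_s**2 * (math.cos(h * (xp - xq)) + math.cos(h * (yp - yq)))
            + c_c**2 * math.cos(h * (gp - gq)))


def feature_embed(pixel, c_s: float, c_c: float) -> np.ndarray:
    """6-D cosine/sine embedding whose inner product reproduces the kernel.

    ``f(p) . f(q) == pixel_similarity(p, q)`` exactly, by the angle-difference
    identity cos(a - b) = cos a cos b + sin a sin b.
    """
    x, y, g = pixel
    _check_normalized(x, y, g)
    h = math.pi / 2.0
    return np.array([
        c_s * math.cos(h * x), c_s * math.sin(h * x),
        c_s * math.cos(h * y), c_s * math.sin(h * y),
        c_c * math.cos(h * g), c_c * math.sin(h * g),
    ])


def _normalize_image(image: np.ndarray) -> np.ndarray:
    lo, hi = float(image.min()), float(image.max())
    if hi > lo:
        return (image - lo) / (hi - lo)
    return np.zeros_like(image, dtype=float)


def _embed_image(image: np.ndarray, c_s: float, c_c: float):
    """Embed every pixel; returns (E, g) with E of shape (H, W, 6)."""
    h_, w_ = image.shape
    g = _normalize_image(np.asarray(image, dtype=float))
    # normalize coordinates to [0, 1] by the image extent
    y = (np.arange(h_, dtype=float) / max(h_ - 1, 1))[:, None] * np.ones((1, w_))
    x = np.ones((h_, 1)) * (np.arange(w_, dtype=float) / max(w_ - 1, 1))[None, :]
    half_pi = np.pi / 2.0
    e = np.empty((h_, w_, 6), dtype=float)
    e[..., 0] = c_s * np.cos(half_pi * x)
    e[..., 1] = c_s * np.sin(half_pi * x)
    e[..., 2] = c_s * np.cos(half_pi * y)
    e[..., 3] = c_s * np.sin(half_pi * y)
    e[..., 4] = c_c * np.cos(half_pi * g)
    e[..., 5] = c_c * np.sin(half_pi * g)
    return e, g


def _seed_centers(g: np.ndarray, k: int):
    """Regular-grid seeds, each perturbed to the lowest-gradient 3x3 pixel."""
    h, w = g.shape
    step = math.sqrt(h * w / k)
    nr = max(1, int(round(h / step)))
    nc = max(1, int(round(w / step)))
    while nr * nc < k:
        if (nr + 1) * nc >= k or nc >= nr:
            nr += 1
        else:
            nc += 1
    rows = ((np.arange(nr) + 0.5) * h / nr).astype(int).clip(0, h - 1)
    cols = ((np.arange(nc) + 0.5) * w / nc).astype(int).clip(0, w - 1)
    gy, gx = np.gradient(g)
    grad = gy**2 + gx**2
    centers = []
    for r0 in rows:
        for c0 in cols:
            r_lo, r_hi = max(r0 - 1, 0), min(r0 + 2, h)
            c_lo, c_hi = max(c0 - 1, 0), min(c0 + 2, w)
            win = grad[r_lo:r_hi, c_lo:c_hi]
            dr, dc = np.unravel_index(int(np.argmin(win)), win.shape)
            centers.append((r_lo + dr, c_lo + dc))
    return np.array(centers, dtype=int), step


def _kmeans_superpixels(e: np.ndarray, centers: np.ndarray, step: float,
                        max_iter: int) -> np.ndarray:
    """Spatially windowed k-means in the embedded feature space.

    Assignment for each cluster is restricted to a 2*step x 2*step window
    centered on its spatial position (SLIC-style); pixel feature norms are
    constant, so minimizing Euclidean distance equals maximizing kernel
    similarity. Uniform pixel weights.
    """
    h, w, _ = e.shape
    k = len(centers)
    feats = e[centers[:, 0], centers[:, 1]].copy()  # (k, 6)
    pos = centers.astype(float)
    win = int(math.ceil(step))
    labels = np.full((h, w), -1, dtype=np.int32)

    for _ in range(max_iter):
        dist = np.full((h, w), np.inf)
        labels.fill(-1)
        for kk in range(k):
            r0 = int(round(pos[kk, 0]))
            c0 = int(round(pos[kk, 1]))
            r_lo, r_hi = max(r0 - win, 0), min(r0 + win + 1, h)
            c_lo, c_hi = max(c0 - win, 0), min(c0 + win + 1, w)
            block = e[r_lo:r_hi, c_lo:c_hi]
            # squared distance up to the constant pixel norm
            d = -2.0 * (block @ feats[kk]) + feats[kk] @ feats[kk]
            sub = dist[r_lo:r_hi, c_lo:c_hi]
            better = d < sub
            sub[better] = d[better]
            labels[r_lo:r_hi, c_lo:c_hi][better] = kk
        # orphans (outside every window) go to the spatially nearest center
        orphan = labels < 0
        if orphan.any():
            orc = np.argwhere(orphan)
            d2 = ((orc[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
            labels[orphan] = np.argmin(d2, axis=1).astype(np.int32)
        # update features and positions as member means
        flat = labels.ravel()
        counts = np.bincount(flat, minlength=k).astype(float)
        nonempty = counts > 0
        for dim in range(6):
            s = np.bincount(flat, weights=e[..., dim].ravel(), minlength=k)
            feats[nonempty, dim] = s[nonempty] / counts[nonempty]
        rr, cc = np.mgrid[0:h, 0:w]
        sr = np.bincount(flat, weights=rr.ravel().astype(float), minlength=k)
        sc = np.bincount(flat, weights=cc.ravel().astype(float), minlength=k)
        pos[nonempty, 0] = sr[nonempty] / counts[nonempty]
        pos[nonempty, 1] = sc[nonempty] / counts[nonempty]
    return labels


def _summaries(labels: np.ndarray):
    """(K, centers, sizes) with each center the member pixel nearest its centroid."""
    k = int(labels.max()) + 1
    flat = labels.ravel()
    sizes = np.bincount(flat, minlength=k)
    h, w = labels.shape
    rr, cc = np.mgrid[0:h, 0:w]
    sr = np.bincount(flat, weights=rr.ravel().astype(float), minlength=k)
    sc = np.bincount(flat, weights=cc.ravel().astype(float), minlength=k)
    centers = np.zeros((k, 2), dtype=int)
    for kk in range(k):
        members = np.argwhere(labels == kk)
        centroid = np.array([sr[kk], sc[kk]]) / sizes[kk]
        d2 = ((members - centroid) ** 2).sum(axis=1)
        centers[kk] = members[int(np.argmin(d2))]
    return k, centers, sizes


def enforce_connectivity(spmap: SuperpixelMap,
                         min_region_fraction: float = 0.25,
                         n_target: int | None = None,
                         image: np.ndarray | None = None) -> SuperpixelMap:
    """Make every superpixel a single 4-connected component.

    Each label keeps its largest connected component; every other fragment,
    and any label whose largest component falls below ``min_region_fraction *
    pixels / K``, is absorbed into an adjacent component — the one with the
    closest mean gray value when ``image`` is given (which preserves boundary
    adherence), else the largest neighbor. Components are then relabeled
    sequentially, so each final label is one connected region and the
    superpixel count stays close to the requested K even when the raw
    clustering fragments. Idempotent on maps that already satisfy the
    invariant (up to relabeling).
    """
    labels = np.asarray(spmap.labels)
    n = labels.size
    k_ref = n_target or spmap.K_actual
    min_size = max(1, int(min_region_fraction * n / k_ref))
    img = None if image is None else np.asarray(image, dtype=float)

    comp = measure.label(labels, background=-1, connectivity=1)  # 1..n_comp
    n_comp = int(comp.max())
    sizes = np.bincount(comp.ravel(), minlength=n_comp + 1).astype(np.int64)
    sums = (np.bincount(comp.ravel(), weights=img.ravel(), minlength=n_comp + 1)
            if img is not None else np.zeros(n_comp + 1))
    # the label each component came from, via one representative pixel
    flat_comp = comp.ravel()
    flat_lab = labels.ravel()
    uniq, first = np.unique(flat_comp, return_index=True)
    comp_label = {int(c): int(flat_lab[i]) for c, i in zip(uniq, first)}
    # keep = the largest component of each label, provided it is big enough
    best: dict[int, int] = {}
    for c in range(1, n_comp + 1):
        lab = comp_label[c]
        if lab not in best or sizes[c] > sizes[best[lab]]:
            best[lab] = c
    keep = {c for c in best.values() if sizes[c] >= min_size}
    if not keep:  # degenerate map: keep the single largest component
        keep = {int(np.argmax(sizes[1:])) + 1}

    for _ in range(50):
        pending = sorted((c for c in range(1, n_comp + 1)
                          if sizes[c] > 0 and c not in keep),
                         key=lambda c: sizes[c])
        if not pending:
            break
        changed = False
        for c in pending:
            region = comp == c
            if not region.any():
                sizes[c] = 0
                continue
            neigh = _adjacent_components(comp, region)
            neigh.discard(c)
            neigh = {t for t in neigh if sizes[t] > 0}
            if not neigh:
                continue
            kept_neigh = neigh & keep
            pool = kept_neigh or neigh
            if img is not None:
                mean_c = sums[c] / sizes[c]
                target = min(pool, key=lambda t: abs(sums[t] / sizes[t] - mean_c))
            else:
                target = max(pool, key=lambda t: sizes[t])
            sums[target] += sums[c]
            sizes[target] += sizes[c]
            sizes[c] = 0
            comp[region] = target
            changed = True
        if not changed:
            break

    _, new_labels = np.unique(comp, return_inverse=True)
    new_labels = new_labels.reshape(labels.shape).astype(np.int32)
    k, centers, sizes = _summaries(new_labels)
    return SuperpixelMap(labels=new_labels, K_actual=k, centers=centers, sizes=sizes)


def _adjacent_components(comp: np.ndarray, region: np.ndarray) -> set:
    neigh: set = set()
    for shift, axis in ((1, 0), (-1, 0), (1, 1), (-1, 1)):
        shifted = np.roll(region, shift, axis=axis)
        if shift == 1:
            if axis == 0:
                shifted[0, :] = False
            else:
                shifted[:, 0] = False
        else:
            if axis == 0:
                shifted[-1, :] = False
            else:
                shifted[:, -1] = False
        neigh.update(np.unique(comp[shifted & ~region]).tolist())
    return neigh


class LSCSuperpixels(BaseEstimator):
    """Grayscale-LSC superpixel segmentation, sklearn-style.

    Parameters mirror :class:`LSCParams`. After :meth:`fit`, the attributes
    ``labels_`` (int32 label field), ``n_superpixels_``, ``centers_`` and
    ``sizes_`` describe the partition; :meth:`transform` returns the
    superpixel-averaged (schematic) image.

    Examples
    --------
    >>> sp = LSCSuperpixels(n_superpixels=16, r=0.25).fit(image)
    >>> schematic = sp.transform(image)
    """

    def __init__(self, n_superpixels: int = 2500, r: float = 0.25,
                 c_c: float = 1.0, max_iter: int = 10,
                 min_region_fraction: float = 0.05, smooth_sigma: float = 1.0,
                 seed: int = 0):
        self.n_superpixels = n_superpixels
        self.r = r
        self.c_c = c_c
        self.max_iter = max_iter
        self.min_region_fraction = min_region_fraction
        self.smooth_sigma = smooth_sigma
        self.seed = seed

    def _image_array(self, image) -> np.ndarray:
        arr = image.data if isinstance(image, GraySlice) else np.asarray(image, dtype=float)
        if arr.ndim != 2:
            raise InvalidInputError("expected a 2-D grayscale image")
        if arr.shape[0] < 32 or arr.shape[1] < 32:
            raise InvalidInputError("image must be at least 32x32")
        return arr

    def fit(self, image, y=None):
        """Segment the image into superpixels."""
        params = LSCParams(self.n_superpixels, self.r, self.c_c,
                           self.max_iter, self.min_region_fraction,
                           self.smooth_sigma, self.seed)
        arr = self._image_array(image)
        n = arr.size
        if params.n_superpixels > n // 4:
            raise InvalidInputError("n_superpixels too large for this image")
        # mild pre-smoothing raises the edge/noise ratio of the gray feature,
        # as is customary before superpixel clustering
        smoothed = (gaussian_filter(arr, params.smooth_sigma)
                    if params.smooth_sigma > 0 else arr)
        c_s = params.r * params.c_c
        e, g = _embed_image(smoothed, c_s, params.c_c)
        centers, step = _seed_centers(g, params.n_superpixels)
        labels = _kmeans_superpixels(e, centers, step, params.max_iter)
        # drop empty seed labels before connectivity cleanup
        _, labels = np.unique(labels, return_inverse=True)
        labels = labels.reshape(arr.shape).astype(np.int32)
        k, ctr, sz = _summaries(labels)
        raw = SuperpixelMap(labels=labels, K_actual=k, centers=ctr, sizes=sz)
        spmap = enforce_connectivity(raw, params.min_region_fraction,
                                     n_target=params.n_superpixels, image=arr)
        self.labels_ = spmap.labels
        self.n_superpixels_ = spmap.K_actual
        self.centers_ = spmap.centers
        self.sizes_ = spmap.sizes
        return self

    def to_map(self) -> SuperpixelMap:
        return SuperpixelMap(labels=self.labels_, K_actual=self.n_superpixels_,
                             centers=self.centers_, sizes=self.sizes_)

    def fit_predict(self, image, y=None) -> np.ndarray:
        return self.fit(image).labels_

    def transform(self, image) -> np.ndarray:
        """Superpixel-averaged image (values of :func:`schematic_map`)."""
        arr = self._image_array(image)
        if arr.shape != self.labels_.shape:
            raise InvalidInputError("image shape differs from the fitted map")
        return _average_by_label(arr, self.labels_, self.n_superpixels_)


def _average_by_label(image: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    flat = labels.ravel()
    sums = np.bincount(flat, weights=image.ravel(), minlength=k)
    counts = np.bincount(flat, minlength=k)
    means = sums / counts
    return means[labels]


def lsc_segment(image, params: LSCParams | None = None, **kwargs) -> SuperpixelMap:
    """Segment a grayscale slice into LSC superpixels (functional interface)."""
    if params is None:
        params = LSCParams(**kwargs) if kwargs else LSCParams()
    est = LSCSuperpixels(params.n_superpixels, params.r, params.c_c,
                         params.max_iter, params.min_region_fraction,
                         params.smooth_sigma, params.seed)
    est.fit(image)
    return est.to_map()


def schematic_map(image, spmap: SuperpixelMap) -> SchematicImage:
    """Replace each pixel by the mean gray value of its superpixel.

    The resulting visual summary is constant per superpixel, conserves the
    global image mean (to floating-point accuracy) and is idempotent.
    """
    arr = image.data if isinstance(image, GraySlice) else np.asarray(image, dtype=float)
    if arr.shape != spmap.labels.shape:
        raise InvalidInputError("image and superpixel map shapes must match")
    values = _average_by_label(arr, spmap.labels, spmap.K_actual)
    return SchematicImage(values=values, source_map=spmap)


# ---------------------------------------------------------------------------
# Simulated-annealing selection of the ratio r
# ---------------------------------------------------------------------------

@dataclass
class SASchedule:
    """Geometric-cooling schedule for the annealing search over r."""

    t0: float = 0.1
    cooling: float = 0.95
    steps: int = 60
    sigma_fraction: float = 0.1  # proposal s.d. as a fraction of the range


@dataclass
class RSearchResult:
    r_star: float
    i_star: float
    trace: list = field(default_factory=list)


def _objective_score(i_value: float) -> float:
    """Scalar SA objective: minimum positive I first, negatives ranked after."""
    return i_value if i_value >= 0 else 2.0 + abs(i_value)


def select_r(image, gt_mask, r_range=(0.05, 1.0),
             sa_schedule: SASchedule | None = None,
             n_superpixels: int = 2500, d: int = 2,
             max_iter: int = 10, seed: int = 0) -> RSearchResult:
    """Pick the spatial/similarity ratio r by simulated annealing.

    The objective at a candidate r is the balance index ``I = 1 - BR/CP`` of
    the LSC segmentation at that r against ``gt_mask``; the search seeks the
    minimum positive I (negative I, where BR exceeds CP, ranks after all
    positive values). Proposals are Gaussian perturbations clipped to
    ``r_range``; worse states are accepted with probability
    ``exp(-delta/T)`` under geometric cooling. Deterministic per seed.

    Returns the best r, its I, and the full trace of
    ``(step, r, I, score, best_score, accepted)`` tuples.
    """
    lo, hi = float(r_range[0]), float(r_range[1])
    if not (0 < lo < hi):
        raise InvalidInputError("r_range must satisfy 0 < lo < hi")
    sched = sa_schedule or SASchedule()
    rng = np.random.default_rng(seed)
    cache: dict[float, float] = {}

    def eval_i(r: float) -> float:
        key = round(r, 4)
        if key not in cache:
            spmap = lsc_segment(image, LSCParams(n_superpixels=n_superpixels, r=key,
                                                 max_iter=max_iter))
            br = compute_br(spmap, gt_mask, d=d)
            cp = compute_cp(spmap)
            cache[key] = balance_index(br, cp)
        return cache[key]

    r_cur = 0.5 * (lo + hi)
    i_cur = eval_i(r_cur)
    s_cur = _objective_score(i_cur)
    r_best, i_best, s_best = r_cur, i_cur, s_cur
    sigma = sched.sigma_fraction * (hi - lo)
    t = sched.t0
    trace = [(0, r_cur, i_cur, s_cur, s_best, True)]

    for step in range(1, sched.steps + 1):
        r_new = float(np.clip(r_cur + rng.normal(0.0, sigma), lo, hi))
        i_new = eval_i(r_new)
        s_new = _objective_score(i_new)
        delta = s_new - s_cur
        accept = delta <= 0 or rng.random() < math.exp(-delta / max(t, 1e-12))
        if accept:
            r_cur, i_cur, s_cur = r_new, i_new, s_new
            if s_cur < s_best:
                r_best, i_best, s_best = r_cur, i_cur, s_cur
        trace.append((step, r_new, i_new, s_new, s_best, accept))
        t *= sched.cooling

    return RSearchResult(r_star=r_best, i_star=i_best, trace=trace)


def quality_table(image, gt_mask, r_values, n_superpixels: int = 2500,
                  d: int = 2, max_iter: int = 10):
    """Quality metrics at each r (rows of K, r, UE, BR, ASA, CP, I)."""
    rows = []
    for r in r_values:
        spmap = lsc_segment(image, LSCParams(n_superpixels=n_superpixels,
                                             r=float(r), max_iter=max_iter))
        q = evaluate_map(spmap, gt_mask, d=d)
        rows.append({"K": spmap.K_actual, "r": float(r), "UE": q.UE, "BR": q.BR,
                     "ASA": q.ASA, "CP": q.CP, "I": q.I})
    return rows
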