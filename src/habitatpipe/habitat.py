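"""Tumor habitat generation: local block features + pooled K-means clustering.

Each tumor VOI is tiled with non-overlapping 3×3×3 voxel blocks (on the
isotropic 1 mm, windowed [0, 1] grid). Every block whose center voxel lies in
the tumor yields a 19-dimensional local feature vector. Blocks pooled over the
training cohort are z-scored and clustered with K-means; the number of
clusters K is chosen by maximizing the Calinski–Harabasz index over a scan
(default k = 2..10). Cluster indices are renumbered by ascending centroid
mean intensity so habitat 1..K are comparable across patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .imaging import CTVolume, RegionMask

__all__ = [
    "LOCAL_FEATURE_NAMES",
    "LocalFeatureBlock",
    "HabitatModel",
    "HabitatLabelMap",
    "compute_local_features",
    "calinski_harabasz",
    "fit_habitats",
    "assign_habitats",
]

#: The 19 per-block statistics of the 27-voxel neighbourhood, in order.
LOCAL_FEATURE_NAMES = [
    "mean", "median", "minimum", "maximum", "range", "variance", "std",
    "skewness", "kurtosis", "energy", "rms", "entropy", "uniformity",
    "mean_absolute_deviation", "p10", "p90", "iqr",
    "coefficient_of_variation", "mean_gradient_magnitude",
]

_ENTROPY_BINS = 16


@dataclass
class LocalFeatureBlock:
    block_index: tuple[int, int, int]
    center_mm: tuple[float, float, float]
    features: np.ndarray  # length 19


@dataclass
class HabitatModel:
    k: int
    centroids: np.ndarray          # (k, 19), z-space, ordered by mean intensity
    feature_mean: np.ndarray       # (19,) pooled-training statistics
    feature_sd: np.ndarray         # (19,)
    ch_scores: dict                # k -> Calinski-Harabasz score
    seed: int

    @property
    def fitted(self) -> bool:
        return self.centroids is not None and len(self.centroids) == self.k


@dataclass
class HabitatLabelMap:
    labels: np.ndarray             # 3-D int grid, 0 outside tumor
    k: int
    cluster_centroids: np.ndarray

    def proportions(self) -> np.ndarray:
        """Fraction of labeled voxels per habitat 1..k (sums to 1)."""
        counts = np.array([(self.labels == h).sum() for h in range(1, self.k + 1)],
                          dtype=float)
        total = counts.sum()
        return counts / total if total > 0 else counts

    def habitat_mask(self, h: int, spacing=(1.0, 1.0, 1.0)) -> RegionMask:
        return RegionMask(self.labels == h, spacing)


def _block_stack(arr: np.ndarray) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Reshape a 3-D array into (nbx, nby, nbz, 27) non-overlapping 3³ blocks."""
    nb = tuple(d // 3 for d in arr.shape)
    a = arr[: nb[0] * 3, : nb[1] * 3, : nb[2] * 3]
    v = (a.reshape(nb[0], 3, nb[1], 3, nb[2], 3)
          .transpose(0, 2, 4, 1, 3, 5)
          .reshape(*nb, 27))
    return v, nb


def _block_features(vals: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """19 statistics per row of a (n, 27) neighbourhood value matrix."""
    n = vals.shape[0]
    out = np.empty((n, 19))
    mean = vals.mean(axis=1)
    out[:, 0] = mean
    out[:, 1] = np.median(vals, axis=1)
    out[:, 2] = vals.min(axis=1)
    out[:, 3] = vals.max(axis=1)
    out[:, 4] = out[:, 3] - out[:, 2]
    centered = vals - mean[:, None]
    m2 = (centered ** 2).mean(axis=1)
    m3 = (centered ** 3).mean(axis=1)
    m4 = (centered ** 4).mean(axis=1)
    out[:, 5] = m2
    sd = np.sqrt(m2)
    out[:, 6] = sd
    safe = m2 > 1e-24
    out[:, 7] = np.where(safe, m3 / np.where(safe, m2, 1.0) ** 1.5, 0.0)
    out[:, 8] = np.where(safe, m4 / np.where(safe, m2, 1.0) ** 2 - 3.0, 0.0)
    out[:, 9] = (vals ** 2).sum(axis=1)
    out[:, 10] = np.sqrt((vals ** 2).mean(axis=1))
    # histogram entropy / uniformity on the fixed windowed [0, 1] range
    bins = np.clip((vals * _ENTROPY_BINS).astype(np.int64), 0, _ENTROPY_BINS - 1)
    codes = (np.arange(n)[:, None] * _ENTROPY_BINS + bins).ravel()
    counts = np.bincount(codes, minlength=n * _ENTROPY_BINS).reshape(n, _ENTROPY_BINS)
    p = counts / 27.0
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    out[:, 11] = -(p * logp).sum(axis=1)
    out[:, 12] = (p ** 2).sum(axis=1)
    out[:, 13] = np.abs(centered).mean(axis=1)
    out[:, 14] = np.percentile(vals, 10, axis=1)
    out[:, 15] = np.percentile(vals, 90, axis=1)
    out[:, 16] = np.percentile(vals, 75, axis=1) - np.percentile(vals, 25, axis=1)
    out[:, 17] = np.where(np.abs(mean) > 1e-12, sd / np.where(np.abs(mean) > 1e-12, mean, 1.0), 0.0)
    out[:, 18] = grad.mean(axis=1)
    return out


def compute_local_features(v: CTVolume, tumor: RegionMask) -> list[LocalFeatureBlock]:
    """One 19-vector per non-overlapping 3³ block whose center voxel is tumor.

    Neighbourhood voxels outside the tumor are included as-is (the window is
    image-defined). Expects the windowed, isotropic volume.
    """
    if v.shape != tumor.shape:
        raise ValueError("volume and tumor mask must share a grid")
    gx, gy, gz = np.gradient(v.voxels.astype(np.float64), *v.spacing)
    gmag = np.sqrt(gx ** 2 + gy ** 2 + gz ** 2)

    blocks, nb = _block_stack(v.voxels.astype(np.float64))
    gblocks, _ = _block_stack(gmag)
    centers = tumor.voxels[1: nb[0] * 3: 3, 1: nb[1] * 3: 3, 1: nb[2] * 3: 3]
    idx = np.argwhere(centers)
    if len(idx) == 0:
        raise ValueError("tumor too small: no 3x3x3 block center falls inside it")
    vals = blocks[centers]
    grads = gblocks[centers]
    feats = _block_features(vals, grads)
    out = []
    for row, f in zip(idx, feats):
        center_vox = row * 3 + 1
        center_mm = tuple(float(c * s + o) for c, s, o
                          in zip(center_vox, v.spacing, v.origin))
        out.append(LocalFeatureBlock(tuple(int(x) for x in row), center_mm, f))
    return out


def features_matrix(blocks: list[LocalFeatureBlock]) -> np.ndarray:
    return np.array([b.features for b in blocks])


def calinski_harabasz(points: np.ndarray, labels: np.ndarray, k: int) -> float:
    """CH = [B/(k−1)] / [W/(N−k)]; returns +inf when W = 0 (duplicated points).

    B is the between-cluster dispersion Σⱼ nⱼ‖cⱼ−c̄‖² and W the pooled
    within-cluster dispersion.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    n = len(points)
    if not (n > k >= 2):
        raise ValueError(f"need N > k >= 2, got N={n}, k={k}")
    uniq = np.unique(labels)
    if len(uniq) != k:
        raise ValueError(f"expected {k} nonempty clusters, found {len(uniq)}")
    grand = points.mean(axis=0)
    b = 0.0
    w = 0.0
    for lab in uniq:
        cluster = points[labels == lab]
        c = cluster.mean(axis=0)
        b += len(cluster) * float(((c - grand) ** 2).sum())
        w += float(((cluster - c) ** 2).sum())
    if w <= 0.0:
        return float("inf")
    return (b / (k - 1)) / (w / (n - k))


def _pool_and_sort(blocks_all) -> np.ndarray:
    """Pool block features over patients in a canonical (sorted) row order.

    Sorting makes the K-means fit independent of patient ordering.
    """
    if blocks_all and isinstance(blocks_all[0], LocalFeatureBlock):
        mats = [features_matrix(blocks_all)]
    else:
        mats = [features_matrix(b) for b in blocks_all if len(b)]
    pool = np.vstack(mats)
    order = np.lexsort(pool.T[::-1])
    return pool[order]


def fit_habitats(blocks_all_patients, k_range=range(2, 11), seed: int = 0):
    """Fit the pooled habitat model; returns ``(k_star, HabitatModel)``.

    ``blocks_all_patients`` is either a flat block list or a per-patient list
    of block lists (training cohort). For each k, K-means runs with k-means++
    init, 10 restarts and tolerance 1e-4; k* maximizes the CH index (ties go
    to the smaller k). Habitat indices are ordered by ascending centroid mean
    intensity.
    """
    pool = _pool_and_sort(blocks_all_patients)
    n = len(pool)
    mean = pool.mean(axis=0)
    sd = pool.std(axis=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    z = (pool - mean) / sd

    ks = sorted(set(int(k) for k in k_range))
    valid = [k for k in ks if 2 <= k <= n - 1]
    if valid != ks:
        warnings.warn(f"k_range clipped to [2, {n - 1}]: using {valid}")
    if not valid:
        raise ValueError("no admissible k in k_range")

    ch_scores: dict[int, float] = {}
    models: dict[int, KMeans] = {}
    for k in valid:
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, tol=1e-4,
                    random_state=seed)
        km.fit(z)
        ch_scores[k] = calinski_harabasz(z, km.labels_, k)
        models[k] = km
    k_star = max(valid, key=lambda k: (ch_scores[k], -k))
    centroids = models[k_star].cluster_centers_
    order = np.argsort(centroids[:, 0], kind="stable")  # ascending mean intensity
    model = HabitatModel(k=k_star, centroids=centroids[order].copy(),
                         feature_mean=mean, feature_sd=sd,
                         ch_scores=ch_scores, seed=seed)
    return k_star, model


def assign_habitats(model: HabitatModel, blocks: list[LocalFeatureBlock],
                    tumor: RegionMask) -> HabitatLabelMap:
    """Label a patient's tumor voxels with nearest-centroid habitat indices.

    All 27 voxels of a block inherit the block's label (then clipped to the
    tumor mask, so labels are nonzero exactly on tumor voxels covered by
    blocks). Distance ties resolve to the lowest habitat index.
    """
    if not model.fitted:
        raise ValueError("habitat model is not fitted")
    labels = np.zeros(tumor.shape, dtype=np.int16)
    if not blocks:
        return HabitatLabelMap(labels, model.k, model.centroids)
    z = (features_matrix(blocks) - model.feature_mean) / model.feature_sd
    d2 = ((z[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1) + 1  # argmin takes the lowest index on ties
    for block, lab in zip(blocks, assign):
        i, j, k = block.block_index
        labels[3 * i: 3 * i + 3, 3 * j: 3 * j + 3, 3 * k: 3 * k + 3] = lab
    labels[~tumor.voxels] = 0
    return HabitatLabelMap(labels, model.k, model.centroids)
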