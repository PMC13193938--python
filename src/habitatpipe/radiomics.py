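"""IBSI-aligned radiomics feature extraction for (volume, ROI) pairs.

The catalogue covers the standard feature classes: 14 shape descriptors plus
93 intensity/texture features — first-order (18), GLCM (24), GLRLM (16),
GLSZM (16), GLDM (14) and NGTDM (5) — computed on the original image and,
when enabled, on 8 one-level stationary-wavelet sub-bands (Coiflet-1,
LLL..HHH) and a sign-preserving logarithm transform: 14 + 93 × 10 = 944
features per ROI in the full configuration.

Gray levels are discretized with a fixed bin width of 0.025 on the windowed
[0, 1] scale (≈ 5 HU under the standard liver window) for the original and
logarithm images; wavelet sub-bands, whose intensity range is not anchored,
use a fixed 40-bin discretization over the ROI range. Texture matrices use a
voxel distance of 1 with the 13 unique 3-D directions; GLCM and GLRLM
features are averaged over directions.

Feature tables are plain pandas DataFrames (patients × named features); the
z-score normalizer stores training statistics so validation/test cohorts are
transformed without touching their data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage import measure

from .imaging import CTVolume, RegionMask

__all__ = [
    "RadiomicsConfig",
    "extract_features",
    "feature_names",
    "zscore_fit_apply",
]

# 13 unique 3-D directions (first nonzero component positive)
OFFSETS_13 = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]
OFFSETS_26 = [(dx, dy, dz)
              for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
              if (dx, dy, dz) != (0, 0, 0)]


@dataclass
class RadiomicsConfig:
    bin_width: float = 0.025          # original / logarithm images
    wavelet_bins: int = 40            # fixed-count fallback for unanchored ranges
    use_wavelet: bool = True
    use_logarithm: bool = True
    min_roi_voxels: int = 27
    max_gray_levels: int = 128

    @property
    def filters(self) -> list[str]:
        names = ["original"]
        if self.use_wavelet:
            names += [f"wavelet_{b}" for b in _WAVELET_BANDS]
        if self.use_logarithm:
            names.append("logarithm")
        return names


_WAVELET_BANDS = ["LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH"]

SHAPE_NAMES = [
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Compactness", "EquivalentSphericalDiameter",
    "Maximum3DDiameter", "MajorAxisLength", "MinorAxisLength",
    "LeastAxisLength", "Elongation", "Flatness", "Extent",
]
FIRSTORDER_NAMES = [
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
]
GLCM_NAMES = [
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC",
]
GLRLM_NAMES = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]
GLSZM_NAMES = [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]
GLDM_NAMES = [
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
]
NGTDM_NAMES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]

_CLASSES = [
    ("firstorder", FIRSTORDER_NAMES), ("glcm", GLCM_NAMES),
    ("glrlm", GLRLM_NAMES), ("glszm", GLSZM_NAMES), ("gldm", GLDM_NAMES),
    ("ngtdm", NGTDM_NAMES),
]


def feature_names(config: RadiomicsConfig) -> list[str]:
    """Ordered feature names for the active configuration."""
    names = [f"original_shape_{n}" for n in SHAPE_NAMES]
    for filt in config.filters:
        for cls, cls_names in _CLASSES:
            names += [f"{filt}_{cls}_{n}" for n in cls_names]
    return names


# --------------------------------------------------------------------------
# discretization and filters

def discretize(values: np.ndarray, bin_width: float | None = None,
               n_bins: int | None = None, max_levels: int = 128):
    """Map intensities to integer gray levels 1..Ng (ROI-min anchored)."""
    vmin = float(values.min())
    vmax = float(values.max())
    if vmax <= vmin:
        return np.ones_like(values, dtype=np.int64), 1
    if bin_width is not None:
        levels = np.floor((values - vmin) / bin_width).astype(np.int64) + 1
        ng = int(levels.max())
        if ng > max_levels:  # extreme dynamic range: fall back to fixed count
            return discretize(values, n_bins=max_levels)
    else:
        width = (vmax - vmin) / n_bins
        levels = np.minimum(np.floor((values - vmin) / width).astype(np.int64),
                            n_bins - 1) + 1
        ng = int(levels.max())
    return levels, ng


def wavelet_subbands(vol: np.ndarray) -> dict[str, np.ndarray]:
    """One-level stationary 3-D Coiflet-1 sub-bands at the original grid size."""
    pads = [(0, s % 2) for s in vol.shape]
    padded = np.pad(vol, pads, mode="edge")
    coeffs = pywt.swtn(padded, "coif1", level=1)[0]
    out = {}
    for key, arr in coeffs.items():
        band = "".join("L" if c == "a" else "H" for c in key)
        out[band] = arr[: vol.shape[0], : vol.shape[1], : vol.shape[2]]
    return out


def logarithm_image(vol: np.ndarray) -> np.ndarray:
    """Sign-preserving log(|x|+1), rescaled back to the input magnitude range."""
    y = np.sign(vol) * np.log(np.abs(vol) + 1.0)
    max_in = np.abs(vol).max()
    max_out = np.abs(y).max()
    if max_out > 0:
        y = y * (max_in / max_out)
    return y


# --------------------------------------------------------------------------
# shape

def shape_features(roi: RegionMask) -> dict[str, float]:
    mask = roi.voxels
    spacing = np.asarray(roi.spacing)
    nvox = int(mask.sum())
    voxvol = float(nvox * spacing.prod())

    # anti-alias the binary mask before meshing: suppresses the staircase
    # bias of marching cubes on voxelized surfaces (area error ~±2%)
    padded = ndimage.gaussian_filter(np.pad(mask.astype(np.float64), 2), 0.8)
    if padded.max() <= 0.5:  # tiny ROI smoothed below the iso level
        padded = np.pad(mask.astype(np.float64), 2)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=tuple(spacing))
    area = float(measure.mesh_surface_area(verts, faces))
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    mesh_vol = float(abs(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum()) / 6.0)

    coords = np.argwhere(mask) * spacing
    if len(coords) >= 5 and np.ptp(coords, axis=0).min() > 0:
        try:
            hull = ConvexHull(coords)
            hp = coords[hull.vertices]
        except Exception:
            hp = coords
    else:
        hp = coords
    d2 = ((hp[:, None, :] - hp[None, :, :]) ** 2).sum(axis=2)
    max_diam = float(np.sqrt(d2.max()))

    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1].clip(0)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    elong = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
    flat = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0

    bbox = np.ptp(np.argwhere(mask), axis=0) + 1
    extent = nvox / float(np.prod(bbox))
    sphericity = (36.0 * np.pi * mesh_vol ** 2) ** (1.0 / 3.0) / area if area > 0 else 0.0
    vals = [
        mesh_vol, voxvol, area, area / mesh_vol if mesh_vol > 0 else 0.0,
        sphericity, 36.0 * np.pi * mesh_vol ** 2 / area ** 3 if area > 0 else 0.0,
        2.0 * (3.0 * mesh_vol / (4.0 * np.pi)) ** (1.0 / 3.0),
        max_diam, major, minor, least, elong, flat, extent,
    ]
    return {f"original_shape_{n}": float(v) for n, v in zip(SHAPE_NAMES, vals)}


# --------------------------------------------------------------------------
# first order

def _xlog2(p: np.ndarray) -> np.ndarray:
    return np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)


def firstorder_features(values: np.ndarray, levels: np.ndarray, ng: int,
                        voxel_volume: float) -> list[float]:
    x = values.astype(np.float64)
    n = x.size
    mean = x.mean()
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    m2 = ((x - mean) ** 2).mean()
    sd = np.sqrt(m2)
    skew = ((x - mean) ** 3).mean() / sd ** 3 if sd > 1e-15 else 0.0
    kurt = ((x - mean) ** 4).mean() / m2 ** 2 if m2 > 1e-30 else 0.0
    robust = x[(x >= p10) & (x <= p90)]
    rmad = np.abs(robust - robust.mean()).mean() if robust.size else 0.0
    p = np.bincount(levels, minlength=ng + 1)[1:] / n
    entropy = float(-_xlog2(p).sum())
    energy = float((x ** 2).sum())
    return [
        energy, energy * voxel_volume, entropy, float(x.min()), float(p10),
        float(p90), float(x.max()), float(mean), float(p50), float(p75 - p25),
        float(x.max() - x.min()), float(np.abs(x - mean).mean()), float(rmad),
        float(np.sqrt((x ** 2).mean())), float(skew), float(kurt), float(m2),
        float((p ** 2).sum()),
    ]


# --------------------------------------------------------------------------
# texture matrices

def _offset_slices(shape, d):
    sa, sb = [], []
    for n, dd in zip(shape, d):
        if dd >= 0:
            sa.append(slice(0, n - dd))
            sb.append(slice(dd, n))
        else:
            sa.append(slice(-dd, n))
            sb.append(slice(0, n + dd))
    return tuple(sa), tuple(sb)


def glcm_matrices(g: np.ndarray, ng: int) -> list[np.ndarray]:
    """Symmetric co-occurrence count matrices for the 13 directions.

    ``g`` has gray levels 1..Ng inside the ROI and 0 outside.
    """
    mats = []
    for d in OFFSETS_13:
        sa, sb = _offset_slices(g.shape, d)
        g1, g2 = g[sa].ravel(), g[sb].ravel()
        valid = (g1 > 0) & (g2 > 0)
        codes = (g1[valid] - 1) * ng + (g2[valid] - 1)
        m = np.bincount(codes, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
        mats.append(m + m.T)
    return mats


def _glcm_features_single(m: np.ndarray) -> list[float]:
    total = m.sum()
    if total == 0:
        return [0.0] * len(GLCM_NAMES)
    p = m / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float((i * px).sum())
    muy = float((i * py).sum())
    sigx = np.sqrt(float(((i - mux) ** 2 * px).sum()))
    sigy = np.sqrt(float(((i - muy) ** 2 * py).sum()))

    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[ii + jj == k].sum() for k in k_sum])
    k_diff = np.arange(0, ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])

    autocorr = float((ii * jj * p).sum())
    contrast = float((((ii - jj) ** 2) * p).sum())
    corr = (autocorr - mux * muy) / (sigx * sigy) if sigx * sigy > 1e-15 else 1.0
    da = float((k_diff * p_diff).sum())
    dent = float(-_xlog2(p_diff).sum())
    dvar = float((((k_diff - da) ** 2) * p_diff).sum())
    jener = float((p ** 2).sum())
    jent = float(-_xlog2(p).sum())
    hx = float(-_xlog2(px).sum())
    hy = float(-_xlog2(py).sum())
    pxy = np.outer(px, py)
    with np.errstate(divide="ignore"):
        logpxy = np.where(pxy > 0, np.log2(np.where(pxy > 0, pxy, 1.0)), 0.0)
    hxy1 = float(-(p * logpxy).sum())
    hxy2 = float(-_xlog2(pxy).sum())
    imc1 = (jent - hxy1) / max(hx, hy) if max(hx, hy) > 1e-15 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - jent)))))
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    idmn = float((p / (1.0 + ((ii - jj) / ng) ** 2)).sum())
    idf = float((p / (1.0 + np.abs(ii - jj))).sum())
    idn = float((p / (1.0 + np.abs(ii - jj) / ng)).sum())
    off = ii != jj
    invvar = float((p[off] / (ii[off] - jj[off]) ** 2).sum())
    maxp = float(p.max())
    sav = float((k_sum * p_sum).sum())
    sent = float(-_xlog2(p_sum).sum())
    ssq = float((((ii - mux) ** 2) * p).sum())
    # MCC via the second-largest eigenvalue of Q
    nz = (px > 0)
    if nz.sum() < 2:
        mcc = 1.0
    else:
        psub = p[np.ix_(nz, nz)]
        pxs, pys = px[nz], py[nz]
        q = (psub / pxs[:, None]) @ (psub / pys[:, None]).T
        ev = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, ev[-2]))) if len(ev) >= 2 else 1.0
    cpro = float((((ii + jj - mux - muy) ** 4) * p).sum())
    cshade = float((((ii + jj - mux - muy) ** 3) * p).sum())
    ctend = float((((ii + jj - mux - muy) ** 2) * p).sum())
    return [autocorr, mux, cpro, cshade, ctend, contrast, corr, da, dent,
            dvar, jener, jent, imc1, imc2, idm, idmn, idf, idn, invvar, maxp,
            sav, sent, ssq, mcc]


def glcm_features(g: np.ndarray, ng: int) -> list[float]:
    feats = np.array([_glcm_features_single(m) for m in glcm_matrices(g, ng)])
    return feats.mean(axis=0).tolist()


def glrlm_matrix(g: np.ndarray, ng: int, d) -> np.ndarray:
    """Run-length count matrix P(level, length) for one direction."""
    shape = g.shape
    dn = np.array(d)
    # run starts: in ROI and the previous voxel along d differs / is outside
    sa, sb = _offset_slices(shape, tuple(-x for x in dn))
    starts = g > 0
    same_prev = np.zeros(shape, dtype=bool)
    same_prev[sa] = (g[sa] > 0) & (g[sa] == g[sb])
    starts &= ~same_prev

    coords = np.argwhere(starts)
    if len(coords) == 0:
        return np.zeros((ng, 1))
    levels = g[starts]
    run_len = np.ones(len(coords), dtype=np.int64)
    idx = np.arange(len(coords))
    cur = coords
    cur_idx = idx
    while len(cur):
        nxt = cur + dn
        ok = np.all((nxt >= 0) & (nxt < np.array(shape)), axis=1)
        if not ok.any():
            break
        nxt_ok = nxt[ok]
        same = g[tuple(nxt_ok.T)] == levels[cur_idx[ok]]
        keep = cur_idx[ok][same]
        if len(keep) == 0:
            break
        run_len[keep] += 1
        cur = nxt_ok[same]
        cur_idx = keep
    lmax = int(run_len.max())
    mat = np.zeros((ng, lmax))
    np.add.at(mat, (levels - 1, run_len - 1), 1.0)
    return mat


def _rl_features(mat: np.ndarray, n_voxels: int) -> list[float]:
    """The 16 run-length-style features shared by GLRLM and GLSZM."""
    nr = mat.sum()
    if nr == 0:
        return [0.0] * 16
    ng, lmax = mat.shape
    i = np.arange(1, ng + 1)[:, None].astype(float)
    l = np.arange(1, lmax + 1)[None, :].astype(float)
    p = mat / nr
    mu_i = float((i * p).sum())
    mu_l = float((l * p).sum())
    return [
        float((mat / l ** 2).sum() / nr),
        float((mat * l ** 2).sum() / nr),
        float((mat.sum(axis=1) ** 2).sum() / nr),
        float((mat.sum(axis=1) ** 2).sum() / nr ** 2),
        float((mat.sum(axis=0) ** 2).sum() / nr),
        float((mat.sum(axis=0) ** 2).sum() / nr ** 2),
        float(nr / n_voxels),
        float((((i - mu_i) ** 2) * p).sum()),
        float((((l - mu_l) ** 2) * p).sum()),
        float(-_xlog2(p).sum()),
        float((mat / i ** 2).sum() / nr),
        float((mat * i ** 2).sum() / nr),
        float((mat / (i ** 2 * l ** 2)).sum() / nr),
        float((mat * i ** 2 / l ** 2).sum() / nr),
        float((mat * l ** 2 / i ** 2).sum() / nr),
        float((mat * i ** 2 * l ** 2).sum() / nr),
    ]


def glrlm_features(g: np.ndarray, ng: int, n_voxels: int) -> list[float]:
    feats = np.array([_rl_features(glrlm_matrix(g, ng, d), n_voxels)
                      for d in OFFSETS_13])
    return feats.mean(axis=0).tolist()


def glszm_features(g: np.ndarray, ng: int, n_voxels: int) -> list[float]:
    structure = np.ones((3, 3, 3), dtype=int)
    zones: dict[tuple[int, int], int] = {}
    smax = 1
    for lvl in range(1, ng + 1):
        binary = g == lvl
        if not binary.any():
            continue
        lab, nlab = ndimage.label(binary, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            zones[(lvl, int(s))] = zones.get((lvl, int(s)), 0) + 1
            smax = max(smax, int(s))
    mat = np.zeros((ng, smax))
    for (lvl, s), c in zones.items():
        mat[lvl - 1, s - 1] = c
    return _rl_features(mat, n_voxels)


def gldm_features(g: np.ndarray, ng: int) -> list[float]:
    roi = g > 0
    dep = np.zeros(g.shape, dtype=np.int64)
    for d in OFFSETS_26:
        sa, sb = _offset_slices(g.shape, d)
        same = np.zeros(g.shape, dtype=np.int64)
        same[sa] = ((g[sa] == g[sb]) & (g[sb] > 0)).astype(np.int64)
        dep += same
    dep[~roi] = 0
    dmax = int(dep[roi].max()) + 1
    mat = np.zeros((ng, dmax + 1))
    np.add.at(mat, (g[roi] - 1, dep[roi]), 1.0)

    nz = mat.sum()
    ngl, nd = mat.shape
    i = np.arange(1, ngl + 1)[:, None].astype(float)
    j = np.arange(1, nd + 1)[None, :].astype(float)  # dependence = k + 1
    p = mat / nz
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    return [
        float((mat / j ** 2).sum() / nz),
        float((mat * j ** 2).sum() / nz),
        float((mat.sum(axis=1) ** 2).sum() / nz),
        float((mat.sum(axis=0) ** 2).sum() / nz),
        float((mat.sum(axis=0) ** 2).sum() / nz ** 2),
        float((((i - mu_i) ** 2) * p).sum()),
        float((((j - mu_j) ** 2) * p).sum()),
        float(-_xlog2(p).sum()),
        float((mat / i ** 2).sum() / nz),
        float((mat * i ** 2).sum() / nz),
        float((mat / (i ** 2 * j ** 2)).sum() / nz),
        float((mat * i ** 2 / j ** 2).sum() / nz),
        float((mat * j ** 2 / i ** 2).sum() / nz),
        float((mat * i ** 2 * j ** 2).sum() / nz),
    ]


def ngtdm_features(g: np.ndarray, ng: int) -> list[float]:
    roi = g > 0
    kernel = np.ones((3, 3, 3))
    kernel[1, 1, 1] = 0
    s_sum = ndimage.correlate(np.where(roi, g, 0).astype(np.float64), kernel,
                              mode="constant")
    c_sum = ndimage.correlate(roi.astype(np.float64), kernel, mode="constant")
    valid = roi & (c_sum > 0)
    avg = np.zeros(g.shape)
    avg[valid] = s_sum[valid] / c_sum[valid]
    diffs = np.abs(g[valid] - avg[valid])
    lv = g[valid]
    n_i = np.bincount(lv - 1, minlength=ng).astype(float)
    s_i = np.bincount(lv - 1, weights=diffs, minlength=ng)
    nvp = n_i.sum()
    if nvp == 0:
        return [0.0] * 5
    p_i = n_i / nvp
    present = p_i > 0
    ngp = int(present.sum())
    i = np.arange(1, ng + 1).astype(float)

    denom = float((p_i * s_i).sum())
    coarseness = 1.0 / denom if denom > 1e-12 else 1e6
    if ngp <= 1:
        contrast = 0.0
        busyness = 0.0
        strength = 0.0
    else:
        pij = np.outer(p_i, p_i)
        dij2 = (i[:, None] - i[None, :]) ** 2
        contrast = float((pij * dij2).sum() / (ngp * (ngp - 1)) * s_i.sum() / nvp)
        ipim = np.abs((i * p_i)[present][:, None] - (i * p_i)[present][None, :])
        bden = float(ipim.sum())
        busyness = denom / bden if bden > 1e-12 else 0.0
        s_tot = float(s_i.sum())
        psum = (p_i[present][:, None] + p_i[present][None, :])
        dsub2 = (i[present][:, None] - i[present][None, :]) ** 2
        strength = float((psum * dsub2).sum() / s_tot) if s_tot > 1e-12 else 0.0
    # complexity
    if ngp <= 1:
        complexity = 0.0
    else:
        pi_s = p_i[present]
        si_s = s_i[present]
        ii = i[present]
        num = (np.abs(ii[:, None] - ii[None, :])
               * (pi_s[:, None] * si_s[:, None] + pi_s[None, :] * si_s[None, :])
               / (pi_s[:, None] + pi_s[None, :]))
        complexity = float(num.sum() / nvp)
    return [float(coarseness), contrast, busyness, complexity, float(strength)]


# --------------------------------------------------------------------------
# driver

def _texture_block(vol: np.ndarray, roi_mask: np.ndarray, config: RadiomicsConfig,
                   anchored: bool) -> list[float]:
    """93 intensity/texture features for one (possibly filtered) image."""
    values = vol[roi_mask]
    if anchored:
        levels_flat, ng = discretize(values, bin_width=config.bin_width,
                                     max_levels=config.max_gray_levels)
    else:
        levels_flat, ng = discretize(values, n_bins=config.wavelet_bins)
    g = np.zeros(vol.shape, dtype=np.int64)
    g[roi_mask] = levels_flat
    nvox = int(roi_mask.sum())
    voxel_volume = 1.0  # isotropic 1 mm grid; mm^3 per voxel
    out = firstorder_features(values, levels_flat, ng, voxel_volume)
    out += glcm_features(g, ng)
    out += glrlm_features(g, ng, nvox)
    out += glszm_features(g, ng, nvox)
    out += gldm_features(g, ng)
    out += ngtdm_features(g, ng)
    return out


def extract_features(v: CTVolume, roi: RegionMask,
                     config: RadiomicsConfig | None = None) -> dict[str, float]:
    """Full named feature vector for one (windowed volume, ROI) pair.

    ROIs below ``config.min_roi_voxels`` yield NaN sentinels (with a warning)
    so the patient can be dropped downstream rather than silently skewing the
    table. The bounding box around the ROI (padded by one voxel) is cropped
    first; all features are translation invariant by construction.
    """
    config = config or RadiomicsConfig()
    names = feature_names(config)
    if roi.count() < config.min_roi_voxels:
        warnings.warn(f"ROI has {roi.count()} voxels (< {config.min_roi_voxels}); "
                      "emitting NaN sentinels")
        return {n: float("nan") for n in names}
    if v.shape != roi.shape:
        raise ValueError("volume and ROI must share a grid")

    out = shape_features(roi)

    # crop to the ROI bounding box (+1 voxel margin keeps filters local)
    idx = np.argwhere(roi.voxels)
    lo = np.maximum(idx.min(axis=0) - 1, 0)
    hi = np.minimum(idx.max(axis=0) + 2, roi.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    vol = v.voxels[sl].astype(np.float64)
    mask = roi.voxels[sl]

    images: list[tuple[str, np.ndarray, bool]] = [("original", vol, True)]
    if config.use_wavelet:
        for band, arr in wavelet_subbands(vol).items():
            images.append((f"wavelet_{band}", arr, False))
    if config.use_logarithm:
        images.append(("logarithm", logarithm_image(vol), True))

    for filt, img, anchored in images:
        vals = _texture_block(img, mask, config, anchored)
        for (cls, cls_names), seg in zip(_CLASSES, _split(vals)):
            for n, val in zip(cls_names, seg):
                out[f"{filt}_{cls}_{n}"] = float(val)
    return {n: out[n] for n in names}


def _split(vals: list[float]):
    sizes = [len(FIRSTORDER_NAMES), len(GLCM_NAMES), len(GLRLM_NAMES),
             len(GLSZM_NAMES), len(GLDM_NAMES), len(NGTDM_NAMES)]
    pos = 0
    for s in sizes:
        yield vals[pos: pos + s]
        pos += s


# --------------------------------------------------------------------------
# normalization

def zscore_fit_apply(train: pd.DataFrame, *others: pd.DataFrame):
    """Z-score features with training statistics (population SD, ddof=0).

    Zero-variance training columns are dropped from every cohort and listed
    in the returned stats. Returns ``(train_z, [others_z...], stats)`` where
    ``stats`` has keys ``mean``, ``sd`` (pandas Series) and ``dropped``.
    """
    if len(train) < 2:
        raise ValueError("need at least 2 training patients to fit z-scores")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    dropped = sd.index[(sd <= 1e-12) | ~np.isfinite(sd)].tolist()
    keep = [c for c in train.columns if c not in dropped]
    mean, sd = mean[keep], sd[keep]
    train_z = (train[keep] - mean) / sd
    others_z = [(o[keep] - mean) / sd for o in others]
    stats = {"mean": mean, "sd": sd, "dropped": dropped}
    return train_z, others_z, stats
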