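"""Histogram, texture and shape feature formulas.

The default histogram/texture registry has 93 formulas:

* 23 first-order (histogram) statistics of the in-mask intensity sample,
* 24 grey-level co-occurrence matrix (GLCM) formulas,
* 16 grey-level run length matrix (GLRLM) formulas,
* 16 grey-level size zone matrix (GLSZM) formulas,
* 14 grey-level dependence matrix (GLDM) formulas.

A separate 12-formula shape set describes region geometry (volume, surface
area, sphericity, axis lengths, ...); evaluated on all five tumor regions it
yields 60 shape features, kept outside the histogram/texture feature space.

Conventions (documented because several are genuinely free choices):
percentiles use linear interpolation; kurtosis is excess kurtosis (normal
sample -> 0); degenerate samples (zero variance) impute 0 for undefined
moments and ratios; grey-level and run/zone/dependence indices are 1-based
inside weighted sums.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from . import texture
from .texture import GLCM, compute_glcm

logger = logging.getLogger(__name__)

__all__ = [
    "HISTOGRAM_FORMULAS",
    "GLCM_FORMULAS",
    "GLRLM_FORMULAS",
    "GLSZM_FORMULAS",
    "GLDM_FORMULAS",
    "DEFAULT_FORMULA_NAMES",
    "FORMULA_CATEGORIES",
    "SHAPE_FORMULAS",
    "histogram_features",
    "compute_glcm",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "shape_features",
    "voi_features",
]

HISTOGRAM_FORMULAS: tuple[str, ...] = (
    "mean", "median", "variance", "stddev", "skewness", "kurtosis",
    "energy", "entropy", "minimum", "maximum", "range",
    "p5", "p10", "p25", "p75", "p90", "p95", "iqr",
    "mean_abs_dev", "robust_mean_abs_dev", "rms", "uniformity", "cv",
)

GLCM_FORMULAS: tuple[str, ...] = (
    "glcm_contrast", "glcm_dissimilarity", "glcm_idm", "glcm_id", "glcm_idmn",
    "glcm_idn", "glcm_joint_energy", "glcm_correlation", "glcm_autocorrelation",
    "glcm_cluster_shade", "glcm_cluster_prominence", "glcm_cluster_tendency",
    "glcm_joint_entropy", "glcm_joint_average", "glcm_joint_variance",
    "glcm_sum_average", "glcm_sum_entropy", "glcm_sum_variance",
    "glcm_difference_average", "glcm_difference_entropy", "glcm_difference_variance",
    "glcm_imc1", "glcm_imc2", "glcm_max_probability",
)

GLRLM_FORMULAS: tuple[str, ...] = tuple(
    "glrlm_" + n for n in (
        "sre", "lre", "gln", "glnn", "rln", "rlnn", "rp", "glv", "rv", "re",
        "lglre", "hglre", "srlgle", "srhgle", "lrlgle", "lrhgle",
    )
)

GLSZM_FORMULAS: tuple[str, ...] = tuple(
    "glszm_" + n for n in (
        "sae", "lae", "gln", "glnn", "szn", "sznn", "zp", "glv", "zv", "ze",
        "lglze", "hglze", "salgle", "sahgle", "lalgle", "lahgle",
    )
)

GLDM_FORMULAS: tuple[str, ...] = tuple(
    "gldm_" + n for n in (
        "sde", "lde", "gln", "dn", "dnn", "glv", "dv", "de",
        "lgle", "hgle", "sdlgle", "sdhgle", "ldlgle", "ldhgle",
    )
)

DEFAULT_FORMULA_NAMES: tuple[str, ...] = (
    HISTOGRAM_FORMULAS + GLCM_FORMULAS + GLRLM_FORMULAS + GLSZM_FORMULAS + GLDM_FORMULAS
)
assert len(DEFAULT_FORMULA_NAMES) == 93

FORMULA_CATEGORIES: dict[str, str] = {}
for _n in HISTOGRAM_FORMULAS:
    FORMULA_CATEGORIES[_n] = "histogram"
for _n in GLCM_FORMULAS:
    FORMULA_CATEGORIES[_n] = "glcm"
for _n in GLRLM_FORMULAS:
    FORMULA_CATEGORIES[_n] = "glrlm"
for _n in GLSZM_FORMULAS:
    FORMULA_CATEGORIES[_n] = "glszm"
for _n in GLDM_FORMULAS:
    FORMULA_CATEGORIES[_n] = "gldm"

SHAPE_FORMULAS: tuple[str, ...] = (
    "volume", "surface_area", "surface_volume_ratio", "sphericity", "compactness",
    "spherical_disproportion", "major_axis_length", "minor_axis_length",
    "least_axis_length", "elongation", "flatness", "max_3d_diameter",
)


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


# ---------------------------------------------------------------------------
# First-order statistics
# ---------------------------------------------------------------------------

def histogram_features(values: np.ndarray, bins: int = 32) -> dict[str, float]:
    """First-order statistics of a 1D intensity sample.

    Entropy and uniformity are computed from an equal-width ``bins``-bin
    histogram over the sample range (base-2 entropy).  Zero-variance samples
    impute 0 for skewness, kurtosis and the coefficient of variation.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("histogram features need a non-empty sample")
    mean = float(values.mean())
    var = float(values.var())
    std = float(np.sqrt(var))
    if var > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            skew = float(stats.skew(values))
            kurt = float(stats.kurtosis(values))  # excess kurtosis
    else:
        skew = 0.0
        kurt = 0.0
    p5, p10, p25, p50, p75, p90, p95 = np.percentile(values, [5, 10, 25, 50, 75, 90, 95])
    hist, _ = np.histogram(values, bins=bins)
    p = hist / values.size
    p = p[p > 0]
    entropy = float(-(p * np.log2(p)).sum())
    in_robust = values[(values >= p10) & (values <= p90)]
    return {
        "mean": mean,
        "median": float(p50),
        "variance": var,
        "stddev": std,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float((values**2).sum()),
        "entropy": entropy,
        "minimum": float(values.min()),
        "maximum": float(values.max()),
        "range": float(values.max() - values.min()),
        "p5": float(p5),
        "p10": float(p10),
        "p25": float(p25),
        "p75": float(p75),
        "p90": float(p90),
        "p95": float(p95),
        "iqr": float(p75 - p25),
        "mean_abs_dev": float(np.abs(values - mean).mean()),
        "robust_mean_abs_dev": float(np.abs(in_robust - in_robust.mean()).mean()) if in_robust.size else 0.0,
        "rms": float(np.sqrt((values**2).mean())),
        "uniformity": float((p**2).sum()),
        "cv": _safe_div(std, mean),
    }


# ---------------------------------------------------------------------------
# GLCM formulas
# ---------------------------------------------------------------------------

def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def glcm_features(g: GLCM) -> dict[str, float]:
    """The 24 co-occurrence formulas, evaluated on a normalized GLCM.

    Grey levels are indexed 1..L inside the weighted sums.  Undefined ratios
    on degenerate matrices (e.g. correlation of a constant region) impute 0.
    """
    p = g.matrix
    L = g.levels
    i = np.arange(1, L + 1, dtype=float)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mux = float((i * px).sum())
    muy = float((i * py).sum())
    sigx = float(np.sqrt(((i - mux) ** 2 * px).sum()))
    sigy = float(np.sqrt(((i - muy) ** 2 * py).sum()))

    # diagonal (difference) and cross-diagonal (sum) marginals
    k_sum = np.arange(2, 2 * L + 1, dtype=float)
    p_sum = np.zeros(2 * L - 1)
    k_diff = np.arange(0, L, dtype=float)
    p_diff = np.zeros(L)
    for a in range(L):
        for b in range(L):
            p_sum[a + b] += p[a, b]
            p_diff[abs(a - b)] += p[a, b]
    sum_avg = float((k_sum * p_sum).sum())
    diff_avg = float((k_diff * p_diff).sum())

    hxy = float(-_xlog2(p).sum())
    hx = float(-_xlog2(px).sum())
    hy = float(-_xlog2(py).sum())
    pxy = np.outer(px, py)
    nz = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxy[nz])).sum())
    nz2 = pxy > 0
    hxy2 = float(-(pxy[nz2] * np.log2(pxy[nz2])).sum())

    imc2_arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    return {
        "glcm_contrast": float((p * (I - J) ** 2).sum()),
        "glcm_dissimilarity": float((p * np.abs(I - J)).sum()),
        "glcm_idm": float((p / (1.0 + (I - J) ** 2)).sum()),
        "glcm_id": float((p / (1.0 + np.abs(I - J))).sum()),
        "glcm_idmn": float((p / (1.0 + (I - J) ** 2 / L**2)).sum()),
        "glcm_idn": float((p / (1.0 + np.abs(I - J) / L)).sum()),
        "glcm_joint_energy": float((p**2).sum()),
        "glcm_correlation": _safe_div(float((I * J * p).sum()) - mux * muy, sigx * sigy),
        "glcm_autocorrelation": float((I * J * p).sum()),
        "glcm_cluster_shade": float((p * (I + J - mux - muy) ** 3).sum()),
        "glcm_cluster_prominence": float((p * (I + J - mux - muy) ** 4).sum()),
        "glcm_cluster_tendency": float((p * (I + J - mux - muy) ** 2).sum()),
        "glcm_joint_entropy": hxy,
        "glcm_joint_average": mux,
        "glcm_joint_variance": float((p * (I - mux) ** 2).sum()),
        "glcm_sum_average": sum_avg,
        "glcm_sum_entropy": float(-_xlog2(p_sum).sum()),
        "glcm_sum_variance": float((p_sum * (k_sum - sum_avg) ** 2).sum()),
        "glcm_difference_average": diff_avg,
        "glcm_difference_entropy": float(-_xlog2(p_diff).sum()),
        "glcm_difference_variance": float((p_diff * (k_diff - diff_avg) ** 2).sum()),
        "glcm_imc1": _safe_div(hxy - hxy1, max(hx, hy)),
        "glcm_imc2": float(np.sqrt(max(imc2_arg, 0.0))),
        "glcm_max_probability": float(p.max()),
    }


# ---------------------------------------------------------------------------
# Run-length / size-zone / dependence formulas (shared algebra)
# ---------------------------------------------------------------------------

def _matrix_stats(P: np.ndarray, n_voxels: int,
                  names: Mapping[str, str]) -> dict[str, float]:
    """Weighted-sum formulas shared by GLRLM/GLSZM/GLDM.

    ``P[g, j]`` counts runs/zones/voxels with grey level g+1 and size/length/
    dependence j+1; ``names`` maps the generic statistic to the registry name.
    """
    N = float(P.sum())
    if N == 0:
        return {v: 0.0 for v in names.values()}
    L, M = P.shape
    gl = np.arange(1, L + 1, dtype=float)[:, None]
    sz = np.arange(1, M + 1, dtype=float)[None, :]
    pg = P.sum(axis=1)
    ps = P.sum(axis=0)
    pnorm = P / N
    mu_g = float((gl * pnorm).sum())
    mu_s = float((sz * pnorm).sum())
    pn = pnorm[pnorm > 0]
    out = {
        "small": float((P / sz**2).sum() / N),
        "large": float((P * sz**2).sum() / N),
        "gln": float((pg**2).sum() / N),
        "glnn": float((pg**2).sum() / N**2),
        "szn": float((ps**2).sum() / N),
        "sznn": float((ps**2).sum() / N**2),
        "pct": N / float(n_voxels) if n_voxels else 0.0,
        "glv": float((pnorm * (gl - mu_g) ** 2).sum()),
        "szv": float((pnorm * (sz - mu_s) ** 2).sum()),
        "entropy": float(-(pn * np.log2(pn)).sum()),
        "lgl": float((P / gl**2).sum() / N),
        "hgl": float((P * gl**2).sum() / N),
        "slgl": float((P / (gl**2 * sz**2)).sum() / N),
        "shgl": float((P * gl**2 / sz**2).sum() / N),
        "llgl": float((P * sz**2 / gl**2).sum() / N),
        "lhgl": float((P * gl**2 * sz**2).sum() / N),
    }
    return {reg_name: out[stat] for stat, reg_name in names.items()}


_GLRLM_MAP = {
    "small": "glrlm_sre", "large": "glrlm_lre", "gln": "glrlm_gln", "glnn": "glrlm_glnn",
    "szn": "glrlm_rln", "sznn": "glrlm_rlnn", "pct": "glrlm_rp", "glv": "glrlm_glv",
    "szv": "glrlm_rv", "entropy": "glrlm_re", "lgl": "glrlm_lglre", "hgl": "glrlm_hglre",
    "slgl": "glrlm_srlgle", "shgl": "glrlm_srhgle", "llgl": "glrlm_lrlgle", "lhgl": "glrlm_lrhgle",
}

_GLSZM_MAP = {
    "small": "glszm_sae", "large": "glszm_lae", "gln": "glszm_gln", "glnn": "glszm_glnn",
    "szn": "glszm_szn", "sznn": "glszm_sznn", "pct": "glszm_zp", "glv": "glszm_glv",
    "szv": "glszm_zv", "entropy": "glszm_ze", "lgl": "glszm_lglze", "hgl": "glszm_hglze",
    "slgl": "glszm_salgle", "shgl": "glszm_sahgle", "llgl": "glszm_lalgle", "lhgl": "glszm_lahgle",
}

_GLDM_MAP = {
    "small": "gldm_sde", "large": "gldm_lde", "gln": "gldm_gln", "szn": "gldm_dn",
    "sznn": "gldm_dnn", "glv": "gldm_glv", "szv": "gldm_dv", "entropy": "gldm_de",
    "lgl": "gldm_lgle", "hgl": "gldm_hgle", "slgl": "gldm_sdlgle", "shgl": "gldm_sdhgle",
    "llgl": "gldm_ldlgle", "lhgl": "gldm_ldhgle",
}


def glrlm_features(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 16 run-length formulas (short/long run emphasis, non-uniformities, ...)."""
    return _matrix_stats(P, n_voxels, _GLRLM_MAP)


def glszm_features(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 16 size-zone formulas (small/large area emphasis, zone percentage, ...)."""
    return _matrix_stats(P, n_voxels, _GLSZM_MAP)


def gldm_features(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 14 dependence formulas (small/large dependence emphasis, ...)."""
    return _matrix_stats(P, n_voxels, _GLDM_MAP)


# ---------------------------------------------------------------------------
# Shape
# ---------------------------------------------------------------------------

def shape_features(mask: np.ndarray, spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> dict[str, float]:
    """Geometry of a binary region: 12 formulas in physical (mm) units.

    Surface area comes from a marching-cubes mesh of the zero-padded mask;
    axis lengths are 4*sqrt(eigenvalue) of the physical-coordinate
    covariance (the full axis length of the matched ellipsoid); the maximum
    3D diameter is the largest pairwise distance between convex-hull
    vertices of the voxel centres.
    """
    from skimage import measure
    from scipy.spatial import ConvexHull

    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("shape features need a non-empty mask")
    spacing = tuple(float(s) for s in spacing)
    voxel_volume = float(np.prod(spacing))
    n = int(mask.sum())
    volume = n * voxel_volume

    padded = np.pad(mask, 1).astype(float)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    area = float(measure.mesh_surface_area(verts, faces))

    coords = np.argwhere(mask).astype(float) * np.asarray(spacing)
    centred = coords - coords.mean(axis=0)
    # eigenvalues of the coordinate covariance, largest first
    cov = np.cov(centred.T) if n > 1 else np.zeros((3, 3))
    eig = np.sort(np.clip(np.linalg.eigvalsh(np.atleast_2d(cov)), 0.0, None))[::-1]
    axes = 4.0 * np.sqrt(eig)

    if n > 3:
        try:
            hull_pts = coords[ConvexHull(coords).vertices]
        except Exception:  # coplanar / degenerate point sets
            hull_pts = coords
    else:
        hull_pts = coords
    diffs = hull_pts[:, None, :] - hull_pts[None, :, :]
    max_diam = float(np.sqrt((diffs**2).sum(axis=-1)).max())

    sphere_area = np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0)
    return {
        "volume": volume,
        "surface_area": area,
        "surface_volume_ratio": _safe_div(area, volume),
        "sphericity": _safe_div(sphere_area, area),
        "compactness": _safe_div(volume, np.sqrt(np.pi) * area**1.5),
        "spherical_disproportion": _safe_div(area, sphere_area),
        "major_axis_length": float(axes[0]),
        "minor_axis_length": float(axes[1]),
        "least_axis_length": float(axes[2]),
        "elongation": float(np.sqrt(_safe_div(eig[1], eig[0]))),
        "flatness": float(np.sqrt(_safe_div(eig[2], eig[0]))),
        "max_3d_diameter": max_diam,
    }


# ---------------------------------------------------------------------------
# Per-VOI dispatcher
# ---------------------------------------------------------------------------

def voi_features(
    volume: np.ndarray,
    mask: np.ndarray,
    formula_names: Iterable[str] = DEFAULT_FORMULA_NAMES,
    levels: int = 32,
) -> dict[str, float]:
    """Evaluate the requested histogram/texture formulas on one VOI.

    ``volume`` is the (already transformed) image restricted to a bounding
    box; ``mask`` selects the VOI voxels.  Texture matrices are computed at
    most once each.  Degenerate VOIs (fewer than two voxels, or zero
    intensity variance) return 0 for every formula, keeping feature tables
    rectangular; callers are expected to log the imputation.
    """
    formula_names = list(formula_names)
    unknown = [f for f in formula_names if f not in FORMULA_CATEGORIES]
    if unknown:
        raise KeyError(f"unknown formulas: {unknown}")
    mask = np.asarray(mask, dtype=bool)
    values = np.asarray(volume, dtype=float)[mask]
    if values.size < 2 or float(values.max()) == float(values.min()):
        return {f: 0.0 for f in formula_names}

    cats = {FORMULA_CATEGORIES[f] for f in formula_names}
    out: dict[str, float] = {}
    if "histogram" in cats:
        out.update(histogram_features(values, bins=levels))
    if cats - {"histogram"}:
        q = texture.quantize(volume, levels, mask=mask)
        n_vox = int(mask.sum())
        if "glcm" in cats:
            g = compute_glcm(volume, mask, levels=levels)
            if g is None:
                out.update({f: 0.0 for f in GLCM_FORMULAS})
            else:
                out.update(glcm_features(g))
        if "glrlm" in cats:
            out.update(glrlm_features(texture.glrlm_matrix(q, mask, levels), n_vox))
        if "glszm" in cats:
            out.update(glszm_features(texture.glszm_matrix(q, mask, levels), n_vox))
        if "gldm" in cats:
            out.update(gldm_features(texture.gldm_matrix(q, mask, levels), n_vox))
    return {f: out[f] for f in formula_names}
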