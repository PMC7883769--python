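"""Stationary image filter bank applied to each volume before feature computation.

Every transform maps a 3D volume to a same-shape 3D volume and is fully
deterministic.  The default registry contains 19 filters:

* ``identity``
* Laplacian-of-Gaussian at kernel widths 0.5, 1, 2, 3 and 5 mm
* the eight first-level 3D Haar wavelet subbands (``lll`` ... ``hhh``),
  upsampled back to the input grid
* a slice-wise (axial) local binary pattern code image
* gradient magnitude (central differences)
* Laplacian-of-Gaussian at 1, 2 and 3 mm applied to the two-level Haar
  approximation (a coarse-scale edge detector)

Convolution borders use mirror padding so that small volumes of interest do
not pick up artificial edge responses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pywt
from scipy import ndimage

__all__ = [
    "TransformSpec",
    "DEFAULT_TRANSFORMS",
    "DEFAULT_TRANSFORM_NAMES",
    "get_transform_spec",
    "apply_transform",
    "log_kernel",
    "lbp_transform",
    "haar_subband",
]

TRANSFORM_KINDS = ("identity", "log", "wavelet", "lbp", "gradient_magnitude", "wavelet_log")


@dataclass(frozen=True)
class TransformSpec:
    """A named, deterministic image filter.

    Parameters live in ``params`` and are kind-specific: ``log`` and
    ``wavelet_log`` take ``width_mm`` (the LoG kernel width, i.e. the Gaussian
    sigma in millimetres), ``wavelet`` takes ``subband`` (a three-letter
    low/high code such as ``"lhh"``), ``lbp`` takes ``points``/``radius``.
    """

    name: str
    kind: str
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in TRANSFORM_KINDS:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind in ("log", "wavelet_log"):
            width = float(self.params.get("width_mm", 0.0))
            if width <= 0:
                raise ValueError(f"transform {self.name!r}: LoG width must be positive, got {width}")
        if self.kind == "wavelet":
            code = str(self.params.get("subband", ""))
            if len(code) != 3 or set(code) - {"l", "h"}:
                raise ValueError(f"transform {self.name!r}: bad Haar subband code {code!r}")


def _build_default_transforms() -> dict[str, TransformSpec]:
    specs: list[TransformSpec] = [TransformSpec("identity", "identity")]
    for width in (0.5, 1.0, 2.0, 3.0, 5.0):
        specs.append(TransformSpec(f"log_{width:g}mm", "log", {"width_mm": width}))
    for code in ("lll", "llh", "lhl", "lhh", "hll", "hlh", "hhl", "hhh"):
        specs.append(TransformSpec(f"haar_{code}", "wavelet", {"subband": code}))
    specs.append(TransformSpec("lbp", "lbp", {"points": 8, "radius": 1}))
    specs.append(TransformSpec("gradient_magnitude", "gradient_magnitude"))
    for width in (1.0, 2.0, 3.0):
        specs.append(TransformSpec(f"haar2_log_{width:g}mm", "wavelet_log", {"width_mm": width, "levels": 2}))
    return {s.name: s for s in specs}


DEFAULT_TRANSFORMS: dict[str, TransformSpec] = _build_default_transforms()
DEFAULT_TRANSFORM_NAMES: tuple[str, ...] = tuple(DEFAULT_TRANSFORMS)
assert len(DEFAULT_TRANSFORM_NAMES) == 19


def get_transform_spec(name: str) -> TransformSpec:
    """Look up a transform by name in the default registry."""
    try:
        return DEFAULT_TRANSFORMS[name]
    except KeyError:
        raise KeyError(f"unknown transform {name!r}; known: {', '.join(DEFAULT_TRANSFORM_NAMES)}") from None


# ---------------------------------------------------------------------------
# Laplacian of Gaussian
# ---------------------------------------------------------------------------

def _log_1d_kernels(sigma_mm: float, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Sampled 1D Gaussian and its second derivative on a grid with ``spacing``.

    The Gaussian is normalized to unit sum; the second-derivative kernel is
    scaled by the same factor and mean-corrected so it sums exactly to zero
    (the discrete analogue of the LoG integrating to zero).
    """
    radius = max(1, int(math.ceil(4.0 * sigma_mm / spacing)))
    x = np.arange(-radius, radius + 1, dtype=float) * spacing
    g = np.exp(-(x**2) / (2.0 * sigma_mm**2))
    norm = g.sum()
    g = g / norm
    g2 = ((x**2 - sigma_mm**2) / sigma_mm**4) * np.exp(-(x**2) / (2.0 * sigma_mm**2)) / norm
    g2 = g2 - g2.mean()
    return g, g2


def log_kernel(width_mm: float, spacing: Sequence[float] = (1.0, 1.0, 1.0)) -> np.ndarray:
    """Explicit 3D Laplacian-of-Gaussian kernel (coefficients sum to ~0).

    The kernel is the sum over axes of (second-derivative-of-Gaussian along
    that axis) x (Gaussian along the others), i.e. exactly the separable
    operator that :func:`apply_transform` applies for ``log`` specs.
    """
    if width_mm <= 0:
        raise ValueError(f"LoG width must be positive, got {width_mm}")
    ones: list[np.ndarray] = []
    seconds: list[np.ndarray] = []
    for sp in spacing:
        g, g2 = _log_1d_kernels(width_mm, float(sp))
        ones.append(g)
        seconds.append(g2)
    shape = tuple(len(g) for g in ones)
    kernel = np.zeros(shape)
    for axis in range(3):
        parts = [seconds[i] if i == axis else ones[i] for i in range(3)]
        kernel += np.einsum("i,j,k->ijk", *parts)
    return kernel


def _apply_log(volume: np.ndarray, width_mm: float, spacing: Sequence[float]) -> np.ndarray:
    out = np.zeros_like(volume, dtype=float)
    kernels = [_log_1d_kernels(width_mm, float(sp)) for sp in spacing]
    for axis in range(3):
        part = volume.astype(float)
        for other in range(3):
            g, g2 = kernels[other]
            weights = g2 if other == axis else g
            part = ndimage.convolve1d(part, weights, axis=other, mode="mirror")
        out += part
    return out


# ---------------------------------------------------------------------------
# Haar wavelet subbands
# ---------------------------------------------------------------------------

def _upsample_to(coeff: np.ndarray, shape: tuple[int, ...], factor: int) -> np.ndarray:
    out = coeff
    for axis in range(3):
        out = np.repeat(out, factor, axis=axis)
    return out[tuple(slice(0, n) for n in shape)]


def haar_subband(volume: np.ndarray, subband: str) -> np.ndarray:
    """One first-level 3D Haar subband, nearest-upsampled to the input shape.

    ``subband`` is a three-letter code over {l, h}, one letter per axis
    (``lll`` is the approximation).  Uses periodization boundary handling so
    the eight subbands form an orthonormal (Parseval) decomposition for
    even-sized volumes.
    """
    key = subband.replace("l", "a").replace("h", "d")
    coeffs = pywt.dwtn(volume, "haar", mode="periodization")
    return _upsample_to(coeffs[key], volume.shape, 2)


def _haar2_approx(volume: np.ndarray) -> np.ndarray:
    a1 = pywt.dwtn(volume, "haar", mode="periodization")["aaa"]
    a2 = pywt.dwtn(a1, "haar", mode="periodization")["aaa"]
    # two decimations halve the grid twice and scale by 2**(3/2) per level
    return _upsample_to(a2, volume.shape, 4) / (2.0 ** 3)


# ---------------------------------------------------------------------------
# Local binary patterns
# ---------------------------------------------------------------------------

_LBP_NEIGHBOURS = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))


def lbp_transform(volume: np.ndarray, points: int = 8, radius: int = 1) -> np.ndarray:
    """Slice-wise (axial) local binary pattern codes.

    For each voxel the 8 in-plane neighbours at radius 1 are compared to the
    centre with a strict "greater than"; bit k is set when neighbour k is
    greater.  A constant slice therefore codes to 0 everywhere, and the
    neighbours of an isolated bright voxel each carry exactly one set bit.
    Slices are mirror-padded.  Only the canonical 8-neighbour, radius-1
    configuration is implemented.
    """
    if points != 8 or radius != 1:
        raise ValueError("only the 8-neighbour, radius-1 LBP is supported")
    if volume.ndim != 3 or volume.shape[1] < 3 or volume.shape[2] < 3:
        raise ValueError("volume in-plane extent must be at least 3 voxels for LBP")
    out = np.zeros(volume.shape, dtype=float)
    padded = np.pad(volume, ((0, 0), (1, 1), (1, 1)), mode="reflect")
    ny, nx = volume.shape[1], volume.shape[2]
    for bit, (dy, dx) in enumerate(_LBP_NEIGHBOURS):
        neigh = padded[:, 1 + dy : 1 + dy + ny, 1 + dx : 1 + dx + nx]
        out += (neigh > volume) * float(1 << bit)
    return out


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def apply_transform(
    volume: np.ndarray,
    spec: TransformSpec | str,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Apply one stationary filter; output has the same shape as the input."""
    if isinstance(spec, str):
        spec = get_transform_spec(spec)
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {volume.shape}")
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite values")

    if spec.kind == "identity":
        return volume.copy()
    if spec.kind == "log":
        return _apply_log(volume, float(spec.params["width_mm"]), spacing)
    if spec.kind == "wavelet":
        return haar_subband(volume, str(spec.params["subband"]))
    if spec.kind == "lbp":
        return lbp_transform(volume, int(spec.params.get("points", 8)), int(spec.params.get("radius", 1)))
    if spec.kind == "gradient_magnitude":
        grads = np.gradient(volume, *[float(s) for s in spacing])
        return np.sqrt(sum(g**2 for g in grads))
    if spec.kind == "wavelet_log":
        approx = _haar2_approx(volume)
        return _apply_log(approx, float(spec.params["width_mm"]), spacing)
    raise ValueError(f"unknown transform kind {spec.kind!r}")  # pragma: no cover
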