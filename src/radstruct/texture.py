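"""Texture matrices computed on quantized volumes of interest.

Implements the four second-order structures the formula registry draws on:
grey-level co-occurrence (GLCM), grey-level run length (GLRLM), grey-level
size zone (GLSZM) and grey-level dependence (GLDM) matrices.  All operate on
a grey-level-quantized 3D array restricted to a boolean mask; voxels outside
the mask never contribute (co-occurrences, runs, zones and dependence counts
all stop at the mask border).

Quantization is equal-width binning over the in-mask intensity range; the
default of 32 levels is standard radiomics practice.  Offsets/directions are
the 13 unique 3D displacement vectors at Chebyshev distance 1 (half of the
26-neighbourhood), and their contributions are pooled into a single matrix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "OFFSETS_13",
    "OFFSETS_26",
    "quantize",
    "GLCM",
    "compute_glcm",
    "glrlm_matrix",
    "glszm_matrix",
    "gldm_matrix",
]

Offset = tuple[int, int, int]


def _unique_directions() -> tuple[Offset, ...]:
    offs = []
    for off in itertools.product((-1, 0, 1), repeat=3):
        if off == (0, 0, 0):
            continue
        # keep one representative per +-pair: first nonzero component positive
        first = next(c for c in off if c != 0)
        if first > 0:
            offs.append(off)
    return tuple(offs)


OFFSETS_13: tuple[Offset, ...] = _unique_directions()
OFFSETS_26: tuple[Offset, ...] = tuple(
    off for off in itertools.product((-1, 0, 1), repeat=3) if off != (0, 0, 0)
)


def quantize(volume: np.ndarray, levels: int, vmin: float | None = None, vmax: float | None = None,
             mask: np.ndarray | None = None) -> np.ndarray:
    """Equal-width quantization of ``volume`` into ``levels`` integer bins.

    The binning range defaults to the (in-mask) value range.  A constant
    input maps to bin 0 everywhere.
    """
    if levels < 2:
        raise ValueError(f"need at least 2 grey levels, got {levels}")
    volume = np.asarray(volume, dtype=float)
    ref = volume[mask] if mask is not None else volume
    lo = float(np.min(ref)) if vmin is None else vmin
    hi = float(np.max(ref)) if vmax is None else vmax
    if hi <= lo:
        return np.zeros(volume.shape, dtype=np.int64)
    q = np.floor((volume - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def _pair_slices(shape: Sequence[int], off: Offset) -> tuple[tuple[slice, ...], tuple[slice, ...]]:
    """Slices (src, dst) such that dst = src + off, both inside the array."""
    src, dst = [], []
    for n, o in zip(shape, off):
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


def _shift_read(arr: np.ndarray, off: Offset, fill=False) -> np.ndarray:
    """Array b with b[x] = arr[x + off] (``fill`` outside the bounds)."""
    out = np.full(arr.shape, fill, dtype=arr.dtype)
    src, dst = _pair_slices(arr.shape, off)
    out[src] = arr[dst]
    return out


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GLCM:
    """A symmetrized, normalized grey-level co-occurrence matrix.

    ``matrix`` is L x L with entries summing to 1; ``offsets`` records which
    displacement vectors were pooled.
    """

    matrix: np.ndarray
    levels: int
    offsets: tuple[Offset, ...]

    def __post_init__(self) -> None:
        if self.matrix.shape != (self.levels, self.levels):
            raise ValueError("GLCM matrix shape inconsistent with level count")
        if not np.isclose(self.matrix.sum(), 1.0):
            raise ValueError("GLCM matrix must be normalized to unit sum")


def compute_glcm(
    volume: np.ndarray,
    mask: np.ndarray,
    levels: int = 32,
    offsets: Sequence[Offset] = OFFSETS_13,
    symmetric: bool = True,
) -> GLCM | None:
    """Co-occurrence matrix of the masked voxels of ``volume``.

    Quantizes over the in-mask range, accumulates co-occurring level pairs
    over every offset (both voxels must be in-mask), symmetrizes and
    normalizes.  Returns ``None`` when no voxel pair co-occurs (e.g. a mask
    of scattered isolated voxels); raises for fewer than two in-mask voxels.
    """
    mask = np.asarray(mask, dtype=bool)
    if int(mask.sum()) < 2:
        raise ValueError("GLCM requires at least two in-mask voxels")
    q = quantize(volume, levels, mask=mask)
    counts = np.zeros((levels, levels))
    for off in offsets:
        src, dst = _pair_slices(q.shape, off)
        valid = mask[src] & mask[dst]
        np.add.at(counts, (q[src][valid], q[dst][valid]), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        return None
    return GLCM(matrix=counts / total, levels=levels, offsets=tuple(offsets))


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_matrix(
    q: np.ndarray,
    mask: np.ndarray,
    levels: int,
    directions: Sequence[Offset] = OFFSETS_13,
) -> np.ndarray:
    """Run-length matrix P[g, r-1]: number of maximal runs of level g and length r.

    Runs are maximal same-level segments along each direction, broken by the
    mask border; every direction contributes independently (an isolated
    voxel is one run of length 1 in each direction).
    """
    mask = np.asarray(mask, dtype=bool)
    max_len = int(max(q.shape))
    out = np.zeros((levels, max_len))
    for d in directions:
        src, dst = _pair_slices(q.shape, d)
        nxt = np.zeros(q.shape, dtype=bool)  # nxt[x]: x and x+d share level, both in mask
        nxt[src] = mask[src] & mask[dst] & (q[src] == q[dst])
        prev = np.zeros(q.shape, dtype=bool)
        prev[dst] = nxt[src]
        start = mask & ~prev
        length = start.astype(np.int64)
        alive = start & nxt
        k = 1
        while alive.any():
            length += alive
            alive = alive & _shift_read(nxt, (k * d[0], k * d[1], k * d[2]))
            k += 1
        np.add.at(out, (q[start], length[start] - 1), 1.0)
    return out


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def glszm_matrix(q: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """Size-zone matrix P[g, s-1]: number of 26-connected zones of level g and size s."""
    mask = np.asarray(mask, dtype=bool)
    structure = np.ones((3, 3, 3), dtype=int)
    zones: list[tuple[int, int]] = []
    max_size = 1
    for g in range(levels):
        comp = mask & (q == g)
        if not comp.any():
            continue
        labelled, n = ndimage.label(comp, structure=structure)
        sizes = np.bincount(labelled.ravel())[1:]
        for s in sizes:
            zones.append((g, int(s)))
            max_size = max(max_size, int(s))
    out = np.zeros((levels, max_size))
    for g, s in zones:
        out[g, s - 1] += 1.0
    return out


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------

def gldm_matrix(q: np.ndarray, mask: np.ndarray, levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence matrix P[g, j]: voxels of level g with j dependent neighbours.

    A 26-neighbour is dependent when it is in-mask and its level differs by
    at most ``alpha``.  Column j counts voxels with exactly j dependent
    neighbours (j = 0 .. 26); downstream formulas use dependence size j+1 so
    isolated voxels contribute rather than dividing by zero.
    """
    mask = np.asarray(mask, dtype=bool)
    dep = np.zeros(q.shape, dtype=np.int64)
    for off in OFFSETS_26:
        src, dst = _pair_slices(q.shape, off)
        ok = mask[src] & mask[dst] & (np.abs(q[src] - q[dst]) <= alpha)
        dep[src] += ok
    out = np.zeros((levels, 27))
    np.add.at(out, (q[mask], dep[mask]), 1.0)
    max_j = int(np.max(np.nonzero(out.sum(axis=0))[0])) if out.any() else 0
    return out[:, : max_j + 1]
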