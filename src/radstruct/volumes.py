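"""Subject volume I/O, normalization and tumor-region label handling.

Subjects are co-registered, skull-stripped multisequence 3D MRI volumes
(T1, T1ce, T2, FLAIR) with a tumor segmentation mask, all on a shared 1 mm
isotropic grid.  Segmentations arrive in the BraTS convention — label 1
(necrotic + non-enhancing tumor), label 2 (peritumoral edema), label 4
(enhancing tumor) — and are remapped to the region scheme the feature space
uses:

* ``enhancing``       — BraTS label 4, unchanged;
* ``necrosis``        — the dark part of BraTS label 1 on T1ce;
* ``t2_abnormality``  — edema plus the non-enhancing (bright-on-T1ce) part
  of label 1;
* ``tumor_core``      — enhancing union necrosis (derived);
* ``whole_tumor``     — union of the three base regions (derived).

Necrosis vs non-enhancing tumor within label 1 is decided by an Otsu
threshold on the T1ce intensities of the label-1 voxels (necrosis below),
with an optional fixed-quantile override; necrotic tissue is reliably dark
on T1ce, which is what makes the split automatic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_ENHANCING",
    "LABEL_NECROSIS",
    "LABEL_T2_ABNORMALITY",
    "BRATS_LABELS",
    "SEQUENCE_NAMES",
    "REGION_NAMES",
    "SubjectVolumes",
    "minmax_normalize",
    "remap_brats_labels",
    "region_mask",
    "read_subject",
    "write_subject",
]

# base (mutually exclusive) labels of the remapped mask
LABEL_BACKGROUND = 0
LABEL_ENHANCING = 1
LABEL_NECROSIS = 2
LABEL_T2_ABNORMALITY = 3

BRATS_LABELS = (0, 1, 2, 4)
SEQUENCE_NAMES = ("T1", "T1ce", "T2", "FLAIR")
REGION_NAMES = ("enhancing", "necrosis", "t2_abnormality", "tumor_core", "whole_tumor")

_BASE_REGION_LABELS = {
    "enhancing": (LABEL_ENHANCING,),
    "necrosis": (LABEL_NECROSIS,),
    "t2_abnormality": (LABEL_T2_ABNORMALITY,),
    "tumor_core": (LABEL_ENHANCING, LABEL_NECROSIS),
    "whole_tumor": (LABEL_ENHANCING, LABEL_NECROSIS, LABEL_T2_ABNORMALITY),
}


class DegenerateInputError(ValueError):
    """An input is too degenerate to process (e.g. constant foreground)."""


@dataclass
class SubjectVolumes:
    """One subject's sequence volumes and remapped mask on a shared grid."""

    subject_id: str
    volumes: dict[str, np.ndarray]
    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        shapes = {name: v.shape for name, v in self.volumes.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"sequence volumes disagree in shape: {shapes}")
        ref = next(iter(shapes.values()))
        if self.mask.shape != ref:
            raise ValueError(f"mask shape {self.mask.shape} != volume shape {ref}")
        self.mask = np.asarray(self.mask)
        known = {LABEL_BACKGROUND, LABEL_ENHANCING, LABEL_NECROSIS, LABEL_T2_ABNORMALITY}
        present = set(np.unique(self.mask).tolist())
        if not present <= known:
            raise ValueError(f"mask contains non-base labels {sorted(present - known)}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape


def minmax_normalize(volume: np.ndarray, foreground_mask: np.ndarray | None = None) -> np.ndarray:
    """Affinely map the foreground to [0, 1]; background is set to 0.

    ``foreground_mask`` defaults to the nonzero voxels (skull-stripped
    volumes are zero outside the brain).  A constant foreground cannot be
    normalized and raises :class:`DegenerateInputError`.
    """
    volume = np.asarray(volume, dtype=float)
    fg = np.asarray(foreground_mask, dtype=bool) if foreground_mask is not None else volume != 0
    if not fg.any():
        raise DegenerateInputError("empty foreground")
    vals = volume[fg]
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        raise DegenerateInputError("constant foreground cannot be min-max normalized")
    out = np.zeros_like(volume)
    out[fg] = (vals - lo) / (hi - lo)
    return out


def remap_brats_labels(
    brats_mask: np.ndarray,
    t1ce: np.ndarray,
    split: str = "otsu",
    quantile: float | None = None,
) -> np.ndarray:
    """Remap a BraTS mask {0,1,2,4} to the base labels {0..3}.

    Label 4 becomes ``enhancing``; label 2 becomes ``t2_abnormality``;
    label 1 is split on T1ce intensity into ``necrosis`` (below threshold)
    and non-enhancing tumor, which is merged into ``t2_abnormality``.
    ``split`` is "otsu" (default) or "quantile" (with ``quantile`` giving
    the necrosis fraction).  The remap preserves the total tumor voxel count.
    """
    brats_mask = np.asarray(brats_mask)
    present = set(np.unique(brats_mask).tolist())
    if not present <= set(BRATS_LABELS):
        raise ValueError(f"unknown BraTS labels {sorted(present - set(BRATS_LABELS))}")
    t1ce = np.asarray(t1ce, dtype=float)
    if t1ce.shape != brats_mask.shape:
        raise ValueError("t1ce and mask shapes differ")

    out = np.zeros(brats_mask.shape, dtype=np.int8)
    out[brats_mask == 4] = LABEL_ENHANCING
    out[brats_mask == 2] = LABEL_T2_ABNORMALITY
    label1 = brats_mask == 1
    if label1.any():
        vals = t1ce[label1]
        if split == "quantile":
            if quantile is None:
                raise ValueError("quantile split requires a quantile")
            thr = float(np.quantile(vals, quantile))
            necrotic = label1 & (t1ce <= thr)
        elif split == "otsu":
            if np.unique(vals).size < 2:
                logger.warning("label-1 T1ce intensities are constant; treating all as necrosis")
                necrotic = label1
            else:
                from skimage.filters import threshold_otsu

                thr = float(threshold_otsu(vals))
                necrotic = label1 & (t1ce <= thr)
        else:
            raise ValueError(f"unknown split rule {split!r}")
        out[necrotic] = LABEL_NECROSIS
        out[label1 & ~necrotic] = LABEL_T2_ABNORMALITY
    return out


def region_mask(subject: "SubjectVolumes | np.ndarray", region: str) -> np.ndarray:
    """Boolean mask of a named tumor region (derived regions are unions)."""
    mask = subject.mask if isinstance(subject, SubjectVolumes) else np.asarray(subject)
    if region not in _BASE_REGION_LABELS:
        raise ValueError(f"unknown region {region!r}; known: {', '.join(REGION_NAMES)}")
    out = np.isin(mask, _BASE_REGION_LABELS[region])
    if not out.any():
        logger.warning("region %r is empty", region)
    return out


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _resample_to_isotropic(data: np.ndarray, zooms: Sequence[float], target: float, order: int) -> np.ndarray:
    factors = [float(z) / target for z in zooms]
    if np.allclose(factors, 1.0):
        return data
    return ndimage.zoom(data, zoom=factors, order=order, mode="nearest", grid_mode=True)


def read_subject(
    paths: Mapping[str, str | Path],
    subject_id: str | None = None,
    target_spacing: float = 1.0,
    normalize: bool = True,
    mask_scheme: str = "brats",
    split: str = "otsu",
    affine_tol: float = 1e-3,
) -> SubjectVolumes:
    """Load a subject from NIfTI files and put it on the common grid.

    ``paths`` maps the lower-cased sequence names ``t1, t1ce, t2, flair``
    plus ``mask`` to files.  Volumes are resampled to ``target_spacing`` mm
    isotropic (trilinear; nearest-neighbour for the mask) when their stored
    spacing differs, min-max normalized over the nonzero foreground, and the
    mask is remapped from BraTS labels (``mask_scheme="base"`` accepts an
    already-remapped mask).
    """
    import nibabel as nib

    required = [s.lower() for s in SEQUENCE_NAMES] + ["mask"]
    for name in required:
        if name not in paths:
            raise ValueError(f"missing path for {name!r}")
        if not Path(paths[name]).exists():
            raise FileNotFoundError(f"{name}: no such file {paths[name]}")

    images = {name: nib.load(str(paths[name])) for name in required}
    affines = [img.affine for img in images.values()]
    for aff in affines[1:]:
        if not np.allclose(aff, affines[0], atol=affine_tol):
            raise ValueError("sequence/mask affines disagree beyond tolerance; co-register first")

    arrays: dict[str, np.ndarray] = {}
    for name, img in images.items():
        zooms = img.header.get_zooms()[:3]
        order = 0 if name == "mask" else 1
        data = np.asarray(img.get_fdata())
        arrays[name] = _resample_to_isotropic(data, zooms, target_spacing, order)

    shapes = {name: a.shape for name, a in arrays.items()}
    if len(set(shapes.values())) != 1:
        raise ValueError(f"volumes disagree in shape after resampling: {shapes}")

    raw_mask = np.rint(arrays.pop("mask")).astype(np.int16)
    volumes = {seq: arrays[seq.lower()] for seq in SEQUENCE_NAMES}
    if mask_scheme == "brats":
        mask = remap_brats_labels(raw_mask, volumes["T1ce"], split=split)
    elif mask_scheme == "base":
        mask = raw_mask.astype(np.int8)
    else:
        raise ValueError(f"unknown mask scheme {mask_scheme!r}")
    if normalize:
        volumes = {seq: minmax_normalize(v) for seq, v in volumes.items()}
    sid = subject_id or Path(paths["mask"]).stem.split(".")[0]
    sp = (target_spacing,) * 3
    return SubjectVolumes(subject_id=sid, volumes=volumes, mask=mask, spacing=sp)


def write_subject(
    outdir: str | Path,
    volumes: Mapping[str, np.ndarray],
    mask: np.ndarray,
    spacing: float = 1.0,
) -> dict[str, Path]:
    """Write sequence volumes and a mask as uncompressed NIfTI (one file each).

    Files are ``t1.nii``, ``t1ce.nii``, ``t2.nii``, ``flair.nii`` and
    ``mask.nii`` with an axis-aligned affine; output is byte-deterministic.
    """
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([spacing, spacing, spacing, 1.0])
    written: dict[str, Path] = {}
    for seq in SEQUENCE_NAMES:
        path = outdir / f"{seq.lower()}.nii"
        nib.save(nib.Nifti1Image(np.asarray(volumes[seq], dtype=np.float32), affine), str(path))
        written[seq.lower()] = path
    path = outdir / "mask.nii"
    nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.int16), affine), str(path))
    written["mask"] = path
    return written
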