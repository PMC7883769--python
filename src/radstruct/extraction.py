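"""Whole-subject feature extraction over the structured feature space.

For each subject the pipeline is: take the normalized sequence volume, apply
every registered image transform to the whole volume, then restrict each
transformed volume to each tumor-region mask and evaluate every registered
histogram/texture formula on that VOI.  Filtering the whole volume before
masking is the default because filtering an isolated region instead creates
mask-edge responses that swamp the in-region texture; ``filter_order="voi"``
(zero the volume outside the region, then filter) is available for
comparison.

Degenerate VOIs — an empty or near-empty region, or a constant transformed
intensity — contribute 0 for every formula (logged), keeping tables
rectangular across subjects.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .feature_space import ComponentRegistry, FeatureTable, build_feature_index, default_registry
from .formulas import SHAPE_FORMULAS, shape_features, voi_features
from .transforms import apply_transform, get_transform_spec
from .volumes import SubjectVolumes, region_mask

logger = logging.getLogger(__name__)

__all__ = ["extract_features", "extract_table", "extract_shape_row"]


def _bounding_box(mask: np.ndarray, pad: int = 0) -> tuple[slice, ...]:
    slices = ndimage.find_objects(mask.astype(np.int8))[0]
    out = []
    for sl, n in zip(slices, mask.shape):
        out.append(slice(max(sl.start - pad, 0), min(sl.stop + pad, n)))
    return tuple(out)


def extract_features(
    subject: SubjectVolumes,
    registry: ComponentRegistry | None = None,
    levels: int = 32,
    filter_order: str = "image",
) -> np.ndarray:
    """One feature row: ``registry.n_features`` values in index order."""
    registry = registry or default_registry()
    if filter_order not in ("image", "voi"):
        raise ValueError(f"filter_order must be 'image' or 'voi', got {filter_order!r}")
    missing = [s for s in registry.sequences if s not in subject.volumes]
    if missing:
        raise ValueError(f"subject {subject.subject_id!r} lacks sequences {missing}")

    masks = {r: region_mask(subject, r) for r in registry.regions}
    if not masks.get("whole_tumor", next(iter(masks.values()))).any():
        raise ValueError(f"subject {subject.subject_id!r} has an empty tumor mask")
    boxes = {r: _bounding_box(m) if m.any() else None for r, m in masks.items()}

    n_formulas = len(registry.formulas)
    row = np.empty(registry.n_features)
    pos = 0
    for seq in registry.sequences:
        vol = subject.volumes[seq]
        filtered: dict[str, np.ndarray] = {}
        if filter_order == "image":
            for tname in registry.transforms:
                filtered[tname] = apply_transform(vol, get_transform_spec(tname), subject.spacing)
        for region in registry.regions:
            mask = masks[region]
            box = boxes[region]
            for tname in registry.transforms:
                if box is None:
                    row[pos : pos + n_formulas] = 0.0
                    pos += n_formulas
                    continue
                if filter_order == "image":
                    sub = filtered[tname][box]
                else:
                    isolated = np.where(mask, vol, 0.0)
                    sub = apply_transform(isolated, get_transform_spec(tname), subject.spacing)[box]
                feats = voi_features(sub, mask[box], registry.formulas, levels=levels)
                row[pos : pos + n_formulas] = [feats[f] for f in registry.formulas]
                pos += n_formulas
    empty = [r for r, b in boxes.items() if b is None]
    if empty:
        logger.warning(
            "subject %s: empty region(s) %s imputed as 0", subject.subject_id, ", ".join(empty)
        )
    assert pos == registry.n_features
    return row


def extract_table(
    subjects: Sequence[SubjectVolumes],
    labels: Iterable[int],
    registry: ComponentRegistry | None = None,
    levels: int = 32,
    filter_order: str = "image",
) -> FeatureTable:
    """Stack per-subject rows into a :class:`FeatureTable`."""
    registry = registry or default_registry()
    keys = tuple(build_feature_index(registry))
    rows = np.empty((len(subjects), len(keys)))
    for i, subject in enumerate(subjects):
        logger.info("extracting %s (%d/%d)", subject.subject_id, i + 1, len(subjects))
        rows[i] = extract_features(subject, registry, levels=levels, filter_order=filter_order)
    return FeatureTable(
        values=rows,
        keys=keys,
        subject_ids=tuple(s.subject_id for s in subjects),
        labels=np.asarray(list(labels), dtype=int),
    )


def extract_shape_row(subject: SubjectVolumes, regions: Sequence[str] | None = None) -> dict[str, float]:
    """The 60-entry shape set: the 12 shape formulas on each tumor region.

    Keys are ``region|formula``.  Empty regions impute 0.
    """
    regions = tuple(regions) if regions is not None else default_registry().regions
    out: dict[str, float] = {}
    for region in regions:
        mask = region_mask(subject, region)
        if mask.any():
            feats = shape_features(mask, subject.spacing)
        else:
            logger.warning("subject %s: empty region %s; shape imputed 0", subject.subject_id, region)
            feats = {f: 0.0 for f in SHAPE_FORMULAS}
        for f in SHAPE_FORMULAS:
            out[f"{region}|{f}"] = feats[f]
    return out
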