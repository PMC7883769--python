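"""The component-structured radiomic feature space.

Every radiomic feature is named by four components: MRI sequence, tumor
region, image transform and histogram/texture formula.  A registry fixes
the ordered name lists per category; the full feature space is the Cartesian
product over the four categories, and one volume of interest (VOI) is one
(sequence, region, transform) triple.  With the default registry —
4 sequences x 5 regions x 19 transforms x 93 formulas — there are 380 VOIs
and 35,340 features per subject.

Feature tables are stored as plain CSV/TSV whose column headers carry the
four components joined by ``|`` (e.g. ``FLAIR|t2_abnormality|log_1mm|skewness``),
so a table is self-describing without a sidecar.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .formulas import DEFAULT_FORMULA_NAMES
from .transforms import DEFAULT_TRANSFORM_NAMES

__all__ = [
    "KEY_SEPARATOR",
    "CATEGORIES",
    "GROUP_LABELS",
    "RegistryError",
    "TableFormatError",
    "FeatureKey",
    "ComponentRegistry",
    "default_registry",
    "registry_from_keys",
    "registry_from_config",
    "build_feature_index",
    "count_vois",
    "FeatureTable",
    "read_annotated_table",
]

KEY_SEPARATOR = "|"
CATEGORIES = ("sequence", "region", "transform", "formula")
GROUP_LABELS = ("Group1", "Group2")  # encoded internally as 0 / 1

DEFAULT_SEQUENCES = ("T1", "T1ce", "T2", "FLAIR")
DEFAULT_REGIONS = ("enhancing", "necrosis", "t2_abnormality", "tumor_core", "whole_tumor")


class RegistryError(ValueError):
    """A component registry is structurally invalid."""


class TableFormatError(ValueError):
    """An annotated feature table file cannot be parsed."""


class FeatureKey(NamedTuple):
    """The 4-tuple naming one radiomic feature."""

    sequence: str
    region: str
    transform: str
    formula: str

    @property
    def column_name(self) -> str:
        return KEY_SEPARATOR.join(self)

    @classmethod
    def from_column(cls, column: str) -> "FeatureKey":
        parts = column.split(KEY_SEPARATOR)
        if len(parts) != 4:
            raise TableFormatError(
                f"column {column!r} does not carry the four components "
                f"'sequence{KEY_SEPARATOR}region{KEY_SEPARATOR}transform{KEY_SEPARATOR}formula'"
            )
        return cls(*parts)


@dataclass(frozen=True)
class ComponentRegistry:
    """Ordered component name lists; the order defines column order and tie-breaks."""

    sequences: tuple[str, ...] = DEFAULT_SEQUENCES
    regions: tuple[str, ...] = DEFAULT_REGIONS
    transforms: tuple[str, ...] = DEFAULT_TRANSFORM_NAMES
    formulas: tuple[str, ...] = DEFAULT_FORMULA_NAMES

    def __post_init__(self) -> None:
        for cat in CATEGORIES:
            names = self.category(cat)
            if len(names) == 0:
                raise RegistryError(f"registry category {cat!r} is empty")
            if len(set(names)) != len(names):
                raise RegistryError(f"registry category {cat!r} has duplicate names")
            bad = [n for n in names if KEY_SEPARATOR in n]
            if bad:
                raise RegistryError(f"names may not contain {KEY_SEPARATOR!r}: {bad}")

    def category(self, cat: str) -> tuple[str, ...]:
        if cat not in CATEGORIES:
            raise RegistryError(f"unknown category {cat!r}")
        return getattr(self, cat + "s")

    def contains(self, key: FeatureKey) -> bool:
        return (
            key.sequence in self.sequences
            and key.region in self.regions
            and key.transform in self.transforms
            and key.formula in self.formulas
        )

    @property
    def n_features(self) -> int:
        return len(self.sequences) * len(self.regions) * len(self.transforms) * len(self.formulas)


def default_registry() -> ComponentRegistry:
    """The packaged default: 4 sequences, 5 regions, 19 transforms, 93 formulas."""
    return ComponentRegistry()


def registry_from_keys(keys: Sequence[FeatureKey]) -> ComponentRegistry:
    """Reconstruct a registry from annotated columns, in first-occurrence order.

    For tables written from a product index, first-occurrence order equals
    registry order, so round-tripping preserves ordering and tie-breaks.
    """
    def ordered(vals: Iterable[str]) -> tuple[str, ...]:
        return tuple(dict.fromkeys(vals))

    return ComponentRegistry(
        sequences=ordered(k.sequence for k in keys),
        regions=ordered(k.region for k in keys),
        transforms=ordered(k.transform for k in keys),
        formulas=ordered(k.formula for k in keys),
    )


def registry_from_config(config: dict) -> ComponentRegistry:
    """Build a registry from a config mapping; unknown keys are rejected."""
    allowed = {"sequences", "regions", "transforms", "formulas"}
    unknown = set(config) - allowed
    if unknown:
        raise RegistryError(f"unknown registry config keys: {sorted(unknown)}")
    kwargs = {k: tuple(v) for k, v in config.items()}
    return ComponentRegistry(**kwargs)


def build_feature_index(registry: ComponentRegistry) -> list[FeatureKey]:
    """The full ordered feature index: the Cartesian product in registry order."""
    return [
        FeatureKey(s, r, t, f)
        for s, r, t, f in itertools.product(
            registry.sequences, registry.regions, registry.transforms, registry.formulas
        )
    ]


def count_vois(registry: ComponentRegistry) -> int:
    """Number of volumes of interest: |sequences| * |regions| * |transforms|."""
    return len(registry.sequences) * len(registry.regions) * len(registry.transforms)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Subjects x features matrix with component-annotated columns.

    ``labels`` are 0 (Group1) / 1 (Group2).  Column order is the key order;
    duplicate keys are rejected.
    """

    values: np.ndarray
    keys: tuple[FeatureKey, ...]
    subject_ids: tuple[str, ...]
    labels: np.ndarray
    _key_index: dict[FeatureKey, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.keys = tuple(self.keys)
        self.subject_ids = tuple(str(s) for s in self.subject_ids)
        if self.values.ndim != 2:
            raise ValueError("feature table values must be 2D (subjects x features)")
        n, p = self.values.shape
        if len(self.keys) != p:
            raise ValueError(f"{len(self.keys)} keys for {p} columns")
        if len(self.subject_ids) != n or self.labels.shape != (n,):
            raise ValueError("subject_ids/labels length must match the row count")
        if len(set(self.keys)) != len(self.keys):
            raise TableFormatError("duplicate feature keys in table")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0 = Group1, 1 = Group2)")
        self._key_index = {k: i for i, k in enumerate(self.keys)}

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column_of(self, key: FeatureKey) -> int:
        return self._key_index[key]

    def subset_columns(self, indices: Sequence[int]) -> "FeatureTable":
        indices = list(indices)
        return FeatureTable(
            values=self.values[:, indices],
            keys=tuple(self.keys[i] for i in indices),
            subject_ids=self.subject_ids,
            labels=self.labels,
        )

    def subset_rows(self, indices: Sequence[int]) -> "FeatureTable":
        indices = list(indices)
        return FeatureTable(
            values=self.values[indices],
            keys=self.keys,
            subject_ids=tuple(self.subject_ids[i] for i in indices),
            labels=self.labels[indices],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[k.column_name for k in self.keys])
        df.insert(0, "subject_id", self.subject_ids)
        df.insert(1, "label", [GROUP_LABELS[l] for l in self.labels])
        return df

    def write_csv(self, path: str | Path) -> None:
        path = Path(path)
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        self.to_dataframe().to_csv(path, sep=sep, index=False)


def _parse_labels(raw_labels: Sequence) -> np.ndarray:
    """Map a label column to {0, 1}.

    Accepted encodings (decided from the whole column, not per cell):
    Group1/Group2, {0, 1} (kept as-is) and {1, 2} (mapped to {0, 1}).
    """
    texts = [str(v).strip() for v in raw_labels]
    lowered = {t.lower() for t in texts}
    if lowered <= {"group1", "group2"}:
        return np.array([0 if t.lower() == "group1" else 1 for t in texts])
    if lowered <= {"0", "1"}:
        return np.array([int(t) for t in texts])
    if lowered <= {"1", "2"}:
        return np.array([int(t) - 1 for t in texts])
    bad = sorted(lowered - {"group1", "group2", "0", "1", "2"})
    raise TableFormatError(f"cannot interpret label values {bad}")


def read_annotated_table(
    path: str | Path,
    registry: ComponentRegistry | None = None,
    validate: bool = True,
) -> FeatureTable:
    """Read a component-annotated CSV/TSV feature table.

    The file needs ``subject_id`` and ``label`` columns; every other column
    header must be the four components joined by ``|``.  Component names are
    validated against ``registry`` (the packaged default when omitted);
    pass ``validate=False`` to accept arbitrary names (the registry is then
    reconstructed from the columns).  Labels may be Group1/Group2, {0,1}
    or {1,2}.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    for required in ("subject_id", "label"):
        if required not in df.columns:
            raise TableFormatError(f"missing required column {required!r}")
    feature_cols = [c for c in df.columns if c not in ("subject_id", "label")]
    if not feature_cols:
        raise TableFormatError("table has no feature columns")
    keys = tuple(FeatureKey.from_column(c) for c in feature_cols)
    if validate:
        reg = registry if registry is not None else default_registry()
        for col, key in zip(feature_cols, keys):
            if not reg.contains(key):
                raise TableFormatError(
                    f"column {col!r} uses component names outside the registry"
                )
    labels = _parse_labels(list(df["label"]))
    values = np.empty((len(df), len(feature_cols)))
    for j, col in enumerate(feature_cols):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError) as exc:
            raise TableFormatError(f"non-numeric value in column {col!r}: {exc}") from exc
    return FeatureTable(
        values=values,
        keys=keys,
        subject_ids=tuple(df["subject_id"].astype(str)),
        labels=labels,
    )
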