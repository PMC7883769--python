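"""Synthetic data generators emulating the study's two input kinds.

Two generators make the whole stack testable without any real MRI:

* :func:`gen_planted_table` draws a structured feature table with
  *component-consistent* signal blocks: every feature whose four components
  fall inside a block gets a class-dependent mean shift (effect size delta,
  in sd units) and a within-block equicorrelation (rho, via a shared latent
  factor); all other features are unit-variance Gaussian noise.  The cohort
  shape defaults to 25 vs 21 subjects, and the default signal placement
  concentrates on the FLAIR sequence, T2-abnormality region and 1 mm LoG
  transform — the configuration the selector is expected to recover.

* :func:`gen_phantom_subject` builds a four-sequence phantom with nested
  ellipsoidal tumor compartments (necrotic core, enhancing rim,
  non-enhancing shell, edema halo).  The two classes differ *only* in the
  sharpness of the halo's intensity boundary: a sigmoid edge of width 0.5 mm
  (sharp, class Group1) versus 3 mm (diffuse/infiltrative, class Group2).
  Everything else — geometry up to per-subject jitter, intensity plateaus,
  noise — is class-independent, so any downstream discrimination must come
  from boundary contour information.

Both generators are deterministic given their seed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .feature_space import (
    ComponentRegistry,
    FeatureKey,
    FeatureTable,
    build_feature_index,
)
from .volumes import (
    LABEL_ENHANCING,
    LABEL_NECROSIS,
    LABEL_T2_ABNORMALITY,
    SEQUENCE_NAMES,
    SubjectVolumes,
    minmax_normalize,
    write_subject,
)

logger = logging.getLogger(__name__)

__all__ = [
    "reduced_registry",
    "SignalBlock",
    "PlantedTableSpec",
    "gen_planted_table",
    "PhantomSpec",
    "gen_phantom_subject",
    "gen_cohort",
]


def reduced_registry() -> ComponentRegistry:
    """A desk-scale registry: 4 sequences x 5 regions x 6 transforms x 12 formulas.

    1,440 features; the component counts (3, 3, 4, 8) still materialize 288
    features on it, so selection behaves exactly as on the full space.
    """
    return ComponentRegistry(
        transforms=("identity", "log_1mm", "log_3mm", "haar_lll", "haar_hhh", "gradient_magnitude"),
        formulas=(
            "mean", "variance", "skewness", "kurtosis", "p90", "energy", "entropy",
            "uniformity", "glcm_contrast", "glcm_cluster_shade", "glcm_correlation", "glcm_imc1",
        ),
    )


# ---------------------------------------------------------------------------
# Planted feature tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignalBlock:
    """A component-consistent block of signal-carrying features."""

    sequences: tuple[str, ...]
    regions: tuple[str, ...]
    transforms: tuple[str, ...]
    formulas: tuple[str, ...]

    def matches(self, key: FeatureKey) -> bool:
        return (
            key.sequence in self.sequences
            and key.region in self.regions
            and key.transform in self.transforms
            and key.formula in self.formulas
        )


# Signal placement: one block per discriminative sequence, both concentrated
# on the T2-abnormality/tumor-core regions under the LoG-1mm and Haar
# transforms.  Block width matters: with ~46 subjects a single feature at
# d = 1 sd is indistinguishable from the extreme order statistics of >1000
# noise features, so recoverable signal must span several features per
# planted component — which is exactly the structural assumption the
# component-frequency selector exploits.
_BLOCK_FORMULAS = ("skewness", "kurtosis", "glcm_contrast", "glcm_cluster_shade")
_BLOCK_REGIONS = ("t2_abnormality", "tumor_core")
_BLOCK_TRANSFORMS = ("log_1mm", "haar_lll")

DEFAULT_BLOCKS = (
    SignalBlock(("FLAIR",), _BLOCK_REGIONS, _BLOCK_TRANSFORMS, _BLOCK_FORMULAS),
    SignalBlock(("T1ce",), _BLOCK_REGIONS, _BLOCK_TRANSFORMS, _BLOCK_FORMULAS),
)


@dataclass(frozen=True)
class PlantedTableSpec:
    """Study conditions for the planted-signal table generator.

    Defaults mirror the cohort shape (25 vs 21 subjects) with two signal
    blocks, a per-feature mean shift of 1 sd between classes and moderate
    within-block correlation.
    """

    n_per_class: tuple[int, int] = (25, 21)
    registry: ComponentRegistry = field(default_factory=reduced_registry)
    blocks: tuple[SignalBlock, ...] = DEFAULT_BLOCKS
    effect_size: float = 1.0
    correlation: float = 0.3
    # per-feature scale heterogeneity (log-normal sigma): radiomic features
    # span orders of magnitude across transforms/formulas, so raw column
    # variance reflects scale, not class signal; 0 disables
    scale_sigma: float = 1.0

    def planted_components(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {"sequence": [], "region": [], "transform": [], "formula": []}
        for b in self.blocks:
            for cat, names in zip(out, (b.sequences, b.regions, b.transforms, b.formulas)):
                for n in names:
                    if n not in out[cat]:
                        out[cat].append(n)
        return {cat: tuple(v) for cat, v in out.items()}


def gen_planted_table(
    spec: PlantedTableSpec | None = None, seed: int = 0
) -> tuple[FeatureTable, dict]:
    """Draw a planted-signal table plus its ground-truth record.

    Group1 features in a signal block are shifted by +delta/2, Group2 by
    -delta/2 (in within-class sd units); within a block, features share a
    latent factor giving pairwise correlation rho.  Each column is finally
    multiplied by a feature-specific log-normal scale, emulating the
    heterogeneous magnitudes of real radiomic features (scale-invariant
    selectors are unaffected).  The truth record lists the signal keys and
    the planted component names per category.
    """
    spec = spec or PlantedTableSpec()
    registry = spec.registry
    index = build_feature_index(registry)
    for block in spec.blocks:
        for cat, names in (
            ("sequence", block.sequences), ("region", block.regions),
            ("transform", block.transforms), ("formula", block.formulas),
        ):
            unknown = set(names) - set(registry.category(cat))
            if unknown:
                raise ValueError(f"signal block references unknown {cat} names {sorted(unknown)}")

    n1, n2 = spec.n_per_class
    n = n1 + n2
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, len(index)))
    labels = np.array([0] * n1 + [1] * n2)
    shift = np.where(labels == 0, 0.5, -0.5) * spec.effect_size

    rho = spec.correlation
    signal_cols: list[int] = []
    for block in spec.blocks:
        cols = [i for i, k in enumerate(index) if block.matches(k)]
        signal_cols.extend(cols)
        z = rng.standard_normal(n)
        X[:, cols] = (
            np.sqrt(rho) * z[:, None]
            + np.sqrt(1.0 - rho) * X[:, cols]
            + shift[:, None]
        )

    if spec.scale_sigma > 0:
        scales = np.exp(rng.normal(0.0, spec.scale_sigma, size=len(index)))
        X = X * scales[None, :]

    table = FeatureTable(
        values=X,
        keys=tuple(index),
        subject_ids=tuple(f"S{i + 1:03d}" for i in range(n)),
        labels=labels,
    )
    truth = {
        "signal_columns": sorted(signal_cols),
        "signal_keys": ["|".join(index[i]) for i in sorted(signal_cols)],
        "components": spec.planted_components(),
        "effect_size": spec.effect_size,
        "correlation": spec.correlation,
        "seed": seed,
    }
    return table, truth


# ---------------------------------------------------------------------------
# Phantom volumes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and noise of the ellipsoidal tumor phantom.

    ``halo_axes`` are the semi-axes (mm) of the outermost (T2-abnormality
    halo) ellipsoid; the inner compartments are fixed fractions of it.  The
    class contrast is carried solely by ``sharp_width_mm`` versus
    ``diffuse_width_mm``, the physical width of the halo's sigmoid intensity
    edge.  Per-subject variability: relative jitter of the semi-axes and a
    translation of the tumor centre.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: float = 1.0
    halo_axes: tuple[float, float, float] = (22.0, 18.0, 15.0)
    core_frac: float = 0.40
    enhancing_frac: float = 0.55
    nonenhancing_frac: float = 0.68
    brain_frac: float = 0.88
    sharp_width_mm: float = 0.5
    diffuse_width_mm: float = 3.0
    noise_sd: float = 0.02
    axes_jitter: float = 0.10
    center_jitter_mm: float = 2.0


# plateau intensities per sequence (arbitrary units before normalization)
_BRAIN = {"T1": 0.55, "T1ce": 0.55, "T2": 0.40, "FLAIR": 0.40}
_HALO_CONTRAST = {"T1": -0.10, "T1ce": -0.08, "T2": 0.25, "FLAIR": 0.45}
_ENHANCING = {"T1": 0.45, "T1ce": 0.90, "T2": 0.55, "FLAIR": 0.55}
_NECROSIS = {"T1": 0.30, "T1ce": 0.05, "T2": 0.75, "FLAIR": 0.30}
_NONENHANCING = {"T1": 0.40, "T1ce": 0.45, "T2": 0.60, "FLAIR": 0.60}


def _ellipsoid_rho(shape: Sequence[int], center: np.ndarray, axes: np.ndarray) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    rho2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return np.sqrt(rho2)


def phantom_fields(
    spec: PhantomSpec,
    class_label: int,
    center: np.ndarray | None = None,
    axes: np.ndarray | None = None,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Noise-free intensity fields and the BraTS-style mask.

    Returns the closed-form (pre-noise, pre-normalization) sequence fields
    and the integer mask with labels {0, 1, 2, 4}.  ``center``/``axes``
    default to the grid centre and the spec's halo semi-axes.
    """
    shape = spec.shape
    center = np.asarray(center if center is not None else [n / 2.0 for n in shape])
    axes = np.asarray(axes if axes is not None else spec.halo_axes) / spec.spacing

    rho_halo = _ellipsoid_rho(shape, center, axes)
    rho_enh = _ellipsoid_rho(shape, center, axes * spec.enhancing_frac)
    rho_core = _ellipsoid_rho(shape, center, axes * spec.core_frac)
    rho_nonenh = _ellipsoid_rho(shape, center, axes * spec.nonenhancing_frac)
    brain_axes = np.array([n / 2.0 for n in shape]) * spec.brain_frac
    rho_brain = _ellipsoid_rho(shape, np.array([n / 2.0 for n in shape]), brain_axes)
    brain = rho_brain <= 1.0

    necrosis = rho_core <= 1.0
    enhancing = (rho_enh <= 1.0) & ~necrosis
    nonenhancing = (rho_nonenh <= 1.0) & ~necrosis & ~enhancing
    edema = (rho_halo <= 1.0) & ~necrosis & ~enhancing & ~nonenhancing

    brats = np.zeros(shape, dtype=np.int16)
    brats[necrosis | nonenhancing] = 1
    brats[edema] = 2
    brats[enhancing] = 4
    brats[~brain] = 0

    width_mm = spec.sharp_width_mm if class_label == 0 else spec.diffuse_width_mm
    w_norm = width_mm / (float(np.mean(axes)) * spec.spacing)
    halo_profile = 1.0 / (1.0 + np.exp((rho_halo - 1.0) / w_norm))

    fields: dict[str, np.ndarray] = {}
    for seq in SEQUENCE_NAMES:
        vol = np.zeros(shape)
        vol[brain] = _BRAIN[seq]
        vol += np.where(brain, _HALO_CONTRAST[seq] * halo_profile, 0.0)
        vol[nonenhancing] = _NONENHANCING[seq]
        vol[enhancing] = _ENHANCING[seq]
        vol[necrosis] = _NECROSIS[seq]
        fields[seq] = vol
    return fields, brats


def gen_phantom_subject(
    spec: PhantomSpec,
    class_label: int,
    seed: int = 0,
    subject_id: str | None = None,
) -> tuple[SubjectVolumes, np.ndarray]:
    """One phantom subject: normalized volumes + base mask, and the BraTS mask.

    ``class_label`` 0 draws the sharp-edged halo, 1 the diffuse one.  Noise
    is i.i.d. Gaussian added inside the brain before normalization; geometry
    jitter perturbs the halo semi-axes and centre per subject.
    """
    if class_label not in (0, 1):
        raise ValueError("class_label must be 0 (sharp) or 1 (diffuse)")
    rng = np.random.default_rng(seed)
    axes = np.asarray(spec.halo_axes) * (1.0 + spec.axes_jitter * rng.uniform(-1, 1, size=3))
    center = np.array([n / 2.0 for n in spec.shape]) + rng.uniform(
        -spec.center_jitter_mm, spec.center_jitter_mm, size=3
    ) / spec.spacing
    limit = (np.asarray(spec.shape) / 2.0) * 0.95
    if np.any(axes / spec.spacing + np.abs(center - np.asarray(spec.shape) / 2.0) > limit):
        raise ValueError("phantom geometry does not fit in the grid")

    fields, brats = phantom_fields(spec, class_label, center=center, axes=axes)
    brain = next(iter(fields.values())) != 0
    volumes: dict[str, np.ndarray] = {}
    for seq in SEQUENCE_NAMES:
        vol = fields[seq].copy()
        if spec.noise_sd > 0:
            vol[brain] += rng.normal(0.0, spec.noise_sd, size=int(brain.sum()))
        volumes[seq] = minmax_normalize(vol, brain)

    base = np.zeros(spec.shape, dtype=np.int8)
    base[brats == 4] = LABEL_ENHANCING
    # label 1 covers necrotic core + non-enhancing shell; the core is the
    # dark-on-T1ce part, matching what the Otsu remap recovers
    rho_core = _ellipsoid_rho(spec.shape, center, (axes / spec.spacing) * spec.core_frac)
    necro = (brats == 1) & (rho_core <= 1.0)
    base[necro] = LABEL_NECROSIS
    base[(brats == 1) & ~necro] = LABEL_T2_ABNORMALITY
    base[brats == 2] = LABEL_T2_ABNORMALITY

    sid = subject_id or f"phantom-{class_label}-{seed}"
    subject = SubjectVolumes(
        subject_id=sid, volumes=volumes, mask=base, spacing=(spec.spacing,) * 3
    )
    return subject, brats


def gen_cohort(
    n_per_class: tuple[int, int] = (20, 20),
    spec: PhantomSpec | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> tuple[list[SubjectVolumes], np.ndarray, list[np.ndarray]]:
    """A reproducible phantom cohort; optionally written to disk as NIfTI.

    Returns (subjects, labels, brats_masks).  With ``outdir`` set, each
    subject is written to ``outdir/<subject_id>/{t1,t1ce,t2,flair,mask}.nii``
    (the mask in BraTS labels, exercising the remap on re-read) plus a
    cohort-level ``labels.csv``.
    """
    spec = spec or PhantomSpec()
    subjects: list[SubjectVolumes] = []
    labels: list[int] = []
    brats_masks: list[np.ndarray] = []
    i = 0
    for cls, n_cls in enumerate(n_per_class):
        for _ in range(int(n_cls)):
            sid = f"sub-{i:03d}"
            subject, brats = gen_phantom_subject(
                spec, cls, seed=int(np.random.default_rng([seed, i]).integers(2**31)), subject_id=sid
            )
            subjects.append(subject)
            labels.append(cls)
            brats_masks.append(brats)
            i += 1
    labels_arr = np.asarray(labels)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "labels.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["subject_id", "label"])
            for subject, cls in zip(subjects, labels):
                writer.writerow([subject.subject_id, f"Group{cls + 1}"])
        for subject, brats in zip(subjects, brats_masks):
            write_subject(outdir / subject.subject_id, subject.volumes, brats, spec.spacing)
    return subjects, labels_arr, brats_masks
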