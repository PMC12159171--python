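"""Automatic ROI selection by color-FA thresholding.

Given atlas-derived projection (CST) and association (SLF) labels already in
the subject's diffusion space, each in-label voxel is scored by how purely
its principal diffusion direction aligns with the axis the tract is supposed
to run along:

    score = (|V1_desired| - |V1_nuisance1| - |V1_nuisance2|) * FA

The desired axis is z (inferior-superior) for projection fibers and y
(anterior-posterior) for association fibers. Subtracting the nuisance
components before multiplying by FA pushes obliquely oriented or isotropic
voxels (CSF, cortex, crossing fibers) to low or negative scores; keeping the
top fraction (default 87%) of in-label voxels then yields orientation-pure
ROIs without manual placement. Hemispheres are processed independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import ConfigurationError, ROIError
from .tensor import DiffusionScalars

DEFAULT_FRACTION = 0.87

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}

#: Desired principal-eigenvector axis per tract kind (RAS convention).
DESIRED_AXIS = {"projection": "z", "association": "y"}


@dataclass
class LabelSet:
    """Per-hemisphere projection/association label masks in subject space."""

    hemispheres: dict  # {'left': {'projection': mask, 'association': mask}, ...}
    provenance: str = "unspecified"

    def validate(self, grid_shape: tuple | None = None) -> None:
        for hemi, kinds in self.hemispheres.items():
            for kind in ("projection", "association"):
                if kind not in kinds:
                    raise ConfigurationError(f"{hemi} hemisphere lacks a {kind} label")
                m = np.asarray(kinds[kind])
                if m.dtype != bool:
                    raise ConfigurationError(
                        f"{hemi}/{kind} label mask must be boolean")
                if grid_shape is not None and m.shape != tuple(grid_shape):
                    raise ConfigurationError(
                        f"{hemi}/{kind} label shape {m.shape} != grid {grid_shape}")
                if not m.any():
                    raise ROIError(f"{hemi}/{kind} label is empty")
            if np.any(kinds["projection"] & kinds["association"]):
                raise ConfigurationError(
                    f"{hemi} projection and association labels overlap")

    @classmethod
    def from_phantom_labels(cls, labels: dict,
                            provenance: str = "synthetic phantom") -> "LabelSet":
        return cls(hemispheres={h: dict(d) for h, d in labels.items()},
                   provenance=provenance)


@dataclass
class ROISet:
    """Final per-hemisphere ROIs after color-FA thresholding."""

    hemispheres: dict  # {'left': {'projection': mask, 'association': mask}}
    voxel_counts: dict  # {('left', 'projection'): int, ...}
    thresholds: dict  # realized score cutoffs, same keys
    fraction: float = DEFAULT_FRACTION
    warnings: list = dc_field(default_factory=list)


def restrict_label(label: np.ndarray, restriction: np.ndarray,
                   name: str = "label") -> np.ndarray:
    """Voxelwise intersection of a label with a restriction mask."""
    label = np.asarray(label, dtype=bool)
    restriction = np.asarray(restriction, dtype=bool)
    if label.shape != restriction.shape:
        raise ConfigurationError(
            f"restriction shape {restriction.shape} != label shape {label.shape}")
    out = label & restriction
    if not out.any():
        raise ROIError(f"restriction leaves {name} empty")
    return out


def color_fa_score(scalars: DiffusionScalars, desired_axis: str) -> np.ndarray:
    """Orientation-purity score (|V1_desired| - sum of nuisance |V1|) * FA.

    In-mask values lie in [-sqrt(2)*FA, FA] (the lower extreme is a V1
    fully in the nuisance plane at 45 degrees); voxels outside the scalar
    mask are set to -inf so they always rank last.
    """
    if desired_axis not in _AXIS_INDEX:
        raise ConfigurationError(
            f"desired_axis must be one of x/y/z, got {desired_axis!r}")
    k = _AXIS_INDEX[desired_axis]
    others = [i for i in range(3) if i != k]
    raw = (scalars.abs_v1[..., k]
           - scalars.abs_v1[..., others[0]]
           - scalars.abs_v1[..., others[1]]) * scalars.fa
    return np.where(scalars.mask, raw, -np.inf)


def threshold_top_fraction(score: np.ndarray, mask: np.ndarray,
                           fraction: float = DEFAULT_FRACTION):
    """Keep the ceil(fraction * N) highest-scoring in-mask voxels.

    Ties at the cutoff are broken deterministically by ascending linearized
    voxel index. Returns (mask, realized score threshold).
    """
    if not 0 < fraction <= 1:
        raise ConfigurationError("fraction must be in (0, 1]")
    mask = np.asarray(mask, dtype=bool)
    if score.shape != mask.shape:
        raise ConfigurationError("score and mask shapes differ")
    idx = np.flatnonzero(mask.ravel())
    if idx.size == 0:
        raise ROIError("thresholding received an empty mask")
    n = idx.size
    k = math.ceil(fraction * n)
    scores = score.ravel()[idx]
    # stable sort on descending score keeps equal scores in ascending
    # linear-index order, the stated tie-break
    order = np.argsort(-scores, kind="stable")
    kept = idx[order[:k]]
    out = np.zeros(mask.shape, dtype=bool).ravel()
    out[kept] = True
    return out.reshape(mask.shape), float(scores[order[k - 1]])


def select_rois(scalars: DiffusionScalars, labels: LabelSet,
                fraction: float = DEFAULT_FRACTION) -> ROISet:
    """Per-hemisphere ROI selection: score by tract-appropriate axis purity,
    then keep the top in-label fraction."""
    labels.validate(grid_shape=scalars.fa.shape)
    scores = {kind: color_fa_score(scalars, axis)
              for kind, axis in DESIRED_AXIS.items()}
    hemis: dict = {}
    counts: dict = {}
    thresholds: dict = {}
    for hemi, kinds in labels.hemispheres.items():
        hemis[hemi] = {}
        for kind in ("projection", "association"):
            roi, thr = threshold_top_fraction(scores[kind], kinds[kind], fraction)
            if not roi.any():
                raise ROIError(f"{hemi}/{kind} ROI is empty after thresholding")
            hemis[hemi][kind] = roi
            counts[(hemi, kind)] = int(roi.sum())
            thresholds[(hemi, kind)] = thr
    return ROISet(hemispheres=hemis, voxel_counts=counts,
                  thresholds=thresholds, fraction=fraction)
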