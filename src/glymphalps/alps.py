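"""ALPS-index computation.

The ALPS ("analysis along the perivascular space") index contrasts
diffusivity along the left-right (x) axis — the direction of perivascular
flow at the lateral-ventricle body — against diffusivity perpendicular to
both the fibers and that flow:

    ALPS = mean(Dxx_projection, Dxx_association)
         / mean(Dyy_projection, Dzz_association)

where each D is the ROI-mean scanner-axis diffusivity. Dyy in the
projection area and Dzz in the association area are each perpendicular to
the local fiber axis and to the x axis, so the ratio isolates the
perivascular contribution; an index of 1 means no preferential
perivascular-direction diffusion. The index is computed per hemisphere and
reported together with the arithmetic mean of the two hemispheres.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import ALPSError
from .roi import ROISet


@dataclass
class ALPSResult:
    """Per-hemisphere Eq. diffusivities and ALPS indices, plus their mean."""

    hemispheres: dict  # {'left': {'dxx_projection': ..., 'alps_index': ...}}
    mean_alps_index: float
    voxel_counts: dict
    n_nonfinite_excluded: int = 0
    warnings: list = dc_field(default_factory=list)

    def to_record(self) -> dict:
        """Flat JSON/CSV-friendly record."""
        rec: dict = {"mean_alps_index": self.mean_alps_index}
        for hemi, vals in self.hemispheres.items():
            for k, v in vals.items():
                rec[f"{hemi}_{k}"] = v
        for (hemi, kind), n in self.voxel_counts.items():
            rec[f"{hemi}_{kind}_n_voxels"] = n
        rec["n_nonfinite_excluded"] = self.n_nonfinite_excluded
        return rec


def roi_mean(volume: np.ndarray, roi: np.ndarray, name: str = "ROI"):
    """Arithmetic mean of a diffusivity map over the finite in-ROI voxels.

    Returns (mean, n_excluded) where n_excluded counts non-finite voxels
    dropped from the average.
    """
    roi = np.asarray(roi, dtype=bool)
    if volume.shape != roi.shape:
        raise ALPSError(f"{name}: map shape {volume.shape} != ROI {roi.shape}")
    if not roi.any():
        raise ALPSError(f"{name}: empty ROI")
    vals = volume[roi]
    finite = np.isfinite(vals)
    n_excluded = int((~finite).sum())
    if not finite.any():
        raise ALPSError(f"{name}: no finite voxels in ROI")
    return float(vals[finite].mean()), n_excluded


def alps_index(dxx_proj: float, dxx_assoc: float,
               dyy_proj: float, dzz_assoc: float) -> float:
    """The ALPS ratio from the four ROI-mean diffusivities."""
    for v in (dxx_proj, dxx_assoc, dyy_proj, dzz_assoc):
        if not np.isfinite(v) or v <= 0:
            raise ALPSError(f"non-positive or non-finite diffusivity: {v}")
    denom = 0.5 * (dyy_proj + dzz_assoc)
    if denom <= 0:
        raise ALPSError("non-positive ALPS denominator")
    return (0.5 * (dxx_proj + dxx_assoc)) / denom


def compute_alps(axis_maps, roiset: ROISet) -> ALPSResult:
    """ALPS-index per hemisphere and averaged.

    ``axis_maps`` is the (Dxx, Dyy, Dzz) triple from
    :func:`glymphalps.tensor.axis_diffusivities`. Non-finite voxels inside
    ROIs are excluded from the means (counted, not fatal).
    """
    dxx, dyy, dzz = axis_maps
    hemis: dict = {}
    n_excl = 0
    warnings: list = []
    for hemi, kinds in roiset.hemispheres.items():
        proj = kinds["projection"]
        assoc = kinds["association"]
        try:
            dxx_p, e1 = roi_mean(dxx, proj, f"{hemi}/projection Dxx")
            dyy_p, e2 = roi_mean(dyy, proj, f"{hemi}/projection Dyy")
            dxx_a, e3 = roi_mean(dxx, assoc, f"{hemi}/association Dxx")
            dzz_a, e4 = roi_mean(dzz, assoc, f"{hemi}/association Dzz")
        except ALPSError as err:
            raise ALPSError(f"{hemi} hemisphere: {err}") from err
        n_excl += e1 + e2 + e3 + e4
        idx = alps_index(dxx_p, dxx_a, dyy_p, dzz_a)
        hemis[hemi] = {
            "dxx_projection": dxx_p,
            "dxx_association": dxx_a,
            "dyy_projection": dyy_p,
            "dzz_association": dzz_a,
            "alps_index": idx,
        }
    if n_excl:
        warnings.append(f"{n_excl} non-finite voxels excluded from ROI means")
    mean_idx = float(np.mean([h["alps_index"] for h in hemis.values()]))
    return ALPSResult(hemispheres=hemis, mean_alps_index=mean_idx,
                      voxel_counts=dict(roiset.voxel_counts),
                      n_nonfinite_excluded=n_excl, warnings=warnings)
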