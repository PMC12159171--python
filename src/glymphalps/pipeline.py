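"""End-to-end orchestration: configuration, staging, manifest, provenance.

A run executes any contiguous sub-chain of
``simulate -> fit -> roi -> compute -> stats`` from a single structured
configuration, writing every stage's outputs plus a JSON manifest with the
package version, a config snapshot, input checksums, per-stage timings and
aggregated warnings. Deterministic stages reproduce bit-identical outputs
when re-run from the same manifest inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .alps import compute_alps
from .errors import ConfigurationError
from .io import (load_dwi, load_labels, read_cohort_csv, save_nifti,
                 save_tensor_field, write_cohort_csv, write_dwi, write_labels)
from .phantom import (CohortSpec, PhantomSpec, make_gradient_table,
                      simulate_cohort, simulate_tensor_field, tensor_to_dwi)
from .roi import DEFAULT_FRACTION, LabelSet, restrict_label, select_rois
from .stats import (ols_with_interaction, run_confounder_adjustment,
                    run_correlation_battery, run_group_comparisons,
                    run_posthoc_regressions)
from .tensor import axis_diffusivities, eigendecompose, fit_tensor

log = logging.getLogger("glymphalps")

STAGES = ("simulate", "fit", "roi", "compute", "stats")


@dataclass
class RunConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    stages: tuple = STAGES
    seed: int = 0
    out_dir: str = "glymphalps_out"
    # simulate
    n_directions: int = 30
    b_value: float = 1000.0
    n_b0: int = 1
    phantom: dict = dc_field(default_factory=dict)   # PhantomSpec overrides
    cohort: dict = dc_field(default_factory=dict)    # CohortSpec overrides
    # fit
    weighted_fit: bool = False
    dwi_path: str | None = None
    bvals_path: str | None = None
    bvecs_path: str | None = None
    mask_path: str | None = None
    # roi
    fraction: float = DEFAULT_FRACTION
    labels_dir: str | None = None
    restriction_dir: str | None = None
    # stats
    cohort_csv: str | None = None
    family_size: int = 14
    mc_permutations: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        order = [STAGES.index(s) for s in self.stages]
        if order != sorted(order) or (order and
                                      order != list(range(order[0], order[-1] + 1))):
            raise ConfigurationError(
                f"stages must form a contiguous chain of {STAGES}")
        if "simulate" not in self.stages:
            if "fit" in self.stages and not self.dwi_path:
                raise ConfigurationError(
                    "fit stage without simulate needs dwi_path/bvals/bvecs")
            if "roi" in self.stages and "fit" not in self.stages:
                raise ConfigurationError("roi stage needs a preceding fit stage")
            if "roi" in self.stages and not self.labels_dir:
                raise ConfigurationError("roi stage needs labels_dir")
            if "stats" in self.stages and len(self.stages) == 1 \
                    and not self.cohort_csv:
                raise ConfigurationError("stats-only run needs cohort_csv")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunManifest:
    version: str
    config: dict
    input_checksums: dict = dc_field(default_factory=dict)
    timings: dict = dc_field(default_factory=dict)
    warnings: dict = dc_field(default_factory=dict)
    outputs: dict = dc_field(default_factory=dict)
    status: str = "ok"
    failed_stage: str | None = None

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         default=str))


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _phantom_spec(config: RunConfig) -> PhantomSpec:
    spec = PhantomSpec(**config.phantom) if config.phantom else PhantomSpec()
    if "seed" not in config.phantom:
        spec.seed = config.seed
    return spec


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None
                 ) -> RunManifest:
    """Execute the configured stage chain; returns the run manifest.

    Stage failures abort the run with the failing stage named in the
    manifest (status='failed'); outputs written before the failure are
    listed but marked invalid.
    """
    config.validate()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    manifest = RunManifest(version=__version__, config=config.to_dict())
    for key in ("dwi_path", "bvals_path", "bvecs_path", "cohort_csv"):
        p = getattr(config, key)
        if p and Path(p).exists():
            manifest.input_checksums[key] = _sha256(p)

    state: dict = {}
    try:
        for stage in config.stages:
            t0 = time.perf_counter()
            log.info("stage %s", stage)
            _STAGE_FUNCS[stage](config, state, out, manifest)
            manifest.timings[stage] = time.perf_counter() - t0
    except Exception as err:
        manifest.status = "failed"
        manifest.failed_stage = stage
        manifest.warnings.setdefault(stage, []).append(str(err))
        manifest.write(out / "manifest.json")
        raise
    manifest.write(out / "manifest.json")
    return manifest


# --------------------------------------------------------------------------
# stage implementations
# --------------------------------------------------------------------------

def _stage_simulate(config, state, out, manifest):
    spec = _phantom_spec(config)
    gtab = make_gradient_table(config.n_directions, config.b_value,
                               config.n_b0, seed=config.seed)
    field, labels, truth = simulate_tensor_field(spec)
    dwi = tensor_to_dwi(field, gtab, s0=spec.s0, noise_sigma=spec.noise_sigma,
                        seed=spec.seed, voxel_size=spec.voxel_size)
    cohort_kwargs = dict(config.cohort)
    cohort_kwargs.setdefault("seed", config.seed)
    cohort = simulate_cohort(CohortSpec(**cohort_kwargs))
    write_dwi(dwi, out)
    write_labels(labels, out, affine=dwi.affine)
    write_labels({h: {k: m for k, m in d.items()}
                  for h, d in truth["restrictions"].items()},
                 out / "restrictions", affine=dwi.affine)
    write_cohort_csv(cohort, out / "cohort.csv")
    state.update(dwi=dwi, labels=labels, truth=truth, cohort=cohort,
                 affine=dwi.affine)
    manifest.outputs["simulate"] = [str(out / "dwi.nii.gz"),
                                    str(out / "cohort.csv")]


def _stage_fit(config, state, out, manifest):
    if "dwi" not in state:
        state["dwi"] = load_dwi(config.dwi_path, config.bvals_path,
                                config.bvecs_path)
        state["affine"] = state["dwi"].affine
    mask = None
    if config.mask_path:
        from .io import load_nifti
        mask, _ = load_nifti(config.mask_path)
        mask = mask.astype(bool)
    field = fit_tensor(state["dwi"], mask=mask, weighted=config.weighted_fit)
    scalars = eigendecompose(field)
    state.update(field=field, scalars=scalars)
    save_tensor_field(field, out / "tensor", affine=state.get("affine"))
    save_nifti(scalars.fa, out / "tensor" / "fa.nii.gz", state.get("affine"))
    save_nifti(scalars.md, out / "tensor" / "md.nii.gz", state.get("affine"))
    save_nifti(scalars.abs_v1, out / "tensor" / "abs_v1.nii.gz",
               state.get("affine"))
    dxx, dyy, dzz = axis_diffusivities(field)
    for name, vol in (("dxx", dxx), ("dyy", dyy), ("dzz", dzz)):
        save_nifti(vol, out / "tensor" / f"{name}.nii.gz", state.get("affine"))
    state["axis_maps"] = (dxx, dyy, dzz)
    if field.warnings:
        manifest.warnings["fit"] = list(field.warnings)
    manifest.outputs["fit"] = [str(out / "tensor")]


def _stage_roi(config, state, out, manifest):
    if "labels" not in state:
        state["labels"] = load_labels(config.labels_dir)
    labels = state["labels"]
    restrictions = None
    if config.restriction_dir:
        restrictions = load_labels(config.restriction_dir)
    elif "truth" in state:
        restrictions = state["truth"]["restrictions"]
    if restrictions is not None:
        labels = {h: {k: restrict_label(labels[h][k], restrictions[h][k],
                                        name=f"{h}/{k}")
                      for k in labels[h]} for h in labels}
    labelset = LabelSet.from_phantom_labels(labels)
    roiset = select_rois(state["scalars"], labelset, fraction=config.fraction)
    state["roiset"] = roiset
    roi_dir = out / "rois"
    write_labels(roiset.hemispheres, roi_dir, affine=state.get("affine"))
    sidecar = {
        "fraction": roiset.fraction,
        "voxel_counts": {f"{h}_{k}": v for (h, k), v in
                         roiset.voxel_counts.items()},
        "thresholds": {f"{h}_{k}": v for (h, k), v in
                       roiset.thresholds.items()},
    }
    (roi_dir / "rois.json").write_text(json.dumps(sidecar, indent=2))
    manifest.outputs["roi"] = [str(roi_dir)]


def _stage_compute(config, state, out, manifest):
    result = compute_alps(state["axis_maps"], state["roiset"])
    state["alps_result"] = result
    record = result.to_record()
    record["pipeline"] = {"fraction": config.fraction,
                          "weighted_fit": config.weighted_fit,
                          "version": __version__}
    (out / "alps.json").write_text(json.dumps(record, indent=2))
    if result.warnings:
        manifest.warnings["compute"] = list(result.warnings)
    manifest.outputs["compute"] = [str(out / "alps.json")]


def _stage_stats(config, state, out, manifest):
    if "cohort" in state:
        cohort = state["cohort"]
    else:
        cohort, warn = read_cohort_csv(config.cohort_csv, require_alps=True)
        if warn:
            manifest.warnings["stats-io"] = warn
    comparisons = run_group_comparisons(
        cohort, mc_permutations=config.mc_permutations, seed=config.seed)
    correlations = run_correlation_battery(cohort, m=config.family_size)
    interaction = ols_with_interaction(cohort)
    posthoc = run_posthoc_regressions(cohort)
    confounders = run_confounder_adjustment(cohort)
    stats_dir = out / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    import pandas as pd
    pd.DataFrame([dataclasses.asdict(c) for c in comparisons]).to_csv(
        stats_dir / "group_comparisons.csv", index=False)
    pd.DataFrame([dataclasses.asdict(c) for c in correlations]).to_csv(
        stats_dir / "correlations.csv", index=False)
    interaction.to_dataframe().to_csv(stats_dir / "regression_interaction.csv",
                                      index=False)
    for grp, tab in posthoc.items():
        tab.to_dataframe().to_csv(stats_dir / f"regression_{grp}.csv",
                                  index=False)
    confounders.to_dataframe().to_csv(stats_dir / "regression_confounders.csv",
                                      index=False)
    summary = {
        "coding": interaction.coding,
        "interaction_B": interaction.coefficient("ahi_x_group")["B"],
        "interaction_p": interaction.coefficient("ahi_x_group")["p"],
        "pd_alps_ahi_rho": next(
            (c.rho for c in correlations
             if c.variable == "ahi" and c.group == "PD"), None),
    }
    (stats_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    state["stats"] = {"comparisons": comparisons, "correlations": correlations,
                      "interaction": interaction, "posthoc": posthoc,
                      "confounders": confounders}
    manifest.outputs["stats"] = [str(stats_dir)]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "roi": _stage_roi,
    "compute": _stage_compute,
    "stats": _stage_stats,
}
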