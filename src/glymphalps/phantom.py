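"""Synthetic diffusion phantoms and simulated sleep/imaging cohorts.

The phantom realizes, in a small voxel grid, the white-matter geometry that
the ALPS construction relies on at the level of the lateral-ventricle body:
projection-fiber (corticospinal-tract-like) regions whose dominant diffusion
axis is inferior-superior (z), association-fiber (superior-longitudinal-
fasciculus-like) regions dominant along anterior-posterior (y), and an added
perivascular diffusivity component ``g`` on the left-right axis (x) in both —
perivascular flow around the medullary veins runs orthogonal to both fiber
systems. Axes follow the RAS convention. With transverse eigenvalue ``base``
and boost ``g``, the noiseless ground-truth ALPS-index of the phantom is
(base + g) / base.

The cohort simulator produces per-subject polysomnographic covariates and a
ground-truth ALPS value with a group-specific ALPS-AHI coupling, emulating a
de novo Parkinson's disease cohort with obstructive sleep apnea of varying
severity alongside matched controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .errors import ConfigurationError
from .tensor import DIFFUSIVITY_SCALE, DWIVolume, GradientTable, TensorField


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Box:
    """Axis-aligned voxel box with half-open bounds per axis."""

    x: tuple[int, int]
    y: tuple[int, int]
    z: tuple[int, int]

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(*self.x), slice(*self.y), slice(*self.z))

    @property
    def n_voxels(self) -> int:
        return ((self.x[1] - self.x[0]) * (self.y[1] - self.y[0])
                * (self.z[1] - self.z[0]))

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(grid_shape, dtype=bool)
        m[self.slices] = True
        return m

    def inside(self, grid_shape: tuple[int, int, int], margin: int = 0) -> bool:
        for (lo, hi), n in zip((self.x, self.y, self.z), grid_shape):
            if lo < margin or hi > n - margin or lo >= hi:
                return False
        return True


_DEFAULT_REGIONS = {
    "left": {
        "projection": Box((3, 9), (4, 10), (6, 14)),
        "association": Box((3, 9), (18, 24), (6, 14)),
    },
    "right": {
        "projection": Box((23, 29), (4, 10), (6, 14)),
        "association": Box((23, 29), (18, 24), (6, 14)),
    },
}


@dataclass
class PhantomSpec:
    """Parameters of the synthetic two-hemisphere fiber phantom.

    Diffusivities are in 1e-3 mm^2/s. ``perivascular_boost`` (g) is added to
    the x-axis diffusivity inside both fiber regions; ``impurity_fraction``
    of in-region voxels receive a randomly rotated copy of the fiber tensor,
    standing in for CSF/cortex contamination that color-FA thresholding has
    to reject.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 20)
    voxel_size: float = 2.0  # mm, isotropic
    regions: dict = dc_field(default_factory=lambda: {
        h: dict(d) for h, d in _DEFAULT_REGIONS.items()})
    base_diffusivity: float = 0.4
    fiber_diffusivity: float = 1.7
    perivascular_boost: float = 0.2
    background_diffusivity: float = 0.8
    impurity_fraction: float = 0.0
    s0: float = 1000.0
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("base_diffusivity", "fiber_diffusivity",
                     "background_diffusivity"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.fiber_diffusivity <= self.base_diffusivity:
            raise ConfigurationError(
                "fiber_diffusivity must exceed base_diffusivity")
        if self.perivascular_boost < 0:
            raise ConfigurationError("perivascular_boost must be >= 0")
        if not 0 <= self.impurity_fraction < 1:
            raise ConfigurationError("impurity_fraction must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.s0 <= 0:
            raise ConfigurationError("s0 must be > 0")
        boxes = [b for h in self.regions.values() for b in h.values()]
        # margin 1 so the one-voxel label dilation stays inside the grid
        for b in boxes:
            if not b.inside(self.grid_shape, margin=1):
                raise ConfigurationError(
                    f"region {b} does not fit inside grid {self.grid_shape} "
                    "with a one-voxel margin")
        occ = np.zeros(self.grid_shape, dtype=int)
        for b in boxes:
            occ[b.slices] += 1
        if np.any(occ > 1):
            raise ConfigurationError("phantom regions overlap")


# --------------------------------------------------------------------------
# gradient scheme
# --------------------------------------------------------------------------

def make_gradient_table(n_directions: int, b_value: float = 1000.0,
                        n_b0: int = 1, seed: int = 0,
                        n_iter: int = 300) -> GradientTable:
    """Repulsion-optimized diffusion-encoding scheme.

    Directions start from a seeded random draw on the sphere and are relaxed
    under an antipodally symmetric electrostatic energy, giving a
    well-spread, deterministic point set (the standard construction for
    "noncolinear" single-shell schemes). b=0 volumes come first.
    """
    if n_directions < 6:
        raise ConfigurationError(
            "at least 6 noncolinear directions are needed for a tensor fit")
    if b_value <= 0:
        raise ConfigurationError("b_value must be > 0")
    if n_b0 < 0:
        raise ConfigurationError("n_b0 must be >= 0")

    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n_directions, 3))
    g /= np.linalg.norm(g, axis=1, keepdims=True)
    step = 0.05
    for _ in range(n_iter):
        # force between antipodal pairs +-g_j acting on g_i
        diff_p = g[:, None, :] - g[None, :, :]
        diff_m = g[:, None, :] + g[None, :, :]
        dp = np.linalg.norm(diff_p, axis=-1)
        dm = np.linalg.norm(diff_m, axis=-1)
        np.fill_diagonal(dp, np.inf)
        np.fill_diagonal(dm, np.inf)
        force = (diff_p / dp[..., None] ** 3).sum(axis=1) \
            + (diff_m / dm[..., None] ** 3).sum(axis=1)
        # project force onto the tangent plane and take a small step
        force -= (force * g).sum(axis=1, keepdims=True) * g
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        g = g + step * force / norm
        g /= np.linalg.norm(g, axis=1, keepdims=True)
    b_values = np.concatenate([np.zeros(n_b0), np.full(n_directions, b_value)])
    directions = np.vstack([np.zeros((n_b0, 3)), g])
    table = GradientTable(b_values=b_values, directions=directions)
    table.validate(for_fitting=True)
    return table


# --------------------------------------------------------------------------
# tensor-field phantom
# --------------------------------------------------------------------------

def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def simulate_tensor_field(spec: PhantomSpec):
    """Build the phantom tensor field, its (deliberately sloppy) labels and
    a ground-truth record.

    Projection-region voxels carry diag(base+g, base, fiber); association
    regions diag(base+g, fiber, base); background is isotropic. Labels are
    the fiber boxes dilated by one voxel — emulating atlas labels that leak
    past the tract — while the truth record keeps the exact boxes as
    restriction masks. An ``impurity_fraction`` of in-region voxels gets the
    fiber tensor under a seeded uniform random rotation.

    Returns (TensorField, labels, truth) where ``labels`` maps hemisphere ->
    {'projection': mask, 'association': mask}.
    """
    spec.validate()
    grid = spec.grid_shape
    base, fib, g = (spec.base_diffusivity, spec.fiber_diffusivity,
                    spec.perivascular_boost)
    D = np.zeros(grid + (3, 3), dtype=float)
    for k in range(3):
        D[..., k, k] = spec.background_diffusivity

    tensors = {
        "projection": np.diag([base + g, base, fib]),
        "association": np.diag([base + g, fib, base]),
    }
    rng = np.random.default_rng(spec.seed)
    labels: dict = {}
    impurity_voxels: dict = {}
    structure = np.ones((3, 3, 3), dtype=bool)
    for hemi in sorted(spec.regions):
        labels[hemi] = {}
        for kind in ("projection", "association"):
            box = spec.regions[hemi][kind]
            D[box.slices] = tensors[kind]
            # plant impurities: floor(f*N) in-region voxels get a rotated tensor
            n_imp = int(np.floor(spec.impurity_fraction * box.n_voxels))
            coords = np.argwhere(box.mask(grid))
            imp_idx = rng.choice(box.n_voxels, size=n_imp, replace=False) \
                if n_imp else np.array([], dtype=int)
            for i in imp_idx:
                R = _random_rotation(rng)
                D[tuple(coords[i])] = R @ tensors[kind] @ R.T
            impurity_voxels[(hemi, kind)] = coords[imp_idx]
            labels[hemi][kind] = ndimage.binary_dilation(
                box.mask(grid), structure=structure)

    field = TensorField.from_matrices(D, s0=spec.s0)
    truth = {
        "g": g,
        "base_diffusivity": base,
        "fiber_diffusivity": fib,
        "expected_alps": (base + g) / base,
        "regions": {h: dict(d) for h, d in spec.regions.items()},
        "restrictions": {h: {k: b.mask(grid) for k, b in d.items()}
                         for h, d in spec.regions.items()},
        "impurity_voxels": impurity_voxels,
    }
    return field, labels, truth


def tensor_to_dwi(field: TensorField, gradients: GradientTable,
                  s0: float | np.ndarray | None = None,
                  noise_sigma: float = 0.0, seed: int = 0,
                  voxel_size: float = 2.0,
                  noise_model: str = "rician") -> DWIVolume:
    """Forward-simulate the DWI signal from a tensor field.

    Noiseless signal per voxel/volume is s0*exp(-b g^T D g); Rician noise
    (the magnitude-MRI noise law) corrupts it as sqrt((S+e1)^2 + e2^2) with
    iid Gaussian e1, e2 of scale ``noise_sigma``. A plain additive Gaussian
    model is available for debugging.
    """
    gradients.validate(for_fitting=False)
    if s0 is None:
        s0 = field.s0
    s0 = np.broadcast_to(np.asarray(s0, dtype=float), field.shape)
    if np.any(s0 <= 0):
        raise ConfigurationError("s0 must be > 0")
    if noise_model not in ("rician", "gaussian"):
        raise ConfigurationError(f"unknown noise model {noise_model!r}")

    D = field.as_matrices()
    g = gradients.directions
    b = gradients.b_values * DIFFUSIVITY_SCALE
    # quadratic form g^T D g for every voxel x volume
    q = np.einsum("...ij,vi,vj->...v", D, g, g)
    signal = s0[..., None] * np.exp(-b * q)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        e1 = rng.normal(0.0, noise_sigma, signal.shape)
        if noise_model == "rician":
            e2 = rng.normal(0.0, noise_sigma, signal.shape)
            signal = np.sqrt((signal + e1) ** 2 + e2 ** 2)
        else:
            signal = signal + e1
    return DWIVolume(signal=signal, gradients=gradients, voxel_size=voxel_size)


def simulate_phantom_dwi(spec: PhantomSpec, gradients: GradientTable | None = None):
    """Convenience wrapper: tensor field -> DWI in one call.

    Returns (DWIVolume, labels, truth).
    """
    if gradients is None:
        gradients = make_gradient_table(30, 1000.0, 1, seed=spec.seed)
    field, labels, truth = simulate_tensor_field(spec)
    dwi = tensor_to_dwi(field, gradients, s0=spec.s0,
                        noise_sigma=spec.noise_sigma, seed=spec.seed,
                        voxel_size=spec.voxel_size)
    return dwi, labels, truth


# --------------------------------------------------------------------------
# cohort simulator
# --------------------------------------------------------------------------

def _gamma_params(mean: float, sd: float) -> tuple[float, float]:
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return shape, scale


@dataclass
class CohortSpec:
    """Parameters of the simulated PD / control sleep-imaging cohort.

    Group marginals (age, BMI, AHI, ODI, PLMI, arousal index, sleep stages,
    TST, SL, SE) are matched to a 54-patient / 32-control de novo PD cohort;
    AHI-family variables use gamma marginals (nonnegative, right-skewed)
    tied together by a Gaussian copula with fixed rank correlations.
    Ground-truth ALPS is linear in age, sex and — in the patient group
    only — AHI, plus Gaussian residual noise.
    """

    n_pd: int = 54
    n_control: int = 32
    age_pd: tuple[float, float] = (58.9, 12.2)          # mean, sd (years)
    age_control: tuple[float, float] = (59.4, 8.3)
    male_frac_pd: float = 37 / 54
    male_frac_control: float = 22 / 32
    bmi_pd: tuple[float, float] = (27.5, 3.7)
    bmi_control: tuple[float, float] = (27.6, 4.0)
    ahi_pd: tuple[float, float] = (16.0, 19.9)          # events/h, gamma
    ahi_control: tuple[float, float] = (18.5, 15.8)
    odi_pd: tuple[float, float] = (14.2, 17.1)
    odi_control: tuple[float, float] = (13.9, 11.4)
    plmi_pd: tuple[float, float] = (8.9, 19.5)
    plmi_control: tuple[float, float] = (10.6, 23.0)
    arousal_pd: tuple[float, float] = (8.1, 7.2)
    arousal_control: tuple[float, float] = (16.6, 7.5)
    tst_pd: tuple[float, float] = (334.4, 90.0)         # min
    tst_control: tuple[float, float] = (332.1, 72.3)
    sl_pd: tuple[float, float] = (25.9, 37.3)
    sl_control: tuple[float, float] = (13.9, 13.0)
    se_pd: tuple[float, float] = (66.8, 21.5)           # %
    se_control: tuple[float, float] = (74.9, 14.6)
    # sleep-stage marginals (% of recording), normalized to sum to 100
    wake_pd: tuple[float, float] = (30.0, 20.4)
    wake_control: tuple[float, float] = (22.7, 13.8)
    n1_pd: tuple[float, float] = (7.9, 5.1)
    n1_control: tuple[float, float] = (8.6, 4.0)
    n2_pd: tuple[float, float] = (33.1, 12.6)
    n2_control: tuple[float, float] = (35.3, 9.9)
    n3_pd: tuple[float, float] = (16.7, 9.8)
    n3_control: tuple[float, float] = (17.4, 7.1)
    r_pd: tuple[float, float] = (12.2, 7.9)
    r_control: tuple[float, float] = (16.0, 7.0)
    # Gaussian-copula rank correlations to AHI
    rank_corr_odi: float = 0.8
    rank_corr_n1: float = 0.4
    rank_corr_arousal: float = 0.5
    # ALPS model
    baseline_alps: float = 1.72
    beta_age: float = -0.005      # ALPS units per year
    beta_sex: float = -0.116      # male vs female
    beta_ahi_pd: float = -0.004   # per event/h, patients only
    residual_sd: float = 0.10
    # comorbidity flags (patients only) and optional planted confounding
    rbd_prevalence: float = 0.35
    rls_prevalence: float = 0.10
    plms_prevalence: float = 0.30
    beta_rbd: float = 0.0         # ALPS shift in RBD-positive patients
    rbd_ahi_shift: float = 0.0    # AHI shift in RBD-positive patients
    seed: int = 0

    def validate(self) -> None:
        if self.n_pd <= 0 or self.n_control <= 0:
            raise ConfigurationError("group sizes must be > 0")
        if self.residual_sd < 0:
            raise ConfigurationError("residual_sd must be >= 0")
        for name in ("male_frac_pd", "male_frac_control", "rbd_prevalence",
                     "rls_prevalence", "plms_prevalence"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")


def _copula_block(rng: np.random.Generator, n: int, spec: CohortSpec,
                  group: str) -> dict:
    """Draw (AHI, ODI, N1, arousal) with gamma marginals tied by a copula."""
    rank_r = np.array([spec.rank_corr_odi, spec.rank_corr_n1,
                       spec.rank_corr_arousal])
    # Spearman -> Pearson correlation of the latent Gaussians
    rho = 2 * np.sin(np.pi / 6 * rank_r)
    C = np.eye(4)
    C[0, 1:] = C[1:, 0] = rho
    # off-diagonals among the dependents via shared factor: rho_i * rho_j
    for i in range(1, 4):
        for j in range(i + 1, 4):
            C[i, j] = C[j, i] = rho[i - 1] * rho[j - 1]
    L = np.linalg.cholesky(C)
    z = rng.standard_normal((n, 4)) @ L.T
    u = sps.norm.cdf(z)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    out = {}
    for col, name in zip(u.T, ("ahi", "odi", "n1", "arousal_index")):
        key = {"ahi": "ahi", "odi": "odi", "n1": "n1",
               "arousal_index": "arousal"}[name]
        mean, sd = getattr(spec, f"{key}_{group}")
        shape, scale = _gamma_params(mean, sd)
        out[name] = sps.gamma.ppf(col, shape, scale=scale)
    return out


def simulate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Simulate the per-subject cohort table.

    Columns: subject_id, group (PD/control), age, sex (F/M), bmi, ahi, odi,
    plmi, arousal_index, tst, sl, se, wake, n1, n2, n3, r, rbd, rls, plms,
    alps_true and alps (a copy of alps_true, the slot a measured index would
    fill). Stage percentages sum to 100 exactly per subject. Deterministic
    for a fixed seed.
    """
    if spec is None:
        spec = CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    frames = []
    for group, n in (("PD", spec.n_pd), ("control", spec.n_control)):
        gkey = "pd" if group == "PD" else "control"
        cop = _copula_block(rng, n, spec, gkey)
        age = rng.normal(*getattr(spec, f"age_{gkey}"), size=n)
        male = (rng.random(n) < getattr(spec, f"male_frac_{gkey}")).astype(int)
        bmi = np.clip(rng.normal(*getattr(spec, f"bmi_{gkey}"), size=n), 12, None)
        tst = np.clip(rng.normal(*getattr(spec, f"tst_{gkey}"), size=n), 0, 480)
        sl_shape, sl_scale = _gamma_params(*getattr(spec, f"sl_{gkey}"))
        sl = sps.gamma.rvs(sl_shape, scale=sl_scale, size=n, random_state=rng)
        se = np.clip(rng.normal(*getattr(spec, f"se_{gkey}"), size=n), 0, 100)
        plmi_m, plmi_s = getattr(spec, f"plmi_{gkey}")
        shape, scale = _gamma_params(plmi_m, plmi_s)
        plmi = sps.gamma.rvs(shape, scale=scale, size=n, random_state=rng)

        n1 = np.clip(cop["n1"], 0.0, 60.0)
        others = {}
        for st in ("wake", "n2", "n3", "r"):
            m, s = getattr(spec, f"{st}_{gkey}")
            sh, sc = _gamma_params(m, s)
            others[st] = sps.gamma.rvs(sh, scale=sc, size=n, random_state=rng)
        tot = sum(others.values())
        tot = np.where(tot <= 0, 1.0, tot)
        scale4 = (100.0 - n1) / tot
        for st in others:
            others[st] = others[st] * scale4

        if group == "PD":
            rbd = (rng.random(n) < spec.rbd_prevalence).astype(int)
            rls = (rng.random(n) < spec.rls_prevalence).astype(int)
            plms = (rng.random(n) < spec.plms_prevalence).astype(int)
        else:
            rbd = rls = plms = np.zeros(n, dtype=int)

        ahi = cop["ahi"] + spec.rbd_ahi_shift * rbd
        ahi = np.clip(ahi, 0.0, None)
        is_pd = 1 if group == "PD" else 0
        alps = (spec.baseline_alps
                + spec.beta_age * age
                + spec.beta_sex * male
                + spec.beta_ahi_pd * ahi * is_pd
                + spec.beta_rbd * rbd
                + rng.normal(0.0, spec.residual_sd, size=n))
        alps = np.maximum(alps, 1e-3)

        frames.append(pd.DataFrame({
            "subject_id": [f"{gkey}-{i:03d}" for i in range(n)],
            "group": group,
            "age": age,
            "sex": np.where(male == 1, "M", "F"),
            "bmi": bmi,
            "ahi": ahi,
            "odi": cop["odi"],
            "plmi": plmi,
            "arousal_index": cop["arousal_index"],
            "tst": tst,
            "sl": sl,
            "se": se,
            "wake": others["wake"],
            "n1": n1,
            "n2": others["n2"],
            "n3": others["n3"],
            "r": others["r"],
            "rbd": rbd,
            "rls": rls,
            "plms": plms,
            "alps_true": alps,
            "alps": alps,
        }))
    return pd.concat(frames, ignore_index=True)


def cohort_phantom_specs(table: pd.DataFrame,
                         template: PhantomSpec | None = None
                         ) -> list[PhantomSpec]:
    """One PhantomSpec per subject whose boost g reproduces that subject's
    ALPS under the noiseless forward model: g = base * (ALPS - 1)."""
    if template is None:
        template = PhantomSpec()
    specs = []
    for i, row in table.iterrows():
        g = template.base_diffusivity * (row["alps_true"] - 1.0)
        specs.append(replace(template, perivascular_boost=float(max(g, 0.0)),
                             seed=template.seed + i))
    return specs
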