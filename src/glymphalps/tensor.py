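"""Diffusion tensor estimation and derived scalar maps.

The diffusion tensor ``D`` is a symmetric positive semi-definite 3x3 matrix
per voxel, expressed throughout this package in units of 1e-3 mm^2/s. The
monoexponential signal model is

    S(b, g) = S0 * exp(-b * g^T D g)

with b in s/mm^2 and g a unit gradient direction, so the exponent carries an
implicit factor of 1e-3 (``DIFFUSIVITY_SCALE``). Fitting is log-linear least
squares on the log signal, the standard approach behind single-shell tensor
tools; the intercept of that fit is the per-voxel log S0 estimate.

Derived quantities follow the usual conventions: eigenvalues sorted
descending, fractional anisotropy

    FA = sqrt(3/2) * sqrt(sum_i (lambda_i - MD)^2) / sqrt(sum_i lambda_i^2)

with MD the eigenvalue mean, and the principal eigenvector V1 reported as
componentwise absolute values (the sign of an eigenvector is arbitrary and
magnitude maps are what the color-FA construction consumes).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import ConfigurationError, FitError

#: b-values are s/mm^2, diffusivities 1e-3 mm^2/s: the product b*D in the
#: signal exponent therefore carries this factor.
DIFFUSIVITY_SCALE = 1e-3

#: Storage order of the six unique tensor components.
COMPONENT_NAMES = ("dxx", "dyy", "dzz", "dxy", "dxz", "dyz")


@dataclass
class GradientTable:
    """Diffusion-encoding scheme: per-volume b-value and unit direction."""

    b_values: np.ndarray  # (n,), s/mm^2
    directions: np.ndarray  # (n, 3), unit vectors for b > 0

    def __post_init__(self) -> None:
        self.b_values = np.asarray(self.b_values, dtype=float).ravel()
        self.directions = np.asarray(self.directions, dtype=float)
        if self.directions.shape != (self.b_values.size, 3):
            raise ConfigurationError(
                f"gradient table shape mismatch: {self.b_values.size} b-values "
                f"vs directions of shape {self.directions.shape}"
            )

    @property
    def n_volumes(self) -> int:
        return self.b_values.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.b_values == 0

    def validate(self, for_fitting: bool = True) -> None:
        if np.any(self.b_values < 0):
            raise ConfigurationError("negative b-values in gradient table")
        dwi = ~self.b0_mask
        norms = np.linalg.norm(self.directions[dwi], axis=1)
        if norms.size and np.any(np.abs(norms - 1.0) > 1e-6):
            bad = int(np.argmax(np.abs(norms - 1.0) > 1e-6))
            raise ConfigurationError(
                f"non-unit gradient direction at diffusion-weighted volume {bad}"
            )
        if for_fitting:
            if not np.any(self.b0_mask):
                raise ConfigurationError("tensor fitting needs at least one b=0 volume")
            distinct = np.unique(np.round(self.directions[dwi], 6), axis=0)
            if distinct.shape[0] < 6:
                raise ConfigurationError(
                    "tensor fitting needs >= 6 distinct nonzero-b directions, "
                    f"got {distinct.shape[0]}"
                )


@dataclass
class DWIVolume:
    """A 4D diffusion-weighted acquisition plus its encoding scheme."""

    signal: np.ndarray  # (x, y, z, n_volumes), nonnegative
    gradients: GradientTable
    voxel_size: float = 2.0  # mm, isotropic
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ConfigurationError("DWI signal must be a 4D array")
        if self.signal.shape[3] != self.gradients.n_volumes:
            raise ConfigurationError(
                f"signal has {self.signal.shape[3]} volumes but gradient table "
                f"has {self.gradients.n_volumes}"
            )
        if self.affine is None:
            self.affine = np.diag([self.voxel_size] * 3 + [1.0])


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor (six unique components).

    ``components`` has shape grid + (6,), ordered per ``COMPONENT_NAMES``;
    units 1e-3 mm^2/s. ``s0`` is the fitted (or constructed) baseline signal,
    ``mask`` marks voxels with a valid tensor.
    """

    components: np.ndarray
    s0: np.ndarray
    mask: np.ndarray
    n_clamped: int = 0  # voxels whose negative eigenvalues were clamped to 0
    warnings: list = dc_field(default_factory=list)

    @property
    def shape(self) -> tuple:
        return self.components.shape[:-1]

    def as_matrices(self) -> np.ndarray:
        """Full 3x3 symmetric matrices, shape grid + (3, 3)."""
        c = self.components
        m = np.empty(c.shape[:-1] + (3, 3), dtype=float)
        m[..., 0, 0] = c[..., 0]
        m[..., 1, 1] = c[..., 1]
        m[..., 2, 2] = c[..., 2]
        m[..., 0, 1] = m[..., 1, 0] = c[..., 3]
        m[..., 0, 2] = m[..., 2, 0] = c[..., 4]
        m[..., 1, 2] = m[..., 2, 1] = c[..., 5]
        return m

    @classmethod
    def from_matrices(cls, m: np.ndarray, s0: np.ndarray | float = 1.0,
                      mask: np.ndarray | None = None) -> "TensorField":
        m = np.asarray(m, dtype=float)
        grid = m.shape[:-2]
        c = np.empty(grid + (6,), dtype=float)
        c[..., 0] = m[..., 0, 0]
        c[..., 1] = m[..., 1, 1]
        c[..., 2] = m[..., 2, 2]
        c[..., 3] = m[..., 0, 1]
        c[..., 4] = m[..., 0, 2]
        c[..., 5] = m[..., 1, 2]
        s0_arr = np.broadcast_to(np.asarray(s0, dtype=float), grid).copy()
        if mask is None:
            mask = np.ones(grid, dtype=bool)
        return cls(components=c, s0=s0_arr, mask=np.asarray(mask, dtype=bool))


@dataclass
class DiffusionScalars:
    """Eigenstructure-derived maps: eigenvalues, V1 magnitudes, FA, MD."""

    eigenvalues: np.ndarray  # grid + (3,), descending, 1e-3 mm^2/s
    v1: np.ndarray  # grid + (3,), unit principal eigenvector (sign arbitrary)
    abs_v1: np.ndarray  # grid + (3,), componentwise |V1| in [0, 1]
    fa: np.ndarray  # grid, unitless in [0, 1]
    md: np.ndarray  # grid, 1e-3 mm^2/s
    mask: np.ndarray
    warnings: list = dc_field(default_factory=list)


def design_matrix(gradients: GradientTable) -> np.ndarray:
    """Log-linear design: log S = X @ (log S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)."""
    b = gradients.b_values * DIFFUSIVITY_SCALE
    g = gradients.directions
    X = np.empty((gradients.n_volumes, 7), dtype=float)
    X[:, 0] = 1.0
    X[:, 1] = -b * g[:, 0] ** 2
    X[:, 2] = -b * g[:, 1] ** 2
    X[:, 3] = -b * g[:, 2] ** 2
    X[:, 4] = -2.0 * b * g[:, 0] * g[:, 1]
    X[:, 5] = -2.0 * b * g[:, 0] * g[:, 2]
    X[:, 6] = -2.0 * b * g[:, 1] * g[:, 2]
    return X


def _clamp_negative_eigenvalues(components: np.ndarray, mask: np.ndarray):
    """Reconstruct tensors whose eigenvalues dip below zero; returns count."""
    flat = components[mask]
    if flat.size == 0:
        return components, 0
    field = TensorField(components=flat.reshape(-1, 6),
                        s0=np.ones(flat.shape[0]),
                        mask=np.ones(flat.shape[0], dtype=bool))
    m = field.as_matrices()
    evals, evecs = np.linalg.eigh(m)
    neg = evals < 0
    n_clamped = int(np.any(neg, axis=-1).sum())
    if n_clamped:
        evals = np.clip(evals, 0.0, None)
        rebuilt = np.einsum("...ij,...j,...kj->...ik", evecs, evals, evecs)
        flat = TensorField.from_matrices(rebuilt).components
        out = components.copy()
        out[mask] = flat
        return out, n_clamped
    return components, 0


def fit_tensor(dwi: DWIVolume, mask: np.ndarray | None = None,
               weighted: bool = False) -> TensorField:
    """Estimate the diffusion tensor per voxel by log-linear least squares.

    Nonpositive signals are excluded from the affected voxel's fit; voxels
    left with fewer than 7 usable volumes are dropped from the output mask.
    ``weighted=True`` applies signal-magnitude weights (WLS), which
    downweights the noisiest log-domain observations.
    """
    dwi.gradients.validate(for_fitting=True)
    grid = dwi.signal.shape[:3]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid:
        raise ConfigurationError(
            f"mask shape {mask.shape} does not match grid {grid}")

    X = design_matrix(dwi.gradients)
    if np.linalg.matrix_rank(X) < 7:
        n_vox = int(mask.sum())
        raise FitError(
            f"rank-deficient gradient design (collinear directions); "
            f"{n_vox} voxels cannot be fitted")

    S = dwi.signal[mask]  # (n_vox, n_vol)
    n_vox = S.shape[0]
    coeffs = np.full((n_vox, 7), np.nan)
    usable = S > 0
    n_usable = usable.sum(axis=1)
    fit_ok = n_usable >= 7
    warnings: list = []

    full = fit_ok & np.all(usable, axis=1)
    if weighted:
        for i in np.flatnonzero(fit_ok):
            u = usable[i]
            w = S[i, u]
            Xw = X[u] * w[:, None]
            yw = np.log(S[i, u]) * w
            coeffs[i], *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    else:
        if np.any(full):
            sol, *_ = np.linalg.lstsq(X, np.log(S[full]).T, rcond=None)
            coeffs[full] = sol.T
        partial = fit_ok & ~full
        for i in np.flatnonzero(partial):
            u = usable[i]
            coeffs[i], *_ = np.linalg.lstsq(X[u], np.log(S[i, u]), rcond=None)

    n_dropped = int((~fit_ok).sum())
    if n_dropped:
        warnings.append(f"{n_dropped} voxels dropped (<7 usable volumes)")
    n_excluded = int(((~usable) & fit_ok[:, None]).sum())
    if n_excluded:
        warnings.append(
            f"{n_excluded} nonpositive signal samples excluded from fits")

    out_mask = mask.copy()
    out_mask[mask] = fit_ok
    components = np.zeros(grid + (6,), dtype=float)
    s0 = np.zeros(grid, dtype=float)
    comp_m = np.zeros((n_vox, 6))
    comp_m[fit_ok] = coeffs[fit_ok, 1:]
    s0_m = np.zeros(n_vox)
    s0_m[fit_ok] = np.exp(coeffs[fit_ok, 0])
    components[mask] = comp_m
    s0[mask] = s0_m

    components, n_clamped = _clamp_negative_eigenvalues(components, out_mask)
    if n_clamped:
        warnings.append(f"{n_clamped} voxels had negative eigenvalues clamped to 0")
    return TensorField(components=components, s0=s0, mask=out_mask,
                       n_clamped=n_clamped, warnings=warnings)


def eigendecompose(field: TensorField) -> DiffusionScalars:
    """Eigenstructure, |V1| maps, FA and MD from a fitted tensor field.

    Non-finite tensors are masked out (counted in ``warnings``). For the zero
    tensor FA is defined as 0; degenerate (tied) eigenvalues get a stable,
    arbitrary eigenvector whose absolute-value map is still well defined.
    """
    grid = field.shape
    finite = np.all(np.isfinite(field.components), axis=-1)
    mask = field.mask & finite
    warnings = list(field.warnings)
    n_bad = int((field.mask & ~finite).sum())
    if n_bad:
        warnings.append(f"{n_bad} voxels masked out (non-finite tensor components)")

    m = field.as_matrices()[mask]
    evals = np.zeros(grid + (3,), dtype=float)
    v1 = np.zeros(grid + (3,), dtype=float)
    fa = np.zeros(grid, dtype=float)
    md = np.zeros(grid, dtype=float)
    if m.shape[0]:
        w, v = np.linalg.eigh(m)  # ascending
        w = w[:, ::-1]
        princ = v[:, :, 2]  # eigenvector of the largest eigenvalue
        mean_d = w.mean(axis=1)
        num = np.sqrt(((w - mean_d[:, None]) ** 2).sum(axis=1))
        den = np.sqrt((w ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            fa_v = np.sqrt(1.5) * np.where(den > 0, num / den, 0.0)
        evals[mask] = w
        v1[mask] = princ
        fa[mask] = np.clip(fa_v, 0.0, 1.0)
        md[mask] = mean_d
    return DiffusionScalars(eigenvalues=evals, v1=v1, abs_v1=np.abs(v1),
                            fa=fa, md=md, mask=mask, warnings=warnings)


def axis_diffusivities(field: TensorField):
    """Scanner-frame axis diffusivities (Dxx, Dyy, Dzz).

    These are the diagonal tensor elements, i.e. e^T D e for the canonical
    axes — independent of eigenvector sign, and distinct from the sorted
    eigenvalues whenever the fiber is oblique to the scanner frame.
    Voxels outside the fit mask are returned as NaN.
    """
    out = []
    for k in range(3):
        vol = np.where(field.mask, field.components[..., k], np.nan)
        out.append(vol)
    return tuple(out)
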