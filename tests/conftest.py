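import numpy as np
import pytest

from glymphalps import (LabelSet, PhantomSpec, compute_alps, eigendecompose,
                        fit_tensor, make_gradient_table, select_rois)
from glymphalps.phantom import simulate_phantom_dwi
from glymphalps.roi import restrict_label
from glymphalps.tensor import axis_diffusivities


@pytest.fixture(scope="session")
def gtab30():
    """The acquisition scheme: 30 noncolinear directions at b=1000 plus b0."""
    return make_gradient_table(30, 1000.0, 1, seed=7)


def run_phantom_pipeline(spec: PhantomSpec, gradients=None, fraction=0.87):
    """Full simulate -> fit -> restrict -> select -> ALPS chain.

    Returns (ALPSResult, ROISet, truth record).
    """
    dwi, labels, truth = simulate_phantom_dwi(spec, gradients)
    field = fit_tensor(dwi)
    scalars = eigendecompose(field)
    restricted = {
        h: {k: restrict_label(labels[h][k], truth["restrictions"][h][k],
                              name=f"{h}/{k}")
            for k in labels[h]}
        for h in labels
    }
    roiset = select_rois(scalars, LabelSet.from_phantom_labels(restricted),
                         fraction=fraction)
    result = compute_alps(axis_diffusivities(field), roiset)
    return result, roiset, truth


@pytest.fixture(scope="session")
def pure_phantom_result(gtab30):
    """Noiseless default phantom (g=0.2) pushed through the whole chain."""
    return run_phantom_pipeline(PhantomSpec(perivascular_boost=0.2), gtab30)


def random_spd_tensors(rng, n, scale=1.0):
    """Random positive-definite tensors (1e-3 mm^2/s), eigenvalues in
    roughly the tissue range [0.1, 2.5]."""
    evals = rng.uniform(0.1, 2.5, size=(n, 3)) * scale
    a = rng.standard_normal((n, 3, 3))
    q, r = np.linalg.qr(a)
    sign = np.sign(np.einsum("nii->ni", r))
    q = q * sign[:, None, :]
    return np.einsum("nij,nj,nkj->nik", q, evals, q)
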