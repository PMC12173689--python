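import numpy as np
import pytest
from hypothesis import settings

import meshivive as mi
from meshivive import reference as ref

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def mesh_pore_pairs():
    """The three SEM-measured (mesh count, pore area) pairs."""
    return [(m, a) for m, a in ref.MEASURED_PORE_AREAS.items()]


@pytest.fixture(scope="session")
def weibull_rows():
    """(pore, a_max, alpha, beta) training rows for the parameter
    regressions (125/230/686 meshes)."""
    return [(ref.WEIBULL_TRAINING_PORES[m], w.a_max, w.alpha, w.beta)
            for m, w in ref.WEIBULL_BY_MESH.items()]


@pytest.fixture(scope="session")
def weibull_regressions(weibull_rows):
    return mi.fit_weibull_param_regressions(weibull_rows)


@pytest.fixture(scope="session")
def geometry():
    return mi.SystemGeometry()


@pytest.fixture(scope="session")
def diclofenac_params():
    return mi.default_metabolism_params("diclofenac")


@pytest.fixture(scope="session")
def diclofenac_fitspec():
    return mi.FitSpec(
        free=("parent_a_max", "metabolite_a_max", "cl_per_cell",
              "metabolite_fraction", "scaling_exponent"),
        fixed={"alpha": 1.56, "beta": -3.3})


@pytest.fixture(scope="session")
def noisy_diclofenac_data():
    """One seeded 10%-CV diclofenac dataset, shared by the fitting tests."""
    design = mi.diclofenac_design(noise_cv=0.10)
    return mi.generate_metabolism_dataset(design, seed=7)


@pytest.fixture(scope="session")
def noisy_diclofenac_fit(noisy_diclofenac_data, diclofenac_fitspec,
                         geometry):
    return mi.fit_metabolism(noisy_diclofenac_data, diclofenac_fitspec,
                             geometry, multistart=3, seed=0)


def rk4_states(rhs, y0, t_end, dt, sample_times):
    """Fixed-step RK4 oracle; returns states at the requested sample
    times (which must be ~multiples of dt)."""
    n_steps = int(round(t_end / dt))
    targets = {int(round(t / dt)): t for t in sample_times}
    y = np.asarray(y0, dtype=float)
    out = {}
    if 0 in targets:
        out[0] = y.copy()
    for i in range(1, n_steps + 1):
        t = (i - 1) * dt
        k1 = rhs(t, y)
        k2 = rhs(t + dt / 2, y + dt / 2 * k1)
        k3 = rhs(t + dt / 2, y + dt / 2 * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if i in targets:
            out[i] = y.copy()
    return np.array([out[int(round(t / dt))] for t in sample_times])
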