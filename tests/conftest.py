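import numpy as np
import pytest

from aortapwv import (
    CinePhantomSpec,
    CohortSpec,
    PhantomSpec,
    make_cine_phantom,
    make_flow_phantom,
    simulate_cohort,
)


def small_flow_spec(**overrides) -> PhantomSpec:
    """A short candy-cane phantom that keeps unit tests fast."""
    kw = dict(
        ascending_mm=40.0,
        arch_radius_mm=20.0,
        descending_mm=45.0,
        lumen_radius_mm=8.0,
        n_phases=30,
        true_pwv=5.0,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless short phantom: (field, true centerline, true mask)."""
    return make_flow_phantom(small_flow_spec())


@pytest.fixture(scope="session")
def cine_phantom():
    spec = CinePhantomSpec(dd_mm=24.0, delta_d_mm=2.0, blur_sd_px=0.8,
                           noise_sd=0.01, seed=1)
    series, truth = make_cine_phantom(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def cohort_df():
    return simulate_cohort(CohortSpec(seed=42))


def seeds_from_centerline(cl, spacing):
    """Voxel seeds at the true centerline endpoints."""
    sp = np.asarray(spacing)
    return (
        tuple(np.round(cl.points[0] / sp).astype(int)),
        tuple(np.round(cl.points[-1] / sp).astype(int)),
    )
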