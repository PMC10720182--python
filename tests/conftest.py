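import numpy as np
import pytest

from myoarch import dti, phantoms


@pytest.fixture(scope="session")
def default_phantom():
    """The default ventricular-wedge phantom (study conditions, seed 0)."""
    return phantoms.make_fiber_phantom(seed=0)


@pytest.fixture(scope="session")
def small_phantom():
    """A small wedge for fast Monte-Carlo style tests."""
    return phantoms.make_fiber_phantom(
        wedge_dims=(9.0, 6.0, 9.0), spacing=0.6,
        triangle_params={"base_width": 4.0, "depth": 4.0, "apex_extent": 6.0},
        seed=0,
    )


@pytest.fixture(scope="session")
def noiseless_fit(default_phantom):
    """Noiseless DWI simulation and tensor fit on the default phantom."""
    dwi = phantoms.simulate_dwi(default_phantom, scheme=phantoms.default_scheme())
    tf = dti.fit_tensor(dwi, mask=default_phantom.myocardium)
    return dwi, tf


def angles_deg(u, v):
    """Antipodal angle in degrees between paired unit vectors."""
    cosang = np.clip(np.abs((np.asarray(u) * np.asarray(v)).sum(-1)), 0.0, 1.0)
    return np.degrees(np.arccos(cosang))
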