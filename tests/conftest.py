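import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hemivol import PhantomSpec, generate_subject_phantom

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def small_spec(**overrides) -> PhantomSpec:
    """Small, noiseless phantom at 2 mm in-plane resolution with constant
    ellipse cross-sections, the geometry analytic-area oracles assume."""
    defaults = dict(
        nx=96, ny=96, dx=2.0, dy=2.0, n_slices=8,
        outer=(80.0, 60.0), inner=(48.0, 34.0), taper=0.0,
        noise_sd=0.0, seed=7,
    )
    defaults.update(overrides)
    return PhantomSpec.default(**defaults)


@pytest.fixture(scope="session")
def ring_blob_phantom():
    """Noiseless SAT ring + VAT blobs with symmetric left/right VAT."""
    spec = small_spec(vat_target=60.0, vat_left_fraction=0.5,
                      vat_margin=8.0, vat_blob_inplane=(8.0, 16.0),
                      vat_blob_axial=(12.0, 22.0))
    stack, truth = generate_subject_phantom(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def scoliosis_phantom():
    """Noiseless phantom with a known per-slice lateral body deviation."""
    n = 8
    sco = 3.0 * np.sin(2 * np.pi * np.arange(n) / n + 0.4)
    spec = small_spec(scoliosis=sco, vat_target=40.0, vat_margin=8.0,
                      vat_blob_inplane=(8.0, 14.0), vat_blob_axial=(12.0, 20.0))
    stack, truth = generate_subject_phantom(spec)
    return spec, stack, truth
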