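import numpy as np
import pytest

from scarquant.phantom import PhantomSpec, ScarSector, generate_phantom, spec_for_scar


@pytest.fixture(scope="session")
def small_spec():
    """Compact phantom: one 90-degree transmural scar on every slice."""
    return spec_for_scar(
        90.0, 1.0, rows=96, cols=96, n_slices=6,
        endo_radius_px=14.0, epi_radius_px=26.0,
    )


@pytest.fixture(scope="session")
def small_case(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def rim_case():
    """Phantom with a gray-zone rim around a transmural scar."""
    spec = spec_for_scar(
        90.0, 1.0, rows=96, cols=96, n_slices=6,
        endo_radius_px=14.0, epi_radius_px=26.0, gray_zone_rim_px=2.0,
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def subendo_case():
    """Phantom with a subendocardial half-wall scar (transmurality 0.5)."""
    spec = spec_for_scar(
        90.0, 0.5, rows=96, cols=96, n_slices=6,
        endo_radius_px=14.0, epi_radius_px=26.0,
    )
    return generate_phantom(spec)
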