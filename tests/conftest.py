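"""Shared fixtures: optical configurations and pre-rendered phantoms.

Session-scoped fixtures cache the more expensive phantom renders and
reconstructions so the suite stays fast; tests must not mutate them.
"""

import numpy as np
import pytest

import holovol as hv

SPHERE_ANALYTIC_UM3 = 4.0 / 3.0 * np.pi * 5.0**3  # 10 um sphere, 523.5988


@pytest.fixture(scope="session")
def silica_config() -> hv.OpticalConfig:
    """10 um silica microspheres (n=1.46) in PBS (n=1.34), 633 nm, 60x."""
    return hv.OpticalConfig(n_object=1.46, n_medium=1.34)


@pytest.fixture(scope="session")
def cell_config() -> hv.OpticalConfig:
    """Macrophage imaging: n_cell=1.38 in medium n=1.33, 633 nm, 60x."""
    return hv.OpticalConfig()


@pytest.fixture(scope="session")
def sphere_gt(silica_config) -> hv.GroundTruth:
    """10 um sphere phantom on a 256^2 grid at 0.0575 um/px."""
    spec = hv.PhantomSpec(kind="sphere", diameter_um=10.0)
    return hv.make_phantom(spec, (256, 256), silica_config)


@pytest.fixture(scope="session")
def cap_gt(cell_config) -> hv.GroundTruth:
    """Rounded-cell (spherical cap) phantom at the small-phenotype volume."""
    spec = hv.PhantomSpec(kind="spherical_cap", target_volume_um3=970.54)
    return hv.make_phantom(spec, (512, 512), cell_config)


@pytest.fixture(scope="session")
def sphere_hologram(sphere_gt, silica_config) -> hv.Hologram:
    """Noise-free, in-focus off-axis hologram of the 10 um sphere."""
    phase = hv.thickness_to_phase(sphere_gt, silica_config)
    return hv.render_hologram(
        phase, hv.default_carrier(silica_config), silica_config, seed=0
    )


@pytest.fixture(scope="session")
def cap_field(cap_gt, cell_config) -> hv.ComplexField:
    """Demodulated in-focus complex field of the cap phantom."""
    phase = hv.thickness_to_phase(cap_gt, cell_config)
    holo = hv.render_hologram(
        phase, hv.default_carrier(cell_config), cell_config, seed=0
    )
    spec = hv.fourier_spectrum(holo)
    return hv.filter_plus_one(spec, hv.locate_sideband(spec))
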