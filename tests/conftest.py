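import numpy as np
import pytest

from stalkscan.synthetic import SyntheticSpec, TransectionSpec, generate


@pytest.fixture(scope="session")
def clean_annulus():
    """Noise-free annulus: bright 200 pith (r=200) in a 120 rind (R=260)."""
    tspec = TransectionSpec(
        center=(380.0, 380.0),
        outer_radius_px=260,
        rind_thickness_px=60,
        pith_intensity=200,
        rind_intensity=120,
        n_bundles=0,
    )
    spec = SyntheticSpec(
        transections=(tspec,),
        illumination_gradient=0.0,
        noise_sigma=0.0,
        texture_amplitude=0.0,
        n_debris=0,
        seed=11,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def realistic_scan():
    """One default-realism section (gradient, noise, texture, debris)."""
    spec = SyntheticSpec(seed=42, transections=(TransectionSpec(n_bundles=120),))
    return generate(spec)


def disc_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
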