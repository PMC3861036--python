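import numpy as np
import pytest

from ureamd.synthetic import (SolventSpec, StickySpec, SyntheticSpec,
                              TelegraphSpec, build_toy_protein,
                              synthesize_trajectory)


@pytest.fixture(scope="session")
def helix16():
    """Ideal 16-residue poly-ALA helix: (system, native coordinates)."""
    return build_toy_protein("helix", 16)


@pytest.fixture(scope="session")
def telegraph_bundle():
    """Telegraph-contact bundle: 20 contacts, k_open = k_close = 1/ns."""
    spec = SyntheticSpec(seed=101, dt_ns=0.05, n_frames=2000,
                         protein="telegraph",
                         telegraph=TelegraphSpec(n_contacts=20,
                                                 k_open=1.0, k_close=1.0))
    return synthesize_trajectory(spec)


@pytest.fixture(scope="session")
def sticky_bundle():
    """Sticky-urea bundle with a scripted long binder (molecule 0)."""
    spec = SyntheticSpec(seed=102, dt_ns=0.05, n_frames=1500, protein="helix",
                         n_residues=16, box=(36.0, 36.0, 36.0),
                         solvent=SolventSpec(n_water=40, n_urea=40),
                         sticky=StickySpec(k_off=1.0),
                         long_binder=(0, 100, 1300))
    return synthesize_trajectory(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
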