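import pytest

from astroglt.glt1 import GLT1Params, IonState
from astroglt.hotspot import centered_field
from astroglt.membrane import MembraneParams
from astroglt.morphology import MorphologyConfig, build_reduced_morphology


@pytest.fixture(scope="session")
def default_params():
    return GLT1Params()


@pytest.fixture(scope="session")
def default_ions():
    return IonState()


@pytest.fixture(scope="session")
def mem_params():
    return MembraneParams()


@pytest.fixture(scope="session")
def small_graph():
    """Reduced morphology for fast coupled-simulation tests."""
    cfg = MorphologyConfig(n_branches=2, segments_per_branch=4,
                           leaflets_per_segment=2, arbor_radius_um=25.0,
                           target_sv_ratio=(0.5, 20.0))
    return build_reduced_morphology(cfg, seed=3)


@pytest.fixture(scope="session")
def short_field(small_graph):
    """Scaled stimulus protocol (same amplitudes, compressed timing)."""
    return centered_field(small_graph, distance_um=10.0,
                          k_onset=0.0, k_duration=150.0,
                          glu_onset=120.0, glu_duration=1.0)
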