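import pytest

from habsi import HabituationParams, build_toy_graph, make_stand_in_networks


@pytest.fixture(scope="session")
def ref_params():
    """The reference habituation kinetics: S=1, alpha=1.05, tau=5, y0=1."""
    return HabituationParams(S=1.0, alpha=1.05, tau=5.0, y0=1.0)


@pytest.fixture(scope="session")
def toy_graph():
    return build_toy_graph()


@pytest.fixture(scope="session")
def stand_ins():
    return make_stand_in_networks(20230412)
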