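import pytest

from vespadrive import ModelParams, PopulationState, wt_equilibrium


@pytest.fixture
def defaults() -> ModelParams:
    """Published default parameters (m=2.5, s=0.02, n=1500, λ=560, b=0)."""
    return ModelParams()


@pytest.fixture
def wt_eq_state(defaults) -> PopulationState:
    """All-wild-type summer census at the model's equilibrium density."""
    return PopulationState.wild_type(wt_equilibrium(defaults))


@pytest.fixture
def mixed_state() -> PopulationState:
    """A generic census with all six classes populated."""
    return PopulationState(
        q_ww_w=800.0,
        q_ww_i=120.0,
        q_wi_w=60.0,
        q_wi_i=30.0,
        q_ii_w=25.0,
        q_ii_i=15.0,
        z=0.9,
    )
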