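import numpy as np
import pytest

from imtkit import (
    HarmonicModelSpec,
    SystemSpec,
    TimeGrid,
    default_triad_model,
    generate_gap_ensemble,
)


@pytest.fixture(scope="session")
def triad():
    """Default four-state underdamped surrogate (spec, model)."""
    return default_triad_model()


@pytest.fixture(scope="session")
def one_mode_model():
    """Single-mode three-state model with known closed forms.

    States: 1 = ground (c = 0), 2 = initial j (c = 1.0), 3 = final k
    (c = 2.55), omega = 2/ps, eps_j - eps_k = -0.5 eV, T = 300 K.
    """
    return HarmonicModelSpec(
        frequencies=[2.0],
        couplings=[[0.0], [1.0], [2.55]],
        offsets=[0.0, 0.0, 0.5],
        temperature=300.0,
    )


@pytest.fixture(scope="session")
def small_emd(triad):
    """Small equilibrium ensemble on state 1 of the triad surrogate."""
    _, model = triad
    return generate_gap_ensemble(
        model, propagation_state=1, sampling_state=1,
        n=2000, grid=TimeGrid(101, 0.04), seed=91,
    )


@pytest.fixture()
def two_state_spec():
    return SystemSpec(
        n_states=2,
        labels=("D", "A"),
        ground_index=2,
        couplings=np.array([[0.0, 0.01], [0.01, 0.0]]),
        temperature=300.0,
    )
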