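import numpy as np
import pytest

from snnlat import FixtureSpec, LayerSpec, NetworkSpec, make_fixture


@pytest.fixture
def identity_neuron():
    """Single input neuron behind a pass-through dense layer (w=1)."""
    return NetworkSpec(
        [LayerSpec("dense", (1,), (1,), has_bias=False)],
        [np.array([[1.0]])],
        [None],
    )


@pytest.fixture
def identity_chain():
    """Two pass-through dense layers: stage rates should all track a^0."""
    layer = LayerSpec("dense", (1,), (1,), has_bias=False)
    w = np.array([[1.0]])
    return NetworkSpec([layer, layer], [w, w.copy()], [None, None])


@pytest.fixture(scope="session")
def positive_fixture():
    """Normalized 3-layer positive-drive net: decomposition is exact here."""
    spec = FixtureSpec(
        layer_sizes=(6, 10, 8, 5),
        n_inputs=4,
        weight_mode="positive",
        bias_mode="positive",
        drive="positive",
        seed=11,
    )
    return make_fixture(spec)


@pytest.fixture(scope="session")
def dyadic_fixture():
    """Small unnormalized net with dyadic weights: float-exact dynamics."""
    spec = FixtureSpec(
        layer_sizes=(4, 6, 3),
        n_inputs=3,
        weight_mode="positive",
        bias_mode="positive",
        drive="positive",
        dyadic=True,
        normalize=False,
        seed=7,
    )
    return make_fixture(spec)


@pytest.fixture(scope="session")
def mixed_fixture():
    """Mixed-sign weights: exercises silent neurons and the eps=0 branch."""
    spec = FixtureSpec(
        layer_sizes=(5, 8, 4),
        n_inputs=4,
        weight_mode="mixed",
        drive="any",
        input_range=(0.0, 0.9),
        seed=3,
    )
    return make_fixture(spec)
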