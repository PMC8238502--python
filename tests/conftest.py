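import numpy as np
import pytest

from isoflux.isocorrect import ElementFormula, TracerConfig


@pytest.fixture
def c2_formula():
    """Two-carbon fragment with no other atoms: binomial closed forms apply."""
    return ElementFormula({"C": 2}, n_tracer=2)


@pytest.fixture
def pure_tracer():
    return TracerConfig(element="C", purity=1.0)


@pytest.fixture
def tbdms_like_formula():
    """A silylated-fragment-like composition with a broad isotope envelope."""
    return ElementFormula({"C": 18, "H": 39, "O": 5, "Si": 3}, n_tracer=4)


def random_fraction_vector(rng: np.random.Generator, n: int) -> np.ndarray:
    x = rng.dirichlet(np.ones(n))
    return x
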