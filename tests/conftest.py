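import numpy as np
import pytest

from nucdep import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_coupled_model():
    """N=6 model with two couplings, plus a matching random sequence."""
    r = np.random.default_rng(42)
    model = synthetic.random_coupling_model(r, 6, n_couplings=2)
    seq = synthetic.random_sequence(r, 6)
    return model, seq


@pytest.fixture
def product_model():
    return synthetic.PairwiseCouplingModel(np.zeros((10, 4)), model_id="product")


def planted_pair_dependency(strength: float = 3.0, wobble: bool = True) -> float:
    """Smallest dependency a Watson-Crick coupling of given strength can
    produce at its pair, minimized over reference base combinations.

    Closed-form calibration constant for stem-calling thresholds on
    synthetic maps, computed on an isolated 2-position model via the
    brute-force oracle.
    """
    from nucdep.oracle import brute_force_dependency
    from nucdep.models import ALPHABET

    spec = synthetic.StemSpec(pairs=[(0, 1)], strength=strength, wobble=wobble)
    model = synthetic.make_stem_model(2, [spec])
    return min(
        brute_force_dependency(model, a + b, 0, 1)
        for a in ALPHABET
        for b in ALPHABET
    )
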