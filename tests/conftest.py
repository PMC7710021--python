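import numpy as np
import pytest

from nfkbrepo.motifs import BackgroundModel, LabelledSequence, PositionWeightMatrix


@pytest.fixture
def uniform_bg():
    return BackgroundModel.uniform()


@pytest.fixture
def ac_pwm():
    """2-position matrix with perfect 'AC' consensus."""
    return PositionWeightMatrix(id="M_AC", probs=np.array([[1, 0, 0, 0], [0, 1, 0, 0]], float))


@pytest.fixture
def random_pwm_factory():
    def make(seed: int, length: int = 6) -> PositionWeightMatrix:
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(4), size=length)
        return PositionWeightMatrix(id=f"M_rand{seed}", probs=probs)

    return make


@pytest.fixture
def random_seq_factory():
    def make(seed: int, length: int = 50, label: int = 0) -> LabelledSequence:
        rng = np.random.default_rng(seed)
        bases = "".join("ACGT"[i] for i in rng.integers(4, size=length))
        return LabelledSequence(f"s{seed}", bases, label)

    return make
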