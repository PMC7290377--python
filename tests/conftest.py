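import numpy as np
import pytest

from satkit import MutationModel, Sequence
from satkit.synth import _mutate_residues


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def mutated_copies(
    template: str, n: int, rate: float, seed: int, prefix: str = "m"
) -> list[Sequence]:
    """Independently mutated copies of one template (star phylogeny)."""
    r = np.random.default_rng(seed)
    model = MutationModel(substitution_rate=rate)
    return [Sequence(f"{prefix}{i}", _mutate_residues(template, model, r)) for i in range(n)]
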