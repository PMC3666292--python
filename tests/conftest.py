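import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from sspipe import SimSpec, simulate


@pytest.fixture(scope="session")
def small_dataset():
    """24 short simulated chains with structures and profiles."""
    return simulate(SimSpec(n_chains=24, length_range=(20, 40), seed=11))


@pytest.fixture(scope="session")
def trained_small(small_dataset):
    """A predictor trained at ws=7 on the small dataset (fast)."""
    from sspipe import SecondaryStructurePredictor

    chains = [c for c, _, _ in small_dataset]
    structures = [s for _, s, _ in small_dataset]
    profiles = {c.id: p for c, _, p in small_dataset}
    model = SecondaryStructurePredictor(window_size=7).fit(
        chains, structures, profiles
    )
    return model, small_dataset


def random_three_state(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("HEC"), size=length))
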