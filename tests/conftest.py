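import numpy as np
import pytest
from hypothesis import settings

from motifinfo.io import BehaviorProfile, Proteome

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def toy_proteome():
    return Proteome(
        [
            ("A", "MSPARQSPIK"),
            ("B", "KKRKLMNPQR"),
            ("C", "AAAAAAAAAA"),
            ("D", "MSPGRKKRKA"),
            ("E", "WYFVLIMCGA"),
        ]
    )


@pytest.fixture
def toy_behavior(toy_proteome):
    # A, D carry SP-like content; classes: 0 = "binder", 1 = "other"
    return BehaviorProfile(list(toy_proteome.ids), [0, 1, 1, 0, 1], ["binder", "other"])


def random_binary_profile(n, k, seed):
    """Presence vector with exactly k carriers at random positions."""
    rng = np.random.default_rng(seed)
    present = np.zeros(n, dtype=bool)
    present[rng.choice(n, size=k, replace=False)] = True
    return present
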