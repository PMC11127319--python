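import numpy as np
import pandas as pd
import pytest

from dmscore.data import screen_from_frame
from dmscore.preprocess import preprocess_screen
from dmscore.simulate import SimConfig, default_summary, simulate_screen


def make_screen(counts, mutation_types=None, positions=None, n_rounds=None, n_reps=None):
    """Assemble a small in-memory screen from a (V, T+1, R) count array."""
    counts = np.asarray(counts, dtype=float)
    V, Tp1, R = counts.shape
    if mutation_types is None:
        mutation_types = ["synonymous"] + ["missense"] * (V - 1)
    if positions is None:
        positions = list(range(1, V + 1))
    ann = pd.DataFrame(
        {
            "variant_id": [f"v{i}" for i in range(V)],
            "position": positions,
            "mutant": [f"m{i}" for i in range(V)],
            "mutation_type": mutation_types,
        }
    )
    return screen_from_frame(ann, counts, n_rounds or Tp1 - 1, n_reps or R)


@pytest.fixture(scope="session")
def sim_default():
    """One standard-mode simulated screen (V=300, T=3, R=3) with truth."""
    return simulate_screen(
        default_summary(), SimConfig(n_positions=20, n_mutants=15, seed=42)
    )


@pytest.fixture(scope="session")
def sim_preprocessed(sim_default):
    return preprocess_screen(sim_default.screen)
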