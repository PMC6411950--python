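import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from kmalpred.dataset import build_windows
from kmalpred.records import NEGATIVE, POSITIVE, PeptideWindow
from kmalpred.synthetic import SyntheticConfig, generate_proteome


def make_window(sequence: str, label: int = NEGATIVE, protein_id: str = "P1",
                position: int = 16) -> PeptideWindow:
    return PeptideWindow(sequence=sequence, label=label,
                         protein_id=protein_id, center_position=position)


@pytest.fixture(scope="session")
def small_truth():
    """A compact strong-effect proteome shared across tests."""
    return generate_proteome(SyntheticConfig(n_proteins=120, seed=11))


@pytest.fixture(scope="session")
def small_windows(small_truth):
    windows, _ = build_windows(small_truth.proteins, small_truth.sites)
    return windows


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
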