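import numpy as np
import pytest

from heteroscape import DemographicParams, SpeciesRegistry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    """Study demographic parameters: R0=15, K=150, alpha=3."""
    return DemographicParams()


@pytest.fixture
def registry():
    return SpeciesRegistry()


def as_arrays(state: dict[tuple[int, int], int], width: int):
    """(x, y)/species -> count dict to flat (patch, species, counts) arrays.

    ``state`` maps (patch_index, species_id) -> count.
    """
    items = sorted(state.items())
    patch = np.array([p for (p, _), _ in items], dtype=np.int64)
    species = np.array([s for (_, s), _ in items], dtype=np.int64)
    counts = np.array([c for _, c in items], dtype=np.int64)
    return patch, species, counts


def as_dict(patch, species, counts) -> dict[tuple[int, int], int]:
    return {
        (int(p), int(s)): int(c) for p, s, c in zip(patch, species, counts)
    }
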