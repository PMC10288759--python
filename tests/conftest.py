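import numpy as np
import pytest

from circguide.constructs import SpacerSet
from circguide.fixtures import (
    default_registry,
    discrimination_linkers,
    discrimination_registry,
    discrimination_spacer,
    toy_spacers,
)

RNG_BASES = np.array(list("ACGU"))


@pytest.fixture(scope="session")
def parts():
    """Default synthetic parts registry (polyAC fillers, hairpin motifs)."""
    return default_registry(seed=0)


@pytest.fixture(scope="session")
def spacer_one():
    return SpacerSet.single("toy", "ACCACAACCAAACCACCAACCAC")


@pytest.fixture(scope="session")
def spacer_panel():
    return toy_spacers(seed=0, n=5)


@pytest.fixture(scope="session")
def disc():
    """The engineered preserve-vs-invade screen fixture."""
    preserving, invading = discrimination_linkers()
    return {
        "parts": discrimination_registry(),
        "spacers": discrimination_spacer(),
        "preserving": preserving,
        "invading": invading,
    }


def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(RNG_BASES, size=n))
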