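import numpy as np
import pytest

from borealacid.speciation import DEFAULT_CONSTANTS, EquilibriumConstants, IonComposition


@pytest.fixture
def constants() -> EquilibriumConstants:
    return DEFAULT_CONSTANTS


@pytest.fixture
def circumneutral_lake() -> IonComposition:
    """A well-buffered lake whose solved pH is above 7."""
    return IonComposition(
        ca=300, mg=100, na=80, k=20, nh4=5, so4=60, cl=50, no3=5, f=2, toc=5
    )


@pytest.fixture
def acid_lake() -> IonComposition:
    """A poorly buffered, sulfate-impacted lake (solved pH well below 5)."""
    return IonComposition(
        ca=40, mg=15, na=30, k=5, nh4=1, so4=120, cl=30, no3=5, f=1, toc=8
    )


def random_composition(rng: np.random.Generator) -> IonComposition:
    """Random but solvable composition used by oracle-equivalence tests."""
    return IonComposition(
        ca=rng.uniform(0, 400),
        mg=rng.uniform(0, 150),
        na=rng.uniform(0, 150),
        k=rng.uniform(0, 40),
        nh4=rng.uniform(0, 10),
        so4=rng.uniform(0, 250),
        cl=rng.uniform(0, 150),
        no3=rng.uniform(0, 30),
        f=rng.uniform(0, 5),
        toc=rng.uniform(0, 32),
    )
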