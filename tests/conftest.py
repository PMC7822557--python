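import numpy as np
import pytest

from nuclattice.energy import EnergyTrack
from nuclattice.lattice import FactorSpec, LatticeSystem


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def _count_states(L: int, lens: list[int]) -> int:
    """DP count of non-overlapping placement configurations (any energies)."""
    c = [0] * (L + 1)
    c[0] = 1
    for i in range(1, L + 1):
        c[i] = c[i - 1] + sum(c[i - l] for l in lens if i >= l)
    return c[L]


def random_small_system(
    rng: np.random.Generator,
    max_L: int = 25,
    max_species: int = 3,
    max_states: int = 200_000,
) -> LatticeSystem:
    """A random tiny lattice suitable for exhaustive enumeration: redraws
    footprint sets whose state space would be too large to enumerate."""
    while True:
        L = int(rng.integers(5, max_L + 1))
        n = int(rng.integers(1, max_species + 1))
        lens = [int(rng.integers(2, 7)) for _ in range(n)]
        lens = [min(l, L) for l in lens]
        if _count_states(L, lens) <= max_states:
            break
    factors = []
    for k, l in enumerate(lens):
        e = rng.normal(0, 1.5, L - l + 1)
        factors.append(
            FactorSpec(
                EnergyTrack(f"f{k}", l, e),
                float(rng.uniform(0.05, 3.0)),
                float(rng.uniform(0.05, 2.0)),
            )
        )
    return LatticeSystem(L, factors)


@pytest.fixture
def toy_L6():
    """L=6 lattice with one zero-energy species of footprint 3 (Z = 6)."""
    track = EnergyTrack("tf", 3, np.zeros(4))
    return LatticeSystem(6, [FactorSpec(track, 1.0, 1.0)])
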