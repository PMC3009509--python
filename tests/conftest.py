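import itertools

import pytest

from seedsense import SpacedSeed


def all_seeds_of_length(m: int) -> list[SpacedSeed]:
    """Every valid seed of length m (both orientations), small m only."""
    if m == 1:
        return [SpacedSeed("1")]
    return [
        SpacedSeed("1" + "".join(mid) + "1")
        for mid in itertools.product("1*", repeat=m - 2)
    ]


@pytest.fixture(scope="session")
def small_seeds() -> list[SpacedSeed]:
    """All seeds with length ≤ 6 — exhaustively checkable against oracles."""
    return [s for m in range(1, 7) for s in all_seeds_of_length(m)]
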