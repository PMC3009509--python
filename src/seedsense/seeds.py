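"""Spaced seeds, binary homologous regions, and compatible-suffix machinery.

A spaced seed is a template over ``{1, *}`` used to filter candidate hits in
homology search: ``1`` requires a match at that offset, ``*`` is a don't-care.
By convention the first and last characters are ``1``.  A homologous region is
a binary match/mismatch string; the seed *hits* the region when some window
satisfies every required-match position.

This module also builds the state space shared by the hit-probability and
hit-integration dynamic programs: the set ``B`` of strings *compatible* with
the seed (right-aligned, every required position is 1) together with, for each
extension ``0b`` that falls outside ``B``, its longest compatible proper
prefix.  That prefix reduction is what keeps both recursions inside ``B``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from math import comb
from typing import Iterator

__all__ = [
    "SpacedSeed",
    "HomologousRegion",
    "CompatibleSuffixSet",
    "parse_seed",
    "reverse_seed",
    "canonical_form",
    "enumerate_seeds",
    "count_seeds",
    "build_suffix_set",
    "seed_hits_region",
]

# Lexicographic order used for canonicalization: '1' sorts before '*'.
_CANON_ORDER = str.maketrans("1*", "01")


def _canon_key(pattern: str) -> str:
    return pattern.translate(_CANON_ORDER)


@dataclass(frozen=True)
class SpacedSeed:
    """A spaced seed: a pattern over {1, *} starting and ending with '1'.

    Attributes
    ----------
    pattern : str
        The seed template, e.g. ``"111*1**1*1**11*111"``.
    """

    pattern: str

    def __post_init__(self) -> None:
        p = self.pattern
        if not p:
            raise ValueError("seed pattern must be non-empty")
        bad = set(p) - {"1", "*"}
        if bad:
            raise ValueError(
                f"seed pattern may only contain '1' and '*', got {sorted(bad)!r}"
            )
        if p[0] != "1" or p[-1] != "1":
            raise ValueError(
                "seed pattern must start and end with '1' "
                f"(got {p!r})"
            )

    @property
    def m(self) -> int:
        """Seed length (number of template positions)."""
        return len(self.pattern)

    @property
    def w(self) -> int:
        """Seed weight (number of required-match positions)."""
        return self.pattern.count("1")

    @property
    def ones(self) -> tuple[int, ...]:
        """0-based offsets of the required-match positions."""
        return tuple(i for i, c in enumerate(self.pattern) if c == "1")

    def __str__(self) -> str:
        return self.pattern


@dataclass(frozen=True)
class HomologousRegion:
    """A gap-free binary view of a pairwise alignment: 1 match, 0 mismatch."""

    bits: str

    def __post_init__(self) -> None:
        if set(self.bits) - {"0", "1"}:
            raise ValueError("region must be a string over {0, 1}")

    @property
    def L(self) -> int:
        return len(self.bits)

    @property
    def similarity(self) -> float:
        """Fraction of matching positions (ones / length)."""
        if not self.bits:
            return 0.0
        return self.bits.count("1") / len(self.bits)

    def __str__(self) -> str:
        return self.bits


def parse_seed(text: str) -> SpacedSeed:
    """Parse a seed pattern string, validating alphabet and end characters."""
    return SpacedSeed(text)


def reverse_seed(seed: SpacedSeed) -> SpacedSeed:
    """The mirror-image seed.

    Under the Bernoulli region model a seed and its reverse have identical
    sensitivity at every similarity level, so seed enumeration keeps only one
    of the pair.
    """
    return SpacedSeed(seed.pattern[::-1])


def canonical_form(seed: SpacedSeed) -> SpacedSeed:
    """The representative of {seed, reverse(seed)}.

    The lexicographically smaller pattern under the fixed character order
    '1' < '*' is chosen; palindromic seeds map to themselves.
    """
    rev = seed.pattern[::-1]
    if _canon_key(rev) < _canon_key(seed.pattern):
        return SpacedSeed(rev)
    return seed


def enumerate_seeds(weight: int, max_length: int) -> Iterator[SpacedSeed]:
    """Yield every canonical seed with the given weight and length ≤ max_length.

    Seeds are produced by length ascending, then lexicographically under the
    '1' < '*' order; of each (seed, reverse) pair only the canonical member is
    yielded, so reversal-equivalent duplicates never appear.
    """
    if weight < 1:
        raise ValueError("weight must be >= 1")
    if max_length < weight:
        raise ValueError("max_length must be >= weight")
    if weight == 1:
        # first == last == '1' forces m == 1
        yield SpacedSeed("1")
        return
    for m in range(weight, max_length + 1):
        patterns = []
        for ones in itertools.combinations(range(1, m - 1), weight - 2):
            chars = ["*"] * m
            chars[0] = chars[-1] = "1"
            for i in ones:
                chars[i] = "1"
            pat = "".join(chars)
            if _canon_key(pat) <= _canon_key(pat[::-1]):
                patterns.append(pat)
        patterns.sort(key=_canon_key)
        for pat in patterns:
            yield SpacedSeed(pat)


def count_seeds(weight: int, max_length: int) -> int:
    """Closed-form count of canonical seeds: (all + palindromes) / 2.

    With both end characters fixed to '1' there are C(m-2, w-2) seeds of
    length m; reversal pairs them up except for palindromes, hence the count
    of canonical representatives is (Σ_m C(m-2, w-2) + #palindromes) / 2.
    """
    if weight == 1:
        return 1 if max_length >= 1 else 0
    total = sum(comb(m - 2, weight - 2) for m in range(weight, max_length + 1))
    pal = 0
    for m in range(weight, max_length + 1):
        inner = m - 2  # positions free to vary, must themselves be palindromic
        k = weight - 2  # ones among them
        if inner % 2 == 0:
            if k % 2 == 0:
                pal += comb(inner // 2, k // 2)
        else:
            # odd inner length: the centre is free; parity of k fixes it
            half = inner // 2
            pal += comb(half, (k - (k % 2)) // 2) if k % 2 == 1 else comb(half, k // 2)
    return (total + pal) // 2


def seed_hits_region(seed: SpacedSeed, region: HomologousRegion | str) -> bool:
    """True iff some fully-contained window of the region matches the seed."""
    bits = region.bits if isinstance(region, HomologousRegion) else region
    m = seed.m
    ones = seed.ones
    for off in range(len(bits) - m + 1):
        if all(bits[off + j] == "1" for j in ones):
            return True
    return False


def _is_compatible(pattern: str, b: str) -> bool:
    """Right-aligned compatibility: b's overlap satisfies every required '1'."""
    m, k = len(pattern), len(b)
    for j in range(min(m, k)):
        if pattern[m - 1 - j] == "1" and b[k - 1 - j] != "1":
            return False
    return True


@dataclass(frozen=True)
class CompatibleSuffixSet:
    """The DP state space for one seed.

    ``members`` holds every string of length 0..m compatible with the seed
    (right-aligned), ordered by length then binary value.  ``prefix_map``
    maps each left extension ``0b`` (b a member, |0b| ≤ m) that is *not*
    itself compatible to its longest compatible proper prefix; the DPs use it
    to fold such states back into the table with a region-index shift of
    |0b| − |prefix|.
    """

    seed: SpacedSeed
    members: tuple[str, ...]
    prefix_map: dict[str, str] = field(hash=False)

    # transition tables, precomputed for the DP modules -------------------
    index: dict[str, int] = field(hash=False, repr=False)
    one_child: tuple[int, ...] = field(repr=False)  # per non-full member: idx of '1'+b
    zero_child: tuple[int, ...] = field(repr=False)  # idx of '0'+b or its reduction
    zero_shift: tuple[int, ...] = field(repr=False)  # region-index shift (0 if '0'+b ∈ B)

    @property
    def size(self) -> int:
        return len(self.members)

    def is_compatible(self, b: str) -> bool:
        return _is_compatible(self.seed.pattern, b)

    def longest_compatible_prefix(self, x: str) -> str:
        """Longest *proper* prefix of x compatible with the seed (ε qualifies)."""
        for k in range(len(x) - 1, -1, -1):
            if _is_compatible(self.seed.pattern, x[:k]):
                return x[:k]
        raise AssertionError("unreachable: the empty string is always compatible")


@lru_cache(maxsize=256)
def build_suffix_set(seed: SpacedSeed) -> CompatibleSuffixSet:
    """Enumerate the compatible set B and precompute the prefix reductions.

    Members of length ℓ are exactly the strings matching the last ℓ seed
    characters with '*' free, so |B| = Σ_ℓ 2^(stars in last ℓ) ≤ m·2^(m−w).
    """
    pattern = seed.pattern
    m = seed.m
    members: list[str] = []
    for ell in range(m + 1):
        tail = pattern[m - ell:]
        free = [t for t, c in enumerate(tail) if c == "*"]
        base = ["1" if c == "1" else "0" for c in tail]
        for assignment in itertools.product("01", repeat=len(free)):
            chars = base[:]
            for t, bit in zip(free, assignment):
                chars[t] = bit
            members.append("".join(chars))
    members_t = tuple(members)
    index = {b: i for i, b in enumerate(members_t)}

    prefix_map: dict[str, str] = {}
    one_child: list[int] = []
    zero_child: list[int] = []
    zero_shift: list[int] = []
    for b in members_t:
        if len(b) == m:
            continue  # full-length states are DP base cases, no transitions
        one_child.append(index["1" + b])
        x = "0" + b
        if x in index:
            zero_child.append(index[x])
            zero_shift.append(0)
        else:
            for k in range(len(x) - 1, -1, -1):
                if _is_compatible(pattern, x[:k]):
                    y = x[:k]
                    break
            prefix_map[x] = y
            zero_child.append(index[y])
            zero_shift.append(len(x) - len(y))
    return CompatibleSuffixSet(
        seed=seed,
        members=members_t,
        prefix_map=prefix_map,
        index=index,
        one_child=tuple(one_child),
        zero_child=tuple(zero_child),
        zero_shift=tuple(zero_shift),
    )
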