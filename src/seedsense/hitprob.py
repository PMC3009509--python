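"""Hit probability of a spaced seed on a Bernoulli region.

For a seed Q and a region of length L whose positions are i.i.d. matches with
probability p (the similarity level), the hit probability f[L, ε] is computed
by dynamic programming over the compatible-suffix states (i, b): the
probability that Q hits a region of total length i whose final |b| characters
are fixed to b and whose earlier characters are random.  The recursion
conditions on the character preceding b,

    f(i, b) = (1 − p)·f(i, 0b) + p·f(i, 1b),

with f = 1 once |b| = m (b then contains a hit), f = 0 when i < |b|, and an
incompatible left extension 0b folded back into the state space via its
longest compatible proper prefix b′ with the region index shifted to
i − |0b| + |b′| (no hit can end inside the discarded stretch).

All routines evaluate a whole grid of similarity levels in one pass; the DP
is vectorized over the grid with numpy.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .seeds import SpacedSeed, build_suffix_set

__all__ = ["hit_probability", "hit_probabilities", "sensitivity_curve"]

# grid chunk size: bounds the DP working set to ~(L+1)·|B|·_CHUNK doubles
_CHUNK = 128


@lru_cache(maxsize=64)
def _dp_layout(seed: SpacedSeed):
    """Group the suffix states by length and stage the transition arrays."""
    ss = build_suffix_set(seed)
    lengths = np.array([len(b) for b in ss.members])
    n_nonfull = int(np.sum(lengths < seed.m))
    one = np.asarray(ss.one_child, dtype=np.intp)
    zero = np.asarray(ss.zero_child, dtype=np.intp)
    shift = np.asarray(ss.zero_shift, dtype=np.intp)
    groups = []  # per length ℓ < m: (self_idx, one_idx, zero_idx, shift)
    for ell in range(seed.m):
        sel = np.flatnonzero(lengths[:n_nonfull] == ell)
        groups.append((sel, one[sel], zero[sel], shift[sel]))
    full_idx = np.flatnonzero(lengths == seed.m)
    eps_idx = ss.index[""]
    return ss, groups, full_idx, eps_idx


def hit_probabilities(
    seed: SpacedSeed, L: int, grid: "np.typing.ArrayLike"
) -> np.ndarray:
    """Hit probability of ``seed`` on a length-``L`` region at each similarity
    level in ``grid``; returns an array aligned with the grid."""
    ps = np.atleast_1d(np.asarray(grid, dtype=float))
    if ps.ndim != 1:
        raise ValueError("grid must be one-dimensional")
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("similarity levels must lie in [0, 1]")
    if L < 0:
        raise ValueError("region length must be non-negative")
    m = seed.m
    if L < m:
        return np.zeros_like(ps)

    _, groups, full_idx, eps_idx = _dp_layout(seed)
    n_states = full_idx[-1] + 1
    out = np.empty_like(ps)
    for lo in range(0, ps.size, _CHUNK):
        chunk = ps[lo: lo + _CHUNK]
        out[lo: lo + chunk.size] = _dp_chunk(
            chunk, L, m, groups, full_idx, eps_idx, n_states
        )
    return out


def _dp_chunk(ps, L, m, groups, full_idx, eps_idx, n_states):
    q = 1.0 - ps
    f = np.zeros((L + 1, n_states, ps.size))
    for i in range(L + 1):
        if i >= m:
            f[i, full_idx] = 1.0
        # states longer than the region stay 0; process |b| ≤ i, longest first
        for ell in range(min(i, m - 1), -1, -1):
            sel, one_idx, zero_idx, shift = groups[ell]
            if sel.size == 0:
                continue
            src1 = f[i, one_idx]
            isrc = i - shift
            src0 = f[np.maximum(isrc, 0), zero_idx]
            if np.any(isrc < 0):
                src0 = src0.copy()
                src0[isrc < 0] = 0.0
            f[i, sel] = q * src0 + ps * src1
    return f[L, eps_idx]


def hit_probability(seed: SpacedSeed, L: int, p: float) -> float:
    """Hit probability f[L, ε] at a single similarity level."""
    return float(hit_probabilities(seed, L, [p])[0])


def sensitivity_curve(
    seed: SpacedSeed, L: int, grid: "np.typing.ArrayLike"
) -> np.ndarray:
    """Hit probability along a grid of similarity levels.

    For an increasing grid the curve is non-decreasing: raising the match
    probability can only make hits more likely.
    """
    return hit_probabilities(seed, L, grid)
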