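"""Independent verification oracles for the sensitivity dynamic programs.

Because a length-L Bernoulli region has only 2^L outcomes, the hit
probability is exactly the polynomial

    f(L)(p) = Σ_k c_k · p^k (1 − p)^(L−k),

where c_k counts the hitting regions with k matches.  For small L the
polynomial is built by exhaustive enumeration with integer arithmetic, its
integral is an exact rational, and both serve as ground truth for the DP
implementations.  Riemann sums and Gauss–Legendre quadrature of the
hit-probability curve give two further, numerically independent routes to
the integral; since the integrand is a polynomial of degree ≤ L, a
Gauss–Legendre rule with ⌈(L+1)/2⌉ or more nodes is exact up to rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np

from .hitint import SimilarityRange
from .hitprob import hit_probabilities
from .seeds import SpacedSeed

__all__ = [
    "HitPolynomial",
    "exact_hit_polynomial",
    "exact_integral",
    "riemann_sum",
    "gauss_quadrature",
]

#: largest region length enumerated exhaustively (2^L regions)
DEFAULT_ENUMERATION_CAP = 16


@dataclass(frozen=True)
class HitPolynomial:
    """Exact hit probability of a seed at region length L, as a polynomial in p.

    ``coefficients[n]`` is the rational coefficient of pⁿ, n = 0..L.
    """

    seed: SpacedSeed
    L: int
    coefficients: tuple[Fraction, ...]

    def __call__(self, p: float) -> float:
        # Horner in float; coefficients are exact
        acc = 0.0
        for c in reversed(self.coefficients):
            acc = acc * p + float(c)
        return acc

    def evaluate_exact(self, p: Fraction) -> Fraction:
        acc = Fraction(0)
        for c in reversed(self.coefficients):
            acc = acc * p + c
        return acc

    def derivative_coefficients(self) -> tuple[Fraction, ...]:
        return tuple(
            n * c for n, c in enumerate(self.coefficients) if n > 0
        )


def exact_hit_polynomial(
    seed: SpacedSeed, L: int, cap: int = DEFAULT_ENUMERATION_CAP
) -> HitPolynomial:
    """Brute-force hit probability polynomial over all 2^L regions.

    Regions are integers with bit i ↔ position i; a window at offset s hits
    when every required-match bit of the shifted mask is set.  Hitting
    regions are tallied by their match count k and the mixture
    Σ c_k p^k(1−p)^(L−k) is expanded in the monomial basis with exact
    integer arithmetic.
    """
    if L > cap:
        raise ValueError(f"L={L} exceeds enumeration cap {cap}")
    if L < 0:
        raise ValueError("region length must be non-negative")
    m = seed.m
    mask = 0
    for j in seed.ones:
        mask |= 1 << j
    counts = np.zeros(L + 1, dtype=np.int64)  # hitting regions by number of 1s
    if L >= m:
        regions = np.arange(1 << L, dtype=np.uint64)
        umask = np.uint64(mask)
        hit = np.zeros(regions.size, dtype=bool)
        for s in range(L - m + 1):
            hit |= (regions >> np.uint64(s)) & umask == umask
        k = np.bitwise_count(regions[hit]).astype(np.intp)
        counts = np.bincount(k, minlength=L + 1)
    coeffs = [Fraction(0)] * (L + 1)
    for k, ck in enumerate(int(c) for c in counts):
        if ck == 0:
            continue
        # p^k (1-p)^(L-k) = Σ_j C(L-k, j) (-1)^j p^(k+j)
        for j in range(L - k + 1):
            coeffs[k + j] += ck * comb(L - k, j) * (-1) ** j
    return HitPolynomial(seed=seed, L=L, coefficients=tuple(coeffs))


def exact_integral(
    poly: HitPolynomial, rng: SimilarityRange | tuple[float, float]
) -> Fraction:
    """Exact rational ∫_a^b poly(p) dp, termwise on the monomial basis."""
    a, b = (rng.a, rng.b) if isinstance(rng, SimilarityRange) else rng
    fa, fb = Fraction(a), Fraction(b)
    total = Fraction(0)
    for n, c in enumerate(poly.coefficients):
        if c:
            total += c * (fb ** (n + 1) - fa ** (n + 1)) / (n + 1)
    return total


def riemann_sum(
    seed: SpacedSeed,
    L: int,
    rng: SimilarityRange,
    N: int,
    rule: str = "midpoint",
) -> float:
    """Riemann sum of the hit-probability curve over N equal sub-ranges.

    The default midpoint rule converges as 1/N² on this smooth integrand;
    ``rule`` may be "left" or "right" for first-order endpoint variants.
    Approximates the *raw* integral HI[0,b] − HI[0,a] (not range-averaged).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    h = rng.width / N
    if rule == "midpoint":
        pts = rng.a + (np.arange(N) + 0.5) * h
    elif rule == "left":
        pts = rng.a + np.arange(N) * h
    elif rule == "right":
        pts = rng.a + (np.arange(N) + 1.0) * h
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return float(np.sum(hit_probabilities(seed, L, pts)) * h)


def gauss_quadrature(
    seed: SpacedSeed, L: int, rng: SimilarityRange, nodes: int | None = None
) -> float:
    """Gauss–Legendre quadrature of the hit-probability curve over the range.

    Defaults to L nodes; ⌈(L+1)/2⌉ nodes already integrate the degree-≤L
    polynomial integrand exactly.  Approximates the raw integral.
    """
    if nodes is None:
        nodes = L
    if nodes < 1:
        raise ValueError("nodes must be >= 1")
    x, w = np.polynomial.legendre.leggauss(nodes)
    mid, half = (rng.a + rng.b) / 2.0, rng.width / 2.0
    pts = mid + half * x
    vals = hit_probabilities(seed, L, pts)
    return float(half * np.dot(w, vals))
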