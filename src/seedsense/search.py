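"""Seed-space evaluation: scoring, ranking, optima, and dominance amounts.

Seeds of equal weight trade sensitivity across similarity levels, and a seed
optimal at one level (the classical PH[0.7] criterion) need not be optimal
elsewhere.  Scoring by range-averaged hit integration HI[a, b] ranks seeds
by their mean sensitivity over a similarity band, and the signed difference
of two seeds' HI over a band quantifies *how much* one dominates the other
there — dominance-range analyses say only which seed wins.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

from .hitint import SimilarityRange, hit_integration_range
from .hitprob import hit_probability
from .seeds import SpacedSeed, _canon_key, enumerate_seeds

__all__ = [
    "SensitivityMeasure",
    "SeedScore",
    "score_seeds",
    "find_optimal",
    "compare_dominance",
]

#: warn above this many seeds in a full sweep (full w=11 spaces take hours)
DEFAULT_SWEEP_CAP = 100_000


@dataclass(frozen=True)
class SensitivityMeasure:
    """A seed-scoring rule: hit probability at a point, or HI over a range.

    Use the constructors: ``SensitivityMeasure.PH(0.7)`` for hit probability
    at similarity 0.7, ``SensitivityMeasure.HI(0.5, 1)`` for range-averaged
    hit integration.  ``L`` is the Bernoulli region length (default 64, the
    conventional random-region length for seed comparisons).
    """

    kind: str  # "hit_probability_at_point" | "hit_integration_over_range"
    L: int = 64
    point: float | None = None
    range: SimilarityRange | None = None

    def __post_init__(self) -> None:
        if self.kind == "hit_probability_at_point":
            if self.point is None or self.range is not None:
                raise ValueError("point measure requires `point` only")
        elif self.kind == "hit_integration_over_range":
            if self.range is None or self.point is not None:
                raise ValueError("range measure requires `range` only")
        else:
            raise ValueError(f"unknown measure kind {self.kind!r}")

    @classmethod
    def PH(cls, p: float, L: int = 64) -> "SensitivityMeasure":
        return cls(kind="hit_probability_at_point", L=L, point=p)

    @classmethod
    def HI(cls, a: float, b: float, L: int = 64) -> "SensitivityMeasure":
        return cls(
            kind="hit_integration_over_range", L=L, range=SimilarityRange(a, b)
        )

    def evaluate(self, seed: SpacedSeed) -> float:
        if self.kind == "hit_probability_at_point":
            return hit_probability(seed, self.L, self.point)
        return hit_integration_range(seed, self.L, self.range)

    @property
    def label(self) -> str:
        if self.kind == "hit_probability_at_point":
            return f"PH[{self.point:g}]"
        return f"HI[{self.range.a:g},{self.range.b:g}]"


@dataclass(frozen=True)
class SeedScore:
    """One seed's value under a measure, with its rank in the evaluated set."""

    seed: SpacedSeed
    measure: SensitivityMeasure
    value: float
    rank: int

    def __str__(self) -> str:
        return f"{self.seed.pattern}\t{self.value:.6f}\t({self.rank})"


def _rank(scored: list[tuple[SpacedSeed, float]], measure) -> list[SeedScore]:
    # descending value; ties broken by canonical pattern order
    scored.sort(key=lambda sv: (-sv[1], _canon_key(sv[0].pattern)))
    return [
        SeedScore(seed=s, measure=measure, value=v, rank=r)
        for r, (s, v) in enumerate(scored, start=1)
    ]


def score_seeds(
    seeds: Sequence[SpacedSeed], measure: SensitivityMeasure
) -> list[SeedScore]:
    """Score every seed under the measure; ranks 1..n by descending value."""
    seeds = list(seeds)
    if not seeds:
        raise ValueError("seed set must be non-empty")
    return _rank([(s, measure.evaluate(s)) for s in seeds], measure)


def find_optimal(
    weight: int,
    max_length: int,
    measure: SensitivityMeasure,
    top_k: int = 5,
    seeds: Iterable[SpacedSeed] | None = None,
    checkpoint: str | os.PathLike | None = None,
    sweep_cap: int = DEFAULT_SWEEP_CAP,
) -> list[SeedScore]:
    """Top-k seeds of a (weight, ≤max_length) space under a measure.

    ``seeds`` restricts the sweep to an explicit set (e.g. a published seed
    list).  A ``checkpoint`` path makes long sweeps resumable: scored seeds
    are appended as tab-separated ``pattern  label  value`` lines and are not
    re-evaluated on restart.
    """
    if seeds is None:
        from .seeds import count_seeds

        n = count_seeds(weight, max_length)
        if n > sweep_cap:
            raise ValueError(
                f"seed space of size {n} exceeds sweep cap {sweep_cap}; "
                "pass an explicit seed set or raise sweep_cap"
            )
        seeds = enumerate_seeds(weight, max_length)
    seeds = list(seeds)

    done: dict[str, float] = {}
    if checkpoint is not None and os.path.exists(checkpoint):
        with open(checkpoint) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                pat, label, val = line.rstrip("\n").split("\t")
                if label == measure.label:
                    done[pat] = float(val)

    out = open(checkpoint, "a") if checkpoint is not None else None
    try:
        scored: list[tuple[SpacedSeed, float]] = []
        for s in seeds:
            if s.pattern in done:
                scored.append((s, done[s.pattern]))
                continue
            v = measure.evaluate(s)
            scored.append((s, v))
            if out is not None:
                out.write(f"{s.pattern}\t{measure.label}\t{v!r}\n")
                out.flush()
    finally:
        if out is not None:
            out.close()
    return _rank(scored, measure)[:top_k]


def compare_dominance(
    seed1: SpacedSeed, seed2: SpacedSeed, L: int, rng: SimilarityRange
) -> float:
    """Signed dominance amount HI[a,b](seed1) − HI[a,b](seed2).

    Positive when seed1 is the more sensitive seed on average over the band;
    antisymmetric in its two seed arguments.
    """
    return hit_integration_range(seed1, L, rng) - hit_integration_range(
        seed2, L, rng
    )
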