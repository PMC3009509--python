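"""Empirical seed sensitivity on binary homologous regions.

A pairwise alignment collapses to a binary string — 1 where the two residues
match, 0 otherwise — and a seed's *experimental sensitivity* on a collection
of such regions is the fraction that contain at least one hit, found by
sliding the seed across each region.  A synthetic generator emulates the
alignment collections used in genome-comparison studies: Bernoulli regions
whose lengths and similarity levels are drawn from configurable
distributions (real alignment similarities cluster unimodally between
roughly 65% and 80%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .seeds import HomologousRegion, SpacedSeed

__all__ = [
    "AlignmentSet",
    "SyntheticConfig",
    "alignment_to_region",
    "split_alignment_at_gaps",
    "generate_regions",
    "experimental_sensitivity",
    "read_regions",
    "write_regions",
    "read_pairwise_fasta",
]

_GAP_CHARS = frozenset("-.")


@dataclass(frozen=True)
class AlignmentSet:
    """A collection of binary homologous regions with a provenance label."""

    regions: tuple[HomologousRegion, ...]
    source_label: str = ""

    def __post_init__(self) -> None:
        if any(r.L == 0 for r in self.regions):
            raise ValueError("all regions must be non-empty")

    def __len__(self) -> int:
        return len(self.regions)

    def similarities(self) -> np.ndarray:
        return np.array([r.similarity for r in self.regions])


def alignment_to_region(seq1: str, seq2: str) -> HomologousRegion:
    """Binary match/mismatch encoding of two aligned sequences.

    A column is 1 when the residues are identical (case-insensitive) and
    neither is a gap; gap columns are 0 — a hit cannot use a gapped position.
    """
    if len(seq1) != len(seq2):
        raise ValueError(
            f"aligned sequences differ in length ({len(seq1)} vs {len(seq2)})"
        )
    bits = []
    for a, b in zip(seq1.upper(), seq2.upper()):
        match = a == b and a not in _GAP_CHARS and b not in _GAP_CHARS
        bits.append("1" if match else "0")
    return HomologousRegion("".join(bits))


def split_alignment_at_gaps(seq1: str, seq2: str) -> list[HomologousRegion]:
    """Gap-split encoding: break the alignment at gap columns.

    Alternative to mapping gaps to 0 — each maximal gap-free stretch becomes
    its own region, so a hit can never span an indel.
    """
    if len(seq1) != len(seq2):
        raise ValueError("aligned sequences differ in length")
    regions: list[HomologousRegion] = []
    buf: list[str] = []
    for a, b in zip(seq1.upper(), seq2.upper()):
        if a in _GAP_CHARS or b in _GAP_CHARS:
            if buf:
                regions.append(HomologousRegion("".join(buf)))
                buf = []
        else:
            buf.append("1" if a == b else "0")
    if buf:
        regions.append(HomologousRegion("".join(buf)))
    return regions


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic homologous-region generator.

    length_distribution:
        ``("fixed", L)``, ``("uniform", lo, hi)`` or ``("loguniform", lo, hi)``
        (integer lengths).
    similarity_distribution:
        ``("point", p)``, ``("uniform", a, b)`` or
        ``("truncnorm", mean, sd, lo, hi)`` — all mass must lie in [0, 1].
    random_seed:
        one integer drives every draw; identical configs give identical sets.
    """

    n_regions: int = 1000
    length_distribution: tuple = ("fixed", 64)
    similarity_distribution: tuple = ("point", 0.7)
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        kind = self.similarity_distribution[0]
        if kind == "point":
            lo = hi = self.similarity_distribution[1]
        elif kind == "uniform":
            lo, hi = self.similarity_distribution[1:3]
        elif kind == "truncnorm":
            lo, hi = self.similarity_distribution[3:5]
        else:
            raise ValueError(f"unknown similarity distribution {kind!r}")
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("similarity mass must lie within [0, 1]")
        lkind = self.length_distribution[0]
        if lkind not in {"fixed", "uniform", "loguniform"}:
            raise ValueError(f"unknown length distribution {lkind!r}")
        if min(self.length_distribution[1:]) < 1:
            raise ValueError("region lengths must be >= 1")

    @classmethod
    def alignment_like(
        cls, n_regions: int = 1000, random_seed: int = 0
    ) -> "SyntheticConfig":
        """Preset emulating genome-alignment collections: similarities
        truncated-normal on [0.5, 1] with mean 0.7 and sd 0.08, lengths
        log-uniform between 30 and 3000.  A synthetic stand-in, not a copy
        of any real data set."""
        return cls(
            n_regions=n_regions,
            length_distribution=("loguniform", 30, 3000),
            similarity_distribution=("truncnorm", 0.7, 0.08, 0.5, 1.0),
            random_seed=random_seed,
        )


def _draw_lengths(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    kind = cfg.length_distribution[0]
    n = cfg.n_regions
    if kind == "fixed":
        return np.full(n, int(cfg.length_distribution[1]))
    lo, hi = cfg.length_distribution[1:3]
    if kind == "uniform":
        return rng.integers(lo, hi + 1, size=n)
    u = rng.uniform(np.log(lo), np.log(hi + 1), size=n)
    return np.minimum(np.exp(u).astype(int), hi)


def _draw_similarities(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    kind = cfg.similarity_distribution[0]
    n = cfg.n_regions
    if kind == "point":
        return np.full(n, float(cfg.similarity_distribution[1]))
    if kind == "uniform":
        a, b = cfg.similarity_distribution[1:3]
        return rng.uniform(a, b, size=n)
    mean, sd, lo, hi = cfg.similarity_distribution[1:5]
    dist = stats.truncnorm((lo - mean) / sd, (hi - mean) / sd, loc=mean, scale=sd)
    return dist.rvs(size=n, random_state=rng)


def generate_regions(config: SyntheticConfig) -> AlignmentSet:
    """Draw Bernoulli match/mismatch regions per the config, reproducibly."""
    rng = np.random.default_rng(config.random_seed)
    lengths = _draw_lengths(config, rng)
    sims = _draw_similarities(config, rng)
    regions = []
    for L, p in zip(lengths, sims):
        bits = rng.random(int(L)) < p
        regions.append(
            HomologousRegion("".join("1" if b else "0" for b in bits))
        )
    return AlignmentSet(
        regions=tuple(regions),
        source_label=f"synthetic(seed={config.random_seed})",
    )


def experimental_sensitivity(
    seed: SpacedSeed, alignments: AlignmentSet | Sequence[HomologousRegion]
) -> float:
    """Fraction of regions the seed hits at least once (exhaustive scan).

    Regions shorter than the seed cannot be hit and count as misses.
    """
    regions = (
        alignments.regions
        if isinstance(alignments, AlignmentSet)
        else tuple(alignments)
    )
    if not regions:
        raise ValueError("alignment set must be non-empty")
    m = seed.m
    ones = np.array(seed.ones)
    # group by length so each group scans as one boolean matrix
    by_len: dict[int, list[int]] = {}
    for k, r in enumerate(regions):
        by_len.setdefault(r.L, []).append(k)
    hits = 0
    for L, idxs in by_len.items():
        if L < m:
            continue
        mat = np.array(
            [[c == "1" for c in regions[k].bits] for k in idxs], dtype=bool
        )
        found = np.zeros(len(idxs), dtype=bool)
        for off in range(L - m + 1):
            found |= mat[:, off + ones].all(axis=1)
            if found.all():
                break
        hits += int(found.sum())
    return hits / len(regions)


# ---------------------------------------------------------------------------
# plain-text region files: one {0,1}-string per line, '#' comments


def read_regions(path: str | Path, source_label: str | None = None) -> AlignmentSet:
    regions = []
    path = Path(path)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            regions.append(HomologousRegion(line))
    return AlignmentSet(
        regions=tuple(regions),
        source_label=source_label if source_label is not None else str(path),
    )


def write_regions(path: str | Path, alignments: AlignmentSet) -> None:
    with open(path, "w") as fh:
        if alignments.source_label:
            fh.write(f"# {alignments.source_label}\n")
        for r in alignments.regions:
            fh.write(r.bits + "\n")


def read_pairwise_fasta(path: str | Path, split_gaps: bool = False) -> AlignmentSet:
    """Convert a pairwise aligned FASTA (exactly two equal-length records)."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(
            f"expected exactly 2 aligned records, found {len(records)}"
        )
    s1, s2 = str(records[0].seq), str(records[1].seq)
    if split_gaps:
        regions = tuple(split_alignment_at_gaps(s1, s2))
    else:
        regions = (alignment_to_region(s1, s2),)
    return AlignmentSet(regions=regions, source_label=str(path))
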