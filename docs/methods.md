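# Methods

## Model

A homologous region is a Bernoulli binary string: `L` independent positions,
each a match (`1`) with probability `p`, the similarity level. A spaced seed
`Q ∈ {1,*}^m` with weight `w` hits the region if some length-`m` window has
a `1` at every required position. This is the standard gap-free model for
seed design; it ignores position dependence (real alignments are locally
correlated), indels inside the window, and base composition. The two
sensitivity measures computed here are

- hit probability `f[L, ε](p)` — probability of at least one hit at one
  similarity level, and
- hit integration `HI[0, p] = ∫₀^p f[L, ε]` with the range average
  `HI[a, b] = (HI[0,b] − HI[0,a])/(b − a)` — mean sensitivity over a band of
  similarity levels, `HI[0, 1]` being the similarity-level-free special case.

## State space

Both quantities are exact DPs over *compatible suffixes*: binary strings `b`
(0 ≤ |b| ≤ m) whose right-aligned overlap with `Q` has a `1` wherever `Q`
requires one. The state `(i, b)` denotes a region of total length `i` whose
final `|b|` characters are fixed to `b` and whose first `i − |b|` characters
are i.i.d. Bernoulli. Extending the suffix to the left, `1b` is always
compatible, while an incompatible `0b` is replaced by its longest compatible
proper prefix `b′` with the region index shifted to `i − |0b| + |b′|`: no
hit can end inside the discarded stretch, because every window ending there
would right-align against an incompatible prefix of `0b`. The prefix map is
precomputed once per seed and cached. The number of states is
`1 + Σ_{ℓ=1..m} 2^(stars in the last ℓ seed characters) ≤ m·2^(m−w) + 1`
(the classical `m·2^(m−w)` bound misses the empty-suffix state for
fully-consecutive seeds).

## Recursions

Hit probability: `f(i, b) = (1−p)·f(i, 0b) + p·f(i, 1b)`, with `f = 1` once
`|b| = m` (a compatible full-length suffix contains a hit) and `f = 0` when
`i < |b|`. Evaluation is bottom-up in `i`, suffixes longest-to-shortest
within each `i`, vectorized with numpy over a grid of similarity levels (the
whole sensitivity curve costs one DP pass per chunk of 128 levels).

Hit integration cannot reuse that recursion directly because `p` multiplies
the recursive terms, so the DP carries a degree index:
`Iⁿ[i, b] = ∫₀^p p′ⁿ f(i, b) dp′`, with

    Iⁿ[i, b] = Iⁿ⁺¹[i, 1b] + Iⁿ[i, 0b] − Iⁿ⁺¹[i, 0b],

base `Iⁿ = p^(n+1)/(n+1)` at `|b| = m` (the definite integral on `[0, p]`,
lower limit 0), `Iⁿ = 0` for `i < |b|`, the same prefix reduction for
incompatible `0b`, and result `I⁰[L, ε] = HI[0, p]`. The degree needed at
`(i, b)` lies between the number of 1s in `b` and `n_max = L − i + |b|`; the
implementation fills whole degree vectors per state and truncates each
region-length row at `L − i + m + 2` columns, which covers every consulted
degree (entries above `n_max` are never read — dependencies of a degree
within its band stay within the bands of the child states). Base-case
precedence tests `i < |b|` before `|b| = m`.

Range averages divide the difference of two raw integrals by the width:
`HI[a,b] = (HI[0,b] − HI[0,a])/(b − a)`. Scalar results are memoized per
`(seed, L, p)`.

## Numerical choices

- Hit probability runs in float64; individual values are accurate to
  ~1e−15 (validated against the exact polynomial oracle below).
- Hit integration accumulates in numpy `longdouble` (80-bit extended
  precision on x86). The recursion differences nearby integrals across tens
  of thousands of states; in float64 the returned value carries ~1e−13
  absolute error, while extended accumulation brings it to the last unit of
  the returned double — 64-node Gauss–Legendre quadrature of the
  hit-probability curve and the DP then agree to ≲1e−15 at `L = 64`.
- Degenerate inputs: `L < m` or `p = 0` return 0 without building tables;
  `p ∉ [0, 1]` and `L < 0` are rejected.
- Working memory for one integration is `(L+1)·|B|·(L+m+2)` long doubles —
  about 150 MB for `m = 18, w = 11, L = 64`.

## Oracles

- `exact_hit_polynomial` enumerates all `2^L` regions (cap `L ≤ 16`),
  tallies hitting regions by match count and expands
  `Σ_k c_k p^k(1−p)^(L−k)` with integer arithmetic; `exact_integral`
  integrates it as an exact rational. These arbitrate both DPs at small
  sizes (agreement demanded to 1e−12).
- `riemann_sum` uses the midpoint rule by default (second-order; `left` and
  `right` variants available) over N equal sub-ranges of hit-probability
  evaluations.
- `gauss_quadrature` defaults to `L` nodes; since `f[L, ε]` is a polynomial
  of degree ≤ `L`, any rule with ≥ ⌈(L+1)/2⌉ nodes is exact up to rounding,
  which is why the DP/quadrature comparison reaches ~1e−15 rather than a
  quadrature-error floor.

## Seed enumeration and search

Seeds with both end characters `1` and fixed weight are enumerated by length
then lexicographically under the documented character order `1 < *`. A seed
and its reverse have identical Bernoulli sensitivity, so only the canonical
member of each pair (the lexicographically smaller pattern; palindromes are
self-canonical) is kept: `(Σ_m C(m−2, w−2) + #palindromes)/2` seeds, which
is 46,252 for weight 11 and length ≤ 20. Ranking assigns descending-value
ranks with deterministic tie-break by canonical pattern order. Full
46,252-seed sweeps at `L = 64` are supported (a checkpoint file makes them
resumable) but take hours in this implementation; routine testing ranks the
nine benchmark seeds and small exhaustive spaces, which exercise the same
code path. Dominance between two seeds over a band is quantified as the
signed difference of their range-averaged hit integrations.

## Empirical module and synthetic data

Pairwise alignments are collapsed to binary regions position-wise
(match → 1, mismatch → 0). Gap columns map to 0 by default — a hit cannot
use a gapped position; an alternative splitter breaks regions at gap runs,
since published pipelines do not always state which encoding they used.
Experimental sensitivity is the fraction of regions with ≥ 1 hit, found by
an exhaustive sliding scan (vectorized per length group); regions shorter
than the seed count as misses.

The synthetic generator draws each region's length and similarity from
configurable distributions, then emits i.i.d. Bernoulli bits, all from one
integer-seeded numpy `default_rng`. The `alignment_like` preset emulates the
shape of real genome-alignment similarity histograms — unimodal on
[0.5, 1.0] with the peak near 65–80% identity — as a truncated normal
(mean 0.7, sd 0.08 on [0.5, 1]) with log-uniform lengths 30–3000, spanning
short exon-scale to long syntenic alignments. It is a labelled synthetic
stand-in: it reproduces the marginal similarity/length mix, not the
positional correlation, indel structure, or repeat content of real
alignments, so passing tests demonstrate correct computation and preserved
seed orderings on such mixtures, not absolute sensitivities on any genome
pair. Fixed-similarity configurations double as Monte-Carlo checks of the
hit-probability DP (binomial 3σ agreement at n = 2·10⁵).

## Testing scale

Exhaustive-oracle tests cover all seeds of length ≤ 6 at region lengths up
to 12 and representative length-8 seeds at L = 14; benchmark regressions run
the nine published weight-11 seeds at L = 64; the Monte-Carlo consistency
check uses 2·10⁵ fixed-similarity regions. These sizes keep the full suite
under a minute on one CPU while exercising every code path at both desk
scale and benchmark scale.

## Known limitations

- Bernoulli regions only: no Markov or coding-frame position models, no
  transition-weighted or multiple simultaneous seeds.
- The integration DP's memory and time grow as `2^(m−w)`; weight-11 seeds
  of length ≳ 22 become impractical.
- Extended-precision accumulation relies on the platform `longdouble`; on
  platforms where numpy's longdouble is an alias of float64 the integration
  error floor rises to ~1e−13.
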