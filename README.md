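# seedsense

Spaced-seed sensitivity across similarity levels: exact dynamic programs for
**hit probability** and **hit integration**, with verification oracles, seed
search, and empirical evaluation on alignment-derived binary regions.

## The problem

Filtration-based homology search (BLAST, PatternHunter) scans for short seed
matches before attempting full alignments. A *spaced seed* is a template
`Q ∈ {1,*}^m` — `1` requires a match, `*` is a don't-care — of length `m` and
weight `w` (number of `1`s). A homologous region is modelled as a Bernoulli
binary string `R` of length `L` whose positions match independently with
probability `p`, the *similarity level*; `Q` hits `R` when some window
`R[i:i+m−1]` has a `1` at every required position.

The classical sensitivity measure is the **hit probability** `f[L, ε]`, the
probability that `Q` hits `R` at one fixed similarity level `p`. Real
homologous regions, however, span a wide band of similarities, and a seed
optimal at `p = 0.7` need not be optimal elsewhere. **Hit integration**
removes the dependence on a single level by accumulating the hit-probability
curve:

    HI[0, p] = ∫₀^p f(L, ε)(p′) dp′,
    HI[a, b] = (HI[0, b] − HI[0, a]) / (b − a),

so `HI[a, b]` is the mean sensitivity over the band `[a, b]` and `HI[0, 1]`
is a similarity-level-free sensitivity. Both quantities are computed exactly
(no quadrature) by dynamic programming over the seed's *compatible suffixes*:
binary strings `b` whose right-aligned overlap with `Q` satisfies every
required position. The hit-probability recursion conditions on the character
preceding the suffix,

    f(i, b) = (1 − p)·f(i, 0b) + p·f(i, 1b),

and hit integration carries one extra index, the degree-indexed integrals
`Iⁿ[i, b] = ∫₀^p p′ⁿ f(i, b) dp′`, which satisfy

    Iⁿ[i, b] = Iⁿ⁺¹[i, 1b] + Iⁿ[i, 0b] − Iⁿ⁺¹[i, 0b]

with base cases `Iⁿ = p^(n+1)/(n+1)` at `|b| = m` and `Iⁿ = 0` for `i < |b|`;
an incompatible extension `0b` is folded back into the state space through
its longest compatible proper prefix. The answer is `I⁰[L, ε]`, at cost
`O(L²·m·2^(m−w))` against `O(L·m·2^(m−w))` for hit probability.

## Worked example

The two headline seeds of weight 11: the classical spaced seed
`111*1**1*1**11*111` (optimal by hit probability at `p = 0.7`) and
`111**1*11**1*1*111` (optimal by hit integration over `[0, 1]`), both on a
random region of length 64.

```text
$ seedsense hitprob --seed 111*1**1*1**11*111 --length 64 --p 0.7
0.467122

$ seedsense hitint --seed 111**1*11**1*1*111 --length 64 --p 1
0.300273

$ seedsense hitint --seed 111**1*11**1*1*111 --length 64 --range 0.5 1
0.598730
```

The first number is a hit probability at one similarity level: at 70%
identity this seed finds 46.7% of length-64 homologous regions. The second
is the similarity-level-free sensitivity `HI[0, 1]` of the range-optimal
seed, and the third its mean sensitivity over the realistic band 50–100%.
Ranking all 46,252 canonical weight-11 seeds of length ≤ 20 by these
measures picks different optima — the point of integrating over the range.

The integration DP can be cross-checked against Gauss–Legendre quadrature of
the hit-probability curve (exact for this polynomial integrand):

```text
$ seedsense validate --seed 111*1**1*1**11*111 -L 64 --gauss 64
hit_integration 0.300265005487991
gauss[64]       0.300265005487991
abs_difference  0
```

and small seed spaces can be ranked directly:

```text
$ seedsense search -w 2 -m 4 --measure HI:0:1 -L 10 -k 3
11      0.685714        1
1*1     0.671789        2
1**1    0.655556        3
```

The same surface is available as a library (`seedsense.hit_probability`,
`seedsense.hit_integration_range`, `seedsense.score_seeds`, …), including an
exhaustive exact-polynomial oracle for small instances
(`seedsense.exact_hit_polynomial`), a synthetic generator of
alignment-like binary regions (`seedsense.generate_regions`), and empirical
sensitivity on region files (`seedsense.experimental_sensitivity`).

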