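# Methods

## The decomposition

For an assemblage with relative abundances `p` and functional
dissimilarities `d(i,j)`, the package computes the Gini–Simpson diversity
`S = 1 − Σ pᵢ²`, Rao's quadratic diversity `Q = Σᵢⱼ pᵢ pⱼ d(i,j)` (full
double sum; the zero diagonal makes it equal to the off-diagonal sum),
functional redundancy `R = S − Q` and Simpson dominance `D = 1 − S`. The
additivity `D + R + Q = 1` is an algebraic identity; the package enforces it
to 1 × 10⁻¹² and clamps a rounding-level negative `R` (|R| < 10⁻⁹) to zero
while preserving the identity. The bound `0 ≤ Q ≤ S` — and hence `R ≥ 0` —
holds **only** when every dissimilarity lies in [0, 1]; `drq_compose`
rejects inputs that violate it and points at the rescaling step.

Single-species assemblages are valid and sit exactly at the D vertex
(S = 0). Species with zero abundance are dropped from an assemblage's
profile before decomposition; this is an exact no-op for S and Q and is
covered by tests.

## Functional distances

The distance pipeline is fixed as **scale → Gower → Lingoes → unit
rescale**:

* *Scaling*: each quantitative trait is min–max scaled over the species
  pool. A constant trait maps to zero everywhere (contributing nothing to
  any distance) rather than erroring, so pipelines keep running on
  degenerate inputs; a trait with no observed value is an error naming the
  trait.
* *Gower*: the plain 1971 form with equal trait weights — the mean over
  traits observed in both species of |xᵢ − xⱼ| (quantitative, scaled) or a
  0/1 mismatch (nominal, exact string equality after whitespace trimming,
  case-sensitive). Missing values are handled by pairwise deletion; a pair
  sharing no observed trait is an error identifying the pair. Mixed-trait
  distance functions in the wild differ in weighting and missing-data
  conventions; the plain form was chosen because it is reproducible from
  first principles and is what the double-loop oracle in the tests
  implements independently.
* *Lingoes*: with `G` the doubly centred Gram matrix of −½d² and λ_min its
  smallest eigenvalue, the matrix is declared Euclidean-embeddable when
  λ_min ≥ −tol (default tol = 10⁻¹⁰). Otherwise `c = −λ_min` and
  `d′ = √(d² + 2c)` off the diagonal — the smallest additive constant that
  makes the configuration embeddable. The transform is monotone, so the
  ordering of dissimilarities is preserved (tested).
* *Unit rescale*: division by the maximum off-diagonal value. The Lingoes
  step can push distances above 1, which would break `Q ≤ S`; rescaling
  restores the [0, 1] range while leaving ratios intact. It is idempotent
  and leaves an all-zero matrix unchanged.

## Abundances and selection rules

Abundance of a parasite species in an assemblage is its **mean count per
examined host individual** — infested and uninfested alike — after pooling
counts and examined hosts across sampling periods. Relative abundances
normalise these means; because the denominator cancels, normalising raw
pooled counts gives the identical result (tested).

Three thresholds gate the inference, all overridable (defaults 10 / 2 / 3):

* assemblages from fewer than **10** examined hosts are dropped — counts
  from few hosts are unreliable because ectoparasites are aggregated among
  host individuals;
* a host species enters the within-host comparison when it occurs in at
  least **2** levels of the partitioning factor and has at least **3**
  assemblage samples *in total* (the per-level reading would demand ≥ 6
  points; a permutation test remains well defined with a level of size 1,
  so the total reading was adopted);
* a factor level enters the between-host comparison when at least **2**
  host species each have at least **3** samples *within that level* (a
  per-species spread needs at least 3 points).

Every exclusion is logged with its triggering rule; the filters commute
with one another (tested).

## Permutational inference

Dissimilarities between DRQ compositions use **Bray–Curtis**, which on
unit-sum triplets equals half the L1 distance. The omnibus statistic is the
one-way PERMANOVA pseudo-F

    SS_total  = (1/N) Σ_{i<j} d²,   SS_within = Σ_g (1/n_g) Σ_{i<j ∈ g} d²,
    F = (SS_between/(a−1)) / (SS_within/(N−a)),

with p-values from uniform random permutations of the label vector
(free raw-data permutation; every design here is one-way, so no restricted
or residual-based scheme is needed — for an intercept-only null, residual
randomisation reduces to exactly this). The p-value convention is
`p = (n_ge + 1)/(n_perm + 1)`: p is never zero, the test is valid, and ties
count conservatively against the null. Default `n_perm = 10 000`; seeds are
explicit, never implicit. When all within-group dissimilarities vanish but
groups differ, F is reported as `+inf`; only permutations that also achieve
perfect separation count as ≥. An exhaustive mode enumerates every distinct
label arrangement (used in tests; Monte Carlo is the default even where
exhaustive is feasible, for uniform behaviour).

Univariate follow-ups on D, R and Q use the classical one-way F with the
same permutation scheme — for one-way designs this equals
Euclidean-distance PERMANOVA on the raw values (asserted as a cross-check).
They are computed for **every** omnibus test and flagged with the omnibus
outcome, so the conventional reading (interpret them only where the omnibus
is significant) is a filter on the output, not a branch in the code. No
multiple-testing correction is applied across strata; the tests are
reported as an omnibus family, one row per stratum.

Significance flags in results tables use p < 0.05. Calibration tests
instead count `p ≤ α` rejections, whose exact size under the add-one
convention is `⌊α(B+1)⌋/(B+1)` — exactly 0.05 at B = 199.

## Ternary mapping

`(D, R, Q) → (x, y) = (Q + D/2, D·√3/2)`: D at the top vertex, R
bottom-left, Q bottom-right. The orientation is a free choice, documented
here and kept fixed; the mapping is a bijection from the 2-simplex to the
triangle and is inverted exactly by `ternary_inverse` (round-trip tested to
10⁻¹²). Figures are deterministic for fixed input and are always
accompanied by a CSV coordinate dump so downstream checks never compare
pixels.

## Synthetic data

The generator emulates the structure the analysis assumes, not any
particular fauna:

* **Traits**: five quantitative traits (lognormal, σ = 1 — trait values
  such as body size and abundance are right-skewed across species) and one
  three-level nominal trait; optional missingness that never strips a
  species or trait bare.
* **Counts**: per (host, unit), `n_examined` uniform on 20–100 and
  negative-binomial species totals with mean `n_examined · μ` and shape
  `k · n_examined` (the distribution of a pooled total over aggregated
  hosts), `k = 0.5` per host — strong aggregation, the regime that
  motivates the ≥ 10-hosts filter.
* **Latent structure**: a community lognormal abundance profile, perturbed
  per host species (`host_divergence = 0.5`, so hosts have distinct but
  overlapping parasite faunas) and per unit (`unit_sd = 0.3` lognormal
  jitter, i.i.d. across units — hence exchangeable under the null).
* **Effects** are injected on the latent relative-abundance profiles of one
  factor level, never on realised counts: `dominance` power-tilts
  `p ∝ p^(1+e)` (raises D), `evenness` applies the inverse tilt,
  `trait` blends toward a reassignment of the same abundance values onto
  functionally central species (lowers Q, raises R, approximately preserves
  S — exactly preserved in the limit where the blend becomes a pure
  permutation). `effect_size = 0` is the identity everywhere, which is what
  makes the null scenarios exchangeable by construction.

The default scenario — 15 parasite species, 4 host species, 2 ecological
levels × 6 units crossed with 2 geographic levels — is deliberately small:
the full pipeline runs in well under a second, so calibration studies with
a thousand replicates complete in minutes. What passing tests on these data
show is that the *machinery* is correct and calibrated; they say nothing
about sampling artefacts real surveys carry (spatial autocorrelation,
detection bias, unbalanced effort, host phylogeny), which the generator
does not emulate.

Calibration and power checks use one pre-specified test per simulated
dataset (the first host's within-host omnibus) so the resulting p-values
are independent across replicates; the power grid is effect_size ∈
{0, 0.5, 3} with 100 replicates per point and B = 199 permutations.

## Numerical conventions

* Simplex inputs are accepted to 10⁻⁹ and renormalised; the additive
  identity is then maintained to 10⁻¹².
* The Lingoes tolerance (10⁻¹⁰) separates "numerically Euclidean" from
  "needs correction"; the corrected Gram matrix's smallest eigenvalue is
  guaranteed ≥ −10⁻¹⁰ (property-tested on random non-Euclidean inputs).
* Distance matrices are stored symmetric with an exactly zero diagonal;
  Gower output is symmetrised explicitly to remove rounding asymmetry.
* Per-test permutation seeds are spawned deterministically from the fit's
  master seed in a fixed order, so refits reproduce byte-identical tables.

## Known limitations

* Trait *construction* (host-specificity indices, phylogenetic diversity of
  host spectra, sampling-effort corrections) is out of scope: traits are
  consumed as given columns.
* Only one-way designs are supported — no interaction terms, dispersion
  (PERMDISP) tests, or pairwise post-hoc comparisons.
* The Gower variant is the plain equally weighted form; analyses built on
  differently weighted mixed-trait distances will differ in the third
  decimal, not in structure.
* The generator draws every (host, unit) combination; real surveys have
  structurally missing cells, which the selection filters would handle but
  the simulations do not exercise.
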