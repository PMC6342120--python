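# Methods

## Functional entities

A functional entity (FE) is a unique combination of categorical trait values;
all species sharing the combination belong to one FE. The default schema
carries six reef-fish traits — body size (6 ordered classes), diet (7
levels), mobility (3), gregariousness (5 ordered classes), period of activity
(3), and vertical position in the water column (3) — for 5,670 theoretically
possible combinations. A bundled fine-to-crude collapse map reduces the level
counts to 3, 3, 2, 3, 2, 2 (216 combinations) for the sensitivity analysis.
The level *names* and the exact grouping of fine levels into crude ones are
conventions shipped as editable configuration (the schema round-trips through
YAML); only the level counts are fixed by the design. Species records are
validated strictly at load: unknown levels, duplicated identifiers, and
species occupying no assemblage are errors, never silently dropped or
imputed. An `imputed` flag column is accepted for bookkeeping but has no
effect — trait infilling is considered an upstream curation step.

Entity tables are deterministic: entities are ordered lexicographically by
level rank, so the table is invariant to the order of input records. Per
assemblage, occupancy counts n_i sum exactly to the species count S, and each
species belongs to exactly one entity; these invariants are property-tested.

## Trait space

Entities are compared with Gower dissimilarity: nominal traits contribute a
0/1 mismatch, ordered traits the absolute rank difference normalized by the
trait's declared rank range (number of levels − 1), averaged without weights
over the six traits. Normalizing by the declared range rather than the range
realized in the data keeps the matrix a function of the schema alone, so
adding or removing entities never rescales existing dissimilarities. Which
traits are ordered is a per-trait switch; the default treats size and
gregariousness as ordered, the rest as nominal.

Principal coordinates analysis embeds the entities. Gower matrices on
categorical data are generally non-Euclidean, so when the doubly-centered
Gram matrix has an eigenvalue below −10⁻⁸·λ_max, the Cailliez additive
constant (the largest real eigenvalue of the 2n×2n companion matrix) is added
to all off-diagonal dissimilarities before re-decomposition; an already
Euclidean input gets a constant of exactly 0. Four axes are retained by
default — in faunas of this kind a fifth axis adds little fidelity — and
requesting more axes than there are positive eigenvalues is an error that
names the maximum.

Space quality is reported two ways: mSD, the mean squared deviation between
the input dissimilarities and the embedded Euclidean distances after both are
standardized by their maxima (a scale-free fidelity measure; 0 for a perfect
embedding), and a Mantel matrix correlation (both r and r², since either may
be quoted) with a one-sided permutation p-value, p = (1 + #{r_perm ≥ r_obs}) /
(permutations + 1), 999 permutations by default; fewer than 99 is flagged in
the result rather than refused. The permutation test is scikit-bio's seeded
`mantel`.

## Diversity indices

With occupancies n_1..n_FE (all ≥ 1) and S = Σ n_i:

- FR = S/FE, reported with the standard error of the n_i across entities,
  sd(n_i)/√FE (NaN for a single entity — dispersion is undefined there);
- FV = 100 · #{i : n_i = 1}/FE, algebraically equal to the
  100·(FE − Σ min(n_i−1, 1))/FE form, an identity the tests exercise;
- FOR = 100 · Σ max(n_i − FR, 0)/S.

FRic is the convex-hull volume (Qhull) of an assemblage's entities on the
retained axes as a percentage of the pooled hull; the pooled assemblage is
100% by construction. An assemblage whose entities are affinely dependent in
m dimensions has no m-volume; FRic is then reported as NaN — an explicit
undefined marker — rather than jittering points, trading convenience for
reproducibility.

The unique-species contribution to FV counts the assemblage's singleton
entities whose sole species occurs in no other region, divided by the
assemblage's FE count. Using FV's denominator makes the value a sub-part of
FV (it can never exceed it), which is the natural reading of "how much of the
vulnerability rests on species that exist nowhere else". For the pooled
assemblage the analogous quantity counts pooled singletons whose species
occupies exactly one region.

Percentages are written to CSV at one decimal; JSON keeps full precision
under a `raw` key.

## Null model

FV and FOR depend on S, FE, and the spread of species over entities; the null
holds S and FE fixed and randomizes the spread under the constraint that
every realized entity stays occupied. The randomization seeds each entity
with one species and scatters the remaining S − FE species as iid uniform
assignments (a symmetric multinomial). This construction is used directly
rather than rejection sampling from the unconditional uniform assignment
because at realistic scale (S ≈ 1,500, FE ≈ 400) an unconditional draw almost
surely leaves entities empty, making rejection infeasible; the scheme name
(`seed-one-scatter-rest`) is recorded in every output so results are never
ambiguous about which null they used.

The default is 9,999 simulated assemblages. The bilateral p-value uses the
add-one Monte-Carlo correction with ties counted toward both tails:
p = min(1, 2·min((1+#{sim ≤ obs}), (1+#{sim ≥ obs}))/(n_sims+1)), so the
smallest attainable p is 2/(n_sims+1). SES = (observed − null mean)/null sd;
a degenerate null (sd = 0, e.g. S = FE where every simulation is all
singletons) flags the result and leaves SES undefined. A master seed spawns
one independent substream per (assemblage, statistic) pair via
`numpy.random.SeedSequence`, so any single test is reproducible in isolation
and results are bit-identical across runs. Calibration is tested: on
occupancies themselves drawn from the null, the rejection rate at α = 0.05
lies near nominal and the SES distribution is centered near zero.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
any particular fauna: ~1,500 species in four nested regional assemblages with
a richness gradient, packed into entities with a strongly right-skewed
occupancy distribution. Entity sizes are drawn iid from a geometric
distribution with success probability `occupancy_skew` (support ≥ 1),
drawing until the sizes sum to `n_species` (the last draw is clipped to
fit). The geometric law is the simplest one-parameter right-skewed count
distribution reproducing the many-singletons/few-giants shape; the default
skew of 0.3 gives a mean occupancy near 3.3 species per entity, in the range
such faunas show. As skew → 1 every entity is a singleton, so entity sizes
become uniform and FOR → 0. Trait tuples are sampled uniformly without
replacement from the schema's Cartesian product (enumeration for small
products, rejection sampling for very large ones); requesting more entities
than the schema allows is an error.

Regions: the richest region holds the whole species pool; each poorer region
keeps a `richness_gradient` fraction of it (default 1.0, 0.69, 0.50, 0.42,
a gradient falling to ~40% like a strong latitudinal richness decline),
sampled without replacement with weight (entity size)^`nestedness`. Larger
entities are thus retained preferentially and singleton entities are lost
first, mirroring the observation that richness loss erodes redundancy before
functional richness. The generator writes the same CSV dialect the loader
reads plus a ground-truth JSON with the per-region occupancy vectors, and the
round trip through the loader recovers those vectors exactly (tested).

What the generator does not emulate: real trait correlations (tuples are
uniform over the Cartesian product, so the realized share of theoretical
combinations is higher than in real faunas), phylogenetic structure, and
abundance — so passing tests demonstrate the machinery and its statistical
calibration, not ecological realism of any particular number.

`generate_null` produces tables whose occupancy is an exact draw from the
null model, used to verify that downstream tests are calibrated (they should
reject at roughly the nominal rate).

## Numerical and scale choices

- Eigenvalues with |λ| < 10⁻⁸·λ_max are treated as zero.
- Hull volumes come from Qhull; a test cross-checks them against hit-or-miss
  Monte-Carlo integration (10⁶ points) to within 2% on random 4-D point sets.
- PCoA is cross-checked against scikit-bio's implementation on Euclidean
  inputs, where no correction is needed.
- Test and example problem sizes (hundreds to a thousand species, null tests
  with 999 simulations, calibration over 500 replicates at S = 150, FE = 60)
  were chosen so the full suite runs in well under a minute while keeping
  Monte-Carlo error far below the tested tolerances; the library defaults
  (9,999 simulations) match the scale a full analysis would use.

## Known limitations

- No abundance or biomass weighting: all indices are presence-based.
- No alternative functional-diversity metrics (FEve, FDiv, FDis, Rao's Q).
- The null model randomizes occupancy counts only; trait-shuffling or
  matrix-swap nulls are out of scope.
- FRic in m dimensions requires at least m+1 affinely independent entities;
  very small assemblages report NaN.
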