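# Methods

`cuvarp` implements cumulative variation partitioning with multiple response
and predictor matrices (CUVARP) for community ecology: four site-aligned data
tables — a native community **H**, an alien community **A**, a mixed-type
environment table **E**, and spatial coordinates **S** — are each reduced to
ordination scores, each in turn is partitioned against the other three on the
adjusted-R² scale, and the four reciprocal partitionings are assembled into
one variance-unit diagram over the subsets of {H, A, E, S}.  This note
records the model, its assumptions, the numerical conventions, and the
choices made where the design was genuinely open.

## The pipeline

1. **Component construction.**  H, A, and E are converted to Gower
   dissimilarities and embedded by principal coordinates analysis (PCoA);
   axes with positive eigenvalues (above tolerance, below) are kept.  S is
   converted to distance-based Moran eigenvector maps (db-MEM): Euclidean
   distances, truncation at threshold *t* with beyond-threshold distances
   replaced by 4*t*, PCoA, positive axes.  The automatic *t* is the largest
   edge of the minimum spanning tree of the distance graph — the smallest
   truncation that keeps the sites connected, which on a 1-D transect equals
   the maximum nearest-neighbour gap.
2. **Consensus axis selection.**  For every ordered pair of roles, the
   predictor role's axes are forward-selected (see below) against the
   response role's full score table; an axis is retained for a role when it
   is selected in at least one analysis in which that role serves as
   predictor.  A role ending empty falls back to axis 1 with a logged
   warning.  This automates what is, in interactive ordination software, a
   judgement call; the union rule is deliberately permissive so that no
   signal seen by any reciprocal analysis is discarded.
3. **Totals.**  The variance of each reduced score table is its PCA total
   variance — the sum of column variances with the n−1 divisor — and the
   grand total is the sum over the four roles.  Totals are computed on the
   *selected*-axes tables, not the full embeddings, so the diagram partitions
   exactly the variance that enters the models.
4. **Reciprocal partitioning.**  Each role's reduced table is the response in
   a three-predictor variation partitioning (RDA with adjusted R²; see
   below), yielding 3 unique, 3 pairwise-shared, and 1 triple-shared
   fraction plus a residual, all of which sum to 1 by construction.
5. **Diagram assembly.**  Region values in variance units: the non-overlap
   (singleton) region of role X is its residual fraction × its total; every
   overlap region of a subset T (|T| ≥ 2) accumulates, from each member X of
   T taken as response, X's fraction keyed by the other members of T, × X's
   total.  Every fraction of every partitioning is used exactly once, so the
   15 regions sum to the grand total identically (asserted to 1e−9).
   Negative fractions (legitimate on the adjusted scale) enter the sums
   as-is and are floored only at render time, flagged `rendered=false`
   together with exact zeros.

The CWM variant replaces H and A by community-weighted means of the trait
tables before step 1.  Its *average* diagram (AVARP) reports each region as
the mean, over the member responses, of the fraction as a percent of that
response's own total — a unitless diagram that weights all four roles
equally regardless of their variance budgets.  The "average" semantics is
this package's definition and is marked in the output `mode` field.

## Supporting statistics

**Gower dissimilarity.**  d(i,j) = Σ w_k δ_k s_k / Σ w_k δ_k with s_k =
|x_i − x_j| / range for quantitative *and ordinal* columns (ordinals as
integer ranks; the Podani ordinal correction is not applied) and 0/1
disagreement for factors and binaries.  δ_k = 0 when either value is
missing (pairwise deletion with weight renormalization); a pair with no
comparable column is a hard error, never a silent zero.  Community count
tables passed to Gower are treated as quantitative columns, range-scaled per
species.

**PCoA.**  Double-centering G = −½ J D² J, symmetric eigendecomposition,
retention of eigenvalues above 1e−8 × max|eigenvalue| ("positive" and
"non-zero" keep policies coincide under this tolerance, which is what
absorbs semimetric noise).  Scores are eigenvectors × √eigenvalue; each
axis's sign is fixed so its largest-magnitude loading is positive, making
runs reproducible across LAPACK builds.  No Lingoes/Cailliez correction is
applied: negative eigenvalues are simply not retained.

**RDA and adjusted R².**  Multivariate least squares of the centered
response on the predictors through a rank-revealing SVD basis; R² is the
trace ratio of fitted to total sums of squares, and the pseudo-F uses the
effective rank m_eff.  Rank decisions compare singular values against the
norm of the predictor block *before* residualization, so a predictor matrix
absorbed by covariates cleanly reports m_eff = 0 (R² = 0, F = 0) instead of
fitting numerical dust.  Adjusted R² is Ezekiel's 1 − (1−R²)(n−1)/(n−m−1),
computed only for simple (covariate-free) models; every partial or shared
quantity is obtained by subtraction and inclusion–exclusion of simple-model
adjusted R²s (the Peres-Neto convention), which is the only scale on which
the fractions are additive.  Negative fractions are preserved everywhere
except the drawing.

**Permutation inference.**  Monte Carlo tests of the pseudo-F permute the
centered response rows (no covariates) or the reduced-model residuals
(Freedman–Lane, with covariates).  Restricted schemes: free; blocks
(within-block free permutation); series (one cyclic shift per block,
optionally mirrored — the restricted scheme for time series and linear
transects); and split-plot (equal-sized whole plots exchanged freely,
internal series order preserved, or cyclically shifted when
`shift_within` is set).  Both hierarchy levels are therefore available and
the choice is logged with the design summary.  When the orbit of achievable
permutations is no larger than the requested draw count the test enumerates
it and the p-value is exact; otherwise p = (exceedances + 1)/(n_perm + 1),
so p ≥ 1/(n_perm + 1) always.  Defaults: 999 permutations, α = 0.05.

**Forward selection.**  Greedy, with a partial permutation test of every
remaining candidate conditioning on the current model, and two stopping
rules: no candidate passes α, or the cumulative adjusted R² has reached the
full all-candidate model's adjusted R² (further entries could only chase
noise).  The Benjamini–Hochberg adjustment at each step is anchored to the
full candidate roster rather than the shrinking remainder: padding the
remaining p-values with 1s keeps the step-up denominator at the roster size,
so the last surviving candidate is not quietly tested at raw α.  Without
this anchoring the probability of admitting a pure-noise candidate after a
genuine one equals α exactly, which defeats the purpose of adjusting at all.
Ties in the adjusted-R² gain break by candidate column order.

**Diversity and traits.**  Shannon entropy in nats; Pielou J = H/ln S,
reported missing (not 0) for monocultures; Hill N2 = 1/Σp².  Rao quadratic
entropy Q = Σ_ij d_ij p_i p_j over ordered pairs, on plain (not squared)
Euclidean distances between species in trait-PCoA space; the ordered-pair
convention makes the equal-distance identity Q = c(1 − Σp²) exact.  CWM
abundance-weights quantitative and ordinal traits and expands factors into
per-level proportion columns; zero-abundance sites yield missing rows.

## The synthetic riverscape

The generator emulates the data situation the pipeline is built for: a 1-D
river transect (default 200 sites, regular spacing), an environment table
mixing a 3-level habitat factor, 0–7 and 1–5 ordinal pressure/flow scores
and a quantitative distance-to-dam, Gaussian/count/binary community tables
for 22 native and 6 alien species, and 11 mixed-type traits per species
drawn from archetype mixtures.

Variance design: per community, latent site signals are √share-weighted sums
of four *exactly orthogonalized* unit-variance channels — environment-only,
space-only (a combination of leading db-MEM eigenfunctions), shared
(spatially structured and expressed in the environment), and noise — so the
realized latent shares equal the design shares.  Both communities load on
the same environment/space/shared channels; only the shares differ.  The
defaults are the study conditions of the test suite: native shares
(env, space, shared, noise) = (0.30, 0.20, 0.10, 0.40) and alien shares
(0.15, 0.10, 0.05, 0.70) — the alien noise share doubled, encoding the
qualitative pattern that invasives are less tied to the measured predictors.
Species are linear loadings on the latents; the Poisson and threshold links
distort the shares on the observed scale, so recovery tolerances are
certified only for the Gaussian-latent model, and the recovery tests measure
against the stored true channels (the environment table's discretization
into ordinal/factor variables deliberately loses information, as real
predictors do).

What passing tests therefore show: the partitioning arithmetic is exact, the
permutation tests are calibrated, and designed latent variance shares are
recovered within ±0.05 at n = 200 (50-seed means) under linear responses
with orthogonal channels.  What they do not show: recovery under strong
nonlinearity, species interactions, non-orthogonal confounding of
environment and space beyond the designed shared channel, or observation
error in the predictors — all present in real survey data.

## Problem sizes and determinism

The test suite and the acceptance script run their simulations at n = 30–200
sites with 49–199 permutations and 20–50 replicate seeds; these sizes give
Monte-Carlo standard errors comfortably inside the asserted tolerances
(e.g. a ±0.05 recovery band against a ≈0.008 standard error of a 50-seed
mean).  Every stochastic routine takes an explicit seed, child seeds are
drawn from a single generator in a fixed order, and identical seeds yield
byte-identical `result.json` artifacts end to end.

## Known limitations

- The consensus union rule of step 2 is one formalization of an interactive
  procedure; other defensible rules (intersection, response-side retention)
  would select different axis sets on noisy data.
- Interactions *within* a predictor class are invisible to the method; the
  diagram speaks only about between-matrix structure.
- The diagram's ellipse rendering is non-proportional; proportional-area
  Euler layout is delegated to external renderers via `diagram.json`.
- Shared fractions are not testable by permutation and never receive
  p-values.
- Gower's treatment of ordinals as range-scaled ranks is one of several
  conventions; it is recorded in the distance-matrix metadata.
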