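# Methods

`morphorate` implements a comparative analysis that asks whether groups of
species defined by a binary ecological character evolve a high-dimensional
morphological trait at different rates. Its motivating application is head
shape in Lake Tanganyika cichlids, where mouthbrooding couples the cranium
to a second function (brood care) and is hypothesized to slow craniofacial
evolution relative to substrate guarding. The package is a complete,
seedable replica of that study design, exercised on synthetic data.

## Shape quantification

Each specimen is a set of k = 16 planar points: 9 fixed landmarks and 7
semilandmarks along the forehead outline. Superimposition is generalized
Procrustes analysis (GPA) in the partial-Procrustes convention: every
configuration is translated to a zero centroid, scaled to unit centroid
size (the square root of summed squared distances of points from their
centroid), and iteratively rotated to the running consensus by the proper
2-D orthogonal-Procrustes rotation (reflections suppressed). No cos(rho)
rescaling is applied afterwards, so each aligned row has exactly unit
centroid size.

Semilandmarks are slid by the minimum-Procrustes-distance criterion: each
slider moves along the unit chord from its previous to its next curve
neighbour by the scalar projection of its offset from the corresponding
consensus point — the 1-D least-squares optimum. Sliding is interleaved
once per GPA iteration, after rotation and before the consensus update,
and the configuration is re-normalized and re-rotated after sliding.
Minimum-bending-energy sliding is deliberately out of scope: the chord
(tangent) projection is the variant consistent with minimizing summed
Euclidean distances, and it needs no thin-plate-spline machinery.

Numerical choices:

* convergence: stop when the summed squared distance to the consensus
  improves by < 1e-10, cap 100 iterations. With sliding enabled the
  objective can keep creeping down by ~1e-5 per iteration for a long time
  (semilandmarks redistributing along a nearly flat direction); the run is
  then flagged `converged=False` rather than silently truncated. The
  aligned coordinates are stable to far better precision than any
  downstream use requires.
* frame canonicalization: the consensus is rotated onto its principal axes
  (sign fixed by the landmark farthest from the centroid, det = +1) and all
  rows follow. This makes the output independent of specimen input order
  and of the digitizing frame, which is asserted to 1e-8 in tests.
* the consensus is the plain arithmetic row mean (not re-normalized), so
  `consensus == coords.mean(axis=0)` holds exactly; species consensus
  shapes *are* re-normalized to unit centroid size because they re-enter
  the analysis as shapes.
* tangent-space projection is available (`project=False` by default is the
  analysed convention: rate estimation consumes superimposed coordinates
  directly).

Species consensus averages aligned rows within species, optionally
restricted to one sex; species with no specimen in a requested cell are
dropped with a warning. A `two_stage` switch re-superimposes the species
means (the alternative reading of "GPA per species"); the default aligns
all specimens jointly and averages, which uses all information and is the
common modern practice.

## Rate estimation and the ratio test

Under Brownian motion on a rooted tree with branch lengths, tip values of
one trait have covariance sigma^2 * C, where C[i,j] is the root-to-MRCA
shared path length. With N species and p = 2k shape coordinates the
multivariate rate is estimated as

    a       = (1' C^-1 1)^-1 1' C^-1 Y          (GLS root estimate)
    U       = C^{-1/2} (Y - 1 a')               (phylogenetic transform)
    sigma^2_mult = sum_i ||U_i||^2 / (N p)

where C^{-1/2} is the inverse symmetric square root from the
eigendecomposition of C. Rows of U are decorrelated with respect to
phylogeny, so ||U_i|| is species i's standardized distance from the root
state. The (N p) normalization makes the estimator reduce exactly to the
standard GLS variance-rate estimator at p = 1, which is verified against a
direct quadratic-form oracle; an N-only normalization would cancel in the
ratio and is not exposed.

Group rates use a single tree-wide transform (one C, one root): the group's
sigma^2_mult averages ||U_i||^2 over that group's rows only. The observed
two-group ratio (focal over reference by default; max-over-min for agnostic
use) is tested against a null distribution generated by re-simulating tip
data nsim = 999 times under a single uniform rate equal to the pooled
estimate, re-running the same estimator, and computing

    p = (1 + #{null ratio >= observed ratio}) / (nsim + 1).

The plus-one rule is slightly conservative relative to a raw 95th-percentile
cut-off but yields valid Monte-Carlo p-values and can never return 0. Null
traits are iid by default (`null_covariance="isotropic"`); `"pooled_R"`
simulates with the estimated residual trait covariance instead. Exact ties
in C (zero-length splits) are regularized by 1e-10 on the diagonal,
recorded in the result metadata.

Choices made where the procedure was genuinely open: the transform is
computed once globally and rows partitioned by group (not re-estimated per
group); with a sample of trees the test is repeated per tree and the
distribution of ratios/p-values reported, with no formal combination rule.

## Discrete characters and stochastic maps

A binary character evolves by a continuous-time Markov chain with rate
matrix Q; the all-rates-different (ARD) parameterization has one rate per
direction. The tip likelihood uses Felsenstein pruning with per-node
rescaling; P(t) = expm(Qt) is computed for all branches at once through the
eigendecomposition of Q (with a scipy `expm` fallback if reconstruction is
inaccurate). Q is fitted by L-BFGS-B over log-rates, 5 starts (a
parsimony-informed guess plus seeded draws), bounds e^-11.5..e^7 on a
unit-depth tree. The fit is checked bit-for-bit against an independent
reference implementation in the test suite. Root prior options: flat
(default, the analysed convention), stationary, or FitzJohn-style
data-driven weights.

Stochastic maps are drawn exactly: node states from their joint conditional
distribution (root from prior x conditional likelihood, then each child
given its parent), and each branch's internal path from the
endpoint-conditioned CTMC by uniformization — the jump count from its exact
conditional distribution under the uniformized chain, intermediate states
from the conditioned discrete chain, jump times as uniform order
statistics. Unlike naive rejection sampling this is exact and efficient at
any rate magnitude. Transition counts are summarized across maps with the
modal total as the headline (a "transition occurred once" statement is read
as a modal summary); the full count distribution and per-state occupancy
times are always retained.

## The synthetic study generator

The generator emulates the statistical structure the analysis presumes, at
the study's design points: 37 species on a pure-birth (Yule) tree rescaled
to unit depth; a care-form character with exactly one origin of
mouthbrooding (forward simulation conditioned on one realized transition,
with the derived clade required to hold 45-90% of species and the ancestral
minority at least 6 — echoing the 9 vs 28 empirical split); a care-provider
character (maternal vs bi-parental) simulated on the induced mouthbrooder
subtree conditioned on five transitions. Shape means evolve as 32
independent Brownian coordinates whose per-branch variance integrates the
care-form history segment by segment: substrate-guarding segments run at
`rate_slow * rate_ratio_true` (default ratio 2.0), mouthbrooding segments
at `rate_slow` (default 2.5e-4 per unit depth, i.e. per-coordinate
divergence ~1.6% of centroid size across the tree — modest, realistic
interspecific shape variation). Rate heterogeneity is therefore painted on
branches through the true character history, while the downstream test only
sees tip groups; that mismatch is intentional, since it is exactly the
inferential situation of the real analysis.

Specimens are the species mean plus isotropic digitizing noise (sd 0.002,
0.2% of centroid size), 5 specimens per species per sex, then randomly
rotated (U(-pi, pi)), scaled (log-scale N(0, 0.1^2)) and translated
(U(-10, 10) per axis) before being written to TPS, so superimposition has
real work to do. All output files round-trip through the package readers,
and everything is reproducible bit-for-bit from the config seed.

What the generator does not emulate: allometry, sexual dimorphism in the
mean shape, correlated trait evolution (coordinates evolve independently),
non-Brownian processes, and phylogenetic uncertainty (one true tree, not a
posterior sample). Passing tests therefore demonstrate correctness of the
machinery and calibration under the model's own assumptions, not robustness
to their violation.

### Measurement error: a known limitation

Species consensus shapes carry sampling error (digitizing noise divided by
specimens per species). The rate estimator attributes all tip variance to
Brownian motion, so consensus error inflates sigma^2_mult most strongly for
taxa on short terminal branches. Because discrete states cluster
phylogenetically, a recently radiated group can appear spuriously fast:
with only 2 specimens per species and 0.5% digitizing noise, a true-null
contrast in this design rejects far above nominal rate. At the defaults (5
specimens, 0.2% noise) the error-to-signal ratio is negligible and the test
holds its nominal level, which is the regime a careful empirical study
operates in. Users applying the package to real data should check specimen
counts and within- vs between-species Procrustes variance before
interpreting rate ratios.

## Pipeline and problem sizes

`run_study` executes one GPA over all specimens, builds three shape
matrices (pooled-sex; male-only and female-only species consensus), runs
the rate-ratio test for three contrasts — substrate guarding vs
mouthbrooding (focal: substrate guarding) on the full tree, and maternal vs
bi-parental care (focal: maternal) within male and within female
mouthbrooders on the induced subtree — and draws 100 stochastic maps for
each character. Per-contrast species lists derive from data availability
(a species missing one sex simply drops out of that contrast), not from a
fixed list. All stage seeds spawn from one root seed; identical config +
seed reproduces the report hash exactly.

The test suite's calibration experiments use 200 replicates for the
type-I-error and ratio-recovery checks (40-tip trees, p = 32, nsim = 999)
and 25 seeded replicates for the end-to-end pattern and transition-count
checks at the full 37-species design — sizes at which the binomial
tolerances quoted in the tests are meaningful while the whole suite stays
comfortably runnable on a laptop.
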