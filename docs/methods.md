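# Methods

`evoscape` approximates and statistically validates a *macroevolutionary
landscape*: a density surface over a low-dimensional morphospace whose peaks
are commonly recurring phenotypes.  The landscape is empirical — a peak is a
frequently occupied region of trait space, not a demonstrated fitness
optimum.  The package treats the landscape as a *hypothesis* that must pass
three checks before it is taken seriously: (i) the traits carry ecological
signal and are independent of the characters used to build the phylogeny (an
attestation recorded in the run config, since it cannot be checked
numerically); (ii) the morphospace contains statistically separated clusters
(PERMANOVA); and (iii) designated cross-clade tip groups are significantly
convergent, so the clusters are not a mere imprint of phylogeny.

## Trait preparation

Taxa are filtered by completeness (observed fraction of the analysed trait
subset, threshold 0.45 by default, inclusive), then each trait is z-scored
over its observed cells (sample variance, n−1).  Distances between taxa are
missing-aware Euclidean with pairwise deletion and rescaling,

d(i,j) = √( (P / m_ij) · Σ_k (x_ik − x_jk)² ),

where the sum runs over the m_ij traits observed in both taxa and P is the
total trait count.  On complete data this is the textbook Euclidean
distance; with missing cells it may violate the triangle inequality, which
is why the ordination applies the Cailliez correction.  The fixed order is
filter → z-transform → distance: z-scores are computed on the filtered taxon
set so dropped fragmentary taxa cannot distort trait scales.

## Clustering and cluster support

Dendrograms use ward.D2 agglomeration on the unsquared distances
(Lance–Williams update `d(ij,k) = √(((n_i+n_k)d_ik² + (n_j+n_k)d_jk² −
n_k d_ij²)/(n_i+n_j+n_k))`, delegated to scipy's `linkage(…, "ward")`, which
implements exactly this recurrence).  Groups come from cutting the merge
sequence to k clusters (k = 2 isolates the two main morphotypes; the sweep
k = 2..10 probes finer structure).

Cluster support is the multiscale-bootstrap AU (approximately unbiased)
p-value.  The *trait* set — never the taxa, which are the objects under
study — is resampled with replacement at sizes r·P for r = 0.5, 1.0, …, 10
(1000 replicates per scale by default).  For each observed node, the
recovery frequency BP_r is transformed to ψ_r = Φ⁻¹(1 − BP_r) and fitted by
weighted least squares to ψ(r) = v√r + c/√r with delta-method weights
B·φ(z)²/(BP(1−BP)); then AU = 1 − Φ(v − c).  Scales with degenerate BP
(exactly 0 or 1) carry no information about the curve and are excluded; a
node with fewer than two informative scales falls back to its clipped
extreme recovery frequency, mirroring the behaviour of the standard
multiscale-bootstrap implementation.  Bootstrap replicates in which some
taxon pair loses all shared traits are skipped and the effective replicate
count per scale is reported.

## Permutation tests

One-way PERMANOVA uses SST = Σ_{i<j} d²_ij/n, SSW summed within groups,
pseudo-F = (SSA/(a−1))/(SSW/(n−a)), with labels permuted (1000 by default)
and p = (1+b)/(1+m) so p is never zero.  The Mantel test correlates
lower-triangle entries of two distance matrices (phenotypic vs patristic
time, or vs difference in taxon age; taxon age defaults to the
stratigraphic-range midpoint, FAD/LAD optional) under simultaneous
row/column permutation, one-tailed upper.  Both tests also offer exhaustive
enumeration for small n, used by the test suite as an exact oracle.

## Ordination

PCoA Gower-centres the squared distances; if a meaningfully negative
eigenvalue appears (below −1e-8·max|λ|), the Cailliez constant — the largest
eigenvalue of the companion matrix [[0, 2Δ₁], [−I, −4Δ₂]] — is added to all
off-diagonal distances, which is the smallest constant making them
Euclidean-embeddable.  Axes with positive eigenvalues are kept; relative
eigenvalues are reported against the positive total.  Downstream axis
subsets ("first two", "first five", "all") refer to these retained axes.

NMDS (k = 2) minimizes Kruskal stress-1 by SMACOF (Guttman-transform) steps
interleaved with pool-adjacent-violators monotone regression of the
configuration distances on the rank order of the input dissimilarities
(ties averaged block-wise).  Each step is guarded by a halving line search,
making stress-1 non-increasing within a start; the best of 20 random starts
plus one metric (PCoA) start is kept (maxit 200, relative tolerance 1e-7),
centred and rotated to principal axes.  Fit is summarized as non-metric
R² = 1 − stress² and the squared Pearson correlation of configuration
distances with the input dissimilarities.

## Landscape construction

Density on the 2-D morphospace is a product-Gaussian kernel estimate with
the convention of the classic 2-D KDE the protocol emulates: the nominal
bandwidth h equals four kernel standard deviations.  The default rule sets
h per axis to the maximum signed coordinate, falling back to the
normal-reference bandwidth when that maximum is not positive, and raising an
error on a constant axis.  The default grid is 25×25 — the classic
estimator's default, against which the 15×15-cell peak neighbourhood is
calibrated (on finer grids the window covers a smaller fraction of the
morphospace and fragment modes appear; grid and window are both config
keys).  `landscape_report` extends the grid limits 3 kernel sd beyond the
data range so essentially all density mass lies on the grid.  A cell is a
peak iff its density strictly exceeds every other cell in the centred
window (truncated at borders); plateaus therefore yield no peak.  Per-time-
bin occupancy assigns each taxon to its nearest peak within the window
radius on the *global* surface, so bins are comparable through time.

## Timescaling and Brownian machinery

The initial chronogram sets tip age = FAD (LAD or midpoint by config),
internal node age = oldest descendant, and pushes the root older by
`root_extension` (default 3 Ma, admittedly arbitrary).  The 'equal'
timescaler lets each maximal root-to-tip run of zero-duration branches share
time equally with the nearest positive ancestral branch by sliding the
intervening node ages (a donor of duration L followed by k zero branches
becomes k+1 branches of L/(k+1)); where zero runs branch, the division
follows the deepest run and a clamping pass keeps ages monotone.  The 'mbl'
timescaler walks tips-to-root raising parents until every branch is at
least `mbl` (default 3 Ma).  Both preserve tip ages and root-to-tip totals
(the root moves only under 'mbl' when forced).

Ancestral states under Brownian motion are the maximum-likelihood values
minimizing Σ (Δx)²/duration — a weighted-Laplacian linear solve whose root
state equals the GLS phylogenetic mean.  Because the solution is linear in
the tip data, the smoother matrix is precomputed once and reused across
simulated datasets.  The evolutionary rate matrix comes from standardized
independent contrasts, R = Σ u_k u_kᵀ/(n−1); multivariate BM simulation
draws per-branch Gaussian increments with covariance duration·R and retains
internal node values.

## Convergence statistics

For a focal pair, Dtip is the tip distance and Dmax the maximum distance
over cross-lineage candidate pairs, each lineage's candidates being the
nodes strictly below the MRCA down to and including the tip.  C1 = 1 −
Dtip/Dmax, C2 = Dmax − Dtip, C3 = C2 / (phenotypic path length of both
MRCA→tip lineages), C4 = C2 / (total phenotypic branch length of the MRCA's
clade).  Multi-tip groups average over unordered pairs.  Significance uses
1000 BM simulations with the fitted rate and reconstructed root; ancestors
are *re-estimated per replicate* with the precomputed ML smoother so
simulated datasets are treated exactly like the observed one (using the
simulations' true node values is available as `anc_mode="true"`).  Note
that C1 has a point mass at zero under the BM null — the focal tips are
frequently their own most divergent candidate pair — so null p-values are
conservative (an atom near p = 1) rather than exactly uniform; significant
values remain interpretable.

The angle-based test mean-centres the ordination coordinates and measures
the angle between tip phenotype vectors; `ang_state` is the mean angle of
the designated set and `ang_state_time` its mean per Ma of patristic
divergence.  Small values indicate convergence; p-values come from random
same-size tip sets (excluding the observed set).  This is a deliberate
simplification of the published angle method, whose regression-derived
ancestral vectors are out of scope; results are comparable at the level of
detected significance, not bit-identical angles.

## Disparity

Disparity is the sum of per-axis sample variances of the retained PCoA
scores (raw z-scored traits optional).  Uncertainty comes from 1000 taxon
bootstraps (median, central 50% and 95% intervals); group differences use
the two-sided Wilcoxon rank-sum (exact enumeration with midranks when both
samples have ≤ 8 values, normal approximation with tie correction
otherwise).  Disparity through time assigns taxa to standard
Jurassic–Cretaceous stage bins by range midpoint (FAD or any-overlap by
config); bins with fewer than two taxa are flagged.  Over/under-dispersion
compares each bin's sum of variances and sum of ranges to 1000 random
same-size subsets drawn without replacement from the whole dataset;
two-tailed p = 2·min(q, 1−q) from the observed quantile.

## Synthetic study conditions

The generator emulates the statistical structure the protocol assumes, at
the scale of the motivating problem: a forward birth–death chronogram
(birth 0.05/Ma, death 0.035/Ma) conditioned on 30 fossil tips whose ages
are anchored to 70–195 Ma so the stage bins are populated; 8 "craniodental"
and 3 "postcranial" traits evolved by exact per-branch Ornstein–Uhlenbeck
steps (mean θ + (x₀−θ)e^{−αt}, variance σ²(1−e^{−2αt})/(2α), reducing to BM
at α = 0); two selective regimes split at the internal branch dividing the
tree most evenly, with craniodental optima 3 z-units apart (α = 0.25/Ma,
σ² = 0.1/Ma — a stationary sd of ~0.45, so regimes are well separated while
within-regime scatter stays realistic); postcranial optima are shared, so
those traits blur rather than reinforce the divide.  Two small subtrees are
painted with regime transitions; their tips are the designated convergent
set.  Missing cells are MCAR *given a per-taxon propensity* drawn from
Beta(3·0.4, 3·0.6) (cell rate 0.4): preservation quality varies by
specimen, so missingness concentrates in poorly preserved taxa and the 45%
completeness filter removes roughly a quarter of the taxa, leaving ~23%
missing cells — the regime the downstream statistics actually operate in.
Masks are redrawn (seeded) until every retained taxon pair shares an
observed trait and the painted tips survive the filter, since a fixture
whose designated exemplars are unanalyzable tests nothing.

What passing tests on these fixtures do *not* show: real morphospaces have
correlated traits, non-Gaussian variation, and non-random fossil sampling
in time; the generator's regimes are cleanly dichotomous and its
missingness carries no phylogenetic signal.  Truth-recovery results should
be read as "the pipeline recovers planted structure under idealized noise",
not as a statement about any empirical dataset.

Measured operating characteristics under the default conditions (20 seeds;
recomputed by `scripts/acceptance.py` and the acceptance tests): the
2-group cut recovers the regimes (Rand index > 0.9) and PERMANOVA separates
them in ≈19–20/20 seeds; the landscape shows exactly 2 peaks in ≈19/20
bimodal runs and 1 peak in ≈20/20 unimodal controls; the painted
convergences are significant by C1 in a majority (≈60%) of seeds — the
painted transitions are single-tip events on finite branches, so partial
convergence and BM-null breadth cap the power.

## Numerical choices and degenerate inputs

Probit-fit BP values are clipped to [1/(B+1), 1−1/(B+1)]; permutation and
randomization p-values use (1+b)/(1+m); zero-duration branches get a
1e-8-of-mean-duration floor in the ASR solve and an exact error in the
two-tip degenerate case; Ward ties break by scipy's nearest-neighbor-chain
order (heights are unaffected); the Cailliez trigger is −1e-8·max|λ|;
NMDS treats tied dissimilarities by block averaging inside the isotonic
fit.  Every stochastic routine accepts either an integer seed or a numpy
Generator; the pipeline derives per-stage seeds deterministically from the
master seed and records them in the run manifest.

## Known limitations

Paper-exact reproduction of the motivating study's tables requires its
supplementary trait matrix, tree set and ranges, which are not shipped;
the package reproduces the *protocol* and validates it on generated data.
The angle-based test is a simplification (above).  AU support assumes the
trait count is large enough that resampling at 0.5× leaves ≥ 2 columns.
The 'equal' timescaler's branching-run rule is a deterministic
generalization of the chain case; other redistribution conventions exist.
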