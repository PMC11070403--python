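# Methods

## The question and the statistic

Given a binary bipartite network (parasites in rows, hosts in columns) and
mixed-type trait tables for both sides, the package asks whether
*functionally similar species interact with similar sets of partners* — a
trait-space analogue of phylogenetic signal in interaction networks. The
test statistic is the Mantel correlation

    M = Pearson( functional distances , partner-composition dissimilarities )

computed over the strict lower triangles of two square matrices on one
side's species: functional distances are patristic distances on that side's
functional dendrogram (or, optionally, its raw Gower dissimilarities), and
partner-composition dissimilarities are unweighted UniFrac distances
between the species' partner sets measured on the *opposite* side's
functional dendrogram. Significance comes from network permutations that
preserve every species' number of partners on both sides; the test is
one-sided (positive association), because the hypothesis is that similar
species share partners.

## Functional dissimilarity and trees

**Gower dissimilarity.** Traits may be continuous, ordinal, nominal,
binary, or grouped multi-label (a set of binary components, e.g. a
combination of lifestyles, treated as one trait). Pairwise dissimilarity is
the weighted mean of per-trait components over the traits observed in both
species: range-normalised absolute differences for continuous traits,
rank-encoded (1..L, then range-normalised) differences for ordinal traits,
0/1 mismatch for nominal and binary traits, and the mean component
mismatch for a multi-label group. Missing values are never imputed; a pair
with no shared observed trait is an error. Continuous traits are
standardized first (sample, n−1, variance; optional log transform for
heavy-tailed traits such as geographic range size).

**Balanced contributions.** Plain Gower lets high-variance traits dominate
the combined matrix. Weights are therefore chosen so that each trait's
*contribution* — the Pearson correlation between its per-trait
dissimilarities and the combined dissimilarities over comparable pairs —
is as uniform as possible. The optimizer is a projected coordinate search
on the weight simplex (move weight from the highest-contribution trait to
the lowest; multiplicative step, shrink on failure, seeded random restart
from the best point when cornered) minimising the variance of the
contributions, stopping when the max−min spread is ≤ 0.02 or after 2000
iterations. Non-convergence returns the best weights found with a warning
and a flag, not an error: on small tables with discrete traits an exactly
uniform contribution is often unattainable (we verified on stuck cases
that a general-purpose simplex optimizer does no better, so the residual
spread is data-intrinsic).

**UPGMA.** The functional tree is average-linkage agglomerative
clustering of the dissimilarity matrix. Node height is half the merge
dissimilarity, so cophenetic (= patristic) distances reproduce merge
values exactly and the tree is strictly ultrametric. Ties between
minimal-distance pairs are broken by the lexicographically smallest pair
of cluster labels (a cluster is labelled by its smallest member), making
topologies reproducible across platforms.

## Partner-composition dissimilarity

Unweighted UniFrac between two partner sets A and B: the tree is
restricted to A ∪ B (branches above the union's most recent common
ancestor are discarded, so the measure depends only on observed partners);
the value is the fraction of restricted branch length leading exclusively
to leaves unique to one set. It is a semimetric in [0, 1], zero iff
A = B, and reduces to the Jaccard distance on a star tree with equal
branch lengths. Internally every pairwise matrix is computed from a
branch × leaf incidence decomposition of the partner tree, which turns the
10⁴-permutation loop into a handful of small matrix products per permuted
network.

## The permutation null

The null ensemble holds every species' number of partners fixed on both
sides: binary matrices with the observed row and column sums, sampled with
the curveball Markov chain (random trades of exclusive partners between
two rows; symmetric moves, uniform stationary distribution over the
fixed-margin set). Burn-in is 10×(number of 1s) exchanged cells and
thinning (number of 1s) exchanged cells between samples; a trade moving k
columns counts 2k cells. A network whose margins admit a single matrix
(no swappable 2×2) yields a degenerate ensemble and p = 1 with a warning.
The p-value uses the add-one estimator p = (1 + #{M_null ≥ M_obs}) /
(1 + n_perm), never zero, floor 1/(n_perm+1) (0.0001 at 4 decimals for
the default 10,000 permutations). A permuted network whose partner
dissimilarities have zero variance has an undefined correlation and is
counted against the signal (conservative).

**Clade scans.** Every internal node of the focal tree with at least
`min_clade_size` (default 15) descendant species — counted among species
present in the network by default; a switch counts all tree tips instead —
defines a sub-network (focal side restricted to the clade, opposite-side
species left without links dropped) on which the same test runs. Raw
p-values are Bonferroni-multiplied by the number of clades actually
tested. Clades with fewer than 3 usable species or fewer than 2 distinct
partner sets are skipped with a logged reason.

## Determinants of detection and strength

Each region contributes a record with four candidate predictors — number
of parasites, number of hosts, network size (product), connectance — and
the per-side test outcome. Detection (binary) is modelled with a logistic
mixed model and strength (the Mantel correlation of significant tests,
≥5 records required) with a linear mixed model, both with realm as a
random intercept and z-scored predictors. Every subset of the four
predictors plus the intercept-only model (16 models) is fitted by maximum
likelihood and ranked by AIC; non-converging subsets are flagged and
excluded. Reported R² follows Nakagawa & Schielzeth: marginal =
var(fixed)/total, conditional = (var(fixed)+var(random))/total, with the
latent-scale residual π²/3 for the logit link and the estimated residual
variance for the Gaussian response.

The logistic fit integrates the random intercept with 25-point
Gauss–Hermite quadrature and maximises the marginal likelihood with an
analytic gradient (L-BFGS-B, τ ≥ 0; refit from τ≈0 guards the boundary);
standard errors come from the numerical Hessian, conditioning on τ when
the joint Hessian is singular at the boundary. The linear fit exploits the
closed form of the compound-symmetric marginal covariance: given the
variance ratio λ = τ²/σ², GLS coefficients and σ² are explicit, so the
profile likelihood is maximised over the single ratio (bounded search on
log λ, λ = 0 always evaluated); a 1e-10 floor on σ² keeps the noiseless
limit defined, where the model degrades gracefully to its fixed-effects
equivalent. The linear backend is cross-checked against statsmodels
MixedLM (ML) in the test suite.

## Synthetic data

The generator emulates regional survey data structure, not any particular
fauna. Trait tables: correlated multivariate-normal continuous traits
(pairwise correlation 0.3), ordinal traits from thresholded latent normals
(four ranked levels at the 25/50/80% quantiles), uniform categorical
nominal traits; cells masked at the requested missing rate without ever
emptying a row or column, and with a repair step guaranteeing every
species pair shares at least one observed trait. An optional clustered
variant shifts continuous means by cluster so the functional dendrogram
splits into known clades.

Networks: each side gets a one-dimensional latent niche score — the first
principal coordinate of its balanced Gower matrix, unit-scaled — and link
probabilities p_ij ∝ exp(−s·|u_i − v_j|), scaled to a target connectance
(clipped at 1). s = 0 gives trait-independent networks (the test's null);
increasing s makes trait-similar species share partners (its alternative);
an optional row subset restricts the trait matching to one planted clade,
other rows receiving the flat average probability. A repair pass adds
(never removes) the highest-probability missing link for any species left
unconnected, breaking ties uniformly at random — deterministic tie-breaking
here would plant structure that the fixed-margin null cannot mimic and
measurably inflates the false-positive rate.

Regional record sets for the determinants stage are shortcut-simulated:
lognormal species counts (medians ≈ 18 and 14 per side, the scale of
regional flea–mammal surveys), uniform connectance in [0.05, 0.3], realms
assigned round-robin, declared effects applied to z-scored predictors on
the logit (detection) or response (strength) scale plus Gaussian realm
intercepts.

What the generator does *not* emulate: real trait distributions and their
phylogenetic correlation, realm-specific faunas, geographic structure, or
sampling effort. Passing tests therefore demonstrate calibration and
recovery under the planted mechanism, not correctness claims about any
empirical system.

## Validation experiments and problem sizes

The packaged experiments (`funcsignal.experiments`) use 25×20-species
networks at connectance 0.1 with 200 permutations per test and a
five-trait mixed configuration (three continuous, one ordinal, one
nominal, 5% missing) — sizes chosen so a full calibration of thousands of
networks runs on a laptop in minutes:

- *Type-I error*: at s = 0 every rejection is false; the add-one estimator
  at 200 permutations has exact level 10/201 ≈ 4.98%, and the measured
  rate over thousands of networks matches it.
- *Power*: mean observed M and the rejection rate rise monotonically in s
  (desk scale: from ≈0 and ≈5% at s = 0 to ≈0.2 and ≈80% at s = 10 under
  the mixed-trait configuration; higher when traits are low-dimensional so
  the 1-D niche captures them well).
- *Clade specificity*: with signal planted in one of two trait clusters,
  the Bonferroni-corrected scan flags the planted clade far more often
  than its sibling.
- *Determinants recovery*: planted predictor effects on detection and
  strength are recovered in sign and selection by the AIC search in the
  majority of simulated 91-region datasets.

## Numerical choices and degenerate inputs

- Pairwise matrices are symmetrised against float noise and UniFrac
  self-comparisons forced to exactly 0.
- Zero-variance focal or partner distance triangles make the correlation
  undefined: the test reports M = NaN, p = 1, with an explanatory note.
- Result files use 6 significant digits, a fixed column order, and no
  timestamps; every stochastic entry point takes a seed and identical
  seeds give byte-identical outputs (child seeds derive from
  `numpy.random.SeedSequence.spawn`).
- Bonferroni-adjusted p-values are capped at 1.

## Known limitations

- The curveball chain's thinning is fixed rather than adaptive; for very
  small networks successive samples are autocorrelated (the 2×2 case
  alternates deterministically), which is harmless for the bounded,
  uniform-marginal tests done here but would matter for variance estimates
  of chain functionals.
- The balanced-weight optimizer guarantees monotone improvement over
  uniform weights, not a global optimum.
- The 1-D latent niche means planted signal strength saturates once the
  first principal coordinate's share of trait variance becomes the
  bottleneck; multi-dimensional niches are out of scope.
- The logistic model's SEs are Wald-type from a numerical Hessian; with
  few realms the random-intercept variance is weakly identified (expected
  for 2-4 groups, and the reason detection models degrade gracefully when
  τ² → 0).
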