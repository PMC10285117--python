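# Methods

`dispmix` implements two linked estimators for pooled SNP data from
georeferenced population samples: a Bayesian hierarchical model of allele-
frequency dispersal within a region (`popdisp_model`), and a windowed
maximum-objective estimator of admixture-graph parameters between regions
(`migadmi_model`). Both operate on *log-balances* of allele frequencies,
`x = log((1 - f) / f)`: in the compositional-data view a frequency is only
meaningful relative to its complement, and the balance is unbounded, so
Gaussian drift models apply without truncation.

## Dispersal model

### Generative structure

A region holds M sampling sites and one (unknown) diffusion center. For SNP
i with ancestral frequency `fA_i` (balance `xA_i`):

    x_i ~ MvN( xA_i * 1,  s_i * V * g(fA_i) )        site balances, length M
    y_ji ~ Binomial( n_ji, f_ji ),  f_ji = 1/(1+exp(x_ji))

- `V` (M x M) encodes the dispersal scenario: `V_jk` is the shared
  root-to-fork path length of sites j and k on the (implicit) dispersal tree
  rooted at the center, and `V_jj` the full center-to-site path. `V` is
  scaled so its diagonal averages one, making `s_i` interpretable as the
  SNP's total drift on the scale of the mean center-to-site path.
- `g` converts Wright-Fisher drift variance `t f (1 - f)` to the balance
  scale. The delta method gives `var(x) = t / (fA (1 - fA))`, so the default
  is `g(fA) = 1 / (fA (1 - fA))` (`variance_mode="delta"`); the literal
  multiplicative form `g = fA (1 - fA)` is kept behind
  `variance_mode="literal"` for comparison. The choice changes how strongly
  intermediate-frequency SNPs drift relative to extreme ones; the delta form
  is consistent with the moment-matching derivation and is used throughout.
- `n_ji = 0` encodes a missing cell: it contributes nothing to the binomial
  term, but the site's balance is still part of the drift vector.

Priors: `fA_i ~ Beta(a_i, b_i)` with a weak hyper-prior — mean
`a/(a+b) ~ Unif(0,1)`, size `a+b ~ Exp(1)` — and `s_i ~ Exp(1)`. Because
sampling runs on `xA` rather than `fA`, the prior carries the logit Jacobian
`fA (1 - fA)`; omitting it leaves the prior without tail decay in `xA` and
chains wander to `|xA| ~ 40` (this failure mode is covered by a test). The
ancestral frequency is additionally confined to `[1e-4, 1 - 1e-4]` through a
smooth tanh bound on `xA` (|xA| <= 9.21), which keeps balances finite and
removes heavy tails for weakly informed SNPs.

### Covariance from distances

For a candidate center, the scenario supplies center-to-site distances `d_j`
and site-to-site distances `x_jk` — geodesic (haversine, R = 6371 km) for
the "linear" scenario, least-cost path costs over a user raster for
"routes" (8-connected Dijkstra; edge weight = mean of the endpoint cell
costs x step length, diagonal steps x sqrt 2). The covariance heuristic is

    rho_jk = max(0, (d_j + d_k - x_jk) / 2),    V_jj = d_j.

On distances that are additive on a rooted binary tree this recovers the
shared-path matrix *exactly* (`d_j + d_k - x_jk` is twice the common path);
for general distances it is a heuristic and can produce an indefinite
matrix, so negative eigenvalues are clipped to zero (simple, deterministic,
roughly diagonal-preserving) before the unit-mean-diagonal scaling. The
negative-`rho` floor reflects that shared dispersal path cannot be negative.
Candidate centers form an even `grid x grid` (default 4 x 4) lattice over
the sites' bounding rectangle shrunk by 10% of each side.

### Sampling and selection

The posterior factorizes over SNPs, so Hamiltonian Monte Carlo runs
vectorized over (chains x SNPs) blocks with per-block accept/reject — exact
for a separable Hamiltonian. Defaults: 3 chains x 50,000 iterations, first
half discarded, 10 leapfrog steps, initial step size 0.01 tuned per block by
dual averaging toward 0.8 acceptance during burn-in, chain c seeded
`seed + c`. Sampling uses a non-centered parametrization
(`x = xA + sqrt(s g(fA)) L z`, `L` the Cholesky factor of `V`): in the
centered form the funnel between the drift scale and the site balances left
split R-hat values above 2 at the standard protocol, while the non-centered
bounded form reaches max R-hat ~ 1.01 on the 8-site x 100-SNP reference
simulation. Split Gelman-Rubin R-hat (floored at 1.0) and an FFT/Geyer
effective sample size are computed per parameter; arviz serves as an
independent oracle for both in the test suite.

Centers and scenarios are compared by a BIC-type score, higher better:

    score = 2 max log L - k log(n_obs),   k = N (M + 3),

with `log L` the data log-likelihood (binomial + Gaussian drift layers) of a
retained draw and `n_obs` the observed site x SNP cells. Since every
candidate shares `k` and `n_obs`, the ranking reduces to maximum
log-likelihood; the penalty matters only when hypotheses change the
parameter count. The regional summary exported for admixture analysis is the
posterior-mean balance per SNP, back-transformed to a frequency
(averaging on the balance scale keeps the frequency and balance tables
consistent — the compositional convention). Note that with a free drift
scale the ancestral frequency is a *regional* quantity: at a single site its
posterior mean sits between the data frequency and 1/2 (exact quadrature of
the M = 1 posterior puts E[fA] at 0.42 for y/n = 0.30), while the site-level
posterior frequency concentrates on y/n as n grows.

## Windowed admixture model

### Graph covariance

A migration hypothesis is a rooted base tree (Newick; branch lengths are
free drift variances) plus ordered admixture events. Event: target `y` is a
weighted mixture of Q >= 2 source lineages `z_q` (weights `w` on the
simplex), then accumulates own variance `t_y`. Each `z_q` is the precursor
of current population `x_q` and shares a fraction `alpha_q in [0,1]` of that
population's own (post-split) variance — one `alpha` per source by default,
tied per event on request.

The covariance is built from independent variance components. Every tree
edge is a component; populations load 1 on their root-path edges. Using
`x_q` as a source splits each of its own components of variance v into a
shared part `alpha_q v` (carried by `z_q`) and a private part
`(1 - alpha_q) v`, every previous loading being preserved on both parts, so
all existing covariances are unchanged. The target's loading vector is the
w-weighted sum of the `z_q` loadings plus a fresh `t_y` component. Then
`V = L diag(vars) L^T` — positive semidefinite by construction — and
`D_jk = V_jj + V_kk - 2 V_jk` is the variance of the balance difference.
Nesting (a target sourcing a later event) falls out of the same bookkeeping;
re-using a source in several events splits its own-variance parts
proportionally so each event shares the stated fraction of the *total* own
variance.

### Objective

Chromosomes are cut into overlapping windows (defaults 3 Mb, step 1 Mb,
anchored at 0, half-open; windows with fewer than 10 SNPs dropped — window
counts follow the chromosome span = last SNP position + 1). Within window w
the root-mean-square balance distance `d_w(j,k)` between each population
pair is modelled as `N(0, D_jk)`, treating SNPs inside a window as sharing
one evolutionary rate (the per-SNP scale is set to 1):

    f(D, w) = sum_{j<k} log N( d_w(j,k) | 0, D_jk )
            + (lambda - 1) sum_q log w_q,          lambda = 0.9.

On single-SNP windows this reduces exactly to the per-SNP pairwise Gaussian
likelihood (tested to 1e-10). Each per-pair term is maximized at
`D_jk = d_w^2`, so the objective rewards a graph whose D matrix
moment-matches the observed RMS distances.

The Dirichlet regularizer with `lambda < 1` has no maximum on the raw
simplex — `(lambda - 1) log w_q` diverges to +inf as any weight reaches 0 —
so per-window estimates are the mode in the unconstrained softmax
parametrization, which adds the change-of-variables term `sum_q log w_q` and
restores an interior optimum. The reported objective per window remains the
formula above. This choice shrinks weights slightly toward equality; on the
reference two-source design (true w1 = 0.7) the median recovered weight is
about 0.63. Weights, own variances and branch lengths are optimized by
L-BFGS-B on unconstrained coordinates (log variances, softmax weights,
logistic alphas) with 5 seeded multi-starts per window; a failed window is
flagged and does not affect the others.

### Decomposition and hypothesis comparison

The variance of an admixed population is attributed as
`share_q = w_q cov(z_q, y) / V_yy` and `own = t_y / V_yy`; shares are
nonnegative and sum to one exactly, and reduce to the familiar
`w_q^2 var(z_q) / V_yy` when sources are independent (cross-covariance terms
are attributed half to each participating source through the bilinear form).
Aggregation over windows weights by SNP count. Hypotheses are ranked by
`2 sum_w f_w - k log(n_windows x n_pairs)` (higher better); the negated
total is also reported for readers using a lower-is-better convention.

## Synthetic data

`simulate_region` draws exactly the dispersal model's generative process:
`fA ~ Beta(2,2)` (away from fixation, configurable), per-SNP drift scale
`s ~ Exp(mean 0.05)` — a within-region F_ST-like magnitude typical of crop
landraces sampled within one region — and 50 pooled calls per site per SNP.
The routes scenario uses a random additive dispersal tree (random joins,
exponential branch lengths), whose distances the covariance heuristic
recovers exactly; the linear scenario uses geodesic distances between
uniformly placed sites. Per-SNP draws come from sub-streams spawned off the
master seed, so datasets regenerate identically regardless of evaluation
order.

`simulate_admixture` draws every variance component of a graph as a Gaussian
increment per SNP, plus a Beta(2,2) ancestral balance, and lays SNPs
uniformly on a 12 Mb chromosome (the last SNP anchored at the end so the
default windowing yields 10 windows). The canonical two-source design
(`two_source_admixture_design`) uses three diverged population pairs (cherry
stems 1.5, terminals 0.3), w = (0.7, 0.3), alpha = 1, t_y = 0.1. The stems
matter: mixture weights enter the covariance between the target and each
source's *sister* (`V[y, sister] = w x stem`), and without diverged sisters
the per-window profile likelihood over w is nearly flat (weights are then
confounded with alpha and t_y).

What the simulator does not emulate: linkage disequilibrium within windows
(SNPs are independent given the window structure), per-accession genotype
structure behind the pooled counts, ascertainment of SNP panels, real
least-cost rasters (costs are user-supplied), and selection. Passing
recovery tests therefore shows correctness of the estimators under their own
assumptions, not robustness to these violations.

## Numerical choices

- `V` is jittered by 1e-8 on the diagonal before inversion/Cholesky; a
  matrix that is not positive definite after jitter is an error.
- Frequencies are clipped to `[1e-12, 1 - 1e-12]` inside `balance`;
  the ancestral frequency is bounded to `[1e-4, 1 - 1e-4]` by the sampler's
  tanh reparametrization.
- Unbounded exponentials in the posterior are clipped at `exp(+-60)`;
  non-finite log-densities reject the proposal rather than propagate NaNs.
- A trajectory with energy error beyond 1000 counts as divergent; more than
  50% divergences abort with advice to shrink the step size.
- Score ties in center/scenario selection keep the first candidate and warn.
- Windows anchor at 0 (0-based, half-open); the anchor is a convention, not
  inferred from data.
- Draws are stored as float32 (3 x 25,000 x 100 x 12 draws ~ 360 MB for the
  reference protocol); diagnostics are computed in float64.

## Problem sizes in the test suite

The suite exercises the standard protocol once (8 sites x 100 SNPs,
3 x 50,000 iterations) and uses shortened chains (2 x 2,000-4,000) for
recovery and scenario-selection checks, where point estimates rather than
tail quantiles are needed; the admixture recovery runs 10 windows x 5
multi-starts at 500 SNPs. These sizes were chosen to keep the full suite in
the tens of minutes on a single core while still simulating every model at
realistic parameter values.

## Known limitations

- The call-rate filter sees only pooled counts; the per-accession
  denominator is approximated by the largest per-SNP total. Datasets whose
  missingness varies strongly between accessions within a site will be
  filtered slightly differently than by a per-genotype rule.
- Biallelic SNPs only; the multiallelic ilr extension is out of scope.
- The score compares user-specified hypotheses; there is no graph-space
  search.
- Admixture weights are only as identifiable as the hypothesis makes them:
  without diverged relatives of the sources the objective is nearly flat in
  w and estimates lean toward equal weights (see above).
- The "own variance" of a population used as a source is shared with its
  precursor at a single fraction per event; time-structure within a branch
  is not modelled.
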