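# Methods

This note records the model, the assumptions behind it, the numerical
choices in the implementation, and the known limitations.

## 1. Study structure and data model

The sampling frame is a set of large (100 km²) grid cells, each holding up
to six small habitat subunits (habitat patches or roadside corridors).
Subunits receive up to three visits; each visit consists of a pair of
surveys (two observers, or one observer surveying twice), so a subunit has
survey indices `k = 1..6` with `visit = ceil(k/2)` and `first_visit ⇔ k ≤ 2`.

The campaign follows a removal design: as soon as any survey in a grid cell
detects the species, all surveys in that cell at visits strictly *after* the
detection visit are cancelled. Both paired surveys of the detection visit
are retained. A single-observer variant additionally skips the second survey
of a pair when the first already detected.

`gridocc.data.Dataset` stores the three tables (grids, subunits, surveys),
validates identifiers, nesting, the `k`/`visit` relationship, value ranges,
and — critically — removal consistency: a dataset in which some grid cell
has conducted surveys after its first-detection visit is rejected with the
offending cells named.

Covariates: per grid cell, the number of occupied neighboring cells (0–8,
Moore neighborhood) and the proportion of developed land cover (NLCD
classes 21–24); per subunit, developed proportion within a 500 m buffer;
per survey, day of year. Continuous covariates are standardized to mean 0,
SD 1 using the sample SD (`ddof=1`), computed from the analysis dataset
itself. The `Standardizer` objects are stored with the design matrices so
predictions and reporting can return to natural units.

## 2. The model

Three nested Bernoulli levels:

- `z_i ~ Bernoulli(psi_i)` — grid-cell occupancy,
- `a_ij ~ Bernoulli(z_i · theta_ij)` — subunit use given the cell,
- `y_ijk ~ Bernoulli(a_ij · p_ijk)` — detection given the subunit,

with logit-linear predictors

- `logit(psi_i) = psi_int[state_i] + b_nb·nb_i + b_dev·dev_i`
- `logit(theta_ij) = theta_int + b_dev500·dev500_ij`
- `logit(p_ijk) = p_int + b_first·first_ijk + b_doy·doy_ijk + b_doy2·doy_ijk²`

State intercepts use a means parameterization (one free intercept per
state). The day-of-year effect is quadratic to allow a mid-season detection
peak.

**Assumptions.** Closure of both `z` and `a` over the season; no false
positives; conditional independence of surveys given `a`; covariate effects
shared across states except the intercept. The removal stopping rule
depends only on already-observed detections, so the censoring is ignorable:
the likelihood over conducted surveys is the correct likelihood.

**Exact marginalization.** For one grid cell with detection indicator
`d_j = 1{any detection in subunit j}`,

```
L_i = psi_i · Π_j [ theta_ij·P(y_ij | a=1) + (1−theta_ij)·1{d_j=0} ]
      + (1−psi_i) · 1{no detection anywhere in i}
```

`gridocc.model.grid_marginal_loglik` evaluates this in log space. The test
suite verifies it against brute-force enumeration of every `(z, a)`
configuration on 1,000 random small survey histories to 1e-10.

## 3. Priors

Independent Normal(0, `prior_sd`) priors on every coefficient on the logit
scale, with `prior_sd = 2.25` by default. This is a deliberate choice: a
Normal(0, σ) logit prior with large σ (e.g. σ = 10) is bathtub-shaped on
the probability scale, piling prior mass near 0 and 1. In this design the
subunit level is weakly informed (removal censoring discards most repeat
visits), and calibration experiments on replicate simulated campaigns
showed that σ = 10 pulls the `theta` intercept outward by close to one
logit unit and drops 95% interval coverage below 80%. With σ = 2.25 the
implied prior on each probability is near-uniform, coverage is at or above
nominal-ish levels (≥ 88% across all coefficients in pilot runs) and
intercept bias is small. `FitConfig(prior_sd=...)` exposes the choice; the
sensitivity is worth re-checking for designs very different from the
default.

## 4. Posterior computation

`gridocc.fit` runs a data-augmented MCMC sampler:

1. **Latent Gibbs draws.** `z_i` is drawn with `a_i·` collapsed out
   (`P(z_i=1 | …) ∝ psi_i · Π_j [theta_ij q_ij + 1 − theta_ij]`, where
   `q_ij = P(no detection in j | a=1)`), then `a_ij | z_i` is drawn; both
   are forced to 1 where detections occurred.
2. **Coefficient updates** per block (psi / theta / p), each conditionally
   a logistic regression on the current latent responses:
   a componentwise random-walk Metropolis sweep with per-coordinate
   adaptive step sizes (target acceptance 0.44), plus a joint
   adaptive-covariance Metropolis step per block (running estimate of the
   posterior covariance, `2.38²/d` scaling, target acceptance 0.25).
   Adaptation decays as `(t+1)^-0.6` and is frozen after burn-in, so the
   retained draws come from a fixed Markov kernel.

Defaults: 3 chains × 25,000 iterations, 5,000 burn-in, thinned to 5,000
retained draws (`full_config`). A shorter `smoke_config`
(3 × 4,000 / 1,000 burn-in) is used for replicate experiments and examples;
the shorter regime was sized so that split R-hat stays near 1 on the default
design — below 3 × ~4,000 iterations the psi block does not reliably mix.

Convergence is summarized by split R-hat (rank-preserving split of each
chain in half; classic pooled form also available), with a RuntimeWarning
raised when any parameter exceeds 1.1, and a separation warning when a
posterior mean runs away on the logit scale (|mean| > 15).

**Validation.** The augmented sampler was checked against an independent
affine-invariant ensemble sampler (`emcee`) running on the *exactly
marginalized* posterior: posterior means agree within twice the combined
Monte-Carlo standard error for every coefficient. A large-sample check also
confirms that posterior mean occupancy matches a direct Nelder–Mead
maximization of the marginal likelihood.

**Derived quantities.** Because the sampler carries `z`, the number of
occupied cells `sum(z)` has a full posterior; it is bounded below by the
number of detection-positive cells by construction. Other derived outputs:
state-level mean occupancy, mean subunit use, detection-vs-day curves, and
the occupancy ratio between neighbor counts (both the posterior mean of the
ratio and the ratio of posterior means are reported, since they differ).

## 5. The simulator

`gridocc.simulate.simulate_study` generates a complete campaign from a
`SimDesign` and `ModelParams`:

- grid counts per state default to 21 (IL) / 17 (MN) / 67 (WI) = 105 cells;
- occupied-neighbor counts are drawn from a per-state empirical
  distribution whose pooled mean is 3.4 and SD 1.9;
- developed proportions are Beta-distributed with mean 0.22 / SD 0.24
  (grid) and 0.21 / SD 0.24 (subunit buffer);
- visit days are scheduled inside a mid-summer window with 10–17 day
  revisit gaps; day-of-year is standardized over the *full planned*
  schedule (before censoring), matching how a field schedule would be
  standardized at design time;
- latent states and detections are drawn from the model, then
  `removal_censor` applies the stopping rule (idempotently), and optional
  single-observer skips and missing subunits thin the design further.

Because the analysis standardizes covariates over *conducted* surveys while
the simulator standardizes the planned schedule, generating coefficients
must be re-expressed before comparison with estimates.
`gridocc.model.reexpress_params` performs this exactly (affine map for
linear terms; for the day-of-year quadratic, the intercept absorbs
`b₁c + b₂c²` and the slope becomes `r(b₁ + 2b₂c)` for shift `c` and scale
ratio `r`). This is an identity of the model, not an approximation.

All simulator randomness flows from a single seed via spawned
`SeedSequence` substreams (covariates, schedule, latent states,
detections), so datasets are reproducible and the stages are independently
stable.

**Scope.** The simulator generates campaigns from the fitted model's own
structure. It does not model spatial autocorrelation beyond the
neighbor-count covariate, observer heterogeneity, false positives, or
within-season colonization/extinction.

## 6. Prioritization

`gridocc.prioritize` works on an explicit row/column lattice with a
three-level status per cell (`occupied_known`, `surveyed_no_detection`,
`unknown`). A cell's neighbor count is the number of `occupied_known` cells
among its 8 Moore neighbors; candidate cells are the `unknown` cells with at
least `min_neighbors` (default 4) occupied neighbors, ranked by count.
`attach_predictions` adds posterior occupancy summaries per candidate from a
fitted model. `simulate_lattice` builds synthetic clustered lattices for
testing and demonstrations.

## 7. Numerical choices

- All likelihood evaluation in log space via `scipy.special.log_expit`,
  using `log P(y|eta) = log_expit((2y−1)·eta)`; per-subunit and per-grid
  sums via `numpy.bincount`.
- Log-likelihoods are floored at `log(tiny) ≈ −708` to keep optimizers and
  samplers finite at extreme parameter values.
- Standardization uses the sample SD (`ddof=1`) and refuses constant
  covariates rather than silently producing zeros.
- Thinning keeps `floor(chains·(iters−burnin)/retained)`-spaced draws
  (12 at the default regime).
- CSV/JSON artifacts are written with fixed float formats and hashed
  (SHA-256) into a manifest so a pipeline run is byte-reproducible from its
  seed.

## 8. Limitations

- The removal design is efficient in the field but information-poor for the
  detection and subunit levels: most subunits contribute one visit, so
  `theta` and `p` have wide posteriors at the default campaign size, and
  results are more prior-sensitive there than at the grid level (§3).
- Day-of-year effects are only weakly identified under removal censoring
  because late-season surveys are mostly cancelled in occupied cells.
- The neighbor-count covariate is treated as fixed and known; in reality it
  is an estimate from earlier surveys, and its error is not propagated.
- Closure violations (mid-season colonization or abandonment) bias
  occupancy upward or downward in the usual ways; the model has no dynamics.
- The prioritization score is a heuristic ranking, not a decision-theoretic
  optimal design.
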