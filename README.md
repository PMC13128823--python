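# gridocc

Multi-scale Bayesian occupancy modelling for rare-species survey grids, with
a removal survey design and neighbor-based prioritization of future surveys.

`gridocc` was built around a concrete monitoring problem: estimating how much
of a sampling frame of 100 km² grid cells is occupied by a rare bumble bee
when the species is hard to detect, surveys stop in a grid cell as soon as
the species is found there, and occupancy operates at two nested spatial
scales — whole grid cells and small habitat subunits (patches or roadside
corridors) within them. The package provides:

- a validated tabular data model for grid / subunit / survey tables,
- a simulator that generates complete removal-design campaigns from known
  parameters,
- an exact marginal likelihood for the two-scale occupancy model and a
  data-augmented MCMC sampler for its Bayesian fit,
- derived quantities (occupied-cell count, state-level occupancy, detection
  seasonality, occupancy ratios between neighbor counts),
- a Moore-neighborhood prioritization of unsurveyed lattice cells, and
- a `gridocc` command-line interface tying the stages together.

## The model

Three nested Bernoulli levels, indexed by grid cell `i`, subunit `j` within
the cell, and survey `k` within the subunit:

```
z_i   ~ Bernoulli(psi_i)            grid-cell occupancy
a_ij  ~ Bernoulli(z_i * theta_ij)   subunit use, conditional on the cell
y_ijk ~ Bernoulli(a_ij * p_ijk)     detection, conditional on the subunit
```

with logit-linear predictors on standardized covariates:

```
logit(psi_i)   = psi_int[state_i] + b_nb * neighbors_i + b_dev * developed_i
logit(theta_ij)= theta_int + b_dev500 * developed500_ij
logit(p_ijk)   = p_int + b_first * first_visit_ijk + b_doy * doy_ijk + b_doy2 * doy_ijk^2
```

State intercepts use a means parameterization (one intercept per state, no
reference level). Surveys come in pairs: two surveys per visit, up to three
visits per subunit; `first_visit` flags the first pair. Under the removal
design all surveys in a grid cell are cancelled at visits strictly after the
first visit with a detection anywhere in the cell (both paired surveys of
the detection visit are kept). Because the stopping rule depends only on
observed data, it is ignorable for the likelihood.

The latent states `(z, a)` are marginalized exactly per grid cell
(`gridocc.model.grid_marginal_loglik`), which makes an independent
maximum-likelihood or ensemble-sampler cross-check possible. The production
sampler (`gridocc.fit`) instead augments the latent states with Gibbs draws
and updates the coefficients blockwise with adaptive Metropolis steps, which
mixes well and yields posterior draws of derived latent quantities such as
the number of occupied cells, `sum(z)`.

## Worked example

Simulate a campaign at the default study design (105 grid cells split
21/17/67 across IL/MN/WI, 4 subunits per cell, up to 6 surveys each under
the removal rule), fit it, and summarize:

```python
import gridocc as g

dataset, truth = g.simulate_study(g.SimDesign(), seed=42)
print(g.design_summary(dataset))

samples = g.fit(dataset, g.smoke_config(seed=0))
print(g.derived_occupied_count(samples))
print(g.mean_subunit_occupancy(samples))
print(g.state_occupancy(samples))
```

Output (exact values for these seeds):

```
{'n_grids': 105, 'n_subunits': 420, 'n_surveys': 1520, 'n_detected_grids': 66,
 'n_detections': 127, 'n_first_visit_detections': 118}
occupied cells : mean 72.44, median 72, 95% CI [66, 83]   (true count: 70)
subunit use    : mean 0.579, 95% CI [0.434, 0.759]
state  mean  lo95  hi95
   IL 0.727 0.463 0.951
   MN 0.247 0.078 0.500
   WI 0.814 0.673 0.945
```

The fit recovers the simulated truth: 70 cells were actually occupied, and
the posterior for `sum(z)` is centred at 72.4 with a 95% interval of
[66, 83]. All split R-hat values for this run are below 1.03. Occupancy
increases with the number of occupied neighboring cells — comparing a cell
with 6 occupied neighbors to one with 4 (other covariates at their means):

```python
print(g.psi_ratio(samples, 6, 4))
# {'mean_ratio': 1.155, 'median_ratio': 1.158,
#  'ratio_lo95': 1.022, 'ratio_hi95': 1.278, 'ratio_of_means': 1.155}
```

Rank unsurveyed cells of a lattice for future effort (cells with at least 4
occupied Moore neighbors):

```python
lattice = g.simulate_lattice(20, 20, seed=7)
cand = g.candidate_cells(lattice, min_neighbors=4)
print(len(cand))        # 72
print(cand.head(3)[["grid_id", "state", "n_occupied_neighbors"]])
#  grid_id state  n_occupied_neighbors
#  L016009    MN                     8
#  L005012    WI                     7
#  L007012    WI                     7
```

The same pipeline is available from the shell:

```sh
gridocc run --seed 3 --out out/         # simulate + fit + predict + prioritize
gridocc simulate --seed 5 --out data/   # just the simulated dataset
gridocc fit --data data/ --profile full --out fit/
gridocc prioritize --grids lattice.csv --out candidates.csv
```

`gridocc run` writes the dataset CSVs, posterior and summary tables,
occupancy/detection prediction curves, ranked candidate cells, a
`results.json` of headline quantities, and a `manifest.json` with SHA-256
hashes of every artifact; repeated runs with the same seed are
byte-identical.

## Layout

- `src/gridocc/data.py` — tables, validation, standardization, tabulations
- `src/gridocc/model.py` — design matrices, exact marginal likelihood
- `src/gridocc/simulate.py` — study designs, campaign simulator, removal rule
- `src/gridocc/mcmc.py` — sampler, diagnostics, derived quantities
- `src/gridocc/prioritize.py` — lattice neighbor counts and candidate ranking
- `src/gridocc/cli.py` — `gridocc` command-line interface
- `docs/methods.md` — modelling and numerical methods note
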