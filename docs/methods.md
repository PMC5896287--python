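# Methods

This note records the statistical models implemented in `spacecohort`, the
defaults and the reasons for them, and the numerical choices that matter for
reproducing results. Notation: areas `i = 1..I` on an adjacency graph, birth
cohorts `t = 1..T`, observed deaths `y_it`, expected deaths `E_it`, covariate
`x_it`.

## 1. Data preparation

### Cohort assignment on the Lexis grid

Inputs are deaths and person-years on an age-class × calendar-period grid per
area, with 5-year age classes (an open-ended top class is treated as one more
5-year band) and unequal period widths. Each (age, period) cell is assigned to
the 10-year birth cohort whose lower bound is `floor5(period_start −
age_upper)`, where `floor5` rounds down to a multiple of 5. Cohorts step by 5
years, so consecutive cohorts overlap by 5 years and each cell belongs to
exactly one cohort; a cohort labelled `1905-15` collects people born between
1905 and 1915.

### Expected counts

A two-factor Poisson model `log rate(a, c) = mu + age_a + cohort_c` is fitted
on region-wide totals with a log person-years offset (iteratively reweighted
least squares via a standard GLM routine). The model is reparameterised so the
cohort with the highest *fitted* cohort effect — the epidemic peak — is the
reference with effect zero; using the fitted effect rather than the crude rate
avoids age confounding, since cohorts are observed at different age ranges.
Expected counts take the reference-cohort age-specific rates,
`E_it = Σ_cells person_years × exp(mu + age_a)`, summed along each area's
cohort diagonal. Cohort effects are deliberately excluded from `E`: the
relative risks `theta_it` then retain between-cohort level differences, which
is what the models decompose. By default the 6 cohorts with the most
person-years are retained, since extreme cohorts are observed in only one or
two Lexis cells.

The fitted regional totals equal the observed totals exactly (the score
equations of a Poisson log-link GLM with intercept), which is used as a
self-check.

### Deprivation covariate

For each census year, the four indicator proportions (unemployment, low
education, rented housing, no bathroom) are standardised across areas
(population standard deviation) and summed; by construction the index has
cross-area mean zero at every census. An indicator with zero cross-area
variance is an error, not a silent zero. Between and beyond censuses the index
is imputed with the conditional expectation of a first-order Gaussian random
walk given the observed censuses: linear interpolation in time inside the
range, nearest observed value outside. Each cohort's covariate is the index at
its person-year-weighted reference year minus a lag (10 years by default,
reflecting that material conditions act on mortality with delay); the lagged
year must fall within half a grid spacing of an available index year, and the
final covariate is centred so the intercept keeps its interpretation.

## 2. The two models

Both models are Poisson in the counts, `y_it ~ Poisson(theta_it E_it)`.

### Shared-component model (primary)

```
log theta_it = beta0 + beta1 x_it + alpha_t + omega_t (gamma_s_i + phi_s_i)
               + gamma_p_it + phi_p_it
```

- `gamma_s + phi_s` is the **shared spatial field**: `phi_s` has an intrinsic
  CAR prior (kernel `exp(−(lambda/2) phi' K phi)` with `K` the graph
  Laplacian), `gamma_s` is exchangeable normal — the usual convolution of
  structured and unstructured heterogeneity.
- `omega_t > 0` scales the shared field per cohort, constrained by
  `Σ_t log omega_t = 0` so the field's overall scale is identified. On the
  sum-zero log subspace the prior is isotropic normal with variance
  `sigma2_omega × T/(T−1)` (default `sigma2_omega = 1`, weakly informative on
  the log scale); this is the proper restriction of a singular covariance with
  diagonal `sigma2` and off-diagonal `−sigma2/(T−1)`. With `T = 2` the
  constraint means `omega_2 = 1/omega_1` exactly.
- `gamma_p_it + phi_p_it` are **cohort-specific** convolution fields (one CAR
  field and one exchangeable field per cohort), capturing spatial structure
  not shared across cohorts.
- `alpha_t` are cohort main effects; `beta0`, `beta1`, `alpha_t` get
  zero-mean normal priors with variance 10⁴ (flat at the scale of log risks).
- The four field precisions get Gamma(shape 0.5, rate 0.0005) priors — mean
  1000, infinite-variance-like heavy right tail — a standard weakly
  informative choice that does not force smoothing on or off.

### Space-cohort interaction model (comparator)

```
log theta_it = beta0 + beta1 x_it + v_i + u_i + phi_t + psi_it
```

with exchangeable `v`, intrinsic-CAR `u`, cohort main effect `phi_t`
(exchangeable), and an interaction field `psi` whose structure matrix is the
Kronecker product `K_psi = K_u ⊗ R` of the spatial Laplacian with a temporal
structure matrix `R`. Two variants are provided:

- `rw1-time` (default): `R` is the first-order random-walk structure matrix,
  so each `psi_it` is conditionally smoothed toward its spatial *and* temporal
  neighbours; interior cells have conditional precision `2 n_i tau_psi`,
  boundary cells `n_i tau_psi`.
- `identity-time`: `R = I`, interaction effects independent across cohorts
  given the spatial structure.

This is an **open design decision**: for a spatially-structured,
cohort-indexed interaction both variants are defensible (independent cohorts
vs a smooth cohort trajectory per area). The default is `rw1-time` because the
stated conditional-precision pattern above (doubling in the interior) is the
signature of a random-walk temporal factor; the variant is a one-line config
switch and the null-space accounting adapts automatically.

## 3. Identifiability and constraints

The intrinsic CAR kernel is improper: its null space is the per-component
constants, and `K_psi`'s null space is larger (dimension `I + T − 1` for a
connected graph under `rw1-time`). The samplers therefore re-centre after
every sweep and compensate the likelihood exactly, so `theta` is unchanged:

- CAR fields are centred per connected component; for a connected graph the
  removed constant is absorbed into `alpha_t` (shared model, scaled by
  `omega_t`) or `beta0`/`phi_t`.
- The shared-model heterogeneity fields are centred globally (`gamma_s`) and
  per cohort (`gamma_p`), with the means absorbed into `alpha`.
- `log omega` is parameterised directly on the sum-zero subspace through an
  orthonormal (Helmert) basis, so the constraint holds bitwise on every
  sample, not approximately. For `T = 2` this makes `log omega_2 ==
  −log omega_1` exactly.
- The interaction field is projected off the numerically determined null space
  of `K_psi`; the removed component is decomposed into area means, cohort
  means and a grand mean, absorbed into `v`, `phi_t` and `beta0`.

Because the constraints are enforced by re-centring (with exact likelihood
compensation) rather than by soft priors, every kept sample satisfies them to
machine precision, and the precision updates can use the correct kernel ranks
(`I − #components` per CAR field, `rank(K_u) × T` or `rank(K_u) × (T−1)` for
the interaction field).

## 4. Sampler

Metropolis-within-Gibbs:

- Field precisions are conjugate: Gamma(shape `a + rank/2`, rate
  `b + quadratic_form/2`), drawn exactly.
- All other sites use Gaussian random-walk Metropolis. Updates are vectorised
  over conditionally independent blocks: exchangeable fields all at once, CAR
  fields by greedy graph colouring (sites of one colour share no edge, so
  their full conditionals factorise), the interaction field by colouring the
  conflict graph of `K_psi`'s off-diagonal pattern. Acceptance tests use cheap
  local increments of the log posterior (likelihood delta plus prior
  quadratic-form delta), never a full-density evaluation.
- Step sizes adapt during burn-in toward 0.44 acceptance (the scalar-update
  optimum) with Robbins-Monro-style damped multiplicative updates in windows
  of 50 iterations, and are frozen afterwards so the kept chain is a valid
  Markov chain. A post-run warning fires if any block's post-adaptation
  acceptance rate leaves [0.05, 0.95].
- Defaults (100,000 burn-in, 1,000 kept at thinning 100) mirror conservative
  practice for strongly dependent CAR chains; the test suite and the worked
  examples use much shorter, explicitly stated runs.

Reproducibility: one `numpy` Generator seeded from `MCMCConfig.seed` drives an
entire run; equal seeds give bitwise-equal chains.

## 5. Diagnostics

`gelman_rubin` implements the classic potential-scale-reduction factor
`sqrt(((n−1)/n W + B/n)/W)` over ≥ 2 chains (identical constant chains return
1; zero within-chain variance with disagreeing chains is an error).
`partial_autocorrelation` uses Levinson-Durbin recursion on the sample
autocovariance. `monitored_subset` assembles the conventional watch list
(regression terms, cohort effects, scalings, precisions, and a fixed-seed
subset of relative risks) from several chains' sample files and flags
convergence at R̂ < 1.1.

## 6. Synthetic data

Two generators with returned ground truth:

- `simulate_smbc_data` draws directly from the shared-component model on a
  rook-adjacency lattice: CAR fields via the pseudo-inverse eigenbasis
  (component-wise centred), exchangeable fields iid, `E` uniform on a given
  range, counts Poisson. Setting a precision to `inf` zeroes that field, which
  gives exact null scenarios.
- `simulate_lexis_and_census` emulates the *raw* inputs: person-years with
  log-normal area sizes and geometric age attrition, deaths from a log-linear
  age effect plus a concave cohort curve peaking mid-range (so the epidemic-
  peak reference cohort is interior), and census indicator proportions drawn
  logistic-normally around an area deprivation truth whose correlation with a
  spatial risk field is a knob. A `deterministic` mode sets deaths to their
  expectations, making age-cohort effect recovery exact.

What the second generator does **not** emulate: migration between areas,
cohort effects that vary by area (its death rates are exactly age × cohort, so
fitted relative risks are correctly near 1), indicator-specific census
artefacts, or missingness. It is a pipeline exerciser, not a population
simulator.

## 7. Numerical choices and limitations

- Structure matrices are sparse CSR; quadratic forms never densify except in
  tests and in the one-off null-space eigendecomposition of `K_psi`
  (`O((IT)³)`, fine for the intended scale of at most a few hundred areas ×
  a handful of cohorts).
- The sum-zero `log omega` subspace uses an orthonormal basis, so the prior
  is isotropic there and the constraint is exact by construction rather than
  by projection.
- Exact floating-point claims are limited to what IEEE arithmetic can
  guarantee: constraints held bitwise in the sampled parameterisation
  (`Σ log omega == 0.0`), while derived products such as
  `exp(log omega_1) × exp(log omega_2)` can differ from 1 by one unit in the
  last place.
- Islands (areas with no neighbours) are legal in the graph structure; their
  CAR full conditionals are undefined and requesting one raises an error, and
  interaction-field sites with zero conditional precision are left at zero.
- The samplers are single-chain per call; multi-chain workflows run several
  seeds and feed the sample files to `diagnose`. No within-run parallelism.
- Hyperprior sensitivity (the Gamma(0.5, 0.0005) choice) and the two
  interaction-variant alternatives are exposed as configuration, not resolved
  internally; with few cohorts the data often cannot distinguish them, and the
  scalings `omega_t` shrink toward 1 on small lattices (visible in the README
  example).
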