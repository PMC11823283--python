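# Methods

## Model

The package fits a Bayesian dynamic spatial factor model to a panel of
counts `Y[i,j,k]` over `I` areal units (counties), `J` years and `K`
outcomes.  Counts are conditionally Poisson,

    Y[i,j,k] ~ Poisson(E[i,j,k] * lambda[i,j,k]),
    log lambda[i,j,k] = Gamma[k,:] @ F[i,j,:] + eps[i,j,k],

with offsets `E[i,j,k] = P[i,j] * r_k` built from unit-year populations and
per-outcome baseline rates, a `K x m` loadings matrix `Gamma` with
structural zeros, `m` latent spatio-temporal factors `F`, and cell-level
Gaussian noise `eps[i,j,k] ~ N(0, sigma2_k)` carrying overdispersion.

The default loadings pattern is confirmatory, "shared plus pairs": with six
outcomes (overdose deaths, drug-overdose ED visits, opioid-use-disorder
treatment counts, HCV diagnoses, buprenorphine patients, HIV diagnoses) and
four factors, factor 1 loads on every outcome (overall syndemic burden) and
factors 2–4 each load on one interpretable pair — (deaths, ED visits):
overdose; (treatment, buprenorphine): treatment; (HCV, HIV): infectious
disease.  One loading per factor (the anchors `gamma_D1, gamma_E2,
gamma_T3, gamma_C4`) has a positive-truncated prior to pin each factor's
sign; all free loadings are otherwise N(0, 10^2).

Baseline rates are the pooled study-region rates of the first (baseline)
year; interval-censored cells enter that total at the integer midpoint 3 of
the suppression interval.  One outcome (treatment counts) is interval
censored: any count in [1, 5] is released only as a flag, and the
likelihood of such a cell is the probability of the whole interval,
`sum_{y=1..5} Poisson(y; E*lambda)`, computed by a stable log-sum-exp.

## Factor prior

Each factor field is intrinsic-CAR in space and AR(1) in time.  Writing
`f[i,j,m] = mu[j,m] + delta[i,j,m]` with the per-(year, factor) sum-to-zero
constraint `sum_i delta[i,j,m] = 0`, the innovations

    e[:,1,m] = delta[:,1,m],
    e[:,j,m] = delta[:,j,m] - eta_m * delta[:,j-1,m]   (j >= 2)

are independent ICAR fields with pairwise-difference log-density
`-1/2 * sum_edges (e_i - e_l)^2`.  This reproduces the conditional
specification exactly — each site's full conditional is Normal with mean
the (AR-shifted) neighbour average and variance `1/degree` (checked
numerically by a Brook's-lemma test on a 3-node path) — and makes the
centering constraint a linear subspace restriction.  The fully specified
conditional variance (no free spatial scale) is what lets the loadings
carry the scale, a prerequisite for identification.  `eta_m` has a
Uniform(0,1) prior; `mu[j,m]` is flat on the real line; `sigma2_k` is
Inv-Gamma(0.5, 0.5).  The adjacency graph must be connected; disconnected
graphs are rejected rather than centred per component.

We centre `(f - mu)`, not `f`, so `mu[j,m]` keeps its meaning as the
study-region mean of factor m in year j.

### The level of the factors

A point worth recording: the innovation density is a pairwise-difference
quadratic, so it is exactly invariant to adding a constant to one year's
innovations — and `mu[j,m]` enters the innovations only as such a constant.
The prior therefore carries no information about `mu`; a conjugate Gaussian
draw for it from the prior alone does not exist.  `mu[j,m]` is instead a
genuine level parameter identified by the data: it is updated by
random-walk Metropolis against the (censored-)Poisson likelihood under its
flat prior.  The sum-to-zero constraint is enforced after every factor
sweep by re-attributing the field mean to `mu` — `f = mu + delta` is
unchanged, so the likelihood is untouched and no Metropolis correction is
needed.  (Subtracting the mean from `delta` alone would silently shift the
likelihood and is not a valid move.)

## Identification

The likelihood is invariant under `(Gamma H, H' F)` for any orthogonal `H`,
and the interpretable pattern above is not lower triangular, so the
standard triangular constraint cannot be imposed at specification time.
Instead every loadings value is mapped to its identified representative
through an LQ decomposition: transpose `Gamma`, split `[A1 | A2]` with `A1`
the m x m block of the first m outcomes (the default outcome order makes it
generically invertible), QR-factorise `A1 = Qg R1` by modified Gram-Schmidt
with positive diagonal enforced, set `R2 = Qg' A2`, and return
`L = [R1 | R2]'`, `Q = Qg'`, so `Gamma = L Q` holds exactly.  The
likelihood inside the sampler is a function of `(L, Q)` only, and the
identified pair reported for inference is `(L, F_tilde = Q F)`; recovery
comparisons are made on these, never on raw `(Gamma, F)`.

Numerical choices: modified (not classical) Gram-Schmidt for stability; a
pivot column whose post-projection norm falls below `1e-12` times the
largest column norm raises a rank error, which the sampler treats as a
prior-support violation (proposal rejected); the orientation `Q = Qg'`
makes `Gamma = L Q` literally true (the transpose convention is otherwise
ambiguous).  A pattern validator checks the leading block has a free entry
in every row and column and is generically invertible (random filling +
rank test), and searches row permutations for a repair proposal when not.

## Sampler

Metropolis-within-Gibbs with block order: loadings, factor fields, cell
noise, yearly means, AR coefficients, noise variances.

* **Loadings** — per free entry, scalar normal random walk; each proposal
  is LQ-decomposed (rank failure or a nonpositive anchor rejects) and the
  acceptance ratio uses the likelihood through `(L*, Q*)`.
* **Factor fields** — two complementary moves per iteration.  (i) Site-wise
  normal random-walk MH, swept by graph colour so that non-adjacent units
  update simultaneously (vectorised, valid because one colour class shares
  no edge); the site target combines the spatial/temporal innovation terms
  at years j and j+1 with the Poisson terms of the outcomes the factor
  touches.  (ii) One elliptical slice update per (year, factor): the
  conditional prior of a year's field given its temporal neighbours is
  Gaussian on the sum-to-zero subspace (precision `(1+eta^2)(D - W)` for
  interior years, `(D - W)` for the last, conditional mean
  `eta/(1+eta^2) * (delta_{j-1} + delta_{j+1})`), so elliptical slice
  sampling applies exactly and makes rejection-free global moves of the
  whole field.  The global moves matter: a weakly loaded factor's field
  must track loadings excursions, and site-wise walks alone can let such a
  factor collapse into a local mode where its loadings sit near zero and
  the cell noise absorbs its signal.
* **Cell noise** — all `eps[i,j,k]` are conditionally independent, so a
  vectorised per-cell random walk with per-cell acceptance is exact.
* **Yearly means** — scalar random-walk MH against the likelihood (above).
* **AR coefficients** — random-walk MH with reflection at 0 and 1 (the
  folded proposal is symmetric); the target is the product of year >= 2
  innovation densities.
* **Noise variances** — exact conjugate draws,
  `sigma2_k | eps ~ Inv-Gamma(0.5 + IJ/2, 0.5 + sum(eps^2)/2)`.

Proposal scales are per-site and adapt only during burn-in (Robbins-Monro
on the log scale toward 0.44 acceptance, clipped to `exp([-12, 3])`), then
freeze, so the retained chain targets the exact posterior.  A prior-only
mode (likelihood off) exists for testing; there the noise field's full
conditional is exactly `N(0, sigma2)` and is drawn directly, which lets the
heavy-tailed `sigma2` prior mix.  Everything is driven by one
`numpy.random.Generator`, so a fit is bit-reproducible given (data, config,
seed).

Initialisation is neutral: anchors 1, other loadings 0, fields 0, eta 0.5,
sigma2 1.  Default chain settings (500,000 iterations, half burn-in, thin
50) mirror a production surveillance analysis; tests and examples use
desk-scale settings.

## Synthetic data and what it does (not) show

The generator mirrors the motivating study's dimensions at desk scale: a
10x10 rook lattice (100 units, like North Carolina's 100 counties), J=5
years, K=6 outcomes, m=4 factors.  Populations are log-uniform on
[1e4, 1e6] (the span of county populations), constant over years by
default; baseline rates are of order 1e-4 to 1e-3 per person-year (deaths
and HIV rare; ED visits, treatment and buprenorphine more common); truth
loadings default to the posterior means reported in the motivating analysis
so the benchmark operates in the empirically relevant regime — they are
inputs to simulation, never asserted outputs.  Default eta = 0.5 per
factor and sigma2 = 0.1 per outcome.  Treatment counts in [1, 5] are
censored, as the surveillance suppression policy dictates.

What passing recovery shows: on data that exactly satisfy the model's
assumptions, the sampler recovers the identified quantities with roughly
nominal uncertainty at desk scale.  What it does not show: robustness to
real-data features the generator omits — population drift over years,
outcome-specific reporting artefacts, non-separable space-time dependence,
loadings that vary over space or time.

A caveat the recovery experiment surfaces honestly: with the
empirically-realistic truth, the infectious-disease pair factor is weak
(loadings 0.30 and 0.13 against cell noise sd ~0.32 plus Poisson noise),
and its posterior is close to bimodal — a "live" mode near the truth and a
"dead" mode where its loadings sit near zero and sigma2 absorbs the
signal.  Short chains can sit in either mode, which chiefly affects the
coverage of that factor's identified loadings.  The fitted baseline rates
(estimated from the baseline year, as in the motivating analysis) also
absorb each outcome's year-1 mean relative risk, so the factor means mu
are recovered up to an outcome-level offset; comparisons of mu and F_tilde
to simulation truth inherit that offset, which is a property of the
estimand, not an error in the chain.

## Limitations

Single-chain inference (split diagnostics are exposed, not gated);
separable space-time structure only; constant loadings; intrinsic (not
proper) CAR; no model selection for the pattern — it is confirmatory by
design.
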