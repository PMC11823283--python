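# dsfm — dynamic spatial factor models for areal count surveillance data

`dsfm` fits a Bayesian dynamic spatial factor model to panels of counts
over areal units, years and multiple related outcomes — the situation of
syndemic surveillance, where several imperfect indicators (overdose
deaths, overdose-related ED visits, treatment counts, buprenorphine
prescriptions, HCV and HIV diagnoses) jointly reflect an epidemic that is
not directly observable.  It is written for spatial epidemiologists and
biostatisticians who want interpretable shared components rather than a
generic dimension reduction.

## Model

Counts are Poisson around population-scaled baseline expectations,

    Y_ijk ~ Poisson(E_ijk λ_ijk),      E_ijk = P_ij r_k,
    log λ_ijk = Γ_k' F_ij + ε_ijk,     ε_ijk ~ N(0, σ²_k),

with m latent factors F_ij following an intrinsic-CAR (spatial) + AR(1)
(temporal) prior with fully specified conditional variance 1/degree, and a
confirmatory K×m loadings matrix Γ: factor 1 loads on all outcomes, each
remaining factor on one interpretable pair.  One outcome's small counts
(treatment, counts in [1,5]) are interval-censored and enter the likelihood
as the probability of the whole interval.

Because the likelihood is invariant to Γ → ΓH, F → H'F for orthogonal H,
and this pattern is not lower triangular, the model is identified through
an LQ decomposition computed inside the MCMC: every proposed Γ is
factorised as Γ = LQ (L lower triangular with positive diagonal, Q
orthogonal, built by modified Gram-Schmidt on the transposed leading
block), the likelihood is evaluated through (L, Q), and inference reports
the identified pair (L, F̃ = QF).  Posterior sampling is
Metropolis-within-Gibbs with per-site adaptive random walks, chromatic
(graph-coloured) vectorised factor updates plus elliptical slice refreshes
of whole factor-year fields, and conjugate inverse-gamma draws for σ².
See `docs/methods.md` for the full account.

## Worked example

Simulate a small synthetic scenario (6×6 lattice, 3 years, 6 outcomes,
4 factors), fit a short chain, and summarise:

```python
import dsfm

cfg = dsfm.TruthConfig(grid=(6, 6), n_times=3)
panel, truth = dsfm.simulate(cfg, seed=7)
graph = dsfm.lattice_graph(6, 6)
out = dsfm.run(panel, graph, dsfm.default_pattern(),
               dsfm.SamplerConfig(n_iter=4000, burn_in=2000, thin=4, seed=1))
print(dsfm.summarize(out, outcome_labels=panel.outcome_labels).head(10))
```

which prints (posterior mean and equal-tailed 95% interval per loading;
structural zeros are exact zeros):

```
         parameter     mean     lo95     hi95
   gamma[deaths,1] 0.394268 0.229662 0.545005
   gamma[deaths,2] 0.552013 0.410454 0.693312
   gamma[deaths,3] 0.000000 0.000000 0.000000
   gamma[deaths,4] 0.000000 0.000000 0.000000
gamma[ed_visits,1] 0.209635 0.125446 0.340737
gamma[ed_visits,2] 0.383265 0.274556 0.481588
gamma[ed_visits,3] 0.000000 0.000000 0.000000
gamma[ed_visits,4] 0.000000 0.000000 0.000000
gamma[treatment,1] 0.691117 0.586239 0.789514
gamma[treatment,2] 0.000000 0.000000 0.000000
```

`gamma[deaths,1] ≈ 0.39` is the weight of the shared (overall-burden)
factor on overdose deaths: a one-unit increase in that factor multiplies
the death relative risk by `exp(0.39) ≈ 1.48`.  Row pairs sharing a factor
(deaths/ED visits on factor 2, …) quantify what those outcomes co-vary in
beyond the overall burden.  Recovery against the simulation truth can be
scored with `dsfm.recovery_metrics(truth, out)`; on this short
desk-scale chain it reports, e.g., 72% coverage of the identified
loadings' 95% intervals and a 20% mean absolute relative bias for σ².

The same workflow is available from the shell:

```sh
dsfm simulate --seed 5 --out scenario/
dsfm fit --counts scenario/counts.csv --edges scenario/edges.txt \
         --iterations 20000 --burn-in 10000 --thin 10 --seed 1 --out fit/
dsfm recover --truth scenario/truth.npz --samples fit/draws.npz --out report.json
```

`fit` writes `summary.csv` (Table-style posterior summary), `draws.npz`
and a `manifest.json` sufficient to re-run the fit bit-identically.

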