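# gridspread

Does historical colonization — how early a place could be reached from
the geographic points where a clade entered a continent — leave a
detectable imprint on today's gridded species richness, once current
climate, paleoclimate change and topography are accounted for?
`gridspread` is a Python toolkit for running that whole analysis on
regular raster grids: a stochastic lattice spread simulator that turns
suitability scenarios into *accessibility* surfaces, a minimal envelope
SDM and richness-stacking stage, and the inference battery used in
macroecology — Spearman screening, variance partitioning, standardized
OLS with backward-AIC selection, Moran's *I* permutation tests, and
maximum-likelihood spatial simultaneous autoregressive (SAR) error
models.

It is aimed at macroecologists and biogeographers who want the method
end to end on their own rasters, and it ships a synthetic-landscape
generator (barrier desert, low-suitability forest, high-suitability
corridors, climate gradients, mountain patches) so every stage is
testable without any data downloads.

## The model in brief

**Accessibility.** On a suitability map *s* ∈ [0,1] (sea missing), an
occupancy front starts from origin cells and updates synchronously: a
cell is occupied at *t*+1 iff its 3×3 neighbourhood contained an
occupied cell at *t* and an independent Bernoulli(*s*) trial succeeds
(origins are an external source pool and never go extinct). With
*t*₁(c) the first iteration cell *c* is occupied, the replicate score is

    a(c) = (T + 1 − t₁(c)) / (T + 1),   a(c) = 0 if never reached,

and accessibility is the mean of a(c) over replicates — 1 on origins, 0
on unreachable cells, decreasing with how late a cell tends to be
colonised. Four standard scenarios grade the map: DISP1 (all land
*s* = 1), DISP2 (desert *s* = 0), DISP3 (additionally forest *s* = 0.2),
DISP4 (additionally corridors *s* = 1, other land *s* = 0.5). Iteration
counts follow the minimum-for-full-spread rule (Dijkstra with expected
colonisation cost 1/*s*).

**Inference.** On the coarse analysis grid (block means of the fine
simulation, cells with >50 % land), richness *y* is modelled as

    y = Xβ + u,        u = λWu + ε        (SAR error model)

with z-scored predictors (standardized coefficients), log(x+1)
transforms for skewed precipitation terms, a second-order term for
precipitation seasonality, backward-AIC selection, Moran's *I* with
999-permutation inference (expectation −1/(n−1)), row-standardized
distance-band weights *W*, and pseudo-R² = squared Pearson correlation
of predicted with observed (trend-only `r2_pred` vs full-signal
`r2_full`).

## Worked example

```python
from gridspread.pipeline import build_study_data, analyse_study

data = build_study_data(seed=1)        # landscape, 4-scenario battery,
                                       # richness with SAR(0.8) errors
report = analyse_study(data, seed=1)

print({k: round(v, 2) for k, v in report.spearman_rho.items()})
print("OLS R2", round(report.ols.r2, 2),
      "| residual Moran's I", round(report.ols_moran_i, 2),
      "p", report.ols_moran_p)
print("SAR lambda", round(report.sar.lam, 2),
      "| R2_full", round(report.sar.r2_full, 2),
      "| residual Moran's p", report.sar.moran_p)
```

prints (seed 1, 116 analysis cells):

```
{'DISP1': 0.22, 'DISP2': 0.35, 'DISP3': 0.34, 'DISP4': 0.4}
OLS R2 0.68 | residual Moran's I 0.14 p 0.003
SAR lambda 0.54 | R2_full 0.73 | residual Moran's p 0.613
```

Read: the corridor scenario (DISP4) — the one the synthetic richness
was actually generated from — wins the univariate screen; the OLS fit
leaves significantly autocorrelated residuals; the SAR error model
absorbs that autocorrelation (Moran's *I* becomes non-significant) and
raises the explained variance from the trend-only value to the
full-signal value.

A command-line front end mirrors the library
(`gridspread synth landscape`, `gridspread disperse battery`,
`gridspread infer ols --backward`, `gridspread spatial sar`, ...); run
`gridspread --help`.

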