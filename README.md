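# lapls

Feature selection for multicollinear regression tables by **lasso-assisted
partial least squares (LAPLS)** — PLS latent-variable regression warm-starting
an L1-penalized coordinate-descent elimination loop.

## The problem

Tables from metabolomics and similar assays routinely have far more feature
columns than samples (hundreds of m/z intensity columns, a few dozen
specimens) and strong multicollinearity: co-eluting peaks, isotopes, and
biologically coupled compounds move together. Ordinary least squares is
unusable there, plain PLS regresses on *all* features and cannot discard the
irrelevant ones, and plain lasso handles sparsity but is destabilized by the
collinearity. LAPLS combines the two:

1. **Standardize** features and response (z-score, sample sd).
2. **PLS warm start.** Extract latent components t_h = E·o_h, where o_h is
   the dominant eigenvector of EᵀFFᵀE (computed from the SVD of EᵀF), with
   rank-one deflation between components. Components are added while the
   leave-one-out cross-validity Q²_h ≥ 0.0975. The component fit is
   back-mapped to a per-feature coefficient vector W = O(PᵀO)⁻¹R.
3. **Penalized elimination.** For outer iterations iter = 1, 2, …, minimize
   J(w) = Σᵢ(yᵢ − Σⱼ wⱼxᵢⱼ)² + λΣⱼ|wⱼ| with λ = e^(iter − k) by cyclic
   coordinate descent (soft-threshold updates with dead zone [−λ/2, λ/2]),
   rescale onto the L1 budget Σ|wⱼ| ≤ s, and permanently drop features whose
   coefficients are exactly zero.
4. **Gold standard.** The iteration with the best fitting-data R² defines the
   selected subset; PLS is refit on that subset to give the final reduced
   model.

## Worked example

Simulate a wide multicollinear table (54 samples × 798 features in correlated
blocks of 20 at ρ = 0.7, ten true predictors), select, and evaluate:

```sh
$ lapls simulate --preset wyhxb-like --seed 1 --out wide.csv
wrote 54x798 table to wide.csv

$ lapls select --input wide.csv --response y --k 8 --s 0.1 \
      --trace trace.csv --out result.json
selected 10 features at iteration 11 (r2=0.0988)

$ lapls evaluate --input wide.csv --response y --k 8 --s 0.1 \
      --repeats 10 --seed 1 --out report.csv
   pls: mean r2=0.4578 rmse=4.6250
 lasso: mean r2=-0.0185 rmse=6.3369
 lapls: mean r2=0.6800 rmse=3.4514
```

The elimination trace (`trace.csv`) shows 798 features shrinking to 10 over
11 iterations as λ grows from e^(1−8). The ten selected features hit five of
the ten planted predictors exactly and stand in for four more through
same-block collinear proxies — the behaviour expected when within-block
correlation is 0.7. On held-out 30% splits the reduced model (mean R² 0.68,
RMSE 3.45 in response units) clearly beats both full PLS (0.46) and the
zero-initialized lasso baseline (−0.02). The reported `r2=0.0988` at
selection time is the fitting-data R² of the budget-rescaled solver
coefficients, used only to rank iterations — the deliverable is the refit
reduced model.

The same workflow is available in Python:

```python
from lapls import LAPLSConfig, generate, preset_spec, run_lapls, zscore

sd = zscore(generate(preset_spec("wyhxb-like", seed=1)))
trace, result = run_lapls(sd, LAPLSConfig(k=8, s=0.1))
print(result.gold_standard, result.best_iteration)
```

`lapls grid` sweeps (k, s) on the full table and reports the best cell, which
is how k and s are chosen before a split evaluation.

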