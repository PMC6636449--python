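# Methods

## Model and procedure

LAPLS addresses single-response linear regression on tables with strong
multicollinearity and, typically, many more features than samples. It
assumes an (approximately) sparse linear signal: the response is driven by a
small subset of the columns, the rest being irrelevant or redundant through
correlation.

**Standardization.** Features X and response Y are z-scored column-wise with
the sample standard deviation (divisor q−1), giving E₀ and F₀. All model
fitting happens on this scale; predictions are mapped back with the stored
means/sds, and RMSE is always reported in original response units.
Responses are standardized exactly like features. Zero-variance feature
columns are dropped with a warning by default (wide assay tables routinely
contain them); strict mode raises instead. A constant response always
raises.

**PLS core.** Component weights o_h are dominant eigenvectors of EᵀFFᵀE,
obtained from the SVD of EᵀF rather than by forming the quartic product —
this avoids squaring the condition number; equivalence is tested against a
dense eigendecomposition oracle. Scores t_h = E·o_h; loadings
p_h = Eᵀt/‖t‖², r_h = Fᵀt/‖t‖²; rank-one deflation between components.
Sign convention: the first non-negligible entry of each weight vector is
positive, making extraction fully deterministic (same input → bit-identical
components).

**Stopping (Q²).** Component h ≥ 2 is retained while
Q²_h = 1 − PRESS_h/SS_{h−1} ≥ 0.0975, where PRESS_h sums squared errors of
h-component predictions for each left-out sample (model refit on the other
q−1 rows) and SS_{h−1} is the full-data (h−1)-component residual sum of
squares, summed over response columns. The first component is always
retained — Q² is defined only from h = 2 and the single-component model is
the base case. LOO folds reuse the global standardization (the data are
standardized once, up front). A zero denominator (perfect previous fit)
returns −∞, i.e. "stop". When `max_components` is not given the cap is
min(q−1, p, 10): the Q² rule almost always halts earlier, and the cap bounds
the cost of the q-fold refits on wide tables.

**Coefficient back-map.** The cumulative fit Σ t_h r_hᵀ is expressed over
the original features as W = O(PᵀO)⁻¹R (O, P stacking weights/loadings
column-wise, R stacking response loadings row-wise). PᵀO is unit lower
triangular for genuinely deflation-extracted components, so the solve is
well-posed; a singular PᵀO signals corrupted input and raises. With all
components retained on full-rank data this W equals the OLS solution — a
tested limit.

**Penalized elimination.** The objective
J(w) = Σᵢ(yᵢ − Σⱼ wⱼxᵢⱼ)² + λΣⱼ|wⱼ| is minimized coordinate-wise: with
ρⱼ the partial-residual correlation and zⱼ = Σᵢx²ᵢⱼ, the update is
(ρⱼ∓λ/2)/zⱼ outside the dead zone and exactly 0 for ρⱼ ∈ [−λ/2, λ/2]
(closed interval — boundary ties are zeros). The λ/2 threshold follows from
the residual term being unscaled. Coordinates are cycled in ascending order
with no randomization, so runs are bit-reproducible; convergence is
max|Δwⱼ| < 1e-6 within a sweep, capped at 1000 sweeps (a warning is logged
when the cap binds, which happens on strongly collinear wide designs — the
returned iterate is still a valid descent point and the elimination loop is
robust to it). The exact zeros are what make coefficients usable for
elimination.

The outer loop runs λ = e^(iter − k) for iter = 1..25 (default). After each
convergence the coefficient vector is radially rescaled onto the L1 ball
Σ|wⱼ| ≤ s if it exceeds the budget — this preserves the zero pattern — and
zero-coefficient features are removed permanently, so the surviving set is
non-increasing by construction. Surviving coefficients warm-start the next
iteration; the PLS fit is not re-run between iterations. The best iteration
is the one with the highest fitting-data R² of the (budget-rescaled)
surviving coefficients, earliest on ties; its surviving set is the selected
subset, refit with PLS to produce the reported reduced model.

How the budget s interacts with the solver is a genuinely open design
point; here λ drives sparsity and s acts as a post-hoc radial projection.
A consequence worth knowing: when s is small relative to the natural L1
norm of the solution, the rescaling shrinks fitted values toward zero and
the trace R² becomes small in absolute terms. It still ranks iterations
usefully — iterations with fewer, stronger survivors need less rescaling
and score higher — and the final reduced model is refit without any budget,
so its predictive quality is unaffected. With s large the budget never
binds, trace R² decreases essentially monotonically in λ, and the first
iteration wins; selection then leans entirely on the elimination path.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 10 | λ-schedule offset; λ = e^(iter−k). Useful range ≈ 8–17; larger k keeps penalties gentle for longer. |
| s | 0.1 | L1 budget on the standardized-scale coefficients (unitless). |
| max_iter | 25 | outer iterations (λ spans e^(1−k)..e^(25−k)). |
| max_components | min(q−1, p, 10) | PLS component cap; Q² stopping usually binds first. |
| tol / max_sweeps | 1e-6 / 1000 | coordinate-descent convergence controls. |
| Q² threshold | 0.0975 | cross-validity acceptance level for components h ≥ 2. |

In practice (k, s) are chosen by the grid utility: sweep k at s = 0.1 on the
full table by best trace R², then sweep s at the chosen k.

## Evaluation protocol

`split_evaluate` draws seeded random 7:3 train/test splits (10 repeats by
default, the same splits for every method — a paired comparison; per-repeat
seeds are seed + repeat index). Standardization parameters are estimated on
the training rows only and applied to the test rows, so held-out data cannot
influence scaling, component selection, the λ path, or elimination (a
leakage test mutates test rows and asserts the fitted model is unchanged).
Note the tuning phase deliberately differs: the grid protocol fits on all
rows, as hyperparameter selection precedes the split evaluation.

Baselines: (a) full PLS with Q² stopping; (b) a lasso that is the in-repo
coordinate-descent solver run with zero initialization over the same λ
schedule and best-R² iteration rule, predicted from its best-iteration
coefficients — so the PLS warm start and the reduced refit are exactly the
differences being measured. A repeat whose training response is constant is
skipped with a warning; fewer than min(3, repeats) valid repeats is an
error.

## Synthetic data

The generator emulates the structure of wide collinear assay tables:
zero-mean Gaussian features with block compound-symmetry correlation
(X_j = √ρ·g + √(1−ρ)·e_j with one shared factor g per block, so every
within-block pair has correlation exactly ρ and the covariance is positive
definite for ρ < 1), and y = X[:, support]·coefs + N(0, noise_sd²).
Compound-symmetry blocks were chosen over factor models for analytic
transparency: one knob, block_corr, controls the severity of the
multicollinearity the method targets.

Defaults (n=200, p=50, five blocks of ten at ρ=0.5, five planted predictors
with |coef| ≥ 1, noise sd 0.5) define the support-recovery benchmark used by
the tests and the acceptance script. Presets mirror common table shapes:
`wyhxb-like` (54×798, blocks of 20 at ρ=0.7, ten predictors, noise 0.5),
`dcqt-like` (10×9), `crime-like` (1994×127). Shapes only — the presets do
not attempt to match any real dataset's values.

What the generator does **not** emulate: mass-spectrometry intensity
distributions (nonnegativity, zero inflation, heteroscedastic
intensity-dependent noise), batch effects, or nonlinear response structure.
Passing tests therefore demonstrate correct behaviour under Gaussian
block-collinear sparse-linear conditions, not performance claims on real
assay data.

`make_missing` knocks out a uniform random fraction of feature cells (never
an entire column) to exercise the mean-imputation path; imputation is
applied to the full table before splitting — the simplest reading, with a
known mild leakage caveat.

## Numerical choices

- Orthogonality/identity tolerances: 1e-8 absolute on the standardized
  scale; standardization round-trips at 1e-10.
- The coordinate-descent sweep kernel is numba-jitted when numba is
  importable, with a bit-identical pure-Python fallback (tested for exact
  agreement); all arrays are handled in Fortran order for column access.
- Degenerate inputs: all-zero columns raise in the solver (they must be
  dropped upstream); an empty active set at the first outer iteration
  raises with advice to increase k or s; an emptied active set later simply
  terminates the loop.
- Determinism: no hidden randomness anywhere in the fitting path; the only
  random sources are the generator and the split/permutation draws, all
  seeded, and the CLI threads a single --seed through everything.

## Problem sizes

The test-suite and acceptance script run entirely on generated data at desk
scale: the recovery benchmark at 200×50 (20 replicates) and the wide
protocol at 54×798 with 10 evaluation repeats. These sizes exercise both the
p ≫ q and p < q regimes end to end.

## Known limitations

- Single-response selection only (the PLS core itself accepts L > 1).
- Permanent elimination cannot recover a feature dropped early; with very
  aggressive schedules (small k) relevant features can be lost before the
  best iteration.
- The best-iteration rule uses fitting-data R², not validation R²; with s
  unbound this degenerates to the first iteration (see above).
- Mean imputation and full-table imputation-before-split are deliberate
  simplifications.
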