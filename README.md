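# rsmann

Response-surface and neural-network workbench for designed-experiment
extraction optimization.

`rsmann` reproduces, as a tested reusable pipeline, the complete
computational analysis behind an ultrasound-assisted extraction
optimization study of chlorogenic acid (CGA) from *Lonicera japonica*
flowers: design construction, second-order model fitting with full
ANOVA diagnostics, surface optimization, a perceptron surrogate, and
the head-to-head comparison of the two surrogates. It is aimed at
scientists who run designed extraction/process-optimization experiments
and want every printed table of such an analysis to be recomputable
from the run data.

## What it computes

**Design.** A 5-level, 4-factor central composite rotatable design
(CCRD): 2⁴ factorial corners (coded ±1), 8 axial points at ±α with
α = (2⁴)^(1/4) = 2, and 3 replicated center runs — 27 treatments. The
factors are temperature X₁ (°C), ethanol concentration X₂ (%),
liquid-to-solid ratio X₃ (mL/g) and ultrasonic power X₄ (W), coded as
(actual − center)/step.

**Quadratic response surface.** The full second-order polynomial

    Y = β₀ + Σᵢ βᵢXᵢ + Σᵢ<ⱼ βᵢⱼXᵢXⱼ + Σᵢ βᵢᵢXᵢ²

(15 coefficients) fitted by ordinary least squares in coded units, with
exact coefficient conversion to actual units. The ANOVA reports
per-term partial (Type-III) sums of squares, the lack-of-fit vs
pure-error split (pure error from the center replicates), PRESS via the
hat matrix, R², adjusted R², CV% and the residual standard deviation.

**Optimization.** Canonical (stationary-point) analysis, classical
ridge-of-maxima paths — for each radius r the point maximizing the
surface on the sphere ‖z‖ = r, via the Lagrangian system (μI − B)z = b/2
with μ above the largest eigenvalue of B — and multi-start
box-constrained maximization over the coded design region [−2, 2]⁴.

**Network surrogate.** A 4-10-1 perceptron (tanh hidden layer, linear
output) on [−1, 1] min–max-normalized inputs/targets, trained by
full-batch BFGS with analytic backpropagation gradients, 70/15/15 run
division, early stopping on the validation subset, and best-of-restarts
selection. Deterministic per seed.

**Comparison.** R² = 1 − Σ(Y_pre−Y_exp)²/Σ(Y_m−Y_exp)², RMSE and
AAD = 100·mean(|Y_exp−Y_pre|/Y_pre) for each surrogate over the design
runs and over 4 external validation runs.

The study's printed run tables ship as checksummed text fixtures, and a
synthetic generator draws CCRD experiments from a known quadratic truth
plus Gaussian replicate noise so every stage is testable end to end.

## Worked example

```python
import rsmann as rm

data = rm.load_fixture("ccrd27")      # 27 runs, yields in mg/g
model = rm.fit_quadratic(data)
aov = rm.anova(model, data)
print(round(aov.summary["r_squared"], 4),
      round(aov.table.loc["Model", "F"], 2))
# 0.7914 3.25

print(round(model.predict([33.56, 65.88, 46.0, 150.0]), 2))
# 45.63  (mg/g at the reported optimal settings)

ann = rm.train_mlp(data, restarts=20, seed=0)
fm = rm.compute_metrics(data.response, ann.predict(data.design.actual))
print(round(fm.r_squared, 4))
# 1.0
```

The quadratic explains 79% of the yield variation and is significant
(F = 3.25, p = 0.024) but shows significant lack of fit; the fitted
surface predicts 45.63 mg/g at the study's optimal settings
(33.56 °C, 65.88 % ethanol, 46 mL/g, 150 W, with power on the edge of
the design region); the over-parameterized network fits the runs to
within replicate noise. The `examples/` scripts walk through each
capability (design, fit+ANOVA, optimization, network, comparison,
simulation) and print these numbers with interpretation.

A thin CLI mirrors the library:

```sh
rsmann design | rsmann fit | rsmann anova | rsmann ridge \
  | rsmann optimize | rsmann ann-train | rsmann compare \
  | rsmann simulate | rsmann report --config cfg.yaml
```

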