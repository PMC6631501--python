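# Methods

This note documents the models, algorithms, parameter choices and
limitations of `rsmann`. It is written for a reader who wants to know
exactly what each number the package prints means and how it was
computed.

## Design and coding

A central composite rotatable design for k factors consists of the 2^k
factorial cube at coded ±1, 2k axial points at coded ±α on one axis
each, and n_center replicated center runs. With α = (2^k)^(1/4) the
fourth-order moment condition [iiii] = 3[iijj] holds and the design is
rotatable (prediction variance depends only on distance from the
center); for k = 4 this gives α = 2 and five evenly spaced levels per
factor. The packaged factor set codes temperature (center 50 °C, step
10 °C), ethanol (75 %, 10 %), liquid-to-solid ratio (30 mL/g, 10 mL/g)
and ultrasonic power (120 W, 15 W); steps are stored in the fixture
rather than recomputed.

Coded units are the canonical internal representation. All fitting
happens in coded space, where the model matrix is well conditioned
(actual-unit columns for power² reach 10⁴–10⁵); coefficients convert to
actual units by the exact closed-form substitution x = c + s·z, which
is linear and invertible in the coefficient vector. Run order is
irrelevant to every quantity the package computes; the generator
therefore defaults to the systematic factorial → axial → center order,
with an opt-in seeded permutation.

## Least squares and ANOVA

The full quadratic (1 + 2k + k(k−1)/2 terms; 15 for k = 4) is fitted by
`numpy.linalg.lstsq` after an explicit rank check (a rank-deficient
matrix raises an error naming the collinear columns via pivoted QR).
The fit consumes the printed duplicate-mean responses — one value per
run — because the underlying duplicate-level measurements were not
published; the corrected total with 26 degrees of freedom confirms the
27-row basis.

ANOVA conventions:

* Per-term sums of squares are partial (Type III): the extra sum of
  squares from deleting that single term from the full model, computed
  in closed form as βⱼ²/[(X'X)⁻¹]ⱼⱼ and verified in the tests against
  refit-and-subtract.
* Pure error pools the within-group sums of squares of all replicated
  design points — here the three center runs (2 df). Lack of fit is the
  residual remainder; with zero pure-error df the lack-of-fit F and p
  are reported as NaN, never fabricated.
* PRESS uses the hat-matrix identity Σ(eᵢ/(1−hᵢᵢ))², verified against
  brute-force leave-one-out refitting.
* F tests are one-tailed from `scipy.stats.f`; CV% = 100·√MS_res/ȳ.

Reproduction tolerances: the printed responses carry two decimals, so
recomputed coefficients and ANOVA entries are compared at 0.5% relative
(with a 5·10⁻⁶ absolute floor for the near-zero interaction
coefficients, whose printed values are themselves rounding-limited).
The printed lack-of-fit F (1983.46) is not a reproduction target: it is
the ratio of a well-determined numerator to a 2-df pure-error mean
square printed as 0.015, so its value is dominated by rounding of that
denominator (the package's full-precision value is ≈ 2091).

## Surface optimization

Writing the coded model as ŷ = b₀ + b'z + z'Bz with B symmetric
(off-diagonal entries are half the interaction coefficients):

* **Canonical analysis** solves 2Bz = −b and classifies the stationary
  point by the eigenvalue signs; a singular B (relative tolerance
  10⁻¹⁰) is flagged degenerate instead of inventing a point. For the
  fitted study surface the stationary point is a saddle.
* **Ridge analysis** finds, for each radius r, the maximizer of ŷ on
  the sphere ‖z‖ = r from the Lagrangian system (μI − B)z = b/2 on the
  branch μ > λ_max(B), where ‖z(μ)‖ is strictly decreasing; μ is
  located by bisection/Brent root-finding to 10⁻¹³. Tests certify each
  ridge point against 10⁴ Monte-Carlo points on its sphere and against
  a generic equality-constrained optimizer.
* **Box-constrained maximization** over the coded region (default
  [−2, 2]⁴) runs L-BFGS-B with analytic gradients from the 3^k
  face/edge/center lattice plus seeded uniform starts (64 by default,
  gradient tolerance 10⁻¹⁰). A quadratic over a box at this scale is
  solved reliably by this scheme; tests verify against dense-grid
  brute force on random quadratics.

For the study's fitted surface the box maximum is 46.72 mg/g at
(30 °C, 64.7 %, 50 mL/g, 150 W) — three factors pinned at region edges
— while the study reports its optimum at (33.56 °C, 65.88 %, 46 mL/g,
150 W) with 45.63 mg/g. Evaluating the fitted surface at those reported
settings reproduces 45.63 mg/g exactly, but the reported point is not a
stationary point, not the box-constrained maximum, and not on the
classical ridge path of this surface (its gradient there is far from
zero). The package therefore treats "predicted maximum yield" as the
surface value at the reported settings, reports the design-region
maximum alongside it, and verifies the consistent facts: power sits on
its upper edge, and the region maximum dominates the reported point.
How the original ridge-style search handled the region boundary cannot
be reconstructed from the published information.

## Network surrogate

Architecture: 4 inputs → 10 tanh hidden units → 1 linear output.
Inputs and targets are min–max normalized to [−1, 1] over the full data
set, with bounds stored on the model and predictions returned in mg/g
(requests outside the bounds warn about extrapolation). Training
minimizes full-batch MSE by BFGS with an Armijo backtracking line
search; gradients are computed analytically by backpropagation and
guarded by a central-finite-difference check (< 10⁻⁶ maximum relative
error on random states, with a sign-bug negative control in the
tests).

Choices the source material does not fix, and how they were made:

* **Initialization**: Nguyen–Widrow-style — hidden-unit input vectors
  with random directions and magnitude 0.7·h^(1/k), biases on a regular
  grid — which spreads the tanh active regions over the input cube and
  converged markedly better than plain fan-in-scaled uniform draws
  (retained as an option).
* **Division**: 70/15/15 train/validation/test by run. When no explicit
  split is given, each restart draws its own division from its seed
  stream, mirroring the default behaviour of the toolchain this
  architecture is conventionally trained with; an explicit `SplitSpec`
  pins one division. One 15% subset drives early stopping; the other is
  never consulted during training.
* **Early stopping**: the parameters of the best validation epoch are
  returned after 30 consecutive validation failures (patience). The
  conventional patience of 6 was measured to abort full-batch BFGS
  within ~12 epochs — quasi-Newton epochs are large, irregular steps,
  so a short failure window fires long before the loss landscape is
  explored — and 30 restores normal convergence without affecting the
  returned best-epoch snapshot. Epoch cap 1000.
* **Selection**: the restart (default 20) with the lowest validation
  MSE at its best epoch; ties resolved to the earlier restart. Bit
  identical results for a given seed.

**Which runs drive the gradient.** By default the full-batch loss is
taken over *all* runs, with the validation subset monitored for early
stopping and restart selection (`strict_holdout=False`). This is the
regime that reproduces the study's published per-run network
predictions and overall R²; those predictions fit every run closely,
including runs that are demonstrably unpredictable from the remaining
runs (a leave-one-out analysis with converged networks shows several
runs deviate 4–15 mg/g from anything learnable without them, capping
any true hold-out fit at overall R² ≈ 0.98 in the best conceivable
division and ≈ 0.95 in practice). The textbook protocol — gradients
from the training subset only, so validation/test runs are genuinely
unseen — is available as `strict_holdout=True` and is the right choice
when the network's *predictive* (rather than descriptive) quality is
the question. Under the default regime the overall R² is an in-sample
fit measure; its ceiling on this data set is 1 − SS_pure_error/SS_total
≈ 0.99998, because the three center replicates carry different measured
yields that no single-valued function can fit simultaneously, and
converged training reaches that ceiling for any seed.

## Comparison statistics

R² = 1 − Σ(Y_pre−Y_exp)²/Σ(Y_m−Y_exp)², RMSE = √(Σ(Y_pre−Y_exp)²/n),
AAD = 100·mean(|Y_exp−Y_pre|/Y_pre). The AAD denominator is the
*predicted* value, following the convention printed with these
formulas; the more common experimental-value denominator is available
behind a flag. Metrics are computed separately for the 27 design runs
and the 4 external validation runs (pooled n = 31 only on request). The
study's published comparison-table RMSE (1.9050/0.7006) and AAD
(1.6541/0.4204) rows could not be reconstructed from these formulas
with either n = 27 or n = 4 (for the quadratic, the recomputed RMSE is
≈ 3.30 over the design runs and ≈ 1.33 over the validation runs); the
package reports its own full-precision values and treats only the R²
row as a reproduction target.

## Synthetic generator

`generate_synthetic` draws a CCRD experiment as truth(x) + iid Gaussian
noise, with the published fitted surface as the default truth. The
default noise sd of 0.12 mg/g on a recorded response is the level
implied by the study's center-replicate pure-error mean square (≈0.015
→ sd ≈ √0.015); a high-noise preset at 4.95 mg/g matches the quadratic
fit's residual standard deviation, i.e. the roughness of the real
response around any smooth surface. With `replicates = r > 1`,
individual determinations are drawn with sd·√r so their recorded mean
keeps the nominal sd. Recorded responses are clipped at zero to respect
the yield domain (never triggered at the default scales).

What the generator emulates: the quadratic mean structure, replicated
center points supplying pure error, homoscedastic Gaussian replicate
noise. What it does not: the systematic lack of fit of the real data
(the real surface deviates from *any* quadratic by far more than
replicate noise — that is the study's central observation),
heteroscedasticity, and any run-order or batch effects. Passing
recovery tests on synthetic data therefore validates the estimation
machinery, not the adequacy of a quadratic for real extraction data.

## Verification summary

The test suite checks, among others: run-count and block structure for
k = 2..6; coding round-trips (property-based); exact reconstruction of
the printed design as a coded point set; agreement of the in-package
OLS with statsmodels; exactness of the coded↔actual coefficient
transform; ANOVA additivity, PRESS and partial-SS oracles; ridge
optimality by Monte-Carlo and by a constrained optimizer;
box-maximization against grid brute force; backprop against finite
differences with a negative control; training determinism; noise-free
closure of the generator against the published coefficients; and a
500-replicate parameter-recovery study at the replicate-noise scale
with nominal 95% interval coverage. Problem sizes (500 simulations,
10⁴-point Monte-Carlo spheres, 20 training restarts) were chosen so the
whole suite runs in well under a minute on one core while keeping
Monte-Carlo error far below the tested tolerances.
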