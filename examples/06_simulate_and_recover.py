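"""Simulate CCRD experiments from a known quadratic truth and check
that the fitting pipeline recovers it.

The generator evaluates the published fitted surface at the 27 design
points and adds homoscedastic Gaussian noise at the replicate scale
(sd 0.12 mg/g, the level implied by the study's center-replicate pure
error).
"""

import numpy as np

import rsmann as rm
from rsmann.quadratic import quadratic_design_matrix

spec = rm.SyntheticSpec(noise_sd=rm.NOISE_SD_PURE_ERROR, seed=0)
truth = spec.truth.beta_coded

errors = []
for s in range(200):
    tbl = rm.generate_synthetic(rm.SyntheticSpec(noise_sd=spec.noise_sd, seed=s))
    errors.append(rm.fit_quadratic(tbl).beta_coded - truth)
errors = np.asarray(errors)

print("Coefficient recovery over 200 simulated experiments (coded units):")
print(f"  mean absolute bias   : {np.abs(errors.mean(axis=0)).max():.5f} (worst term)")
print(f"  empirical sd (median): {np.median(errors.std(axis=0)):.5f}")

design = rm.build_ccrd(spec.factors, n_center=3)
X = quadratic_design_matrix(design.coded)
theory = spec.noise_sd * np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
print(f"  theoretical sd (median): {np.median(theory):.5f}")
print(
    "\nBias is at Monte-Carlo noise level and the empirical spread matches"
    " the least-squares theory — the generator and the fitter agree."
)
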