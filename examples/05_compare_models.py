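"""Head-to-head comparison of the quadratic surface and the network.

Both surrogates are scored by R^2, RMSE (mg/g) and AAD (%) on the 27
design runs and on the 4 external validation runs the models never saw
during the design of the comparison.
"""

import rsmann as rm

data = rm.load_fixture("ccrd27")
extra = rm.load_fixture("validation4")

rsm = rm.fit_quadratic(data)
ann = rm.train_mlp(data, restarts=20, seed=0)
rep = rm.compare_models(data, rsm, ann, extra=extra)

for ds, by_model in rep.metrics.items():
    print(f"\n{ds} runs (n={by_model['rsm'].n}):")
    for name, fm in by_model.items():
        print(f"  {name.upper():3s}: R^2 {fm.r_squared:7.4f}   "
              f"RMSE {fm.rmse:6.3f} mg/g   AAD {fm.aad:6.3f} %")
    print(f"  better by R^2: {rep.better[ds]['r_squared'].upper()}")

print(
    "\nThe network dominates in-sample (it can absorb the lack-of-fit the"
    " quadratic provably cannot); on the external runs the two are closer,"
    " which is the honest measure of predictive merit."
)
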