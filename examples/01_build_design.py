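"""Build the five-level central composite rotatable design of the study.

Four factors (temperature, ethanol fraction, liquid-to-solid ratio,
ultrasonic power), axial distance 2 and three replicated center runs
give the 27-treatment design the extraction experiments followed.
"""

import rsmann as rm

factors = rm.load_factors()
design = rm.build_ccrd(factors, alpha=2.0, n_center=3)

print(design.frame.to_string(index=False))
print(
    f"\n{design.n_runs} runs = 2^4 factorial (16) + 2*4 axial (8) + 3 center;"
    " each factor spans five coded levels -2..+2, e.g. temperature"
    f" {factors[0].levels(alpha=2).tolist()} degC."
)
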