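"""Run the six-step one-sided certification test H0: C_L <= c*.

Fits the progressively censored HPLC sample (56 blood samples, 24 observed
failures, times scaled by 980), then tests whether the lifetime performance
index clears the target c* = 0.9 at the 5% level.  Rejecting H0 certifies
that the product meets the desired performance level.
"""

import omegaperf as op

sample = op.load_fixture("hplc_censored")
spec = op.PerformanceSpec(L=0.0191, c_star=0.9, level=0.05)

fit = op.fit_mle(sample, L=spec.L)
result = op.conduct_test(fit, spec)
print(result.summary())
print("\nThe lower bound LB is a one-sided 95% confidence bound for C_L; "
      "c* below LB means the target performance is certified.")
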