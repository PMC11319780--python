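"""Map the lifetime performance index C_L to the conforming rate P_r.

For fixed Omega parameters, the lower specification limit implied by a target
C_L is L = mu - C_L * sigma, and the conforming rate is the probability a
unit survives past L.  The printed table shows that certifying C_L = 1 for
these parameters is the same as certifying that ~83% of units conform.
"""

import omegaperf as op

params = op.OmegaParams(4.28, 2.61, 57.79)
summary = op.moments(params)
print(f"process mean mu = {summary.mu:.5f}, sd sigma = {summary.sigma:.5f}")
print(f"survival exponent a = alpha*gamma^beta/2 = {summary.a_exp:.1f}\n")

table = op.tabulate_cl_pr(params, [-1.0, 0.0, 0.3, 0.5, 1.0, 1.5, 2.0])
print(table.to_string(index=False, float_format=lambda v: f"{v:.5f}"))
print("\nP_r rises monotonically with C_L: a larger index certifies a larger "
      "fraction of conforming product.")
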