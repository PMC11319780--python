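"""Monte-Carlo bias/MSE study of the maximum-likelihood estimators.

Draws complete samples from a known Omega law at two sample sizes, refits
each one, and reports the average bias and mean squared error per parameter.
The MSE of the shape estimates shrinks as n grows; gamma is weakly identified
(Weibull-limit ridge), so its error stays large without hurting C_L.

A scaled-down run (the published design uses 1000 replicates over six sample
sizes; pass reps/sizes of your own for the full study).
"""

import omegaperf as op

design = op.SimulationDesign(
    theta_true=op.OmegaParams(2.0, 1.5, 10.0),
    sample_sizes=(30, 100),
    reps=100,
    seed=1,
)
report = op.run_simulation(design)
print(report.table.to_string(float_format=lambda v: f"{v:10.5f}"))
print("\nfailed fits per n:", report.failed_fits)
print("Shape-parameter MSE shrinks with n: the estimator is consistent "
      "where the data are informative.")
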