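"""Quantile-threshold discretization of a zero-inflated training-load column.

Builds a synthetic daily-kilometres variable (70% rest days at zero, a
lognormal tail on active days), fits the Gaussian-kernel KDE, cuts it at the
50% and 75% CDF fractions into three ordered levels, and validates the
grouping with a one-way ANOVA.
"""

import numpy as np

from ordcause import ContinuousSample, anova_validate, qtf_discretize
from ordcause.synthetic import zero_inflated_lognormal

values = zero_inflated_lognormal(5000, zero_weight=0.7, seed=0)
sample = ContinuousSample(values, name="daily_km")

column, model = qtf_discretize(sample, n_levels_minus_one=2, start_index=2)
print(f"bandwidth h = {model.bandwidth:.4f}")
print(f"thresholds Q = {np.round(model.thresholds, 3)} "
      f"at CDF fractions {model.target_fractions}")
print(f"level occupancies = {np.round(column.proportions(), 3)}")

res = anova_validate(sample, column)
for g, (mu, sd, n) in enumerate(zip(res.group_means, res.group_sds, res.group_ns)):
    print(f"  level {g}: mean {mu:.3f} +- {sd:.3f}  (n={n})")
print(f"F = {res.F:.1f}, p = {res.p:.3g} {res.stars()}")
# The thresholds sit where the smoothed CDF crosses 0.5 and 0.75, so the low
# level absorbs the rest-day spike at zero; a large F with p < 0.05 confirms
# the three levels separate the raw distances.
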