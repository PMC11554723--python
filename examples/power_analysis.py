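"""A priori sample size for a four-predictor normative regression.

Noncentral-F power computation with noncentrality f^2 * N.
"""

from corsinorm import PowerSpec, required_sample_size
from corsinorm.norming import regression_power

spec = PowerSpec(f_squared=0.04, n_predictors=4, alpha=0.05, power=0.80)
n = required_sample_size(spec)
print(f"minimum N for f^2 = 0.04, u = 4, alpha = 0.05, power = 0.80: {n}")
# -> 304, the sample-size floor for a small effect in a 4-predictor model.
print(f"power at N = {n}: {regression_power(n, spec):.4f}")
print(f"power at N = {n - 1}: {regression_power(n - 1, spec):.4f}")
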