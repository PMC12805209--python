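"""Estimate a between-group slope from a CSV of two-level data.

Builds a small balanced dataset (20 groups of 5), writes it to CSV the way a
user's data would arrive, reads it back, and runs both the regularized
Bayesian and the ML estimator.  The printed lambda is the weight on the
data-based between-group variance in the shrinkage denominator; prior_loc is
the prior-implied variance it is pulled toward.
"""

import tempfile

from groupslope import (
    ScenarioSpec,
    generate_dataset,
    ml_result,
    read_grouped_csv,
    regularized_bayes,
)

spec = ScenarioSpec(icc_x=0.1, J=20, n=5, beta_b=0.5, beta_w=0.5, seed=12)
with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
    generate_dataset(spec, 0).to_csv(fh.name)
    data, dropped = read_grouped_csv(fh.name, y="y", x="x", group="group")

rb = regularized_bayes(data)
ml = ml_result(data)

print(f"true between-group slope used by the generator: {spec.beta_b}")
print(f"ML estimate                : {ml.beta_hat:+.4f}  (SE {ml.se:.4f})")
print(f"regularized Bayes estimate : {rb.beta_hat:+.4f}  (SE {rb.se:.4f})")
print(f"selected lambda = {rb.prior_star.lam:.3f}, "
      f"prior_loc = {rb.prior_star.prior_loc:.4f}")
print("The shrinkage estimate trades bias for a much smaller standard")
print("error; at this low ICC and small J the shrinkage is deliberately")
print("strong, and at larger J the two estimates coincide.")
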