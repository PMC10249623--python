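"""Score log K_aw prediction models against experimental values.

Builds two synthetic prediction sets against the experimental K_aw
table — one accurate with a small negative bias, one badly scattered —
and ranks them by RMSE.  Shows how a consistent bias can be removed
(mean error subtracted), shrinking the RMSE toward its debiased floor
sqrt(RMSE^2 - ME^2).
"""

import numpy as np

import kawcycle as kc

values = kc.load_measured_values()
exp_rows = values[(values["quantity"] == "aw") & (values["method"] == "cycle")]
experimental = dict(zip(exp_rows["compound"], exp_rows["log_k"]))

rng = np.random.default_rng(7)
accurate = kc.PredictionSet(
    "theory-based",
    {c: v - 0.34 + rng.normal(0, 0.25) for c, v in experimental.items()},
)
scattered = kc.PredictionSet(
    "empirical-QSPR",
    {c: v + rng.normal(1.5, 1.8) for c, v in experimental.items()},
)

table = kc.compare_models([accurate, scattered], experimental)
print(table.to_string(index=False, float_format="%.2f"))

s = kc.error_summary(accurate, experimental)
corrected = kc.apply_offset(accurate, -s.me)
s2 = kc.error_summary(corrected, experimental)
print(f"\n{accurate.model_name}: RMSE {s.rmse:.2f}, ME {s.me:+.2f}")
print(f"after removing the bias: RMSE {s2.rmse:.2f} "
      f"(= sqrt({s.rmse:.2f}^2 - {abs(s.me):.2f}^2))")
# RMSE ranks overall accuracy; ME isolates systematic bias. A biased
# but precise model beats an unbiased scattered one once corrected.
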