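"""Day-to-day reproducibility of expression profiles.

Simulates a 19-participant cohort on the two-day 9/13/17/21 h protocol,
pairs day-1 against day-2 fold changes at identical clock times, and
reports the pooled error metrics (MAE/MSE/RMSE/MBE) plus the per-gene
Wilcoxon signed-rank test with Bonferroni correction. Small errors and
non-significant Wilcoxon p-values mean the two days tell the same story.
"""

from salivaclock import (CohortConfig, delta_delta_ct, error_metrics,
                         generate_cohort, pair_days, wilcoxon_bonferroni)

cohort = generate_cohort(CohortConfig(n_participants=19, seed=4))
series = delta_delta_ct(cohort.ct)

pairs = pair_days(series, min_points=2)
print(f"{len(pairs.df)} paired observations "
      f"({len(pairs.exclusions)} series excluded)")

m = error_metrics(pairs)
print(f"MAE={m.mae:.3f}  MSE={m.mse:.3f}  RMSE={m.rmse:.3f}  MBE={m.mbe:+.3f}")
print("-> MAE is the average day-1 vs day-2 deviation in fold-change units; "
      "MBE near 0 means neither day runs systematically higher.")

print(wilcoxon_bonferroni(pairs).to_string(index=False))
print("-> adjusted p >> 0.05: no significant day effect for any gene.")
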