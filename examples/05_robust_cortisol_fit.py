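"""Robust cosinor fitting of a cortisol awakening profile.

Cortisol is sampled at 0, 0.5, 1, 2, 5, 8 and 12 h after waking and
declines from a post-awakening peak. A single gross outlier (a stress
spike, say) can drag the ordinary least-squares acrophase hours away; the
soft-L1 loss is quadratic for small residuals and linear for large ones,
so the robust fit shrugs the outlier off.
"""

import numpy as np

from salivaclock import circular_diff, fit_harmonic, fit_harmonic_robust

rng = np.random.default_rng(0)
t = np.array([0.0, 0.5, 1.0, 2.0, 5.0, 8.0, 12.0])  # hours since waking
true_phase = 1.0
y = 6.3 + 3.5 * np.cos(2 * np.pi * (t - true_phase) / 24) + rng.normal(0, 0.3, 7)
y_outlier = y.copy()
y_outlier[4] += 12.0  # gross spike at the 5-h sample

for label, data in (("clean", y), ("with outlier", y_outlier)):
    ols = fit_harmonic((t, data))
    rob = fit_harmonic_robust((t, data))
    print(f"{label:13s} OLS acrophase {ols.acrophase_h:5.2f} h "
          f"(err {circular_diff(ols.acrophase_h, true_phase):4.2f}), "
          f"soft-L1 {rob.acrophase_h:5.2f} h "
          f"(err {circular_diff(rob.acrophase_h, true_phase):4.2f})")
print("-> on clean data the two fits agree; under the outlier the robust "
      "acrophase stays near the true 1 h peak while OLS drifts.")
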