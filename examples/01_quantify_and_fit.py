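"""From raw qPCR cycle thresholds to circadian parameters.

Builds a small CT table for one participant sampled at 9/13/17/21 h on two
consecutive days, quantifies relative expression with the two-step
delta-delta-CT scheme (normalize to GAPDH, then to the series mean), and
fits the fixed-24-h cosinor. The printed mesor/amplitude/acrophase describe
the oscillation: the acrophase is the clock time of peak expression, and
the LRT p-value says whether the rhythm is distinguishable from a flat
profile.
"""

import numpy as np
import pandas as pd

from salivaclock import CtTable, delta_delta_ct, fit_harmonic, rhythmicity_lrt

rows = []
true_phase = 18.0  # evening peak, ARNTL1-like
for day in (1, 2):
    for t in (9.0, 13.0, 17.0, 21.0):
        expr = 1.0 + 0.5 * np.cos(2 * np.pi * (24 * (day - 1) + t - true_phase) / 24)
        rows.append(("P01", day, t, "ARNTL1", 20.0 - np.log2(expr)))
        rows.append(("P01", day, t, "GAPDH", 20.0))
table = CtTable(pd.DataFrame(rows, columns=["participant", "day", "time_h",
                                            "gene", "ct"]))

series = delta_delta_ct(table, reference_gene="GAPDH")[0]
print("fold changes:", np.round(series.values("fold_change"), 3))

fit = fit_harmonic(series)
stat, p = rhythmicity_lrt(fit, method="f")
print(f"mesor={fit.mu:.3f}  amplitude={fit.amplitude:.3f}  "
      f"acrophase={fit.acrophase_h:.2f} h  LRT p={p:.2e}")
print("-> the fitted peak time matches the generating 18 h acrophase; "
      "geometric-mean normalization rescales the mesor to ~1.")
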