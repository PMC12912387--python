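"""Cross-layer associations: clock genes, cortisol, melatonin, bedtime.

Simulates a cohort with built-in physiological couplings, fits cortisol
awakening profiles with the robust soft-L1 cosinor, assembles the
per-participant feature table, and reports the Spearman correlations the
couplings should induce: cortisol level anti-correlates with melatonin,
the ARNTL1 acrophase anti-correlates with the cortisol acrophase, PER2
level correlates positively with melatonin, and later bedtimes mean later
acrophases. MI/MIC capture the same dependencies without assuming
monotonicity.
"""

from salivaclock import (CohortConfig, build_feature_table, delta_delta_ct,
                         generate_cohort, maximal_information_coefficient,
                         mutual_information, spearman_matrix)

cohort = generate_cohort(CohortConfig(n_participants=60, seed=2))
features = build_feature_table(expression_series=delta_delta_ct(cohort.ct),
                               hormone_series=cohort.hormones,
                               participants=cohort.participants)
matrix = spearman_matrix(features)

for a, b in [("cortisol_mesor", "melatonin"),
             ("ARNTL1_acrophase_h", "cortisol_acrophase_h"),
             ("PER2_mesor", "melatonin"),
             ("ARNTL1_acrophase_h", "bedtime_h")]:
    row = matrix.get(a, b)
    print(f"{a:22s} vs {b:22s} r={row['spearman_r']:+.2f}  "
          f"p={row['p']:.1e}  n={row['n']}")

ok = features.df.dropna(subset=["ARNTL1_acrophase_h", "cortisol_acrophase_h"])
x = ok["ARNTL1_acrophase_h"].to_numpy()
y = ok["cortisol_acrophase_h"].to_numpy()
print(f"MI(ARNTL1 phase, cortisol phase)  = {mutual_information(x, y):.2f} nats")
print(f"MIC(ARNTL1 phase, cortisol phase) = "
      f"{maximal_information_coefficient(x, y):.2f}")
print("-> signs match the built-in couplings. The moderate (r ~ -0.5) "
      "phase-phase coupling yields a correspondingly modest MI/MIC at this "
      "cohort size; both rise toward their maxima as the coupling strengthens.")
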