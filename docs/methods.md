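# Methods

## Rhythm model and fitting

All rhythm estimation uses the fixed-period cosinor
y(t) = μ + a·cos(ωt) + b·sin(ωt) with ω = 2π/24 h, fitted by ordinary
least squares on absolute time (hours since the first sampling midnight,
so a two-day protocol occupies [0, 48)). The fixed 24-h period is an
assumption, not an estimate: with 3–4 samples per day over two days there
is no information to identify the period, and entrained human subjects are
expected at ~24 h. Amplitude is √(a² + b²) and the acrophase
(24/2π)·atan2(b, a) mod 24. Fitting on absolute time rather than folding
both days onto one cycle keeps day-to-day level differences visible to the
residuals; a day-folded analysis can be had by passing folded times.

Degenerate designs are handled explicitly rather than silently:

- fewer than 3 distinct phases mod 24 h → `SingularDesignError`;
- exactly 3 points → the fit is exactly determined (`saturated=True`,
  RSS = 0); parameters are returned but no p-value, because a p computed
  from a zero residual would fabricate rhythmicity;
- RSS₁ < 10⁻¹²·RSS₀ → reported as a perfect fit with p = 0 and a flag,
  instead of dividing by ~0.

### Rhythmicity test

Two forms of the nested-model comparison against the intercept-only model
are provided:

- `chi2` (default): the Gaussian likelihood-ratio statistic
  n·ln(RSS₀/RSS₁) referred to χ²(2);
- `f`: the exact finite-sample F statistic ((RSS₀−RSS₁)/2)/(RSS₁/(n−3))
  referred to F(2, n−3).

At the protocol's n = 8 the χ² approximation is strongly anticonservative
(analytically, its rejection rule corresponds to F > 2.79 where the exact
5% point of F(2,5) is 5.79, i.e. a true type-I rate of ~15% at nominal 5%).
The F form is therefore the calibrated choice for small series, verified
by simulation in the test suite; the χ² form is kept as the default
likelihood-ratio reading and is what the sampling-design engine uses for
detection, where the question is power at moderate signal rather than
exact size (its inflation only makes the "no-rhythm" boundary cases
slightly optimistic, and the saturation rule, not the test, is what
excludes 3-point designs). The chosen form is recorded in fit results and
run manifests.

### Robust hormone fitting

Cortisol awakening profiles (samples at 0, 0.5, 1, 2, 5, 8, 12 h after
waking) are fitted with the soft-L1 robustified cosinor: minimize
Σ f²·ρ((rᵢ/f)²), ρ(z) = 2(√(1+z)−1), with `scipy.optimize.least_squares`
(loss `soft_l1`, `f_scale = 0.1`, initialization
(a, b, μ) = (−0.31084448, 2.33838041, 6.33268443)). Because the model is
linear in its parameters the soft-L1 objective is convex, so the fixed
initialization converges globally regardless of data scale; the loss is
quadratic near zero, so on clean data the robust fit coincides with OLS to
numerical precision, while a single gross outlier is down-weighted
linearly. Non-convergence is flagged (`converged=False`), never papered
over.

## ΔΔCT quantification

ΔCT = CT_target − CT_reference per timepoint; ΔΔCT subtracts the mean ΔCT
over the participant's series for that gene (both days — one normalization
window, since the protocol's mean-reference is the series mean); fold
change = 2^(−ΔΔCT) (Livak sign convention: lower CT ⇒ higher expression;
the sign is flippable in config). By construction the geometric mean of
each series' fold changes is 1, which erases between-participant level
differences — deliberately, for profile-shape comparisons. Analyses of
expression *levels* (mean expression, amplitude–mean coupling, hormone
couplings to gene mesors) therefore use the single-delta scale 2^(−ΔCT),
carried in the same series object. Timepoints missing either the target or
the reference CT are excluded with a log entry (config-visible, default =
drop that timepoint); a gene with no usable point yields an empty, flagged
series.

## Reproducibility metrics

Day-1 and day-2 values are paired at identical clock times only (the
protocol fixes sampling times; nearest-neighbour matching would invent
pairs). Series with ≤2 total points over both days are excluded, with the
exclusion logged. Pooled and per-gene MAE/MSE/RMSE/MBE are reported
(day 1 = "predicted", day 2 = "observed", so MBE > 0 means day 2 runs
higher); RMSE ≥ MAE ≥ |MBE| is asserted as a property test. Per-gene
Wilcoxon signed-rank tests (two-sided, zeros dropped by the classical
convention, Pratt handling available; exact null for small tie-free
samples, normal approximation with continuity correction otherwise) are
Bonferroni-corrected across genes. Mean±SEM profiles treat each series
(one participant's day pair) as one independent unit; SEM is reported
missing, not zero, where only one unit contributes.

## Association layer

- **Spearman matrices** use midrank ties and pairwise-complete
  observations; fewer than 4 complete pairs or a constant variable yields
  a flagged NaN. Raw p-values are reported (no multiplicity correction by
  default; Bonferroni/BH behind a flag), matching common practice for
  small exploratory cohorts.
- **Circular variables** (acrophases, bedtime) are re-centered before
  ranking: values are mapped to [ref, ref + 24) so that phases straddling
  midnight stay adjacent. `ref="auto"` (the antipode of the variable's own
  circular mean) is the default used in analyses; a fixed reference (4 h,
  the typical human activity trough) and a fully uncentered replication
  mode are also available. Rank correlation of circular data is only
  meaningful when the phases cluster away from the cut — auto-centering
  guarantees that whenever a cluster exists.
- **Mutual information** is the plug-in estimate in nats on a discretized
  joint: equal-frequency bins (rank-based, so exactly balanced for
  tie-free data), n_bins = round(n^(1/3)) by default; equal-width binning
  is available. The estimator has the usual positive bias O((k−1)²/2n),
  visible in the null tests.
- **MIC** maximizes MI(r×c grid)/ln(min(r,c)) over all grids with
  r·c ≤ n^0.6 (the exponent of the original formulation). Axis partitions
  are equal-frequency; for small problems (min(r,c) ≤ 4 and n ≤ 50) the
  cut positions of each axis are additionally optimized exhaustively given
  an equal-frequency partition of the other axis, bounded at 25 000
  combinations. This is a deliberately conservative approximation of the
  full dynamic-programming MIC search: it scores noiseless functional
  relationships at exactly 1 and independent data near 0, but for noisy
  intermediate dependence it can sit below a full MINE-style optimizer,
  which overfits cut positions upward. Implemented in-house; no installed
  package provides MIC.
- **Cell composition**: the L/E ratio sums leukocyte and epithelial counts
  over the 8 microscopy fields of a slide before dividing (ratio of sums,
  not mean of ratios — fields are small and zero-epithelial fields are
  common); a slide with zero epithelial cells overall is flagged
  undefined. Time-dependence is tested by classical one-way ANOVA.
- **Chronotype**: standard MEQ cut-offs (16–41 evening, 42–58
  intermediate, 59–86 morning), range-checked.

## Synthetic cohort generator

The generator emulates the two-day saliva protocol and is the ground-truth
oracle for every pipeline stage. Per participant and gene,
E(t) = mesor·(1 + rel_amplitude·cos(2π(t−φ)/24)) on the fold-change scale,
converted to CT via CT_target = CT_ref − log₂E + ε with ε additive
Gaussian on the CT scale — qPCR error is approximately homoscedastic in
cycles, making fold-change noise lognormal, exactly what the 2^x transform
implies — plus a per participant-and-day offset creating day-to-day
variation. Defaults, chosen once as realistic study conditions:

| parameter | default | rationale |
|---|---|---|
| sampling times | 9, 13, 17, 21 h × 2 days | the study protocol |
| CT noise sd | 0.2 cycles | typical qPCR replicate scatter |
| day-effect sd | 0.1 cycles | multiplicative day-to-day drift ~7% |
| rel_amplitude | 0.5 (all genes) | saliva clock-gene max/min ≈ 3× |
| acrophase priors | ARNTL1 N(18, 1.5²), PER2/NR1D1 N(10, 1.5²) h | evening vs morning peakers |
| participant mesor | lognormal, σ_log = 0.4 | between-subject level spread |
| bedtime | N(23, 1²) h; phase slope 0.75 h/h | no published effect size exists; a moderate coupling, documented as a free modelling choice |
| cortisol | mesor 6.3 (lognormal σ 0.25), amplitude 3.5 nmol/L, acrophase 1 h after wake ± 0.5 h, phase coupling −0.8 to the ARNTL1 phase deviation, noise 0.8, LOD 2 | awakening-response shape; values below LOD are emitted as the `"<2"` dialect |
| melatonin | mean 20 pg/mL, lognormal couplings −0.8 (cortisol mesor) and +0.5 (PER2 mesor), log-noise 0.3, ULOQ 100 | induces the expected negative/positive correlations; values above ULOQ emitted as `">100"` |
| cells | Poisson(50)/field × 8 fields, 36% epithelial | adult saliva smear composition |
| MEQ | round N(50, 8²), clipped 16–86 | mostly intermediate chronotypes |

Because rel_amplitude is constant across participants while the mesor
varies, the max–min range scales with the mean — the amplitude–mean
coupling seen in mammalian reference tissues. What the generator does
**not** emulate: non-sinusoidal waveforms, multi-day phase drift, seasonal
and sex effects, missing-at-random dropout patterns, saliva degradation or
microbiome content. Passing tests therefore demonstrate correctness of the
estimators under the stated noise model, not robustness to every
real-world artefact.

Hormone censoring policy: below-LOD cortisol values are substituted by 1
(the conventional plotting value; LOD/2 substitution is a config option)
and flagged; above-ULOQ melatonin values are retained in the record but
excluded from analysis sets by default, with exclusions logged and
counted — rows in equal rows out plus logged exclusions, always.

## Sampling-design evaluation

Candidate designs are k points per day inside a waking window (default
9–21 h), evenly spaced (`evenly_spaced_design`, which reproduces the
9/13/17/21 protocol at k = 4), spread across days (`spread_design`), or
enumerated on a time grid (`enumerate_designs`). Each design is scored by
Monte-Carlo refitting against a generative cosine with multiplicative
noise (sd as a fraction of the local mean, default 10%): per replicate,
simulate at the design offsets, fit, and record feasibility
(non-saturated), detection (LRT p < α) and the circular acrophase error.
Success — feasibility 100%, detection rate ≥ 80% at α = 0.05, median
circular phase error ≤ 2 h — is an operationalization chosen here (no
canonical criterion exists); all three thresholds live in config and are
stamped into run manifests. Simulation happens directly at the design
offsets rather than by snapping to the 3-h grid of the emulated dense
series, because protocol-relevant designs (9/13/17/21 h) do not lie on
that grid; `subsample_series` provides literal nearest-time subsetting for
measured dense series. Single-day three-point designs are infeasible by
parameter counting, independent of noise — the reported minimum of 4
points/day is therefore a floor imposed by the model plus a power
statement about 4-point designs.

Problem sizes used throughout (200 replicates per design, 6 designs;
recovery checks on ~2000 participant×gene series; 1000-series null
calibrations) keep every analysis in the seconds-to-a-few-minutes range on
one CPU while leaving Monte-Carlo standard errors well inside the asserted
tolerances.

## Determinism and manifests

Every stochastic routine takes an explicit seed (`numpy.random.default_rng`);
identical config + seed reproduce byte-identical output tables. Each
result directory carries a JSON manifest with the config echo and hash,
seed, package and library versions and per-table row counts.

## Known limitations

- The cosinor is first-harmonic only; strongly non-sinusoidal profiles
  (e.g. sharp cortisol awakening responses) are approximated, which is why
  the robust loss matters there. No 12-h component, no free-period fit,
  no nonparametric rhythm tests.
- MIC is the conservative approximation described above, not the full
  dynamic-programming search.
- Rank correlation of circular variables, even re-centered, degrades when
  phases spread over most of the circle; circular–linear correlation
  coefficients are not implemented.
- The reproducibility layer assumes independence between days; no
  mixed-effects day modelling or ICCs.
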