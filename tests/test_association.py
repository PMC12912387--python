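import numpy as np
import pandas as pd
import pytest

from salivaclock import (classify_chronotype, le_ratio, linregress_with_p,
                         maximal_information_coefficient, mutual_information,
                         oneway_anova, recenter_circular, spearman_matrix)
from salivaclock.association import FeatureTable
from salivaclock.io_formats import CellCountTable


def _features(**cols):
    df = pd.DataFrame({"participant": [f"P{i}" for i in range(
        len(next(iter(cols.values()))))], **cols})
    circular = [c for c in cols if c.endswith(("acrophase_h", "bedtime_h"))]
    return FeatureTable(df, circular)


def test_spearman_worked_example():
    m = spearman_matrix(_features(x=[1.0, 2.0, 3.0], y=[3.0, 1.0, 2.0]), min_n=3)
    assert m.get("x", "y")["spearman_r"] == pytest.approx(-0.5)


def test_spearman_monotone_invariance():
    rng = np.random.default_rng(0)
    x = rng.normal(0, 1, 30)
    y = rng.normal(0, 1, 30)
    base = spearman_matrix(_features(x=x, y=y)).get("x", "y")["spearman_r"]
    trans = spearman_matrix(_features(x=np.exp(x), y=y)).get("x", "y")["spearman_r"]
    assert trans == pytest.approx(base)
    perfect = spearman_matrix(_features(x=x, y=np.exp(x))).get("x", "y")
    assert perfect["spearman_r"] == pytest.approx(1.0)


def test_spearman_flags_constant_and_small_n():
    m = spearman_matrix(_features(x=[1.0, 2.0, 3.0, 4.0], y=[5.0] * 4))
    assert np.isnan(m.get("x", "y")["spearman_r"])
    m2 = spearman_matrix(_features(x=[1.0, 2.0, 3.0], y=[1.0, 3.0, 2.0]), min_n=4)
    assert np.isnan(m2.get("x", "y")["spearman_r"])


def test_circular_recentering_heals_midnight_wrap():
    # phases straddling midnight: raw ranks are scrambled, recentered are not
    phases = np.array([22.0, 23.0, 0.5, 1.5])
    recentered = recenter_circular(phases, ref_h="auto")
    assert np.all(np.diff(recentered) > 0)
    fixed_ref = recenter_circular(phases, ref_h=4.0)
    assert np.all(np.diff(fixed_ref) > 0)
    untouched = recenter_circular(phases, ref_h=None)
    assert np.array_equal(untouched, phases)


def test_linregress_exact_line_and_slope():
    res = linregress_with_p([0.0, 1.0, 2.0], [0.0, 2.0, 4.0])
    assert res.slope == pytest.approx(2.0)
    assert res.intercept == pytest.approx(0.0, abs=1e-12)
    assert res.perfect_fit and res.p == 0.0
    res2 = linregress_with_p([0.0, 1.0, 2.0, 3.0], [5.0, 4.0, 3.0, 2.0])
    assert res2.slope == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        linregress_with_p([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


def test_linregress_p_matches_permutation_oracle():
    rng = np.random.default_rng(8)
    x = rng.uniform(0, 1, 20)
    y = 0.8 * x + rng.normal(0, 1, 20)
    res = linregress_with_p(x, y)
    r_obs = abs(np.corrcoef(x, y)[0, 1])
    n_perm = 20000
    count = 0
    for _ in range(n_perm):
        count += abs(np.corrcoef(x, rng.permutation(y))[0, 1]) >= r_obs
    p_perm = count / n_perm
    se = np.sqrt(max(p_perm, 1e-4) * (1 - p_perm) / n_perm)
    assert abs(res.p - p_perm) < max(4 * se, 0.01)


def test_slope_recovery_within_standard_errors():
    rng = np.random.default_rng(21)
    x = rng.uniform(0, 2, 20)
    y = 3.0 * x + rng.normal(0, 1, 20)
    res = linregress_with_p(x, y)
    assert abs(res.slope - 3.0) < 3 * res.stderr


def test_mutual_information_identity_is_log_bins():
    rng = np.random.default_rng(4)
    x = rng.uniform(0, 1, 1000)
    assert mutual_information(x, x, n_bins=4) == pytest.approx(np.log(4))
    # MI(x, x) = entropy of the binned marginal in general
    assert mutual_information(x, x, n_bins=10) == pytest.approx(np.log(10), rel=1e-6)


def test_mutual_information_null_is_small_and_nonnegative():
    rng = np.random.default_rng(9)
    vals = [mutual_information(rng.uniform(0, 1, 1000), rng.uniform(0, 1, 1000))
            for _ in range(20)]
    assert all(v >= 0 for v in vals)
    assert np.mean(vals) < 0.05  # plug-in bias only


def test_mutual_information_validation():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        mutual_information([1, 2, 3], [1, 2, 3])
    with pytest.raises(ValueError):
        mutual_information(rng.uniform(0, 1, 50), rng.uniform(0, 1, 50), n_bins=1)


def test_mic_functional_relationship_scores_one():
    rng = np.random.default_rng(10)
    x = rng.uniform(0, 1, 200)
    assert maximal_information_coefficient(x, x) == pytest.approx(1.0)
    assert maximal_information_coefficient(x, -3 * x + 2) == pytest.approx(1.0)
    x_small = rng.uniform(0, 1, 30)  # exhaustive cut-optimization path
    assert maximal_information_coefficient(x_small, x_small) == pytest.approx(1.0)


def test_mic_null_and_degenerate():
    rng = np.random.default_rng(12)
    vals = [maximal_information_coefficient(rng.uniform(0, 1, 200),
                                            rng.uniform(0, 1, 200))
            for _ in range(10)]
    assert 0.0 <= min(vals) and np.mean(vals) < 0.3
    assert maximal_information_coefficient(np.ones(50), rng.uniform(0, 1, 50)) == 0.0


def test_mic_decreases_under_heavy_noise():
    rng = np.random.default_rng(13)
    x = np.linspace(0, 1, 200)
    clean = np.sin(2 * np.pi * x)
    noisy = clean + rng.normal(0, 1.5, 200)
    assert (maximal_information_coefficient(x, clean)
            >= maximal_information_coefficient(x, noisy))


def _counts(rows):
    return CellCountTable(pd.DataFrame(
        rows, columns=["participant", "day", "time_h", "field_index",
                       "leukocytes", "epithelial"]))


def test_le_ratio_sums_over_fields():
    table = _counts([("P01", 1, 9.0, 1, 2, 1), ("P01", 1, 9.0, 2, 3, 4)])
    out = le_ratio(table)
    assert out.loc[0, "le_ratio"] == pytest.approx(1.0)  # 5/5
    equal = _counts([("P01", 1, 9.0, 1, 7, 7)])
    assert le_ratio(equal).loc[0, "le_ratio"] == pytest.approx(1.0)


def test_le_ratio_zero_epithelial_flagged_and_share_conversion():
    table = _counts([("P01", 1, 9.0, 1, 5, 0)])
    out = le_ratio(table)
    assert out.loc[0, "undefined"] and np.isnan(out.loc[0, "le_ratio"])
    # 36% epithelial share corresponds to L/E = 64/36
    table2 = _counts([("P01", 1, 9.0, 1, 64, 36)])
    assert le_ratio(table2).loc[0, "le_ratio"] == pytest.approx(64 / 36)


def test_oneway_anova_worked_example_and_null_size():
    f, _ = oneway_anova({"9": [1.0, 2.0], "13": [3.0, 4.0]})
    assert f == pytest.approx(8.0)
    rng = np.random.default_rng(30)
    rejections = 0
    n_sim = 1000
    for _ in range(n_sim):
        groups = {k: rng.normal(0, 1, 6) for k in ("a", "b", "c")}
        rejections += oneway_anova(groups)[1] < 0.05
    se = np.sqrt(0.05 * 0.95 / n_sim)
    assert abs(rejections / n_sim - 0.05) < 3 * se


@pytest.mark.parametrize("score,expected", [
    (41, "evening"), (42, "intermediate"), (58, "intermediate"),
    (59, "morning"), (70, "morning"), (16, "evening"), (86, "morning"),
])
def test_chronotype_cutoffs(score, expected):
    assert classify_chronotype(score) == expected


def test_chronotype_out_of_range():
    with pytest.raises(ValueError):
        classify_chronotype(15)
    with pytest.raises(ValueError):
        classify_chronotype(87)
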