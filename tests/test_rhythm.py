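import numpy as np
import pytest
from scipy import stats

from salivaclock import (HarmonicFit, SingularDesignError, circadian_summary,
                         circular_diff, fit_harmonic, fit_harmonic_robust,
                         restrict_to_interval, rhythmicity_lrt)

TWO_DAY_TIMES = np.array([9.0, 13.0, 17.0, 21.0, 33.0, 37.0, 41.0, 45.0])


def test_exact_cosine_interpolation(cosine):
    t = np.array([0.0, 6.0, 12.0, 18.0])
    fit = fit_harmonic((t, cosine(t, mesor=2.0, amplitude=1.0, acrophase_h=0.0)))
    assert fit.mu == pytest.approx(2.0)
    assert fit.a == pytest.approx(1.0) and fit.b == pytest.approx(0.0, abs=1e-12)
    assert fit.amplitude == pytest.approx(1.0)
    assert fit.acrophase_h == pytest.approx(0.0, abs=1e-9)


def test_constant_series_has_zero_amplitude():
    fit = fit_harmonic((np.array([9.0, 13.0, 17.0, 21.0]), np.full(4, 3.3)))
    assert fit.amplitude == pytest.approx(0.0, abs=1e-12)


def test_singular_design_raises():
    with pytest.raises(SingularDesignError):
        fit_harmonic((np.array([9.0, 9.0, 33.0, 33.0]), np.arange(4.0)))


def test_three_point_fit_is_saturated_without_p_value(cosine):
    t = np.array([9.0, 15.0, 21.0])
    fit = fit_harmonic((t, cosine(t)))
    assert fit.saturated and fit.rss_full == 0.0
    stat, p = rhythmicity_lrt(fit)
    assert stat is None and p is None


def test_monte_carlo_recovery_of_amplitude_and_phase(cosine):
    """500 noisy draws at A=1, acrophase 16 h, sigma=0.2: mean recovered
    acrophase within 0.2 h, mean amplitude within 5%."""
    rng = np.random.default_rng(99)
    t = np.arange(0.0, 48.0, 4.0)
    phases, amps = [], []
    for _ in range(500):
        y = cosine(t, mesor=2.0, amplitude=1.0, acrophase_h=16.0)
        fit = fit_harmonic((t, y + rng.normal(0, 0.2, len(t))))
        phases.append(fit.acrophase_h)
        amps.append(fit.amplitude)
    mean_phase = (stats.circmean(np.array(phases) * 2 * np.pi / 24)) * 24 / (2 * np.pi)
    assert circular_diff(mean_phase, 16.0) < 0.2
    assert abs(np.mean(amps) - 1.0) < 0.05


def test_ols_matches_dense_grid_search_oracle(cosine):
    """On short series the OLS cosinor coincides with a brute-force search
    over acrophase (with mesor/amplitude solved per phase)."""
    rng = np.random.default_rng(7)
    w = 2 * np.pi / 24.0
    for _ in range(3):
        n = rng.integers(5, 13)
        t = np.sort(rng.uniform(0, 48, n))
        y = cosine(t, mesor=rng.uniform(1, 3), amplitude=rng.uniform(0.3, 1.0),
                   acrophase_h=rng.uniform(0, 24)) + rng.normal(0, 0.3, n)
        phis = np.arange(0.0, 24.0, 4e-4)
        c = np.cos(w * (t[None, :] - phis[:, None]))
        s_c, s_cc = c.sum(axis=1), (c * c).sum(axis=1)
        s_y, s_cy = y.sum(), (c * y).sum(axis=1)
        det = n * s_cc - s_c ** 2
        amp = (n * s_cy - s_c * s_y) / det
        mu = (s_y - amp * s_c) / n
        rss = ((y[None, :] - mu[:, None] - amp[:, None] * c) ** 2).sum(axis=1)
        best = int(np.argmin(rss))
        a_o = amp[best] * np.cos(w * phis[best])
        b_o = amp[best] * np.sin(w * phis[best])
        fit = fit_harmonic((t, y))
        assert fit.rss_full <= rss[best] + 1e-12
        assert np.allclose([fit.mu, fit.a, fit.b], [mu[best], a_o, b_o], atol=1e-4)


def test_time_shift_covariance(cosine):
    rng = np.random.default_rng(11)
    t = TWO_DAY_TIMES
    y = cosine(t, acrophase_h=16.0) + rng.normal(0, 0.1, len(t))
    base = fit_harmonic((t, y))
    rhythmicity_lrt(base)
    for delta in (1.0, 5.5, 13.0):
        shifted = fit_harmonic((t + delta, y))
        rhythmicity_lrt(shifted)
        assert circular_diff(shifted.acrophase_h, (base.acrophase_h + delta) % 24) < 1e-9
        assert shifted.amplitude == pytest.approx(base.amplitude, abs=1e-9)
        assert shifted.mu == pytest.approx(base.mu, abs=1e-9)
        assert shifted.lrt_stat == pytest.approx(base.lrt_stat, abs=1e-9)


def test_amplitude_identity_and_max_min_bound(cosine):
    rng = np.random.default_rng(2)
    t = np.sort(rng.uniform(0, 48, 10))
    fit = fit_harmonic((t, cosine(t, amplitude=0.7, acrophase_h=5.0)))
    assert fit.amplitude == pytest.approx(0.7)
    summary = circadian_summary((t, cosine(t, amplitude=0.7, acrophase_h=5.0)))
    assert summary.max_min <= 2 * fit.amplitude + 1e-12
    # equality when peak and trough are both sampled
    t2 = np.array([5.0, 11.0, 17.0, 23.0])
    s2 = circadian_summary((t2, cosine(t2, amplitude=0.7, acrophase_h=5.0)))
    assert s2.max_min == pytest.approx(1.4)


def test_lrt_closed_form_and_degenerate_cases():
    fit = HarmonicFit(mu=0, a=0, b=0, period_h=24.0, rss_full=1.0,
                      rss_null=float(np.e), n_points=8)
    stat, p = rhythmicity_lrt(fit, method="chi2")
    assert stat == pytest.approx(8.0)
    assert p == pytest.approx(stats.chi2.sf(8.0, 2))  # ~0.0183
    flat = HarmonicFit(mu=0, a=0, b=0, period_h=24.0, rss_full=2.0,
                       rss_null=2.0, n_points=8)
    assert rhythmicity_lrt(flat, method="chi2") == (0.0, 1.0)
    perfect = HarmonicFit(mu=0, a=1, b=0, period_h=24.0, rss_full=0.0,
                          rss_null=4.0, n_points=8, perfect_fit=True)
    assert rhythmicity_lrt(perfect) == (float("inf"), 0.0)


def test_f_form_is_calibrated_chi2_form_is_anticonservative():
    """Flat-noise null at n=8: the exact F form rejects at ~alpha while the
    chi-square approximation rejects far too often at this sample size."""
    rng = np.random.default_rng(3)
    rej_f = rej_chi2 = 0
    n_sim = 1000
    for _ in range(n_sim):
        fit = fit_harmonic((TWO_DAY_TIMES, rng.normal(0, 1, 8)))
        rej_f += rhythmicity_lrt(fit, method="f")[1] < 0.05
        rej_chi2 += rhythmicity_lrt(fit, method="chi2")[1] < 0.05
    se = np.sqrt(0.05 * 0.95 / n_sim)
    assert abs(rej_f / n_sim - 0.05) < 2 * se
    assert rej_chi2 / n_sim > 0.05 + 4 * se


def test_robust_fit_equals_ols_on_clean_data(cosine):
    t = np.arange(0.0, 24.0, 3.0)
    y = cosine(t, mesor=2.0, amplitude=1.0, acrophase_h=16.0)
    ols, rob = fit_harmonic((t, y)), fit_harmonic_robust((t, y))
    assert np.allclose([ols.mu, ols.a, ols.b], [rob.mu, rob.a, rob.b], atol=1e-6)


def test_robust_fit_beats_ols_under_single_outlier(cosine):
    """One gross outlier (10x the amplitude): the soft-L1 fit recovers the
    acrophase better than OLS in >=95% of paired replicates."""
    rng = np.random.default_rng(42)
    t = np.arange(0.0, 24.0, 3.0)
    wins, n_rep = 0, 200
    for _ in range(n_rep):
        phi = rng.uniform(0, 24)
        y = cosine(t, mesor=2.0, amplitude=1.0, acrophase_h=phi)
        y = y + rng.normal(0, 0.05, len(t))
        y[rng.integers(len(t))] += 10.0
        err_rob = circular_diff(fit_harmonic_robust((t, y)).acrophase_h, phi)
        err_ols = circular_diff(fit_harmonic((t, y)).acrophase_h, phi)
        wins += err_rob < err_ols
    assert wins / n_rep >= 0.95


def test_robust_fit_uses_published_initialization():
    from salivaclock.rhythm import ROBUST_F_SCALE, ROBUST_X0
    assert ROBUST_X0 == (-0.31084448, 2.33838041, 6.33268443)
    assert ROBUST_F_SCALE == 0.1


def test_circadian_summary_worked_example():
    s = circadian_summary((np.array([9.0, 13.0, 17.0, 21.0]),
                           np.array([1.0, 3.0, 2.0, 5.0])))
    assert (s.max_min, s.max_val, s.mean_val) == (4.0, 5.0, 2.75)
    assert s.peak_time_h == 21.0
    assert s.rel_amplitude == pytest.approx(4.0 / 2.75)


def test_circadian_summary_tie_takes_first_peak():
    s = circadian_summary((np.array([9.0, 13.0, 17.0, 21.0]),
                           np.array([5.0, 1.0, 2.0, 5.0])))
    assert s.peak_time_h == 9.0
    flat = circadian_summary((np.array([9.0, 13.0]), np.array([2.0, 2.0])))
    assert flat.max_min == 0.0 and flat.rel_amplitude == 0.0


@pytest.mark.parametrize("p1,p2,expected", [
    (23.5, 0.5, 1.0),   # phases across midnight are close
    (6.0, 18.0, 12.0),  # antipodal: the maximum
    (4.0, 4.0, 0.0),
    (1.0, 23.0, 2.0),
])
def test_circular_difference(p1, p2, expected):
    assert circular_diff(p1, p2) == pytest.approx(expected)
    assert circular_diff(p2, p1) == pytest.approx(expected)


def test_restrict_to_interval_waking_windows():
    t = np.arange(0.0, 48.1, 2.0)
    y = np.arange(len(t), dtype=float)
    kept_t, _ = restrict_to_interval((t, y), [[4.0, 14.0], [26.0, 38.0]])
    assert len(kept_t) == 13  # 6 + 7 inclusive boundary points
    all_t, _ = restrict_to_interval((t, y), [[0.0, 48.0]])
    assert np.array_equal(all_t, t)
    only_zero, _ = restrict_to_interval((t, y), [[0.0, 0.0]])
    assert list(only_zero) == [0.0]
    with pytest.raises(ValueError, match="non-overlapping"):
        restrict_to_interval((t, y), [[0.0, 10.0], [5.0, 20.0]])
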