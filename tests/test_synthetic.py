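import numpy as np
import pandas as pd
import pytest

from salivaclock import (CohortConfig, GeneParams, build_feature_table,
                         delta_delta_ct, generate_cohort, generate_dense_series,
                         spearman_matrix)
from salivaclock.io_formats import hormone_series_to_frame


def test_determinism_same_seed_identical_tables():
    a = generate_cohort(CohortConfig(n_participants=4, seed=7))
    b = generate_cohort(CohortConfig(n_participants=4, seed=7))
    pd.testing.assert_frame_equal(a.ct.records, b.ct.records)
    pd.testing.assert_frame_equal(a.truth.genes, b.truth.genes)
    pd.testing.assert_frame_equal(hormone_series_to_frame(a.hormones),
                                  hormone_series_to_frame(b.hormones))
    c = generate_cohort(CohortConfig(n_participants=4, seed=8))
    assert not a.ct.records["ct"].equals(c.ct.records["ct"])


def test_cohort_shape_follows_protocol(small_cohort):
    cfg = small_cohort.config
    n_rows = (cfg.n_participants * cfg.n_days * len(cfg.sampling_times_h)
              * (len(cfg.genes) + 1))  # + reference gene
    assert len(small_cohort.ct.records) == n_rows
    assert small_cohort.ct.incomplete_timepoints("GAPDH").empty
    cort = [h for h in small_cohort.hormones if h.analyte == "cortisol"]
    assert all(len(h.samples) == 7 for h in cort)
    assert all([s.time_h for s in h.samples] ==
               [0.0, 0.5, 1.0, 2.0, 5.0, 8.0, 12.0] for h in cort)
    mel = [h for h in small_cohort.hormones if h.analyte == "melatonin"]
    assert all(len(h.samples) == cfg.n_days for h in mel)
    # 8 fields per slide
    per_slide = small_cohort.cells.df.groupby(
        ["participant", "day", "time_h"])["field_index"].count()
    assert (per_slide == 8).all()


def test_config_validation():
    with pytest.raises(ValueError):
        GeneParams("X", mesor=-1.0)
    with pytest.raises(ValueError):
        GeneParams("X", rel_amplitude=1.5)
    with pytest.raises(ValueError):
        CohortConfig(ct_noise_sd=-0.1)
    with pytest.raises(ValueError):
        CohortConfig(sampling_times_h=(9.0, 25.0))


def test_dense_series_point_count_and_noiseless_curve():
    params = GeneParams("ARNTL1", mesor=1.0, rel_amplitude=0.5, acrophase_h=18.0)
    s = generate_dense_series(params, interval_h=3.0, duration_h=30.0, noise_sd=0.0)
    assert len(s.points) == 11  # every 3 h over 30 h
    t = s.abs_time_h()
    assert np.allclose(s.values("fold_change"), params.curve(t))
    with pytest.raises(ValueError):
        generate_dense_series(params, interval_h=0.0, duration_h=30.0)


def test_dense_series_noise_averages_out():
    params = GeneParams("PER2", mesor=2.0, rel_amplitude=0.4, acrophase_h=10.0)
    stack = np.stack([generate_dense_series(params, noise_sd=0.2, seed=s)
                      .values("fold_change") for s in range(300)])
    t = generate_dense_series(params, noise_sd=0.0).abs_time_h()
    assert np.allclose(stack.mean(axis=0), params.curve(t), atol=0.05)
    assert not np.allclose(stack[0], stack[1])


def test_amplitude_scales_with_mean_across_participants():
    """rel_amplitude is constant across participants, so the max-min range
    of the level-preserving expression scales with its mean."""
    cohort = generate_cohort(CohortConfig(n_participants=60, seed=3))
    rows = []
    for s in delta_delta_ct(cohort.ct):
        if s.gene != "PER2":
            continue
        v = s.values("rel_expr")
        rows.append((v.max() - v.min(), v.mean()))
    max_min, mean = np.array(rows).T
    r = np.corrcoef(max_min, mean)[0, 1]
    assert r > 0.7


def test_induced_coupling_signs_at_n200():
    """Built-in couplings are recoverable by the association machinery:
    cortisol level vs melatonin negative, ARNTL1 phase vs cortisol phase
    negative, PER2 level vs melatonin positive, phase vs bedtime positive."""
    cohort = generate_cohort(CohortConfig(n_participants=200, seed=11))
    series = delta_delta_ct(cohort.ct)
    features = build_feature_table(expression_series=series,
                                   hormone_series=cohort.hormones,
                                   participants=cohort.participants)
    matrix = spearman_matrix(features)
    checks = [
        ("cortisol_mesor", "melatonin", -1),
        ("ARNTL1_acrophase_h", "cortisol_acrophase_h", -1),
        ("PER2_mesor", "melatonin", +1),
        ("ARNTL1_acrophase_h", "bedtime_h", +1),
    ]
    for a, b, sign in checks:
        row = matrix.get(a, b)
        assert np.sign(row["spearman_r"]) == sign, (a, b, row["spearman_r"])
        assert row["p"] < 0.01
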