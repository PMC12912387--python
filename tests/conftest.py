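import numpy as np
import pandas as pd
import pytest

from salivaclock import CohortConfig, CtTable, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Six participants sampled at the 9/13/17/21 protocol over two days."""
    return generate_cohort(CohortConfig(n_participants=6, seed=123))


@pytest.fixture
def protocol_ct():
    """Hand-built CT table: one participant, 4 times x 2 days, 2 genes."""
    rows = []
    cts = {"ARNTL1": [25.0, 24.0, 26.0, 25.0], "GAPDH": [20.0] * 4}
    for day in (1, 2):
        for i, t in enumerate((9.0, 13.0, 17.0, 21.0)):
            for gene, vals in cts.items():
                rows.append(("P01", day, t, gene, vals[i]))
    return CtTable(pd.DataFrame(rows, columns=["participant", "day", "time_h",
                                               "gene", "ct"]))


@pytest.fixture
def cosine():
    """Noiseless sampled cosine generator."""

    def make(t, mesor=2.0, amplitude=1.0, acrophase_h=0.0, period_h=24.0):
        t = np.asarray(t, dtype=float)
        return mesor + amplitude * np.cos(2 * np.pi * (t - acrophase_h) / period_h)

    return make
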