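"""Day-to-day consistency of expression profiles.

Day 1 values are treated as "predicted" and day 2 values as "observed";
pairing is by identical clock time (the protocol fixes sampling times, so
no nearest-neighbour matching is done). Series contributing two or fewer
points over both days are excluded from the analysis, with the exclusion
logged. Error metrics follow the usual definitions:

    MAE  = mean |d2 - d1|          MSE = mean (d2 - d1)^2
    RMSE = sqrt(MSE)               MBE = mean (d2 - d1)

so RMSE >= MAE >= |MBE| always, and a positive MBE means day-2 values run
higher. Per-gene reproducibility is tested with the two-sided Wilcoxon
signed-rank test followed by Bonferroni correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .qpcr import ExpressionSeries

logger = logging.getLogger("salivaclock")


@dataclass
class PairedDayTable:
    df: pd.DataFrame  # participant, gene, time_h, value_day1, value_day2
    exclusions: list[str] = field(default_factory=list)

    def __len__(self):
        return len(self.df)


def pair_days(series_set: list[ExpressionSeries], min_points: int = 2,
              value_col: str = "fold_change",
              days: tuple[int, int] = (1, 2)) -> PairedDayTable:
    """Match identical clock times between two sampling days.

    Series with ``min_points`` or fewer total points over the two days are
    excluded (default 2, the protocol's exclusion rule); series without any
    overlapping times yield no pairs but are logged, not errors.
    """
    rows, exclusions = [], []
    d1, d2 = days
    for s in series_set:
        n_total = int(s.points["day"].isin(days).sum())
        if n_total <= min_points:
            exclusions.append(
                f"{s.participant_id}/{s.gene}: {n_total} points over both days")
            continue
        p1 = s.points[s.points["day"] == d1].set_index("time_h")[value_col]
        p2 = s.points[s.points["day"] == d2].set_index("time_h")[value_col]
        common = sorted(set(np.round(p1.index, 6)) & set(np.round(p2.index, 6)))
        if not common:
            exclusions.append(f"{s.participant_id}/{s.gene}: no overlapping times")
            continue
        for t in common:
            rows.append({"participant": s.participant_id, "gene": s.gene,
                         "time_h": float(t), "value_day1": float(p1.loc[t]),
                         "value_day2": float(p2.loc[t])})
    for msg in exclusions:
        logger.info("pair_days: excluded %s", msg)
    return PairedDayTable(
        pd.DataFrame(rows, columns=["participant", "gene", "time_h",
                                    "value_day1", "value_day2"]),
        exclusions)


@dataclass
class ErrorMetrics:
    mae: float
    mse: float
    rmse: float
    mbe: float
    n: int

    def as_dict(self):
        return {"MAE": self.mae, "MSE": self.mse, "RMSE": self.rmse,
                "MBE": self.mbe, "n": self.n}


def error_metrics(pairs: PairedDayTable | pd.DataFrame) -> ErrorMetrics:
    """Pooled MAE / MSE / RMSE / MBE over all day-1/day-2 pairs."""
    df = pairs.df if isinstance(pairs, PairedDayTable) else pairs
    if len(df) == 0:
        raise ValueError("no paired observations")
    d = df["value_day2"].to_numpy(float) - df["value_day1"].to_numpy(float)
    mse = float(np.mean(d ** 2))
    return ErrorMetrics(mae=float(np.mean(np.abs(d))), mse=mse,
                        rmse=float(np.sqrt(mse)), mbe=float(np.mean(d)),
                        n=len(d))


def error_metrics_by_gene(pairs: PairedDayTable) -> pd.DataFrame:
    rows = []
    for gene, grp in pairs.df.groupby("gene", sort=True):
        m = error_metrics(grp)
        rows.append({"gene": gene, **{k.lower(): v for k, v in m.as_dict().items()}})
    return pd.DataFrame(rows)


def wilcoxon_bonferroni(pairs: PairedDayTable, zero_method: str = "wilcox") -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon signed-rank test, Bonferroni-adjusted.

    Zero differences are dropped before ranking (the classical Wilcoxon
    convention; ``zero_method="pratt"`` keeps them). All-zero groups are
    degenerate: no evidence against equality, so p = 1 with a flag. The
    exact null distribution is used for n <= 25 without ties, the normal
    approximation with continuity correction otherwise (scipy's policy).
    """
    groups = list(pairs.df.groupby("gene", sort=True))
    rows = []
    for gene, grp in groups:
        d1 = grp["value_day1"].to_numpy(float)
        d2 = grp["value_day2"].to_numpy(float)
        diffs = d2 - d1
        if np.allclose(diffs, 0.0):
            rows.append({"gene": gene, "n_pairs": len(diffs), "statistic": np.nan,
                         "p_raw": 1.0, "degenerate": True})
            continue
        res = stats.wilcoxon(d2, d1, zero_method=zero_method, method="auto")
        rows.append({"gene": gene, "n_pairs": len(diffs),
                     "statistic": float(res.statistic),
                     "p_raw": float(res.pvalue), "degenerate": False})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(1.0, out["p_raw"] * len(groups))
    return out


def mean_profile_with_sem(series_set: list[ExpressionSeries],
                          grid: np.ndarray | None = None,
                          value_col: str = "fold_change") -> pd.DataFrame:
    """Mean +/- SEM expression profile across series on an absolute-hour grid.

    Each series (one participant's pair of days) counts as one independent
    unit; SEM = sd/sqrt(n) with ddof=1 and is reported missing where only
    one series contributes.
    """
    buckets: dict[float, list[float]] = {}
    for s in series_set:
        for t, v in zip(np.round(s.abs_time_h(), 6), s.values(value_col)):
            buckets.setdefault(float(t), []).append(float(v))
    if grid is None:
        grid = np.asarray(sorted(buckets), dtype=float)
    rows = []
    for t in np.asarray(grid, dtype=float):
        vals = np.asarray(buckets.get(float(np.round(t, 6)), []), dtype=float)
        n = len(vals)
        mean = float(vals.mean()) if n else np.nan
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
        rows.append({"abs_time_h": float(t), "mean": mean, "sem": sem, "n": n})
    return pd.DataFrame(rows)
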