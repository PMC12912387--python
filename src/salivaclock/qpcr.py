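"""Relative qPCR quantification via the two-step delta-delta-CT scheme.

CT values are normalized first to the reference gene (GAPDH), giving
dCT = CT_target - CT_ref per timepoint, and then to the mean of that
participant's dCT values for the gene across both sampling days:
ddCT = dCT - mean(dCT). Fold change follows the Livak convention,
2^(-ddCT), so a lower CT means higher expression and every series has
geometric mean 1 over its normalization window by construction.

The single-delta relative expression 2^(-dCT) is carried alongside: it
preserves between-participant level differences (the "mean expression"
scale), which the double-normalized fold changes deliberately erase.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CtTable

logger = logging.getLogger("salivaclock")

POINT_COLUMNS = ["day", "time_h", "fold_change", "rel_expr"]


@dataclass
class ExpressionSeries:
    """Relative expression time series for one participant x gene.

    ``points`` has columns day, time_h, fold_change (2^-ddCT, geometric
    mean 1 over the series) and rel_expr (2^-dCT, GAPDH-normalized only),
    sorted by absolute time. ``excluded`` records timepoints dropped for a
    missing reference or target CT.
    """

    participant_id: str
    gene: str
    points: pd.DataFrame
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.points) and (self.points["fold_change"] <= 0).any():
            raise ValueError("fold changes must be strictly positive")

    @property
    def empty(self) -> bool:
        return len(self.points) == 0

    def abs_time_h(self) -> np.ndarray:
        return (24.0 * (self.points["day"].to_numpy(dtype=float) - 1)
                + self.points["time_h"].to_numpy(dtype=float))

    def values(self, col: str = "fold_change") -> np.ndarray:
        return self.points[col].to_numpy(dtype=float)

    def day_subset(self, day: int) -> "ExpressionSeries":
        sub = self.points[self.points["day"] == day].reset_index(drop=True)
        return ExpressionSeries(self.participant_id, self.gene, sub)


def delta_delta_ct(ct: CtTable, reference_gene: str = "GAPDH",
                   sign_convention: int = -1) -> list[ExpressionSeries]:
    """Two-step relative quantification of every participant x target gene.

    fold_change = 2^(sign_convention * ddCT) with the Livak default
    sign_convention = -1. Timepoints lacking a reference-gene CT (or with a
    missing target CT) are excluded and logged, never silently dropped; a
    gene with no usable point yields an empty, flagged series.
    """
    if sign_convention not in (-1, +1):
        raise ValueError("sign_convention must be -1 or +1")
    df = ct.records
    ref = df[(df["gene"] == reference_gene) & df["ct"].notna()]
    ref_map = {(p, d, t): c for p, d, t, c in
               ref[["participant", "day", "time_h", "ct"]].itertuples(index=False)}
    out: list[ExpressionSeries] = []
    targets = df[df["gene"] != reference_gene]
    for (pid, gene), grp in targets.groupby(["participant", "gene"], sort=True):
        rows, excluded = [], []
        for _, r in grp.iterrows():
            key = (r["participant"], r["day"], r["time_h"])
            label = f"day {r['day']} t={r['time_h']:g}h"
            if not np.isfinite(r["ct"]):
                excluded.append(f"{label}: missing target CT")
                continue
            if key not in ref_map:
                excluded.append(f"{label}: missing {reference_gene} CT")
                continue
            rows.append((int(r["day"]), float(r["time_h"]),
                         float(r["ct"]) - ref_map[key]))
        for msg in excluded:
            logger.info("delta_delta_ct %s/%s: excluded %s", pid, gene, msg)
        if not rows:
            out.append(ExpressionSeries(pid, gene,
                                        pd.DataFrame(columns=POINT_COLUMNS),
                                        excluded))
            continue
        pts = pd.DataFrame(rows, columns=["day", "time_h", "dct"])
        ddct = pts["dct"] - pts["dct"].mean()
        pts["fold_change"] = np.power(2.0, sign_convention * ddct)
        pts["rel_expr"] = np.power(2.0, sign_convention * pts["dct"])
        pts["abs_t"] = 24.0 * (pts["day"] - 1) + pts["time_h"]
        pts = pts.sort_values("abs_t", kind="stable").reset_index(drop=True)
        out.append(ExpressionSeries(pid, gene, pts[POINT_COLUMNS], excluded))
    return out


def mean_expression(series: ExpressionSeries, window: str = "overall",
                    value_col: str = "fold_change"):
    """Arithmetic mean expression over a window.

    window="overall" gives one number; window="per_day" a {day: mean} dict.
    """
    if series.empty:
        raise ValueError("mean_expression of an empty series")
    if window == "overall":
        return float(series.points[value_col].mean())
    if window == "per_day":
        return {int(d): float(g[value_col].mean())
                for d, g in series.points.groupby("day")}
    raise ValueError(f"unknown window: {window!r}")


def expression_to_frame(series: list[ExpressionSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for _, p in s.points.iterrows():
            rows.append({"participant": s.participant_id, "gene": s.gene,
                         "day": int(p["day"]), "time_h": p["time_h"],
                         "fold_change": p["fold_change"],
                         "rel_expr": p["rel_expr"]})
    return pd.DataFrame(rows, columns=["participant", "gene", "day", "time_h",
                                       "fold_change", "rel_expr"])


def frame_to_expression(df: pd.DataFrame) -> list[ExpressionSeries]:
    out = []
    for (pid, gene), grp in df.groupby(["participant", "gene"], sort=True):
        pts = grp[POINT_COLUMNS].reset_index(drop=True)
        out.append(ExpressionSeries(str(pid), str(gene), pts))
    return out
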