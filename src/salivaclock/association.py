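"""Cross-layer association statistics.

Links the circadian parameters extracted from gene expression (mesor,
amplitude, acrophase) to hormone profiles (cortisol, melatonin), sleep
timing, chronotype scores and saliva cell composition. Rank (Spearman)
correlation is the workhorse; mutual information and the maximal
information coefficient capture non-monotone dependence. Acrophases and
bedtimes are circular: before rank correlation they can be re-centered on
a reference hour so that values just before and after midnight stay
adjacent (ref="auto" centres each variable on the antipode of its own
circular mean; uncentered mode is kept for exact replication of analyses
that rank raw phases).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mutual_info_score

logger = logging.getLogger("salivaclock")


# --------------------------------------------------------------------------
# circular utilities

def recenter_circular(values, ref_h="auto", period_h: float = 24.0) -> np.ndarray:
    """Map circular hours onto the linear interval [ref, ref + period).

    ``ref_h="auto"`` picks the antipode of the circular mean, putting the
    cut as far from the data cluster as possible; a numeric reference (the
    conventional choice is 4 h, the typical human activity trough) is used
    as-is. ``ref_h=None`` leaves values untouched (replication mode).
    """
    v = np.asarray(values, dtype=float)
    if ref_h is None:
        return v
    if isinstance(ref_h, str) and ref_h == "auto":
        ang = v[np.isfinite(v)] * 2 * np.pi / period_h
        if len(ang) == 0:
            return v
        mean_ang = math.atan2(np.sin(ang).mean(), np.cos(ang).mean())
        ref = (mean_ang * period_h / (2 * np.pi) - period_h / 2) % period_h
    else:
        ref = float(ref_h)
    return np.mod(v - ref, period_h) + ref


# --------------------------------------------------------------------------
# feature table

CIRCULAR_SUFFIXES = ("acrophase_h", "bedtime_h", "peak_time_h")


@dataclass
class FeatureTable:
    """One row per participant: circadian parameters across data layers.

    ``circular`` names the columns that live on the 24-h circle.
    """

    df: pd.DataFrame
    circular: list[str]


def is_circular(column: str) -> bool:
    return column.endswith(CIRCULAR_SUFFIXES)


def build_feature_table(expression_series=None, hormone_series=None,
                        cell_counts=None, participants: pd.DataFrame | None = None,
                        lrt_method: str = "chi2") -> FeatureTable:
    """Assemble the per-participant feature table from pipeline outputs.

    Per gene: mesor (mean 2^-dCT relative expression), harmonic amplitude
    and acrophase of the fold-change profile. Cortisol: robust soft-L1
    cosinor mesor/amplitude/acrophase on the awakening profile. Melatonin:
    mean of the uncensored bedtime values. Plus bedtime, MEQ score and the
    mean leukocyte/epithelial ratio where available. Missing layers stay
    missing (NaN), they are never imputed.
    """
    from .qpcr import mean_expression
    from .rhythm import fit_harmonic, fit_harmonic_robust, rhythmicity_lrt

    rows: dict[str, dict] = {}

    def row(pid):
        return rows.setdefault(str(pid), {"participant": str(pid)})

    for s in expression_series or []:
        if s.empty:
            continue
        r = row(s.participant_id)
        r[f"{s.gene}_mesor"] = mean_expression(s, value_col="rel_expr")
        try:
            fit = fit_harmonic(s)
            rhythmicity_lrt(fit, method=lrt_method)
            r[f"{s.gene}_amplitude"] = fit.amplitude
            r[f"{s.gene}_acrophase_h"] = fit.acrophase_h
            r[f"{s.gene}_lrt_p"] = fit.lrt_p
        except Exception as exc:  # singular design: keep level, drop rhythm
            logger.info("feature table: no fit for %s/%s (%s)",
                        s.participant_id, s.gene, exc)

    for h in hormone_series or []:
        r = row(h.participant_id)
        t, v = h.analysis_values()
        if h.analyte == "cortisol" and len(v) >= 4:
            fit = fit_harmonic_robust((t, v))
            r["cortisol_mesor"] = fit.mu
            r["cortisol_amplitude"] = fit.amplitude
            r["cortisol_acrophase_h"] = fit.acrophase_h
        elif h.analyte == "melatonin" and len(v):
            r["melatonin"] = float(np.mean(v))

    if cell_counts is not None:
        for _, slide in le_ratio(cell_counts).iterrows():
            r = row(slide["participant"])
            r.setdefault("_le", []).append(slide["le_ratio"])
        for r in rows.values():
            if "_le" in r:
                vals = [x for x in r.pop("_le") if np.isfinite(x)]
                r["le_ratio"] = float(np.mean(vals)) if vals else np.nan

    if participants is not None:
        for _, p in participants.iterrows():
            r = row(p["participant"])
            for col in participants.columns:
                if col != "participant":
                    r[col] = p[col]

    df = pd.DataFrame(sorted(rows.values(), key=lambda r: r["participant"]))
    circular = [c for c in df.columns if is_circular(c)]
    return FeatureTable(df, circular)


# --------------------------------------------------------------------------
# rank correlation

@dataclass
class AssociationMatrix:
    df: pd.DataFrame  # long format: var1, var2, spearman_r, p, n

    def to_square(self, value: str = "spearman_r") -> pd.DataFrame:
        return self.df.pivot(index="var1", columns="var2", values=value)

    def get(self, a: str, b: str):
        hit = self.df[(self.df["var1"] == a) & (self.df["var2"] == b)]
        return hit.iloc[0] if len(hit) else None


def spearman_matrix(features: FeatureTable | pd.DataFrame,
                    pairs=None, min_n: int = 4,
                    circular_ref="auto") -> AssociationMatrix:
    """Pairwise Spearman rank correlation, pairwise-complete observations.

    Circular columns are re-centered (see ``recenter_circular``) before
    ranking; pass ``circular_ref=None`` to rank raw phases. Comparisons
    with fewer than ``min_n`` complete pairs or a constant variable are
    flagged with r = NaN.
    """
    if isinstance(features, FeatureTable):
        df, circular = features.df, features.circular
    else:
        df = features
        circular = [c for c in df.columns if is_circular(c)]
    cols = [c for c in df.columns if c != "participant"
            and pd.api.types.is_numeric_dtype(df[c])]
    work = df[cols].astype(float).copy()
    for c in circular:
        if c in work:
            work[c] = recenter_circular(work[c].to_numpy(), circular_ref)
    wanted = pairs if pairs is not None else list(itertools.combinations(cols, 2))
    rows = [{"var1": c, "var2": c, "spearman_r": 1.0, "p": 0.0,
             "n": int(work[c].notna().sum())} for c in cols]
    for a, b in wanted:
        x, y = work[a], work[b]
        ok = x.notna() & y.notna()
        n = int(ok.sum())
        if n < min_n or x[ok].nunique() < 2 or y[ok].nunique() < 2:
            r, p = np.nan, np.nan
        else:
            r, p = stats.spearmanr(x[ok], y[ok])
        for v1, v2 in ((a, b), (b, a)):
            rows.append({"var1": v1, "var2": v2, "spearman_r": float(r),
                         "p": float(p), "n": n})
    return AssociationMatrix(pd.DataFrame(rows).drop_duplicates(["var1", "var2"]))


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    stderr: float
    perfect_fit: bool


def linregress_with_p(x, y) -> RegressionResult:
    """Least-squares line with the two-sided t-test p-value on the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    res = stats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    rss = float(np.sum((y - yhat) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    perfect = rss <= 1e-12 * max(tss, 1.0)
    p = 0.0 if perfect else float(res.pvalue)
    return RegressionResult(float(res.slope), float(res.intercept),
                            float(res.rvalue), p, float(res.stderr), perfect)


# --------------------------------------------------------------------------
# information-theoretic dependence

def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    ranks = stats.rankdata(x, method="average")
    return np.minimum(n_bins - 1, ((ranks - 1) * n_bins / len(x)).astype(int))


def _equal_width_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = np.min(x), np.max(x)
    if hi == lo:
        return np.zeros(len(x), dtype=int)
    edges = np.linspace(lo, hi, n_bins + 1)
    return np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)


def mutual_information(x, y, binning: str = "equal-frequency",
                       n_bins: int | None = None) -> float:
    """Plug-in mutual information (nats) of the discretized joint.

    Defaults: equal-frequency bins, n_bins = round(n**(1/3)). MI is 0 iff
    the binned variables are independent; MI(x, x) equals the entropy of
    the binned marginal (ln k for k uniform bins).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("length mismatch")
    if n < 8:
        raise ValueError("need n >= 8 for a meaningful MI estimate")
    if n_bins is None:
        n_bins = max(2, int(round(n ** (1.0 / 3.0))))
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    binner = {"equal-frequency": _equal_frequency_bins,
              "equal-width": _equal_width_bins}[binning]
    return float(mutual_info_score(binner(x, n_bins), binner(y, n_bins)))


def _mi_from_labels(bx: np.ndarray, by: np.ndarray, r: int, c: int) -> float:
    joint = np.bincount(bx * c + by, minlength=r * c).reshape(r, c).astype(float)
    n = joint.sum()
    px = joint.sum(axis=1) / n
    py = joint.sum(axis=0) / n
    pxy = joint / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * (np.log(pxy) - np.log(px[:, None]) - np.log(py[None, :]))
    return float(np.nansum(terms))


def _best_cuts_exhaustive(values: np.ndarray, fixed_labels: np.ndarray,
                          n_parts: int, n_fixed: int) -> float:
    """Exhaustively optimize one axis's cut points given the other axis."""
    order = np.argsort(values, kind="stable")
    v_sorted = values[order]
    f_sorted = fixed_labels[order]
    n = len(values)
    gaps = [i for i in range(1, n) if v_sorted[i] > v_sorted[i - 1]]
    k = n_parts - 1
    if len(gaps) < k or math.comb(len(gaps), k) > 25000:
        return 0.0
    best = 0.0
    norm = math.log(min(n_parts, n_fixed))
    for cuts in itertools.combinations(gaps, k):
        labels = np.zeros(n, dtype=int)
        for c in cuts:
            labels[c:] += 1
        mi = _mi_from_labels(labels, f_sorted, n_parts, n_fixed)
        best = max(best, mi / norm)
    return best


def maximal_information_coefficient(x, y, grid_limit_exponent: float = 0.6,
                                    exhaustive: bool | None = None) -> float:
    """Maximal information coefficient in [0, 1].

    Maximizes MI(X binned into c columns, Y binned into r rows)/ln(min(r,c))
    over all grids with r*c <= n**grid_limit_exponent. Axis partitions are
    equal-frequency; for small problems (min(r, c) <= 4 and n <= 50, or
    ``exhaustive=True``) the cut positions of each axis are additionally
    optimized exhaustively given an equal-frequency partition of the other.
    Noiseless functional relationships score 1 by construction of the
    normalization; a constant input is degenerate and scores 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("length mismatch")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.info("MIC: degenerate constant input -> 0")
        return 0.0
    budget = max(4.0, n ** grid_limit_exponent)
    best = 0.0
    for r in range(2, int(budget // 2) + 1):
        for c in range(2, int(budget // r) + 1):
            bx = _equal_frequency_bins(y, r)   # rows index y
            by = _equal_frequency_bins(x, c)   # cols index x
            mi = _mi_from_labels(bx, by, r, c)
            best = max(best, mi / math.log(min(r, c)))
            do_exhaustive = (exhaustive if exhaustive is not None
                             else (min(r, c) <= 4 and n <= 50))
            if do_exhaustive:
                best = max(best, _best_cuts_exhaustive(y, by, r, c))
                best = max(best, _best_cuts_exhaustive(x, bx, c, r))
    return float(min(best, 1.0))


# --------------------------------------------------------------------------
# cell composition, ANOVA, chronotype

def le_ratio(counts, scope: str = "slide") -> pd.DataFrame:
    """Leukocyte/epithelial ratio per slide (summing over the 8 fields).

    A slide with zero epithelial cells in every field has an undefined
    ratio (NaN, flagged), not an error.
    """
    df = counts.df if hasattr(counts, "df") else counts
    keys = ["participant", "day", "time_h"] if scope == "slide" else ["participant"]
    rows = []
    for key, grp in df.groupby(keys, sort=True):
        leuk = int(grp["leukocytes"].sum())
        epi = int(grp["epithelial"].sum())
        rows.append({**dict(zip(keys, key if isinstance(key, tuple) else (key,))),
                     "leukocytes": leuk, "epithelial": epi,
                     "le_ratio": leuk / epi if epi > 0 else np.nan,
                     "undefined": epi == 0})
    return pd.DataFrame(rows)


def oneway_anova(groups: dict) -> tuple[float, float]:
    """Classical one-way F test across groups keyed by (e.g.) time of day."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(np.ptp(a) == 0 for a in arrays) and np.ptp(np.concatenate(arrays)) == 0:
        logger.info("oneway_anova: zero variance everywhere -> degenerate")
        return float("nan"), float("nan")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


MEQ_MIN, MEQ_MAX = 16, 86


def classify_chronotype(meq_score: int) -> str:
    """Standard MEQ cut-offs: <=41 evening, 42-58 intermediate, >=59 morning."""
    score = int(meq_score)
    if not (MEQ_MIN <= score <= MEQ_MAX):
        raise ValueError(f"MEQ score {score} outside [{MEQ_MIN}, {MEQ_MAX}]")
    if score <= 41:
        return "evening"
    if score <= 58:
        return "intermediate"
    return "morning"
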