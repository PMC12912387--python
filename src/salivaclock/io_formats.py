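"""Readers and writers for every table the pipeline touches.

All tables are plain delimited text (comma or tab, auto-detected). Clock
times are decimal hours-of-day in [0, 24); consecutive sampling days are
distinguished by a 1-based day index, and absolute time is
``24*(day-1) + time_h``. Hormone tables may contain the censoring dialects
``"<x"`` (below the limit of detection) and ``">x"`` (above the upper limit
of quantification); censored rows are never silently dropped — they are
flagged and the downstream exclusion policy is explicit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("salivaclock")

CT_COLUMNS = ["participant", "day", "time_h", "gene", "ct"]

CENSOR_NONE = "none"
CENSOR_BELOW = "below_lod"
CENSOR_ABOVE = "above_uloq"

_TIME_RE = re.compile(r"^\s*(\d{1,2})(?::(\d{2}))?\s*h?\s*$")


class TableFormatError(ValueError):
    """Raised on malformed input tables (duplicate keys, bad tokens...)."""


def parse_time_of_day(token) -> float:
    """Parse ``"9"``, ``"9:30"`` or ``"9 h"`` into decimal hours-of-day.

    Plain decimal numbers (e.g. ``9.5``) are accepted as-is.
    """
    if isinstance(token, (int, float)) and not isinstance(token, bool):
        value = float(token)
    else:
        text = str(token)
        m = _TIME_RE.match(text)
        if m:
            value = float(m.group(1)) + (float(m.group(2)) / 60.0 if m.group(2) else 0.0)
        else:
            try:
                value = float(text)
            except ValueError:
                raise TableFormatError(f"unparseable time of day: {token!r}") from None
    if not (0.0 <= value < 24.0):
        raise TableFormatError(f"time of day {value} outside [0, 24)")
    return value


def _read_delimited(path) -> pd.DataFrame:
    # sep=None lets the python engine sniff comma vs tab
    return pd.read_csv(path, sep=None, engine="python")


@dataclass
class CtTable:
    """Raw qPCR cycle-threshold observations.

    One row per (participant, day, time_h, gene); ``ct`` is the PCR cycle
    threshold in cycles (NaN marks a failed/missing measurement, which is
    preserved rather than dropped).
    """

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in CT_COLUMNS if c not in self.df.columns]
        if missing:
            raise TableFormatError(f"CT table lacks columns: {missing}")
        self.df = self.df[CT_COLUMNS].copy()
        self.df["participant"] = self.df["participant"].astype(str)
        self.df["day"] = self.df["day"].astype(int)
        self.df["time_h"] = self.df["time_h"].astype(float)
        self.df["gene"] = self.df["gene"].astype(str)
        self.df["ct"] = self.df["ct"].astype(float)
        if (self.df["day"] < 1).any():
            raise TableFormatError("day indices must be >= 1")
        dup = self.df.duplicated(subset=["participant", "day", "time_h", "gene"])
        if dup.any():
            key = self.df.loc[dup.idxmax(), ["participant", "day", "time_h", "gene"]]
            raise TableFormatError(f"duplicate CT key: {tuple(key)}")

    @property
    def records(self) -> pd.DataFrame:
        return self.df

    def genes(self) -> list[str]:
        return sorted(self.df["gene"].unique())

    def participants(self) -> list[str]:
        return sorted(self.df["participant"].unique())

    def incomplete_timepoints(self, reference_gene: str) -> pd.DataFrame:
        """Timepoints carrying a target-gene CT but no reference-gene CT."""
        have_ref = self.df[(self.df["gene"] == reference_gene) & self.df["ct"].notna()]
        ref_keys = set(map(tuple, have_ref[["participant", "day", "time_h"]].values))
        targets = self.df[(self.df["gene"] != reference_gene) & self.df["ct"].notna()]
        mask = [
            tuple(row) not in ref_keys
            for row in targets[["participant", "day", "time_h"]].values
        ]
        return targets.loc[mask]


def read_ct_table(path, dialect: dict | None = None) -> CtTable:
    """Read a long-format CT table (participant, day, time_h, gene, ct).

    Times may be written as ``9``, ``9:00`` or ``9 h``. Missing CT values
    are preserved as NaN. Duplicate keys and unparseable times are hard
    errors naming the offending row.
    """
    raw = _read_delimited(path)
    missing = [c for c in CT_COLUMNS if c not in raw.columns]
    if missing:
        raise TableFormatError(f"{path}: CT table lacks columns {missing}")
    times = []
    for i, tok in enumerate(raw["time_h"]):
        try:
            times.append(parse_time_of_day(tok))
        except TableFormatError as exc:
            raise TableFormatError(f"{path} row {i + 2}: {exc}") from None
    out = raw.copy()
    out["time_h"] = times
    table = CtTable(out)
    logger.info("read_ct_table: %d records, %d participants, genes=%s",
                len(table.df), len(table.participants()), table.genes())
    return table


@dataclass
class HormoneSample:
    day: int
    time_h: float  # hours since awakening (cortisol) / sampling hour (melatonin)
    value: float
    censor: str = CENSOR_NONE
    raw: str | None = None


@dataclass
class HormoneSeries:
    """One analyte's samples for one participant.

    Cortisol follows the 7-offset awakening protocol (0, 0.5, 1, 2, 5, 8,
    12 h since wake); melatonin is one bedtime value per day. Censored
    samples keep their raw token; above-ULOQ samples are retained but
    excluded from analysis value sets by default.
    """

    participant_id: str
    analyte: str  # "cortisol" | "melatonin"
    samples: list[HormoneSample] = field(default_factory=list)

    def analysis_values(self, include_above_uloq: bool = False):
        """(times, values) used for statistics.

        Below-LOD samples enter at their substituted value; above-ULOQ
        samples are excluded unless requested. Exclusions are logged, never
        silent.
        """
        kept_t, kept_v, excluded = [], [], 0
        for s in self.samples:
            if s.censor == CENSOR_ABOVE and not include_above_uloq:
                excluded += 1
                continue
            kept_t.append(s.time_h)
            kept_v.append(s.value)
        if excluded:
            logger.info("%s/%s: excluded %d above-ULOQ sample(s)",
                        self.participant_id, self.analyte, excluded)
        return np.asarray(kept_t, dtype=float), np.asarray(kept_v, dtype=float)


_CENSOR_RE = re.compile(r"^\s*([<>])\s*([0-9.]+)\s*$")


def parse_hormone_value(token, below_lod_substitute: float = 1.0):
    """Parse a hormone value token.

    ``"<x"`` maps to the substitute value (the conventional plotting value
    of 1 by default) flagged below_lod; ``">x"`` keeps the bound x flagged
    above_uloq; plain numbers pass through. Unknown tokens are hard errors.
    """
    if isinstance(token, (int, float)) and not isinstance(token, bool):
        if np.isnan(token):
            raise TableFormatError("missing hormone value")
        return float(token), CENSOR_NONE, None
    text = str(token).strip()
    m = _CENSOR_RE.match(text)
    if m:
        bound = float(m.group(2))
        if m.group(1) == "<":
            return below_lod_substitute, CENSOR_BELOW, text
        return bound, CENSOR_ABOVE, text
    try:
        return float(text), CENSOR_NONE, None
    except ValueError:
        raise TableFormatError(f"unknown hormone value token: {token!r}") from None


def read_hormone_table(path, below_lod_substitute: float = 1.0) -> list[HormoneSeries]:
    """Read a long hormone table (participant, analyte, day, time_h, value).

    The value column may mix numbers with ``"<x"`` / ``">x"`` censoring
    tokens.
    """
    raw = _read_delimited(path)
    needed = ["participant", "analyte", "day", "time_h", "value"]
    missing = [c for c in needed if c not in raw.columns]
    if missing:
        raise TableFormatError(f"{path}: hormone table lacks columns {missing}")
    series: dict[tuple[str, str], HormoneSeries] = {}
    for i, row in raw.iterrows():
        try:
            value, censor, token = parse_hormone_value(row["value"], below_lod_substitute)
        except TableFormatError as exc:
            raise TableFormatError(f"{path} row {i + 2}: {exc}") from None
        key = (str(row["participant"]), str(row["analyte"]))
        series.setdefault(key, HormoneSeries(key[0], key[1])).samples.append(
            HormoneSample(int(row["day"]), float(row["time_h"]), value, censor, token)
        )
    out = list(series.values())
    n_cens = sum(1 for s in out for x in s.samples if x.censor != CENSOR_NONE)
    logger.info("read_hormone_table: %d series, %d censored samples", len(out), n_cens)
    return out


def hormone_series_to_frame(series: Iterable[HormoneSeries]) -> pd.DataFrame:
    rows = []
    for s in series:
        for x in s.samples:
            rows.append({
                "participant": s.participant_id, "analyte": s.analyte,
                "day": x.day, "time_h": x.time_h,
                "value": x.raw if x.raw is not None else x.value,
            })
    return pd.DataFrame(rows, columns=["participant", "analyte", "day", "time_h", "value"])


@dataclass
class CellCountTable:
    """Per-field leukocyte/epithelial counts of stained saliva smears.

    Eight microscopy fields are counted per slide (= one participant, day
    and sampling time).
    """

    df: pd.DataFrame

    COLUMNS = ["participant", "day", "time_h", "field_index", "leukocytes", "epithelial"]

    def __post_init__(self):
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise TableFormatError(f"cell-count table lacks columns: {missing}")
        self.df = self.df[self.COLUMNS].copy()
        for col in ("leukocytes", "epithelial"):
            vals = self.df[col]
            if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
                raise TableFormatError(f"{col} counts must be non-negative integers")
            self.df[col] = vals.astype(int)


def read_cell_count_table(path) -> CellCountTable:
    return CellCountTable(_read_delimited(path))


@dataclass
class ExpressionMatrix:
    """Dense genes x timepoints expression matrix (reference series).

    Index = gene labels (unique), columns = timepoints in hours (strictly
    increasing).
    """

    values: pd.DataFrame
    meta: pd.DataFrame | None = None

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise TableFormatError("duplicate gene labels in expression matrix")
        tp = np.asarray(self.values.columns, dtype=float)
        if len(tp) > 1 and not np.all(np.diff(tp) > 0):
            raise TableFormatError("timepoints must be strictly increasing")
        self.values = self.values.astype(float)
        self.values.columns = tp

    @property
    def timepoints_h(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=float)


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a series-matrix-style TSV: header of timepoints, one gene/row."""
    df = _read_delimited(path)
    df = df.set_index(df.columns[0])
    df.index.name = "gene"
    return ExpressionMatrix(df)


def filter_low_expression(matrix: ExpressionMatrix, threshold: float = 0.5) -> ExpressionMatrix:
    """Drop genes whose mean over all timepoints is below ``threshold``.

    The cutoff is inclusive (mean exactly at threshold is retained) and
    gene order is preserved. The conventional cutoff is 0.5 on the CPM
    scale for RNA-seq time courses.
    """
    if matrix.values.empty:
        return ExpressionMatrix(matrix.values.copy(), matrix.meta)
    keep = matrix.values.mean(axis=1) >= threshold
    logger.info("filter_low_expression: kept %d/%d genes at threshold %g",
                int(keep.sum()), len(keep), threshold)
    meta = matrix.meta.loc[keep[keep].index] if matrix.meta is not None else None
    return ExpressionMatrix(matrix.values.loc[keep], meta)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.insert(0, "gene", out.index)
    out.to_csv(path, sep="\t", index=False)


def _config_hash(config) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(tables: dict[str, pd.DataFrame], out_dir,
                  config: dict | None = None, seed: int | None = None) -> dict:
    """Write one TSV per result table plus a JSON run manifest.

    The manifest records a config hash, the seed, package/library versions
    and per-table row counts — everything needed to reproduce the run.
    Identical tables + config + seed produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import salivaclock

    manifest = {
        "config": config if config is not None else {},
        "config_hash": _config_hash(config or {}),
        "seed": seed,
        "versions": {
            "salivaclock": salivaclock.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "tables": {},
    }
    for name, df in tables.items():
        path = out / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        manifest["tables"][name] = {"rows": int(len(df)), "file": path.name}
        logger.info("wrote %s (%d rows)", path, len(df))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_result_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
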