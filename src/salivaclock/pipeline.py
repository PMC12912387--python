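"""End-to-end orchestration: simulate -> quantify -> fit -> reproducibility
-> associate -> design, driven by a single YAML-able config with one seed.

The run config contains exactly one of an ``inputs`` block (paths to CT,
hormone, cell-count and participant tables) or a ``simulate`` block (a
cohort-generator config, seed mandatory). Every stage writes its tables
through ``io_formats.write_results`` so a manifest with the config echo,
seed and versions always accompanies the outputs; identical config + seed
reproduce byte-identical tables.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import association, design, io_formats, qpcr, reproducibility, rhythm
from .synthetic import CohortConfig, CohortData, generate_cohort

logger = logging.getLogger("salivaclock")

ALL_STAGES = ("simulate", "quantify", "fit", "repro", "associate", "design")

DEFAULTS = {
    "reference_gene": "GAPDH",
    "lrt_method": "chi2",
    "min_points": 2,
    "design": {
        "k_min": 3, "k_max": 8, "n_days": 1, "noise_sd": 0.1,
        "n_replicates": 200, "alpha": 0.05, "phase_tol_h": 2.0,
        "detection_threshold": 0.8, "wake_window": [9.0, 21.0],
    },
}


class ConfigError(ValueError):
    pass


def _load_inputs(paths: dict):
    ct = io_formats.read_ct_table(paths["ct"])
    hormones = (io_formats.read_hormone_table(paths["hormones"])
                if paths.get("hormones") else [])
    cells = (io_formats.read_cell_count_table(paths["cells"])
             if paths.get("cells") else None)
    participants = (pd.read_csv(paths["participants"], sep=None, engine="python")
                    if paths.get("participants") else None)
    return ct, hormones, cells, participants


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the configured stages; returns a summary dict.

    Raises ConfigError on an invalid config; a stage failure propagates
    after earlier outputs are already on disk.
    """
    out = Path(out_dir)
    stages = list(config.get("stages", ALL_STAGES))
    seed = config.get("seed")
    has_inputs = bool(config.get("inputs"))
    has_sim = "simulate" in config
    if has_inputs == has_sim:
        raise ConfigError("config needs exactly one of 'inputs' or 'simulate'")
    if has_sim and seed is None and "seed" not in (config.get("simulate") or {}):
        raise ConfigError("seed is mandatory for simulated runs")

    tables: dict[str, pd.DataFrame] = {}
    summary: dict = {"stages": []}
    cohort: CohortData | None = None

    if has_sim:
        sim_cfg = dict(config.get("simulate") or {})
        if seed is not None:
            sim_cfg.setdefault("seed", seed)
        cohort = generate_cohort(CohortConfig(**sim_cfg))
        ct, hormones, cells = cohort.ct, cohort.hormones, cohort.cells
        participants = cohort.participants
        if "simulate" in stages:
            tables["ct"] = ct.records
            tables["hormones"] = io_formats.hormone_series_to_frame(hormones)
            tables["cell_counts"] = cells.df
            tables["participants"] = participants
            tables["truth_genes"] = cohort.truth.genes
            tables["truth_participants"] = cohort.truth.participants
            summary["stages"].append("simulate")
    else:
        ct, hormones, cells, participants = _load_inputs(config["inputs"])

    series = []
    if "quantify" in stages or "fit" in stages or "repro" in stages \
            or "associate" in stages:
        series = qpcr.delta_delta_ct(
            ct, reference_gene=config.get("reference_gene",
                                          DEFAULTS["reference_gene"]))
        if "quantify" in stages:
            tables["expression"] = qpcr.expression_to_frame(series)
            summary["stages"].append("quantify")

    lrt_method = config.get("lrt_method", DEFAULTS["lrt_method"])
    if "fit" in stages:
        fits, summaries = {}, {}
        for s in series:
            if s.empty:
                continue
            try:
                fit = rhythm.fit_harmonic(s)
                rhythm.rhythmicity_lrt(fit, method=lrt_method)
                fits[(s.participant_id, s.gene)] = fit
            except rhythm.SingularDesignError as exc:
                logger.warning("fit: skipping %s/%s (%s)",
                               s.participant_id, s.gene, exc)
            if len(s.points) >= 2:
                summaries[(s.participant_id, s.gene)] = rhythm.circadian_summary(s)
        tables["fits"] = rhythm.fits_to_frame(fits, summaries)
        summary["stages"].append("fit")
        summary["n_fits"] = len(fits)

    if "repro" in stages:
        pairs = reproducibility.pair_days(
            series, min_points=config.get("min_points", DEFAULTS["min_points"]))
        tables["paired_days"] = pairs.df
        if len(pairs.df):
            metrics = reproducibility.error_metrics(pairs)
            summary["error_metrics"] = metrics.as_dict()
            tables["repro_by_gene"] = reproducibility.error_metrics_by_gene(pairs)
            tables["wilcoxon"] = reproducibility.wilcoxon_bonferroni(pairs)
        summary["stages"].append("repro")
        summary["n_pairs"] = len(pairs.df)
        summary["n_excluded_series"] = len(pairs.exclusions)

    if "associate" in stages:
        features = association.build_feature_table(
            expression_series=series, hormone_series=hormones,
            cell_counts=cells, participants=participants,
            lrt_method=lrt_method)
        tables["features"] = features.df
        matrix = association.spearman_matrix(features)
        tables["associations"] = matrix.df
        summary["stages"].append("associate")
        summary["n_features"] = len(features.df.columns) - 1

    if "design" in stages:
        dcfg = {**DEFAULTS["design"], **(config.get("design") or {})}
        min_k, evaluations = design.minimal_points_per_day(
            k_range=range(int(dcfg["k_min"]), int(dcfg["k_max"]) + 1),
            n_days=int(dcfg["n_days"]), wake_window=tuple(dcfg["wake_window"]),
            noise_sd=float(dcfg["noise_sd"]),
            n_replicates=int(dcfg["n_replicates"]), alpha=float(dcfg["alpha"]),
            phase_tol_h=float(dcfg["phase_tol_h"]),
            detection_threshold=float(dcfg["detection_threshold"]),
            lrt_method=dcfg.get("lrt_method", lrt_method),
            seed=int(seed if seed is not None else 0))
        tables["design_evaluations"] = design.evaluations_to_frame(evaluations)
        summary["stages"].append("design")
        summary["minimal_points_per_day"] = min_k

    manifest = io_formats.write_results(tables, out, config=config, seed=seed)
    summary["manifest"] = manifest
    summary["out_dir"] = str(out)
    return summary
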