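"""Synthetic saliva-study cohorts with the statistical structure the
analysis assumes.

The generator emulates a two-day saliva sampling protocol (default clock
times 9, 13, 17, 21 h): per participant x gene, expression follows a
24-h cosine on the fold-change scale,

    E(t) = mesor * (1 + rel_amplitude * cos(2*pi*(t - acrophase)/24)),

which is converted to qPCR cycle thresholds via
CT_target = CT_ref - log2(E) + noise, with additive Gaussian noise on the
CT scale (qPCR error is approximately homoscedastic in cycles, making
fold-change noise lognormal) plus a per participant-and-day offset that
creates day-to-day variation. Morning genes (PER2, NR1D1) peak before
noon, ARNTL1 in the evening; a participant-level bedtime shifts all gene
acrophases coherently (later bedtime -> later clock). Cortisol follows the
7-offset awakening protocol with its acrophase negatively coupled to the
participant's ARNTL1 acrophase deviation; the single bedtime melatonin
value is negatively coupled to cortisol mesor and positively to PER2
mesor. Cell counts have a time-independent expected composition (36%
epithelial). Every coupling is recorded in a per-participant truth table
so that downstream stages can be scored for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_formats import (CENSOR_ABOVE, CENSOR_BELOW, CellCountTable,
                         CtTable, HormoneSample, HormoneSeries)
from .qpcr import POINT_COLUMNS, ExpressionSeries

PERIOD_H = 24.0


@dataclass
class GeneParams:
    """Generative circadian parameters of one gene.

    mesor is on the GAPDH-relative fold-change scale (> 0); rel_amplitude
    in [0, 1] keeps expression positive; acrophase_h is the population
    peak time (clock hours), with between-participant spread
    acrophase_sd_h.
    """

    gene: str
    mesor: float = 1.0
    rel_amplitude: float = 0.5
    acrophase_h: float = 12.0
    acrophase_sd_h: float = 1.5

    def __post_init__(self):
        if self.mesor <= 0:
            raise ValueError(f"{self.gene}: mesor must be > 0")
        if not (0.0 <= self.rel_amplitude <= 1.0):
            raise ValueError(f"{self.gene}: rel_amplitude must be in [0, 1]")

    def curve(self, t_abs_h, mesor=None, acrophase_h=None):
        m = self.mesor if mesor is None else mesor
        phi = self.acrophase_h if acrophase_h is None else acrophase_h
        t = np.asarray(t_abs_h, dtype=float)
        return m * (1.0 + self.rel_amplitude
                    * np.cos(2 * np.pi * (t - phi) / PERIOD_H))


def default_gene_params() -> list[GeneParams]:
    """Evening-peaking ARNTL1, morning-peaking PER2/NR1D1 priors."""
    return [
        GeneParams("ARNTL1", mesor=1.0, rel_amplitude=0.5, acrophase_h=18.0),
        GeneParams("PER2", mesor=1.0, rel_amplitude=0.5, acrophase_h=10.0),
        GeneParams("NR1D1", mesor=1.0, rel_amplitude=0.5, acrophase_h=10.0),
    ]


@dataclass
class CohortConfig:
    n_participants: int = 20
    sampling_times_h: tuple = (9.0, 13.0, 17.0, 21.0)
    n_days: int = 2
    genes: list[GeneParams] = field(default_factory=default_gene_params)
    reference_gene: str = "GAPDH"
    reference_ct: float = 20.0
    ct_noise_sd: float = 0.2        # cycles, per measurement
    day_effect_sd: float = 0.1      # cycles, shared within participant x day
    mesor_log_sd: float = 0.4       # between-participant lognormal spread
    bedtime_mean_h: float = 23.0
    bedtime_sd_h: float = 1.0
    phase_bedtime_slope: float = 0.75   # h acrophase shift per h of bedtime
    # cortisol (nmol/L), sampled at hours since awakening
    cortisol_times: tuple = (0.0, 0.5, 1.0, 2.0, 5.0, 8.0, 12.0)
    cortisol_mesor: float = 6.3
    cortisol_mesor_log_sd: float = 0.25
    cortisol_amplitude: float = 3.5
    cortisol_acrophase_base_h: float = 1.0   # hours since wake
    cortisol_phase_coupling: float = 0.8     # negative coupling to ARNTL1 phase
    cortisol_phase_sd_h: float = 0.5
    cortisol_noise_sd: float = 0.8
    cortisol_lod: float = 2.0
    # melatonin (pg/mL), one bedtime value per day
    melatonin_mean: float = 20.0
    melatonin_cortisol_coupling: float = -0.8
    melatonin_per2_coupling: float = 0.5
    melatonin_log_noise_sd: float = 0.3
    melatonin_uloq: float = 100.0
    # saliva smear cell counts
    cells_per_field: float = 50.0
    epithelial_fraction: float = 0.36
    n_fields: int = 8
    cell_timepoints: int = 3   # slides made at the first k sampling times
    # chronotype questionnaire
    meq_mean: float = 50.0
    meq_sd: float = 8.0
    seed: int = 0

    def __post_init__(self):
        for name in ("ct_noise_sd", "day_effect_sd", "bedtime_sd_h",
                     "cortisol_phase_sd_h", "cortisol_noise_sd",
                     "melatonin_log_noise_sd", "meq_sd", "mesor_log_sd",
                     "cortisol_mesor_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for t in self.sampling_times_h:
            if not (0.0 <= t < 24.0):
                raise ValueError("sampling times must lie in [0, 24)")
        self.genes = [g if isinstance(g, GeneParams) else GeneParams(**g)
                      for g in self.genes]


@dataclass
class TruthTable:
    """Generating parameters: the oracle for parameter-recovery scoring."""

    genes: pd.DataFrame         # participant, gene, mesor, rel_amplitude, amplitude, acrophase_h
    participants: pd.DataFrame  # participant, bedtime_h, cortisol mesor/acrophase, melatonin, meq


@dataclass
class CohortData:
    ct: CtTable
    hormones: list[HormoneSeries]
    cells: CellCountTable
    participants: pd.DataFrame  # observed covariates: bedtime_h, meq_score
    truth: TruthTable
    config: CohortConfig


def _participant_ids(n: int) -> list[str]:
    return [f"P{i + 1:03d}" for i in range(n)]


def generate_cohort(config: CohortConfig | None = None, **overrides) -> CohortData:
    """Draw a full synthetic cohort; identical seed -> identical output."""
    if config is None:
        config = CohortConfig(**overrides)
    elif overrides:
        config = CohortConfig(**{**asdict_config(config), **overrides})
    rng = np.random.default_rng(config.seed)
    pids = _participant_ids(config.n_participants)
    genes = {g.gene: g for g in config.genes}
    per2_name = "PER2" if "PER2" in genes else config.genes[-1].gene
    arntl_name = "ARNTL1" if "ARNTL1" in genes else config.genes[0].gene

    bedtimes = config.bedtime_mean_h + config.bedtime_sd_h * rng.standard_normal(len(pids))
    clock_shift = config.phase_bedtime_slope * (bedtimes - config.bedtime_mean_h)

    truth_gene_rows, truth_part_rows, ct_rows = [], [], []
    hormones: list[HormoneSeries] = []
    cell_rows = []
    times = np.asarray(config.sampling_times_h, dtype=float)
    meq = np.clip(np.round(config.meq_mean
                           + config.meq_sd * rng.standard_normal(len(pids))),
                  16, 86).astype(int)

    for i, pid in enumerate(pids):
        acro, mesor_pg = {}, {}
        for g in config.genes:
            phi = (g.acrophase_h + clock_shift[i]
                   + g.acrophase_sd_h * rng.standard_normal())
            m = g.mesor * np.exp(config.mesor_log_sd * rng.standard_normal())
            acro[g.gene], mesor_pg[g.gene] = phi, m
            truth_gene_rows.append({
                "participant": pid, "gene": g.gene, "mesor": m,
                "rel_amplitude": g.rel_amplitude,
                "amplitude": g.rel_amplitude * m,
                "acrophase_h": phi % PERIOD_H,
            })
        day_offsets = config.day_effect_sd * rng.standard_normal(config.n_days)
        for d in range(1, config.n_days + 1):
            for t in times:
                t_abs = PERIOD_H * (d - 1) + t
                ct_rows.append((pid, d, t, config.reference_gene,
                                config.reference_ct))
                for g in config.genes:
                    e = g.curve(t_abs, mesor=mesor_pg[g.gene],
                                acrophase_h=acro[g.gene])
                    ct_val = (config.reference_ct - np.log2(e)
                              + config.ct_noise_sd * rng.standard_normal()
                              + day_offsets[d - 1])
                    ct_rows.append((pid, d, t, g.gene, ct_val))

        # hormones -------------------------------------------------------
        cort_mesor = config.cortisol_mesor * np.exp(
            config.cortisol_mesor_log_sd * rng.standard_normal())
        z_cort = (np.log(cort_mesor / config.cortisol_mesor)
                  / max(config.cortisol_mesor_log_sd, 1e-12))
        cort_phi = (config.cortisol_acrophase_base_h
                    - config.cortisol_phase_coupling
                    * (acro[arntl_name] - genes[arntl_name].acrophase_h)
                    + config.cortisol_phase_sd_h * rng.standard_normal())
        cort = HormoneSeries(pid, "cortisol")
        for t in config.cortisol_times:
            v = (cort_mesor + config.cortisol_amplitude
                 * np.cos(2 * np.pi * (t - cort_phi) / PERIOD_H)
                 + config.cortisol_noise_sd * rng.standard_normal())
            if v < config.cortisol_lod:
                cort.samples.append(HormoneSample(1, float(t), 1.0, CENSOR_BELOW,
                                                  f"<{config.cortisol_lod:g}"))
            else:
                cort.samples.append(HormoneSample(1, float(t), float(v)))
        hormones.append(cort)

        z_per2 = (np.log(mesor_pg[per2_name] / genes[per2_name].mesor)
                  / max(config.mesor_log_sd, 1e-12))
        mel_level = config.melatonin_mean * np.exp(
            config.melatonin_cortisol_coupling * z_cort
            + config.melatonin_per2_coupling * z_per2
            + config.melatonin_log_noise_sd * rng.standard_normal())
        mel = HormoneSeries(pid, "melatonin")
        for d in range(1, config.n_days + 1):
            v = mel_level * np.exp(0.05 * rng.standard_normal())
            t_sample = (bedtimes[i] - 0.5) % PERIOD_H
            if v > config.melatonin_uloq:
                mel.samples.append(HormoneSample(d, t_sample,
                                                 float(config.melatonin_uloq),
                                                 CENSOR_ABOVE,
                                                 f">{config.melatonin_uloq:g}"))
            else:
                mel.samples.append(HormoneSample(d, t_sample, float(v)))
        hormones.append(mel)

        # cell counts ----------------------------------------------------
        for d in range(1, config.n_days + 1):
            for t in times[:config.cell_timepoints]:
                totals = rng.poisson(config.cells_per_field, size=config.n_fields)
                epi = rng.binomial(totals, config.epithelial_fraction)
                for f_idx in range(config.n_fields):
                    cell_rows.append({
                        "participant": pid, "day": d, "time_h": float(t),
                        "field_index": f_idx + 1,
                        "leukocytes": int(totals[f_idx] - epi[f_idx]),
                        "epithelial": int(epi[f_idx]),
                    })

        truth_part_rows.append({
            "participant": pid, "bedtime_h": bedtimes[i],
            "cortisol_mesor": cort_mesor,
            "cortisol_acrophase_h": cort_phi % PERIOD_H,
            "melatonin": mel_level, "meq_score": int(meq[i]),
        })

    ct = CtTable(pd.DataFrame(ct_rows, columns=["participant", "day", "time_h",
                                                "gene", "ct"]))
    cells = CellCountTable(pd.DataFrame(cell_rows))
    participants = pd.DataFrame({
        "participant": pids,
        "bedtime_h": np.mod(bedtimes, PERIOD_H),
        "meq_score": meq,
    })
    truth = TruthTable(pd.DataFrame(truth_gene_rows), pd.DataFrame(truth_part_rows))
    return CohortData(ct, hormones, cells, participants, truth, config)


def asdict_config(config: CohortConfig) -> dict:
    d = asdict(config)
    d["genes"] = [asdict(g) if isinstance(g, GeneParams) else g
                  for g in config.genes]
    return d


def generate_dense_series(params: GeneParams, interval_h: float = 3.0,
                          duration_h: float = 30.0, noise_sd: float = 0.1,
                          seed: int = 0) -> ExpressionSeries:
    """Dense reference series: floor(duration/interval)+1 samples of the
    gene's cosine with multiplicative Gaussian noise (sd as a fraction of
    the local mean), emulating an every-3-h / 30-h culture time course.
    """
    if interval_h <= 0 or duration_h < interval_h:
        raise ValueError("need interval_h > 0 and duration_h >= interval_h")
    rng = np.random.default_rng(seed)
    n = int(np.floor(duration_h / interval_h)) + 1
    t = np.arange(n) * interval_h
    y = params.curve(t) * (1.0 + noise_sd * rng.standard_normal(n))
    pts = pd.DataFrame({
        "day": (t // PERIOD_H).astype(int) + 1,
        "time_h": np.mod(t, PERIOD_H),
        "fold_change": np.maximum(y, 1e-9),
        "rel_expr": np.maximum(y, 1e-9),
    })
    return ExpressionSeries("sim", params.gene, pts[POINT_COLUMNS])
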