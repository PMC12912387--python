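"""In-silico evaluation of reduced circadian sampling schemes.

Given a generative circadian profile (a 24-h cosine with multiplicative
noise, emulating a dense every-3-h reference time course), each candidate
design — k sampling times per day inside a waking window, over one or two
days — is scored by Monte-Carlo refitting: simulate at the design's
offsets, fit the fixed-24-h cosinor, and record (a) feasibility (the fit
is not saturated: a single-day 3-point design is exactly determined by the
3-parameter model and can never yield evidence of rhythmicity), (b)
detection (rhythmicity LRT p < alpha) and (c) the circular acrophase
error. A design is successful when every fit is feasible, the detection
rate reaches the threshold and the median circular phase error is within
tolerance. The headline question this answers: how few within-day samples
still allow a reliable circadian assessment?
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rhythm import SingularDesignError, circular_diff, fit_harmonic, rhythmicity_lrt
from .synthetic import PERIOD_H, GeneParams

logger = logging.getLogger("salivaclock")

DEFAULT_WAKE_WINDOW = (9.0, 21.0)


@dataclass(frozen=True)
class SamplingDesign:
    """A concrete sampling scheme: (day, clock hour) offsets in a wake window."""

    offsets: tuple  # of (day, time_h)
    wake_window: tuple = DEFAULT_WAKE_WINDOW

    def __post_init__(self):
        lo, hi = self.wake_window
        if len(set(self.offsets)) != len(self.offsets):
            raise ValueError("design offsets must be unique")
        for _, t in self.offsets:
            if not (lo - 1e-9 <= t <= hi + 1e-9):
                raise ValueError(f"offset {t} h outside wake window {self.wake_window}")

    @property
    def n_points(self) -> int:
        return len(self.offsets)

    @property
    def n_days(self) -> int:
        return len({d for d, _ in self.offsets})

    @property
    def points_per_day(self) -> int:
        days = [d for d, _ in self.offsets]
        return max(days.count(d) for d in set(days))

    def abs_times_h(self) -> np.ndarray:
        return np.asarray([PERIOD_H * (d - 1) + t for d, t in self.offsets])

    def label(self) -> str:
        return f"k={self.points_per_day}/day x {self.n_days}d"


def evenly_spaced_design(k: int, n_days: int = 1,
                         wake_window=DEFAULT_WAKE_WINDOW) -> SamplingDesign:
    """k points per day, evenly spaced across the wake window, same times
    every day (k=4 in a 9-21 h window gives the 9/13/17/21 h protocol)."""
    lo, hi = wake_window
    times = np.linspace(lo, hi, k)
    offsets = tuple((d, round(float(t), 6))
                    for d in range(1, n_days + 1) for t in times)
    return SamplingDesign(offsets, tuple(wake_window))


def spread_design(k: int, n_days: int, wake_window=DEFAULT_WAKE_WINDOW) -> SamplingDesign:
    """k points in total, spread evenly over the waking hours of all days
    (e.g. 5 points across 2 days)."""
    lo, hi = wake_window
    width = hi - lo
    positions = np.linspace(0.0, n_days * width, k)
    offsets = []
    for s in positions:
        day = min(int(s // width), n_days - 1)
        offsets.append((day + 1, round(float(lo + (s - day * width)), 6)))
    return SamplingDesign(tuple(dict.fromkeys(offsets)), tuple(wake_window))


def enumerate_designs(points_per_day, n_days=(1,), wake_window=DEFAULT_WAKE_WINDOW,
                      grid_step_h: float = 2.0,
                      include_protocol: bool = True) -> list[SamplingDesign]:
    """All evenly spaced designs on the grid, plus the 9/13/17/21 protocol.

    For each k and day count, every arithmetic progression of k grid times
    (grid anchored at the window start, spacing a positive multiple of the
    grid step) that fits inside the wake window, replicated over the days.
    """
    lo, hi = wake_window
    if hi <= lo:
        raise ValueError("empty wake window")
    if isinstance(points_per_day, int):
        points_per_day = [points_per_day]
    if isinstance(n_days, int):
        n_days = [n_days]
    grid = np.arange(lo, hi + 1e-9, grid_step_h)
    designs: dict[tuple, SamplingDesign] = {}
    for nd in n_days:
        for k in points_per_day:
            for spacing_mult in range(1, len(grid)):
                spacing = spacing_mult * grid_step_h
                for start in grid:
                    end = start + (k - 1) * spacing
                    if end > hi + 1e-9:
                        continue
                    times = tuple(round(start + j * spacing, 6) for j in range(k))
                    offsets = tuple((d, t) for d in range(1, nd + 1) for t in times)
                    designs.setdefault(offsets, SamplingDesign(offsets, tuple(wake_window)))
            if include_protocol and k == 4 and lo <= 9.0 and hi >= 21.0:
                proto = tuple((d, t) for d in range(1, nd + 1)
                              for t in (9.0, 13.0, 17.0, 21.0))
                designs.setdefault(proto, SamplingDesign(proto, tuple(wake_window)))
    return list(designs.values())


@dataclass
class DesignEvaluation:
    design: SamplingDesign
    n_replicates: int
    feasible_fraction: float
    detection_rate: float
    median_phase_error_h: float
    median_amplitude_rel_error: float
    success: bool
    alpha: float
    phase_tol_h: float
    detection_threshold: float

    def as_row(self) -> dict:
        return {
            "design": self.design.label(),
            "points_per_day": self.design.points_per_day,
            "n_days": self.design.n_days,
            "n_points": self.design.n_points,
            "n_replicates": self.n_replicates,
            "feasible_fraction": self.feasible_fraction,
            "detection_rate": self.detection_rate,
            "median_phase_error_h": self.median_phase_error_h,
            "median_amplitude_rel_error": self.median_amplitude_rel_error,
            "success": self.success,
        }


def evaluate_design(truth: GeneParams, design: SamplingDesign,
                    noise_sd: float = 0.1, n_replicates: int = 200,
                    alpha: float = 0.05, phase_tol_h: float = 2.0,
                    detection_threshold: float = 0.8,
                    lrt_method: str = "chi2", seed: int = 0) -> DesignEvaluation:
    """Monte-Carlo recovery statistics for one design.

    Per replicate the generative cosine is simulated at the design offsets
    with multiplicative Gaussian noise (sd a fraction of the local mean),
    then refitted. Success requires feasible_fraction == 1, detection_rate
    >= detection_threshold at level alpha, and median circular acrophase
    error <= phase_tol_h. Designs with fewer than 3 distinct clock phases
    (or exactly 3 points) are analytically infeasible and reported as such
    without simulation of the test.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    t = design.abs_times_h()
    mean_curve = truth.curve(t)
    amp_true = truth.rel_amplitude * truth.mesor
    feasible, detected, phase_err, amp_err = [], [], [], []
    for _ in range(n_replicates):
        y = mean_curve * (1.0 + noise_sd * rng.standard_normal(len(t)))
        try:
            fit = fit_harmonic((t, y))
        except SingularDesignError:
            feasible.append(False)
            continue
        if fit.saturated:
            feasible.append(False)
            continue
        feasible.append(True)
        _, p = rhythmicity_lrt(fit, method=lrt_method)
        detected.append(p is not None and p < alpha)
        phase_err.append(circular_diff(fit.acrophase_h, truth.acrophase_h))
        if amp_true > 0:
            amp_err.append(abs(fit.amplitude - amp_true) / amp_true)
    feasible_fraction = float(np.mean(feasible)) if feasible else 0.0
    detection_rate = float(np.mean(detected)) if detected else 0.0
    med_phase = float(np.median(phase_err)) if phase_err else float("inf")
    med_amp = float(np.median(amp_err)) if amp_err else float("inf")
    success = (feasible_fraction >= 1.0
               and detection_rate >= detection_threshold
               and med_phase <= phase_tol_h)
    return DesignEvaluation(design, n_replicates, feasible_fraction,
                            detection_rate, med_phase, med_amp, bool(success),
                            alpha, phase_tol_h, detection_threshold)


def minimal_sufficient_design(evaluations: list[DesignEvaluation]) -> dict:
    """Smallest points-per-day achieving success, reported per day count.

    Designs must cover a contiguous k range per day count; day counts with
    no successful design map to None (an explicit "none", not an error).
    """
    out: dict[int, int | None] = {}
    by_days: dict[int, list[DesignEvaluation]] = {}
    for ev in evaluations:
        by_days.setdefault(ev.design.n_days, []).append(ev)
    for nd, evs in sorted(by_days.items()):
        ks = sorted({ev.design.points_per_day for ev in evs})
        if ks and ks != list(range(ks[0], ks[-1] + 1)):
            raise ValueError(f"evaluations for {nd} day(s) do not cover a "
                             f"contiguous points-per-day range: {ks}")
        winners = [ev.design.points_per_day for ev in evs if ev.success]
        out[nd] = min(winners) if winners else None
    return out


def evaluations_to_frame(evaluations: list[DesignEvaluation]) -> pd.DataFrame:
    return pd.DataFrame([ev.as_row() for ev in evaluations])


def subsample_series(series, design: SamplingDesign, tol_h: float = 1e-6):
    """Restrict a measured dense series to a design's offsets (nearest-time
    match within tolerance), for leave-out refitting against the full-data
    fit when a dense empirical series is available instead of a generator."""
    t = series.abs_time_h()
    want = design.abs_times_h()
    keep = np.zeros(len(t), dtype=bool)
    for w in want:
        idx = int(np.argmin(np.abs(t - w)))
        if abs(t[idx] - w) <= tol_h:
            keep[idx] = True
    from .qpcr import ExpressionSeries
    return ExpressionSeries(series.participant_id, series.gene,
                            series.points.loc[keep].reset_index(drop=True))


def minimal_points_per_day(truth: GeneParams | None = None,
                           k_range=range(3, 9), n_days: int = 1,
                           wake_window=DEFAULT_WAKE_WINDOW,
                           noise_sd: float = 0.1, n_replicates: int = 200,
                           alpha: float = 0.05, phase_tol_h: float = 2.0,
                           detection_threshold: float = 0.8,
                           lrt_method: str = "chi2", seed: int = 0):
    """Convenience wrapper: evaluate evenly spaced k-point designs and return
    (minimal successful k or None, evaluations)."""
    if truth is None:
        truth = GeneParams("ARNTL1", mesor=1.0, rel_amplitude=0.5, acrophase_h=18.0)
    evaluations = []
    for j, k in enumerate(k_range):
        design = evenly_spaced_design(k, n_days=n_days, wake_window=wake_window)
        evaluations.append(evaluate_design(
            truth, design, noise_sd=noise_sd, n_replicates=n_replicates,
            alpha=alpha, phase_tol_h=phase_tol_h,
            detection_threshold=detection_threshold, lrt_method=lrt_method,
            seed=seed + j))
    return minimal_sufficient_design(evaluations).get(n_days), evaluations
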