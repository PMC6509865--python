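"""Drug-response analysis: kill rates, Bliss synergy, combination timing.

Kill rates are read off simulated survival-rate curves as
``kill = 1 - survival`` at a configurable evaluation time (default: end
of run).  The Bliss independence score of a combination is

    CI = R12 - (R1 + R2 - R1*R2)

where R1/R2 are the single-agent kill rates and R12 the combination kill
rate; CI > 0 means synergy, CI < 0 antagonism, and CI = 0 exact
independence (kill probabilities multiply).

Multi-arm experiments run with *paired seeds*: every arm of a comparison
shares the same master seed, so arms share their random streams until
the schedules make the dynamics diverge (common random numbers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .errors import DomainError
from .engine import run_simulation

#: survival-rate rise above its minimum that counts as a rebound
#: (emergence of drug resistance), in absolute survival-rate units
DEFAULT_REBOUND_TOL = 0.02


@dataclass
class KillRates:
    """Tumor-cell kill rates: EGFRI alone, VEGFRI alone, combination."""

    r1: float
    r2: float
    r12: float

    def __post_init__(self):
        for name in ("r1", "r2", "r12"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"kill rate {name}={v} outside [0, 1]")


def bliss_ci(rates, r2=None, r12=None) -> float:
    """Bliss combination index; accepts a :class:`KillRates` or three floats."""
    if not isinstance(rates, KillRates):
        rates = KillRates(float(rates), float(r2), float(r12))
    return rates.r12 - (rates.r1 + rates.r2 - rates.r1 * rates.r2)


def kill_rate_from_survival(survival_rate_at_t: float) -> float:
    """Complement of the survival rate at the evaluation time."""
    s = float(survival_rate_at_t)
    if not 0.0 <= s <= 1.0:
        raise DomainError(f"survival rate {s} outside [0, 1]")
    return 1.0 - s


# ---------------------------------------------------------------------------
# census-curve analysis
# ---------------------------------------------------------------------------

def survival_at(series: pd.Series, eval_time: float | None = None) -> float:
    """Survival rate at the last census time <= eval_time (default: final)."""
    if eval_time is None:
        return float(series.iloc[-1])
    sel = series[series.index <= eval_time]
    if sel.empty:
        raise DomainError(f"no census rows at or before t={eval_time}")
    return float(sel.iloc[-1])


def rebound_onset(series: pd.Series, tol: float = DEFAULT_REBOUND_TOL):
    """(rebounded, onset_time) of a survival-rate curve.

    The onset is the census time of the curve's minimum when the curve
    later rises more than ``tol`` above that minimum; otherwise
    ``(False, None)``.
    """
    values = series.values.astype(float)
    if len(values) < 2:
        return False, None
    i_min = int(np.argmin(values))
    if i_min == len(values) - 1:
        return False, None
    rise = values[i_min:].max() - values[i_min]
    if rise > tol:
        return True, float(series.index[i_min])
    return False, None


def first_apoptosis_time(frame: pd.DataFrame):
    """First census time with any cumulative apoptotic count, else None."""
    hit = frame[frame["apoptotic_cumulative"] > 0]
    return None if hit.empty else float(hit["time_h"].iloc[0])


def steepest_decline_time(series: pd.Series):
    """Census time of the most negative survival-rate slope before the minimum."""
    values = series.values.astype(float)
    if len(values) < 2:
        return None
    i_min = int(np.argmin(values))
    if i_min == 0:
        return None
    dv = np.diff(values[: i_min + 1])
    j = int(np.argmin(dv))
    return float(series.index[j + 1])


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def _arm(config: SimulationConfig, seed: int, egfri_start, vegfri_start) -> SimulationConfig:
    arm = config.copy()
    arm.simulation.seed = int(seed)
    arm.drugs["egfri"].start_time = None if egfri_start is None else float(egfri_start)
    arm.drugs["vegfri"].start_time = None if vegfri_start is None else float(vegfri_start)
    return arm


@dataclass
class SynergyResult:
    rates: KillRates          # mean kill rates across seeds
    ci_mean: float
    ci_std: float             # across-seed dispersion of the Bliss index
    per_seed: pd.DataFrame


def synergy_experiment(config: SimulationConfig, eval_time: float | None = None,
                       seeds=(0, 1, 2), egfri_start: float = 0.0,
                       vegfri_start: float = 240.0) -> SynergyResult:
    """Three paired arms (EGFRI-only, VEGFRI-only, combination) -> Bliss CI.

    The arms differ only in their drug schedules; each seed is reused
    across the three arms.
    """
    rows = []
    for seed in seeds:
        r1 = kill_rate_from_survival(survival_at(
            run_simulation(_arm(config, seed, egfri_start, None)).survival_series(), eval_time))
        r2 = kill_rate_from_survival(survival_at(
            run_simulation(_arm(config, seed, None, vegfri_start)).survival_series(), eval_time))
        r12 = kill_rate_from_survival(survival_at(
            run_simulation(_arm(config, seed, egfri_start, vegfri_start)).survival_series(), eval_time))
        rows.append({"seed": seed, "r1": r1, "r2": r2, "r12": r12,
                     "ci": bliss_ci(r1, r2, r12)})
    per_seed = pd.DataFrame(rows)
    rates = KillRates(float(per_seed["r1"].mean()), float(per_seed["r2"].mean()),
                      float(per_seed["r12"].mean()))
    return SynergyResult(rates=rates, ci_mean=float(per_seed["ci"].mean()),
                         ci_std=float(per_seed["ci"].std(ddof=0)), per_seed=per_seed)


def timing_scan(config: SimulationConfig, vegfri_start_times, seeds=(0, 1, 2),
                egfri_start: float = 0.0,
                rebound_tol: float = DEFAULT_REBOUND_TOL) -> pd.DataFrame:
    """Sweep the VEGFRI onset over a fixed EGFRI backbone with paired seeds.

    Returns one row per (onset, seed) with the final survival rate and
    whether that run's survival curve rebounded.
    """
    rows = []
    for start in vegfri_start_times:
        for seed in seeds:
            res = run_simulation(_arm(config, seed, egfri_start, start))
            series = res.survival_series()
            rebounded, onset = rebound_onset(series, rebound_tol)
            rows.append({
                "start_time": float(start), "seed": seed,
                "final_survival": float(series.iloc[-1]),
                "rebound": bool(rebounded),
                "rebound_time": onset,
            })
    return pd.DataFrame(rows)


def optimal_onset(scan: pd.DataFrame, indistinguishable_tol: float = 0.03):
    """Latest VEGFRI onset that abolishes the rebound without losing ground.

    An onset qualifies when (a) no rebound occurs in the majority of its
    seeds and (b) its mean final survival exceeds no earlier qualifying
    onset's by more than ``indistinguishable_tol`` (paired seeds make the
    mean difference a low-variance estimate).  Returns the latest
    qualifying onset, or None.
    """
    grouped = (scan.groupby("start_time")
               .agg(final=("final_survival", "mean"), rebound=("rebound", "mean"))
               .sort_index())
    no_rebound = grouped[grouped["rebound"] < 0.5]
    best = None
    for start, row in no_rebound.iterrows():
        earlier = no_rebound[no_rebound.index < start]
        if earlier.empty or row["final"] <= earlier["final"].min() + indistinguishable_tol:
            best = float(start)
    return best
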