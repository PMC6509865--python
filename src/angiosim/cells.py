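"""Tumor-cell agents: phenotype switching, migration, division, census.

Cells live one-per-voxel on the lattice.  Each update a living cell is
reassigned a phenotype by strict rule precedence

    1. apoptotic    -- acute starvation (glucose or oxygen below its death
                       threshold for the configured number of consecutive
                       updates) or chronic starvation (the hunger integral
                       accrued below quiescence-level glucose exceeds the
                       starvation tolerance)
    2. active       -- PLCgamma changing faster than the migration threshold
                       (migration-competent)
    3. proliferative-- the cell-cycle clock has armed division and a free
                       Moore neighbour exists
    4. quiescent    -- otherwise

Chronic starvation accrues at rate (1 - glucose/quiescence_threshold)
per hour while glucose sits below the quiescence threshold and resets on
recovery, so how long a quiescent cell survives depends on how deep its
nutrient deficit is; a vessel growing into reach rescues it.

Apoptosis is absorbing: a dead cell takes no further actions, keeps its
death time, and stops blocking its voxel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .config import PhenotypeRulesConfig
from .errors import ConsistencyError, DomainError
from .grid import Grid3D
from .signaling import CellCycleState, EGFRPathwayState

PHENOTYPES = ("active", "proliferative", "quiescent", "apoptotic")
PhenotypeRules = PhenotypeRulesConfig  # rule thresholds live in the config block

_ENV_KEYS = ("glucose", "oxygen", "tgfa", "egfri")


@dataclass
class TumorCell:
    id: int
    position: tuple
    phenotype: str = "quiescent"
    egfr_state: EGFRPathwayState = field(default_factory=EGFRPathwayState)
    cycle_state: CellCycleState = field(default_factory=CellCycleState)
    birth_time: float = 0.0
    death_time: float | None = None
    #: consecutive updates (including the current one) spent below a death
    #: threshold; maintained by the engine before each phenotype decision
    starved_steps: int = 0
    #: accumulated hunger (h) below quiescence-level glucose; engine-maintained
    hunger_h: float = 0.0

    @property
    def alive(self) -> bool:
        return self.phenotype != "apoptotic"


@dataclass
class CensusRecord:
    time_h: float
    active: int
    proliferative: int
    quiescent: int
    apoptotic_cumulative: int
    ec_count: int
    survival_rate: float

    @property
    def living(self) -> int:
        return self.active + self.proliferative + self.quiescent


def decide_phenotype(cell: TumorCell, local_env: dict,
                     rules: PhenotypeRulesConfig,
                     has_free_neighbor: bool = True) -> str:
    """Phenotype by rule precedence (death > migration > division > quiescence).

    ``cell.starved_steps`` and ``cell.hunger_h`` must already count the
    current update, so with ``death_sustained_steps == 1`` a single acutely
    starved update kills.
    """
    missing = [k for k in _ENV_KEYS if k not in local_env]
    if missing:
        raise ConsistencyError(f"local environment missing species: {missing}")
    if cell.phenotype == "apoptotic":
        return "apoptotic"
    starving = (local_env["glucose"] < rules.glucose_death_threshold
                or local_env["oxygen"] < rules.oxygen_death_threshold)
    if starving and cell.starved_steps >= rules.death_sustained_steps:
        return "apoptotic"
    if (rules.starvation_tolerance_h is not None
            and cell.hunger_h >= rules.starvation_tolerance_h):
        return "apoptotic"
    if cell.egfr_state.plcg_rate > rules.plcg_rate_migration_threshold:
        return "active"
    if cell.cycle_state.division_ready and has_free_neighbor:
        return "proliferative"
    return "quiescent"


def free_neighbors(position, occupancy: np.ndarray, grid: Grid3D) -> list:
    """Moore neighbours not blocked by a living tumor cell."""
    return [n for n in grid.neighbors26(position) if not occupancy[n]]


def migrate_cell(cell: TumorCell, attraction_field: np.ndarray,
                 occupancy: np.ndarray, grid: Grid3D, rng: np.random.Generator,
                 eps: float = 1e-15) -> tuple:
    """Move an active cell to a free neighbour with probability proportional
    to the attraction score there (default usage: local TGFa, which is
    vessel-sourced, so active cells drift towards vasculature).

    Returns the new position; a fully blocked cell stays put.  Occupancy
    is updated atomically.
    """
    frees = free_neighbors(cell.position, occupancy, grid)
    if not frees:
        return cell.position
    weights = np.array([attraction_field[n] for n in frees], dtype=float) + eps
    probs = weights / weights.sum()
    new_pos = frees[int(rng.choice(len(frees), p=probs))]
    occupancy[cell.position] = False
    occupancy[new_pos] = True
    cell.position = new_pos
    return new_pos


def eligible_neighbors(position, occupancy: np.ndarray, grid: Grid3D,
                       nutrient_field: np.ndarray | None = None,
                       nutrient_min: float = 0.0) -> list:
    """Free Moore neighbours, optionally restricted to nutrient-viable voxels.

    Daughter placement uses this with the quiescence-level glucose
    threshold: a population at the edge of its supplied niche saturates
    instead of spilling newborns into voxels where they would starve.
    """
    out = free_neighbors(position, occupancy, grid)
    if nutrient_field is not None:
        out = [n for n in out if nutrient_field[n] >= nutrient_min]
    return out


def divide_cell(cell: TumorCell, occupancy: np.ndarray, grid: Grid3D,
                rng: np.random.Generator, daughter_id: int,
                time_h: float, nutrient_field: np.ndarray | None = None,
                nutrient_min: float = 0.0) -> TumorCell | None:
    """Place a daughter in a uniformly chosen free (and, when a nutrient
    field is given, nutrient-viable) neighbour.

    Both cells restart their cycle clock; the daughter inherits a copy of
    the mother's EGFR-pathway state.  Returns None (division deferred)
    when no admissible neighbour exists; the caller then re-enters
    quiescence.
    """
    frees = eligible_neighbors(cell.position, occupancy, grid,
                               nutrient_field, nutrient_min)
    if not frees:
        return None
    pos = frees[int(rng.integers(len(frees)))]
    cell.cycle_state = CellCycleState()
    daughter = TumorCell(
        id=daughter_id,
        position=pos,
        phenotype="quiescent",
        egfr_state=dataclasses.replace(cell.egfr_state),
        cycle_state=CellCycleState(),
        birth_time=time_h,
    )
    occupancy[pos] = True
    return daughter


def census(cells, ec_count: int = 0, time_h: float = 0.0,
           survival_definition: str = "cumulative",
           peak_living: int | None = None) -> CensusRecord:
    """Per-step counts by phenotype plus the tumor-cell survival rate.

    The default survival rate is living / (living + cumulative apoptotic),
    i.e. the fraction of all cells ever created that is still alive; the
    alternative 'peak' definition divides by the historical living maximum.
    """
    counts = {p: 0 for p in PHENOTYPES}
    for cell in cells:
        counts[cell.phenotype] += 1
    living = counts["active"] + counts["proliferative"] + counts["quiescent"]
    if survival_definition == "cumulative":
        total = living + counts["apoptotic"]
        survival = living / total if total else 1.0
    elif survival_definition == "peak":
        peak = max(peak_living or 0, living)
        survival = living / peak if peak else 1.0
    else:
        raise DomainError(f"unknown survival definition {survival_definition!r}")
    return CensusRecord(time_h=time_h, active=counts["active"],
                        proliferative=counts["proliferative"],
                        quiescent=counts["quiescent"],
                        apoptotic_cumulative=counts["apoptotic"],
                        ec_count=ec_count, survival_rate=survival)
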