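"""Simulation engine: the four-scale update loop and run bookkeeping.

Each cell-update interval (default 1 h) advances, in fixed order:

  1. microenvironment -- rebuild occupancy indicators, then sub-step the
     reaction-diffusion fields (drug sources gated by their schedules);
  2. molecular        -- per-cell effective EGFR from the local inhibitor
     level, then the EGFR-cascade and cell-cycle ODEs (vectorised);
  3. cellular         -- phenotype decisions and actions (death, migration,
     division) over living cells in a randomised order;
  4. tissue           -- the tip-EC survival rule, then tip migration and
     sprout branching.

A master seed spawns named substreams (cells / tips / placement), so a
config plus seed fully determines every output byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .cells import (TumorCell, census, decide_phenotype, divide_cell,
                    eligible_neighbors, free_neighbors, migrate_cell)
from .config import DRUGS, SPECIES, SimulationConfig
from .errors import AngiosimError, ConfigurationError
from .grid import (Grid3D, Indicators, STEPPERS, ScalarField, make_grid,
                   rebuild_indicators, stable_dt, step_drug_field, step_fibronectin_field,
                   step_nutrient_field, step_taf_field)
from .signaling import (BindingParams, EGFRPathwayState, effective_egfr,
                        step_cycle_batch, step_egfr_batch)
from .vessels import branch_sprout, check_ec_survival, initialize_network, migrate_tip, vessel_census

CENSUS_COLUMNS = ("time_h", "active", "proliferative", "quiescent",
                  "apoptotic_cumulative", "ec_count", "survival_rate")


@dataclass
class SimulationResult:
    config: SimulationConfig
    census: list
    cells: list
    network: object
    fields: dict
    manifest: dict
    snapshots: list = field(default_factory=list)

    def census_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {c: getattr(r, c) for c in CENSUS_COLUMNS} for r in self.census
        ])

    def survival_series(self) -> pd.Series:
        frame = self.census_frame()
        return pd.Series(frame["survival_rate"].values, index=frame["time_h"].values)

    def final_survival_rate(self) -> float:
        return float(self.census[-1].survival_rate)


def _seed_cluster(grid: Grid3D, center, n: int):
    """The n voxels nearest the centre (ties broken lexicographically)."""
    if n == 0:
        return []
    cx, cy, cz = center
    nx, ny, nz = grid.shape
    r = 0
    voxels = []
    while len(voxels) < n and r <= max(grid.shape):
        r += 1
        voxels = [(x, y, z)
                  for x in range(max(0, cx - r), min(nx, cx + r + 1))
                  for y in range(max(0, cy - r), min(ny, cy + r + 1))
                  for z in range(max(0, cz - r), min(nz, cz + r + 1))]
        voxels.sort(key=lambda v: ((v[0] - cx) ** 2 + (v[1] - cy) ** 2 + (v[2] - cz) ** 2, v))
    return voxels[:n]


class _Run:
    """Mutable state of one simulation run."""

    def __init__(self, config: SimulationConfig):
        config.validate()
        self.config = config
        self.grid = make_grid(config)
        sim = config.simulation
        ss = np.random.SeedSequence(sim.seed)
        kids = ss.spawn(3)
        self.rng_cells = np.random.default_rng(kids[0])
        self.rng_tips = np.random.default_rng(kids[1])
        self.rng_place = np.random.default_rng(kids[2])

        self.network = initialize_network(self.grid, config.vasculature, self.rng_tips)
        self.fields = {
            name: ScalarField.uniform(name, self.grid, config.fields[name])
            for name in SPECIES
        }
        self.occupancy = np.zeros(self.grid.shape, dtype=bool)
        self.cells: list = []
        center = config.tumor.center
        if center is None:
            nx, ny, nz = self.grid.shape
            center = (nx // 2, ny // 2, int(round(0.7 * nz)))
        for i, pos in enumerate(_seed_cluster(self.grid, center, config.tumor.n_initial_cells)):
            # start the PLCgamma module at its unstimulated fixed point so
            # migration competence develops from signalling, not from the
            # relaxation transient of an arbitrary initial state
            state = EGFRPathwayState(plc=config.egfr_pathway.osc_a)
            self.cells.append(TumorCell(id=i, position=pos, egfr_state=state))
            self.occupancy[pos] = True
        self.next_cell_id = len(self.cells)
        self.total_created = len(self.cells)
        self.peak_living = len(self.cells)
        self.dt = sim.cell_update_interval
        self.substeps = {}
        for name in SPECIES:
            if sim.field_substeps is not None:
                self.substeps[name] = sim.field_substeps
            else:
                bound = stable_dt(config.fields[name], self.grid)
                self.substeps[name] = max(1, int(np.ceil(self.dt / bound))) if np.isfinite(bound) else 1
        self.census: list = []
        self.snapshots: list = []

    # -- helpers ------------------------------------------------------------

    def living(self):
        return [c for c in self.cells if c.alive]

    def drug_on(self, drug: str, t: float) -> bool:
        sched = self.config.drugs[drug]
        return sched.start_time is not None and t >= sched.start_time

    def indicators(self) -> Indicators:
        ind = rebuild_indicators(self.cells, self.network, self.grid)
        tumor = self.config.tumor
        if tumor.starvation_taf_enabled:
            weights = ind.chi_tum.astype(float)
            starved = (self.fields["glucose"].values
                       < self.config.phenotype.glucose_quiescence_threshold)
            weights[starved & (ind.chi_tum == 1)] *= tumor.taf_starvation_multiplier
            ind.taf_secretion = weights
        return ind

    # -- the four scales ----------------------------------------------------

    def step_fields(self, ind: Indicators, t: float) -> None:
        for name in SPECIES:
            f = self.fields[name]
            n = self.substeps[name]
            h = self.dt / n
            if name in DRUGS:
                if not self.drug_on(name, t):
                    continue  # sourceless and initially zero: stays zero
                H = self.config.drugs[name].in_blood_concentration
                for _ in range(n):
                    step_drug_field(f, ind, self.grid, h, in_blood=H)
            elif name == "taf":
                for _ in range(n):
                    step_taf_field(f, ind, self.grid, h,
                                   consumed_by_tips=self.config.simulation.taf_consumed_by_tips)
            elif name == "fibronectin":
                for _ in range(n):
                    step_fibronectin_field(f, ind, self.grid, h)
            else:
                for _ in range(n):
                    step_nutrient_field(f, ind, self.grid, h)

    def step_molecular(self) -> None:
        living = self.living()
        if not living:
            return
        cfg = self.config
        pos = tuple(np.array([c.position[k] for c in living]) for k in range(3))
        i1 = self.fields["egfri"].values[pos]
        ligand = self.fields["tgfa"].values[pos]
        glucose = self.fields["glucose"].values[pos]
        r_eff = effective_egfr(cfg.binding.egfr_total, i1, cfg.binding.km_egfri)
        egfr_states = np.array([c.egfr_state.as_array() for c in living])
        egfr_states, plc_rate = step_egfr_batch(egfr_states, ligand, r_eff,
                                                cfg.egfr_pathway, self.dt)
        cc = cfg.cell_cycle
        growth = egfr_states[:, 3]
        growth_n = growth ** cc.growth_hill
        gluc_n = glucose ** cc.glucose_hill
        gs = (growth_n / (cc.growth_half ** cc.growth_hill + growth_n + 1e-300)) * \
             (gluc_n / (cc.glucose_half ** cc.glucose_hill + gluc_n + 1e-300))
        cyc_states = np.array([c.cycle_state.as_array() for c in living])
        cyc_states, ready = step_cycle_batch(cyc_states, gs, cc, self.dt)
        for j, c in enumerate(living):
            st = c.egfr_state
            st.receptor_signal, st.plc, st.plc_substrate, st.growth = egfr_states[j]
            st.plcg_rate = float(plc_rate[j])
            cy = c.cycle_state
            cy.cyclin, cy.progress = cyc_states[j]
            cy.division_ready = bool(cy.division_ready or ready[j])

    def step_cellular(self, t_next: float) -> None:
        cfg = self.config
        rules = cfg.phenotype
        living = self.living()
        order = self.rng_cells.permutation(len(living))
        gl = self.fields["glucose"].values
        ox = self.fields["oxygen"].values
        tg = self.fields["tgfa"].values
        eg = self.fields["egfri"].values
        attraction = tg ** rules.migration_attraction_exponent
        for idx in order:
            cell = living[idx]
            if not cell.alive:
                continue
            p = cell.position
            env = {"glucose": float(gl[p]), "oxygen": float(ox[p]),
                   "tgfa": float(tg[p]), "egfri": float(eg[p])}
            starving = (env["glucose"] < rules.glucose_death_threshold
                        or env["oxygen"] < rules.oxygen_death_threshold)
            cell.starved_steps = cell.starved_steps + 1 if starving else 0
            if env["glucose"] < rules.glucose_quiescence_threshold:
                cell.hunger_h += self.dt * (
                    1.0 - env["glucose"] / rules.glucose_quiescence_threshold)
            else:
                cell.hunger_h = 0.0
            nutrient = gl if rules.daughter_needs_nutrient else None
            nmin = rules.daughter_nutrient_min
            frees = eligible_neighbors(p, self.occupancy, self.grid, nutrient, nmin)
            phenotype = decide_phenotype(cell, env, rules, has_free_neighbor=bool(frees))
            cell.phenotype = phenotype
            if phenotype == "apoptotic":
                cell.death_time = t_next
                self.occupancy[p] = False
            elif phenotype == "active":
                migrate_cell(cell, attraction, self.occupancy, self.grid, self.rng_cells)
            elif phenotype == "proliferative":
                daughter = divide_cell(cell, self.occupancy, self.grid,
                                       self.rng_place, self.next_cell_id, t_next,
                                       nutrient, nmin)
                if daughter is None:
                    cell.phenotype = "quiescent"
                else:
                    self.next_cell_id += 1
                    self.total_created += 1
                    self.cells.append(daughter)
                    cell.phenotype = "quiescent"

    def step_tissue(self, t_next: float) -> None:
        cfg = self.config
        binding = BindingParams(km=cfg.binding.km_vegfri, r0=cfg.binding.vegfr_total)
        check_ec_survival(self.network.tips, self.fields["vegfri"].values, binding)
        taf = self.fields["taf"].values
        fib = self.fields["fibronectin"].values
        tips = self.network.active_tips()
        order = self.rng_tips.permutation(len(tips))
        for idx in order:
            tip = tips[idx]
            tip.age += self.dt
            if tip.anastomosed or not tip.active:
                continue
            if self.rng_tips.random() < cfg.vasculature.tip_move_prob * self.dt:
                migrate_tip(tip, taf, fib, self.network, self.grid,
                            self.rng_tips, cfg.vasculature, t_next)
            branch_sprout(tip, taf, self.network, self.grid,
                          self.rng_tips, cfg.vasculature, t_next)

    def record(self, t: float) -> None:
        ec_count, _ = vessel_census(self.network)
        rec = census(self.cells, ec_count=ec_count, time_h=t,
                     survival_definition=self.config.simulation.survival_definition,
                     peak_living=self.peak_living)
        self.peak_living = max(self.peak_living, rec.living)
        self.census.append(rec)


def run_simulation(config: SimulationConfig, snapshot_every: float | None = None) -> SimulationResult:
    """Execute one run; identical config and seed give identical results."""
    run = _Run(config)
    sim = config.simulation
    n_steps = int(round(sim.t_end / sim.cell_update_interval))
    run.record(0.0)
    if snapshot_every is not None:
        run.snapshots.append((0.0, {s: run.fields[s].values.copy() for s in SPECIES}))
    stage = "init"
    try:
        for step in range(n_steps):
            t = step * sim.cell_update_interval
            t_next = (step + 1) * sim.cell_update_interval
            stage = "microenvironment"
            ind = run.indicators()
            run.step_fields(ind, t)
            stage = "molecular"
            run.step_molecular()
            stage = "cellular"
            run.step_cellular(t_next)
            stage = "tissue"
            run.step_tissue(t_next)
            stage = "census"
            run.record(t_next)
            if snapshot_every is not None and (step + 1) % max(1, int(round(
                    snapshot_every / sim.cell_update_interval))) == 0:
                run.snapshots.append(
                    (t_next, {s: run.fields[s].values.copy() for s in SPECIES}))
    except AngiosimError as exc:
        raise type(exc)(f"[t={t:.1f} h, stage '{stage}'] {exc}") from exc

    manifest = {
        "package": "angiosim",
        "version": _pkg_version,
        "seed": sim.seed,
        "numpy": np.__version__,
        "config": config.to_dict(),
    }
    return SimulationResult(config=config, census=run.census, cells=run.cells,
                            network=run.network, fields=run.fields,
                            manifest=manifest, snapshots=run.snapshots)


# ---------------------------------------------------------------------------
# output writing
# ---------------------------------------------------------------------------

def census_csv(result: SimulationResult) -> str:
    return result.census_frame().to_csv(index=False, float_format="%.10g")


def write_census_csv(result: SimulationResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(census_csv(result))


def write_cells_csv(result: SimulationResult, path) -> None:
    rows = [{"id": c.id, "x": c.position[0], "y": c.position[1], "z": c.position[2],
             "phenotype": c.phenotype, "birth_time": c.birth_time,
             "death_time": "" if c.death_time is None else c.death_time}
            for c in result.cells]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_vessels_csv(result: SimulationResult, seg_path, tip_path) -> None:
    segs = [{"sprout_id": s.sprout_id, "x0": s.a[0], "y0": s.a[1], "z0": s.a[2],
             "x1": s.b[0], "y1": s.b[1], "z1": s.b[2], "created_at": s.created_at}
            for s in result.network.segments]
    pd.DataFrame(segs, columns=["sprout_id", "x0", "y0", "z0", "x1", "y1", "z1",
                                "created_at"]).to_csv(seg_path, index=False)
    tips = [{"sprout_id": t.sprout_id, "x": t.position[0], "y": t.position[1],
             "z": t.position[2], "active": t.active, "age": t.age}
            for t in result.network.tips]
    pd.DataFrame(tips, columns=["sprout_id", "x", "y", "z", "active",
                                "age"]).to_csv(tip_path, index=False)


def save_manifest(result: SimulationResult, path) -> None:
    """Run record: every resolved parameter value, seed and versions."""
    with open(path, "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)


def export_fields_hdf5(result: SimulationResult, path) -> None:
    """Snapshot container laid out as /fields/<species>/<time>."""
    import h5py

    with h5py.File(path, "w") as fh:
        for t, arrays in result.snapshots:
            for species, arr in arrays.items():
                fh.create_dataset(f"/fields/{species}/{t:g}", data=arr)


def export_field_slices_csv(result: SimulationResult, directory, axis: int = 2) -> None:
    """Per-slice CSV export of the final fields (small grids only)."""
    import os

    for species, f in result.fields.items():
        arr = np.moveaxis(f.values, axis, 0)
        for k in range(arr.shape[0]):
            pd.DataFrame(arr[k]).to_csv(
                os.path.join(directory, f"{species}_slice{k:03d}.csv"),
                index=False, header=False)


def load_config(path) -> SimulationConfig:
    return SimulationConfig.load(path)
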