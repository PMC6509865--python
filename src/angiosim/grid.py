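"""3-D lattice, occupancy indicator fields and reaction-diffusion stepping.

All extracellular species (nutrients, growth factors, matrix, drugs) live
on the same regular voxel lattice and are advanced with an explicit
forward-Euler step and a 7-point second-order Laplacian.  Within one step
the operators are applied in a fixed order -- diffusion, trans-vessel
exchange, agent uptake, first-order decay -- so runs are bit-reproducible;
the splitting error is within the order of the scheme.

Uptake sinks are applied as ``min(u*dt, value)`` per voxel, which makes
nonnegativity structural rather than incidental.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .config import DiffusionParams, GridConfig, SimulationConfig
from .errors import ConfigurationError, ConsistencyError, NumericalError

#: all 26 neighbour offsets of a voxel (3-D Moore neighbourhood)
NEIGHBOR_OFFSETS = tuple(
    off for off in itertools.product((-1, 0, 1), repeat=3) if off != (0, 0, 0)
)

_STABILITY_SAFETY = 0.9


@dataclass(frozen=True)
class Grid3D:
    """Regular lattice: ``shape`` voxels of edge ``spacing`` micrometres.

    Voxel indices are 0-based integer triples; the physical position of a
    voxel is its centre, so the index<->location mapping is bijective.
    """

    shape: tuple
    spacing: float
    boundary: str = "no-flux"
    fixed_value: float = 0.0

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def contains(self, idx) -> bool:
        return all(0 <= i < n for i, n in zip(idx, self.shape))

    def voxel_center(self, idx):
        """Physical position (um) of the voxel centre."""
        if not self.contains(idx):
            raise ConsistencyError(f"voxel index {tuple(idx)} outside grid {self.shape}")
        return tuple((i + 0.5) * self.spacing for i in idx)

    def locate(self, position):
        """Inverse of :meth:`voxel_center` (nearest-voxel for interior points)."""
        idx = tuple(int(p // self.spacing) for p in position)
        if not self.contains(idx):
            raise ConsistencyError(f"position {position} outside grid")
        return idx

    def neighbors26(self, idx):
        """In-grid Moore neighbours of a voxel, in deterministic offset order."""
        out = []
        x, y, z = idx
        nx, ny, nz = self.shape
        for dx, dy, dz in NEIGHBOR_OFFSETS:
            p = (x + dx, y + dy, z + dz)
            if 0 <= p[0] < nx and 0 <= p[1] < ny and 0 <= p[2] < nz:
                out.append(p)
        return out

    def zeros(self) -> np.ndarray:
        return np.zeros(self.shape, dtype=float)


def make_grid(config: SimulationConfig | GridConfig) -> Grid3D:
    gc = config.grid if isinstance(config, SimulationConfig) else config
    problems: list = []
    gc.validate("grid", problems)
    if problems:
        raise ConfigurationError(problems)
    return Grid3D(shape=tuple(gc.shape), spacing=float(gc.spacing),
                  boundary=gc.boundary, fixed_value=float(gc.fixed_value))


@dataclass
class ScalarField:
    """One diffusible species on the lattice."""

    species: str
    values: np.ndarray
    params: DiffusionParams

    @classmethod
    def uniform(cls, species: str, grid: Grid3D, params: DiffusionParams,
                value: float | None = None) -> "ScalarField":
        v = params.initial if value is None else value
        return cls(species, np.full(grid.shape, float(v)), params)


@dataclass
class IndicatorField:
    """0/1 voxel-occupancy mask (chi_ves, chi_tum or chi_tipEC)."""

    kind: str
    mask: np.ndarray


@dataclass
class Indicators:
    chi_ves: np.ndarray
    chi_tum: np.ndarray
    chi_tipEC: np.ndarray
    #: per-voxel TAF secretion weights (chi_tum scaled up where starved)
    taf_secretion: np.ndarray | None = None


def rebuild_indicators(cells, network, grid: Grid3D) -> Indicators:
    """Voxelise living tumor cells, the vessel network and active tips.

    Apoptotic tumor cells and inactive (apoptotic) tip ECs are excluded.
    """
    chi_tum = np.zeros(grid.shape, dtype=np.uint8)
    chi_ves = np.zeros(grid.shape, dtype=np.uint8)
    chi_tip = np.zeros(grid.shape, dtype=np.uint8)
    for cell in cells:
        if cell.phenotype == "apoptotic":
            continue
        if not grid.contains(cell.position):
            raise ConsistencyError(f"tumor cell at {cell.position} outside grid {grid.shape}")
        chi_tum[cell.position] = 1
    if network is not None:
        for vox in network.vessel_voxels():
            if not grid.contains(vox):
                raise ConsistencyError(f"vessel voxel {vox} outside grid {grid.shape}")
            chi_ves[vox] = 1
        for tip in network.tips:
            if not tip.active:
                continue
            if not grid.contains(tip.position):
                raise ConsistencyError(f"tip EC at {tip.position} outside grid {grid.shape}")
            chi_tip[tip.position] = 1
    return Indicators(chi_ves=chi_ves, chi_tum=chi_tum, chi_tipEC=chi_tip)


# ---------------------------------------------------------------------------
# numerics
# ---------------------------------------------------------------------------

def laplacian(values: np.ndarray, grid: Grid3D) -> np.ndarray:
    """7-point central Laplacian with the grid's boundary condition.

    No-flux is realised by edge padding (ghost voxel = boundary voxel),
    fixed-value by constant padding.
    """
    if grid.boundary == "no-flux":
        p = np.pad(values, 1, mode="edge")
    else:
        p = np.pad(values, 1, mode="constant", constant_values=grid.fixed_value)
    out = (p[:-2, 1:-1, 1:-1] + p[2:, 1:-1, 1:-1]
           + p[1:-1, :-2, 1:-1] + p[1:-1, 2:, 1:-1]
           + p[1:-1, 1:-1, :-2] + p[1:-1, 1:-1, 2:]
           - 6.0 * values)
    return out / grid.spacing ** 2


def stable_dt(params: DiffusionParams, grid: Grid3D) -> float:
    """Largest admissible explicit time step for one species (with safety 0.9)."""
    bound = np.inf
    if params.D > 0:
        bound = min(bound, grid.spacing ** 2 / (6.0 * params.D))
    rate = params.q + params.delta
    if rate > 0:
        bound = min(bound, 1.0 / rate)
    return _STABILITY_SAFETY * bound


def _check_dt(field: ScalarField, grid: Grid3D, dt: float) -> None:
    limit = stable_dt(field.params, grid) / _STABILITY_SAFETY
    if dt > limit * (1 + 1e-12):
        raise NumericalError(
            f"field step dt={dt:g} h violates the stability bound for "
            f"'{field.species}'; maximum admissible dt is {limit:g} h")


def _finish(field: ScalarField, values: np.ndarray) -> ScalarField:
    if not np.all(np.isfinite(values)):
        raise NumericalError(f"non-finite values in field '{field.species}' after step")
    np.clip(values, 0.0, None, out=values)
    field.values = values
    return field


def step_drug_field(field: ScalarField, indicators: Indicators, grid: Grid3D,
                    dt: float, in_blood: float | None = None) -> ScalarField:
    """One explicit step of an inhibitor field.

    Vessel voxels exchange with blood at rate q towards the in-blood level
    H; the uptake sink acts on tumor-cell voxels for the EGFR inhibitor
    and on active-tip voxels for the VEGFR inhibitor.
    """
    _check_dt(field, grid, dt)
    p = field.params
    H = p.H if in_blood is None else float(in_blood)
    c = field.values
    c = c + dt * p.D * laplacian(c, grid)
    ves = indicators.chi_ves.astype(float)
    c = c + dt * p.q * ves * (H - c)
    sink_mask = indicators.chi_tipEC if field.species == "vegfri" else indicators.chi_tum
    c = c - np.minimum(p.u * dt * sink_mask.astype(float), np.clip(c, 0.0, None))
    c = c - dt * p.delta * c
    return _finish(field, c)


def step_nutrient_field(field: ScalarField, indicators: Indicators, grid: Grid3D,
                        dt: float) -> ScalarField:
    """Glucose / oxygen / TGFa: vessel source, tumor-cell uptake, diffusion, decay."""
    _check_dt(field, grid, dt)
    p = field.params
    c = field.values
    c = c + dt * p.D * laplacian(c, grid)
    c = c + dt * p.q * indicators.chi_ves.astype(float) * (p.H - c)
    c = c - np.minimum(p.u * dt * indicators.chi_tum.astype(float), np.clip(c, 0.0, None))
    c = c - dt * p.delta * c
    return _finish(field, c)


def step_taf_field(field: ScalarField, indicators: Indicators, grid: Grid3D,
                   dt: float, consumed_by_tips: bool = True) -> ScalarField:
    """Angiogenic factor: secreted by tumor cells, optionally consumed by tips.

    ``indicators.taf_secretion`` (when set) carries per-voxel secretion
    weights so nutrient-starved cells can secrete more; otherwise every
    living tumor cell secretes at the base rate.
    """
    _check_dt(field, grid, dt)
    p = field.params
    c = field.values
    c = c + dt * p.D * laplacian(c, grid)
    weights = indicators.taf_secretion
    if weights is None:
        weights = indicators.chi_tum.astype(float)
    c = c + dt * p.secretion * weights
    if consumed_by_tips:
        c = c - np.minimum(p.u * dt * indicators.chi_tipEC.astype(float),
                           np.clip(c, 0.0, None))
    c = c - dt * p.delta * c
    return _finish(field, c)


def step_fibronectin_field(field: ScalarField, indicators: Indicators, grid: Grid3D,
                           dt: float) -> ScalarField:
    """Matrix fibronectin: deposited near vessels (saturating at 1), degraded
    by migrating tips, non-diffusing unless a diffusivity is configured."""
    _check_dt(field, grid, dt)
    p = field.params
    c = field.values
    if p.D > 0:
        c = c + dt * p.D * laplacian(c, grid)
    c = c + dt * p.secretion * indicators.chi_ves.astype(float) * np.clip(1.0 - c, 0.0, None)
    c = c - np.minimum(p.u * dt * indicators.chi_tipEC.astype(float), np.clip(c, 0.0, None))
    c = c - dt * p.delta * c
    return _finish(field, c)


STEPPERS = {
    "glucose": step_nutrient_field,
    "oxygen": step_nutrient_field,
    "tgfa": step_nutrient_field,
    "taf": step_taf_field,
    "fibronectin": step_fibronectin_field,
    "egfri": step_drug_field,
    "vegfri": step_drug_field,
}
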