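"""Sprouting angiogenesis on the lattice.

A parent vessel lies on the bottom face (z = 0) of the grid.  Tip
endothelial cells (ECs) sprout from it and migrate voxel-to-voxel up the
angiogenic-factor (TAF) gradient, with a haptotactic contribution from
matrix fibronectin; the trail behind a tip becomes permanent vessel
segments (the model has no pruning, so the segment set only grows).
Eligible tips may branch into a new sprout.

Under VEGFR-inhibitor exposure each active tip's *effective* (unbound)
VEGFR is computed from the drug concentration in its own voxel.  A tip
whose effective VEGFR falls strictly below the average over all active
tips -- the average taken once, before any deactivation that step --
enters an irreversible apoptotic state and never migrates or branches
again.  Ties survive, so a uniform drug field is a fixed point and a
drug-free network never loses tips.

Self-avoidance: a tip may not step onto its own trail or the parent
vessel; stepping onto another sprout's voxel is anastomosis, which ends
that tip's migration but leaves it alive as a connected loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import VasculatureConfig
from .errors import ConsistencyError
from .grid import Grid3D
from .signaling import BindingParams, effective_vegfr


@dataclass
class TipEC:
    position: tuple
    sprout_id: int
    active: bool = True
    age: float = 0.0
    effective_vegfr: float = 0.0
    anastomosed: bool = False
    born_at: float = 0.0


@dataclass
class VesselSegment:
    a: tuple
    b: tuple
    sprout_id: int
    created_at: float = 0.0

    def __post_init__(self):
        if max(abs(i - j) for i, j in zip(self.a, self.b)) != 1:
            raise ConsistencyError(
                f"segment endpoints {self.a}-{self.b} are not lattice-adjacent")


@dataclass
class VesselNetwork:
    parent_voxels: list = field(default_factory=list)
    segments: list = field(default_factory=list)
    tips: list = field(default_factory=list)
    #: voxel -> sprout id that first claimed it (segment endpoints only)
    voxel_owner: dict = field(default_factory=dict)
    #: per-sprout trail voxels, for self-avoidance
    sprout_voxels: dict = field(default_factory=dict)
    _next_sprout_id: int = 0

    def vessel_voxels(self):
        """All voxels carrying vasculature: parent vessel plus every sprout."""
        seen = set(self.parent_voxels)
        seen.update(self.voxel_owner)
        return seen

    def new_sprout_id(self) -> int:
        sid = self._next_sprout_id
        self._next_sprout_id += 1
        return sid

    def active_tips(self):
        return [t for t in self.tips if t.active]


def initialize_network(grid: Grid3D, params: VasculatureConfig,
                       rng: np.random.Generator | None = None) -> VesselNetwork:
    """Parent vessel lines (or a full plane) on z=0 with evenly spaced tips."""
    nx, ny, _ = grid.shape
    net = VesselNetwork()
    if params.parent_layout == "plane":
        net.parent_voxels = [(x, y, 0) for x in range(nx) for y in range(ny)]
    else:
        k = params.n_parent_lines
        ys = [int(round((j + 1) * ny / (k + 1))) for j in range(k)]
        net.parent_voxels = [(x, y, 0) for y in ys for x in range(nx)]
    if params.n_initial_tips > 0 and net.parent_voxels:
        idx = np.linspace(0, len(net.parent_voxels) - 1,
                          params.n_initial_tips).round().astype(int)
        for i in idx:
            pos = net.parent_voxels[int(i)]
            sid = net.new_sprout_id()
            net.tips.append(TipEC(position=pos, sprout_id=sid))
            net.sprout_voxels[sid] = {pos}
    return net


def migrate_tip(tip: TipEC, taf_field: np.ndarray, fib_field: np.ndarray,
                network: VesselNetwork, grid: Grid3D, rng: np.random.Generator,
                params: VasculatureConfig, time_h: float = 0.0) -> tuple:
    """One chemotaxis/haptotaxis step of an active tip.

    The move kernel weights each admissible neighbour n by
    ``exp(w_chemo * (TAF[n]-TAF[here]) + w_hapto * (FIB[n]-FIB[here]))``;
    chemotaxis and haptotaxis therefore combine multiplicatively.  A
    segment is appended from the old to the new position.  Fully blocked
    (or inactive/anastomosed) tips stay put.
    """
    if not tip.active or tip.anastomosed:
        return tip.position
    here = tip.position
    own = network.sprout_voxels.setdefault(tip.sprout_id, {here})
    parent = set(network.parent_voxels)
    candidates = [n for n in grid.neighbors26(here)
                  if n not in own and n not in parent]
    if not candidates:
        return here
    dtaf = np.array([taf_field[n] - taf_field[here] for n in candidates])
    dfib = np.array([fib_field[n] - fib_field[here] for n in candidates])
    logw = params.w_chemo * dtaf + params.w_hapto * dfib
    logw -= logw.max()  # overflow guard; shifts cancel in the normalisation
    w = np.exp(logw)
    new_pos = candidates[int(rng.choice(len(candidates), p=w / w.sum()))]
    network.segments.append(VesselSegment(here, new_pos, tip.sprout_id, time_h))
    if new_pos in network.voxel_owner:
        tip.anastomosed = True  # merged into another sprout; stays alive
    else:
        network.voxel_owner[new_pos] = tip.sprout_id
    own.add(new_pos)
    tip.position = new_pos
    return new_pos


def branch_sprout(tip: TipEC, taf_field: np.ndarray, network: VesselNetwork,
                  grid: Grid3D, rng: np.random.Generator,
                  params: VasculatureConfig, time_h: float = 0.0) -> TipEC | None:
    """Possibly spawn a new sprout from an eligible tip.

    Requires the tip to be active, old enough, and in sufficient TAF;
    then branches with the configured probability into a free neighbour.
    """
    if not tip.active or tip.anastomosed:
        return None
    if tip.age < params.min_branch_age:
        return None
    if taf_field[tip.position] < params.branch_taf_threshold:
        return None
    if len(network.active_tips()) >= params.max_tips:
        return None
    if rng.random() >= params.branch_prob:
        return None
    taken = network.vessel_voxels()
    frees = [n for n in grid.neighbors26(tip.position) if n not in taken]
    if not frees:
        return None
    pos = frees[int(rng.integers(len(frees)))]
    sid = network.new_sprout_id()
    network.segments.append(VesselSegment(tip.position, pos, sid, time_h))
    network.voxel_owner[pos] = sid
    network.sprout_voxels[sid] = {tip.position, pos}
    child = TipEC(position=pos, sprout_id=sid, born_at=time_h)
    network.tips.append(child)
    return child


def check_ec_survival(tips, vegfri_field: np.ndarray,
                      binding: BindingParams) -> list:
    """Apply the tip-EC fate rule; returns the tips deactivated this step.

    Effective VEGFR is evaluated per active tip from the drug level in its
    voxel; the population mean is computed once over the currently active
    tips, and only tips *strictly* below the mean die.
    """
    active = [t for t in tips if t.active]
    if not active:
        return []
    effs = np.array([
        effective_vegfr(binding.r0, float(vegfri_field[t.position]), binding.km)
        for t in active])
    for t, e in zip(active, effs):
        t.effective_vegfr = float(e)
    mean = float(effs.mean())
    killed = []
    for t, e in zip(active, effs):
        if e < mean:
            t.active = False
            killed.append(t)
    return killed


def vessel_census(network: VesselNetwork):
    """(ec_count, segment_count): active tips plus one stalk EC per segment."""
    return len(network.active_tips()) + len(network.segments), len(network.segments)
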