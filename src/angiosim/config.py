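"""Simulation configuration: typed parameter blocks, YAML round-trip, fixtures.

Every tunable of the simulator lives here as a dataclass field with a
documented default.  The defaults constitute the *canonical scaled-down
configuration*: a 20x20x20 lattice (40 um voxels, 800 um cube) run for
450 h that reproduces the qualitative treatment dynamics of a full-size
vascular tumor at desk scale.  All kinetic and transport values are
calibrated model units (concentrations normalised to an O(1) tissue
level), not literature measurements; see docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import difflib
from dataclasses import dataclass, field, fields as dc_fields
from typing import Optional

import yaml

from .errors import ConfigurationError

SPECIES = ("glucose", "oxygen", "tgfa", "taf", "fibronectin", "egfri", "vegfri")
DRUGS = ("egfri", "vegfri")
NUTRIENTS = ("glucose", "oxygen", "tgfa")


# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------

@dataclass
class GridConfig:
    """Lattice geometry.  ``spacing`` is the voxel edge in micrometres."""

    shape: tuple = (20, 20, 20)
    spacing: float = 40.0
    boundary: str = "no-flux"          # "no-flux" | "fixed-value"
    fixed_value: float = 0.0           # boundary concentration when fixed-value

    def validate(self, path: str, problems: list) -> None:
        shape = tuple(self.shape)
        if len(shape) != 3 or any(int(n) != n for n in shape):
            problems.append(f"{path}.shape: must be an integer triple, got {self.shape!r}")
            return
        self.shape = tuple(int(n) for n in shape)
        if any(n < 3 for n in self.shape):
            problems.append(f"{path}.shape: every dimension must be >= 3, got {self.shape}")
        if self.spacing <= 0:
            problems.append(f"{path}.spacing: must be > 0, got {self.spacing}")
        if self.boundary not in ("no-flux", "fixed-value"):
            problems.append(f"{path}.boundary: must be 'no-flux' or 'fixed-value', got {self.boundary!r}")


@dataclass
class DiffusionParams:
    """Transport/reaction coefficients of one diffusible species.

    D      diffusivity (um^2/h)
    q      trans-vessel exchange rate (1/h), active on vessel voxels
    H      in-blood concentration the vessel exchange relaxes towards
    u      per-agent uptake rate (concentration/h) on occupied voxels
    delta  first-order decay rate (1/h)
    secretion  per-agent release rate (concentration/h) on source voxels
    initial    uniform initial concentration
    """

    D: float = 0.0
    q: float = 0.0
    H: float = 0.0
    u: float = 0.0
    delta: float = 0.0
    secretion: float = 0.0
    initial: float = 0.0

    def validate(self, path: str, problems: list) -> None:
        for name in ("D", "q", "H", "u", "delta", "secretion", "initial"):
            v = getattr(self, name)
            if v < 0:
                problems.append(f"{path}.{name}: must be >= 0, got {v}")


@dataclass
class BindingConfig:
    """Quasi-equilibrium inhibitor-receptor binding constants (Hill form)."""

    km_egfri: float = 0.2      # Michaelis constant of EGFRI:EGFR binding
    km_vegfri: float = 0.2     # Michaelis constant of VEGFRI:VEGFR binding
    egfr_total: float = 1.0    # total EGFR per tumor cell, normalised
    vegfr_total: float = 1.0   # total VEGFR per tip EC, normalised

    def validate(self, path: str, problems: list) -> None:
        if self.km_egfri <= 0:
            problems.append(f"{path}.km_egfri: must be > 0, got {self.km_egfri}")
        if self.km_vegfri <= 0:
            problems.append(f"{path}.km_vegfri: must be > 0, got {self.km_vegfri}")
        for name in ("egfr_total", "vegfr_total"):
            if getattr(self, name) < 0:
                problems.append(f"{path}.{name}: must be >= 0, got {getattr(self, name)}")


@dataclass
class EGFRPathwayParams:
    """Calibrated EGFR cascade: receptor signal -> PLCgamma oscillator -> growth.

    The receptor signal x relaxes towards (k_act/d_act) * ligand * EGFR_eff.
    PLCgamma follows an activator-depletion oscillator driven by x: below
    the drive threshold x = 1 + osc_a^2 it settles to a quiet fixed point,
    above it PLCgamma cycles with amplitude growing in the drive, emulating
    the Ca2+/PLCgamma oscillations that underlie migratory signalling.  A
    drug-suppressed receptor therefore yields a flat PLCgamma trace and a
    low migration potential.
    """

    k_act: float = 0.8       # receptor-signal activation per (ligand x eff. receptor)
    d_act: float = 0.1       # receptor-signal decay (1/h)
    osc_a: float = 0.5       # basal PLCgamma production of the oscillator
    osc_rate: float = 0.3    # oscillator timescale (1/h)
    osc_bmax: float = 3.0    # saturating ceiling of the oscillator drive
    osc_xhalf: float = 1.5   # receptor signal at half-maximal drive
    k_growth: float = 0.2    # growth-signal production per unit receptor signal
    d_growth: float = 0.1    # growth-signal decay (1/h)

    def validate(self, path: str, problems: list) -> None:
        for f in dc_fields(self):
            if getattr(self, f.name) < 0:
                problems.append(f"{path}.{f.name}: must be >= 0, got {getattr(self, f.name)}")


@dataclass
class CellCycleParams:
    """Two-variable cycle: cyclin pool driven by the growth signal feeds a
    progression variable; crossing ``division_threshold`` arms division."""

    k_cyclin: float = 0.2
    d_cyclin: float = 0.1
    k_progress: float = 0.08
    division_threshold: float = 1.0
    growth_half: float = 0.5     # half-saturation of pathway growth signal
    growth_hill: float = 1.0     # Hill exponent of the growth-signal response
    glucose_half: float = 0.3    # half-saturation of the nutrient gate
    glucose_hill: float = 3.0    # Hill exponent: cycling shuts off sharply
                                 # below quiescence-level glucose

    def validate(self, path: str, problems: list) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if v < 0:
                problems.append(f"{path}.{f.name}: must be >= 0, got {v}")
        if self.division_threshold <= 0:
            problems.append(f"{path}.division_threshold: must be > 0")


@dataclass
class PhenotypeRulesConfig:
    """Thresholds of the rule-based phenotype switch."""

    glucose_quiescence_threshold: float = 0.3
    glucose_death_threshold: float = 0.12
    oxygen_death_threshold: float = 0.02
    #: optional chronic-starvation channel: below the quiescence threshold a
    #: cell accrues hunger at rate (1 - glucose/threshold) per hour and dies
    #: when the integral exceeds this tolerance; recovery resets it.  None
    #: disables the channel (acute starvation below the death threshold is
    #: then the only death route, as in the canonical configuration).
    starvation_tolerance_h: Optional[float] = None
    plcg_rate_migration_threshold: float = 0.04   # concentration/h
    #: exponent on the TGFa attraction score for active-cell moves; >1
    #: sharpens the drift towards vasculature
    migration_attraction_exponent: float = 8.0
    #: optionally restrict daughter placement to voxels with at least this
    #: much glucose (growth then saturates at the supplied niche instead of
    #: spilling newborns into starving voxels)
    daughter_needs_nutrient: bool = False
    daughter_nutrient_min: float = 0.45
    death_sustained_steps: int = 2    # consecutive starved updates before apoptosis
    crowding_rule: str = "26-neighborhood"

    def validate(self, path: str, problems: list) -> None:
        if self.glucose_death_threshold > self.glucose_quiescence_threshold:
            problems.append(
                f"{path}: glucose_death_threshold ({self.glucose_death_threshold}) must be "
                f"<= glucose_quiescence_threshold ({self.glucose_quiescence_threshold})")
        for name in ("glucose_quiescence_threshold", "glucose_death_threshold",
                     "oxygen_death_threshold", "plcg_rate_migration_threshold"):
            if getattr(self, name) < 0:
                problems.append(f"{path}.{name}: must be >= 0")
        if self.death_sustained_steps < 1:
            problems.append(f"{path}.death_sustained_steps: must be >= 1")
        if self.crowding_rule != "26-neighborhood":
            problems.append(f"{path}.crowding_rule: only '26-neighborhood' is supported")


@dataclass
class VasculatureConfig:
    """Parent-vessel layout and sprouting/migration parameters of tip ECs."""

    parent_layout: str = "lines"   # "lines" (bottom-face vessel lines) | "plane"
    n_parent_lines: int = 1
    n_initial_tips: int = 5
    tip_move_prob: float = 0.045   # per-hour probability a tip attempts a step
    w_chemo: float = 30.0          # chemotaxis weight on the TAF difference
    w_hapto: float = 2.0           # haptotaxis weight on the fibronectin difference
    branch_prob: float = 0.06      # per-hour branching probability when eligible
    branch_taf_threshold: float = 0.02
    min_branch_age: float = 30.0   # h a tip must exist before it may branch
    max_tips: int = 25             # agent cap keeping desk-scale runs bounded

    def validate(self, path: str, problems: list) -> None:
        if self.parent_layout not in ("lines", "plane"):
            problems.append(f"{path}.parent_layout: must be 'lines' or 'plane'")
        if self.n_parent_lines < 1:
            problems.append(f"{path}.n_parent_lines: must be >= 1")
        if self.n_initial_tips < 0:
            problems.append(f"{path}.n_initial_tips: must be >= 0")
        for name in ("tip_move_prob", "branch_prob"):
            if not 0 <= getattr(self, name) <= 1:
                problems.append(f"{path}.{name}: must be in [0, 1]")
        for name in ("w_chemo", "w_hapto", "branch_taf_threshold", "min_branch_age"):
            if getattr(self, name) < 0:
                problems.append(f"{path}.{name}: must be >= 0")
        if self.max_tips < 1:
            problems.append(f"{path}.max_tips: must be >= 1")


@dataclass
class TumorConfig:
    """Initial tumor seed and TAF secretion behaviour."""

    n_initial_cells: int = 7          # 7 = centre voxel plus its six face neighbours
    center: Optional[tuple] = None    # voxel index; None -> (nx//2, ny//2, round(0.7*nz))
    taf_starvation_multiplier: float = 2.0  # secretion boost below the quiescence threshold
    starvation_taf_enabled: bool = True

    def validate(self, path: str, problems: list) -> None:
        if self.n_initial_cells < 0:
            problems.append(f"{path}.n_initial_cells: must be >= 0")
        if self.center is not None:
            c = tuple(self.center)
            if len(c) != 3:
                problems.append(f"{path}.center: must be an index triple")
            else:
                self.center = tuple(int(v) for v in c)
        if self.taf_starvation_multiplier < 0:
            problems.append(f"{path}.taf_starvation_multiplier: must be >= 0")


@dataclass
class DrugScheduleConfig:
    """One drug arm: onset time and constant in-blood level while on.

    ``start_time is None`` means the drug is never given; its field then
    stays identically zero for the whole run.
    """

    start_time: Optional[float] = None
    in_blood_concentration: float = 1.0

    def validate(self, path: str, problems: list) -> None:
        if self.start_time is not None and self.start_time < 0:
            problems.append(f"{path}.start_time: must be >= 0 or null, got {self.start_time}")
        if self.in_blood_concentration < 0:
            problems.append(f"{path}.in_blood_concentration: must be >= 0")


@dataclass
class SimulationSettings:
    t_end: float = 450.0
    cell_update_interval: float = 1.0   # h between agent/ODE updates
    field_substeps: Optional[int] = None  # None -> derived from the stability bound
    seed: int = 0
    survival_definition: str = "cumulative"  # living/(living+dead) | "peak": living/max(living)
    taf_consumed_by_tips: bool = True
    record_interval: float = 1.0        # h between census rows

    def validate(self, path: str, problems: list) -> None:
        if self.t_end < 0:
            problems.append(f"{path}.t_end: must be >= 0")
        if self.cell_update_interval <= 0:
            problems.append(f"{path}.cell_update_interval: must be > 0")
        if self.field_substeps is not None and self.field_substeps < 1:
            problems.append(f"{path}.field_substeps: must be >= 1 or null")
        if self.survival_definition not in ("cumulative", "peak"):
            problems.append(f"{path}.survival_definition: must be 'cumulative' or 'peak'")
        if self.record_interval <= 0:
            problems.append(f"{path}.record_interval: must be > 0")


def _default_fields() -> dict:
    """Calibrated transport defaults for the canonical configuration."""
    return {
        "glucose": DiffusionParams(D=1000.0, q=2.0, H=1.0, u=0.2, delta=0.002, initial=1.0),
        "oxygen": DiffusionParams(D=2000.0, q=2.0, H=1.0, u=0.02, delta=0.002, initial=1.0),
        "tgfa": DiffusionParams(D=1500.0, q=1.0, H=1.0, u=0.001, delta=0.05, initial=0.2),
        "taf": DiffusionParams(D=2000.0, u=0.05, delta=0.010, secretion=0.05),
        "fibronectin": DiffusionParams(u=0.05, secretion=0.01, initial=0.1),
        "egfri": DiffusionParams(D=2000.0, q=2.0, u=0.001, delta=0.005),
        "vegfri": DiffusionParams(D=2000.0, q=2.0, u=0.002, delta=0.005),
    }


def _default_drugs() -> dict:
    return {"egfri": DrugScheduleConfig(), "vegfri": DrugScheduleConfig()}


@dataclass
class SimulationConfig:
    """Complete, validated description of one simulation run."""

    grid: GridConfig = field(default_factory=GridConfig)
    fields: dict = field(default_factory=_default_fields)
    binding: BindingConfig = field(default_factory=BindingConfig)
    egfr_pathway: EGFRPathwayParams = field(default_factory=EGFRPathwayParams)
    cell_cycle: CellCycleParams = field(default_factory=CellCycleParams)
    phenotype: PhenotypeRulesConfig = field(default_factory=PhenotypeRulesConfig)
    vasculature: VasculatureConfig = field(default_factory=VasculatureConfig)
    tumor: TumorConfig = field(default_factory=TumorConfig)
    drugs: dict = field(default_factory=_default_drugs)
    simulation: SimulationSettings = field(default_factory=SimulationSettings)

    # -- validation ---------------------------------------------------------

    def validate(self) -> "SimulationConfig":
        problems: list = []
        self.grid.validate("grid", problems)
        for name in SPECIES:
            if name not in self.fields:
                problems.append(f"fields.{name}: missing species block")
        for name, params in self.fields.items():
            if name not in SPECIES:
                problems.append(
                    f"fields.{name}: unknown species" + _suggest(name, SPECIES))
            else:
                params.validate(f"fields.{name}", problems)
        self.binding.validate("binding", problems)
        self.egfr_pathway.validate("egfr_pathway", problems)
        self.cell_cycle.validate("cell_cycle", problems)
        self.phenotype.validate("phenotype", problems)
        self.vasculature.validate("vasculature", problems)
        self.tumor.validate("tumor", problems)
        for name, sched in self.drugs.items():
            if name not in DRUGS:
                problems.append(f"drugs.{name}: unknown drug" + _suggest(name, DRUGS))
            else:
                sched.validate(f"drugs.{name}", problems)
        for name in DRUGS:
            if name not in self.drugs:
                problems.append(f"drugs.{name}: missing schedule block")
        self.simulation.validate("simulation", problems)
        if not problems and self.tumor.center is not None:
            nx, ny, nz = self.grid.shape
            cx, cy, cz = self.tumor.center
            if not (0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz):
                problems.append(f"tumor.center: {self.tumor.center} outside grid {self.grid.shape}")
        if problems:
            raise ConfigurationError(problems)
        return self

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return _to_plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, data: Optional[dict]) -> "SimulationConfig":
        data = dict(data or {})
        problems: list = []
        cfg = cls()
        top_known = [f.name for f in dc_fields(cls)]
        for key in list(data):
            if key not in top_known:
                problems.append(f"{key}: unknown key" + _suggest(key, top_known))
                data.pop(key)
        for f in dc_fields(cls):
            if f.name not in data:
                continue
            block = data[f.name]
            if f.name == "fields":
                out = dict(_default_fields())
                _merge_block_map(out, block, "fields", DiffusionParams, SPECIES, problems)
                cfg.fields = out
            elif f.name == "drugs":
                out = dict(_default_drugs())
                _merge_block_map(out, block, "drugs", DrugScheduleConfig, DRUGS, problems)
                cfg.drugs = out
            else:
                setattr(cfg, f.name,
                        _dataclass_from(type(getattr(cfg, f.name)), block, f.name, problems))
        if problems:
            raise ConfigurationError(problems)
        return cfg.validate()

    def copy(self) -> "SimulationConfig":
        return SimulationConfig.from_dict(self.to_dict())

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data is not None and not isinstance(data, dict):
            raise ConfigurationError([f"{path}: top level must be a mapping"])
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _suggest(key: str, known) -> str:
    close = difflib.get_close_matches(str(key), list(known), n=1)
    return f" (did you mean '{close[0]}'?)" if close else ""


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, list):
        return [_to_plain(v) for v in obj]
    return obj


def _dataclass_from(cls, data, path, problems):
    if data is None:
        return cls()
    if not isinstance(data, dict):
        problems.append(f"{path}: expected a mapping, got {type(data).__name__}")
        return cls()
    known = [f.name for f in dc_fields(cls)]
    obj = cls()
    for key, value in data.items():
        if key not in known:
            problems.append(f"{path}.{key}: unknown key" + _suggest(key, known))
            continue
        default = getattr(obj, key)
        if isinstance(value, list) and isinstance(default, (tuple, type(None))) and key in ("shape", "center"):
            value = tuple(value)
        expected = type(default)
        if default is not None and not isinstance(value, expected):
            # ints promote to floats; bools are not numbers
            if expected is float and isinstance(value, int) and not isinstance(value, bool):
                value = float(value)
            elif expected is int and isinstance(value, float) and value.is_integer():
                value = int(value)
            elif expected is tuple and isinstance(value, list):
                value = tuple(value)
            elif not (expected is bool and isinstance(value, bool)):
                problems.append(
                    f"{path}.{key}: expected {expected.__name__}, got {type(value).__name__} ({value!r})")
                continue
        setattr(obj, key, value)
    return obj


def _merge_block_map(out, block, path, cls, known, problems):
    if block is None:
        return
    if not isinstance(block, dict):
        problems.append(f"{path}: expected a mapping")
        return
    for name, sub in block.items():
        if name not in known:
            problems.append(f"{path}.{name}: unknown key" + _suggest(name, known))
            continue
        merged = dataclasses.asdict(out[name])
        if sub is not None:
            if not isinstance(sub, dict):
                problems.append(f"{path}.{name}: expected a mapping")
                continue
            bad = [k for k in sub if k not in merged]
            for k in bad:
                problems.append(f"{path}.{name}.{k}: unknown key" + _suggest(k, merged))
            merged.update({k: v for k, v in sub.items() if k not in bad})
        out[name] = _dataclass_from(cls, merged, f"{path}.{name}", problems)


# ---------------------------------------------------------------------------
# canonical and fixture configurations
# ---------------------------------------------------------------------------

def canonical_config(seed: int = 0) -> SimulationConfig:
    """The calibrated scaled-down reference configuration (no treatment).

    20^3 lattice, 450 h horizon.  Treatment arms are derived from it by
    setting ``drugs.egfri.start_time`` / ``drugs.vegfri.start_time``.
    """
    cfg = SimulationConfig()
    cfg.simulation.seed = int(seed)
    return cfg.validate()


def egfri_arm(cfg: SimulationConfig, start: float = 0.0) -> SimulationConfig:
    out = cfg.copy()
    out.drugs["egfri"].start_time = float(start)
    return out


def combo_arm(cfg: SimulationConfig, egfri_start: float = 0.0,
              vegfri_start: float = 240.0) -> SimulationConfig:
    out = cfg.copy()
    out.drugs["egfri"].start_time = float(egfri_start)
    out.drugs["vegfri"].start_time = float(vegfri_start)
    return out


def fixture_configs() -> dict:
    """Small named configurations used by the test-suite, each sub-minute.

    tiny-notx    no treatment, 12^3 grid, 72 h horizon
    tiny-egfri   as tiny-notx but EGFRI on from t=0
    tiny-combo-240h-equivalent
                 as tiny-egfri plus VEGFRI at the horizon-scaled onset
                 (240/450 of the 72 h horizon)
    slab-1d      3x3x40 column with a single vessel plane at z=0 and no
                 tumor; the geometry of the analytic boundary-layer oracle
    """
    tiny = SimulationConfig()
    tiny.grid = GridConfig(shape=(12, 12, 12), spacing=40.0)
    tiny.simulation.t_end = 72.0
    tiny.vasculature.n_initial_tips = 3
    tiny.tumor.center = (6, 6, 8)
    tiny.validate()

    tiny_egfri = tiny.copy()
    tiny_egfri.drugs["egfri"].start_time = 0.0
    tiny_egfri.validate()

    tiny_combo = tiny_egfri.copy()
    tiny_combo.drugs["vegfri"].start_time = round(240.0 / 450.0 * 72.0, 1)
    tiny_combo.validate()

    slab = SimulationConfig()
    slab.grid = GridConfig(shape=(3, 3, 40), spacing=20.0)
    slab.vasculature.parent_layout = "plane"
    slab.vasculature.n_initial_tips = 0
    slab.tumor.n_initial_cells = 0
    slab.simulation.t_end = 50.0
    slab.validate()

    return {
        "tiny-notx": tiny,
        "tiny-egfri": tiny_egfri,
        "tiny-combo-240h-equivalent": tiny_combo,
        "slab-1d": slab,
    }
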