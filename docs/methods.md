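# Model and methods

`angiosim` simulates vascular brain-tumor growth under receptor-targeted
therapy as a single-cell lattice model coupling four scales. This note
documents the model, its assumptions, the calibrated defaults, the
numerical choices, and what the scaled-down test configuration can and
cannot show.

## Overview

A tumor spheroid sits in a 3-D tissue cube discretised into cubic voxels
(default 20×20×20 at 40 µm). A parent blood vessel runs along the bottom
face with a few tip endothelial cells (ECs). Per 1 h update the engine
advances, in fixed order:

1. **Microenvironment.** Seven diffusible species — glucose, oxygen,
   TGFα, TAF (VEGF-like angiogenic factor), fibronectin, and the two
   inhibitors (EGFRI, VEGFRI) — obey reaction–diffusion equations of the
   form ∂c/∂t = D∆c + χ_ves·q(H−c) − χ_sink·u − δc, where the χ masks
   are rebuilt from agent positions every step. Vessels act as sources
   relaxing the local concentration toward the in-blood level H; tumor
   cells (or tip ECs, for the VEGFR inhibitor and TAF) are point sinks;
   tumor cells are the TAF source, secreting at a higher rate when
   nutrient-starved.
2. **Molecular.** Per living tumor cell, the *effective* (unbound) EGFR
   is computed from the local inhibitor level by quasi-equilibrium
   binding, `R_eff = R0 − R0·I/(km+I)`, and clamped into an intracellular
   ODE system (below); a two-variable cell-cycle clock integrates a
   growth signal into division readiness.
3. **Cellular.** Each living cell, in randomised order, is reassigned a
   phenotype by strict precedence — apoptotic (starvation), active
   (migration-competent), proliferative, quiescent — and acts on it.
4. **Tissue.** Tip ECs are subjected to the VEGFR survival rule, then
   migrate chemotactically/haptotactically and may branch; their trails
   become permanent vessel segments (no pruning or flow model).

All randomness flows from one master seed through named substreams
(cells / tips / placement), so a configuration plus seed reproduces every
output byte.

## Intracellular signalling

The EGFR cascade per tumor cell is

    receptor signal:  dx/dt = k_act·L·R_eff − d_act·x
    PLCγ:             dp/dt = s·(a − (b(x)+1)·p + p²w)
    PLC substrate:    dw/dt = s·(b(x)·p − p²w)
    growth signal:    dg/dt = k_growth·x − d_growth·g

with L the local TGFα and b(x) = b_max·x/(x+x_half) a saturating drive.
The (p, w) pair is the classic activator–depletion oscillator: below the
drive threshold b = 1+a² it has a stable quiet fixed point; above it,
PLCγ cycles with amplitude growing in the drive. This stands in for the
Ca²⁺/PLCγ oscillations that accompany growth-factor-driven migration: a
cell whose PLCγ is *changing fast* (backward difference over the last
update above a threshold, default 0.04 h⁻¹) is migration-competent.
EGFR inhibition lowers R_eff, pushes the drive subthreshold, flattens
the PLCγ trace and removes migration competence — while leaving the
growth signal merely reduced, so division slows rather than stops.
Because an oscillator's pointwise rate is phase-dependent, the
dose–response property (PLCγ activity non-increasing in inhibitor dose)
is defined on the sustained amplitude from the basal state.

The cell cycle is a cyclin pool driven by a saturating function of the
growth signal, gated by local glucose (Hill form, half 0.3, exponent 3),
feeding a progression integrator; crossing the threshold arms division,
and division resets both mother and daughter clocks.

## Phenotype rules

Death has precedence. A cell dies when glucose or oxygen sits below its
death threshold for `death_sustained_steps` consecutive updates
(acute starvation), or — optionally, off in the canonical configuration —
when a hunger integral accrued below quiescence-level glucose exceeds a
tolerance (chronic starvation). Next, a super-threshold PLCγ rate makes
the cell *active*: it moves to a free Moore neighbour with probability
proportional to local TGFα raised to a sharpening exponent (default 8),
i.e. up the vessel-sourced growth-factor gradient. Next, an armed cycle
clock with a free neighbour makes it *proliferative*; otherwise it is
quiescent. Apoptosis is absorbing and frees the voxel.

## Vasculature and drug action on ECs

Tip ECs migrate with probability `tip_move_prob` per hour to a neighbour
weighted by exp(w_c·ΔTAF + w_h·Δfibronectin); they avoid their own trail
and the parent vessel, and merging into another sprout (anastomosis)
ends migration without killing the tip. Eligible tips (old enough, TAF
above threshold, below the tip cap) branch with a configured
probability. Under VEGFR-inhibitor exposure the effective VEGFR of each
active tip is evaluated from the drug in its own voxel; tips strictly
below the mean over active tips (computed once per step, before any
deactivation) become irreversibly apoptotic. Ties survive, so a uniform
field — in particular, no drug — never kills ECs.

## What drives the simulated treatment response

On the canonical configuration the EGFRI-monotherapy curve reproduces
the reference dynamics: the spheroid grows until its glucose demand
outruns diffusive supply (first apoptotic cells near ~100 h), the
survival rate L/(L+D) crashes (steepest fall near ~105 h) and then
declines slowly while births and starvation deaths churn at the supply
limit; meanwhile angiogenesis keeps adding exchange surface, and when
vascular supply overtakes demand the churn ends and the curve rebounds
(near ~250–280 h seed-averaged), settling around 55 % at 450 h. The tip
cap (25) bounds the late exchange surface and thereby the rebound
magnitude.

## Calibrated defaults

No laboratory parameter set ships with the model; all kinetic, transport
and threshold values are calibrated model units (concentrations
normalised to an O(1) tissue level), chosen so the canonical
configuration reproduces the reference treatment dynamics at desk scale.
Key values (all overridable in the YAML config):

| block | parameter | default | role |
|---|---|---|---|
| glucose | D, q, H, u, δ | 1000 µm²/h, 2 /h, 1, 0.2 /h, 0.002 /h | supply-limited nutrient economy |
| tgfa | D, q, δ, init | 1500, 1, 0.05, 0.2 | vessel-sourced ligand and migration attractant |
| taf | D, δ, secretion, u | 2000, 0.01, 0.05, 0.05 | tumor-sourced chemoattractant, tip-consumed |
| binding | km (both drugs), R0 | 0.2, 1.0 | quasi-equilibrium inhibition |
| pathway | k_act/d_act, a, s, b_max, x_half | 0.8/0.1, 0.5, 0.3, 3, 1.5 | gain 8 puts untreated cells above, inhibited cells below, the oscillation threshold |
| cycle | k_progress, glucose gate | 0.08, half 0.3 hill 3 | untreated division period ≈ 15–25 h |
| phenotype | death thr, sustained | 0.12, 2 h | acute starvation |
| vasculature | tips, move prob, branch prob, cap | 5, 0.045, 0.06, 25 | rebound timing and magnitude |
| tumor | seed cells, centre | 7, (nx/2, ny/2, 0.7·nz) | spheroid above the parent vessel |

## Numerics

Fields use explicit forward Euler with the 7-point second-order
Laplacian; per species the sub-step is derived from
0.9·min(h²/6D, 1/(q+δ)) at configuration time, and a step that violates
the bound raises an error reporting the admissible maximum. Within one
field step the operator order is fixed: diffusion → vessel exchange →
uptake → decay; uptake is applied as min(u·dt, c) per voxel so
nonnegativity is structural. Boundaries are no-flux on all six faces by
default (fixed-value available). Intracellular ODEs use fixed-step RK4
with 0.05 h sub-steps, which matches an adaptive reference integration
to ~1e-6 relative over one update, including oscillator spike phases.
Ties in the EC fate rule survive; the mean is computed before any
deactivation so the rule is order-independent.

## Scaled-down test configuration: scope and limitations

The canonical configuration is a deliberately small system — 8000
voxels, a few thousand cells, one parent vessel — calibrated to
reproduce the *shape and timing* of the reference treatment curves, not
tissue-scale magnitudes. Quantities measured on it are seed-averaged
over 5 paired runs (common master seeds across arms). Passing tests on
it demonstrate internal consistency and the calibrated dynamics; they do
not validate the model against real tumors.

Two known limitations of this scaled-down economy, visible in the
combination-therapy tests:

- **Rebound abolition at late onsets.** Because the built vasculature
  keeps functioning after its tips die (the model deliberately excludes
  vessel regression and permeability changes), freezing angiogenesis at
  240 h leaves enough exchange surface for a weakened rebound, so the
  late-onset arms are less distinguishable from monotherapy than in a
  larger system where new vessel growth dominates local supply.
- **Bliss index sign.** Kill rates are defined as 1 − survival at the
  evaluation time. On a small closed lattice the *untreated* backbone
  also suffers substantial starvation mortality, which enters both
  single-agent kill rates and biases the Bliss score negative; the score
  is computed and reported as defined.

Other limitations: no cell mechanics or pushing, no blood flow or
hematocrit, no interstitial pressure, constant in-blood drug levels
while a schedule is on, one EC per segment, and a lattice (voxel)
representation of both cells and vessels.
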