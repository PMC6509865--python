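# angiosim

A single-cell, multiscale simulator of vascular brain-tumor growth under
receptor-targeted therapy: an EGFR inhibitor (EGFRI, e.g. gefitinib)
acting on tumor cells and a VEGFR inhibitor (VEGFRI, e.g. sorafenib)
acting on sprouting endothelial cells. It is aimed at computational
oncology / systems-biology work on angiogenesis-mediated drug
resistance: why an EGFRI-treated tumor's survival curve crashes and then
*rebounds* as new vasculature delivers nutrients, and when adding a
VEGFRI pays off.

## Model

Four coupled scales on a 3-D voxel lattice:

- **Microenvironment** — reaction–diffusion fields for glucose, oxygen,
  TGFα, the angiogenic factor (TAF/VEGF), matrix fibronectin and both
  drugs: ∂c/∂t = D∆c + χ_ves·q(H−c) − χ_sink·u − δc, with vessel voxels
  as sources and cell/tip voxels as sinks.
- **Molecular** — per-cell EGFR cascade with quasi-equilibrium inhibitor
  binding, [R:I] = [R]₀[I]/(km+[I]), so the effective receptor is
  [R]_eff = [R]₀ − [R:I]; a PLCγ oscillator whose rate of change encodes
  migration potential; a glucose-gated cell-cycle clock.
- **Cellular** — rule-based phenotype switching with strict precedence:
  apoptotic (starvation) → active/migrating → proliferative → quiescent.
- **Tissue** — tip ECs chemotax up the TAF gradient (haptotaxis on
  fibronectin), branch, and leave permanent vessel segments; under
  VEGFRI, any active tip whose effective VEGFR falls strictly below the
  mean over active tips dies irreversibly.

Drug combinations are scored with the Bliss independence index
CI = R₁₂ − (R₁ + R₂ − R₁·R₂), where kill rates are R = 1 − survival at
the evaluation time; CI > 0 indicates synergy. The survival rate is
living / (living + cumulative apoptotic).

See `docs/methods.md` for the full model description, calibrated
defaults, and known limitations of the scaled-down configuration.

## Worked example

Simulate EGFRI monotherapy on the canonical scaled-down configuration
(20³ lattice, 450 h):

```python
import angiosim as a

cfg = a.egfri_arm(a.canonical_config(seed=1))   # EGFRI on from t = 0
result = a.run_simulation(cfg)
print(result.census_frame().iloc[-1])
```

or from the shell (writes `census.csv`, final cell/vessel tables and a
JSON run manifest):

```bash
angiosim simulate --config egfri.yaml --seed 1 --out run1
# t=450 h: living=255 apoptotic=207 ec=263 survival=0.552
```

Reading the census rows of that run: the tumor grows from 7 to ~87 cells
with survival 1.0 until ~98 h; starvation deaths then drive a sharp
crash (survival 0.91 at 108 h, minimum ≈ 0.45 around 253 h) while
endothelial cells increase steadily (19 → 125 → 262); once the growing
vasculature catches up with nutrient demand the curve rebounds and ends
near 55 % — acquired, angiogenesis-driven resistance to the EGFRI.

Combination experiments:

```bash
angiosim synergy --out syn            # 3-arm Bliss CI with paired seeds
angiosim timing-scan --out scan       # sweep the VEGFRI onset time
```

Both print a one-line summary (e.g. `Bliss CI = -0.213 +/- 0.049 ...`)
and write per-seed CSV tables.

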