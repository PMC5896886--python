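# explantmech

Analysis pipeline for tissue-explant pulling assays: probe-deflection force
calibration, viscoelastic stress-relaxation fitting, marker-track
morphometrics, force-per-cell estimation, and a seeded ground-truth
simulator of the whole experiment.

## What it does

| Module | Purpose |
| --- | --- |
| `explantmech.force_trace` | Convert probe deflection (pixels) to force via `F = D·M·K_P`, linear drift correction from pre/post unstressed probe positions, hourly mean ± SEM summaries, optional static-friction compensation. |
| `explantmech.stress_relaxation` | Structural stiffness `SS(t) = (F/area)/strain` (μN/mm² ≡ Pa); bounded nonlinear least-squares fit of the standard linear solid `SS(t) = S_inf + S_sp·e^(−t/τ)` with `η = τ·S_inf`; residual stiffness at 180 s, bulk spring stiffness, plastic-deformation fraction, recoil metrics. |
| `explantmech.morphometrics` | Convergence rates (μm/min and %/hr), signed regional strain rates, shear w.r.t. attachment strips (edge minus sled convergence), sagittal-sectional-area regression models (linear, capped quadratic, constant). |
| `explantmech.cell_force` | Force-per-cell (nN) and tensional-stress (Pa) tables from force, effective SSA and mean cell sectional area. |
| `explantmech.synthetic` | Seeded generators with exact ground truth: a quasi-static chain of active motor–spring–dashpot elements pulling against a probe spring (linear force–velocity motors, plastic yield flow, scheduled motor recruitment, measurement noise/drift/friction on the emitted record only); forward SLS relaxation traces; marker tracks under piecewise exponential strain. |
| `explantmech.io` / `explantmech.cli` | `#`-metadata CSV formats with exact float round-trips, JSON run manifests, and the CLI below. |

The shipped simulator default (`default_pull_config`) is a documented
*calibration* that reproduces the landmark two-phase force trace (first
plateau ≈ 2 μN pinned at a flanking yield tension, second rise after motor
recruitment to ≈ 4–5 μN, single-motor ceiling at its stall force). It is not
a measurement.

Note: the cell sectional area used for per-cell forces is interpreted as
625 μm² (a 25 μm × 25 μm cell). The source table's printed unit (nm²) is
dimensionally inconsistent with its own per-cell force column; the μm²
interpretation reproduces the printed values.

## CLI

All subcommands write a JSON manifest (`<out>.manifest.json`) with config
hash, input digests, seed and package version. Stochastic commands require
an explicit seed.

```sh
explantmech summarize-pull --trace trace.csv --out summary.csv [--friction-offset 0.2]
explantmech fit-relaxation --trace relax.csv --out params.json [--ramp-end 3]
explantmech morpho --tracks tracks.csv --windows windows.yaml --out table.csv
explantmech cell-force --rows rows.csv --cell-area 625 --out table2.csv
explantmech simulate-pull --config chain.yaml --out trace.csv --truth truth.json
explantmech simulate-relaxation --s-inf 14 --s-sp 25 --tau 45 --seed 1 --out relax.csv
explantmech simulate-tracks --config tracks.yaml --out tracks.csv
explantmech run --config pipeline.yaml --out-dir results/
```

`run` executes a staged simulate-then-analyze pipeline
(`simulate_relaxation`, `fit_relaxation`, `simulate_pull`,
`summarize_pull`) and writes a deterministic `summary.json`.

Trace CSVs carry their calibration/metadata as `#` header lines, e.g.

```
# probe_id: 3
# spring_constant_uN_per_um: 27.0
# magnification_um_per_px: 0.25
# pre_unstressed_px: 0.0
# post_unstressed_px: 4.0
time_min,deflection_px
0.0,0.0
6.0,1.5
```

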