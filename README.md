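# nevosim

Agent-based simulation of melanocytic proliferations (nevi) on a geometric
model of the dermo-epidermal junction.

The basal membrane is modelled as a composite differentiable manifold: a
planar base, dermal papillae as B-spline surfaces of revolution over
disjoint base disks, and a coarse vertical deformation field. Melanocyte
agents glide along the membrane via tangent projection and geodesic
translation, divide stochastically under generation- and density-dependent
damping, differentiate into nest-forming strains, and emigrate from nests.
Renderers produce dermatoscopy-style and histology-style images; the
analysis module quantifies lesion area growth (smallest enclosing disk and
0.9-quantile disk), nest dynamics, and vertical cell distributions, and
provides deterministic expectation recursions used as oracles for the
stochastic engine.

## Layout

| module | role |
| --- | --- |
| `nevosim.membrane_geometry` | shape curves, charts, metric, geodesic stepping |
| `nevosim.tissue_synthesis`  | shape fitting, distribution fitting, disk packing, membrane generation |
| `nevosim.agent_dynamics`    | melanocyte state, density measure, division/differentiation/emigration |
| `nevosim.migration`         | velocity composition, collision correction, position updates |
| `nevosim.engine`            | vectorized simulation loop, snapshots, trajectory I/O |
| `nevosim.rendering`         | dermatoscopic / histologic / overhead images |
| `nevosim.analysis`          | enclosing disks, growth slopes, t-tests, nest statistics, oracles |
| `nevosim.presets`           | named scenario presets `reticular-1..4`, `globular-1..4` |
| `nevosim.data_fixtures`     | emulated measurement spreadsheets (microanatomy, lesion growth) |

## CLI

```bash
nevosim generate-membrane --seed 1 --out membrane.json --obj membrane.obj
nevosim simulate --scenario globular-1 --seed 1 --out traj/
nevosim render --trajectory traj/ --mode dermatoscopic --out lesion.png
nevosim render --trajectory traj/ --membrane membrane.json --mode histologic --out section.png
nevosim analyze --trajectory traj/ --out report.json
```

`simulate` accepts a YAML config (`--config`) overriding `scenario`,
`extent`, `horizon`, `dt` and `snapshot_interval`. Trajectories are
directories of per-snapshot CSV files plus a JSON manifest.

## Notes

- All lengths are micrometres, times are days; altitude zero is the base
  plane of the rete ridges.
- Simulations are deterministic for a fixed seed: independent named RNG
  streams are derived from the master seed per stochastic process.
- Scenario damping-curve control points are calibrated presets (see module
  docstrings); `dt` ∈ {0.1 … 1} gives statistically consistent trajectories.
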