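# panelpet

Desk-scale simulation and analysis chain for a flat-panel, limited-angle
TOF-PET design study: a simplified Monte Carlo coincidence simulator, a
list-mode TOF-MLEM reconstructor, and NEMA-style performance metrics, so
that design comparisons (crystal cross-section/length, CTR, readout
level, flat panels vs. a reference ring scanner) can be reproduced and
extended without GATE/CASToR or HPC resources.

## What is in the box

| module | role |
| --- | --- |
| `panelpet.geometry` | four-panel flat scanner and 78 cm-bore reference ring: indexing, world transforms, readout grouping, scintillator-volume arithmetic |
| `panelpet.phantoms` | analytic activity/attenuation phantoms (NEMA IQ body, point-source grids, normalization cube, NECR cylinder, hot-rod), emission sampling, voxelization |
| `panelpet.simulation` | back-to-back 511 keV pairs with 0.5° non-colinearity, Woodcock photon transport with Klein–Nishina Compton scattering, crystal interaction physics, Poisson decay timing |
| `panelpet.coincidence` | readout grouping (crystal / 5×5 submodule, winner-take-all / energy centroid), energy & time blurring, energy window, sliding-window coincidence sorter with truth classes |
| `panelpet.reconstruction` | Siddon ray tracing with Gaussian TOF kernel, MC sensitivity image, list-mode MLEM (optional image-space resolution model), Gaussian post-filter, NIfTI/raw I/O |
| `panelpet.metrics` | 3D Gaussian spatial-resolution fit, NEMA IQ contrast/variability with homogeneous-cube normalization, axial sensitivity, NECR & TOF-effective NECR, SSIM |
| `panelpet.experiments` / `panelpet.cli` | config-driven studies, scanner naming scheme (`CS3_L10_CTR75[_pitch2][submod]`), summary-table aggregation |

## CLI

```bash
panelpet simulate    --config run.yaml --seed 1 --out out/        # list-mode CSV
panelpet reconstruct --listmode out/listmode.csv --scanner CS3_L10_CTR75 \
                     --voxel 0.8 --iters 30 --tof --grid-n 64 --out img.nii.gz
panelpet analyze     --config study.yaml --seed 1 --out out/      # one study
panelpet table1      --results results/ --out out/                # summary table
```

Example `run.yaml`:

```yaml
scanner: CS3_L10_CTR75
duration_s: 1.0
phantom:
  kind: point_with_background
  source_center: [37.0, 0.0, 0.0]
  source_activity_Bq: 70000.0
  bg_activity_kBq: 28800.0
```

`analyze` studies (`study:` key): `resolution-single`, `resolution-grid`,
`iq`, `sensitivity`, `necr`, `qualitative`; each takes a `scale` factor
that rescales event counts relative to the full protocol and stamps a
provenance record next to its output tables.

## Desk-scale caveats

Event counts are 10²–10⁴ below the published protocols; activity boosts
and scale factors are explicit parameters, and variance-sensitive
metrics (background variability, NECR at high activity) are inflated
accordingly. Absolute sensitivities depend on the simplified cross-
section tables and are meant for *relative* design comparisons.
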