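# earlbench

Phantom-based benchmarking of harmonized PET/CT reconstruction protocols
for radiotherapy target definition.

`earlbench` simulates digital activity phantoms, emulates two harmonized
reconstruction protocols (EARL1: Gaussian FWHM 6 mm on a
3.1819 × 3.1819 × 5 mm³ grid; EARL2: FWHM 5 mm on a
1.5910 × 1.5910 × 1.5 mm³ grid), and evaluates how two-stage resampling
chains (PET grid → CT grid → dose-calculation grid, with nearest-neighbor,
trilinear, or tricubic-spline interpolation at each stage) affect
metabolic-target segmentation. It computes:

- **SUV statistics** — SUVmax, SUVmean, and SUVpeak (highest mean over a
  12 mm sphere placed on any lesion voxel center),
- **recovery coefficients** for the six-sphere image-quality phantom, with
  inclusive acceptance intervals (EARL1 0.27–0.43, EARL2 0.39–0.61) and a
  SUV = 1 ± 10% uniformity check,
- **segmentation** by 41%-of-max thresholding per lesion ROI, with
  affinity-propagation sub-clustering splitting heterogeneous lesions into
  an inner high-uptake tier and an outer remainder,
- **scores** — volumes, signed percent deviations from the analytic insert
  volumes, Jaccard shape coefficients, cumulative (product) shape scores
  per chain, and a chain-selection rule.

Three stock phantoms are built in: a uniform 6 L calibration cylinder
(70 MBq), a six-sphere phantom (10–37 mm diameters at 10× background
concentration, 20 MBq in 10 L), and a two-lesion insert set (a 0.3 mL tube,
plus a 0.3 mL tube nested inside a 2 mL vial for heterogeneous uptake).
Rasterization is partial-volume aware (supersampled boundary voxels,
innermost-wins nesting) and fully deterministic.

## CLI

```bash
earlbench simulate --phantom insert --spacing 1.0 --out truth.nii.gz --masks-out labels.nii.gz
earlbench reconstruct truth.nii.gz --protocol EARL2 --out pet.nii.gz
earlbench resample pet.nii.gz --stage1 linear --stage2 nn --ct-out ct.nii.gz --dose-out dose.nii.gz
earlbench segment ct.nii.gz --fraction 0.41 --subcluster --out matv.nii.gz
earlbench qc --protocol EARL1 --report qc.json
earlbench evaluate --all-chains --out study.csv
earlbench run --config config.yaml
earlbench sc mask_a.nii.gz mask_b.nii.gz
```

A run config is YAML, e.g.

```yaml
phantom: insert
protocols: [EARL1, EARL2]
chains: [[linear, linear], [spline, linear]]
truth_spacing_mm: 1.0
threshold_fraction: 0.41
output_dir: out
seed: 0
```

`earlbench run` writes `volumes.csv`, `chains.json`, and a `manifest.json`
carrying the config hash, seed, and library versions; identical configs
produce byte-identical reports.

## Python API

```python
from earlbench import (
    make_insert_phantom, rasterize, EARL1, EARL2, emulate_recon,
    ResamplingChain, run_chain, threshold_matv, shape_coefficient,
)
from earlbench.pipeline import run_insert_study

study = run_insert_study()  # 2 protocols x 9 chains, one DataFrame row per
                            # (protocol, chain, structure, grid stage)
```

## Layout

- `src/earlbench/grids.py` — voxel-lattice geometry, images, masks
- `src/earlbench/phantoms.py` — analytic phantoms and rasterization
- `src/earlbench/recon.py` — protocol emulation (Gaussian PSF, grid binning, SUV)
- `src/earlbench/suvmetrics.py` — SUV statistics, recovery, limits
- `src/earlbench/resample.py` — interpolation methods and chains
- `src/earlbench/segment.py` — threshold MATV, affinity propagation, tiering
- `src/earlbench/evalmetrics.py` — volumes, deviations, shape coefficients
- `src/earlbench/nifti.py`, `pipeline.py`, `cli.py` — I/O and orchestration
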