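# stedcoloc

Slab-wise Pearson colocalization analysis for two-channel 3D STED image
stacks of filter-grown brain endothelial cells — with a synthetic
ground-truth simulator that makes every stage of the pipeline verifiable
by parameter recovery.

## The problem

Dual-color STED imaging of cells cultured on Transwell polycarbonate
filters is the natural way to ask whether a cargo (here α-synuclein,
green channel) rides in vesicular carriers decorated by a marker (Rab7 or
VPS35, red channel).  A naive whole-stack Pearson correlation coefficient
(PC) is badly biased in these data: the filter membrane autofluoresces
inhomogeneously in *both* channels, and the sparse sub-diffraction puncta
are drowned among empty voxels.  This package implements the corrected
score:

1. 3×3×3 median filter per channel;
2. local background correction of each xz-slice by greyscale erosion +
   dilation with a radius-5 disk (white top-hat by default);
3. division of each cell into 400-nm sections along y and
   maximum-intensity projection within each section;
4. per-section Pearson coefficient

   `p = Σ(R_i − R_av)(G_i − G_av) / sqrt(Σ(R_i − R_av)² · Σ(G_i − G_av)²)`

   over the projected in-ROI pixels (R = red, G = green);
5. per-cell score = mean of the section coefficients.

It also ships a seeded simulator of two-channel stacks with a planted
co-positioned fraction `f`, membrane autofluorescence and shot/read noise
(`stedcoloc.synthetic`), an object-based spot co-occurrence score
(`stedcoloc.spotcoloc`), and transwell ELISA transport arithmetic
(`stedcoloc.transwell`).  See `docs/methods.md` for the full model
description and the design choices.

## Worked example

```python
import numpy as np
import stedcoloc as sc

# Simulate a 32x128x128 stack at 40 nm pixels: 60 puncta per channel,
# half the red puncta have a co-positioned green partner (f = 0.5),
# membrane autofluorescence and noise on.
params = sc.SimulationParams(coloc_fraction=0.5, seed=1)
stack, truth = sc.simulate_stack(params)
print(len(truth.pairing))                 # 30  (round(0.5 * 60) planted pairs)
print(round(sc.global_pearson(stack), 3)) # 0.8 (naive PC, inflated by membrane)

roi = sc.CellROI(np.ones(stack.shape, bool), cell_id="cell1")
result = sc.cell_coloc_score(stack, roi, sc.PreprocessParams(), slab_nm=400.0)
print(len(result.slab_pcs), round(result.mean_pc, 3))  # 13 0.479
```

The naive whole-stack PC reads 0.80 even though only half the puncta are
truly paired — the shared membrane layer alone contributes a PC of ~0.64
(run `analysis/04_background_correction_benefit.py`).  The pipeline score
of 0.479 tracks the planted fraction of 0.5.  Running the recovery study
(`analysis/03_parameter_recovery.py`, 10 replicates per fraction) prints:

```
      pipeline_pc_mean  pipeline_pc_std  naive_pc_mean  naive_pc_std
f
0.00             0.012            0.018          0.641         0.004
0.25             0.250            0.042          0.726         0.007
0.50             0.463            0.021          0.804         0.004
0.75             0.701            0.036          0.886         0.003
1.00             0.946            0.005          0.964         0.003
```

i.e. the pipeline score is an approximately unbiased, strictly monotone
readout of the true co-positioned fraction, while the naive score is
compressed into [0.64, 0.96] by the background.

## Analysis scripts

Numbered drivers under `analysis/` re-run the studies and write their
tables to `results/`:

| script | what it shows |
|---|---|
| `01_simulate_example_stack.py` | one simulated stack + planted truth |
| `02_score_example_stack.py` | the full per-cell scoring pipeline on it |
| `03_parameter_recovery.py` | pipeline vs naive PC over planted f |
| `04_background_correction_benefit.py` | de-biasing at f = 0, membrane on/off |
| `05_transwell_quantification.py` | ELISA calibration + percent-transport |

## Command line

```bash
stedcoloc simulate --config sim.yaml --seed 3 --out stack.ome.tiff --truth truth.json
stedcoloc analyze  --stack stack.ome.tiff --roi cells.tiff --slab-nm 400 \
                   --median-size 3 --disk-radius 5 --out results.csv
stedcoloc spots    --stack stack.ome.tiff --spot-sigma-nm 80 --radius-nm 200 --out spots.csv
stedcoloc elisa    --plate plate.csv --out elisa.csv
stedcoloc recover  --f-values 0,0.25,0.5,0.75,1 --n-reps 10 --seed 7 --out-dir run/
```

Stacks are TIFF/OME-TIFF (pixel sizes from OME metadata or
`--pixel-size-nm X Y Z`); ROIs are label-image TIFFs or JSON polygon
lists; reports are plain CSV.  Every run writes a `manifest.json` with the
merged configuration, package version and input checksums, and identical
config + seed reproduce every output byte-identically.

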