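# phantomrad

Virtual-phantom CT acquisition simulation with radiomics stability and
variability analysis.

The package simulates the full CT chain on a synthetic anthropomorphic
abdominal phantom and quantifies how acquisition parameters affect
radiomics features:

1. **Phantom** (`phantomrad.phantom`) — a seeded digital phantom with HU
   confined to the printable −100..1000 range and six ROIs in four tissue
   classes (2 normal liver, 2 cysts, 1 hemangioma, 1 metastasis), each
   with class-distinct mean HU and correlated Gaussian texture. NIfTI I/O
   for volumes and masks.
2. **Geometry & projection** (`geometry`, `projection`) — explicit-vector
   helical cone-beam geometries (source 500 mm / detector 1000 mm from the
   rotation axis, flat 512×512 detector of 1 mm pixels, pitch 1), a
   Joseph-style ray-traced forward projector realised as a sparse system
   matrix, and its exact adjoint. A 2D fan-beam "fast mode" (single-row
   detector, circular trajectory) drives desk-scale studies.
3. **Noise** (`noise`) — Poisson projection noise
   `k ~ Poisson(I0·exp(−I_image))`, `I_final = −log(k/I0)` with noise
   level `A = 1/I0`, plus calibration of the linear σ²-vs-A relation and
   its inversion to match target image-domain variances.
4. **Reconstruction** (`reconstruction`) — FDK-style filtered
   back-projection (Ram-Lak) and SIRT (default 500 iterations) with
   HU output.
5. **Radiomics** (`radiomics`) — 86 features (18 first-order, 22 GLCM,
   14 GLDM, 16 GLRLM, 16 GLSZM) with fixed bin width 25, neighbour
   distance 1, symmetric aggregated GLCM, dependence tolerance 0, and no
   resampling/normalisation/resegmentation.
6. **Stability** (`stability`) — the standardized Mann–Whitney magnitude
   `W` (tie-corrected, no continuity correction) with the `W < 1`
   stability / `W > 1` discrimination convention, per-feature
   stability and discriminative-power percentages over grouped designs,
   rankings, and top-k overlap curves (10% of 86 → top 9).
7. **Variability** (`variability`) — 2-component PCA fitted on a
   reference feature table, projection of test tables, per-ROI centroid
   offset / spread-ratio / 95%-ellipse comparison.
8. **Pipeline** (`pipeline`, `cli`) — study presets (the 8-group
   SIRT/FBP × 150–300-projection design at A = 1e-4 with 10 seeds, the
   240-acquisition empirical replication, the multi-center preset) and a
   resumable end-to-end runner with provenance.

## CLI

```bash
phantomrad generate-phantom --shape 128,128,64 --seed 0 --out phantom/
phantomrad project --phantom phantom/phantom.nii.gz --nproj 450 --out sino/
phantomrad add-noise --sino sino/ --A 1e-4 --seed 7 --out noisy/
phantomrad reconstruct --sino noisy/ --algo sirt --iters 500 --grid 128,128,64 --out vol.nii.gz
phantomrad extract --vol vol.nii.gz --masks phantom/ --out features.csv
phantomrad stability --features features.csv --out report/
phantomrad pca-compare --ref empirical.csv --test simulated.csv --plot --out cmp/
phantomrad calibrate --a-grid 5e-5,1e-4,2e-4 --reps 5 --out fit.json
phantomrad run-study --grid-size 64 --mode 2d --out study/
```

`run-study` executes the full 8-group stability/discriminative-power
study (project → noise → reconstruct → extract 86 features per ROI →
Wilcoxon-W analysis) and writes `features.csv`, `stability_report.csv`
and `provenance.json`.

## Notes on scale

Default desk-scale settings use the 2D fast mode on a 64² slice and a
reduced SIRT iteration count; the full 3D helical geometry (512×512
detector, 500 SIRT iterations) is available through the same APIs but is
compute- and memory-intensive on a single CPU since the projector
materialises a sparse system matrix per (geometry, grid) pair.
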