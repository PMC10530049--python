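# hypermet

Post-acquisition analysis of dynamic hyperpolarized [2-¹³C]pyruvate brain
MRI, for researchers quantifying cerebral energy metabolism from
dissolution-DNP ¹³C studies.  After an intravenous bolus of hyperpolarized
[2-¹³C]pyruvate, metabolite-selective EPI acquires dynamic images of
pyruvate, [5-¹³C]glutamate and the two J-coupled peaks of the
[2-¹³C]lactate doublet.  `hypermet` turns the raw per-coil complex image
series into quantitative maps of the apparent conversion rates
k<sub>PL</sub> (pyruvate→lactate, LDH) and k<sub>PG</sub>
(pyruvate→glutamate, TCA-cycle exchange), together with AUC ratio maps
and doublet quality-control metrics — and ships a digital brain phantom
with complete ground truth so every stage is verifiable.

## Pipeline

1. **Preprocessing** — coil noise covariance from signal-free frames,
   prewhitening by its inverse Cholesky factor, SVD-based coil combination
   with pyruvate-derived sensitivities, per-voxel zeroth-order phasing.
2. **Denoising** — patch-grouped higher-order SVD: similar spatiotemporal
   patches are stacked into a (patch-pixels × frames × group) tensor whose
   HOSVD core is hard-thresholded at k·σ·√(2 ln N)
   (k<sub>global</sub> = 0.4 for the full-volume pass, k<sub>local</sub> = 0.8
   per patch group; step 2; patch 3 / search radius 4 at low resolution,
   patch 5 / radius 6 at high resolution).
3. **Quantification** — AUC maps (sum over timeframes), signal maps
   normalized to global peak pyruvate, total lactate from the doublet sum,
   Pearson r and SSIM between the doublet peaks, SNR<sub>AUC</sub> maps.
4. **Kinetic fitting** — irreversible three-site exchange:

       dP/dt = −(kPL + kPG + R1P)·P,   dL/dt = kPL·P − R1L·L,   dG/dt = kPG·P − R1G·G

   with per-frame sampling losses (signal M·sin θ, remaining M·cos θ,
   effective flips = 0.8 × nominal).  The measured pyruvate acts as the
   source ("inputless" fit); a single rate per metabolite is estimated by
   bounded least squares with a Jacobian-based relative standard error.
   Voxels require SNR<sub>AUC</sub> > 3, fit error < 30 % and > 40 %
   gray+white-matter fraction to enter whole-volume statistics.

The phantom emulates the study conditions: 32×32 matrix, 5 slices, 20
frames at 3 s; pyruvate at 7.5 mm / 20°, metabolites at 22.5 mm / 60°;
gamma-variate bolus; three-site kinetics; smooth complex coil
sensitivities; circular complex Gaussian noise.

## Worked example

```python
from hypermet import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(seed=0, phantom="uniform", noise_sigma=0.0))
for k in ("kpl_mean", "kpg_mean", "kpg_over_kpl", "auc_lac_over_pyr_mean"):
    print(k, res.report[k])
```

prints

```
kpl_mean 0.00960467
kpg_mean 0.00140068
kpg_over_kpl 0.145833
auc_lac_over_pyr_mean 0.159198
```

i.e. the full chain (prewhitening skipped for the noiseless covariance,
combination, phasing, denoising stage, doublet summation, filtering,
voxelwise fitting) recovers the simulated whole-volume rates
k<sub>PL</sub> = 0.0096 s⁻¹ and k<sub>PG</sub> = 0.0014 s⁻¹ to within
0.05 %, a rate ratio of ≈ 1/7, and a lactate-to-pyruvate AUC ratio of
0.159 that matches the closed-form value implied by the simulated time
courses.  The same entry point with `phantom="tissue"` runs the noisy
ellipse-brain phantom, where denoising visibly increases the fraction of
voxels passing the SNR and fit-error filters.

A `hypermet` console script exposes the stages
(`simulate`, `preprocess`, `denoise`, `quantify`, `fit`, `report`,
`accept`) with a YAML config and `--set key=value` overrides.

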