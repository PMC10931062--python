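# octscan

Minimum-requirement analysis of OCT scanning parameters for retinal fluid
biomarkers.

Macular OCT devices trade off scan size (field of view, FOV) and scan
density (interscan distance, ISD, the spacing between B-scans) very
differently across vendors and clinics, yet treatment decisions in exudative
AMD and RVO hinge on detecting small fluid pockets — intraretinal fluid
(IRF), subretinal fluid (SRF) and pigment epithelium detachment (PED) — in
those volumes. `octscan` quantifies, on labeled segmentation volumes, how
much detection sensitivity and volume quantification degrade when the FOV
shrinks or the ISD grows. It is aimed at people who have per-eye fluid
segmentations (from graders or a segmentation model) and want to reason
about imaging-protocol requirements; a synthetic cohort generator provides
statistically realistic stand-in data so the whole pipeline runs without any
clinical dataset.

## What it computes

Given a cohort of labeled volumes `[bscan, depth, ascan]` with codes
{0 background, 1 retina (ILM→Bruch's membrane), 2 IRF, 3 SRF, 4 PED}:

1. **Population heatmaps + Gaussian fit.** Left eyes are mirrored so +x is
   nasal; each biomarker is projected along depth and binarized to an
   en-face presence map; the per-pixel fraction of positive eyes is fit by
   the isotropic Gaussian

   f(x, y) = A · exp(−((x − μₓ)² + (y − μᵧ)²) / (2σ²)),

   in physical µm coordinates, with the coefficient of determination
   R² = 1 − SS_res/SS_tot reported.
2. **FOV sensitivity maps.** Fovea-centered crops on a 250 µm size grid;
   each cell holds the fraction of reference-positive eyes still showing the
   biomarker inside the crop (the 3×3, 2×2 and 1×1 mm crops are highlighted).
3. **ISD degradation.** B-scans are decimated by factors 2, 4, 8 (ISD
   125→250→500→1000 µm for the default 49-scan protocol, borders always
   kept). Per level it reports detection sensitivity and a border-corrected
   slice-sum volume (cross-section × ISD, half-ISD at the two border scans,
   so the analyzed extent is constant), summarized across eyes as the mean
   absolute percentage error MAPE = (1/n) Σ |V_ref − V_reduced| / V_ref,
   in percent, excluding eyes with zero reference volume.

## Worked example

```python
from octscan import (SyntheticCohortConfig, amd_preset, aggregate, fit_gaussian,
                     sensitivity_map, isd_analysis, Biomarker)
from octscan.enface import enface_map
from octscan.fov import exemplary_sensitivities
from octscan.synthetic import iter_cohort

cfg = SyntheticCohortConfig(n_eyes=80, preset=amd_preset(), seed=1835504127)
maps = [enface_map(v, Biomarker.PED) for v in iter_cohort(cfg)]

print(fit_gaussian(aggregate(maps)))
# GaussianFitResult(A=0.156, mu_x_um=3187.95, mu_y_um=2935.82,
#                   sigma_um=792.89, r_squared=0.8475, converged=True)

print(exemplary_sensitivities(sensitivity_map(maps)))
# {'full': 1.0, '3x3_mm': 1.0, '2x2_mm': 0.96, '1x1_mm': 0.71}

result = isd_analysis(iter_cohort(cfg), factors=(1, 2, 4, 8))
print(result.mape_table.round(2))
#                     IRF    SRF  IRF_SRF    PED  retina
# effective_isd_um
# 250.0              8.33   4.55     5.56   5.21    0.00
# 500.0             23.50  21.31    21.37  25.52    0.01
# 1000.0            66.93  81.77    73.50  78.73    0.10
```

Reading: the PED occurrence heatmap of this 80-eye synthetic AMD cohort is
well described by a fovea-centered Gaussian (σ ≈ 793 µm, R² ≈ 0.85);
cropping the scan to 2×2 mm still detects PED in 96% of PED-positive eyes
but 1×1 mm misses nearly 30%; and while doubling the ISD only mildly
perturbs fluid volumes (MAPE ≈ 5–8%), an ISD of 1000 µm makes fluid
volumetry unusable (MAPE > 65%) even though total retinal volume stays
within 0.1%.

The same analyses are available from the shell:

```bash
octscan generate --config cohort.yaml --out cohort/
octscan run-all --manifest cohort/manifest.csv --out results/
```

which writes `summary.json`, CSV tables and the heatmap / sensitivity-map /
boxplot figures (ETDRS grid overlay, per-biomarker color scales).

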