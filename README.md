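# fatomics

Hand-crafted epicardial adipose tissue (EAT) features and penalized Cox
survival modeling of MACE risk from noncontrast cardiac CT.

EAT — the fat depot inside the pericardial sac, in direct contact with the
myocardium and coronary arteries — is visible for free on every CT calcium
score examination, but is usually summarized by a single volume or mean
attenuation. This package computes a much richer, fully explainable
148-entry "fat-omics" descriptor of EAT from a HU-calibrated CT volume plus
a pericardial-sac segmentation, and turns it into a survival model of major
adverse cardiovascular events (MACE). It is aimed at cardiac imaging
researchers who have sac segmentations (manual or from a segmentation
network) and time-to-event follow-up, and want reproducible, feature-level
risk modeling rather than a black box.

## What it computes

**Features** (148, fixed catalog, units in cm³ / mm / HU):

- *morphologic*: EAT and sac volumes, their ratio, sac principal axis
  lengths `4·√λᵢ` from the physical-coordinate covariance, aspect ratio;
- *HU distribution*: mean, min, max, SD, Fisher skewness `g₁`,
  `Negative_skewness = −g₁` (elevated-HU burden, a marker of adipose
  inflammation), non-excess kurtosis, and equal-width histogram bins over
  the fat window [−190, −30] HU — 8 bins of 20 HU and 4 of 40 HU, as
  absolute bin volumes (`vol_50_30` …) and normalized probabilities
  (`Pro_50_30` …);
- *spatial*: the sac split into 4 axial slabs `PQ1..PQ4` (bottom → top of
  the heart) and 4 concentric shells (erosion by multiples of
  `w = major_axis/8`, anisotropy-aware distance transform), with 12 EAT
  features per subregion;
- *thickness*: a 180×360 map of ray-cast EAT thickness — 64,800 rays at 1°
  steps from the sac centroid, thickness = Euclidean distance between the
  first and last fat sample along each ray — summarized by distribution
  statistics and four fixed 8-mm bins.

**Model**: survival-aware mRMR reduces 148 → 50 features (relevance =
univariable Cox |z|, redundancy = mean |Pearson r| with selected features);
a Cox proportional-hazards elastic net (mixing α = 0.8, Breslow ties,
10-fold cross-validated λ) then yields a sparse linear risk score
`Σ βⱼ·xⱼ`, re-tightened along the λ path to at most 15 active features.

**Evaluation**: Harrell's C-index, IPCW time-dependent AUC at 2 years,
AIC of the unpenalized refit, median-split Kaplan–Meier stratification with
log-rank test and between-group hazard ratio, out-of-bag bootstrap
validation, and categorical net reclassification improvement (NRI) against
an EAT-volume-only reference model.

**Phantoms**: every stage has a ground-truth oracle — ellipsoidal sac
phantoms with controllable shell-thickness fields and Gaussian/skew-normal
HU models, and a Weibull proportional-hazards cohort simulator with known
coefficients and calibrated administrative censoring.

## Worked example

Extract features from a synthetic phantom (default scaled-down grid,
lobed 8 ± 4 mm shell):

```python
import fatomics as f

vol, sac, truth = f.generate_phantom(f.PhantomSpec(seed=5))
fv = f.extract_all(vol, sac)
for name in ("EAT_vol", "SAC_vol", "EAT_HUmean", "Thickness_Max", "Vol_PQ4"):
    print(f"{name:15s} {fv[name]:10.3f}")
```

```
EAT_vol           227.570
SAC_vol           598.800
EAT_HUmean        -80.760
Thickness_Max      12.000
Vol_PQ4            57.100
```

227.6 cm³ of fat inside a 598.8 cm³ sac, mean attenuation −80.8 HU (well
inside the adipose window), a maximum ray-cast thickness of 12 mm (the
truth field peaks at 8 + 4 mm), and 57.1 cm³ of fat in the top slab of the
heart — the region closest to the proximal coronary arteries.

Fit and evaluate on a simulated 400-subject cohort with 56% events and a
strong 15-feature signal:

```python
import numpy as np

X = f.simulate_feature_table(400, seed=31)
rng = np.random.default_rng(32)
strong = ["EAT_vol", "Pro_50_30", "Negative_skewness", "Thickness_Kurtosis",
          "Vol_PQ4", "vol_50_30", "Thickness_Max", "EAT_HUmean", "Major_axis",
          "Vol_Shell1", "HUmean_PQ4", "vol_70_50", "Thickness_Mean",
          "EAT_sac_fraction", "Pro_70_50"]
beta = {n: rng.uniform(0.25, 0.6) * (1 if i % 3 else -1)
        for i, n in enumerate(strong)}
surv = f.simulate_survival(X, f.CohortSpec(beta=beta, event_fraction=0.56, seed=33))
model, report = f.cmd_fit_eval(X, surv, f.PipelineConfig(seed=34, bootstrap_iterations=50))
```

which prints (via the report):

```
selected 15 features
train C = 0.847  AUC2y = 0.891  AIC = 1496.3
bootstrap C = 0.839 [0.812, 0.867]
test  C = 0.841  AUC2y = 0.890
KM train: HR = 7.80  logrank p = 1.1e-36
NRI vs EAT_vol (train): 0.551
```

The model keeps 15 of 148 features; held-out discrimination (test C = 0.84)
sits inside the bootstrap spread, the median risk split separates the KM
curves decisively, and reclassification beats the volume-only baseline.
(The strong simulated signal makes these numbers optimistic relative to
clinical cohorts — see `docs/methods.md`.)

The same flow is available from the shell:

```sh
fatomics phantom --out studies/p0 --seed 0
fatomics extract manifest.csv --out features.csv
fatomics fit-eval features.csv survival.csv --out-model model.json --out-report report.json
```

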