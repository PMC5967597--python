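# metagrad

Model-based quantitation of 3-D FDG-PET tumor uptake for heterogeneity and
metabolic-gradient assessment, with the conventional radiomic feature frame
alongside it.

## The problem

Semiquantitative SUV summaries (SUVmax, SUVmean, TLG) ignore the spatial
organisation of tracer uptake inside a tumor. Radiomic texture features
capture local statistical structure but are not tied to a biological or
geometric model. `metagrad` implements a complementary, model-based route:
uptake is referred to a rigid ellipsoidal template, and heterogeneity is
defined as the data's lack of fit to that template, while the fitted radial
profile yields a new per-voxel variable — the signed metabolic gradient.

For each in-mask voxel at world position `x` with uptake `Y`, the radial
coordinate under the ellipsoid `theta = (mu, Sigma)` is the squared
Mahalanobis radius

    u(theta) = (x - mu)' Sigma^{-1} (x - mu)

and uptake follows a shape-constrained semiparametric regression

    Y_i = f[u_i(theta)] + eps_i,

where `f` is a unimodal (up-then-down) step function fit by isotonic
regression; `theta` is estimated by minimizing the profiled residual sum of
squares. A GCV-smoothed spline `f~` through the step fit gives fitted
values `Yhat_i = f~(u_i)` and the structural variables

    H0 = RSS / (sum Y^2 / N)      H1 = RSS / Var(Y)          (heterogeneity)
    g = -f~'(u)   g~ = g / max(Yhat)   gY = Y g~             (gradients)

summarized per study by the 25th/95th percentiles of each gradient family.
`g` is negative where uptake still rises with radius (e.g. around a
necrotic core) and positive on the decaying flank.

The package also computes the comparison feature frame on the same
segmented, Q=32-requantized VoI: 12 histogram, 8 GLCM (averaged over the 13
directions of the 3-D grid), 2 GLSZM, asphericity and 5 PCA-morphology
features, plus avidity (SUVmax, SUVmean, TLG) — a 44-variable table in
clinical / structural / textural frames, with correlation, scaled PCA,
k-means variable clustering and cluster-centroid covariates for downstream
risk modelling. Since clinical cohorts cannot be shipped, a phantom module
generates ellipsoidal tumors with known ground truth (monotone or
necrotic-core profiles, PSF blur, noise) so the whole pipeline is testable.

## Worked example

Generate a necrotic-core phantom and fit the structural model:

```
$ metagrad --seed 2 phantom --kind unimodal_necrotic_core --noise-sd 0.2 --out ph.nii.gz
$ metagrad --seed 2 profile --image ph.nii.gz --voi voi.json \
      --dump-profile profile.csv --summary-json summary.json
Ellipsoidal uptake model fit
==============================================
n voxels                                  1586
profiled RSS                           81.1273
H0 (lack of fit)                       2.02523
H1 (lack of fit / Var Y)               29.0946
mu (mm)              138.488    133.084    135.500
semi-axes (mm)        16.621     13.407     10.164
profile mode u                           1.777
----------------------------------------------
gradient quantiles        q25          q95
  g               0.12144        2.524
  g.n            0.013945      0.28983
  g.w            0.072495       1.9329
```

Reading this: 1586 voxels survived threshold segmentation inside the crude
VoI (`voi.json` holds its center and semi-axes in mm). H0 near 2 on ~1600
voxels is a very good fit (noiseless data would give ~0; at 10% noise H0
runs in the tens). The profile mode sits at u = 1.78 > 0 — the fitted
profile rises before it decays, the necrotic-core signature — and
correspondingly the lower gradient quantiles are small positive while
g[0.95] = 2.5 reflects the steeply decaying rim. `profile.csv` holds the
per-voxel `(u, Y, Y_step, Y_smooth, g, g.n, g.w)` sample for mapping
gradients back onto the volume. Note that u, the mode location and raw
gradient magnitudes are in the study's own radial scale (the fit pins
`det(Sigma)`); the normalized gradients `g.n` are the cross-study
comparable form.

Batch extraction and feature-space exploration:

```
$ metagrad --seed 1 extract --n-phantoms 4 --out-dir out/
$ metagrad --seed 1 explore --features out/features.csv --k 5 --var-frac 0.95 \
      --out-dir out/explore/
```

`out/features.csv` is the 44-variable table (one row per study, frame
labels in the second line); `explore/` receives the correlation matrix,
the cluster model and per-study centroid covariates.

As a library, the same fit is two calls:

```python
from metagrad import EllipsoidalUptakeModel
model = EllipsoidalUptakeModel.from_volume(vol, mask)   # statsmodels-style
res = model.fit(seed=1)                                 # -> results object
print(res.summary()); res.structural_summary().to_dict()
```

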