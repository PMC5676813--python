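# cortmorph

Cortical surface morphometry for developmental studies: compute four
complementary surface indices from triangulated cortical reconstructions,
aggregate them over lobar regions, and model how they relate to each other
and change across adolescence.

## Who this is for

Researchers analyzing FreeSurfer-style cortical reconstructions (paired
white/pial triangle meshes with per-vertex atlas labels) who want, per
region and subject:

- **Intrinsic curvature (IC) skew** — the Gaussian curvature K = k₁·k₂ is
  estimated per vertex from a local quadric fit, filtered for values the
  mesh resolution cannot support, folded to |K|, and summarized by the
  moment skewness g₁ = m₃/m₂^{3/2} of the regional distribution.  IC
  distributions pile up near zero; *lower* skew means *more* intrinsic
  (differential-expansion) deformation.
- **Cortical thickness (CT)** — symmetric average of the closest distances
  between corresponding white and pial surfaces (mm).
- **Local gyrification index (LGI)** — the pial surface is enclosed in an
  outer hull built by morphological closing (default 15 mm sphere at 1 mm
  voxels); at every 100th hull vertex the ratio of pial to hull area
  inside a 10 mm-diameter ball is computed and propagated back to pial
  vertices by inverse distance to the sample's normal line.  LGI ≥ 1;
  larger means more surface buried in folds.
- **Surface area (SA)** — tessellation area apportioned one-third per
  incident triangle to each vertex, summed over the region (mm²).

and the statistics that connect them:

- **Associations** (per region, all index pairs): Pearson partial
  correlations adjusting for age, with significance from an OLS model
  adjusting for age and sex, Bonferroni-controlled (36 tests → p < 0.001).
- **Developmental trajectories**: penalized-spline mixed models
  y = f(age) + sex + scanner + family + ε, with the smooth in mixed-model
  form (uniform cubic B-splines, second-difference penalty; smoothing
  parameter and the family random intercept estimated jointly by REML),
  reported as Age F / Sex t grids with full-model R², Bonferroni-flagged
  at p < 0.002 (24 tests), plus fitted age curves with pointwise SEs.

Everything is validated end-to-end on synthetic surfaces with closed-form
differential geometry (spheres, developable waves, egg-crate sheets,
gyrified spheres) and on simulated cohorts that mirror a two-site,
family-clustered design (n = 218, 126 families, ages 8–29).

## Worked example

Simulate a cohort and run both statistical stages (the `analysis/` scripts
wrap the same calls):

```bash
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_index_associations.py
python analysis/03_age_trajectories.py
```

The association stage prints a Table-1-style grid of age-adjusted partial
correlations (stars from the age+sex model):

```
pair                   frontal    parietal    temporal   occipital   cingulate      insula
ic_skew~ct_mean           0.02        0.03        0.02        0.06        0.04        0.03
lgi_mean~sa            0.66***     0.58***     0.58***     0.64***     0.62***     0.66***
adjusted significance level p < 0.001 (36 tests); stars: * p<0.001, ** p<0.0003, *** p<3e-05
```

LGI and SA are strongly coupled (both scale with brain size); curvature
skew and thickness are not — exactly the dissociation the generative model
builds in.  The trajectory stage prints a Table-2-style grid; excerpts:

```
   index    region   age_F    age_p   sex_t    sex_p  r2_percent
 ic_skew   frontal    17.2 1.14e-07    1.01    0.314          14
 ct_mean occipital    32.3 5.36e-13  0.0441    0.965          24
lgi_mean  temporal    15.7   0.0001    6.99 3.46e-11        26.8
      sa   frontal   0.527    0.591     6.6 3.23e-10        18.6
```

IC skew rises and CT/LGI fall with age (age F large), SA is age-stable;
sex affects LGI and SA only.  Re-running the LGI models with total SA as a
covariate removes every LGI sex effect — the brain-size mediation pattern:

```
sex effects significant without total SA but not with it:
  lgi_mean x {frontal, parietal, temporal, occipital, cingulate, insula}, ...
```

For the geometry half, `analysis/04_synthetic_subject_pipeline.py` builds
mirrored gyrified-sphere hemispheres with a 2.5 mm parallel white surface
and recovers, per region, CT = 2.484–2.485 mm, LGI ≈ 1.02, and positive
IC skew ≈ 1.8–2.1.

Real data run through the same path via the CLI:

```bash
cortmorph metrics manifest.csv --outdir out/ --subject-table subjects.csv
cortmorph associate out/regional_metrics.tsv
cortmorph trajectories out/regional_metrics.tsv --with-total-sa --age-min 10 --age-max 22
```

where `manifest.csv` lists per-subject white/pial/label file paths per
hemisphere (FreeSurfer binary, OFF, or PLY surfaces; sparse `.label` or
dense TSV labelings).

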