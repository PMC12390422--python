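# marrowvar

Quantitative analysis of bone-marrow heterogeneity from proton density fat
fraction (PDFF) MRI in mouse models of myelofibrosis.

## The problem

Myelofibrosis replaces the normally fat-rich bone marrow with malignant
hematopoietic cells and fibrosis. PDFF-MRI maps the percentage of fat versus
cells (water) in each voxel, so disease progression in the distal tibia —
the only part of the mouse tibia that normally holds substantial fat
(~50% PDFF) — shows up as PDFF values collapsing toward zero. Mean PDFF
alone hides spatial structure; this package tracks the **variance** of the
voxel values instead: healthy marrow is spatially heterogeneous (high
variance), while marrow packed wall-to-wall with hematopoietic cells is
uniform (variance near zero).

For each image the pipeline:

1. computes the **axial mean trajectory** — per-slice mean PDFF along the
   bone — and splits the marrow ROI into proximal, transition and distal
   regions with a plateau-fraction rule (the transition region is discarded,
   the proximal region is uninformative for disease);
2. collects the distal-ROI voxel values, drops values above the **90th
   percentile** (extreme-outlier trim; one-sided, because low PDFF is the
   disease signal), and reports their **sample variance** — one
   heterogeneity score per mouse per scan day, in percent²;
3. compares groups with **label-permutation tests** (difference in group
   means), **PCA** (per-mouse score trajectories in 2D; baseline scores in
   1D), **per-mouse OLS regressions** of score on study day pooled into
   group lines, quartile summaries for violin plots, and a spleen-volume /
   PDFF-trend **responder classification**.

A synthetic phantom module generates longitudinal tibia studies with the
same statistical structure (three axial zones, Beta-distributed voxel
values with prescribed mean/variance, post-irradiation day-0 variance
inflation, exponential disease courses, scheduled dropout), so every stage
of the pipeline runs and is tested with no real MRI data. The per-mouse
variance table of the source study is bundled as a CSV fixture
(15 healthy, 17 + 12 diseased mice).

## Worked example

```python
import marrowvar as mv

table = mv.load_table1_fixture()            # bundled per-mouse score table
model = mv.CohortHeterogeneityModel(table)  # healthy vs two disease cohorts
results = model.fit(n_perm=10_000, seed=1)
print(results.summary())
```

```
             Bone-marrow PDFF heterogeneity analysis
==================================================================
Groups: disease1 (n=17), disease2 (n=12), healthy (n=15)
Records: 124   baseline day: 0   alpha: 0.05
------------------------------------------------------------------
Permutation tests (difference in group means)
  disease (day 0) > healthy : stat=  67.968  p=0.0003  [10000 perms]
  disease1 vs disease2 (two-sided)  : stat=   4.414  p=0.7393  [10000 perms]
------------------------------------------------------------------
PCA
  baseline 1D (healthy vs disease): centroid distance=67.97  p=0.0027
  trajectory 2D (cohort split): centroid distance=54.91  p=0.1355  EVR=[0.90, 0.07]
------------------------------------------------------------------
Group regression lines (score = intercept + slope * day)
  disease1     slope=  -1.926  intercept=  138.95  (mean of 17 mouse fits)
  disease2     slope=  -0.835  intercept=   82.94  (mean of 12 mouse fits)
  healthy      horizontal reference at mean score 51.60
==================================================================
```

Reading the output: day-0 diseased marrow (irradiated, pre-treatment) has
scores on average 68 percent² **above** healthy marrow — a significant
difference (p = 0.0003) — whereas the two independently run disease cohorts
are statistically indistinguishable (p = 0.74 two-sided; trajectory-PCA
separation p = 0.14), which justifies pooling them. Each disease group's
pooled regression line starts high and falls steeply as hypercellular
marrow replaces fat, crossing below the flat healthy reference of
~52 percent².

The same analysis from a shell:

```bash
marrowvar fixture-stats --out run_fixture --seed 1
marrowvar simulate --out run_phantom --seed 1 --write-images   # synthetic study
marrowvar analyze --manifest run_phantom/manifest.csv --out run_reanalysis --seed 1
```

Each run writes `scores.csv`, `stats.json`, `regressions.csv`,
`quartiles.csv`, `group_lines.csv`, `summary.txt` and a `run_manifest.json`
that, together with the seed, reproduces the bundle byte-for-byte.

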