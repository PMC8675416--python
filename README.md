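# shapemeta

Vertex-wise subcortical surface shape analysis with multi-site
random-effects meta-analysis.

`shapemeta` is for researchers running collaborative (federated)
morphometry studies of deep-brain structures — hippocampus, amygdala,
caudate, accumbens, putamen, pallidum, thalamus — where each site holds
its own subjects' triangulated surface meshes in vertex-to-vertex
correspondence with a shared template atlas, and only site-level summary
statistics are exchanged.

## What it computes

Per subject and structure, two shape measures at every template vertex:

* **thickness** `t(v)` — Euclidean distance from vertex `v` to the
  structure's medial curve. For a cylindrical structure the medial curve
  is the central axis and `t(v)` is the radius of the local cross-section.
* **log-Jacobian** `J(v) = ln(A(v) / A_template(v))` — log ratio of the
  one-ring triangle area around `v` to the same quantity on the template;
  positive values mean local surface expansion, negative contraction.

From the atlas's left–right vertex correspondence it derives the
asymmetry index `|L(v) − R(v)|` and the interhemispheric mean
`(L(v) + R(v))/2`.

Per site, mass-univariate OLS at every vertex with the fixed design

    measure ~ intercept + predictor + sex + age + age×sex + age² + age²×sex + ICV

where the predictor of interest is diagnosis, chlorpromazine dose
equivalents, or SAPS total score (the latter two in patients only). The
predictor's t statistic is converted to Cohen's *d* with sampling
variance, and sites' `(d_i, var_i)` are pooled per vertex by
inverse-variance random-effects meta-analysis,

    w_i = 1/(var_i + τ²),   d̂ = Σ w_i d_i / Σ w_i,   se = (Σ w_i)^{-1/2},

with τ² estimated by REML (default) or DerSimonian–Laird. Pooled p-value
maps are thresholded with a searchlight false-discovery-rate procedure
applied globally across all structures, vertices, and both measures of
each model family: a vertex is significant when its p-value passes the
Benjamini–Hochberg step-up threshold computed within its searchlight
neighbourhood (same-structure vertices within a radius; cross-structure
distance is infinite), at a working level calibrated so a plug-in
estimate of the global FDR stays at the requested level.

A synthetic-cohort generator (`shapemeta.synthetic_cohort`) produces
multi-site datasets — template atlas, per-subject corresponded meshes,
covariate tables — with planted diagnosis/dose/symptom patches, covariate
effects, site heterogeneity, and measurement noise, all recorded in a
ground-truth manifest.

## Worked example

Simulate a 3-site cohort (50 patients + 50 controls per site) with a
planted 0.05 mm thinning patch on the hippocampus, run the full analysis
in memory, and inspect the result:

```python
import numpy as np
from shapemeta import MODELS, RunConfig, SimConfig
from shapemeta.pipeline import analyze_dataset
from shapemeta.synthetic_cohort import Patch, simulate_multisite

cfg = SimConfig(n_sites=3, n_patients=50, n_controls=50, n_vertices=200, seed=7)
patch = Patch("hippocampus", 100, 12.0, -0.05, "dx")
dataset = simulate_multisite(cfg, patches=[patch])
result = analyze_dataset(dataset, RunConfig(models=tuple(MODELS)))

meta = result.meta[("m1_dx_thickness", "hippocampus", "mean_thickness")]
patch_vertices = dataset.manifest["patch_vertices"]["dx"]["hippocampus"]
print(f"pooled d in patch:  {meta.pooled_d[patch_vertices].mean():+.3f}")
print(f"pooled d elsewhere: {np.delete(meta.pooled_d, patch_vertices).mean():+.3f}")
mask = result.masks["diagnosis_mean"]
sig = mask.significant[("hippocampus", "mean_thickness")]
print(f"significant vertices (searchlight FDR, q=0.05): {int(sig.sum())} "
      f"of {len(sig)}; {sig[patch_vertices].mean():.0%} of the planted patch")
```

prints

```
pooled d in patch:  -0.809
pooled d elsewhere: -0.021
significant vertices (searchlight FDR, q=0.05): 102 of 192; 100% of the planted patch
```

The planted thinning produces a strongly negative pooled Cohen's *d*
inside the patch, near-zero *d* elsewhere, and the searchlight mask
recovers the whole patch. `result.concordance` additionally reports, per
structure, how often the two measures flag the same vertices in the same
direction (0.95 here — thinning and surface contraction are concordant).

The same analysis runs as a two-phase file pipeline (site phase →
exchangeable CSVs → meta phase) from the command line:

```sh
shapemeta simulate --out data --seed 7 --patch hippocampus:100:12:-0.05
shapemeta run-all --config run.yaml
```

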