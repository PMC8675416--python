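# Methods

This note records the models, algorithms, parameter choices, and known
limitations of `shapemeta`, in the package's own terms.

## Shape measures

**Medial curve.** Structures are treated as tubular: each mesh gets a 1-D
medial curve, computed deterministically as follows.

1. The first principal axis of the vertex cloud is taken from the SVD of
   the centred vertices. A mesh with no distinguished long axis — the two
   leading singular values within 10% of each other — is declared
   *near-spherical*; its "curve" degenerates to the single centroid point
   (with a warning) and thickness becomes distance-to-centroid, the
   continuous limit of the definition.
2. Vertices are sorted by their projection on the axis and split into
   `n_bands` (default 30) equal-count bands. A band cut is deferred while
   consecutive projections are tied to within a relative 1e-8, so
   lattice-like vertex rings are never split by floating-point jitter;
   this makes the banding exactly equivariant under rigid motions.
3. Each band contributes a medial knot. The knot's axial position is the
   band mean; its cross-axial position is the centre of a least-squares
   (Kåsa) circle fit to the band's vertices projected on the plane
   orthogonal to the axis, falling back to the plain centroid when the
   band has fewer than 6 vertices, the fit is rank-deficient, or the
   fitted centre escapes twice the band's spread (degenerate
   cross-sections). The circle fit is the load-bearing choice: the raw
   vertex centroid of an azimuthally incomplete band is biased by
   ~radius/√(band size), which at a few hundred vertices per structure
   inflates thickness noise several-fold; the fitted centre is exact for
   circular cross-sections and its error scales with the *noise*, not the
   radius.
4. Knots are smoothed with a 3-point running mean (consecutive bands cut
   complementary azimuthal arcs, so averaging cancels residual
   cross-axial bias; a no-op for knots already on the axis), then
   interpolated by a cubic smoothing spline per coordinate over a
   chord-length parameterization and sampled at `n_samples` (default 100,
   floor 50) points. The spline's smoothing target is set automatically
   from the knots' second differences (`E[Δ²y²] = 6σ²` for white knot
   noise), so exact tubular data receives an interpolating spline.

For cylinders of radius 0.5–2 mm and aspect ratios 3–10 the curve
coincides with the central axis and mean thickness equals the radius to
well under 1% (measured; the package's contract allows 2%).

**Thickness** is the minimum Euclidean distance from a vertex to the
piecewise-linear curve (distance to segments, not knots), vectorised over
all vertices × segments.

**Log-Jacobian.** The local area around vertex `v` is the sum of the
areas of its one-ring (incident) triangles; the measure is
`ln(ring_subject/ring_template)`. The one-ring sum is smooth,
topology-local, and reduces exactly to `2 ln s` under uniform scaling
`s`. Triangle areas are floored at 1e-12 mm² (counted and logged) so the
log never diverges on degenerate faces. No surface smoothing is applied
to any measure map.

**Bilateral maps.** The atlas stores a left↔right vertex bijection per
structure; the asymmetry index is `|L(v) − R(lr(v))|` and the
interhemispheric mean `(L(v) + R(lr(v)))/2`. Asymmetry maps are
non-negative by construction; their within-group distribution is
folded-normal-like, which the site GLM treats as an ordinary outcome
(inference on the group coefficient is asymptotically calibrated; see
limitations).

## Site-level model

One OLS fit per vertex with exactly eight columns: intercept, predictor
of interest, sex, age, age×sex, age², age²×sex, ICV. Age is centred at
the site mean before powers and interactions are formed — this is pure
reparameterization (predictor inference unchanged) and conditions the
normal equations. Sites with fewer than 10 usable rows, fewer than 5 per
group (diagnosis models), or a rank-deficient design are flagged unusable
and excluded from pooling with a recorded reason; rows with missing
required fields are dropped and counted, never imputed.

Effect sizes: for the two-group (diagnosis) models,
`d = t (n1+n2)/(√(n1 n2) √df)` with
`var_d = (n1+n2)/(n1 n2) + d²/(2(n1+n2))`; for continuous predictors
(dose, symptoms), through the partial correlation `r = t/√(t²+df)`,
`d = 2r/√(1−r²) = 2t/√df` and, by the delta method,
`var_d = 4/(df+2) · (1−r²)^{-2}`. Standardized effect sizes for
continuous predictors conflate the predictor's scale; the per-unit slope
`β` and its standard error are therefore always reported alongside, and
downstream consumers can pool either.

## Meta-analysis

Each vertex is pooled independently (mass-univariate). τ² is estimated by
REML via the standard fixed-point iteration (converged at |Δτ²| < 1e-10
or 100 iterations, vectorised across vertices, DL start), or by the
DerSimonian–Laird moment estimator; REML is the default. Two-sided
p-values use the normal approximation `z = d̂/se` by default; the
Knapp–Hartung small-sample adjustment (t reference with k−1 df, scaled
se) is available by flag but off by default. With τ² = 0 the pooled
answer equals the fixed-effect inverse-variance result exactly; a vertex
covered by a single site carries that site's estimate flagged `k = 1`.
Heterogeneity is summarised by Cochran's Q and I².

A known property, measured on ideal simulated inputs: with few sites
(k ≈ 5) the normal-approximation p-values are mildly *conservative*
(≈3.8% of null vertices below p = 0.05) because estimating τ² inflates
the standard error about half the time. This is a property of the
estimator itself, not of the surrounding pipeline, and it biases the
procedure away from false positives.

## Searchlight FDR

Correction is applied globally per model family — all structures, all
vertices, both measures. Families: the diagnosis models on per-hemisphere
measures (14 structure-sides × 2 measures), the diagnosis models on
interhemispheric means, the two asymmetry models, the dose models, and
the symptom models.

Stage 1: vertex `v` is a candidate at working level `q*` if `p(v)` passes
the Benjamini–Hochberg step-up threshold over the p-values in its
searchlight neighbourhood — the same-structure vertices within `radius`
mm of `v` in template space (default 10 mm, of the order of structure
size; configurable). Distance between structures is infinite, so
neighbourhoods, and hence rejections, never cross structure boundaries.
The two measures share spatial neighbourhoods but are not mixed locally;
they meet in the global calibration.

Stage 2: `q*` is calibrated so that the plug-in estimate
`FDR ≈ m̂0 · t̄ / max(1, R)` stays ≤ q (default 0.05), where `R` is the
total rejection count, `t̄` the mean local threshold over rejected
vertices, and `m̂0` the estimated null count — `m` (the family size) by
default, or Storey's λ = 0.5 estimator on request. With `m̂0 = m` and
neighbourhoods spanning the whole family the procedure reduces *exactly*
to global BH (the plug-in estimate at each candidate level equals the BH
adjusted p-value), which is the reason `m̂0 = m` is the default. Because
the estimate is not monotone in `q*` for heterogeneous neighbourhoods,
calibration scans a fixed 129-point log-spaced grid (always including q)
and refines the best feasible bracket by 50 bisection steps; ties in
p-values resolve by vertex order, so output is bit-reproducible.
Per-vertex local thresholds and the calibrated `q*` are reported.

Under a full-null family of 14 structure-sides × 2 measures the measured
realized FDR is ≈ q. In planted-patch simulations the searchlight rejects
at least as many true positives as global BH at the same level. The power
gain is bounded, however: the stage-2 estimate charges every rejection
the mean rejected-vertex threshold times `m̂0`, which is what guarantees
null-regime control but also caps the per-vertex threshold near the BH
scale when the signal region is small.

## Synthetic cohorts

The generator emulates a multi-site shape study with computable ground
truth. Subject meshes are the template plus a per-vertex radial offset
along the template vertex normal:

    offset(v) = dx·[effect(v) + site_dev] + cpz·slope_cpz(v)
              + saps·slope_saps(v) + dx·(±1)·asym(v)
              + β_age (age − 40) + β_icv (icv − mean) + ε(v),

with `ε ~ N(0, noise_sd)` i.i.d., smoothed over the one-ring (mean of the
vertex and its edge neighbours) to keep meshes valid; planted effect
fields are not smoothed, so patch ground truth is exact. The radial
model is chosen because both measures respond analytically: thickness
shifts by the offset and the log-Jacobian by the induced area change.
Site heterogeneity adds a scalar `N(0, τ²)` deviation to the diagnosis
amplitude inside the patches. One RNG stream per (site, subject) is
derived from the master seed with `SeedSequence(seed, spawn_key=(site,
subject))`, so datasets are byte-identical regardless of generation
order. Offsets that would invert any triangle raise an error instructing
smaller amplitudes.

Default study conditions: templates are capped cylinders (ellipsoid and
bumpy-ellipsoid available) of radius 4 mm and length 40 mm; the thin
radius lets a 12 mm Euclidean-ball patch cover full cross-sections (max
chord 2r = 8 mm < 12 mm), which keeps the planted thickness response
exactly equal to the amplitude — an azimuthally partial patch is partly
absorbed by the subject's own medial curve, as any per-subject medial
model would. Covariates: age ~ U(18, 60); sex ~ Bernoulli(0.60) for
patients / 0.55 controls; ICV ~ N(1.5e6, 1.5e5) mm³; dose ~ LogNormal
matched to a 376 mg/day mean; SAPS ~ N(17, 6) truncated at 0. These are
plausibility defaults, not assertions about any cohort. Default
measurement noise is 0.3 mm radial before smoothing, giving ≈ 0.09 mm
thickness noise per hemisphere on the default lattice.

`calibrate_patch_amplitude` converts a target standardized effect
(Cohen's d) into a planted amplitude using a deterministic pilot: a
covariates-only pilot site measures the residual SD of the measure, and a
single noise-free planted subject measures the geometric attenuation of
the measure response; the amplitude is `d · sd / attenuation`.

What the generator does *not* emulate: segmentation and registration
error (subject meshes are exactly corresponded), non-radial deformations,
spatially correlated measurement noise, scanner/protocol differences
beyond a scalar site effect, and realistic anatomy. Passing recovery
tests therefore demonstrates the statistical machinery on idealized
corresponded surfaces, not robustness to registration failure.

## Validation scales

Test and acceptance runs use desk-scale problem sizes chosen as the
package's own study conditions: 120–500 vertices per structure, 3–5
sites, up to 100+100 subjects per site, 20 replicate datasets for
recovery statistics, and 200 replicates for the null-FDR simulation. At
the planted pooled effect of d = 0.15 across five 100+100 sites the
pooled z per vertex is ≈ 2.4; at that signal-to-noise the maximum patch
sensitivity any FDR-0.05-valid procedure can reach is ≈ 35–40% (an oracle
threshold at 80% sensitivity would incur FDR ≈ 0.5 in the 600-test
family), and the searchlight achieves ≈ 30% versus ≈ 25% for global BH.
Sensitivity statements at small effect sizes should be read against that
bound.

## Known limitations

* The medial curve is a 1-D proxy; sheet-like (medial surface) structures
  are out of scope, and near-spherical meshes fall back to a centroid.
* Thickness near structure ends measures distance to the curve endpoint
  and is noisier than over the tubular interior.
* Asymmetry-index outcomes are folded distributions; site GLM inference
  on them relies on large-sample normality of the coefficient estimate.
* Meta-analytic p-values with few sites are conservative (see above);
  the Knapp–Hartung option trades this for a t reference.
* The searchlight FDR is one concrete member of the family of regional
  FDR procedures; equivalence with any particular published variant is
  not claimed.
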