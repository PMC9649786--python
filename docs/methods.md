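# Methods

`lvshape` implements a statistical shape modelling (SSM) workflow for the
left ventricle (LV): a population template and per-subject deformations
estimated with a kernel control-point diffeomorphic model, PCA shape
modes of the deformation parameters, classical CMR morphometric indices,
and the statistical layer that relates shape to myocardial strain and
clinical covariates. A synthetic cohort generator with fully known
ground truth stands in for clinical data, so every stage is testable
end-to-end offline.

## Deformation model and atlas estimation

Shapes are open triangulated surfaces in mm (the LV endocardium, clipped
at the base). Deformations are parameterised by momentum vectors
`p_a` at control points `c_a` on a regular grid; the velocity field is
the Gaussian-kernel interpolation

    v(x) = sum_a exp(-|x - c_a|^2 / lambda_diffeos^2) p_a

and a shape is deformed by integrating the Hamiltonian point system
(control points and momenta evolve jointly; vertices are advected) with
explicit Euler steps (`n_steps = 10` by default). Zero momenta give the
exact identity. `lambda_diffeos` (default **35 mm**) sets the stiffness
of the deformation: larger values give more global deformations. The
control grid spacing equals `lambda_diffeos` and the grid covers the
population bounding box plus half a kernel width of margin.

The data-attachment term is an **unoriented varifold** metric with a
Gaussian kernel of width `lambda_surface` (default **11 mm**) on face
centers, unit normals entering through `(n_f . n_g)^2` weighted by face
areas. Unoriented (varifold) rather than oriented (current) attachment
was chosen because the clipped LV surface is open and the orientation of
triangles near the rim is fragile. Larger `lambda_surface` blurs away
smaller surface features.

Atlas estimation minimises, over the template vertices and one momentum
field per subject,

    sum_s [ varifold(shoot(template, p_s), subject_s) / F_T
            + reg_weight * |p_s|^2_K ]

with `F_T` the template face count (this normalisation makes
`reg_weight`, default `1e-2`, roughly resolution-independent). The
optimiser alternates three moves per iteration, each accepted only if it
lowers the objective, so the loss trace is non-increasing:

1. **Momenta**: a few warm-started L-BFGS iterations per subject (the
   registration subproblem is smooth and nearly quadratic in `p`; plain
   gradient steps provably under-converge at any desk-scale budget and
   leave a shared-residual artifact as the leading PCA mode).
2. **Template**: a backtracking step along the Sobolev-smoothed gradient
   (the raw varifold gradient multiplied by a Gaussian kernel of width
   `lambda_surface`), which avoids vertex-scale noise.
3. **Centering**: shoot the template along the mean momenta and subtract
   the mean from every subject. With a weak momentum penalty, the
   attachment term alone leaves the template position nearly degenerate
   (momenta can absorb any common offset); centering strictly reduces
   the penalty while barely changing the fits and restores template
   identifiability. On a synthetic equal-weight mixture of spheres with
   radii 18 and 22 mm the estimated template lands at radius 19.98 mm.

All gradients are in closed form: hand-derived vector-Jacobian products
through the Euler steps and the varifold term, verified against finite
differences in the test suite. Template initialisation is the varifold
medoid of the population (configurable to "first subject"). Convergence
is declared when the relative loss change over five iterations falls
below `tol` (default `1e-5`); otherwise the best iterate is returned
with a warning. Runs are deterministic given inputs and seed. The
per-subject "atlas error" is reported as mean and max point-to-surface
distance from the deformed template to the subject mesh; the max is the
labelled atlas error.

## Shape modes

PCA is computed on the per-subject **initial momenta** (not vertex
displacements) under the deformation-kernel inner product
`<m, m'>_K = sum_ab K(c_a, c_b) m_a . m'_b`, the natural metric of a
kernel atlas (a euclidean metric is available as a fallback and for
cross-checks). The decomposition is done on the n-by-n centred Gram
matrix; eigenvalues use the (n-1) normalisation so each mode's
eigenvalue equals the variance of the subjects' scores along it. Per-
mode "inertia" is the percentage of total variance; percentages are
computed over every positive mode and sum to 100. Mode signs follow a
deterministic convention (largest-|.| loading positive). The default
retention rule keeps the smallest k whose cumulative inertia reaches
54%, the cut conventionally used for the first five clinical LV modes;
a fixed k can be forced. Mode extremities for visualisation are the
template shot to +/-2.7 SD along a mode (the conventional display
amplitude for LV mode extremes).

## Morphometric indices

2D long-axis contours (two views, emulating 2- and 4-chamber cines):

* **Sphericity** = B/A; A is the distance from the mitral-valve midpoint
  C to the apex (the contour point farthest from C, ties broken by
  lowest index), B the chord through the midpoint of A perpendicular to
  the C-apex direction.
* **Conicity** = E/B; E is the diameter of the least-squares circle
  (algebraic Kasa fit refined by Gauss-Newton) over contour points whose
  long-axis projection falls in the apical third (fraction
  configurable).
* Values from the two views are averaged; a single available view is
  used with a `single_view` flag.

3D aortic centerlines between the sinotubular junction (STJ) and the
mid-descending aorta:

* **W** = straight-line distance between the two landmark points;
  **l** = centerline arc length between them; **H** = maximal elevation
  of the arch above the W segment along the vertical axis (`up_axis`,
  supplied with the data).
* **Gothicity** = H/W, **tortuosity** = 1 - W/l.

These landmark-to-landmark definitions make the analytic oracles exact
(straight line: 0/0; semicircle: gothicity 0.5, tortuosity 1 - 2/pi) and
all four indices invariant to rigid motion and uniform scale. A
consequence worth knowing: with these definitions, a curve with
gothicity g must have tortuosity >= 1 - 1/sqrt(1 + 4 g^2), so clinical
report pairs like (gothicity 1.25, tortuosity 0.46) - which come from
measuring W between the ascending/descending limbs and l on a short
pulmonary-artery-bounded arch segment - are not jointly representable
here. The synthetic arch presets therefore match the clinical gothicity
range (about 1.2-1.3) and let tortuosity land where the geometry puts it
(about 0.65).

## Association statistics

* **Group comparison**: Shapiro-Wilk per group at the same alpha; if all
  groups pass, one-way ANOVA, else Kruskal-Wallis with Dunn's rank-based
  post hoc, Holm-adjusted (the adjustment is a documented choice; the
  alternative adjustments change little at these group counts). Constant
  data across groups returns p = 1 by convention.
* **Regression**: OLS (statsmodels); aortic regurgitation/stenosis
  severity enters binarised (none or mild = 0, moderate or severe = 1),
  sex and hypertension as 0/1. Complete-case per model with n reported.
  Rank-deficient designs are rejected naming the collinear columns.
* **Reproducibility**: ICC(A,1) - two-way random effects, absolute
  agreement, single measurement (via pingouin), the standard form for
  test-retest of a measurement procedure; Bland-Altman bias with
  bias +/- 1.96 SD limits; median percentage difference with range.
* **Battery** (`run_association_suite`): each mode vs
  sphericity/conicity, each strain vs each mode and each index, and the
  covariate-adjusted strain models (sphericity + AR + AS; sphericity +
  gothicity + tortuosity; M3 or sphericity + age + hypertension;
  sphericity + BMI + sex). Unadjusted p-values at alpha 0.05 by default,
  matching how such batteries are conventionally reported; a flag adds
  Benjamini-Hochberg. Models with missing columns are skipped with a
  logged warning.

## Synthetic cohort

One subject's LV is a superellipsoid of revolution
`r(z) = R (1 - |2z/L - 1|^e)^(1/e)` with a small (1% of length) cap
removed at the base pole so the surface is open like a clipped LV, plus
a low-order azimuthal bump field (default 0.5 mm) for texture.
Measured sphericity of this family equals the recorded ground truth
2R(1+0.18 w)/L to about 1%.

Cohort-level shape variation uses three geometrically independent
factors:

* **size** - uniform scale (SD 0.09),
* **height** - elongation at fixed volume: length up, radius down
  (SD 0.055),
* **waist** - a rounding profile (equator out, poles in at fixed
  length) that carries the planted group sphericity; its radial profile
  is tilted (`sin^2(pi t) - 0.82`) so that, under the deformation-kernel
  metric, rounding is near-orthogonal to uniform scaling (equator-out
  motion carries more surface area than pole-in motion, so an untilted
  profile looks like inflation).

A naive (scale, length-only, radius-only) factor triple is geometrically
rank-2 - log-length and log-radius span only two dimensions - and no PCA
can separate three such factors; the waist adds the third degree of
freedom. The apex exponent e (SD 0.15 around group means 1.2-1.4) is a
fourth, conicity-like axis. Group sphericity means follow the cohort
table (0.62/0.62/0.59/0.57); group sizes default to 25/30/30/25.

Strain values (GLS, GRS, GCS, apical radial/circumferential) are
*generated*, not computed from deformation - feature-tracking strain is
an input to this pipeline - as `a + b * true_sphericity + noise`, with
`b` and the noise SD calibrated so each relation's population R^2
matches its reported clinical effect size (0.04-0.17) at the generator's
measured population sphericity SD (0.0705), and the strain marginals
match the cohort means/SDs. Signs encode "rounder LV, reduced strain"
(radial strains positive, longitudinal/circumferential negative).
Covariates (age, sex, BMI, hypertension, valve-disease severities) and
volumetric measures follow the cohort tables per group; volumes are
drawn independently of geometry. Aortic centerlines are generated only
for the three patient groups (healthy controls lack the 3D aortic
sequence). Re-segmentation is emulated by re-perturbing 20% of subjects
with a normal-displacement field whose systematic component (SD 0.72 mm)
is calibrated to a ~4% median surface-area difference.

Everything is deterministic from the master seed via spawned
per-subject seed sequences.

### What a green test does and does not establish

The generator produces smooth axisymmetric-plus-texture surfaces with
exactly linear factor structure and Gaussian noise. Real LV shapes have
trabeculation, papillary anatomy, regional remodelling and non-Gaussian
covariate structure; real strain is measured, not drawn from the planted
model. Green recovery tests establish that the pipeline's machinery -
registration, metric PCA, measurement, inference - recovers structure
that is present; they say nothing about whether such structure exists in
any clinical population. Synthetic conicity sits ~0.1-0.2 above the
clinical 0.47-0.52 range: with B measured at the long-axis midpoint, the
superellipse family cannot push E/B below ~0.59 even at a near-conical
apex; conicity remains a monotone readout of the planted apex factor,
which is what the tests require.

## Numerical choices and limitations

* Explicit Euler with 10 steps is accurate to the tested tolerances for
  deformations up to roughly 20% of object scale; the inverse-flow error
  is ~2% of the forward displacement at the amplitudes used here.
* Varifold terms are O(F^2) per mesh pair; desk-scale meshes (500-2000
  faces) keep a 60-110 subject atlas within minutes on one CPU.
* Remeshing is the classic split/collapse/flip/tangential-relax loop
  with back-projection onto the input surface; boundary loops are
  preserved and never smoothed.
* The +/- mode reconstructions are equidistant from the template only
  for small multiples (small-geodesic regime); at +/-2.7 SD the varifold
  distances differ visibly because the metric weights area.
* The R^2 of a planted effect has a wide sampling distribution at
  n = 110 (SD ~0.065 at R^2 = 0.17); recovery bands of +-1.4 SD capture
  ~86-88% of replicates, not more, regardless of implementation.
* No GPU path; no cine/time-series atlases (end-diastole only); no
  automatic landmarking (mitral points and arch landmarks are inputs).
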