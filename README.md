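# lvshape

Statistical shape modelling of the left ventricle (LV): diffeomorphic
atlas/template estimation with kernel deformations, PCA shape modes with
per-mode inertia, CMR-style morphometric indices (sphericity, conicity,
aortic-arch gothicity and tortuosity), and the association statistics
that relate LV shape to myocardial strain and clinical covariates.

It is written for researchers studying LV remodelling — for example in
congenital aortic disease (aortic coarctation, bicuspid aortic valve)
versus controls — who have segmented LV endocardial surfaces and
standard CMR measurements and want a reproducible, scriptable pipeline
from meshes to statistics. A synthetic cohort generator with complete
ground truth is included, so the whole pipeline can be exercised and
validated without any clinical data.

## The model in brief

Shapes are open triangulated LV surfaces (mm). A population template
T and per-subject momenta p_s at control points c on a regular grid
(spacing λ_diffeos = 35 mm) are estimated by minimising

    Σ_s [ d_W( φ_{p_s}(T), S_s ) / F_T  +  γ ‖p_s‖²_K ]

where φ_p is the flow of the kernel velocity field
v(x) = Σ_a exp(−|x−c_a|²/λ²) p_a (Hamiltonian geodesic shooting, 10
Euler steps), d_W is a squared unoriented-varifold distance with kernel
width λ_surface = 11 mm, F_T the template face count and γ = 10⁻².
Shape modes are the PCA of the centred momenta under the kernel metric
⟨m,m'⟩_K = Σ_ab K(c_a,c_b) m_a·m'_b; a mode's "inertia %" is its share
of total variance, and per-subject scores along the modes feed the
statistics layer. Morphometrics follow the classical definitions:
sphericity B/A, conicity E/B on long-axis contours; gothicity H/W and
tortuosity 1 − W/l on arch centerlines. Group tests switch between
ANOVA and Kruskal–Wallis (Dunn post hoc) on per-group normality;
regressions are OLS with the conventional 0/1 codings; test–retest
reproducibility reports ICC(A,1), Bland–Altman limits and median %
difference. See `docs/methods.md` for assumptions and numerical
choices.

## Worked example

Simulate a small cohort (6 subjects per group, coarse meshes) and run
the full pipeline — preprocess → atlas → modes → morphometrics →
association battery:

```python
from lvshape import CohortSpec, RunConfig, generate_cohort, run_pipeline

spec = CohortSpec(master_seed=42, mesh_resolution=(24, 12))
for g in spec.group_params:
    spec.group_params[g]["n"] = 6
generate_cohort(spec, out_dir="demo/cohort")

cfg = RunConfig(input_dir="demo/cohort", output_dir="demo/run",
                max_iter=8, seed=42)
run_pipeline(cfg)
```

`demo/run/modes/eigen.csv` then contains the mode spectrum:

```
 mode  eigenvalue  inertia_pct  cumulative_pct
    1     118.351       51.298          51.298
    2      68.727       29.789          81.087
    3      36.204       15.692          96.780
```

Three modes dominate because the generator plants exactly three
independent shape factors (overall size, height, sphericity); on larger
default cohorts the leading modes correlate >0.9 each with their own
planted factor. `demo/run/results.csv` holds the association battery;
e.g. the bivariate strain-on-sphericity rows:

```
                      model       term  estimate      se      p     R2  n
           GRS ~ sphericity sphericity  -29.4860 16.5242 0.0882 0.1264 24
 apical_radial ~ sphericity sphericity  -38.5300 33.6300 0.2642 0.0563 24
```

The planted effect ("rounder LV, lower radial strain") shows the
expected negative slopes; at n = 24 the p-values are not yet
significant — at the default n = 110 the same battery flags them at
α = 0.05. `demo/run/reproducibility.json` summarises the emulated
re-segmentation panel (ICC 0.983, median area difference 1.8% for this
small panel), and `manifest.json` records the config, seed and
checksums of every output so identical runs are byte-identical.

The same workflow is available from the shell:

```sh
lvshape simulate --out demo/cohort --seed 42 --n-per-group 6 --coarse
lvshape run --input demo/cohort --out demo/run --seed 42
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
generates a seeded synthetic cohort, runs the complete pipeline
(atlas, modes, morphometrics, association battery and the
reproducibility panel) end-to-end, prints a one-line completion summary
and writes the JSON summary file.
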