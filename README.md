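# hipshape

Statistical shape modelling of the proximal femur and hip-fracture risk
discrimination.

Hip fracture risk depends not only on bone mineral density (BMD) but on the
geometry of the proximal femur. This package implements the
landmark-based analysis used to quantify that geometry: 60-point outlines
of the right proximal femur are superimposed by **generalized Procrustes
analysis** (translation, scale and rotation removed), decomposed by PCA
into orthonormal **modes of variation**, and every hip is expressed as SD-unit
scores on each mode,

- s_j = φ_jᵀ(x − x̄) / √λ_j,

where x̄ is the mean shape and (φ_j, λ_j) the j-th eigenvector/eigenvalue
of the aligned-shape covariance. The mode scores — together with classical
comparator measures (femoral neck length, neck width, head diameter) and
BMD — enter age/BMI-adjusted logistic models of incident fracture, compared
by in-sample AUROC with DeLong 95% CIs, McFadden pseudo-R², per-mode odds
ratios with Wald CIs, fracture-site subsets, femoral-neck T-score strata,
and a random-relabeling null check.

Because the source radiograph cohort is not public, the package includes a
first-class **synthetic cohort generator**: femur-like outlines with ten
planted orthonormal shape modes (the mode-4 analog encodes the high-risk
"longer neck / smaller head / narrower neck" axis), landmark noise, random
in-plane similarity transforms, covariates with realistic case/control
group means, and fracture outcomes with planted per-SD odds ratios
(2.48 on the mode-4 analog). Every pipeline stage is validated by
parameter recovery against this known truth.

It is intended for researchers in skeletal epidemiology and medical image
analysis who want a tested, reproducible reference implementation of the
outline-ASM + logistic/AUROC methodology.

## Layout

- `src/hipshape/` — the library: `io` (CSV/TPS landmark and covariate I/O,
  cohort summaries), `procrustes` (GPA), `model` (PCA point-distribution
  model and SD-unit scores), `geometry` (neck length/width, head diameter),
  `risk` (logistic models, AUROC/DeLong, strata), `permutation`
  (relabeling null check), `simulate` (synthetic cohorts with truth
  ledger), `pipeline` + `cli` (orchestration).
- `analysis/01…05_*.py` — the numbered analysis drivers: simulate → align
  and fit modes → geometry → risk tables → permutation check, writing
  their tables under `results/`.
- `scripts/acceptance.py` — recomputes the headline numbers from scratch.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_align_and_fit_modes.py
python analysis/04_fracture_risk_tables.py
```

prints, among other things (seed 0):

```
cohort: 399 subjects, 167 cases, 232 controls (target 168/231)
10 modes capture 97.5% of total shape variance
adjusted in-sample AUROC, all fractures:
        hip_shape_modes_1_10: 0.828 (0.787-0.870)  pseudo-R2 0.250
            femoral_neck_bmd: 0.688 (0.636-0.740)  pseudo-R2 0.081
       hip_shape_plus_fn_bmd: 0.836 (0.796-0.876)  pseudo-R2 0.267
per-mode odds ratios (age/BMI/BMD adjusted, truth-oriented):
    mode4: OR  2.57 (1.93-3.42)  p=1.2e-10   planted 2.48
```

Reading: ten modes explain 97.5% of the Procrustes shape variance; the
10-mode model discriminates the planted fracture outcomes far better than
any single comparator (AUROC 0.83 vs 0.64–0.69), combining shape with BMD
helps slightly, and the adjusted logistic model recovers the planted
mode-4 odds ratio of 2.48 per SD within sampling error. The same pipeline
is available as one command, `hipshape report --preset paper --seed 0`,
and each stage as its own CLI verb (`simulate`, `align`, `fit`, `score`,
`geometry`, `risk`, `permute`).

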