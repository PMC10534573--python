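# chromdoe

Design-of-experiments toolkit for quality-by-design (AQbD) development of
chromatographic methods: Box–Behnken response-surface modelling of gradient
HPLC retention behaviour, Monte Carlo design-space probability mapping, and
Plackett–Burman screening of quantitative robustness — with a synthetic-data
generator standing in for the instrument so the whole pipeline is testable
offline.

## The problem

When a gradient HPLC method for a drug substance and its impurities is
developed under ICH Q14 / AQbD principles, the controllable method
parameters (CMPs) — here the initial methanol fraction x₁, the final
methanol fraction x₂ and the gradient duration x₃ — must be related to the
critical method attributes (CMAs) that define acceptable separations: the
retention time of the last-eluting impurity peak (t_imp_V < 15.5 min), the
elution span (t_imp_V − t_imp_I < 12 min), the separation factor of the
critical peak pair (S = t_b_imp_III − t_e_imp_x ≥ 0 min), and the mean USP
peak width (⟨W_USP⟩ ≤ 0.235 min).

The workflow implemented here:

1. **Response surfaces.** A 16-run Box–Behnken design (12 edge runs + 4
   replicated centre runs) supports full quadratic models on coded factors,

   y = b₀ + b₁x₁ + b₂x₂ + b₃x₃ + b₁₂x₁x₂ + b₁₃x₁x₃ + b₂₃x₂x₃ + b₁₁x₁² + b₂₂x₂² + b₃₃x₃²,

   fitted by OLS, with R², adjusted R², PRESS/predicted R² (leave-one-out)
   and a lack-of-fit F test against pure error from the centre replicates.
2. **Design space.** The factor region is discretised (21 × 21 × 11 = 4851
   points); at each point, 5000 Monte Carlo iterations perturb every model
   coefficient by a uniform error of half-width one standard error, and
   π = P(all CMAs jointly satisfied) is estimated. The design space is the
   region with π ≥ 0.80, from which a working point is picked and verified.
3. **Robustness.** A 12-run Plackett–Burman design with 7 real factors and
   4 dummy columns estimates main effects on the peak-area responses; the
   root-mean-square of the dummy effects provides the effect standard error
   for t tests (df = 4).
4. **Validation statistics.** Calibration regression, recovery and RSD
   with the pharmacopoeial acceptance bands for actives and impurities.

The two study tables (the Box–Behnken response table and the
Plackett–Burman peak-area table) ship as plain-CSV fixtures, alongside the
published coefficient set used as ground truth by the synthetic generator.

## Worked example

```python
import chromdoe as cd
from chromdoe import datasets

study  = datasets.load_bbd_study()                      # bundled 16-run study
fitted = cd.fit_all_models(study, datasets.DEFAULT_MODEL_TERMS)
print(fitted["t_imp_V"].params.round(4).to_dict())
# {'b0': 15.555, 'b1': -0.51, 'b2': -1.0737, 'b3': 1.3212, 'b12': 0.0275,
#  'b13': -0.0875, 'b23': -0.09, 'b11': -0.05, 'b22': 0.0925, 'b33': 0.0075}

ds   = cd.DesignSpace(fitted, datasets.bbd_factors())
grid = cd.GridSpec({"methanol_initial": (35, 0.25, 40),
                    "methanol_final":   (75, 0.5, 85),
                    "gradient_duration": (15, 0.5, 20)})
pg   = ds.probability_map(grid, cd.MonteCarloConfig(5000, seed=20230914))
region = pg.design_space(0.8)
print(region.n_points, region.bounding_box)
# 53 {'methanol_initial': (37.5, 39.75), 'methanol_final': (76.5, 80.0),
#     'gradient_duration': (16.0, 17.5)}

print(ds.working_point_report([38.5, 77.5, 16.25]).to_string(index=False))
#                      criterion  predicted  bound  pass
#                 t_imp_V < 15.5  15.233750 15.500  True
#                 t_range < 12.0  11.132483 12.000  True
# t_b_imp_III - t_e_imp_x >= 0.0   0.021900  0.000  True
#                 W_USP <= 0.235   0.232000  0.235  True
```

The fitted coefficients say the gradient duration (b₃ = 1.32 min per coded
unit) dominates retention, the final methanol fraction (b₂ = −1.07) comes
second, and the initial fraction matters least; the working point at
(38.5 % v/v, 77.5 % v/v, 16.25 min) satisfies all four attribute bounds
with margin on retention and span but a thin separation margin
(S ≈ 0.022 min). Of the 4851 grid points, 53 meet all criteria with
π ≥ 0.80 under the default seed.

The same workflow is scriptable from the shell:

```sh
chromdoe fit --response t_imp_V
chromdoe ds map --seed 20230914 -o pi_map.csv
chromdoe ds verify --point 38.5,77.5,16.25
chromdoe robustness
chromdoe pipeline --outdir out/
```

## Layout

- `chromdoe.designs` — factor coding, Box–Behnken and Plackett–Burman plans
- `chromdoe.rsm` — `ResponseSurfaceModel` / `RSMResults` (OLS + diagnostics)
- `chromdoe.design_space` — criteria, grids, Monte Carlo π maps, slices,
  working-point reports
- `chromdoe.robustness` — `PlackettBurmanModel` / `PBResults`
- `chromdoe.validation` — calibration, recovery, RSD with acceptance bands
- `chromdoe.synthetic` — study generators with known ground truth
- `chromdoe.workflow`, `chromdoe.cli` — configuration, pipeline, console
  script
- `docs/methods.md` — modelling assumptions, numerical choices, limitations
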