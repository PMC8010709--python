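# bindkit

Quantitative analysis of carbohydrate-binding module (CBM) and processive
cellulase binding to crystalline cellulose allomorphs.

Native crystalline cellulose (cellulose I) can be converted by anhydrous
liquid-ammonia pretreatment into the cellulose III allomorph, which whole
cellulase cocktails hydrolyze much faster — yet individual processive
exocellulases such as *T. reesei* Cel7A bind and move *worse* on
cellulose III. Resolving that paradox requires combining very different
measurements: equilibrium pull-down adsorption assays, single-molecule
optical-tweezer motility and bond-rupture experiments, FRAP and QCM-D
binding kinetics, and powder XRD substrate characterization. `bindkit`
implements the complete quantitative analysis layer for all of these, plus
seeded synthetic-data generators so every stage is testable without
instrument data.

## What it computes

| Stage | Model / statistic |
|---|---|
| `isotherm` | Langmuir one-site `B = n_max F/(K_d + F)`, two-site, and Langmuir–Freundlich `B = n_max F^m/(K_d^m + F^m)` fits; partition coefficient (initial slope, → `n_max/K_d`); truncation sensitivity; Scatchard curvature diagnostic |
| `motility` | Penalized change-point step detection on bead traces; dwell-time exponential MLE (censoring/truncation aware); fundamental vs 2× step-size Gaussian mixture; regression velocities; binding-commitment classification (committed / unstable / no binding) |
| `rupture` | 2.5-pN force binning; Bell slip-bond fit `tau(F) = tau0 exp(−F x‡/k_BT)` weighted by 1/SEM²; exponential-mixture EM with parametric-bootstrap order selection (multimodality test); one-way ANOVA across bins |
| `kinetics` | Binding-dominated FRAP recovery `I(t) = I0 + F_M (1 − e^{−k_off t})`; QCM-D Langmuir kinetics with Sauerbrey conversion `Δm = −C Δf/n` |
| `buffon` | Needle-model CBM orientation statistics: crossing probability `2L/(πd)` and Monte-Carlo along-axis fractions, including needle-shortening mutants |
| `xrd` | Allomorph peak matching (14.9/17.1/23.0° vs 11.8/17.4/20.9° 2θ), Segal crystallinity index, Scherrer crystallite size |
| `workbench` | Deterministic pipeline over both substrates; derived deltas (velocity reduction %, commitment reduction %, K_d and k_off fold changes) |

Fit-shaped operations are scikit-learn style estimators
(`IsothermRegressor`, `StepDetector`, `BellSlipBondModel`,
`ExponentialMixture`, `FrapRecoveryModel`, `QcmdKineticsModel`) with
`fit`/`predict` and underscored fitted attributes; module-level functions
wrap them for one-call use.

## Worked example

Generate pull-down adsorption data for both allomorphs from reported
one-site parameters (cellulose I: n_max 4.34 µmol/g, K_d 8.69 µM;
cellulose III: 3.32, 10.55), refit, and compare affinities:

```python
from bindkit import synthetic as syn, isotherm as iso
from bindkit.isotherm import IsothermParams

fits = {}
for substrate, p in [("cellulose_I", IsothermParams(4.34, 8.69)),
                     ("cellulose_III", IsothermParams(3.32, 10.55))]:
    data = syn.gen_isotherm(syn.IsothermGenConfig(
        params=p, noise_sd=0.1, replicates=3, seed=7))
    fits[substrate] = iso.fit_isotherm(data, "one_site")
    r = fits[substrate]
    print(f"{substrate}: n_max = {r.params.n_max:.2f} +/- {r.std_errors['n_max']:.2f} umol/g, "
          f"K_d = {r.params.K_d:.2f} +/- {r.std_errors['K_d']:.2f} uM (RMSE {r.rmse:.3f})")
fold = iso.affinity_fold_change(fits["cellulose_I"], fits["cellulose_III"])
print(f"K_d fold change (III vs I): {fold:.2f}")
```

```
cellulose_I: n_max = 4.36 +/- 0.03 umol/g, K_d = 8.41 +/- 0.23 uM (RMSE 0.089)
cellulose_III: n_max = 3.34 +/- 0.03 umol/g, K_d = 10.06 +/- 0.37 uM (RMSE 0.088)
K_d fold change (III vs I): 1.20
```

The ~1.2-fold K_d increase quantifies the weaker CBM1 binding to
cellulose III under the one-site model; the fitted capacities recover the
generator truth within their standard errors.

The same workflow is available from the shell:

```bash
bindkit demo --seed 1 --out report.json   # full two-substrate pipeline
bindkit isotherm fit data.csv --model one_site
bindkit buffon --ratio 0.9 --trials 1000000 --seed 1
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the entire synthetic pipeline from scratch under the given master
seed — generator truths taken from the reported parameter tables
(adsorption constants, motility statistics, QCM-D rates, XRD positions) —
and writes the results JSON to `--out`, with the full two-substrate
comparison report saved next to it as `comparison_report.json`.

## Layout

```
src/bindkit/        datasets, synthetic, isotherm, motility, rupture,
                    kinetics, buffon, xrd, workbench, reference, cli
tests/              unit + property tests and the acceptance suite
docs/methods.md     models, assumptions, numerical choices, limitations
```
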