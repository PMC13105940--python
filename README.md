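# geowaz

Bayesian geoadditive Gaussian modelling of child weight-for-age z-scores
(WAZ), for epidemiologists and biostatisticians analysing cluster-survey
anthropometric data (DHS-style surveys). The package fits structured
additive regression models that combine smooth nonlinear effects of
metrical covariates, a region-level spatial effect, and parametric fixed
effects, with fully Bayesian inference by Gibbs sampling — and ships a
synthetic survey generator with known ground truth so the whole pipeline
is testable without restricted micro-data.

## The model

For child *i* with WAZ response *y&#8202;<sub>i</sub>*,

> y<sub>i</sub> = f<sub>1</sub>(x<sub>i1</sub>) + … + f<sub>p</sub>(x<sub>ip</sub>) + f<sub>spat</sub>(s<sub>i</sub>) + ω<sub>i</sub>′γ + ε<sub>i</sub>,  ε<sub>i</sub> ~ N(0, σ²)

* each **f<sub>j</sub>** is a **P-spline**: a cubic B-spline basis (20
  equidistant knots by default) whose coefficients carry a second-order
  difference (random-walk-2) penalty with smoothing variance τ²<sub>j</sub>;
* **f<sub>spat</sub>** is an **intrinsic Markov-random-field** effect over
  regions: the prior precision is the adjacency-graph Laplacian, scaled by
  a spatial variance τ²<sub>spat</sub>;
* **γ** are dummy-coded fixed effects (child sex, residence, electricity,
  household-head sex, diarrhoea, anaemia level, maternal education) with a
  flat prior;
* every variance (τ²<sub>j</sub>, τ²<sub>spat</sub>, σ²) has a conjugate
  inverse-gamma IG(0.001, 0.001) hyperprior.

All full conditionals are conjugate, so inference is a systematic-scan
Gibbs sweep; smooth and spatial blocks are centred each sweep for
identifiability. Model comparison uses DIC; a term is "significant" when
its 95% credible interval excludes zero; predicted severity is mapped by
inverse-distance-weighted (IDW) interpolation with hotspot flagging.

## Worked example

```python
from geowaz import (HyperPriors, MCMCConfig, ModelSpec, SmoothSpec,
                    assemble_design, run_gibbs, smooth_variance_table)
from geowaz.simulate import recovery_scenario, simulate

scenario = recovery_scenario(seed=11)          # n = 2,000, 11 regions
data, truth = simulate(scenario)
spec = ModelSpec(
    response="waz",
    categorical={"child_sex": "male", "residence": "urban",
                 "electricity": "yes", "head_sex": "male", "diarrhoea": "no",
                 "anaemia": "not_anaemic", "education": "no"},
    smooths=(SmoothSpec("child_age_months"), SmoothSpec("mother_age"),
             SmoothSpec("mother_bmi")),
    spatial="region",
)
design = assemble_design(data, spec, adjacency=scenario.adjacency())
samples = run_gibbs(design, HyperPriors(),
                    MCMCConfig(iterations=4000, burnin=1000, thin=3, seed=3))
print(smooth_variance_table(samples).round(4))
```

prints (run `python examples/03_fit_geoadditive.py` for the full output):

```
                        Mean      SD    2.5%     50%   97.5% significance     Min     Max
sx(child_age_months)  0.0110  0.0177  0.0012  0.0067  0.0450     positive  0.0005  0.3519
sx(mother_age)        0.0081  0.0127  0.0013  0.0051  0.0311     positive  0.0006  0.2295
sx(mother_bmi)        0.0097  0.0125  0.0014  0.0057  0.0455     positive  0.0008  0.1463
sx(spatial)           0.8205  0.5063  0.2953  0.6905  2.0579     positive  0.1889  6.0548
Sigma2                1.3547  0.0421  1.2796  1.3530  1.4368     positive
```

Each `sx(...)` row is the posterior of one smoothing variance — all four
penalized terms (three smooths plus the spatial effect) are clearly
active. `Sigma2` is the residual WAZ variance; its posterior mean 1.35
matches the generating value (the scenario simulates σ² = 1.3511). The
fitted region effects correlate 0.99 with the generating truth on this
scenario.

The `examples/` directory holds one short script per capability:
z-scores, simulation, fitting, spatial/hotspot mapping, nonlinearity
screening, and DIC-based model selection. A thin CLI wraps the same
pipeline (`geowaz simulate|fit|summarize|map`).

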