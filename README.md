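# engagejm

Joint models for intensively collected mHealth engagement data with
informative dropout.

## The problem

Engagement with a mobile-health intervention is usually measured through the
same channel that delivers the intervention — e.g. *days of app use per
week*, collected weekly for up to six months. When a participant disengages,
they tend to stop providing data altogether, so low engagement values are
exactly the ones most likely to be missing. This missingness is
**nonignorable (MNAR)**: standard longitudinal models (mixed effects, latent
growth) are biased because, toward the end of the study, only the most
engaged participants are still contributing data.

`engagejm` implements the **shared-parameter joint model** that corrects
this, alongside the naive analyses it replaces, for biostatisticians and
mHealth researchers analysing weekly engagement outcomes.

## The model

The longitudinal submodel is a quadratic-trend linear mixed model for weekly
engagement y_i(t) (days/week, 0–7):

    y_i(t) = m_i(t) + ε_i(t),
    m_i(t) = β₀ + β₁ t + β₂ t² + b_{0i} + b_{1i} t,

with random intercept/slope b_i ~ N(0, D) and ε_i(t) ~ N(0, σ²). The
time-to-dropout submodel is a proportional-hazards model in which the
*error-free* current engagement m_i(t) enters as a time-varying covariate:

    h_i(t) = λ(t) · exp{γ′w_i + α m_i(t)},

with baseline covariates w_i (centered age, male, race with white reference)
and a piecewise-constant baseline hazard λ(t). The association α is the log
hazard ratio of dropout per day/week of true engagement; exp(α) < 1 means
engaged users stay longer. Because the same random effects drive both
processes, maximising the joint likelihood — with the bivariate random
effects integrated out by adaptive Gauss–Hermite quadrature — yields
trajectory estimates that properly account for the dropout mechanism.

The package also provides the naive comparators (standalone ML mixed model,
Breslow-ties Cox model, Kaplan–Meier dropout curve), a synthetic-cohort
generator that draws data from exactly this joint mechanism with known
ground truth, and a pipeline producing the side-by-side naive-vs-joint
comparison.

## Worked example

```python
import engagejm as ej

# a 342-subject cohort from the default study-like mechanism (alpha = -0.26)
cohort, truth = ej.generate_cohort(ej.GeneratorConfig(), seed=2)

print(ej.km_estimate(cohort.survival).median)   # 21.86 weeks to median dropout

joint = ej.JointModel(cohort).fit()
naive = ej.EngagementLMM(cohort).fit()

jp, _ = joint.predict_mean([26.0])
np_, _ = naive.predict_mean([26.0])
print(round(jp[0], 2), round(np_[0], 2))        # 2.03 2.07 - naive overshoots
print(round(joint.alpha_hazard_ratio(), 3))     # 0.743 = exp(-0.298)
```

The naive mixed model predicts higher engagement at six months than the
joint model because it implicitly extrapolates from the engaged participants
who remained; the joint model removes that selection. On the published
coefficient scale the same arithmetic gives 2.9 (naive) vs 1.8 (joint)
days/week at week 26, and exp(−0.26) = 0.77 — a 23% lower dropout risk per
extra day/week of engagement.

A command-line interface mirrors the library:

```bash
engagejm generate --out-prefix cohort --seed 1
engagejm fit-joint --longitudinal cohort_longitudinal.csv \
                   --survival cohort_survival.csv --out joint.json
engagejm analyze --config pipeline.yaml
```

## Documentation

See `docs/methods.md` for the estimation details: quadrature, baseline
hazard parameterisation, optimisation, standard errors, what the synthetic
generator does and does not emulate, and known limitations.
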