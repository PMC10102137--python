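# ahatraj

Latent **Active and Healthy Ageing (AHA)** metric construction, trajectory
class discovery and socio-economic correlates — a tested, reusable
implementation of the full analysis chain for longitudinal ageing panels,
exercised on synthetic cohorts.

Ageing research increasingly wants a single 0–100 score that combines
self-reported function, measured performance tests and biomarkers across
survey waves, and then asks: do people follow distinct trajectories of that
score, and is membership in the worse trajectories patterned by education,
occupational class and wealth?  The real panel this design targets (an
English cohort of adults aged 50+, eight biennial waves, ~51 mixed-type
items of which 45 are anchors) is safeguarded, so the package ships a
first-class synthetic-cohort generator with the same statistical structure,
and every stage is validated against that generator's known truth.

The pipeline:

1. **Item preparation** — orientation recoding (higher = better), biomarker
   dichotomisation at clinical cut-offs (e.g. fibrinogen > 4.0 g/L,
   HbA1c ≥ 6.5%), SD-band trichotomisation of measured tests, a ≤ 25%
   baseline-missingness gate, and a 70/30 development/validation split.
2. **Dimensionality** — polychoric correlations, minres EFA with Geomin
   oblique rotation, loading-based item retention (drop cross-loaders
   > 0.32, keep single-factor loadings ≥ 0.25), and a second-order CFA with
   CFI/TLI/RMSEA fit indices.
3. **Measurement** — Bayesian multilevel IRT: a probit graded response
   model P(Y_pkt ≥ c) = Φ(a_kt·θ_pt − b_kc − u_kt) with wave-level random
   item effects in four variance structures, fitted by a data-augmented
   Gibbs sampler; EAP scores, EAP reliability, DIC, wave-level ICC, and the
   0–100 rescaling.
4. **Trajectories** — latent-basis growth curves
   θ_pt = η0 + λ_t·η1 + ε (λ_1 = 0, λ_T = 1) and growth mixture models for
   K = 2..6 by multistart EM under FIML, with AIC/BIC/SSABIC, relative
   entropy, VLMR / adjusted-LMR enumeration tests and a rule-based class
   selection.
5. **Covariates** — the manual three-step procedure: modal assignment,
   classification-error matrix Q, then ML regression of the latent class on
   SES covariates with the measurement error fixed at Q, plus a
   class-specific distal quality-of-life outcome and odds-ratio reporting.
6. **Validation** — sex-adjusted clustered ROC/AUC via placement values and
   ML mixed models of lifestyle behaviours on the score with LRT model
   comparison.

## Worked example

Fit the three-class mixture on a synthetic cohort and regress class
membership on wealth:

```python
import numpy as np
from ahatraj import synthetic as syn, trajectories as tr, class_covariates as cc

cfg = syn.SimConfig(n_persons=2000, seed=7)          # study-condition defaults
cohort = syn.apply_missingness(syn.simulate_cohort(cfg))
scores = np.where(cohort.in_panel, cohort.theta, np.nan)

fit = tr.fit_gmm(scores, tr.GrowthSpec(K=3, seed=1, n_starts=20, n_final=5))
print("class shares:", np.round(fit.pi, 3))
print("mean intercepts:", np.round(fit.mu[:, 0], 1))
print("mean slopes:", np.round(fit.mu[:, 1], 1))
print("entropy:", round(fit.fit["entropy"], 3))

W, Q = cc.step2_classify(fit.posterior)
res = cc.step3_fit(W, Q, syn.covariate_design(cohort.covariates),
                   distal_outcome=cohort.distal_outcome)
mod = int(np.argsort(fit.mu[:, 0])[0])  # lowest-intercept class
row = res.coefficients.set_index(["class", "covariate"]).loc[(mod, "wealth_q5")]
print(f"wealth Q5 (moderate vs high): coef {row['coef']:.3f} "
      f"(SE {row['se']:.3f}), OR {row['or']:.3f} "
      f"({row['or_lo']:.3f}-{row['or_hi']:.3f})")
```

Output:

```
class shares: [0.805 0.078 0.117]
mean intercepts: [84.1 77.4 43.6]
mean slopes: [ -6.7 -49.4  -4.4]
entropy: 0.918
wealth Q5 (moderate vs high): coef -2.512 (SE 0.349), OR 0.081 (0.041-0.161)
```

Reading it: the EM recovers the three generating trajectory classes — a
dominant high-stable group (~80%, baseline 84, mild decline), a small
decliner group (baseline 77, total drop ≈ 49 points over follow-up), and a
moderate-stable group (baseline 44).  Entropy 0.918 means modal
classification is sharp.  The three-step regression then recovers the
generating wealth gradient: people in the top wealth quintile have 0.08
times the odds of being in the moderate-stable rather than the high-stable
class (the truth built into the generator is −2.5 on the logit scale).  The
class-specific distal model gives the high-stable class the highest
probability of good quality-of-life at the final wave (0.575 here).

The same analysis, end to end with the IRT measurement stage in between,
runs from the shell:

```bash
ahatraj all --seed 42 --out pipeline_out        # writes per-stage artefacts
ahatraj trajectories --seed 42 --out pipeline_out  # stop after a stage
```

Each stage directory carries a `manifest.json` (seed, parameters, output
hashes); `pipeline_out/report.md` collects variant comparison,
model-selection, class-regression, descriptive and sensitivity tables.

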