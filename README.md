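# concussion-profiles

Tools for analyzing acute symptom presentation and recovery after
sport-related concussion (SRC) in collegiate athletes, built around the SCAT5
symptom checklist and the six-profile clinical taxonomy (vestibular,
cognitive, fatigue, anxiety/mood, headache/migraine, ocular).

The package is aimed at sports-medicine and biostatistics researchers who work
with daily SCAT5 symptom evaluations and want a tested, reproducible pipeline
from raw symptom CSVs to fitted hierarchical models — plus a synthetic cohort
generator with the same statistical structure, so every stage can be exercised
and validated without access to protected athlete data.

## What it computes

* **Severity scoring** — the SCAT5 injury severity score, the sum of 22
  symptom ratings on a 0–6 Likert scale (range 0–132).
* **Clinical-profile classification** — profile *p* is present when the
  athlete endorses (severity ≥ 1) at least ⌊|Sₚ|/2⌋ (min 1) of the symptoms
  Sₚ defining the profile; profiles are not mutually exclusive.  The
  symptom-to-profile mapping is configuration (YAML), not code.
* **Cohort assembly** — inclusion filtering on injury mechanism,
  sport-group collapsing, time-to-recovery (day of the final asymptomatic
  evaluation) and return-to-play (RTP) clearance day, descriptive tables.
* **Mixed models** — a Laplace-approximation estimator for Bernoulli,
  binomial(k), Poisson, NB2 and zero-inflated NB2 (ZINB) generalized linear
  mixed models with random intercepts (athletes nested in sport groups) and
  natural-spline covariate effects:

  P(y) = π·1[y=0] + (1−π)·NB2(y; μ, θ),  log μ = Xβ + Zb,  b ~ N(0, D)

  with conditional-effect prediction (delta-method CIs), Nakagawa
  marginal/conditional R², Wald contrasts, and Cohen's-d effect-size
  classification.
* **The analysis pipeline** — temporal trends of severity and profile count
  (spline of days post-injury), per-profile sex comparisons of presentation
  probability, initial severity and recovery time, the severity → profile-count
  curve, and profile-count → recovery/RTP curves with per-count sex contrasts.

## Worked example

```python
import pandas as pd
from concussion_profiles import SimulationConfig, generate_cohort, default_registry
from concussion_profiles.cohort import apply_inclusion_filter, build_daily_table
from concussion_profiles.pipeline import temporal_trends

episodes = apply_inclusion_filter(generate_cohort(SimulationConfig(n_athletes=500, seed=1)))
daily = build_daily_table(episodes, default_registry())
trends = temporal_trends(daily, include_profiles=False, include_linear=False, seed=1)
print(f"decline day 0 -> 14: {trends.severity_decline_pct:.2f}%")
print({k: round(v, 3) for k, v in trends.severity_r2.items()})
```

prints

```
decline day 0 -> 14: 90.99%
{'marginal_r2': 0.433, 'conditional_r2': 0.821, 'random_share_of_explained': 0.472}
```

The synthetic cohort decays at 0.18/day, so the expected mean severity falls
by 1 − e^(−0.18·14) ≈ 92% over two weeks; the fitted ZINB-spline mixed model
recovers that decline from the simulated daily evaluations.  Roughly half of
the explained variance is attributable to the athlete-within-sport-group
random intercepts, and the model explains ~82% of severity variance overall.

The same pipeline runs from the shell:

```bash
concussion-profiles simulate --config run.yaml --seed 1 --out data/
concussion-profiles analyze  --config run.yaml --seed 1 --out results/report.json
concussion-profiles report   --report results/report.json
```

where `run.yaml` holds a `simulate:` block (or paths to symptom/metadata
CSVs), the registry path, and model settings.

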