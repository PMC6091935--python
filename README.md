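# rrtvalid

Estimation and individual-level validation of **randomized response
techniques** (RRTs) for sensitive survey questions, built around
incentivized dice games with a known chance structure.

## The problem

Self-reports on norm-breaking behavior (shoplifting, tax evasion,
cheating for money) are distorted by social desirability.  Indirect
questioning designs try to fix this by deliberately garbling the link
between the true answer and the recorded response:

* **DQ** — direct questioning (the benchmark);
* **CM** — the crosswise model: answer whether a sensitive and an
  unrelated question get "the same" or "different" answers;
* **UQ** — the unrelated-question RRT: a private random digit routes the
  respondent to the sensitive or to an innocuous question;
* **FR** — the forced-response RRT: a random instruction forces some
  respondents to answer "yes" (or "no") unconditionally.

Each design implies known misclassification probabilities
`p₁|₁ = Pr(Y=1 | Y*=1)` and `p₁|₀ = Pr(Y=1 | Y*=0)` between the true
answer `Y*` and the observed response `Y`, so prevalence is recovered by
inverting the mixture:

```
π̂ = (Ȳ − p₁|₀) / (p₁|₁ − p₁|₀),      V(π̂) = V(Ȳ) / (p₁|₁ − p₁|₀)²
```

Higher estimates alone do not prove a design works, though: an inflated
estimate can come from *false positives* (non-bearers "admitting" the
trait through confusion or non-compliance) just as well as from reduced
underreporting.  Telling those apart requires a criterion at the
individual level.  This package implements the full validation machinery
for surveys in which respondents play a dice game they can cheat at — a
**roll-a-six game** where the recorded roll makes each cheater visible
(`X* ` observed), and a **prediction game** where cheating is private but
the 1/6 win probability identifies the cheating rate as `Pr(X=1) − 1/6`.
From these it estimates, per questioning technique:

* **TPR** — share of cheaters whose corrected response admits cheating;
* **FPR** — share of non-cheaters falsely "admitting";
* **CCR** — overall correct-classification rate,
  `TPR·Pr(X≠X*) + (1−FPR)·Pr(X=X*)`.

For the prediction game the rates are identified under assumption A1 (no
false losers) plus A2 (equal false-positive rates for true winners and
true losers) or the more extreme A2′ (zero false-positive rate for true
winners).  Standard errors come from the delta method applied to the
joint component means, with a seeded nonparametric bootstrap as a
cross-check.  A configurable synthetic survey generator (game arms,
technique arms, Benford-digit and birthday randomizing devices,
honest / lying / confused / self-protective response behavior) makes the
entire analysis runnable and testable without any external data.

## Worked example

```python
from rrtvalid import (SimulationConfig, simulate_survey, apply_exclusions,
                      recode_items, PrevalenceModel, DiceGameValidationModel,
                      RRTDesign, Technique)

survey = simulate_survey(SimulationConfig(n=6505, seed=1))
sample, ledger = apply_exclusions(survey)
sample = recode_items(sample)        # orient items so 1 = sensitive answer
print(ledger.to_dict())

cm = sample[(sample.technique == "CM") & (sample.game == "prediction")]
design = RRTDesign(Technique.CM, p_z=float(cm.pz_cheating.mean()))

print(PrevalenceModel(cm.resp_cheating, design,
                      item="cheating (prediction game)").fit().summary())

model = DiceGameValidationModel(responses=cm.resp_cheating,
                                claim=cm.claimed_win, design=design)
print(model.fit(assumption="A1_A2").summary())
```

Output:

```
{'total_recruited': 6505, 'completed_sensitive_part': 6472, 'removed_screener': 188,
 'removed_no_roll': 135, 'removed_false_loser': 0, 'final_n': 6149}
Prevalence estimate: cheating (prediction game)
----------------------------------------------
  n                        1111
  observed mean          0.7075
  p11, p10               0.1810 0.8190
  pi_hat                 0.1748
  std. err.              0.0214
  95% CI             [0.1329, 0.2168]

Individual-level validation  (n=1111, assumption=A1_A2, variance=delta)
-----------------------------------------------------------------------
  cheat rate    0.2483   (se 0.0148)
  TPR           0.3146   (se 0.0605)
  FPR           0.1286   (se 0.0271)
  CCR           0.7331   (se 0.0302)
```

Reading this: of 6,505 recruited respondents, 6,149 survive the
exclusion rules.  In the prediction-game crosswise arm the corrected
prevalence estimate of cheating is 17.5% — well below the identified
true cheating rate of 24.8% — and the individual-level decomposition
shows why the CM *looks* good at the aggregate level: a relatively high
TPR (31%) is offset by a 13% false-positive rate among non-cheaters, so
its overall classification accuracy is the worst of the four designs.

The same analysis runs end to end from the shell:

```bash
rrtvalid reproduce --n 6505 --seed 1 --out-dir results/
rrtvalid simulate --n 6505 --seed 1 --out survey.csv
rrtvalid analyze --data survey.csv --out-dir results/
```

writing tidy CSV tables for the comparative, aggregate-level and
individual-level validation stages plus the exclusion ledger.

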