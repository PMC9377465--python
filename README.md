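# emcog — ecological momentary cognitive testing toolkit

`emcog` is a Python toolkit for **ecological momentary cognitive testing
(EMCT)**: brief, repeatable cognitive tests delivered on smartphones
several times a day in people's everyday environments. It is aimed at
researchers in psychiatry and neuropsychology who design or evaluate
ambulatory testing protocols — for example in bipolar disorder, where
cognitive performance fluctuates and single laboratory visits can
mischaracterize a person's functioning.

The package contains four pieces:

1. **Test engines** — deterministic state machines for seven mobile
   cognitive tests, with their exact adaptive and scoring rules:
   - *Matching Pair* (processing speed): 90 s of colour-pair search on a
     grid growing 2×2 → 4×4; a correct trial adds the grid's tile count
     to a running weighted-accuracy score (e.g. a correct 3×3 trial on a
     running score of 246 gives 9 + 246 = 255).
   - *Memory Matrix* (visual working memory): adaptive span task; the
     highlighted-tile count rises by 1 per correct answer (max 11) and
     falls by 1 per error; each correct trial adds the span to the
     score; the session ends at 3 errors.
   - *Odd One Out* (visual working memory / speed): 9 trials of six
     symbols, five identical plus one odd; score 0–9, with per-trial
     reaction time as a secondary speed outcome.
   - *VLMT* (recognition memory): a 12-word list studied for 30 s, then
     a 24-item yes/no recognition phase (12 targets + 12 foils); score =
     hits + correct rejections, max 24; a later same-day recognition of
     the same list measures delayed retention.
   - *Quick Tap 1* (processing speed): 12 simple reaction-time trials
     with target onset uniform in 1–5 s and a 2 s timeout; score = mean
     RT over correct trials.
   - *Quick Tap 2* (response inhibition): go/no-go variant; foils appear
     with a per-trial probability drawn from 30–60%; score 0–12.
   - *CopyKat* (visual working memory): Simon-style sequence
     reproduction over four tiles; correct trials extend the sequence by
     one, errors re-present it; ends at 3 errors; score = correct trials.

   Every trial is logged (stimulus, response, latency, correctness) and
   every session can be re-scored from its raw log, so stored data and
   reported scores are always mutually auditable.

2. **Protocol scheduler** — builds and validates the 14-day ambulatory
   design: 3 notification windows per day (morning / midday / early
   evening) fitted to each participant's wake span, ≥ 2 h between
   sessions, 1 h link expiry, and a counterbalanced assignment grid
   under which each test is administered 9 times over 14 days (the
   list-memory test daily, with 8 same-day delayed recognitions).

3. **Respondent simulator** — virtual two-group cohorts (default
   45 + 21) with latent per-test abilities, practice drifts, lognormal
   reaction times, and session missingness that is logistic in study
   day, so the entire analysis pipeline can be exercised and validated
   without collecting data.

4. **Psychometric pipeline** — the full evaluation battery:
   - adherence (% of scheduled tests completed) with group comparison;
   - a mixed-effects logistic *fatigue* model,
     logit P(miss) = β₀ + β₁·day + u_participant;
   - linear (or Poisson, for count-scored outcomes) mixed *practice*
     models `score ~ day × group + (1 | participant)` with the rule that
     a non-significant interaction (p ≥ .05) drops diagnostic group from
     the model;
   - piecewise-linear spline mixed models locating the *stabilization
     day* (the knot after which the slope is no longer significant);
   - intraindividual variability via the mean square of successive
     differences, MSSD = Σ(xᵢ₊₁ − xᵢ)² / (2(n − 1));
   - one-way random-effects ICC(1) with an unbalanced-design correction;
   - a composite score (log / square skew transforms → Z-scores →
     orientation → mean);
   - Levene-gated t-tests with Cohen's d, and Pearson validity
     correlations against a laboratory battery table.

## Worked example

```python
from emcog import (CohortSpec, sample_cohort, simulate_study,
                   adherence, fit_fatigue_model, fit_practice_model)

cohort = sample_cohort(CohortSpec(n_bd=45, n_hv=21, seed=1))
data = simulate_study(cohort, seed=1)
table = data.long_table

per, summary = adherence(table)
print(f"adherence: mean {summary['mean']:.1f}%  SD {summary['sd']:.1f}%")

fat = fit_fatigue_model(table)
print(f"fatigue: day log-odds {fat.estimate('day'):.3f}  "
      f"OR {fat.extra['odds_ratio_day']:.3f}")

pf = fit_practice_model(table, "memory_matrix")
hv, bd = pf.group_slopes["HV"], pf.group_slopes["BD"]
print(f"interaction p={pf.interaction_p:.3f}; HV slope {hv['estimate']:.3f}, "
      f"BD slope {bd['estimate']:.3f}")
```

prints

```
adherence: mean 69.6%  SD 18.0%
fatigue: day log-odds 0.109  OR 1.115
interaction p=0.034; HV slope 0.351, BD slope -0.086
```

Read: this simulated cohort completed 69.6% of its scheduled tests; the
odds of missing a test rose by ~11% per study day (the generator's
fatigue slope was 0.093, and the refit recovers it within sampling
error); and the memory-span test showed a practice effect that differed
by group, with healthy volunteers improving (+0.35 score units/day) and
the patient group not.

The same pipeline is available from the shell:

```bash
emcog simulate --seed 1 --n-bd 45 --n-hv 21 --out run1
emcog score run1/trials.jsonl --out run1/rescored.csv
emcog analyze run1/sessions.csv --battery run1/battery.csv --out run1/results
```

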