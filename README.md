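# actidx

Context-aware actigraphy classification of childhood hyperactivity.

Hyperactivity — a core symptom of ADHD combined and predominantly
hyperactive/impulsive presentations — is still assessed almost entirely by
parent and teacher questionnaires. A wrist-worn accelerometer measures gross
motor activity objectively, but raw motion alone cannot separate hyperactive
from typically active children: running in a playground is normal, running
during story time is not. `actidx` implements a context-conditioned
classification pipeline for exactly this problem: parent-supplied 30-minute
activity labels (sleeping, sitting/quiet, everyday/household, exercise, not
worn) stratify the motion features, so the classifier can ask "how much does
this child move *when children are expected to sit still*?"

The pipeline, intended for researchers in digital phenotyping and
wearable-sensor behavioral assessment, is:

1. **Ingestion & filtering** (`actidx.sensor_io`) — per-day tri-axial
   accelerometer CSVs, activity diaries on the 06:00–24:00 half-hour grid,
   optional heart-rate/GPS/Bluetooth channels, and a cohort manifest. For
   children in the hyperactive group only unmedicated days enter the
   analysis (titrated stimulants suppress the symptom being measured).
2. **Feature extraction** (`actidx.features`) — three feature families per
   window: *shape* (population skewness `m₃/m₂^{3/2}`, kurtosis `m₄/m₂²`),
   *summary* (mean, population variance, median, mean magnitude) and
   *cumulative motion* (total variation `Σ|Δa|`, gravity-invariant), each
   over axes {X, Y, Z, composite} × windows {1, 5, 10 min} × contexts
   {whole-day, sitting/quiet, household, exercise}, aggregated per
   participant by the mean and variance over windows, plus hourly
   25/50/75% quantiles of 1-minute cumulative motion and optional
   context-sensor summaries. Missing features are imputed with −1.
3. **Stability selection** (`actidx.selection`) — randomized L1-penalized
   logistic regression: B subsamples of participants, a sparse logistic fit
   with jittered penalty on each, and per-feature selection frequency
   `π_j = #{b : β_j^{(b)} ≠ 0}/B`; the top k = 20 features are retained.
4. **Evaluation** (`actidx.model_eval`) — leave-one-participant-out
   cross-validation of a random forest (default 2000 trees; optional
   decision-stump mode), reduced to a 2×2 confusion table
   (hyperactive = positive class), the five diagnostic ratios (accuracy,
   sensitivity, specificity, PPV, NPV) and a 1-df Pearson chi-square test
   against chance, `χ² = N(TP·TN − FN·FP)² / ((TP+FN)(FP+TN)(TP+FP)(FN+TN))`,
   without continuity correction.
5. **Synthetic cohorts** (`actidx.synthetic`) — a seeded generator producing
   diaries, accelerometer streams and context channels with the structure
   the method assumes: groups share household/exercise motion intensity and
   differ only during quiet contexts (default ×1.35), so the group contrast
   is essentially invisible to whole-day features but strong once
   stratified by context.

## Worked example

Simulate a 30-child cohort (15 per group, the study's design), run the
full pipeline, and compare feature configurations:

```sh
actidx simulate --out cohort --seed 7 --n-adhd 15 --n-control 15 --rate 8
actidx run --manifest cohort/manifest.csv --rate 8 --out results \
    --seed 7 --trees 500 --subsamples 50
```

which prints (and writes to `results/report.md`):

```
| Model | Accuracy | Sensitivity | Specificity | PPV | NPV | chi2(1) | P |
|---|---|---|---|---|---|---|---|
| motion_only | 0.60 | 0.60 | 0.60 | 0.60 | 0.60 | 1.20 | 0.273 |
| motion_plus_context | 0.50 | 0.47 | 0.53 | 0.50 | 0.50 | 0.00 | 1.000 |
| motion_plus_labels | 0.83 | 0.87 | 0.80 | 0.81 | 0.86 | 13.39 | 0.000 |
```

Whole-day motion summaries cannot reject chance (χ²₁ = 1.20, P = .27) —
both groups contain calm and very active children, and the quiet-context
elevation is diluted by household and exercise time. Once the same motion
features are conditioned on the parent-reported context
(`motion_plus_labels`), the held-out accuracy rises to 0.83 and the
chi-square test clearly rejects chance (χ²₁ = 13.39, P < .001): the group
difference lives almost entirely in the sitting/quiet blocks.
`results/predictions.csv` holds the per-child held-out votes and
`results/report.json` the full table.

Feature columns follow the grammar
`<family>__<stat>__<axis>__<win>s__<context>__<agg>`, e.g.
`cumulative__motion__x__600s__sitting_quiet__var` is the variance across
10-minute windows of the X-axis total-variation motion during
sitting/quiet time.

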