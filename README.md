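# actichild

Free-living physical-activity classification for preschool-aged children
from raw tri-axial accelerometry.

Researchers measuring young children's physical activity increasingly pair
body-worn accelerometers (hip and/or wrist) with machine-learned activity
classifiers instead of count-threshold "cut-point" methods. `actichild`
implements that pipeline end to end for the free-living setting, where
ground truth comes from video-based direct observation of free play:

1. **Ingest** raw 100 Hz tri-axial recordings and observer event logs,
   and align codes to samples (half-open event intervals, `[start, end)`).
2. **Window** each recording into non-overlapping segments of 1–15 s,
   labeled by the activity class covering a strict majority (>50%) of the
   window; windows straddling several activities are flagged *mixed*.
3. **Featurize**: 20 time/frequency features of the per-window vector
   magnitude `VM_i = √(ax² + ay² + az²)` (moments, percentiles, signal
   power, median crossings, cross-axis correlations, dominant frequency in
   0.25–5 Hz and its magnitude), optionally plus 5 lag/lead features — the
   VM standard deviations of the 1- and 2-step neighboring windows and the
   population SD of the five surrounding per-window VM means (n = 5).
4. **Classify** with a 500-tree Random Forest per placement (hip, wrist, or
   hip+wrist feature fusion), `mtry` tuned by out-of-bag error.
5. **Evaluate** by leave-one-subject-out cross-validation (LOSO): per-class
   precision/recall/F-scores F = 2PR/(P+R), a support-weighted average
   F-score, and column-normalized confusion matrices. Unweighted Cohen's
   kappa is provided for inter-observer agreement checks.

A synthetic free-play simulator (semi-Markov bout chains, class-specific
signal signatures, correlated hip/wrist channels, out-of-view gaps,
subject random effects) generates cohorts with known ground truth, so the
entire pipeline — including end-to-end LOSO recovery — is testable without
any study data. See `docs/methods.md` for the model details and design
choices.

The five activity classes: `SED` (sedentary), `LIGHT_AG` (light activities
and games), `MV_AG` (moderate-to-vigorous activities and games), `WALK`,
`RUN`; observers may additionally code `OUT_OF_VIEW`.

## File formats

Recording CSV (one per subject × placement), acceleration in g:

```csv
timestamp,x,y,z
2019-03-01T09:00:00.000,0.012,-0.031,1.004
2019-03-01T09:00:00.010,0.018,-0.027,0.998
```

Event-log CSV (one per subject):

```csv
subject_id,start,end,code
S01,2019-03-01T09:00:00.000,2019-03-01T09:00:24.510,SED
S01,2019-03-01T09:00:24.510,2019-03-01T09:00:31.240,WALK
```

## Worked example

Simulate a small cohort (6 children, 10 min sessions), then run a LOSO
evaluation of the hip model with lag/lead features on 10 s windows:

```sh
actichild simulate -n 6 --session-s 600 --seed 7 -o data/
actichild evaluate --data-dir data/ --placement hip --features lag_lead \
    --window 10 --seed 7 -o results/
```

which prints

```
weighted F = 0.823; wrote results/hip_lag_lead_10s_metrics.csv
```

and the metrics file begins

```csv
# placement=hip feature_set=lag_lead window_s=10.0 n_trees=500 seed=7
# weighted_f=0.822726 mixed_fraction=0.467949
class,precision,recall,f_score,support
SED,0.8793103448275862,0.8793103448275862,0.8793103448275863,116
LIGHT_AG,0.7927927927927928,0.8148148148148148,0.8036529680365296,108
...
```

A weighted F of 0.82 means that, pooling the held-out predictions of all
six subjects, 82% is the support-weighted harmonic mean of precision and
recall across the five activity classes; 47% of the evaluated windows
overlapped more than one observed activity (mixed windows), which is
typical for 10 s windows over bout-structured child behavior. The
companion `*_confusion_pct.csv` gives the confusion matrix as percentages
of each observed class (columns sum to 100; rows are predictions), so the
diagonal is per-class recall in percent.

The same is available as a library:

```python
from actichild import ModelSpec, build_feature_table, loso_evaluate
from actichild.synthetic import SimConfig, cohort_tables, make_cohort

recs, logs = cohort_tables(make_cohort(SimConfig(n_subjects=6, session_s=600, seed=7)))
table = build_feature_table(recs, logs, window_s=10, include_temporal=True, placement="hip")
report = loso_evaluate(table, ModelSpec(placement="hip", window_s=10, seed=7))
print(report.weighted_f)          # 0.8227...
print(report.per_class)           # precision/recall/F/support per class
```

`actichild sweep -c examples/sweep.yaml` runs the full 3 placements × 2
feature sets × 4 window sizes grid (24 LOSO-evaluated models) and writes
one summary table plus per-cell metrics and confusion matrices.

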