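# convosync

Turn-taking, prosodic coordination and dyad-aware classification for
two-party conversations.

## The problem

Conversational speech carries clinically interesting structure beyond the
words: how fast people articulate, how variable their pitch and loudness
are, how quickly turns pass back and forth, and how strongly partners adapt
to each other. In autism research, such automatically extracted speech and
turn-taking features have been used to ask whether a *mixed* dyad (one
autistic and one non-autistic stranger) can be distinguished from a
*non-autistic* dyad from ~10-minute free conversations alone — a low-tech,
scalable complement to time-consuming diagnostic interviews.

`convosync` is a reusable, tested implementation of that analysis chain for
anyone working with annotated dyadic speech: behavioural-signal-processing
researchers, computational-psychiatry groups, conversation analysts. It
ingests Praat TextGrid or RTTM speaking-instance annotations plus
frame-level pitch/intensity tracks, and provides:

* **Turn structure** — turns defined as all speaking instances of one
  interactant until the end of the instance preceding the partner's next
  instance; signed turn-taking gaps; silence-to-turn ratio; speech rate.
* **Prosodic features** — articulation rate via syllable-nucleus detection
  (intensity peaks with a 2 dB dip criterion on voiced frames), pauses,
  phonation time, pitch/intensity variance.
* **Coordination** — windowed cross-lagged correlation (WCLC) synchrony
  (window 16 s, step 8 s, lag ±2 s; mean of per-window peak correlations)
  and turn-based adaptation (correlation of own turn values with the
  partner's previous turn), each compared against a segment-shuffling
  surrogate null ("pseudosynchrony") with a one-sided paired
  Jeffreys–Zellner–Siow Bayes factor.
* **Classification** — a linear L2-regularised squared-hinge SVM predicting
  each individual's dyad type from 30 per-task features, inside a repeated
  nested stratified cross-validation that always keeps both members of a
  dyad in the same fold (outer 7 folds × 10 permutations, inner 10 × 1),
  with training-only scaling/pruning, inner-loop penalty selection,
  Youden-J threshold shifting, balanced accuracy / sensitivity /
  specificity / AUC, and a dyad-level label-permutation test.
* **Group comparison** — Bayes factors on the natural-log scale graded by
  the symmetric Jeffreys thresholds (decisive beyond ln 100 ≈ 4.6), a
  BIC-approximate two-factor (task × group) repeated-measures model
  comparison with matched-model inclusion BFs, and a rank-approximate
  two-sample BF.
* **A synthetic-conversation generator** — alternating turns (log-normal
  lengths, median 1.8 s; gaps, median 0.2 s), within-turn pauses, AR(1)
  prosody with syllable-scale intensity bumps, planted turn-based
  adaptation and lagged cross-partner intensity coupling, and configurable
  group effects with known ground truth, so the whole pipeline is testable
  end to end without any audio data.

The core coordination statistic, per conversation and signal, is

    WCLC(a, b) = mean over windows w of  max over lags ℓ ∈ [−L, L] of
                 corr( a[w], b[w + ℓ] ),

and chance coordination is estimated by recomputing it after permuting one
partner's series in window-length segments.

## Worked example

```python
from convosync import (GeneratorConfig, generate_corpus, extract_corpus_features,
                       build_feature_matrix, make_cv_plan, fit_predict_nested,
                       grade_evidence)
from convosync.features import coordination_report

cfg = GeneratorConfig(n_mixed_dyads=8, n_nonautistic_dyads=8,
                      duration_s=120.0, seed=0)
records, truth = generate_corpus(cfg)          # 16 dyads x 2 tasks
table = extract_corpus_features(records)       # one row per individual x task

sync, log_bf = coordination_report(
    [r for r in records if r.annotations.task == "hobbies"],
    signal="intensity", n_surrogates=20, seed=1)
print(f"intensity synchrony: observed {sync['observed'].mean():.3f} "
      f"vs pseudo {sync['pseudo_mean'].mean():.3f}, "
      f"log BF10 {log_bf:.2f} ({grade_evidence(log_bf).label})")

fm = build_feature_matrix(table, truth.dyad_types())
plan = make_cv_plan(fm.dyads, fm.dyad_labels(), seed=2)
report = fit_predict_nested(fm, plan)
print(f"balanced accuracy {report.balanced_accuracy:.3f} "
      f"(sensitivity {report.sensitivity:.3f}, specificity {report.specificity:.3f}, "
      f"AUC {report.auc:.3f})")
```

Output:

```
intensity synchrony: observed 0.355 vs pseudo 0.228, log BF10 10.81 (decisive evidence for)
balanced accuracy 0.969 (sensitivity 0.938, specificity 1.000, AUC 1.000)
```

Reading: across the 16 "hobbies" conversations, observed intensity
synchrony (0.355) clearly exceeds its segment-shuffled chance level
(0.228) — decisive evidence of above-chance coordination, which the
generator indeed planted. The nested, dyad-aware SVM then separates
members of mixed vs. non-autistic dyads almost perfectly because this
corpus uses the default planted group effects; with
`EffectMultipliers.null_world()` the same pipeline hovers at chance.

A CLI mirrors the library: `convosync simulate`, `features`,
`coordination`, `classify`, `compare` (see `convosync --help`).

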