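# Methods

`convosync` analyses two-party conversations from two inputs per speaker:
speaking-instance annotations (intervals in seconds) and frame-level prosody
tracks (pitch in Hz, intensity in dB, 10 ms frames by default, missing where
the speaker is silent or unvoiced). Everything downstream — turns, prosodic
features, coordination, classification, group comparison — is derived from
these, so the package is agnostic to how the tracks were produced (Praat,
any pitch tracker, or the built-in simulator). Raw-audio feature extraction
is deliberately out of scope.

## Turn model

A turn is all speaking instances of one interactant until the end of the
speaking instance preceding the other interactant's next speaking instance.
Operationally: sort all segments by onset; maximal runs of same-speaker
segments form turns, so alternation holds by construction. Decisions the
definition leaves open:

* **Gaps are signed.** `gap_before = onset − previous turn's offset`; an
  overlapping floor start yields a negative gap that is kept in the mean
  rather than clipped, preserving overlap information.
* **Simultaneous onsets.** The speaker currently holding the floor loses it:
  the other speaker's turn starts first. Deterministic and symmetric in
  expectation.
* **Silence-to-turn ratio** uses the conversation's *total* non-speech time
  (duration minus the union of all speaking segments, so leading/trailing
  silence counts) over the summed turn spans. The numerator choice follows
  the measure's gloss as "silence vs. talking"; the cited original
  definition is not fully reproduced in the literature we work from.
* Overlapped speech retains its full duration for both speakers; no
  ownership arbitration is attempted.

## Prosodic features

Per participant and task: phonation time (summed own-segment duration),
number of pauses (silent stretches ≥ 0.3 s between own segments *within one
own turn*; whether cross-turn silences should count is genuinely ambiguous,
and the within-turn reading is the conservative one), syllable count,
articulation rate (syllables per second of phonation), and pitch/intensity
variance over all own voiced/speaking frames of the task (one variance per
participant-task, not per-turn-then-pooled). Pitch stays in Hz; a semitone
re-expression would only change the variance features monotonically per
speaker and is left to the caller.

Syllable nuclei are local intensity maxima inside speaking segments that
(a) exceed the median intensity over voiced in-segment frames, (b) rise at
least 2 dB above the minimum since the previous accepted nucleus (or the
start of speech), and (c) fall on a voiced frame. The 2 dB dip, the
median-based floor and the 0.3 s pause threshold are the conventional
nucleus-counting defaults for intensity-based syllable detection.

Frame convention: frame `i` sits at `i * frame_step_s`; a frame belongs to a
half-open segment `[start, end)` if its time does.

## Coordination

**WCLC.** Windowed cross-lagged correlation with window 16 s, step 8 s,
maximum lag 2 s (integer-frame lags, lag 0 included). Per window the peak
correlation across lags is taken — by default the largest *signed*
correlation (`max_signed`), since synchrony here means in-phase similarity;
`max_abs` is available for compatibility with tooling that aggregates
magnitudes. The conversation summary is the mean of per-window peaks.
Missing frames are handled pairwise-complete per window-lag; a window-lag
with fewer than 50% valid pairs, or with (numerically) zero variance on
either side, is skipped; a conversation with no usable window has undefined
synchrony. The production implementation computes all lag sums with
`numpy.correlate` on zero-filled validity-masked series; a transparent
per-frame reference loop (`wclc_synchrony_reference`) is shipped and the two
must agree to 1e−10 (this is checked in the tests and the acceptance
script).

**Gap bridging.** A single speaker's prosody is undefined while the partner
holds the floor, so raw cross-partner tracks have almost no pairwise-present
frames in an alternating conversation. The pipeline therefore bridges
missing stretches by linear interpolation (edges extended) before WCLC —
the standard move in speech-synchrony tooling, which requires gap-free
series. The per-speaker *feature* computations (variances, nuclei) always
use the raw, un-bridged tracks.

**Turn adaptation.** For pitch, intensity and articulation rate: the Pearson
correlation across a speaker's turns between the own turn value and the
partner's immediately preceding turn value; undefined below 3 valid pairs or
under zero variance.

**Surrogate nulls.** Pseudosynchrony permutes one partner's series in
WCLC-window-length (16 s) segments, the trailing partial segment staying in
place — shuffling destroys cross-partner timing while preserving local
signal structure. Pseudoadaptation permutes the partner's turn-feature
sequence. Each null uses 100 surrogates by default; the observed values are
compared to the per-dyad surrogate means with a **one-sided paired JZS
Bayes factor** (Cauchy prior scale √2/2 on the standardized effect,
evaluated by adaptive quadrature after the substitution δ = r·tanθ, which
turns the Cauchy prior into a uniform measure and keeps the integrand
bounded). One-sided because the hypothesis of interest is directional:
observed coordination exceeding chance coordination.

## Classification

A linear L2-regularised, squared-hinge SVM (scikit-learn `LinearSVC`,
tolerance 1e−6) classifies each individual as a member of a mixed vs.
non-autistic dyad from the feature table (default: both tasks' features
concatenated, 2 × 15 = 30 columns, dyadic values repeated for both members;
averaging over tasks is available — whether to concatenate or average is
not determined by the setting we emulate, and concatenation is the more
informative default). The cross-validation is *dyad-integral* and
stratified: folds are assigned at the dyad level (round-robin within class
after a seeded shuffle, so per-fold class counts differ by at most one
dyad), with an outer loop of 7 folds × 10 permutations and an inner loop of
10 folds × 1 permutation.

Inside each outer training partition only: features are pruned of zero
training variance and scaled to [−1, 1] by training min/max; the inner loop
picks the penalty C from the grid 2⁻⁶ … 2⁶ by out-of-fold balanced accuracy
(ties to the smaller C); the decision threshold is shifted to the Youden-J
optimum of the inner out-of-fold ROC (the concrete reading of "post-hoc
ROC optimisation", which the emulated setting does not define); class
weights are inversely proportional to class frequencies. Per-individual
outer-test decision scores are averaged over the 10 outer permutations and
labels are majority-voted (ties resolved by the mean score's sign).
Reported: balanced accuracy (mean of sensitivity and specificity — an exact
identity in the report), sensitivity, specificity, AUC of the mean scores.

Significance: dyad-level label permutation (both members relabelled
together) with the fold structure held fixed, the full nested pipeline
re-run per permutation, and `p = (1 + #{perm ≥ observed}) / (1 + n_perm)`;
5000 permutations by default, configurable down for desk-scale runs.

## Bayes factors and evidence grading

All Bayes factors are natural-log; grading uses symmetric thresholds on
|ln BF|: anecdotal < 1.1 ≤ moderate < 2.3 ≤ strong < 3.4 ≤ very strong <
4.6 ≤ decisive (ln 100 ≈ 4.6), the sign giving the direction. Boundaries
are closed from below; ln BF = 0 grades as anecdotal-for.

`mixed_anova_bf` compares the candidate set {null, +task, +group,
+task+group, full} for a balanced two-level within (task) × two-group
between design using **BIC-approximate** marginal likelihoods,
`ln BF = (BIC_null − BIC_model)/2`, with matched-model inclusion BFs
(task: {task, task+group} vs {null, group}; interaction: full vs
task+group). The compound-symmetry likelihood factorizes exactly over
per-subject sums and differences of the two task levels, so every model is
fitted in closed form by ML — no iterative mixed-model optimisation, no
convergence failures. The variance components are profiled without the
non-negativity constraint on the subject variance, and residual variances
are floored at a scale-aware 1e−12 so degenerate (zero-residual) fits stay
finite. `rank_group_bf` is a rank-approximate two-sample test: the
two-sided JZS BF on rank-transformed pooled data. Both are labelled
approximations; default-prior Bayes factors from dedicated Bayesian
packages will differ numerically, while the evidence *grading* machinery is
exact.

## Synthetic corpus generator

The generator emulates the study conditions every downstream stage is
tested under: per dyad, one conversation per task ("hobbies",
"meal planning"), 600 s each by default, with

* alternating turns, log-normal lengths with median 1.8 s (log-sd 0.6) and
  log-normal inter-turn gaps with median 0.2 s (log-sd 0.7) — the medians
  are the only distributional anchors reported for free dyadic conversation
  between strangers, hence the log-normal (positive, right-skewed) family
  parameterized by median; turn lengths are clamped below at 0.2 s;
* within-turn pauses as a Poisson process (0.15 pauses per second of turn,
  log-normal durations, median 0.5 s) carving turns into speaking segments;
* per-speaker pitch base drawn from a bimodal, voice-register-like range
  (uniform over 100–140 Hz or 180–220 Hz), intensity base 60 ± 3 dB;
* frame prosody = base + per-turn offset + stationary AR(1) noise
  (coefficient 0.95 at 10 ms frames, mimicking smooth contours; pitch sd
  20 Hz, intensity sd 1.0 dB) plus Hanning-shaped syllable intensity bumps
  (6 dB, 0.20 s wide) placed at the speaker's articulation rate (4.0
  syllables/s of phonation). The bump-dominated contour is what makes
  nucleus detection recover the planted rate to within ~10%; bump amplitude
  scales with the speaker's intensity-variability multiplier so "flatter"
  speakers are flat in both senses;
* turn-level offsets that follow the partner's previous turn with gain 0.3
  (innovation sds 10 Hz / 1.2 dB / 0.35 syll/s) — this AR chain across
  alternating turns is what plants turn-based adaptation;
* lagged linear cross-partner coupling: each speaker's speaking-frame
  intensity (and, weakly, pitch) receives gain × the partner's gap-bridged
  intensity deviation at t − 1 s. The 1 s lag sits inside the 2 s WCLC lag
  bound; gains default to 0.25 (intensity, non-autistic dyads; ×2 in mixed
  dyads) and 0.15 (pitch, both dyad types).

Group effects are multipliers relative to the non-autistic baseline
(autistic speakers: pitch-sd ×0.7, intensity-sd ×0.85, articulation ×0.85;
mixed dyads: gap median ×1.4, pause durations ×1.4, intensity coupling
×2.0), matching the directions reported for conversational speech in the
autism literature — all magnitudes are configuration, not empirical claims.
`EffectMultipliers.null_world()` (all ones) removes every group effect;
`EffectMultipliers.strong()` is a high-signal preset used to verify that
the classifier recovers a strong planted pattern. Mixed dyads contain
exactly one autistic member, enforced as an invariant. Output is
deterministic given the seed (NumPy PCG64 `default_rng` with fixed
per-dyad/per-task keys), and each dyad draws from its own stream.

What the generator does **not** emulate: lexical content, waveform-level
acoustics, backchannels and overlap dynamics beyond random gap draws,
unvoiced-within-speech frames, microphone/room effects, and any covariate
structure (gender composition is not modelled; the dyad-filter option in
the comparison layer exists for subgroup re-runs on real data). Passing
tests therefore demonstrate that the *pipeline* recovers what was planted
under these idealized conditions — not that real conversations carry these
effect sizes.

One representational caveat: intensity variance in mixed dyads is inflated
by the (stronger) planted coupling itself, which can mask the per-speaker
intensity-variability multiplier in group contrasts; the parameter-recovery
report includes the contrast but its sign is only interpretable when
coupling is equal across dyad types.

## Numerical and scale choices

* WCLC sums are computed on globally mean-centred series; a window-lag
  variance below 1e−9 of its raw sum-of-squares counts as zero (guards
  against catastrophic cancellation on near-constant stretches).
* JZS quadrature: integrand maximum located on a 201-point θ grid and
  factored out before `scipy.integrate.quad`, keeping extreme Bayes factors
  (|ln BF| ≫ 10) in a safe dynamic range.
* Degenerate inputs fail loudly (`UndefinedStatisticError`) at the
  statistic level; the corpus-level feature pipeline records such values as
  missing and continues, and the classifier median-imputes residual missing
  feature cells.
* Test and acceptance runs scale the *problem sizes*, never the method
  parameters: conversations of 120–240 s instead of 600 s, 20 surrogates
  instead of 100 where only a mean is needed, 2–3 outer CV permutations in
  replicate studies, reduced C grids and 100–200 label permutations in
  calibration loops. The surrogate-calibration study uses 200 uncoupled
  dyads; the permutation-test calibration uses 50 replicates of 10-dyad
  Gaussian feature matrices (the type-I property belongs to the CV/
  permutation machinery, not to the corpus generator) with a 3-fold outer
  loop.

## Known limitations

* The BIC and rank approximations will not reproduce default-prior Bayes
  factors from dedicated Bayesian software numerically.
* WCLC lag symmetry holds exactly per window only away from series edges;
  edge windows can differ slightly between `wclc(a, b)` and `wclc(b, a)`
  because zero-padding truncates lagged pairs asymmetrically.
* The turn definition assigns overlapped speech to both speakers in full;
  heavy-overlap conversations (not generated by default) would need an
  explicit overlap policy.
* `LinearSVC` decision scores are uncalibrated margins; only their order
  and sign are used (threshold shifts, majority votes, AUC), never their
  magnitude as probabilities.
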