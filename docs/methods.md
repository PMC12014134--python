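# Methods

This note documents the statistical procedures implemented in `avcortex`, the
assumptions behind the synthetic-session generator, and the numerical choices
made where the conventions of the field leave room.

## Task and data model

The package analyzes trial-aligned extracellular spike trains recorded while a
subject performs a two-alternative forced-choice multisensory discrimination:
six task cues — two tones (A3k, A10k), two visual stimuli (Vhz, Vvt), and two
matched audiovisual pairings (A3kVhz, A10kVvt) — each mapped to a left or
right response port, plus optionally two unmatched pairings (A10kVhz, A3kVvt)
whose components indicate opposite ports and for which either choice is
rewarded. A session is two CSV tables: one spike per row
(`neuron_id,trial_id,spike_time_ms`, times in milliseconds relative to cue
onset) and one trial per row (`trial_id,cue,choice,correct,reaction_time_ms`).
All windows are half-open `[start, end)` so adjacent windows partition the
epoch without double-counting boundary spikes. The recorded epoch defaults to
[−700, +1500] ms.

## PSTHs, normalization, responsiveness

PSTHs are binned at 10 ms, smoothed with a Gaussian kernel of σ = 50 ms
truncated at ±3σ and renormalized at the edges (dividing by the convolved
window function), so the smoothed curve preserves the spike-count integral and
does not droop at the epoch boundaries. Bins are converted to Z-scores using
the mean and SD of the smoothed rate in the 400 ms pre-cue baseline window; a
zero baseline SD is flagged as degenerate rather than producing infinities.

A neuron counts as responsive to a cue when its baseline-subtracted evoked
rate in the 0–300 ms window exceeds 2 spikes/s **and** the per-trial window
rates are significantly above the per-trial baseline rates (one-sided Wilcoxon
signed-rank, α = 0.05, no correction across cues). Categories follow the
response pattern: auditory-only, visual-only, AV (both unisensory),
AV-only (responsive only to the audiovisual pairing), unresponsive.
Responsiveness uses all trials of a cue; the selectivity, interaction, and
additivity statistics below use correct trials only, where the evoked
responses are most reliable. A whole-epoch mean-rate filter (≥ 2 Hz) gates
inclusion in population summaries; session-stability screening would require
recording metadata and is out of scope.

## ROC selectivity and the multisensory interactive index

Cue selectivity between two conditions is `SI = 2·(auROC − 0.5)` computed on
analysis-window (default 0–150 ms) spike counts. Two auROC estimators are
provided:

- `exact_rank` (default): the exact Mann–Whitney statistic,
  (wins + 0.5·ties)/(n_a·n_b) over all cross pairs, computed via ranks. It is
  deterministic, tie-exact, and the limit of any criterion-level construction.
- `discretized12`: 12 linearly spaced criterion levels spanning the pooled
  range; at each criterion the fraction of condition-A trials strictly
  exceeding it is plotted against the fraction of condition-B trials, and the
  area is taken by the trapezoid rule with (0,0) and (1,1) anchors. On
  Poisson-like count data the two estimators agree within 0.05 (and exactly
  when the samples take at most 12 distinct levels spanning the grid); the
  spacing rule for the 12 levels is otherwise under-determined, which is why
  `exact_rank` is the default.

Significance is a two-tailed permutation test (default 2000 permutations; one
source also cites 5000 resamples for the same figure family — both counts are
exposed in the configuration): trial labels are randomly reassigned between
the two conditions, SI recomputed, and the p-value taken as
`2·min(r_hi+1, r_lo+1)/(n+1)` so it is never exactly zero. For the rank
estimator the permutation null is computed in a fully vectorized form using
the invariance of pooled ranks under label reassignment.

The multisensory interactive index (MSI) applies the same machinery with
condition A = the audiovisual pairing and condition B = the **stronger**
unisensory component (higher mean analysis-window rate on correct trials;
ties break toward the auditory component, configurable). MSI > 0 with p <
0.05 is enhancement, MSI < 0 inhibition. Permutations reassign labels between
these two conditions only. The choice-split variant computes MSI separately
on correct- and incorrect-choice subsets, requires at least 9 trials per
choice for the pairing and both components (configurable), and fixes the
stronger component from correct trials so both indices compare the same pair
of conditions.

## Bootstrap additive-model test

For a pairing with components A and V, per-trial responses are
baseline-subtracted analysis-window rates on correct trials (the additive
model is applied to evoked activity so the baseline is not summed twice). A
benchmark distribution of predicted multisensory responses is built by
repeatedly drawing `min(n_AV, pool)` trials per modality and summing the two
draw means, optionally scaled by a coefficient; the observed multisensory
mean is then expressed as a Z-score against this benchmark
(default 5000 iterations).

Two numerical choices matter here:

1. **Resampling scheme.** Drawing the full pool without replacement would
   make every draw identical and the benchmark degenerate whenever
   `n_AV ≥ pool` — the common balanced-design case. The draw is therefore
   made **with replacement whenever it would span the whole pool** (the
   ordinary bootstrap), and without replacement only for genuinely smaller
   draws.
2. **Z denominator.** Both the benchmark and the observed mean carry sampling
   noise of the same order. Dividing by the benchmark SD alone would leave
   the observation's own standard error out and inflate the score by √2
   under true additivity (≈ 17% false flags at the 1.96 cutoff). The
   implemented score is
   `z = (observed − benchmark mean) / sqrt(benchmark SD² + observed SE²)`,
   which is approximately standard normal for an additive neuron (measured
   false-flag rate ≈ 5%). `|z| ≥ 1.96` classifies superadditive (positive)
   or subadditive (negative).

The scaling coefficient `ĉ = mean AV evoked / (mean A evoked + mean V
evoked)` quantifies sub-additivity directly; re-running the test with
`coefficient = ĉ` recenters the Z near zero (self-consistency).

## Pseudo-population decoding

Neurons (from one or more sessions) with more than 30 correct trials for both
cues of a contrast are combined into a pseudo population: per resample, 30
trials per cue are drawn per neuron without replacement and concatenated
across neurons with random within-class pairing — which destroys noise
correlations; the generator produces none, and the analysis assumes none.
Counts are taken in a 100 ms window stepped by 10 ms; a linear-kernel SVM
(unit cost, raw counts, no z-scoring) is trained and tested independently per
window under stratified 10-fold cross-validation; the resampling repeats 100
times and the mean ± SD across resamples is reported. Chance level comes from
refitting under shuffled trial labels (default 1000 iterations) at the single
most informative window — for balanced classes the chance distribution is
window-independent, and per-window nulls would multiply the cost by the
window count. The first-crossing statistic returns the earliest window center
whose mean accuracy reaches a level (default 0.9), without interpolation. The
all-pairs matrix applies the same machinery to a single 0–150 ms window for
every unordered cue pair, with 0.5 on the diagonal by convention.

## Population statistics

Paired comparisons (reaction times, selectivity, MSI across conditions) pass
through a normality gate: Shapiro–Wilk on the paired differences at α = 0.05
selects the paired t-test or the Wilcoxon signed-rank test; both the gate
p-value and the chosen test are reported, and an all-zero difference vector is
flagged degenerate rather than tested. Proportions of responsive neurons
between groups use an uncorrected Pearson chi-square on the 2×2 table
(continuity correction available by flag; no correction scheme is inferred
from published values, which do not pin one down). Correct rate is
100·(correct trials)/(scorable trials), excluding unmatched cues whose
correctness is undefined; reaction-time summaries use correct trials only.

## Synthetic sessions

The generator exists so every stage is testable without recordings. Spiking
is an inhomogeneous Poisson process with a piecewise-constant rate — the
analyses use only window counts, so no refractoriness or renewal structure is
modelled. Per neuron: a baseline rate (uniform 2–8 spikes/s by default);
evoked gains added from modality-specific latencies (auditory 20 ms, visual
50 ms — auditory leading, both configurable) for a 130 ms response duration;
and on audiovisual trials

    rate(t) = baseline + c_pair · (evoked_A(t) + evoked_V(t)),

with c = 1 additive, c > 1 enhancement, c < 1 suppression. The interaction
multiplies the summed evoked rates only, keeping baseline statistics
interaction-free. On incorrect-choice trials c shrinks toward 1 by a factor
in [0, 1] (`c → 1 + shrink·(c − 1)`), leaving unisensory responses unchanged
— the minimal mechanism for choice-dependent enhancement. An optional
audiovisual-only gain produces the small class of neurons responsive solely
to the combination.

Behavior: correct-choice probabilities default to 0.90 (multisensory) and
0.82 (either unisensory); reaction times are shifted lognormals whose default
parameters give means near 370 ms (multisensory), 430 ms (auditory) and
420 ms (visual); unmatched cues draw the choice fairly.

Presets bundle population statistics for the training conditions studied:
`trained_right_AC` (80% of tuned neurons prefer A10k/Vvt; interaction
c(A10kVvt) drawn from N(1.5, 0.25) truncated at 0, c = 1 elsewhere; error
shrink 0.5), its mirror `trained_left_AC`, `free_choice` (symmetric
preferences, all c = 1, chance-level behavior), `unisensory_trained` (mild
auditory preference only) and `unmatched_cues` (adds the unmatched pairings).
Preferred-cue gains are uniform on 6–14 spikes/s (auditory) and 4–10
(visual); non-preferred gains are zero with probability 0.7, else uniform on
0–4 / 0–3. These magnitudes put single-trial counts in the low-integer range
typical of 150 ms cortical windows while keeping effects recoverable at
30–40 trials per cue.

What the generator does **not** emulate: across-neuron noise correlations
(none are specified by the phenomena modelled, and pseudo-population assembly
destroys them anyway), non-Poisson spiking statistics, slow drifts or session
nonstationarity, and spike-sorting artifacts. Tests passing on this generator
therefore validate the estimators and their calibration — not robustness to
those features of real recordings.

## Problem sizes and determinism

The test suite and the acceptance script run everything from scratch at desk
scale: calibration suites use 400–2000 synthetic neurons with 300–2000
resamples per test, decoding checks use 20–50 neurons with 20 resamples and
200 label shuffles over a restricted time range, and the end-to-end trained
condition uses 120–200 neurons at 40–50 trials per cue with 500
permutations. All randomness flows through explicit NumPy generators seeded
from a single master seed (sub-seeds derived by a fixed counter scheme), so
repeated runs are bit-identical.

## Known limitations

- The discretized 12-level auROC can deviate from the exact rank statistic by
  more than 0.05 on adversarial two-point distributions; the agreement bound
  is a statistical property of count-like data.
- Permutation p-values are conditional on the observed counts; with very low
  rates and few trials the achievable p-values are coarse and the test is
  conservative.
- The additive-model Z assumes per-trial responses are exchangeable within
  condition; slow drifts would violate this.
- Decoding uses a fixed unit-cost linear SVM; no regularization search is
  performed, so absolute accuracies at small trial counts should be compared
  only within a fixed configuration.
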