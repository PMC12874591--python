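# Methods

## Session model and time base

All times are seconds as floating point on a per-session clock.  Windows
quoted in milliseconds in the literature are converted to seconds exactly
once, in the central epoch table (`session.EPOCHS`); every analysis stage
resolves window bounds through that table rather than re-deriving offsets.
Alignment windows are half-open `[start, end)`, so a spike on the shared
boundary of adjacent windows is counted exactly once.  Trials without a
water-port visit (no-go correct, go error) have their water-port fields
absent rather than carrying sentinel times; epochs anchored to absent events
resolve to a typed `Refusal`, which downstream stages treat as "condition
excluded", the same mechanism that implements the minimum-of-five-trials
inclusion rule.  Catch trials are excluded from behavioral accuracy because
they are unrewarded regardless of the animal's choice.  The drinking epoch
is analyzed from the water-valve opening to +1,000 ms; no lick-based
termination is modeled.

## Synthetic sessions

The generator's defaults are the study conditions: a 3 s inter-trial
interval, 500 ms odor presentation, 2 s response window, 300 ms pre-reward
wait, one catch trial in ten, behavioral accuracy 0.85, and nose-poke
durations drawn from log-normal distributions parameterized by the published
medians and interquartile ranges (927 ms, IQR 745–1,123 ms on go trials;
758 ms, IQR 660–910 ms on no-go).  The log-normal is fitted by
`mu = ln(median)` and `sigma = ln(q75/q25) / (2 z_0.75)` — positive support
and right skew are typical of reaction times, and the two printed quantile
summaries pin both parameters.  Pokes are clipped below at the odor duration
plus 20 ms (the animal must sniff the full stimulus); clipping the lower
~3–6% tail leaves the median untouched.  Go/no-go odors are assigned with
probability 0.5 among non-catch trials; the odor-port-exit-to-water-port
movement time is gamma distributed with mean 0.4 s, clipped to the response
window.  Error semantics: a go error is failure to enter the water port; a
no-go error is a false-alarm entry (water port entered, valve never opens);
catch-trial movement is a fair coin.

Four archetypes, with piecewise-linear rate profiles so thinning ceilings
and expected counts are exact:

* `go_cue_late` — baseline except a plateau from odor-valve closure to
  odor-port exit on go trials (50 ms linear edges).
* `waiting_phasic` — the same go-cue plateau plus a phasic bump after
  water-port entry (peak at +50 ms, back to baseline by +250 ms, i.e. before
  the valve opens).
* `drinking_ramp` — suppressed to half baseline while engaged in the trial,
  ramping up from 200 ms before valve opening, holding 250 ms into drinking,
  and decaying over a further 200 ms.
* `untuned` — constant baseline.

Baseline rates of 3–4 Hz and peaks of 18–20 Hz are conventions typical for
this cell class, not reproductions of measured values; they are
configurable.  Spikes are inhomogeneous Poisson by thinning against the
exact knot-wise ceiling.  Determinism: a `SeedSequence` spawns one child per
neuron plus one for behavior, so a seed reproduces a session bit-exactly and
neuron results are independent of neuron order.

What the generator does *not* emulate: bursting and refractoriness
(renewal-Poisson only), firing-rate drift, correlated noise across neurons,
spike-sorting contamination, or session-to-session variability.  Passing
recovery tests therefore demonstrates that the analysis chain is correct and
calibrated under Poisson variability at realistic rates and trial counts —
not that it is robust to every pathology of real recordings.

## Rate estimation

PETHs use 20 ms bins; smoothing convolves with a Gaussian kernel whose SD is
60 ms ("60 ms wide" is read as the SD, the common usage in this literature;
the width is configurable and no selectivity decision depends on it —
smoothed rates feed only displays and the GLM response).  The kernel is
truncated at the analysis window and renormalized by its in-window mass,
avoiding spurious rate dips at epoch edges.  Sliding counts use 100 ms
windows stepped by 20 ms, timestamped at window centers; the "0 ms" bin is
the window centered on the event.  The nose-poking analysis grid is bin
centers 0–1.8 s after odor onset: 91 bins.

## auROC selectivity

ROC area is computed from pooled midranks (Mann–Whitney U with half tie
credit).  The versus-baseline contrast compares each bin's per-trial 100 ms
counts against the same trials' 200 ms baseline counts scaled by 0.5, so
both samples have equal exposure.  Permutation significance reassigns values
to the two groups with group sizes preserved; one-sided p-values use the
add-one correction `(1 + k)/(1 + n_perm)` so p = 0 is impossible (negligible
against α = 0.01 at 1,000 permutations).  Excitation and inhibition are
tested separately, each at α = 0.01.  Because pooled midranks are invariant
under label permutation, a permuted auROC is a rank-subset sum; the
implementation evaluates all permutations of a batch of bins as one matrix
product and shares the block of permutations across the bins of a batch
(bins of one neuron, which already share ~80% of their data through
overlapping windows; each bin's marginal p-value is exact either way).
Fresh permutation blocks are drawn per neuron from a generator derived from
(session seed, neuron index).

On low-rate bins the test is conservative: spike counts are small integers,
ties are massive, and the attainable p-values are coarse, so the empirical
false-positive rate at α = 0.01 falls well below 0.01 (it reaches ~0.01 on
continuous data).  This is inherent to exact permutation tests on sparse
counts and is the safe direction for selectivity claims.

By default a trial stops contributing to bins whose center lies past that
trial's odor-port exit, so late bins are not contaminated by post-exit
activity, and bins retaining fewer than five trials are NaN (never
significant).  The population-matrix pipeline instead keeps every trial in
every bin (`exclude_after=None`) so that all 91 bins are defined for all
neurons — a complete-matrix requirement of the PCA stage.

Classification: ≥ 5 consecutive significantly excited bins in the go-correct
(or no-go-correct) versus-baseline series; if both qualify, the longer run
wins, ties broken by peak auROC (dual qualification has not been observed).
The center of mass averages significant bin times weighted by their auROC
values (an unweighted variant is available by flag); the qualifying run is
the maximal ≥ 5-bin block containing the significant bin nearest the center
of mass; duration is run length × step + (width − step); onset is the first
bin of the run.  Reward-epoch labels assign a neuron to waiting
(entry → valve) or drinking (valve → +1 s) by where its center of mass
falls in the water-port-entry-aligned series.

## Encoding GLM

Rows are 20 ms bins from odor onset to 500 ms after odor-port exit,
concatenated over go/no-go trials (catch trials carry no odor and are
skipped).  The six predictor groups use 25/25/22/13/15/15 binary lag
columns; the late-window lag counts (22 go, 13 no-go) are fixed at the
published architecture rather than recomputed per dataset — the generator's
poke medians make them consistent.  Early-exit trials are included with
predictor support truncated at the available rows.  Columns are z-scored
over all rows (never-active columns stay zero); the fit is ordinary least
squares with an unpenalized intercept, with a tiny-ridge fallback only on
rank-deficient designs.  R² is 1 − SSE/SST pooled over held-out bins with
5-fold cross-validation over trials (never bins) — this definition, not a
squared correlation, is what allows negative partial contributions to
arise.  Exclusion modes: zeroing the fitted coefficients (default),
refitting without the columns, and the zeroing rule on lasso fits (lasso
regularization path chosen by inner 5-fold CV on each training fold).
Contribution significance compares a variable's R² drop with the mean ± 2 SD
of drops from zeroing ⌈10% × 115⌉ = 12 columns drawn uniformly from all
columns, 1,000 times; the within-group reading of "10% of predictors" is one
flag away.  The pre-exit window-robustness sweep (100/200/300 ms → 5/10/15
lags) resets the generator state per setting so fold partitions are
identical and the comparison is paired.

## Population dynamics

The population matrix stacks each neuron's go and no-go versus-baseline
auROC series as a (182 × N) matrix (go bins first).  Neurons with refusals
or NaN bins are dropped, never imputed.  PCA is fitted on this nose-poking
matrix only (column-mean-centered SVD); component signs follow the
largest-loading-positive convention for cross-platform determinism.
Separation is the Euclidean distance between the two 3-component
trajectories per bin, thresholded at mean + 2 SD of distances obtained by
projecting a pre-odor baseline-window matrix (1.2–1.0 s before odor-port
entry, same pipeline) into the already-fitted subspace — the threshold must
live in the same coordinates as the distances it gates.  Distance in all
retained components jointly is the default (3 components; all-component
variant by argument).

## Decoding

Pseudo-trial k of each type concatenates every neuron's k-th correct trial
of that type from the start of its session; 40 trials per type.  The
classifier is a linear-kernel SVM with C = 1 (the conventional default; only
the kernel is dictated), 10-fold stratified cross-validation with seeded
shuffling, accuracy in percent, chance 50%.  The time course trains and
tests independently per 100 ms window and reports the first window reaching
the behavioral-accuracy reference; the population-size curve averages 20
random neuron subsets per size (SD over folds for the time course, over
subsets for the size curve).  Fold assignment precedes any window
computation; no preprocessing statistics cross the train/test boundary.

## Stability

Trial-order stability is the Pearson correlation between baseline-subtracted
go-trial nose-poking rates and trial order, compared with the 0.5th/99.5th
percentiles of 1,000 rate-sequence shuffles (a two-tailed 1% criterion).
The subtracted baseline is the neuron's session-wide mean inter-trial-
interval rate — a constant that cannot change the correlation, retained for
axis-convention comparability.  The covariate analysis correlates late-phase
rates with a per-trial covariate (e.g. sampling duration), pooled across
trials within neuron, with the parametric p of the Pearson coefficient;
Spearman is available by flag.

## Problem sizes and numerical choices

Recovery and calibration experiments run on sessions of 120–150 trials with
40–100 neurons — enough for ~45 correct trials per type and all per-bin
minimum-trial rules, and small enough that the entire test suite and the
reproduction script each complete in minutes on one CPU.  Permutation counts
follow the analysis conventions (1,000; 500 where only dynamics are
displayed; smaller in a few smoke tests that do not assert on p-values).
Tolerances: exact identities are asserted at machine precision; Monte Carlo
quantities at 3 standard errors of their estimator; qualitative shape checks
(separation onset, crossing times) assert on sustained ≥ 5-bin runs rather
than isolated bins, because neighboring sliding bins are strongly correlated
and isolated threshold crossings occur at the expected chance rate.

## Known limitations

* Relative contributions split shared variance between overlapping predictor
  groups (the late nose-poking and pre-exit windows overlap on typical
  trials); dominance statements are about the largest contribution, not
  about unique variance.
* The global-10% significance control tends to label truly-unsupported
  variables "negative" on strongly tuned neurons, because their drop is ~0
  while random controls mostly hit informative columns.
* Permutation p-values on very sparse bins are conservative (see above).
* The pseudo-population assumes independence across neurons from different
  sessions; within-session noise correlations are neither modeled by the
  generator nor exploited by the decoder.
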