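# odorgng

Analysis pipeline for single-unit electrophysiology recorded during the
odor-guided go/no-go task, aimed at systems/behavioral neuroscientists who
want the complete chain from event-aligned spike times to population-level
claims: sliding-window auROC selectivity with permutation significance,
response-shape measures, a lagged-predictor encoding GLM with relative
contributions, population trajectory analysis, pseudo-population SVM
decoding, and within-session stability tests.  A synthetic session generator
emulates the task timeline and canonical neuron archetypes, so every stage
can be exercised — and its calibration checked — without any recorded data.

## The task and the statistics

In the task, a mouse pokes an odor port, receives one of two odors for
500 ms, and holds its nose in the port (the *nose-poking epoch*, ending at
odor-port exit).  A go cue instructs movement to a water port, a 300 ms
*waiting epoch* there, and water delivery (*drinking epoch*); a no-go cue
instructs withholding.  One trial in ten is an odorless catch trial.

The core selectivity statistic is an ideal-observer measure: for each 100 ms
sliding bin (20 ms step), per-trial spike counts are compared with
exposure-matched baseline counts through the ROC area, rescaled as

    auROC = 2 (ROCarea − 0.5)  ∈ [−1, 1],

where ROCarea is the Mann–Whitney U statistic (half credit for ties) over
sample pairs.  Significance per bin and direction comes from a label
permutation test at α = 0.01, and a neuron is *go-cue selective* when its
go-correct versus-baseline series is significantly excited for ≥ 5
consecutive bins.  Significant series are summarized by the time of center
of mass, onset, and duration of the qualifying run.

The encoding model regresses the smoothed firing rate (20 ms bins, 60 ms
Gaussian kernel) on 115 binary event-lag predictors in six groups (odor
onset, late nose-poking, and pre-exit filters, each for go and no-go), and
each group's *relative contribution* is its normalized drop in 5-fold
cross-validated explained variance when excluded:

    (1 − R²ₚᵢ/R²_f) / Σⱼ (1 − R²ₚⱼ/R²_f),   negative terms clipped to 0.

Population analyses build a (2 conditions × 91 bins) × neurons auROC matrix,
project it onto three principal components, and threshold the Euclidean
go/no-go trajectory separation against baseline mean + 2 SD; decoding trains
a linear SVM on pseudo-population spike counts (40 trials per type, 10-fold
cross-validation) per sliding window.

## Worked example

```python
import numpy as np
import odorgng as og

task = og.TaskConfig(n_trials=150)
session, truth = og.simulate_session(
    task,
    [(og.DEFAULT_ARCHETYPES["go_cue_late"], 20),
     (og.DEFAULT_ARCHETYPES["untuned"], 20)],
    seed=8,
)
go = [t for t in session.trials
      if t.trial_type is og.TrialType.GO and t.outcome is og.Outcome.CORRECT]
nogo = [t for t in session.trials
        if t.trial_type is og.TrialType.NOGO and t.outcome is og.Outcome.CORRECT]
print(f"{len(session.trials)} trials ({len(go)} go-correct, "
      f"{len(nogo)} no-go-correct), accuracy {session.behavioral_accuracy:.3f}")

n_selective = 0
for i, train in enumerate(session.spikes):
    rng = np.random.default_rng(np.random.SeedSequence([8, i]))
    label = og.classify_cue_selective(
        og.sliding_auroc(train, go, rng), og.sliding_auroc(train, nogo, rng))
    n_selective += label.label == "go_cue_selective"
print(f"go-cue-selective neurons: {n_selective}/40")

train = session.spikes[0]
rng = np.random.default_rng(np.random.SeedSequence([8, 0]))
m = og.response_measures(og.sliding_auroc(train, go, rng))
print(f"neuron {train.neuron_id}: center of mass {m.center_of_mass:.3f} s, "
      f"onset {m.onset:.2f} s, duration {m.duration:.2f} s")

trials = [t for t in session.trials if t.trial_type is not og.TrialType.CATCH]
dm = og.build_design_matrix(train, trials)
res = og.relative_contributions(dm, np.random.default_rng(8))
top = ", ".join(f"{k}={v:.3f}" for k, v in
                sorted(res["contributions"].items(), key=lambda kv: -kv[1])[:3])
print(f"GLM R2 = {res['r2_full']:.3f}; top contributions: {top}")

pop = og.build_pseudopopulation([session], np.array([0.7]))
acc, _ = og.decode(pop.at(0), pop.labels, np.random.default_rng(8))
print(f"decoding accuracy at 0.7 s: {acc:.1f}% (chance 50%)")
```

prints

```
150 trials (44 go-correct, 63 no-go-correct), accuracy 0.793
go-cue-selective neurons: 20/40
neuron n000: center of mass 0.841 s, onset 0.44 s, duration 0.80 s
GLM R2 = 0.337; top contributions: go_late=0.663, pre_go_exit=0.310, go_early=0.023
decoding accuracy at 0.7 s: 73.8% (chance 50%)
```

All 20 late-phase go-cue neurons are recovered and none of the untuned ones
is flagged; the example neuron's excitation starts just before valve closure
(0.44 s, the window half-width ahead of the 0.5 s plateau onset) and its
encoding-model variance is dominated by the late go-cue nose-poking
variable, with the overlapping pre-go-exit filters picking up the remainder.

A `odorgng` command-line tool wraps the same pipeline
(`simulate`, `validate`, `selectivity`, `glm`, `decode`, `stability`).

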