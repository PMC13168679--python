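# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and what the package's tests do and do not establish.

## Task environment

The probabilistic selection task (PST) is implemented as two concurrent
two-armed discriminations: pair A/B with 80%/20% probability of "Correct"
feedback and pair C/D with 70%/30%. Within each training pair the two
probabilities are complementary by construction (validated at configuration
time). Training comprises 4 blocks × 60 trials; each block contains exactly
30 AB and 30 CD presentations in a uniformly shuffled order — no run-length
constraint is imposed, since none is specified for the task. Feedback is an
independent Bernoulli draw on the chosen stimulus's probability each trial.
The test phase presents each of the six unordered stimulus pairings (AB,
CD, AC, AD, BC, BD) four times, without feedback. Halves are defined as
blocks 1–2 (H1) and blocks 3–4 (H2). Left/right stimulus position is not
modelled; pairs are unordered because only choice identity is analyzed.

## Q-learning agent

Each stimulus i carries a value Q_i, initialized at 0.5 for all stimuli
(an uninformed prior midway between the two outcomes). After feedback
R ∈ {0, 1} on the chosen stimulus:

    δ = R − Q_chosen
    Q_chosen ← Q_chosen + α_gain·δ   if δ > 0
    Q_chosen ← Q_chosen + α_loss·δ   if δ < 0

A zero prediction error applies no update (either rate would give the same
result). For rewards in {0, 1} and rates in [0, 1], values provably stay in
[0, 1]. Only the chosen stimulus updates; there is no fictive update of the
unchosen option, no eligibility trace, and no perseveration kernel.

Choice probabilities over the presented pair come from a softmax. Two
exponent conventions are implemented because the literature uses both and
labels β inconsistently:

* `gain` (default): P(i) ∝ exp(β·Q_i). Larger β → more deterministic
  choice, which matches the behavioral interpretation of β as choice
  consistency.
* `temperature`: P(i) ∝ exp(Q_i/β). Larger β → *more* stochastic choice.

The default is the gain form; with the temperature form, β values near 4–5
combined with Q differences ≤ 0.6 would put choice probabilities within a
few percent of chance, which cannot produce the 80%+ training accuracies
the task reliably elicits. Test-phase choices are drawn from the softmax
over final Q values with no feedback and no updating; they are scored
behaviorally but never enter the likelihood.

Reaction times are needed for behavioral summaries but no standard RT model
exists for this task, so the generator uses a descriptive log-normal:

    log RT ~ N(log(900 ms) − 0.3·|ΔQ| − 0.4·(maxQ − 0.5), 0.25²)

plus a ×1.45 multiplier on test trials. The conflict term (|ΔQ|) makes
responses faster as discriminations are learned; the value term (maxQ)
makes high-value (approach) test pairs faster than low-value (avoidance)
pairs, reproducing the approach/avoidance RT asymmetry. These parameters
are descriptive conditions of the generator, not fitted quantities.

## Maximum-likelihood fitting

`QLearningModel` replays the update recursion deterministically over the
observed (choice, feedback) sequence from Q_init and sums the log softmax
probability of each observed training choice. The likelihood is maximized
by Nelder–Mead (Simplex) from 10 uniformly drawn starting points within
bounds α ∈ [0, 1], β ∈ [0.01, 20]; bounds are enforced by a logistic
transform so the simplex itself is unconstrained. A probability floor of
1e-12 inside the log keeps the objective finite at degenerate parameters.
Fits are deterministic given the seed. The replay loop is JIT-compiled with
numba when available; the pure-Python fallback is the identical function.

Goodness of fit is the likelihood pseudo-R² against a two-alternative
chance model, r = n·ln(½):

    pseudo-R² = (LLE − r) / (−r)

oriented so 0 is chance and 1 is perfect prediction (the raw (LLE − r)/r
form is negative for any above-chance fit because r < 0).

Two estimation facts worth knowing:

* On data from a zero-learning (coin-flipping) agent, the fitted NLL sits
  up to a few nats *below* 240·ln 2 — ordinary in-sample overfitting by a
  3-parameter MLE (≈ χ²(3)/2 nats), not a defect. The NLL *evaluated at*
  zero learning rates equals 240·ln 2 exactly.
* At 240 trials, recovery of α_gain is good (rank correlation ≈ 0.7 across
  a grid of generating values) and α_loss slightly better in this design;
  β is weakly identified and recovered with substantial bias. Asymmetric
  feedback frequencies limit identifiability at this trial count.

The brute-force grid oracle (`grid_min_nll`, default 11³ points) provides
an optimizer-independent lower-bound check: the fitted NLL must never
exceed the grid minimum.

## TD(0) backpropagation

A separate, deliberately minimal illustration of RPE migration (parallel
to, not coupled with, the Q-learning agent): a chain of k = 3 intra-trial
states (cue, response, pre-feedback) traversed once per trial, with a
Bernoulli(p = 0.8) reward on the transition out of the final state,
α_TD = 0.1 and γ = 0.95. Values start at 0 so the first rewarded feedback
yields a full positive RPE. The cue-onset RPE is the prediction jump from a
fixed zero-value pre-trial baseline, γ·V(cue). At the fixed point
E[V(cue)] = p·γ^(k−1) = 0.722, the feedback RPE's mean vanishes and the cue
RPE saturates — the backpropagation crossing. Block-averaged curves are
monotone up to Monte-Carlo noise once the feedback RPE has converged to
zero (seed-averaged tests allow 3e-3 of slack there).

## ERP generator

Each training trial yields one cue-locked and one feedback-locked epoch,
−200…600 ms. Components are Gaussian bumps (SD 25 ms) at the grand-average
peak latencies used for measurement: cue P200 170 ms / N200 285 ms / P300
490 ms; feedback P200 210 ms / N200 270 ms / P300 360 ms. The RewP shares
the N200 latency — that superposition is the point: on positive-RPE trials
the positive RewP partially cancels the negative N200, so valence effects
in the raw waveform are RewP effects in disguise. P200, N200 and RewP
project to channel "Fz", P300 to "Pz" (two channels, constant topography).

Per-trial amplitude drivers:

* feedback RewP: max(δ, 0) — the positive part of that trial's RPE;
* cue RewP: max(maxQ_pair − Q_init, 0) — the pair's acquired predictive
  value (a monotone proxy; no formula for "predictive value" is canonical);
* feedback P300: −log empirical frequency of the feedback category
  (the oddball effect: infrequent negative feedback → larger P300);
* everything else: fixed.

Noise is white Gaussian filtered to AR(1) with lag-1 coefficient 0.95 and
stationary SD 8 µV, approximating band-limited EEG after the usual
0.1–20 Hz filtering. The coefficient is applied per sample at whatever
sampling rate is in use (1000 Hz default; cohort simulations use 250 Hz
for speed — the measurement windows are rate-agnostic).

### Generator calibration

The µV-per-unit-RPE coupling has no empirical anchor, and the population
distribution of agent parameters is a modelling choice. They were set, in
order, by two design targets and then frozen:

1. **Behavioral realism.** Population parameters α_gain ~ TN(0.09, 0.08),
   α_loss ~ TN(0.05, 0.035), β ~ TN(5.0, 1.5; [1, 10]) reproduce the
   training-accuracy trajectory human PST cohorts show (~75% first half,
   ~82–85% second half; median-split rapid group near 90%, slow group near
   70%). Gradual value growth across the whole session is essential: with
   learning rates near the *fitted* means often reported for humans
   (α_gain ≈ 0.34), agents saturate within ~10 trials and no half-wise
   RPE⁺ difference remains for the ERP coupling to transmit. (Fitted rates
   overestimate the generative rates of sharp learners; the printed
   accuracy curve is the better generative target.)
2. **Detectability by design.** Given that population, the coupling gains
   (feedback RewP 20 µV, cue RewP 16 µV per unit driver) and the noise SD
   (8 µV) were sized from the measured signal/noise decomposition of the
   per-subject interaction contrast so that the Feedback × Half interaction
   is detectable (α = 0.05) in well over 80% of simulated cohorts of
   n = 73. The resulting synthetic ΔRewP values (≈ 3–4 µV) are of the same
   order as, though somewhat larger than, typical human effects.

### What the generator does *not* emulate

Real head-volume conduction and topography, ocular and muscle artifacts,
1/f spectra, latency jitter across trials and subjects, habituation of the
fixed components, and any coupling of negative RPEs to the ERP. Passing
tests therefore show that the *pipeline* correctly recovers a migration
that is present by construction — they are consistency checks of
measurement and inference, not evidence about human cortex.

## Measurement pipeline

Baseline correction subtracts the per-epoch, per-channel mean over
[−200, 0] ms (window endpoints inclusive throughout; a sample at t belongs
to [a, b] iff a ≤ t ≤ b). After correction the baseline mean is zero up to
floating-point summation residue (~1e-15; asserted at ≤ 1e-9). Artifact
rejection drops an epoch iff any channel exceeds ±100 µV anywhere (strict
inequality) or any consecutive-sample difference exceeds 50 µV at the
native sampling rate; rejection reasons are logged with amplitude taking
precedence. Epochs average within six conditions (cue × half; feedback ×
valence × half), with under-populated conditions flagged rather than
dropped. Windowed mean amplitudes use the ±25 ms windows around the peaks
listed above. ΔRewP difference waves are pointwise condition differences
(positive − negative within half; cue H2 − H1).

The 2×2 within-subject interaction is computed via the
difference-of-differences identity — a paired t on
(pos,H1 − neg,H1) − (pos,H2 − neg,H2) with F = t², df = (1, n−1) — which is
algebraically identical to the repeated-measures ANOVA interaction for this
design. Zero-variance contrasts are flagged degenerate instead of
producing meaningless statistics. Cohen's d is mean(diff)/sd(diff). No
multiple-testing correction is applied anywhere.

The learner median split labels subjects strictly above the first-half
accuracy median "rapid" and everyone else (including ties) "slow", so every
subject is labeled deterministically.

## Problem sizes used by the test suite

Chosen as the package's own verification scales: contingency checks at
100,000 draws (binomial SE ≈ 0.13 points); recovery at 200 fits across a
5×5 generating-alpha grid plus 200 agents per point for the group-ordering
check; TD convergence over 50–100 seeds × 1000 trials; cohort migration
over 50 seeded cohorts of 73 subjects at 250 Hz. The full suite runs in a
few minutes on one CPU.

## Known limitations

* β recovery is poor at 240 trials; comparisons of fitted β between groups
  on synthetic data should be interpreted with that in mind.
* The accuracy–α_gain relation is an inverted U: beyond the gradual-
  learning regime (α ≳ 0.3 at β = 5), higher gain rates *reduce* accuracy
  because single rewards on the suboptimal stimulus overshoot its value.
* The cue-value driver (maxQ − Q_init)⁺ is one reasonable proxy among
  several (e.g. softmax-weighted pair value); results are qualitatively
  insensitive to this choice but magnitudes are not.
* Epoch "800 ms" geometry is sample-count × interval; the last sample sits
  one interval before +600 ms, matching standard epoching conventions.
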