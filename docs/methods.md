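# Methods

`obslearn` implements a model-based analysis of observational
reinforcement learning: a two-deck card game in which a subject plays
one trial per round and then watches two other players, a normative
Bayesian account of how deck values are learned from all three players'
outcomes, behavioural regressions linking the model's latent terms to
choices and choice times, and a spike-train analysis that asks whether
single neurons encode the observational prediction error. Because the
clinical recordings this kind of analysis targets are never public, the
package ships a first-class synthetic-data generator whose outputs
carry the statistical structure every downstream stage assumes.

## Task model

A session is 12 games of 5 rounds; each round is one self-experienced
trial followed by two observed trials (180 card trials: 60 self, 120
observed). One deck wins with probability 0.7 and the other with 0.3;
at each game boundary the assignment flips with probability 0.5. Wins
and losses pay ±$10 or ±$100, equiprobable within sign. On every trial
the chosen card is highlighted for 1 s before the outcome is shown for
3 s, so outcome onset = choice onset + 1.0 s and offset = onset + 3.0 s;
all analyses anchor t = 0 at outcome onset. After the card game a slot
machine wins with probability 0.5; a win doubles the running total, a
loss halves it, and the total never goes below $0 (80 slot trials per
session by default, matching the ~79.6-trial average of ad-libitum
play).

The observed players' choice rule is not recoverable from the task
description (they were scripted agents); the generator exposes
pluggable policies, with uniform-random choice as the default and a
balanced "variance-seeking" alternation as an alternative. The first
game's good deck is assigned uniformly at random.

## Bayesian reversal-learning observer

The observer tracks q = P(left deck wins) on a discrete grid over
[0, 1], jointly with the reversal hazard v on its own grid (101 × 21
points by default; the joint prior is uniform). Because deck outcomes
are inversely related, one observation fully determines the trial's
contingency: the likelihood of a left-deck win (or right-deck loss) is
q, and 1 − q otherwise, so every trial — self or observed — updates the
belief. At each reversal opportunity the belief mixes with its mirror
image: mass(q, v) → (1 − v)·mass(q, v) + v·mass(1 − q, v). The default
applies this only at game boundaries, which is what subjects were told;
a per-trial hazard mode is provided because the model description
applies the transition "on trial t". The belief is never reset within
a session.

The marginal posterior mean of q is the expected value (EV) of the
left deck; the right deck's EV is its complement. Choice entropy
CE = −Σ p log₂ p over the EV pair measures decision difficulty
(0–1 bits). Choices follow a softmax over EVs with temperature τ,
estimated per subject by bounded 1-D maximum likelihood seeded from a
coarse log-spaced scan; fits at a search bound or with a flat
likelihood (ΔlogL < 2 to the random-choice limit) are flagged.
Prediction errors are obtained minus expected reward, in binary units
(win = 1) or dollars; the dollar scale multiplies EV by $55, the mean
winning magnitude, so a fully expected average win has zero error.
Grid note: with point masses on an endpoint-inclusive uniform grid the
posterior-mean discretization error is O(1/n_q); 101 points give ~3×10⁻³
after one observation and the conjugate-oracle comparisons use 1001
points to reach the 10⁻³ regime.

## Synthetic cohorts

`simulate_behaviour` re-runs the observer sequentially through a
session, drawing each self choice from the softmax at the current EVs
(τ = 0.2 by default) and its outcome from the true contingency, so the
emitted learner output is self-consistent with the simulated choices.
Choice time is intercept (1.0 s) + 0.4 s/bit × CE + 0.5 s on round 1 +
Gaussian noise (SD 0.3 s), truncated at 150 ms; the round-1 surcharge
deliberately confounds the CE slope the way first-round ignorance does,
which matters when interpreting slope recovery (see Calibration).

Spike trains are inhomogeneous Poisson: baseline rate (area defaults
2.51 / 1.72 / 2.28 Hz for AMY / rmPFC / rACC) plus event-locked
half-cosine bumps (onset 250 ms, duration 600 ms) scaled by planted
regressor values, thinned on a 2-ms grid with a 3-ms refractory floor.
Coding profiles: `null`, `outcome` (win/lose sign at outcome), `amount`
(signed dollars/100, with separate self and observed gains so same-sign
and opposite-sign populations can be built), `tripartite_PE` (+EV at
the observed choice, +amount and −EV at the observed outcome — the
temporal-difference signature), and `shadenfreude` (outcome sign
flipped between self and observed trials). Default tripartite gains
(5 / 3 / 5 Hz per unit regressor) were chosen so that a 22-of-138-unit
subpopulation is recoverable at the study's trial counts; true effect
sizes in real recordings are unknowable, so these defaults are for
testability, not fidelity. A default cohort is 31 sessions across 10
subjects with units assigned round-robin to sessions.

What the generator does *not* emulate: rate drift and unit instability,
bursting/refractory structure beyond a hard floor, correlated noise
across simultaneously recorded units, reaction-time distributions
beyond truncated-Gaussian, and any anatomical structure. Passing tests
therefore demonstrate that the analysis code recovers what it assumes,
not that real recordings satisfy those assumptions.

## Behavioural statistics

All group inference is a one-sample t-test across per-subject
coefficients (df = n_subjects − 1), one-tailed where the learning
account predicts a direction (positive EV-difference and PE effects;
positive = slowing for CE on choice time). Choice models are logistic
in the left-deck log-odds with V_L−R and CE as terms; subjects with
complete separation are flagged and excluded from the group test.
Choice-time models are linear. The lagged-outcome regression predicts
the self choice from win/no-win indicators per deck at lags 1–6; the
round structure makes lags 3 and 6 the subject's own outcomes and lags
1, 2, 4, 5 observed ones — asserted from the player column, never
assumed. It is fitted as a linear probability model, as described, with
a logistic variant behind a flag. Per lag we summarize the pro-choice
evidence weight (β_left − β_right)/2 and average it over the self and
observed lag sets; the lagged-PE variant replaces outcomes with the
most recent per-player prediction errors (lag 3 self; lags 1–2
observed; dollar units by default). Descriptive choice-time tests
(better vs worse deck, after observed win vs loss, left vs right,
coherent-outcome rank correlation, round ANOVAs) pool trials across
subjects by default, which matches the trial counts such tests are
conventionally reported with; a per-subject mode is available.

## Neural analysis

Firing rates are moving-average PSTHs: 300-ms windows stepped by 10 ms,
half-open [start, end) so an edge spike lands in exactly one window;
bin timestamps are window centers. The trial-wise GLM has nine
regressors — a main effect per player role plus that role's EV and
amount modulators, the modulators mean-centered within their trial type
so the main effects carry trial-type means (the design spans the
intercept, so none is added). Contrasts pool the observed players:
observed EV, observed amount, and observed PE = amount − EV. Per-bin
OLS t-statistics are computed from −1.0 to +1.5 s around outcome.

Cluster inference: consecutive mean-t values beyond ±0.2 are summed
into cluster masses;
the null rebuilds the selected-set mean 10,000 times (configurable)
from randomly drawn same-area units, each contributing one of its
label-shuffled GLM t-courses, and a cluster is significant when its
mass lies outside the sign-matched 99th percentile of the null extreme
masses. Positive and negative clusters are tested separately against
sign-matched nulls. Selection criteria: outcome-responsive units by a
one-tailed paired t-test between −900..−300 ms and 300..900 ms
(p < 0.01), or p < 0.05 with h ≥ 1, or h ≥ 1.5, where h is a pluggable
response-strength score; the packaged default is the mean pre/post rate
change standardized by its bootstrap SD, and any callable with the same
signature can be substituted. Amount-coding populations are
selected for a positive observed-amount effect in any post-outcome bin
(one-tailed p < 0.05/2) and then tested on the *self*-amount contrast,
which the selection never touched; tripartite candidates are selected
for a positive observed-EV effect during the choice window, leaving all
post-outcome contrasts selection-unbiased. The quartile check compares
upper vs lower PE-quartile rates bin-wise by non-overlapping s.e.m.,
with the population count tested against an empirically shuffled null
rate (the "chance" rate is not derivable analytically, so it is
estimated from PE-label permutations by default and config-overridable).
The model-free analysis contrasts early (rounds 1–2) vs late (rounds
4–5) wins per player and amount within each game, averaging over games;
round 3 never enters.

Slot-machine trials enter only the response-difference analyses, never
the GLM. The response window for window-averaged correlations defaults
to 300–900 ms.

## Calibration and numerical notes

* Problem sizes in the shipped tests: behavioural calibrations run
  1,000 null repeats on a 10-subject cohort; cluster-permutation
  calibration runs 1,000 null unit-sets at 1,000 shuffles each (the
  analysis default remains 10,000); recovery cohorts use the study's
  unit counts (138 rACC units with a 22-unit tripartite subpopulation,
  125/95-unit amount cohorts scaled to one area).
* The self-lag aggregate of the lagged-outcome regression is
  intrinsically conservative under the null: its lag-3/lag-6 regressors
  are functions of earlier values of the dependent choice series, whose
  small-sample dynamic-regression bias is negative (~−0.017 on the
  aggregate, ~1.5–2% rejections at α = 0.05). This is a property of the
  regression design itself; the calibration suite asserts nominal
  rejection rates for every other test and an anticonservatism bound
  for this one.
* Calibration of the lagged regressions is measured over freshly
  generated null sessions per repeat; conditioning on a single fixed
  design across repeats measures a conditional rate that can sit well
  away from the marginal one.
* The one-bin parametric selection step has inflated tails on low-rate
  Poisson data (skewed window counts against leveraged EV regressors),
  so null units are selected above the nominal rate; downstream cluster
  inference is immune because its null is built by label shuffling the
  same units. Planted subpopulations are still selected at a much
  higher rate than null units.
* The model-free early/late contrast is directional by construction
  (stochastic outcomes make some late prediction errors large), so its
  checks assert the sign pattern — positive observed difference,
  null self difference — rather than a significance threshold.
* Cluster-null calibration uses exchangeable smoothed Gaussian
  t-courses rather than full spike simulations: the test statistic
  consumes only t-course matrices, and exchangeability between the
  observed set and the shuffle pool is what the percentile criterion
  assumes; this keeps 1,000 repeats tractable.
* Degenerate inputs: constant predictors, constant PEs, zero-variance
  units, empty selections, missing win/lose cells and flat envelopes
  all raise or flag explicitly rather than propagating NaNs; ties at
  quartile/tercile boundaries are broken by stable trial order.
* Determinism: every stochastic routine takes a seed or Generator;
  cohort generation derives child streams from one root seed, and
  written manifests carry file checksums so reruns are verifiable.

## Known limitations

The observed-player policy, the h-coefficient, the envelope smoothing
kernel (Gaussian, 50 ms SD) and the amount-PE dollar scale are
documented choices where the procedure being modelled leaves the
detail open; all are config-exposed. The EV complementarity EV₂ = 1 − EV₁ is asserted
from the task's inverse outcome structure. No mixed-effects group
models, no alternative learners, no spike sorting, no anatomical
mapping, and plotting is out of scope.
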