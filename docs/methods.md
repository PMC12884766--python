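# Methods

`sferlab` analyzes the long-term evolution of hippocampal place fields
tracked across recording sessions. Its object of study is the binary
*field-state sequence*: a registered field is observed once per session
as active (1) or inactive (0), starting with 1 at its formation session.
This note documents the models the package implements, the synthetic
data it generates, and the numerical and design choices behind both.

## The evolution rule

Two empirical regularities summarize history dependence of single
fields:

* **Retention** — the probability that a field active for `t_a`
  consecutive sessions stays active rises with `t_a`, well described by
  a reciprocal curve `r(t_a) = 1 − L1/(t_a + b1)`.
* **Recovery** — the probability that a field silent for `t_i`
  consecutive sessions becomes active again falls with `t_i`, well
  described by a stretched exponential (Kohlrausch–Williams–Watts, KWW)
  curve `q(t_i) = a·exp(−(t_i/b)^c)`.

The general, recursive form of the rule tracks a latent re-expression
probability `P_t` per field:

    P_t = s_{t−1} · f(P_{t−1}) + (1 − s_{t−1}) · g(P_{t−1})

where `f` lies above the diagonal (an active state raises the
probability of being active next session) and `g` below it (an inactive
state lowers it). `P_2`, the probability immediately after formation, is
a single pooled constant: the mean of the second state over all
sequences of length ≥ 2.

### Counting rule for the hazards

Every position in a sequence with an observed successor contributes one
sample at the length of the run ending there, so a field retained for 5
sessions also counts as retained for 4, 3, 2 and 1; likewise for silent
runs. Duration bins with fewer than 5 samples are dropped. The retained
duration resets to 1 after each recovery (run-based counting). 95%
intervals on the empirical curves are Wilson intervals. Empirical curves
are *not* forced to be monotone; monotonicity is an empirical finding,
asserted only on calibrated synthetic cohorts.

The reciprocal form is implemented as `1 − L1/(t_a + b1)` — the bounded,
monotone reading of the fitted "reciprocal function" — with the
alternative reading `1 − L1/t_a + b1` available behind a flag.

## Synthetic cohorts

No public dataset accompanies this line of work, so every downstream
stage is exercised on synthetic cohorts whose defaults are the study
conditions themselves:

| parameter | default | meaning |
|---|---|---|
| `n_neurons` | 500 | neurons in the population cohort |
| `track_length_m` | 9.0 | linearized track length (m) |
| `gamma_shape`, `gamma_rate` | 5.3, 9.4 | per-neuron field propensity λᵢ ~ Gamma (fields/m) |
| `n_sessions` | 26 | tracked sessions |
| retention calibration | r(1)=0.525, r(8)=0.898 | pins the reciprocal curve |
| recovery calibration | q(1)=0.297, q(8)=0.035 | pins the KWW curve |
| `fluct_sigma` | 0.1 | SD of neuron-level day-to-day fluctuation |
| `step_noise_sigma` | 0.01 | SD of per-step noise on P_t |
| `gate` | 8 | consecutive silent sessions before permanent withdrawal |
| `initial_prob` | r(1) = 0.525 | P₂ |

Two points do not pin three KWW parameters; the stretch exponent is
fixed at `c = 0.8` (a typical stretched-exponential value) and `a`, `b`
then follow in closed form. Initial field counts are drawn as
`Poisson(λᵢ·L)`; with the Gamma defaults this yields ≈ 2537 fields for
500 neurons on 9 m, the scale the population cohort is built around.

The generator has two modes. **hazard** mode draws each transition from
the duration-based curves (a semi-Markov process — the direct embodiment
of the calibration). **sfer** mode runs the recursive rule; its default
link functions are linear least-squares fits to the one-step transition
pairs the hazard calibration implies (active-run, silent-run and
cross-transition pairs), computed deterministically at configuration
time. These induced links have the expected dual-attractor structure
(stable fixed points near 0.89 under `f` and 0.06 under `g`).

Missing entries are censored independently per cell at `missing_rate`,
never at the formation session (the censoring process itself is not
documented anywhere; independence is the neutral choice). Sequence
preparation in-fills a *single* missing entry flanked by active sessions
with 1 (runs of two or more missing entries are never in-filled), then
splits at remaining missing entries; each emitted segment starts at its
first active session.

The population cohort allocates fields to neurons, holds the number of
*active* fields constant at its initial value M₀ by injecting new fields
each session (assigned by the satiety multinomial, below), and adds the
neuron-level fluctuation to all sibling fields before clipping P to
[0, 1].

### What the generator does and does not emulate

It reproduces the statistical structure the analyses assume: sequences
beginning active, duration-dependent hazards, Gamma–Poisson multi-field
allocation, shared within-neuron fluctuations, censoring. It does not
emulate raw calcium dynamics, within-session (lap) structure, spatial
drift of field centers, or registration errors; passing tests on these
cohorts therefore validates the estimators and simulators, not the
upstream imaging pipeline.

## Model families

Ten families predict `P_t` from a sequence's history; all are trained by
negative log-likelihood (NLL), evaluated at a fixed step `t` over the
sequences long enough to reach it, with probabilities clipped at 1e−6:

* **VI equal rate** — one constant (MLE frequency).
* **I state-dependent rates** — constants `Pa`, `Pi` conditioned on the
  previous state.
* **II duration hazards** — the fitted reciprocal/KWW curves indexed by
  the current run duration; durations beyond the fitted range use the
  parametric curve (extrapolation), not the last empirical bin.
* **III HMM** — hidden states with a *fixed* emission ladder: the active
  emission of state i of N is `(2i−1)/(2N)`; the initial state is the
  one-hot ladder entry nearest P₂; only the transition matrix is
  learned, by Baum–Welch (tolerance 1e−6 on the log-likelihood, at most
  500 iterations, near-identity initialization with symmetric leak
  0.05). Predictions come from the forward filter. The forward pass is
  checked against hmmlearn to 1e−10 in the test suite.
* **IV recursive rule** — `f`/`g` as linear, logistic, quadratic or
  cubic polynomials (the decrement link is a polynomial in `1 − P`; the
  logistic pair is `f = σ(a₁P + b₁)`, `g = 1 − σ(a₂(1−P) + b₂)`).
  Updates are clipped to [0, 1]. The likelihood is non-convex, so
  fitting uses Nelder–Mead from 8 seeded starts (the first start at the
  identity maps).
* **V gated recurrent network** — a GRU (hidden size 8/16/32) over
  inputs `[s_t, P_t]` with a linear + sigmoid head, written in numpy
  with hand-derived backpropagation through time (gradient-checked
  against finite differences). Training: Adam, batch 2048, learning
  rate 0.001, at most 1000 epochs, early stopping with patience 100 on
  a 10% held-out slice of the training split. The probability fed back
  as an input is treated as a constant during backpropagation
  (stop-gradient); this stabilizes training and leaves the forward
  recursion unchanged.
* **VII–X logistic regressions** — on nine standardized per-field
  covariates (behavioral progression, training sessions, session
  interval, in-field time, peak rate, within-field stability, first
  lap, peak transient, center fluctuation), with the stated imputations
  for inactive sessions (stability → 0, center fluctuation → 0, first
  lap → last lap). VIII adds `s_{t−1}`; IX additionally adds `P_{t−1}`
  from a cubic recursive-rule fit (taken as 1 at the formation step,
  which is certain); X uses one covariate.

Evaluation uses k = 10 random 80/20 splits by default (model II refits
its hazard curves per fold). Cross-cohort transfer fits on one cohort
and evaluates on others, excluding the diagonal.

### Update-direction audit

The audit measures how often a model's consecutive predictions move in
the state-consistent direction (`P_t > P_{t−1}` after an active state,
`<` after an inactive one; ties count as violations). By default it
covers updates the model's dynamics produce — `P_4` vs `P_3` onward. The
very first update compares `P_3` against the shared constant `P_2`; for
an HMM with a one-hot initial state that comparison is state-independent
by construction (a degenerate posterior ignores its first observation),
so it reflects a boundary condition rather than the update rule.
`include_boundary=True` counts it anyway.

## The drift simulator

The stochastic discrete dynamical system: per session, each online field
draws `s ~ Bernoulli(P)`, updates `P` through `f`/`g` plus
`Normal(0, 0.01)` step noise, clipped to [0, 1]. A field silent for 8
consecutive sessions (counting the current one) is withdrawn at the end
of that session ("drifted"); with injection on, it is replaced the same
session by a fresh field at `(s = 1, P₂)`, keeping the online total
constant. Defaults simulate 10,000 fields for 200 sessions; plateau
statistics average the final 10% of sessions. The P-density uses 40 bins
on (0, 1]; peak tracking labels up to three local maxima ("new" near P₂,
"low", "high"). Fixed points of a link are bracketed roots of
`h(P) = P` on a 2001-point grid, stable when `|h′| < 1`.

A calibration note: with curves pinned only at durations 1 and 8 by the
printed values, the equilibrium drift rate of the fitted quadratic
system lands near 3–5% of online fields per session, above the ≈1%
equilibrium that the same procedure yields when the links are fitted to
real recordings. Simulating the
calibrated semi-Markov hazard process directly gives ≈3% as well, so the
gap reflects what the two calibration points leave unconstrained (the
retention tail beyond duration 8 and the shape between the pinned
points), not the fitting or simulation machinery.

## Coordination

Between consecutive sessions each field undergoes disappearance
`[1,0]`, formation `[0,1]` or retention `[1,1]` ([0,0] and missing are
excluded). Sibling pairs are same-neuron pairs with centers ≥ 50 cm
apart; the non-sibling baseline is an equal-sized random sample of
cross-neuron pairs. The chi-square statistic is

    χ² = N · Σᵢⱼ (P(eᵢ,eⱼ) − PᵢPⱼ)² / P(eᵢ,eⱼ)

with N the number of (unordered) pairs and the *observed* joint in the
denominator; zero-joint cells are skipped, and a flag switches to the
textbook expected-count denominator.
The residual matrix is `R = P(eᵢ,eⱼ) − PᵢPⱼ`; its diagonal measures
synchronization. A permutation null (event labels shuffled across
fields) provides p-values.

The two interaction mechanisms: a neuron's *satiety* for new fields is
`u = (1 − PoissonCDF(X; λL)) · λ` given its current count X, and new
fields are allocated multinomially with probabilities `u/Σu`; day-to-day
fluctuations add one `Normal(0, 0.1)` draw per neuron per session to all
sibling P values. In the synthetic cohorts every neuron is observed in
every session, so entries before a field's formation (and after its
withdrawal) are treated as inactive states for event classification —
otherwise assignment-driven formation synchrony would be invisible.

## Spatial toolkit

Scenes are 20 Hz trajectories with lap labels plus binary event tables
on a 48×48 grid of 2 cm bins. Events are deconvolved values above 3 SD;
frames slower than 2.5 cm/s are discarded. Rate maps divide event counts
by occupancy (bins under 50 ms are invalid) and smooth with a Gaussian
(σ = 2 bins) in *geodesic* (in-maze) distance, renormalized over
reachable valid bins so no mass crosses a wall; geodesic distances come
from shortest paths on the 4-connected bin graph with wall edges
removed. Spatial information is the Skaggs bits-per-event measure.
Place-cell classification requires the real SI to exceed the 95th
percentile of each of three 1000-sample nulls: circular temporal shift
(minimum 20 s — the minimum is not documented anywhere and is exposed as
a parameter), inter-event-interval shuffle, and random event placement.
Fields are connected components above 0.2 Hz with ≥ 5 events in ≥ 5
laps; components with several peaks are watershed-split and re-merged
whenever the saddle-to-peak ratio (saddle rate over the lower peak)
exceeds 0.5. Field-statistics fits (lognormal/gamma for sizes, negative
binomial for counts) use a parametric-bootstrap Lilliefors-corrected KS
test after downsampling to the reference sample sizes (1621 sizes, 500
counts).

The decoder is naive Bayes over per-bin Bernoulli event probabilities
with a *distance* loss: the decoded bin minimizes the
posterior-expected distance `D·p`, with D geodesic by default
(Euclidean optional). Accuracy is the per-lap median absolute error in
cm under rolling-lap cross-validation with 60% training laps.
Cross-session decoding downsamples shared neurons to 100 (5 resamples,
mean loss).

Registration links per-session fields across sessions at ≥ 75% bin-set
overlap, measured against the *smaller* field (the denominator is not
specified anywhere; `min` lets shrinking fields keep registering and is
configurable), then merges same-neuron registered fields whose summed
normalized rate profiles lack a deep saddle (ratio > 0.5). Chance
levels re-register after relocating each field uniformly within the
grid, preserving per-neuron field counts and sizes.

## Re-matching

Registration tools emit one index map (sessions × registered neurons,
0 = undetected) per reference session; defaults use references
(1,3,7,10,13) for 13-session runs and (1,3,7,10,13,17,20,23,26) for 26.
Per neuron, corresponding columns across maps (maximal session-position
agreement, ties by higher mean pairwise likelihood) form the candidate
matrix. An assignment J is scored by

    RS(J; α) = α · mean(pairwise same-cell likelihoods among detected
               sessions) + (1 − α) · (detected sessions / S),  α = 0.5

where the mean runs over non-missing upper-triangle likelihood cells
and contributes 0 when empty. Greedy coordinate ascent (at most 20
sweeps; only neurons with more than six detections) updates one session
entry at a time, never decreasing the score; changes are returned as
proposals for review. On toy instances the tests compare greedy against
the exhaustive optimum and require only that greedy never exceeds it —
greedy optimality is not guaranteed.

## Problem sizes and reproducibility

All randomness flows through explicitly seeded `numpy` generators;
seeded runs are bit-reproducible. Default analysis sizes — 10,000
sequences of 26 sessions for hazard estimation and model training,
10,000 fields × 200 sessions for simulation — run in minutes on one
core; the test suite exercises the same code paths at reduced sizes
(hundreds to a few thousand sequences, smaller grids and shuffle
counts) chosen so estimator variance stays within the asserted
statistical tolerances.

## Known limitations

* The KWW stretch exponent of the default calibration (`c = 0.8`) is a
  modeling choice; only two points of each hazard curve are pinned, and
  quantities sensitive to the unconstrained tails (notably the
  equilibrium drift rate) inherit that uncertainty.
* The GLM families model covariate effects as linear on the logit;
  interactions and nonlinear effects are out of scope.
* The HMM's fixed emission ladder and one-hot initial state make its
  first update state-independent (see the audit section).
* Registration operates on provided per-session field sets; footprint
  alignment and same-cell likelihood modeling are upstream of this
  package.
* No within-session (lap-by-lap) dynamics: the session is the atomic
  time step everywhere outside the spatial toolkit.
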