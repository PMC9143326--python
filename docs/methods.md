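# Methods

`replete` implements an offline reinforcement-learning pipeline for
electrolyte repletion in critical care: potassium (K), magnesium (Mg), or
phosphate (P) repletion decisions at 6-hour intervals are modeled as a
Markov decision process (MDP), a repletion policy is learned from logged
data by fitted Q-iteration (FQI), the reward weights implicit in logged
behavior are estimated by inverse reinforcement learning (IRL), policies
are compared off-line by fitted-Q evaluation (FQE), and the financial
footprint of learned versus historical repletion is priced by a
configurable cost model.  Because real hospital extracts cannot be
redistributed, a synthetic cohort generator supplies data with the
statistical structure the analysis assumes; it is first-class, tested code.

## The decision process

Each ICU visit is divided into half-open 6-h bins (a clinically actionable
cadence).  The state s_t is a numeric feature vector for bin t: the serum
electrolyte level, nuisance vitals and labs, demographics, and the previous
interval's repletion dose levels.  The action a_t comes from a discrete
per-electrolyte catalog of oral (PO) doses and intravenous (IV)
dose/duration pairs, plus all PO x IV combinations and the no-action
option — 28 actions for K, 20 for Mg, 16 for P.  The reward is a negated
weighted sum of four binary penalty indicators evaluated on the transition:

    phi(s, a, s') = (1[a has IV], 1[a has PO],
                     1[level' above range], 1[level' below range])
    R = -(w_iv, w_po, w_high, w_low) . phi

Weight vectors are L1-normalized; signs are unconstrained because weights
recovered from historical behavior can be negative.  A graded variant
(penalty proportional to the distance from the range bound) is available
behind `MDPSpec.graded_penalty` but binary indicators are the default: they
are the simplest form consistent with a four-condition weighted sum, keep
rewards bounded in [-1, 0] for non-negative weights, and make the weights
directly interpretable as relative priorities.

The discount factor defaults to gamma = 0.9, a standard choice for
horizons of ~30 six-hour steps (an 8-day maximal stay); it is configurable
and nothing in the package depends on this exact value.

Terminal handling: the last bin of a visit emits a terminal sample whose
target is the reward alone (no bootstrap).  Because no later measurement
exists, the terminal reward's range indicators are computed from the last
bin's own level; the action-cost indicators are unchanged.

## Preprocessing

* **Selection.** Adults (age strictly over 18), stays of 1-8 days
  (24-192 h inclusive), at least one recorded value of every required
  variable, an admission weight on file, and at least one repletion event
  of the target electrolyte.  Exclusions are attributed to the first failed
  filter, in that order, so the selection funnel is well defined.
* **Stay length.** The raw-table contract has no explicit discharge time,
  so the stay length is the ceiling of the latest event time; the synthetic
  generator always emits a vital in the final bin, making the inferred and
  true lengths equal on generated data.
* **Binning.** Within each half-open 6-h bin, values outside a per-variable
  plausibility range are discarded and the arithmetic mean of survivors
  fills the cell.  Medication rows belong to the bin containing their start
  time (an order placed in a bin is the action taken at that decision
  point).
* **Imputation.** Missing cells carry the most recent observation forward
  while that observation is at most 48 h old at the bin being filled
  (measured from the true observation, not from carried values, so carry
  chains cannot grow unboundedly); older gaps take the population mean of
  observed cells.  The population mean is computed on the training split by
  default.  The observed-cell mask is preserved so downstream analyses can
  distinguish measurements from imputations.
* **Dose encoding.** Free-form medication rows are snapped to the catalog:
  same-route rows in a bin are summed; PO totals snap to the nearest grid
  dose; IV totals snap by dose distance first, then duration distance; all
  ties break toward the lower catalog level.

## Policy learning (FQI)

FQI regresses bootstrapped targets y = r + gamma * max_a' Q(s', a')
(terminal: y = r) on [state || one-hot(action)] inputs, refitting a fresh
regressor each sweep.  The default approximator is an ensemble of extremely
randomized trees (60 trees, minimum leaf 40), the classical FQI choice; it
is pluggable via `regressor_spec`, and a `TabularRegressor` (exact
interpolation) exists for validating the loop against dynamic programming
on enumerable MDPs.

Two numerical choices matter in the clinical regime:

* **Analytic action-cost decomposition.** The route-cost part of the reward
  is a deterministic function of the action, and the Q-gaps it induces
  (~0.04 under the potassium training weights) are smaller than tree-leaf
  noise.  The fitted loops therefore subtract the known per-action cost
  from regression targets and add it back at prediction; the regressor only
  models the stochastic range-penalty dynamics.  With an exact regressor
  the decomposition is a no-op.
* **Tie-breaking.** The greedy readout breaks ties by catalog order with
  the no-action option first — do not treat on indifference.

Recommendations decode the flat greedy action hierarchically (replete? ->
route -> dose/duration) and expose all per-action Q-values for audit.
One Q-model spans the whole catalog (state plus one-hot action) rather than
one model per action: rare catalog actions would otherwise have too few
samples to fit on.

## Off-policy evaluation (FQE)

FQE iterates y = r + gamma * Q(s', pi(s')) for a fixed policy pi;
evaluating the logged historical policy substitutes the recorded next
action (the samples carry it).  Value comparisons (learned vs historical)
are computed on the identical test sample set.  Frequency comparisons are
state-matched — the learned policy is queried at historically visited
states — because the counterfactual trajectory after a deviation is
unknowable from retrospective data.  Pre/post-repletion distributions use
only genuinely measured cells (the observed mask), with the pre level taken
from the last observed bin at or before the order and the post level from
the first observed bin strictly after the bin containing the infusion end.

## Inverse RL

The four reward weights driving logged behavior are estimated by
apprenticeship-style feature matching on the penalty features.  A candidate
weight vector w is scored by learning the FQI-optimal policy under -w.phi
on the behavior samples and measuring the Euclidean gap between that
policy's per-step feature profile and behavior's on the same states.  The
profile's components are estimated with the sharpest applicable estimator,
identically for both sides so estimator bias cancels: the IV/PO components
are exact state-matched usage rates (the action-cost part of phi is
deterministic in the chosen action), and the above-/below-range components
are discounted exposures-to-go from a two-output FQE, scaled by (1 - gamma)
to per-step rates so all four components are commensurate.  No simulator is
needed, so the method works on real data.  Every proposal shares the same
inner regression seeds (common random numbers), so matching-error
differences reflect the proposals rather than seed draws.

Proposals start from a fixed symmetric grid: the simplex centroid plus, per
component, a moderately and a strongly dominant point (interior, because a
zero route cost makes repletion free and the induced policy is tie noise;
two dominance rings, because the induced policy depends on penalty-to-cost
*ratios* — how eagerly to treat — so the grid must span ratios, not just
orderings).  Remaining proposals follow the classical projection update:
the residual of projecting behavior's profile onto the convex hull of the
candidates' profiles.  The reported weights are the best-scoring proposal,
L1-normalized with signs unconstrained; convergence failure is flagged in
the diagnostics, never silent.  When behavior shows no penalty signal at
all (never repletes, never leaves the range) the weights are
unidentifiable and the diagnostics say so.  The definitional start-state
feature expectation (discounted sums averaged over visits) remains
available as `behavior_feature_expectations` / `policy_feature_expectations`
for diagnostics and reporting.

## Financial model

Each repletion event is priced as drug cost + per-task staff minutes times
role wages + attributed follow-up lab work; combination orders sum their PO
and IV components, and the no-action option costs nothing.  All prices are
configuration read from YAML; the shipped defaults are illustrative round
numbers for demonstrations and tests, not any hospital's or payer's actual
schedule, so every monetary output is config-dependent by construction.
Itemized components sum exactly to totals.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis needs, not
ICU physiology:

* **Dynamics.** Serum levels follow first-order mean reversion toward a
  healthy set point (a fraction `reversion_rate` of the gap closes per
  6-h bin) with additive, immediate dose response and Gaussian process
  noise.  Illness appears as rare, deep *depletion shocks* in the noise
  term (default: 6% of bins, a drop of ~2 mEq/L for K).  This shape is
  deliberate: shocks from any in-range level land below the range, so
  pre-emptively topping up an in-range patient cannot avert the penalty,
  while the dose grid can recover from any shock depth in about one bin —
  making "replete only when low" the optimal policy and giving learned
  policies a checkable ground truth.  A smooth low-attractor illness (the
  `illness_drift` parameter) is also available, but as the default it would
  make pre-emptive in-range repletion genuinely optimal, which defeats the
  generator's purpose as a test bed.
* **Behavior policy.** A threshold rule: below the repletion threshold an
  order is placed unless missed (10% miss probability by default — logged
  data needs some "no action while low" coverage for the below-range
  penalty to be identifiable offline, and missed lows are a documented
  feature of provider-driven care); at or above threshold an order is
  placed with the configurable over-repletion probability.  Routes are IV
  with probability 0.25, otherwise PO; 5% of orders add the other route's
  component (a PO+IV combination); IV dose tiers are uniform over the
  catalog so logged data covers the full action space, which offline
  learning requires.
* **Sampling.** Electrolyte labs appear with probability
  `measurement_prob` per bin and report the true level at the bin start;
  nuisance vitals/labs are stationary noise around plausible means, missing
  with probability `missing_prob_vitals` — their irrelevance is something
  the learner must discover.  Visit lengths are uniform over whole bins
  from 18 h to the horizon (some below the 24-h cohort floor, so the
  exclusion funnel is exercised); a few visits have a missing admission
  weight or age under 19 for the same reason.
* **What it does not model.** Multi-electrolyte coupling, outcome/mortality
  processes, assay error, inter-hospital practice variation, or any
  distributional property of real hospital systems.  Tests passing on this
  generator show the *algorithms* behave as specified under known ground
  truth; they are not evidence about real cohorts.

## Validation experiment design

* **Exact checks.** On random deterministic finite MDPs with full
  state-action coverage and the exact-interpolation regressor, k FQI sweeps
  equal k value-iteration backups to machine precision and FQE equals the
  linear-solve policy evaluation; greedy policies match the optimal ones.
* **Monte-Carlo check.** FQE of the behavior policy on its own logged
  rollouts is compared with the mean discounted Monte-Carlo return of the
  same trajectories; agreement is required within 0.05 of the return scale
  1/(1-gamma), i.e. 0.5 at gamma = 0.9.
* **Weight recovery.** Behavior data are 2,000-visit rollouts of the
  FQI-optimal policy under known weights, softened with 10% lazy
  exploration (the action is skipped) plus 5% uniform dose exploration:
  a purely deterministic demonstrator leaves no "no action while low"
  coverage and makes every candidate reward observationally equivalent.
  Recovery is scored by the cosine similarity between the estimated and
  generating weight vectors, median over 5 seeds.
* **Policy sanity.** A full pipeline run on a 2,000-visit default cohort
  checks the directional claims: the policy recommends no action in at
  least 95% of above-range states, recommends fewer repletions than the
  over-repleting behavior, and scores a higher mean FQE value.

Problem sizes in the shipped tests (visit counts, rollout horizons of
10-20 bins, forest sizes) are chosen so the whole suite validates every
claim at desk scale; all are parameters, and larger runs only tighten the
same estimates.

## Known limitations

* FQE and FQI inherit the usual offline-RL caveats: values extrapolate at
  state-action pairs the behavior policy rarely visited, and the value
  comparison between policies shares this optimism.  The package reports
  state-matched frequencies and value gaps, not causal treatment effects.
* IRL identifiability is limited by the behavior data: distinct weight
  vectors that induce the same optimal policy cannot be distinguished, and
  the recovered vector is the best-matching member of that equivalence
  class.
* The 48-h LOCF window, the medication-to-bin rule, and the first-failed
  exclusion attribution are conventions; alternatives are defensible and
  all are configurable.
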