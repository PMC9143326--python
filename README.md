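# replete

Offline reinforcement learning for electrolyte repletion in critical care.

Serum potassium, magnesium, and phosphate have narrow therapeutic ranges,
yet ICU repletion practice is reactive and frequently orders replacements
while the level is already within or above range.  `replete` treats the
repletion task as a Markov decision process on 6-hour decision intervals
and learns, from logged EHR data alone, a policy that repletes when — and
only when — the patient needs it:

* **cohort**: long-format EHR tables → exclusion funnel → half-open 6-h
  binning with outlier filtering → 48-h last-observation-carried-forward /
  population-mean imputation → train/test split.
* **mdp**: per-electrolyte discrete action catalogs (oral doses,
  IV dose/duration pairs, combinations; 28/20/16 actions for K/Mg/P), and
  the four-term penalty reward
  `R = -(w_iv, w_po, w_high, w_low) . phi(s, a, s')` over binary indicators
  for IV use, PO use, and above-/below-range excursions of the next level.
* **policy**: fitted Q-iteration (FQI) with a pluggable regressor
  (extremely randomized trees by default), greedy readout with a
  do-not-treat-on-indifference tie-break, and hierarchical recommendations
  (replete? → route → dose/duration) with per-action Q-values for audit.
* **irl**: inverse reinforcement learning — apprenticeship-style feature
  matching over the four penalty components — to estimate the weights
  implicit in historical behavior.
* **evaluation**: fitted-Q evaluation (FQE) of learned and historical
  policies on the identical test set, state-matched action-frequency
  comparison, pre/post-repletion level distributions, and per-visit
  trajectory overlays.
* **finance**: config-driven costing (drug, staff time × wages, follow-up
  labs) of historical versus recommended repletion.
* **synthetic_ehr**: a seeded generator of ICU cohorts with mean-reverting
  electrolyte dynamics, depletion shocks, a threshold-driven over-repleting
  behavior policy, and realistic missingness — the test bed that stands in
  for restricted hospital data.

The model and the validation experiments are described in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate a 2,000-visit potassium cohort, learn a repletion policy, and
compare it with the simulated clinicians (who over-replete 30% of the time
at in-range levels):

```sh
replete run-all --seed 1 --out runs/demo
```

or in Python:

```python
from replete import PipelineConfig, run_pipeline
run_dir = run_pipeline(PipelineConfig(output_dir="runs/demo", seed=1,
                                      n_visits=2000, fqi_iterations=6,
                                      fqe_iterations=12))
```

The run directory then contains, among other artifacts,
`frequency_report.json` and `fqe_report.json`:

```
repletion_change_pct : -30.0      # the policy orders 30% fewer repletions
learned_mean_q       : -0.506     # mean estimated Q on test state-action pairs
behavior_mean_q      : -0.603     # clinicians score lower under the same reward
```

Negative Q-values are accumulated discounted penalties (range excursions
and route costs), so less negative is better: the learned policy both
treats less often and is expected to collect fewer penalties, because it
stops repleting patients who are already in or above the reference range
while still treating every genuinely low level.  `pre_post_report.json`
shows the behavior signature being corrected — most historical orders were
placed at within-or-above-range levels — and `finance_report.json` prices
the difference per visit under the configurable cost model.
`replete report runs/demo` renders the standard figures (pre/post
distributions, dosage-frequency shift, trajectory overlay, Q-value
comparison) from the report files alone.

A single state can be queried against a saved policy:

```sh
replete recommend --policy-dir runs/demo/policy --state-csv state.csv
```

which prints a JSON recommendation (route, dose, infusion duration, and
all per-action Q-values).

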