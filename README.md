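# twostep

Simulation and analysis toolkit for the two-stage sequential Markov decision
task used to dissociate model-free (habitual) from model-based (goal-directed)
control, including a within-subject dietary-intervention study design.

The package covers the full behavioural pipeline:

* **`twostep.task`** — generative task environment: 70/30 transition
  structure, Gaussian-random-walk reward probabilities reflected at
  [0.25, 0.75], 201-trial sessions, optional missing trials.
* **`twostep.agent`** — the seven-parameter hybrid reinforcement-learning
  agent (β1, β2, α1, α2, λ, ω, π): SARSA model-free learning with
  stage-skipping eligibility, model-based planning over the known transition
  matrix, and an ω-weighted softmax choice rule with perseveration.
* **`twostep.cohort`** — synthetic cohort generator: subjects × three
  interventions (ATD / BAL / ATL) in randomized cross-over order, subject-level
  parameter heterogeneity, optional intervention effects on any parameter
  (applied on unconstrained scales), per-subject trial missingness, and
  four-timepoint blood tryptophan/ΣLNAA ratio series.
* **`twostep.fitting`** — per-session maximum-likelihood estimation
  (multi-start L-BFGS-B in an unconstrained parameterization), a brute-force
  likelihood oracle, and a simulate-then-refit parameter-recovery audit.
* **`twostep.stats`** — stay-probability factorial statistics (reward ×
  transition cells, MF and MB scores), the >30%-missing exclusion filter, and
  a one-way repeated-measures ANOVA with partial eta squared, applied to every
  behavioural outcome.
* **`twostep.blood`** — tryptophan/ΣLNAA ratio (threonine, lysine, methionine
  excluded from the sum), baseline-normalized trapezoidal AUC over hours
  (0, 1, 3, 6.5), and the intervention ANOVA on AUC.
* **`twostep.cli` / `twostep.io`** — TSV/JSON pipeline binding it all.

## Command-line pipeline

```sh
# 1. simulate a cohort (98 subjects x 3 sessions x 201 trials by default)
twostep simulate-cohort --out-dir scratch/cohort --seed 1 --n-subjects 24 \
    --effect ATL:omega:0.5        # optional intervention effect on a parameter

# 2. fit the hybrid model to every subject-session
twostep fit scratch/cohort/trials.tsv --out scratch/fits.tsv --restarts 10 --seed 1

# 3. factorial + model-parameter + blood ANOVAs
twostep analyze --trials scratch/cohort/trials.tsv --fits scratch/fits.tsv \
    --blood scratch/cohort/blood.tsv --out-dir scratch/analysis
twostep report scratch/analysis/analysis_report.tsv

# extras
twostep stay-analysis scratch/cohort/trials.tsv --out scratch/stay.tsv
twostep recover --out scratch/recovery.tsv --n-subjects 50 --seed 1
```

## Notes

* All randomness flows through `numpy.random.Generator`; identical seeds give
  byte-identical outputs, end to end.
* Missing trials are encoded as `NA` in the TSV dialect; trial pairs spanning
  a missing trial are excluded from stay-probability cells, and missing trials
  freeze the agent state in both simulation and likelihood.
* The random-walk step SD (0.025) and uniform initial reward probabilities
  are configurable conventions; fitted parameters are reported on their
  natural scales.
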