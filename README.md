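# revlearn

Instructed probabilistic reversal learning, end to end: a generative task
simulator, Bayesian hidden-Markov and model-free reinforcement-learning
agents, per-subject model fitting with BIC comparison, the task's
behavioural statistics, and ERP component quantification (FRN, SPN, P3,
P1, N1) exercised on synthetic EEG.

## Who this is for

Computational cognitive neuroscientists studying how explicit instruction
(about environment volatility or feedback reliability) interacts with
trial-and-error learning. The package lets you simulate the task designs,
generate agent behaviour with known parameters, recover those parameters by
fitting, compute the behavioural measures, and validate ERP quantification
pipelines against closed-form synthetic ground truth — all without any
recorded human data.

## The task and the models

In each block a learner must discover which of two stimulus-response
mappings is correct, from feedback that matches the rule-correctness of the
response only with probability ρ (the feedback reliability, e.g. 0.75). A
single unannounced reversal of the correct mapping may occur mid-block. A
pre-block instruction manipulates beliefs: volatility vs stability
(experiment 1: reversals in 2/3 vs 1/3 of blocks, reversal at the block
midpoint, trials 13/17/21), or instructed feedback reliability
(experiment 2: ρ ∈ {0.875, 0.75, 0.625}, reversals in 3/4 of blocks at
trial 9/17/25).

**Bayesian hidden-Markov observer.** The hidden state s_t (which mapping is
correct) reverses with per-trial hazard h; feedback is an emission matching
rule-correctness with probability ρ. The observer tracks the posterior
p_t = P(applied mapping correct | feedback so far):

    transition:  p ← p(1−h) + (1−p)h
    update:      p ← pL / (pL + (1−p)(1−L)),  L = ρ (positive) or 1−ρ (negative)

and logs the surprise I = −log₂ of the predictive probability of each
feedback and the belief entropy H(p) = −p log₂ p − (1−p) log₂(1−p), both in
bits. It abandons its mapping when the belief both disfavours it (p < 0.5)
and has resolved (H ≤ α). The entropy-aversion threshold α is a single
value in the instruction-blind variant and instruction-specific (α_v, α_s)
in the instruction-sensitive variant; larger α means earlier switching.

**Model-free control.** A Rescorla-Wagner learner (δ = r − q,
q ← q + ηδ, η = 0.5, rewards 1/0) replayed over logs provides
instruction-blind reward-prediction errors.

**Fitting.** The belief filter is replayed on a subject's observed choices
and feedback (so the trajectory is α-free); α is grid-searched at 0.01
resolution on [0, 1] against a lapse-Bernoulli likelihood with the lapse
rate ε profiled analytically. Variants are compared per subject with
BIC = k ln n − 2 logL, summed over subjects.

## Worked example

Simulate 28 instruction-sensitive subjects at the fitted group means
(α_v = 0.7, α_s = 0.52, 5% lapses) on the 36-block design, then refit:

```python
import numpy as np
import revlearn as rl
from revlearn.agents import AgentParams
from revlearn import fitting

params = AgentParams(alpha_v=0.7, alpha_s=0.52, epsilon=0.05)
log = rl.simulate_group(rl.exp1a_config(), params,
                        "instruction_sensitive", n_subjects=28, seed=1)
summary = rl.behaviour_summary(log).groupby("instruction").mean(numeric_only=True)
print(summary[["accuracy_pre", "accuracy_post", "ttr_post"]].round(2))

fits_s = fitting.fit_subjects(log, "instruction_sensitive")
fits_b = fitting.fit_subjects(log, "blind")
print("recovered alpha_v = %.3f, alpha_s = %.3f"
      % (np.mean([f.alpha_v for f in fits_s]),
         np.mean([f.alpha_s for f in fits_s])))
print("mean %% correctly predicted = %.1f"
      % np.mean([f.pct_predicted for f in fits_s]))
comparison = fitting.compare_models(fits_b, fits_s)
print("group delta BIC = %.1f (%s)"
      % (comparison.delta_bic_group, comparison.verdict))
```

Output:

```
             accuracy_pre  accuracy_post  ttr_post
instruction
stability           81.01          60.05      7.61
volatility          81.51          64.02      7.06
recovered alpha_v = 0.689, alpha_s = 0.516
mean % correctly predicted = 95.1
group delta BIC = 1332.3 (strong evidence for instruction-sensitive)
```

Reading this: pre-reversal accuracy is matched across instructions (the
design premise), while the more entropy-averse volatility setting adapts
faster after reversals (higher post-reversal accuracy, fewer
trials-to-repetition). The grid search recovers the generating thresholds
to within ~0.01–0.02, the fitted model predicts ~95% of choices (the
remainder is mostly the 5% lapse rate), and the BIC comparison correctly
identifies the instruction-sensitive generator.

The same pipeline is available from the shell:

```
simulate-behaviour --config exp1a --agent hmm_sensitive --subjects 2 --seed 5 --out log.tsv
fit-models --log log.tsv --variant both --out fits.json
behaviour-stats --log log.tsv --out behaviour.json
simulate-eeg --log log.tsv --seed 2 --out epochs
quantify-erp --epochs epochs --component frn --out frn.json
```

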