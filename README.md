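# surpriserl

A toolkit for modelling how **surprise devalues decision outcomes** in
human reinforcement learning. It is aimed at computational cognitive
scientists who simulate, fit and compare trial-by-trial choice models
on bandit-style tasks.

## The model

In standard Q-learning, the value of the chosen option is updated by the
reward prediction error δ(t) = r(t) − Q(t):

    Q(t+1) = Q(t) + α′ · (r(t) − Q(t)),      α′ = α + 0.5 / (1 + T_s)

where α′ carries a decaying bonus driven by T_s, the number of times
the stimulus's outcome has been experienced. The **surprise-sensitive
utility model** posits that surprise — the absolute prediction error,
regardless of valence — reduces the subjective value of the outcome:

    S(t) = r(t) − d · |r(t) − Q(t)|
    Q(t+1) = Q(t) + α′ · (S(t) − Q(t))

with surprise decay rate d ∈ [−1, 1]. Choices follow a softmax with
inverse temperature β: P(a = i) ∝ exp(β·Q_i). A risky option generates
frequent surprises, so agents with d > 0 become risk averse; after a
*surprising* reward they are also less likely to repeat their choice.

The package implements this model alongside its three classical
comparators — plain Q-learning, the nonlinear-utility model
(U(0)=0, U(20)=20, U(40)=a·20) and risk-sensitive Q-learning (separate
learning rates α⁺/α⁻ for positive/negative prediction errors) — plus:

* the three tasks used to study them: a 234-trial risky probabilistic
  learning task (mixed forced/choice trials over five payoff machines),
  Bernoulli two-armed bandits and a four-armed Gaussian bandit
  (`surpriserl.tasks`, presets `risk234`, `bandit2`, `gauss4`);
* agent simulation and behavioral summaries: probability of the sure
  choice, reward-history-conditioned stay probability, choice rates
  (`surpriserl.simulate`, `surpriserl.experiments`);
* per-subject MAP fitting under the standard priors (Beta(2,2) on
  learning rates, Gamma(2, scale 3) on β, uniform on a and d) with
  Laplace-approximated log model evidence (`surpriserl.fitting`);
* random-effects Bayesian model selection: variational Dirichlet over
  population model frequencies, exceedance probabilities, Bayes omnibus
  risk and protected exceedance probabilities
  (`surpriserl.model_selection`);
* synthetic cohorts with known parameters for parameter- and
  model-recovery studies (`surpriserl.cohort`).

See `docs/methods.md` for the full model account, the simulation
conditions, and numerical details.

## Worked example

Reproduce the reward-history signature that separates the surprise
model from Q-learning on a 0.8/0.2 two-armed bandit:

```python
from surpriserl import (ModelParams, build_bernoulli_bandit,
                        simulate_agent, stay_probability_table, map_fit)

task = build_bernoulli_bandit(p=(0.8, 0.2), r=(1.0, 1.0), n_trials=500)
models = {
    "qlearning": ModelParams("qlearning", alpha=0.3, beta=2.0),
    "surprise": ModelParams("surprise", alpha=0.3, beta=2.0, d=0.5),
}
for name, params in models.items():
    sessions = [simulate_agent(params, task, seed, decay=False)
                for seed in range(200)]
    print(name)
    print(stay_probability_table(sessions)[["stay_prob", "sem"]].round(3))
```

```
qlearning
                  stay_prob    sem
label
r(t-1)=0, r(t)=0      0.433  0.004
r(t-1)=0, r(t)=1      0.744  0.003
r(t-1)=1, r(t)=0      0.449  0.003
r(t-1)=1, r(t)=1      0.779  0.002
surprise
                  stay_prob    sem
label
r(t-1)=0, r(t)=0      0.430  0.004
r(t-1)=0, r(t)=1      0.682  0.003
r(t-1)=1, r(t)=0      0.420  0.003
r(t-1)=1, r(t)=1      0.734  0.003
```

Both models mostly stay after a rewarded trial (r(t) = 1 rows), but the
surprise model stays less, and the deficit is largest after a
*surprising* reward (r(t−1) = 0, r(t) = 1: 0.682 vs 0.744) — the
reward was devalued by the prediction error it carried. Refitting the
surprise model to one simulated agent recovers its parameters:

```python
sess = simulate_agent(models["surprise"], task, seed=0, decay=False)
fit = map_fit("surprise", sess, seed=1)
print(fit.params_hat.to_dict(), fit.log_evidence)
```

```
{'model_name': 'surprise', 'alpha': 0.263, 'beta': 2.178, 'd': 0.676} -309.5
```

(the generating values were α = 0.3, β = 2, d = 0.5; single-session
estimates carry sampling noise, and cohort-level recovery correlations
are ≈ 0.9, see `surpriserl.cohort.recovery_experiment`).

The same workflows are scriptable from the shell:

```bash
surpriserl cohort --model surprise --task risk234 --n-subjects 16 --seed 1 --out cohort.csv
surpriserl fit --sessions cohort.csv --task risk234 --seed 1 --out fits.json
surpriserl bms --evidence fits.json.evidence.csv --seed 1 --out bms.json
surpriserl experiment stay-compare --n-agents 1000 --out stay.csv
```

Every command writes a `<out>.config.json` with the resolved
configuration so any artifact can be regenerated from it alone.

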