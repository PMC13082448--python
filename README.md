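# risktransfer

Lung cancer is most common in middle-aged and older adults, and its risk is
not static: smoking behaviour changes — quitting, staying quit longer,
smoking less — move a person between risk levels over the years. This
package models that process end to end for longitudinal survey cohorts
(biennial follow-up waves of the HRS/CHARLS kind): it stratifies subjects
into four ordered risk states (high, medium, low, non-risk) with a neural
weight score, fits a risk-transfer Markov decision process over those
states, trains a deep Q-learning agent to find the behavioural pathway that
most reduces lung-cancer incidence, and evaluates pathways by simulated
incidence decline and Kaplan-Meier survival. It is written for
epidemiologists and biostatisticians who want a fully testable, simulation-
backed implementation of this modelling chain: because real survey extracts
are access-controlled, the package ships a synthetic-cohort generator with
*known* risk dynamics, so every stage can be checked against ground truth.

## Model

**Risk stratification.** A feed-forward rectifier network (56 inputs, three
hidden layers of 22 units, one output) maps each subject-wave's covariates
x to a weight score y = f(x, θ) = f_{L−1}(W_{L−1} f_{L−2}(⋯ f_1(W_1 x + b_1))
+ b_{L−1}), with f(z) = max(z, 0) and a logistic squash at the output so
y ∈ [0, 1]. Year-specific thresholds partition the score: for 1992,
non-risk [0, 0.2), low [0.2, 0.5), medium [0.5, 0.71), high [0.71, 1].

**Risk-transfer MDP.** States are the four strata plus an absorbing
lung-cancer state; actions are transfer strategies (risk maintenance,
extending smoking-cessation duration to 1/3/>5 years, reducing smoking
frequency everyday→someday, someday→quit, everyday→quit). Transition
probabilities per 2-year cycle are estimated from stratified wave pairs by
additively smoothed maximum likelihood. The reward r (the *transfer
effect*) is +1 per level of risk improvement, 0 for maintenance, −1 per
level of deterioration, and −10 for lung-cancer occurrence.

**Deep Q-learning.** The agent minimises
L_i(θ_i) = E_{s,a∼ρ}[(Q_i − Q(s, a; θ_i))²] with bootstrapped targets
Q_i = E_{s′∼ε}[r + γ max_{a′} Q(s′, a′; θ_{i−1})], by plain stochastic
gradient descent over uniform samples from a FIFO experience-replay buffer,
with an ε-greedy behaviour policy and a periodically copied target network
θ_{i−1}; γ ∈ [0.9, 1] (default 0.95). A value-iteration solver provides the
exact Q* oracle on any finite MDP, so the learned policy can be verified.

**Evaluation.** Transfer pathways (20 in total: 6 improvement, 10
deterioration including the four drops into lung-cancer occurrence, 4
maintenance) are classified by direction; incidence decline is
100·(before − after)/before on per-100,000 rates; survival uses the
product-limit estimator S(t) = ∏_{t_i ≤ t}(1 − d_i/n_i).

## Worked example

```python
import risktransfer as rt
from risktransfer.dqn import DQNConfig, train_dqn, greedy_policy, value_iteration
from risktransfer.pathways import optimal_pathway, simulate_incidence_trend, incidence_decline

# simulate a biennial cohort with known risk dynamics
config = rt.CohortConfig(n_subjects=8000, n_waves=10, seed=2, behavior_policy="uniform")
cohort = rt.generate_cohort(config)

# estimate per-cycle transition probabilities per transfer action
model = rt.estimate_transitions(cohort.records, smoothing=0.5, actions=config.action_list)
print("P(high -> medium | extend cessation >5y) =",
      round(model.row("high", "extend_cessation_5y")[1], 3))

# learn the transfer policy and compare with exact value iteration
env = rt.build_env(model, rt.RewardSpec(), horizon=14)
net, log = train_dqn(env, DQNConfig(learning_rate=0.15, learning_rate_end=0.01,
                                    batch_size=64, episodes=500, gamma=0.95,
                                    seed=50, hidden=(), replay_capacity=5000,
                                    target_update_every=50))
q_star, pi_star = value_iteration(env, gamma=0.95, tol=1e-10)
print("optimal pathway from high risk:", optimal_pathway("high", pi_star, model))

# transfer effect: simulated incidence under maintenance vs the learned policy
policy = greedy_policy(net, env)
maintain = simulate_incidence_trend({s: "maintain" for s in rt.RISK_STATES},
                                    model, config.state_hazards, 10, 50_000, seed=3)
improved = simulate_incidence_trend(policy, model, config.state_hazards,
                                    10, 50_000, seed=4)
before = maintain.query("start_stratum == 'high' and cycle == 10").incidence_per_100k.iloc[0]
after = improved.query("start_stratum == 'high' and cycle == 10").incidence_per_100k.iloc[0]
print(f"high-risk 20-year incidence: {before:.0f} -> {after:.0f} per 100,000 "
      f"({incidence_decline(before, after):.2f}% decline)")
```

Output:

```
P(high -> medium | extend cessation >5y) = 0.464
optimal pathway from high risk: high→medium→low→non
high-risk 20-year incidence: 8008 -> 3708 per 100,000 (53.70% decline)
```

The estimated transition row recovers the generator's dynamics; the exact
solver's optimal pathway from high risk is the full improvement chain
high→medium→low→non; and simulating the learned intervention policy
roughly halves the 20-year cumulative incidence of the high-risk stratum
relative to risk maintenance.

## Analysis pipeline

The `analysis/` drivers run the full study on simulated cohorts, each
writing its tables under `results/analysis/`:

1. `01_simulate_cohorts.py` — HRS-like development and CHARLS-like external
   cohorts with missingness, plus ground-truth sidecars.
2. `02_preprocess.py` — dialect harmonization, cessation derivation,
   56-feature encoding, iterative imputation, SVD denoising, person-level
   split, SMOTE balancing.
3. `03_stratify.py` — weight-score network training and four-level
   stratification with calibration and confusion matrices.
4. `04_fit_mdp.py` — action labelling and transition-model estimation with
   held-out next-state accuracy/AUROC.
5. `05_train_dqn.py` — deep Q-learning on the fitted environment, checked
   against value iteration.
6. `06_evaluate_pathways.py` — pathway catalog, per-stratum optimal
   pathways, incidence-decline table, trend curves, Kaplan-Meier curves and
   the baseline table.

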