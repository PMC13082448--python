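#!/usr/bin/env python
"""Train the deep Q-learning agent on the estimated risk-transfer MDP.

Builds the environment from the fitted transition model and the default
transfer-effect rewards, trains the flat-mode Q-network with experience
replay and a target network, compares the greedy policy with exact value
iteration, and writes the policy with its training log.
"""

import argparse
import json
from pathlib import Path

import numpy as np

import risktransfer as rt
from risktransfer.dqn import DQNConfig, greedy_policy, train_dqn, value_iteration
from risktransfer.mdp import TransitionModel

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=50)
parser.add_argument("--episodes", type=int, default=500)
parser.add_argument("--data", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

model = TransitionModel.from_json(args.data / "mdp.json")
env = rt.build_env(model, rt.RewardSpec(), horizon=14)

config = DQNConfig(
    learning_rate=0.15, learning_rate_end=0.01, batch_size=64,
    episodes=args.episodes, gamma=0.95, seed=args.seed,
    replay_capacity=5000, target_update_every=50, hidden=(),
)
net, log = train_dqn(env, config)
log.to_csv(args.data / "dqn_training_log.csv", index=False)

q_star, pi_star = value_iteration(env, gamma=0.95, tol=1e-10)
q_hat = net.forward(np.eye(env.n_states))
pi_hat = greedy_policy(net, env)

payload = {
    "actions": list(model.actions),
    "states": list(rt.ALL_STATES),
    "dqn_policy": {s: model.actions[pi_hat[i]] for i, s in enumerate(rt.RISK_STATES)},
    "value_iteration_policy": {
        s: model.actions[pi_star[i]] for i, s in enumerate(rt.RISK_STATES)
    },
    "q_values_dqn": q_hat[:4].round(4).tolist(),
    "q_values_exact": q_star[:4].round(4).tolist(),
}
(args.data / "policy.json").write_text(json.dumps(payload, indent=1))

gap = np.abs(q_hat[:4] - q_star[:4]).max()
print(f"trained {args.episodes} episodes; final mean TD loss "
      f"{log['loss'].tail(50).mean():.4f}")
print(f"max |Q_dqn - Q*| over risk states: {gap:.3f}")
for s in rt.RISK_STATES:
    print(f"  {s}: dqn={payload['dqn_policy'][s]}  exact={payload['value_iteration_policy'][s]}")
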