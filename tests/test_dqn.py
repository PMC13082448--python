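"""Deep Q-learning: TD targets, loss, replay, training, the value-iteration
oracle, and policy evaluation."""

import numpy as np
import pandas as pd
import pytest

import risktransfer as rt
from risktransfer.dqn import (
    ConvQNetwork,
    DQNConfig,
    QNetwork,
    ReplayBuffer,
    evaluate_policy,
    greedy_policy,
    loss,
    td_target,
    train_dqn,
    value_iteration,
)
from risktransfer.mdp import FiniteMDPEnv, TransitionModel
from risktransfer.states import N_STATES, RISK_STATES


def random_mdp(seed: int, n_states: int = 5, horizon: int = 25) -> FiniteMDPEnv:
    rng = np.random.default_rng(seed)
    n_actions = int(rng.integers(2, 7))
    P = rng.dirichlet(np.ones(n_states), size=(n_actions, n_states))
    R = np.tile(
        rng.uniform(0, 1, size=(n_states, n_actions))[:, :, None], (1, 1, n_states)
    )
    return FiniteMDPEnv(
        P=P, R=R, terminal=np.zeros(n_states, dtype=bool), horizon=horizon
    )


# --- TD target and loss -----------------------------------------------------


def test_td_target_done_returns_reward():
    assert td_target(2.5, np.array([5.0, 9.0]), 0.95, True) == 2.5


def test_td_target_myopic_limit():
    assert td_target(1.5, np.array([5.0, 9.0]), 0.0, False) == 1.5


def test_td_target_hand_arithmetic():
    assert td_target(1.0, np.array([1.0, 3.0, 2.0]), 0.9, False) == pytest.approx(3.7)


def test_td_target_vectorized_over_batch():
    out = td_target(
        np.array([1.0, 1.0]),
        np.array([[1.0, 3.0], [2.0, 0.0]]),
        0.5,
        np.array([False, True]),
    )
    np.testing.assert_allclose(out, [2.5, 1.0])


def test_loss_zero_at_fixed_point():
    """Zero-reward MDP: the all-zero network is a Bellman fixed point."""
    net = QNetwork(3, 2, hidden=(), rng=np.random.default_rng(0))
    net.weights[0][:] = 0.0
    batch = (
        np.array([0, 1, 2]),
        np.array([0, 1, 0]),
        np.zeros(3),
        np.array([1, 2, 0]),
        np.array([False, False, False]),
    )
    assert loss(batch, net, net.copy(), gamma=0.95) == pytest.approx(0.0, abs=1e-10)


def test_loss_single_transition_hand_arithmetic():
    net = QNetwork(2, 2, hidden=(), rng=np.random.default_rng(0))
    net.weights[0][:] = np.array([[1.0, 0.0], [0.0, 2.0]])  # Q(s,·) = (s==0, 2*(s==1))
    batch = (np.array([0]), np.array([0]), np.array([1.0]), np.array([1]),
             np.array([False]))
    # target = 1 + 0.9 * max(0, 2) = 2.8 ; Q(0,0) = 1 → loss = (1 − 2.8)² = 3.24
    assert loss(batch, net, net.copy(), gamma=0.9) == pytest.approx(3.24)


def test_loss_empty_batch_rejected():
    net = QNetwork(2, 2, hidden=())
    empty = (np.array([], dtype=int),) * 2 + (np.array([]),) + (np.array([], dtype=int),
                                                                np.array([], dtype=bool))
    with pytest.raises(ValueError, match="empty"):
        loss(empty, net, net.copy(), gamma=0.9)


def test_loss_non_negative_random_batches():
    rng = np.random.default_rng(1)
    net = QNetwork(4, 3, hidden=(8,), rng=rng)
    batch = (rng.integers(0, 4, 16), rng.integers(0, 3, 16), rng.normal(size=16),
             rng.integers(0, 4, 16), rng.random(16) < 0.2)
    assert loss(batch, net, net.copy(), gamma=0.95) >= 0.0


# --- replay buffer ----------------------------------------------------------


def test_replay_fifo_eviction_and_capacity():
    buf = ReplayBuffer(capacity=3)
    for i in range(5):
        buf.push(i, 0, float(i), i + 1, False)
    assert len(buf) == 3
    stored = {item[0] for item in buf._data}
    assert stored == {2, 3, 4}  # oldest evicted first


def test_replay_sampling_reproducible():
    buf = ReplayBuffer(capacity=10)
    for i in range(10):
        buf.push(i, 0, float(i), i, False)
    a = buf.sample(4, np.random.default_rng(3))
    b = buf.sample(4, np.random.default_rng(3))
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x, y)


# --- value iteration --------------------------------------------------------


def test_value_iteration_geometric_series():
    P = np.ones((1, 1, 1))
    R = np.ones((1, 1, 1))
    Q, pi = value_iteration(P, R, gamma=0.9, tol=1e-12)
    assert Q[0, 0] == pytest.approx(10.0, abs=1e-6)  # 1/(1−γ)


def test_value_iteration_two_state_chain_hand_solved():
    # state 0 --a0--> state 1 (terminal), reward 2; a1 stays in 0, reward 1
    P = np.zeros((2, 2, 2))
    P[0, 0, 1] = 1.0
    P[1, 0, 0] = 1.0
    P[:, 1, 1] = 1.0
    R = np.zeros((2, 2, 2))
    R[0, 0, 1] = 2.0
    R[0, 1, 0] = 1.0
    terminal = np.array([False, True])
    Q, pi = value_iteration(P, R, gamma=0.9, tol=1e-12, terminal=terminal)
    # staying forever earns 1/(1−0.9) = 10 > 2, so action 1 is optimal
    assert pi[0] == 1
    assert Q[0, 1] == pytest.approx(10.0, abs=1e-6)
    assert Q[0, 0] == pytest.approx(2.0, abs=1e-6)


def test_value_iteration_bellman_residual_contract():
    env = random_mdp(0)
    Q, _ = value_iteration(env, gamma=0.95, tol=1e-10)
    expected_r = np.einsum("asx,sax->sa", env.P, env.R)
    backup = expected_r + 0.95 * np.einsum("asx,x->sa", env.P, Q.max(axis=1))
    assert np.abs(backup - Q).max() <= 1e-8


def test_value_iteration_gamma_one_divergence_detected():
    P = np.ones((1, 1, 1))
    R = np.ones((1, 1, 1))
    with pytest.raises(ValueError, match="did not converge"):
        value_iteration(P, R, gamma=1.0, tol=1e-12, max_iter=2000)


# --- training ---------------------------------------------------------------


def _oracle_dqn_config(seed: int) -> DQNConfig:
    """Training configuration for the tabular-oracle checks: exact tabular
    parameterization (no hidden layer) and a larger SGD step."""
    return DQNConfig(
        learning_rate=0.15,
        learning_rate_end=0.01,
        batch_size=64,
        episodes=500,
        gamma=0.95,
        seed=seed,
        replay_capacity=5000,
        target_update_every=50,
        hidden=(),
    )


def test_dqn_matches_value_iteration_on_toy_mdp():
    env = random_mdp(1)
    Q, pi = value_iteration(env, gamma=0.95, tol=1e-10)
    net, _ = train_dqn(env, _oracle_dqn_config(seed=101))
    np.testing.assert_array_equal(greedy_policy(net, env), pi)


def test_dqn_zero_reward_environment_learns_zero_q():
    env = random_mdp(2)
    env.R[:] = 0.0
    cfg = _oracle_dqn_config(seed=5)
    net, _ = train_dqn(env, cfg)
    assert np.abs(net.forward(np.eye(env.n_states))).max() < 1e-2


def test_dqn_deterministic_given_seed():
    env1, env2 = random_mdp(3), random_mdp(3)
    cfg = DQNConfig(learning_rate=0.05, batch_size=32, episodes=40, gamma=0.95,
                    seed=9, replay_capacity=2000, hidden=(16,))
    n1, log1 = train_dqn(env1, cfg)
    n2, log2 = train_dqn(env2, cfg)
    for W1, W2 in zip(n1.weights, n2.weights):
        np.testing.assert_array_equal(W1, W2)
    pd.testing.assert_frame_equal(log1, log2)


def test_dqn_gamma_zero_reduces_to_reward_regression():
    env = random_mdp(4)
    cfg = DQNConfig(learning_rate=0.1, batch_size=64, episodes=300, gamma=0.0,
                    seed=2, replay_capacity=5000, hidden=(),
                    allow_gamma_outside=True)
    net, _ = train_dqn(env, cfg)
    expected_r = np.einsum("asx,sax->sa", env.P, env.R)
    learned = net.forward(np.eye(env.n_states))
    assert np.abs(learned - expected_r).max() < 0.05


def test_dqn_divergence_aborts_with_diagnostic():
    env = random_mdp(5)
    env.R[:] = 1e6
    cfg = DQNConfig(learning_rate=1e4, batch_size=32, episodes=50, gamma=0.95,
                    seed=1, replay_capacity=1000, hidden=(8,))
    with pytest.raises(RuntimeError, match="divergent"):
        train_dqn(env, cfg)


def test_gamma_outside_range_requires_override():
    with pytest.raises(ValueError, match="gamma"):
        DQNConfig(gamma=0.5)
    DQNConfig(gamma=0.5, allow_gamma_outside=True)  # no error


def test_training_return_stabilizes_on_risk_environment(risk_env_fit):
    """Mean return over the final fifth of training is no worse than the
    post-exploration middle of training, within Monte-Carlo noise."""
    _, _, _, env, _, _ = risk_env_fit
    cfg = DQNConfig(learning_rate=0.01, batch_size=256, episodes=500, gamma=0.95,
                    seed=50, hidden=(32,))
    _, log = train_dqn(env, cfg)
    r = log["return"]
    mid, final = r.iloc[200:300], r.iloc[400:]
    se_diff = np.sqrt(mid.var() / len(mid) + final.var() / len(final))
    assert final.mean() >= mid.mean() - 3 * se_diff


def test_grid_mode_conv_network_trains_on_risk_environment(risk_env_fit):
    """The 32×32 convolutional mode runs end to end and reduces its TD loss."""
    _, _, model, _, _, _ = risk_env_fit
    env = rt.build_env(model, rt.RewardSpec(), horizon=4)
    cfg = DQNConfig(learning_rate=0.01, batch_size=16, episodes=12, gamma=0.95,
                    seed=3, replay_capacity=500, hidden=(), mode="grid")
    net, log = train_dqn(env, cfg)
    assert isinstance(net, ConvQNetwork)
    assert net.forward(np.zeros((32, 32))).shape == (1, env.n_actions)
    fitted = log["loss"].dropna()
    assert fitted.iloc[-1] < fitted.iloc[0] * 2  # bounded, finite training


# --- policy evaluation ------------------------------------------------------


def _identity_model(actions=("maintain",)):
    probs = {}
    for i, s in enumerate(RISK_STATES):
        row = np.zeros(N_STATES)
        row[i] = 1.0
        for a in actions:
            probs[(s, a)] = row
    return TransitionModel(probabilities=probs, actions=actions)


def test_evaluate_policy_deterministic_match_accuracy_one():
    rows = []
    for i, s in enumerate(RISK_STATES):
        rows += [
            {"person_id": f"p{i}", "wave_index": 0, "latent_state": s,
             "action": "maintain", "lung_cancer_event": False},
            {"person_id": f"p{i}", "wave_index": 1, "latent_state": s,
             "action": "", "lung_cancer_event": False},
        ]
    acc, auroc = evaluate_policy(_identity_model(), pd.DataFrame(rows))
    assert acc == 1.0


def test_evaluate_policy_hand_tally():
    model = _identity_model()
    rows = []
    seqs = [("high", "high"), ("high", "high"), ("high", "medium"),
            ("low", "low"), ("low", "non"), ("non", "non")]
    for i, (a, b) in enumerate(seqs):
        rows += [
            {"person_id": f"p{i}", "wave_index": 0, "latent_state": a,
             "action": "maintain", "lung_cancer_event": False},
            {"person_id": f"p{i}", "wave_index": 1, "latent_state": b,
             "action": "", "lung_cancer_event": False},
        ]
    acc, _ = evaluate_policy(model, pd.DataFrame(rows))
    assert acc == pytest.approx(4 / 6)  # identity predicts the 4 unchanged pairs


def test_evaluate_policy_single_class_auroc_absent():
    rows = [
        {"person_id": "p", "wave_index": 0, "latent_state": "high",
         "action": "maintain", "lung_cancer_event": False},
        {"person_id": "p", "wave_index": 1, "latent_state": "high",
         "action": "", "lung_cancer_event": False},
    ]
    acc, auroc = evaluate_policy(_identity_model(), pd.DataFrame(rows))
    assert auroc is None


def test_evaluate_policy_uninformative_probabilities_chance_auroc():
    probs = {(s, "maintain"): np.full(N_STATES, 0.2) for s in RISK_STATES}
    model = TransitionModel(probabilities=probs, actions=("maintain",))
    rng = np.random.default_rng(6)
    rows = []
    for i in range(200):
        a, b = rng.choice(RISK_STATES, size=2)
        rows += [
            {"person_id": f"p{i}", "wave_index": 0, "latent_state": a,
             "action": "maintain", "lung_cancer_event": False},
            {"person_id": f"p{i}", "wave_index": 1, "latent_state": b,
             "action": "", "lung_cancer_event": False},
        ]
    _, auroc = evaluate_policy(model, pd.DataFrame(rows))
    assert auroc == pytest.approx(0.5, abs=1e-9)
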