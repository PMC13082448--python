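"""Deep Q-learning with experience replay and a target network.

The agent learns the action-value function Q(s, a; θ) of the risk-transfer
MDP by minimising the squared temporal-difference error

    L_i(θ_i) = E[(Q_i − Q(s, a; θ_i))²],
    Q_i      = E[r + γ max_a' Q(s', a'; θ_{i−1})],

with plain stochastic gradient descent, uniform sampling from a FIFO replay
buffer, an ε-greedy behaviour policy and periodic copying of θ into the
target network θ_{i−1}.  The flat mode (small feed-forward net over one-hot
states) is the tested default; the grid mode (three convolution stages with
5×5, 4×4 and 3×3 kernels over a 32×32 state image) mirrors the stated CNN
architecture.  A value-iteration solver provides the exact Q* oracle for
finite MDPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .mdp import FiniteMDPEnv, TransitionModel
from .states import ALL_STATES, RISK_STATES, STATE_INDEX

__all__ = [
    "DQNConfig",
    "QNetwork",
    "ConvQNetwork",
    "ReplayBuffer",
    "td_target",
    "loss",
    "train_dqn",
    "value_iteration",
    "greedy_policy",
    "evaluate_policy",
]


@dataclass
class DQNConfig:
    learning_rate: float = 0.01
    #: optional final SGD step size; when set, the step decays linearly from
    #: ``learning_rate`` to this value over the episodes (Robbins-Monro style)
    learning_rate_end: float | None = None
    batch_size: int = 256
    episodes: int = 500
    gamma: float = 0.95
    seed: int = 50
    epsilon_start: float = 1.0
    epsilon_end: float = 0.05
    epsilon_decay_frac: float = 0.6  # linear decay over the first 60% of episodes
    replay_capacity: int = 10_000
    target_update_every: int = 100  # gradient steps between target-network copies
    hidden: tuple[int, ...] = (32,)
    mode: str = "flat"  # "flat" or "grid"
    allow_gamma_outside: bool = False

    def __post_init__(self) -> None:
        if not self.allow_gamma_outside and not 0.9 <= self.gamma <= 1.0:
            raise ValueError(
                "gamma must lie in [0.9, 1.0]; set allow_gamma_outside=True to override"
            )
        if self.batch_size > self.replay_capacity:
            raise ValueError("batch_size cannot exceed replay capacity")
        if self.mode not in ("flat", "grid"):
            raise ValueError(f"mode must be 'flat' or 'grid', got {self.mode!r}")


class QNetwork:
    """Feed-forward Q-network: state encoding in, one Q-value per action out."""

    def __init__(
        self,
        input_dim: int,
        n_actions: int,
        hidden: tuple[int, ...] = (32,),
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        sizes = (input_dim,) + tuple(hidden) + (n_actions,)
        self.weights = [
            rng.normal(0.0, np.sqrt(2.0 / fi), size=(fo, fi))
            for fi, fo in zip(sizes, sizes[1:])
        ]
        self.biases = [np.zeros(fo) for fo in sizes[1:]]
        self.n_actions = n_actions

    def copy(self) -> "QNetwork":
        out = object.__new__(QNetwork)
        out.weights = [W.copy() for W in self.weights]
        out.biases = [b.copy() for b in self.biases]
        out.n_actions = self.n_actions
        return out

    def _pass(self, X: np.ndarray):
        acts = [X]
        h = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            h = np.maximum(h @ W.T + b, 0.0)
            acts.append(h)
        return acts, h @ self.weights[-1].T + self.biases[-1]

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Q-values, shape (n, n_actions); accepts a single encoding too."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self._pass(X)[1]

    def sgd_step(
        self, X: np.ndarray, actions: np.ndarray, targets: np.ndarray, lr: float
    ) -> float:
        """One SGD step on the squared TD error of the taken actions."""
        n = X.shape[0]
        acts, Q = self._pass(X)
        diff = Q[np.arange(n), actions] - targets
        with np.errstate(over="ignore"):  # divergence is reported by the caller
            batch_loss = float(np.mean(diff**2))
        dQ = np.zeros_like(Q)
        dQ[np.arange(n), actions] = 2.0 * diff / n
        delta = dQ
        for k in range(len(self.weights) - 1, -1, -1):
            gW = delta.T @ acts[k]
            gb = delta.sum(axis=0)
            if k > 0:
                delta = (delta @ self.weights[k]) * (acts[k] > 0)
            self.weights[k] -= lr * gW
            self.biases[k] -= lr * gb
        return batch_loss


def _im2col(X: np.ndarray, k: int, stride: int) -> tuple[np.ndarray, int, int]:
    n, C, H, W = X.shape
    H2 = (H - k) // stride + 1
    W2 = (W - k) // stride + 1
    cols = np.empty((n, C * k * k, H2 * W2))
    idx = 0
    for c in range(C):
        for di in range(k):
            for dj in range(k):
                patch = X[:, c, di : di + stride * H2 : stride, dj : dj + stride * W2 : stride]
                cols[:, idx, :] = patch.reshape(n, -1)
                idx += 1
    return cols, H2, W2


def _col2im(dcols: np.ndarray, shape: tuple, k: int, stride: int, H2: int, W2: int):
    n, C, H, W = shape
    dX = np.zeros(shape)
    idx = 0
    for c in range(C):
        for di in range(k):
            for dj in range(k):
                dX[:, c, di : di + stride * H2 : stride, dj : dj + stride * W2 : stride] += (
                    dcols[:, idx, :].reshape(n, H2, W2)
                )
                idx += 1
    return dX


class ConvQNetwork:
    """Grid-mode Q-network: 5×5, 4×4 and 3×3 convolution stages over a
    32×32 state image, rectified, then a linear output layer over actions."""

    _SPEC = ((4, 5, 2), (8, 4, 2), (8, 3, 1))  # (filters, kernel, stride)

    def __init__(self, n_actions: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.n_actions = n_actions
        self.filters, self.fbias = [], []
        c_in, size = 1, 32
        for f, k, s in self._SPEC:
            fan_in = c_in * k * k
            self.filters.append(rng.normal(0, np.sqrt(2.0 / fan_in), size=(f, fan_in)))
            self.fbias.append(np.zeros(f))
            size = (size - k) // s + 1
            c_in = f
        flat = c_in * size * size
        self.W_out = rng.normal(0, np.sqrt(2.0 / flat), size=(n_actions, flat))
        self.b_out = np.zeros(n_actions)

    def copy(self) -> "ConvQNetwork":
        out = object.__new__(ConvQNetwork)
        out.n_actions = self.n_actions
        out.filters = [F.copy() for F in self.filters]
        out.fbias = [b.copy() for b in self.fbias]
        out.W_out = self.W_out.copy()
        out.b_out = self.b_out.copy()
        return out

    def _pass(self, X: np.ndarray):
        cache = []
        h = X
        for (f, k, s), F, b in zip(self._SPEC, self.filters, self.fbias):
            cols, H2, W2 = _im2col(h, k, s)
            z = np.einsum("fc,ncp->nfp", F, cols) + b[None, :, None]
            a = np.maximum(z, 0.0).reshape(h.shape[0], f, H2, W2)
            cache.append((h.shape, cols, z, H2, W2))
            h = a
        flat = h.reshape(h.shape[0], -1)
        Q = flat @ self.W_out.T + self.b_out
        return cache, h, flat, Q

    def forward(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        if X.ndim == 3:
            X = X[:, None]
        return self._pass(X)[3]

    def sgd_step(
        self, X: np.ndarray, actions: np.ndarray, targets: np.ndarray, lr: float
    ) -> float:
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X[:, None]
        n = X.shape[0]
        cache, h, flat, Q = self._pass(X)
        diff = Q[np.arange(n), actions] - targets
        batch_loss = float(np.mean(diff**2))
        dQ = np.zeros_like(Q)
        dQ[np.arange(n), actions] = 2.0 * diff / n
        gW_out = dQ.T @ flat
        gb_out = dQ.sum(axis=0)
        dflat = dQ @ self.W_out
        dh = dflat.reshape(h.shape)
        for layer in range(len(self.filters) - 1, -1, -1):
            shape, cols, z, H2, W2 = cache[layer]
            f, k, s = self._SPEC[layer]
            dz = (dh.reshape(n, f, -1)) * (z > 0)
            gF = np.einsum("nfp,ncp->fc", dz, cols)
            gb = dz.sum(axis=(0, 2))
            dcols = np.einsum("fc,nfp->ncp", self.filters[layer], dz)
            dh = _col2im(dcols, shape, k, s, H2, W2)
            self.filters[layer] -= lr * gF
            self.fbias[layer] -= lr * gb
        self.W_out -= lr * gW_out
        self.b_out -= lr * gb_out
        return batch_loss


class ReplayBuffer:
    """FIFO experience store with uniform, seed-reproducible sampling."""

    def __init__(self, capacity: int):
        self.capacity = capacity
        self._data: list[tuple] = []
        self._pos = 0

    def push(self, s: int, a: int, r: float, s2: int, terminal: bool) -> None:
        item = (s, a, r, s2, terminal)
        if len(self._data) < self.capacity:
            self._data.append(item)
        else:
            self._data[self._pos] = item
        self._pos = (self._pos + 1) % self.capacity

    def __len__(self) -> int:
        return len(self._data)

    def sample(self, batch_size: int, rng: np.random.Generator):
        idx = rng.integers(0, len(self._data), size=batch_size)
        s, a, r, s2, term = zip(*(self._data[i] for i in idx))
        return (
            np.asarray(s),
            np.asarray(a),
            np.asarray(r, dtype=float),
            np.asarray(s2),
            np.asarray(term, dtype=bool),
        )


def td_target(
    reward: float | np.ndarray,
    next_q: np.ndarray,
    gamma: float,
    done: bool | np.ndarray,
) -> float | np.ndarray:
    """Bootstrapped target r + γ·max_a' Q(s', a'; θ_{i−1}), or r when done.

    ``next_q`` holds the target network's Q-values at s' (last axis =
    actions); vectorizes over leading axes.
    """
    next_q = np.asarray(next_q, dtype=float)
    best = next_q.max(axis=-1)
    out = np.asarray(reward, dtype=float) + gamma * best * ~np.asarray(done, dtype=bool)
    return float(out) if out.ndim == 0 else out


def loss(
    batch: tuple,
    net: QNetwork,
    target_net: QNetwork,
    gamma: float,
    encode: np.ndarray | None = None,
) -> float:
    """Mean squared TD error of a replay batch under the current parameters."""
    s, a, r, s2, term = batch
    if len(np.atleast_1d(s)) == 0:
        raise ValueError("empty batch")
    enc = encode if encode is not None else np.eye(net.weights[0].shape[1])
    targets = td_target(r, target_net.forward(enc[s2]), gamma, term)
    q = net.forward(enc[s])[np.arange(len(s)), a]
    return float(np.mean((q - targets) ** 2))


def train_dqn(
    env: FiniteMDPEnv, config: DQNConfig | None = None
) -> tuple[QNetwork, pd.DataFrame]:
    """ε-greedy deep Q-learning on a finite environment.

    Interacts with ``env`` for ``config.episodes`` episodes, stores
    transitions in the replay buffer, takes one SGD step on the squared TD
    error per environment step (once the buffer holds a batch), and copies
    the online network into the target network every
    ``config.target_update_every`` gradient steps.  Fully reproducible from
    ``config.seed``.  Aborts with a diagnostic if the loss becomes
    non-finite.
    """
    config = config or DQNConfig()
    rng = np.random.default_rng(config.seed)
    env.set_rng(rng)
    if config.mode == "grid":
        net: QNetwork | ConvQNetwork = ConvQNetwork(env.n_actions, rng=rng)
        from .mdp import encode_state_grid

        enc = np.stack([encode_state_grid(s) for s in ALL_STATES])
        if env.n_states != len(ALL_STATES):
            raise ValueError("grid mode expects the 5-state risk environment")
    else:
        net = QNetwork(env.n_states, env.n_actions, hidden=config.hidden, rng=rng)
        enc = np.eye(env.n_states)
    target = net.copy()

    buffer = ReplayBuffer(config.replay_capacity)
    decay_eps = max(int(config.episodes * config.epsilon_decay_frac), 1)
    grad_steps = 0
    log: list[dict] = []
    for ep in range(config.episodes):
        frac = min(ep / decay_eps, 1.0)
        epsilon = config.epsilon_start + frac * (config.epsilon_end - config.epsilon_start)
        lr = config.learning_rate
        if config.learning_rate_end is not None:
            t = ep / max(config.episodes - 1, 1)
            lr = config.learning_rate + t * (config.learning_rate_end - config.learning_rate)
        s = env.reset()
        done = False
        ep_return = 0.0
        ep_losses: list[float] = []
        while not done:
            if rng.random() < epsilon:
                a = int(rng.integers(env.n_actions))
            else:
                a = int(np.argmax(net.forward(enc[s])[0]))
            s2, r, done = env.step(a)
            buffer.push(s, a, r, s2, bool(env.terminal[s2]))
            ep_return += r
            s = s2
            if len(buffer) >= config.batch_size:
                bs, ba, br, bs2, bterm = buffer.sample(config.batch_size, rng)
                targets = td_target(br, target.forward(enc[bs2]), config.gamma, bterm)
                step_loss = net.sgd_step(enc[bs], ba, targets, lr)
                if not np.isfinite(step_loss):
                    raise RuntimeError(
                        f"divergent TD loss at episode {ep}, step {grad_steps}: "
                        f"{step_loss}; reduce the learning rate"
                    )
                ep_losses.append(step_loss)
                grad_steps += 1
                if grad_steps % config.target_update_every == 0:
                    target = net.copy()
        log.append(
            {
                "episode": ep,
                "return": ep_return,
                "loss": float(np.mean(ep_losses)) if ep_losses else np.nan,
                "epsilon": epsilon,
            }
        )
    return net, pd.DataFrame(log, columns=["episode", "return", "loss", "epsilon"])


def value_iteration(
    P: np.ndarray | FiniteMDPEnv,
    R: np.ndarray | None = None,
    gamma: float = 0.95,
    tol: float = 1e-8,
    terminal: np.ndarray | None = None,
    max_iter: int = 200_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact Q* and greedy policy of a finite MDP by successive approximation.

    Accepts either a :class:`FiniteMDPEnv` or raw (A,S,S) transition and
    (S,A,S) reward tensors.  Terminal states contribute zero continuation
    value.  Ties in the policy break toward the lowest action index.
    Raises when the Bellman backup fails to contract (e.g. γ=1 with
    rewarding non-absorbing cycles).
    """
    if isinstance(P, FiniteMDPEnv):
        env = P
        P, R, terminal = env.P, env.R, env.terminal
    assert R is not None
    A, S, _ = P.shape
    if terminal is None:
        terminal = np.zeros(S, dtype=bool)
    Q = np.zeros((S, A))
    expected_r = np.einsum("asx,sax->sa", P, R)
    for _ in range(max_iter):
        V = Q.max(axis=1)
        V[terminal] = 0.0
        Q_new = expected_r + gamma * np.einsum("asx,x->sa", P, V)
        Q_new[terminal] = 0.0
        resid = np.max(np.abs(Q_new - Q))
        Q = Q_new
        if resid <= tol:
            break
    else:
        raise ValueError(
            f"value iteration did not converge (gamma={gamma}); "
            "divergent with non-absorbing reward cycles"
        )
    return Q, Q.argmax(axis=1)


def greedy_policy(net: QNetwork | ConvQNetwork, env: FiniteMDPEnv) -> np.ndarray:
    """Greedy action per state under the trained network (flat encoding)."""
    enc = np.eye(env.n_states)
    return net.forward(enc).argmax(axis=1)


def evaluate_policy(
    transitions: TransitionModel,
    records: pd.DataFrame,
    state_col: str = "latent_state",
    action_col: str = "action",
) -> tuple[float, float | None]:
    """Next-state prediction quality on held-out stratified wave pairs.

    Accuracy is the fraction of observed next states matching the model's
    most probable next state under the observed action; AUROC is the
    one-vs-rest area over the model's next-state probability vectors, or
    None when the held-out next states are single-class.
    """
    df = records.sort_values(["person_id", "wave_index"], kind="stable").reset_index(drop=True)
    grp = df.groupby("person_id", sort=False)
    nxt = grp[state_col].shift(-1)
    nxt_event = grp["lung_cancer_event"].shift(-1)
    valid = nxt.notna() & ~df["lung_cancer_event"].astype(bool)
    cur = df.loc[valid, state_col].to_numpy(dtype=object)
    act = df.loc[valid, action_col].to_numpy(dtype=object)
    true_next = np.where(
        nxt_event[valid].astype(bool).to_numpy(), "lung_cancer", nxt[valid].to_numpy(dtype=object)
    )
    keep = np.array([s in RISK_STATES and a in transitions.actions for s, a in zip(cur, act)])
    if not keep.any():
        raise ValueError("no evaluable wave pairs")
    cur, act, true_next = cur[keep], act[keep], true_next[keep]
    probs = np.stack([transitions.row(s, a) for s, a in zip(cur, act)])
    pred = np.asarray(ALL_STATES, dtype=object)[probs.argmax(axis=1)]
    accuracy = float(np.mean(pred == true_next))
    classes = np.unique(true_next)
    if classes.size < 2:
        return accuracy, None
    y_idx = np.array([STATE_INDEX[s] for s in true_next])
    present = np.unique(y_idx)
    p = probs[:, present]
    p = p / p.sum(axis=1, keepdims=True)
    auroc = float(
        roc_auc_score(y_idx, p if present.size > 2 else p[:, 1], labels=present,
                      multi_class="ovr", average="macro")
        if present.size > 2
        else roc_auc_score(y_idx == present[1], p[:, 1])
    )
    return accuracy, auroc
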