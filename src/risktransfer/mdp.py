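"""Risk-transfer Markov decision process.

States are the four risk strata plus an absorbing lung-cancer state; actions
are the smoking-related transfer strategies; transition probabilities per
biennial cycle are estimated from stratified cohort wave pairs by additively
smoothed maximum likelihood.  The reward ("transfer effect") orders the
three transfer directions: positive per level of risk improvement, zero for
maintenance, negative per level of deterioration, and strictly smallest for
lung-cancer occurrence.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .states import (
    ACTIONS,
    ALL_STATES,
    LUNG_CANCER,
    N_STATES,
    RISK_STATES,
    STATE_INDEX,
    risk_level,
)

__all__ = [
    "TransitionModel",
    "RewardSpec",
    "FiniteMDPEnv",
    "estimate_transitions",
    "label_actions",
    "env_step",
    "encode_state_grid",
    "encode_state_flat",
    "build_env",
]


@dataclass
class TransitionModel:
    """Per-(state, action) next-state distributions over one 2-year cycle."""

    probabilities: dict[tuple[str, str], np.ndarray]
    counts: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    smoothing: float = 0.0
    actions: tuple[str, ...] = ACTIONS

    def __post_init__(self) -> None:
        for key, p in self.probabilities.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (N_STATES,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"probabilities[{key}] is not a distribution over states")
            self.probabilities[key] = p

    def row(self, state: str, action: str) -> np.ndarray:
        try:
            return self.probabilities[(state, action)]
        except KeyError:
            raise KeyError(f"no transition row for state={state!r}, action={action!r}")

    def as_tensor(self) -> np.ndarray:
        """(n_actions, n_states, n_states) tensor; lung cancer self-absorbs."""
        P = np.zeros((len(self.actions), N_STATES, N_STATES))
        for ai, a in enumerate(self.actions):
            for s in RISK_STATES:
                P[ai, STATE_INDEX[s]] = self.row(s, a)
            P[ai, STATE_INDEX[LUNG_CANCER], STATE_INDEX[LUNG_CANCER]] = 1.0
        return P

    def to_json(self, path: str | Path) -> None:
        payload = {
            "actions": list(self.actions),
            "states": list(ALL_STATES),
            "smoothing": self.smoothing,
            "probabilities": {
                f"{s}|{a}": p.tolist() for (s, a), p in self.probabilities.items()
            },
            "counts": {f"{s}|{a}": c.tolist() for (s, a), c in self.counts.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TransitionModel":
        payload = json.loads(Path(path).read_text())
        probs = {
            tuple(k.split("|")): np.asarray(v, dtype=float)
            for k, v in payload["probabilities"].items()
        }
        counts = {
            tuple(k.split("|")): np.asarray(v, dtype=float)
            for k, v in payload.get("counts", {}).items()
        }
        return cls(
            probabilities={(s, a): p for (s, a), p in probs.items()},
            counts={(s, a): c for (s, a), c in counts.items()},
            smoothing=payload.get("smoothing", 0.0),
            actions=tuple(payload["actions"]),
        )


@dataclass
class RewardSpec:
    """Transfer effect r(s, a, s') per transition.

    Defaults: +1 per level of risk improvement (so high→non earns +3),
    0 for maintenance, −1 per level of deterioration, −10 for entering the
    absorbing lung-cancer state; explicit overrides win.  The lung-cancer
    entry must stay strictly smallest.
    """

    improvement_per_level: float = 1.0
    deterioration_per_level: float = -1.0
    maintenance: float = 0.0
    lung_cancer: float = -10.0
    overrides: dict[tuple[str, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        worst_ladder = 3 * self.deterioration_per_level
        if self.lung_cancer >= min(worst_ladder, self.maintenance):
            raise ValueError("lung-cancer reward must be strictly smallest")

    def reward(self, state: str, action: str, next_state: str) -> float:
        key = (state, action, next_state)
        if key in self.overrides:
            return self.overrides[key]
        if next_state == LUNG_CANCER:
            return self.lung_cancer
        delta = risk_level(next_state) - risk_level(state)  # + = toward non-risk
        if delta > 0:
            return delta * self.improvement_per_level
        if delta < 0:
            return -delta * self.deterioration_per_level
        return self.maintenance

    def as_tensor(self, actions: tuple[str, ...] = ACTIONS) -> np.ndarray:
        R = np.zeros((N_STATES, len(actions), N_STATES))
        for si, s in enumerate(RISK_STATES):
            for ai, a in enumerate(actions):
                for sj, s2 in enumerate(ALL_STATES):
                    R[si, ai, sj] = self.reward(s, a, s2)
        return R


#: How an observed change in smoking behaviour between consecutive waves is
#: labelled as a transfer action.  First matching rule wins; anything else
#: is risk maintenance.
_CESS_ACTION = {"1 year": "extend_cessation_1y", "3 years": "extend_cessation_3y",
                ">5 years": "extend_cessation_5y"}
_FREQ_ACTION = {
    ("everyday", "someday"): "reduce_freq_everyday_to_someday",
    ("someday", "quit"): "reduce_freq_someday_to_quit",
    ("everyday", "quit"): "reduce_freq_everyday_to_quit",
}
_CESS_ORDER = {"<1 month": 0, "1 year": 1, "3 years": 2, ">5 years": 3}


def label_actions(records: pd.DataFrame) -> pd.Series:
    """Derive the transfer action taken between wave w and w+1 for each row.

    A frequency drop (everyday→someday, someday→quit, everyday→quit) labels
    the frequency-reduction action; otherwise a cessation-duration increase
    labels the corresponding extension action; everything else is
    maintenance.  The last wave of each person gets no label (empty string).
    """
    df = records.sort_values(["person_id", "wave_index"], kind="stable")
    nxt = df.groupby("person_id", sort=False)[["smoking_frequency", "cessation_duration"]].shift(
        -1
    )
    out = np.full(len(df), "", dtype=object)
    has_next = nxt["smoking_frequency"].notna().to_numpy()
    freq_pair = list(zip(df["smoking_frequency"], nxt["smoking_frequency"]))
    cess_now = df["cessation_duration"].to_numpy(dtype=object)
    cess_next = nxt["cessation_duration"].to_numpy(dtype=object)
    for i in np.flatnonzero(has_next):
        action = "maintain"
        pair = freq_pair[i]
        if pair in _FREQ_ACTION:
            action = _FREQ_ACTION[pair]
        else:
            a, b = cess_now[i], cess_next[i]
            if a in _CESS_ORDER and b in _CESS_ORDER and _CESS_ORDER[b] > _CESS_ORDER[a]:
                action = _CESS_ACTION.get(b, "maintain")
        out[i] = action
    return pd.Series(out, index=df.index).reindex(records.index)


def estimate_transitions(
    records: pd.DataFrame,
    state_col: str = "latent_state",
    action_col: str = "action",
    smoothing: float = 0.5,
    actions: tuple[str, ...] = ACTIONS,
) -> TransitionModel:
    """Additively smoothed ML estimate of per-cycle transition probabilities.

    Expects a strata-labelled long table with one row per subject-wave; a
    wave pair (w, w+1) of the same person contributes one (state, action,
    next-state) count, where a lung-cancer event at w+1 counts as entering
    the absorbing state.  Rows for unobserved (state, action) cells default
    to self-transition with a warning.
    """
    if records.empty:
        raise ValueError("cannot estimate transitions from an empty cohort")
    df = records.sort_values(["person_id", "wave_index"], kind="stable").reset_index(drop=True)
    grp = df.groupby("person_id", sort=False)
    nxt_state = grp[state_col].shift(-1)
    nxt_event = grp["lung_cancer_event"].shift(-1)
    cur_event = df["lung_cancer_event"].astype(bool)

    valid = nxt_state.notna() & ~cur_event
    cur = df.loc[valid, state_col].to_numpy(dtype=object)
    act = df.loc[valid, action_col].to_numpy(dtype=object)
    nxt = nxt_state[valid].to_numpy(dtype=object)
    nxt = np.where(nxt_event[valid].astype(bool).to_numpy(), LUNG_CANCER, nxt)

    counts: dict[tuple[str, str], np.ndarray] = {
        (s, a): np.zeros(N_STATES) for s in RISK_STATES for a in actions
    }
    action_set = set(actions)
    for s, a, s2 in zip(cur, act, nxt):
        if a in action_set and s in RISK_STATES:
            counts[(s, a)][STATE_INDEX[s2]] += 1.0

    probs: dict[tuple[str, str], np.ndarray] = {}
    unobserved = []
    for key, c in counts.items():
        total = c.sum()
        if total == 0:
            unobserved.append(key)
            p = np.zeros(N_STATES)
            p[STATE_INDEX[key[0]]] = 1.0
        else:
            p = (c + smoothing) / (total + smoothing * N_STATES)
        probs[key] = p
    if unobserved:
        warnings.warn(
            f"{len(unobserved)} unobserved (state, action) cells default to "
            f"self-transition: {unobserved[:5]}{'...' if len(unobserved) > 5 else ''}",
            stacklevel=2,
        )
    return TransitionModel(
        probabilities=probs, counts=counts, smoothing=smoothing, actions=tuple(actions)
    )


def env_step(
    state: str,
    action: str,
    transitions: TransitionModel,
    rewards: RewardSpec,
    rng: np.random.Generator,
) -> tuple[str, float, bool]:
    """Sample one environment cycle: next state, transfer effect, terminal flag."""
    if state == LUNG_CANCER:
        return LUNG_CANCER, rewards.lung_cancer, True
    p = transitions.row(state, action)
    nxt = ALL_STATES[int(rng.choice(N_STATES, p=p))]
    r = rewards.reward(state, action, nxt)
    return nxt, r, nxt == LUNG_CANCER


# --- state encodings --------------------------------------------------------


def encode_state_flat(state: str, covariates: np.ndarray | None = None) -> np.ndarray:
    """One-hot state block plus optional normalized covariate channel."""
    v = np.zeros(N_STATES if covariates is None else N_STATES + len(covariates))
    v[STATE_INDEX[state]] = 1.0
    if covariates is not None:
        v[N_STATES:] = np.clip(np.asarray(covariates, dtype=float), 0.0, 1.0)
    return v


def encode_state_grid(state: str, covariates: np.ndarray | None = None) -> np.ndarray:
    """Fixed injective 32×32 grid encoding of a risk state.

    Layout: rows 0–24 tile the one-hot state block (five 5-row bands, the
    active state's band set to 1); rows 25+ carry covariate channels clipped
    to [0,1], one value broadcast per row, zero-padded.  All entries lie in
    [0,1].
    """
    grid = np.zeros((32, 32))
    band = STATE_INDEX[state]
    grid[band * 5 : band * 5 + 5, :] = 1.0
    if covariates is not None:
        cov = np.clip(np.asarray(covariates, dtype=float), 0.0, 1.0)[:7]
        for i, val in enumerate(cov):
            grid[25 + i, :] = val
    return grid


@dataclass
class FiniteMDPEnv:
    """Generic finite MDP used both for the risk-transfer environment and
    for randomly generated test MDPs.

    ``P`` is (n_actions, n_states, n_states) row-stochastic, ``R`` is
    (n_states, n_actions, n_states), ``terminal`` marks absorbing states
    that end an episode, ``horizon`` caps the cycle budget per episode.
    """

    P: np.ndarray
    R: np.ndarray
    terminal: np.ndarray
    horizon: int = 14
    initial_states: np.ndarray | None = None
    state_names: tuple[str, ...] | None = None
    action_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        A, S, S2 = self.P.shape
        if S != S2 or self.R.shape != (S, A, S):
            raise ValueError("P must be (A,S,S) and R must be (S,A,S)")
        if not np.allclose(self.P.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("P rows must sum to 1")
        self._rng = np.random.default_rng(0)
        self._state = 0
        self._t = 0
        self._cumP = np.cumsum(self.P, axis=2)

    @property
    def n_states(self) -> int:
        return self.P.shape[1]

    @property
    def n_actions(self) -> int:
        return self.P.shape[0]

    def set_rng(self, rng: np.random.Generator) -> None:
        self._rng = rng

    def reset(self, state: int | None = None) -> int:
        if state is None:
            if self.initial_states is None:
                cand = np.flatnonzero(~self.terminal)
            else:
                cand = np.asarray(self.initial_states)
            state = int(cand[self._rng.integers(len(cand))])
        self._state = int(state)
        self._t = 0
        return self._state

    def step(self, action: int) -> tuple[int, float, bool]:
        s = self._state
        u = self._rng.random()
        nxt = int(np.searchsorted(self._cumP[action, s], u, side="right"))
        nxt = min(nxt, self.n_states - 1)
        r = float(self.R[s, action, nxt])
        self._state = nxt
        self._t += 1
        done = bool(self.terminal[nxt]) or self._t >= self.horizon
        return nxt, r, done

    def encode(self, state: int) -> np.ndarray:
        v = np.zeros(self.n_states)
        v[state] = 1.0
        return v


def build_env(
    transitions: TransitionModel,
    rewards: RewardSpec | None = None,
    horizon: int = 14,
    initial_state: str | None = None,
) -> FiniteMDPEnv:
    """Assemble the risk-transfer environment from estimated components.

    ``initial_state`` restricts episode starts to one risk group — the four
    per-group views share the same transition model.
    """
    rewards = rewards or RewardSpec()
    P = transitions.as_tensor()
    R = rewards.as_tensor(transitions.actions)
    terminal = np.zeros(N_STATES, dtype=bool)
    terminal[STATE_INDEX[LUNG_CANCER]] = True
    init = None
    if initial_state is not None:
        init = np.array([STATE_INDEX[initial_state]])
    return FiniteMDPEnv(
        P=P,
        R=R,
        terminal=terminal,
        horizon=horizon,
        initial_states=init,
        state_names=ALL_STATES,
        action_names=transitions.actions,
    )
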