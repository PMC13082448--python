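"""Transfer-pathway taxonomy, incidence evaluation and survival curves.

Enumerates the catalog of risk-transfer pathways (improvement,
deterioration, maintenance), walks the learned policy to the optimal
pathway per stratum, converts simulated lung-cancer events into per-100,000
incidence declines and trends, and estimates Kaplan-Meier product-limit
survival curves for the stratified risk groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mdp import TransitionModel
from .states import ALL_STATES, LUNG_CANCER, RISK_STATES, STATE_INDEX, risk_level

__all__ = [
    "Pathway",
    "IncidenceResult",
    "SurvivalCurve",
    "enumerate_pathways",
    "optimal_pathway",
    "incidence_decline",
    "simulate_incidence_trend",
    "km_curve",
    "extract_survival",
    "baseline_table",
]


@dataclass(frozen=True)
class Pathway:
    """Ordered risk-state sequence with its transfer direction."""

    states: tuple[str, ...]
    direction: str
    actions: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.direction != _classify(self.states):
            raise ValueError(
                f"direction {self.direction!r} inconsistent with states {self.states}"
            )
        if self.actions is not None and len(self.actions) != len(self.states) - 1:
            raise ValueError("actions must align with state steps")

    @classmethod
    def from_states(cls, states, actions=None) -> "Pathway":
        states = tuple(states)
        return cls(states=states, direction=_classify(states), actions=actions)

    def __str__(self) -> str:
        return "→".join(self.states)


def _classify(states: tuple[str, ...]) -> str:
    """Transfer direction of a state sequence.

    Singletons are maintenance; a sequence ending in lung-cancer occurrence
    or moving strictly up the risk ladder is deterioration; strictly down
    the ladder is improvement.
    """
    if len(states) == 0:
        raise ValueError("empty pathway")
    if len(states) == 1:
        return "maintenance"
    if states[-1] == LUNG_CANCER:
        if LUNG_CANCER in states[:-1]:
            raise ValueError("lung cancer is absorbing")
        return "deterioration"
    levels = [risk_level(s) for s in states]
    deltas = [b - a for a, b in zip(levels, levels[1:])]
    if all(d > 0 for d in deltas):
        return "improvement"  # toward non-risk
    if all(d < 0 for d in deltas):
        return "deterioration"
    if all(d == 0 for d in deltas):
        return "maintenance"
    raise ValueError(f"mixed-direction sequence {states}")


def enumerate_pathways(
    states: tuple[str, ...] = RISK_STATES, max_length: int = 4
) -> list[Pathway]:
    """The 20-pathway transfer catalog: 6 improvement, 10 deterioration,
    4 maintenance.

    Improvement: the stepwise chains down the ladder ending at non-risk
    (high→medium→low→non, medium→low→non, low→non), the direct jumps to
    non-risk (high→non, medium→non) and the one-skip chain high→low→non.
    Deterioration mirrors this toward high risk (with the one-skip chain
    non→medium→high) plus the four single-step drops into lung-cancer
    occurrence.  Maintenance: each stratum remaining unchanged.
    ``max_length`` truncates the catalog to sequences of at most that many
    states.
    """
    if max_length < 1:
        raise ValueError("max_length must be >= 1")
    ladder = list(states)  # high → non
    down = ladder
    improvement = [
        tuple(down[i:]) for i in range(len(down) - 1)  # stepwise chains to non
    ] + [
        (s, down[-1]) for s in down[:-2]  # direct jumps to non
    ] + [(down[0], down[2], down[3])]  # one-skip chain
    up = ladder[::-1]  # non → high
    deterioration = (
        [tuple(up[i:]) for i in range(len(up) - 1)]
        + [(s, up[-1]) for s in up[:-2]]
        + [(up[0], up[2], up[3])]
        + [(s, LUNG_CANCER) for s in ladder]
    )
    maintenance = [(s,) for s in ladder]

    def _dedupe(seqs):
        seen, out = set(), []
        for s in seqs:
            if s not in seen:
                seen.add(s)
                out.append(s)
        return out

    all_seqs = _dedupe(improvement) + _dedupe(deterioration) + maintenance
    return [Pathway.from_states(s) for s in all_seqs if len(s) <= max_length]


def _policy_action(policy, state: str, actions: tuple[str, ...]) -> str:
    if isinstance(policy, dict):
        if state not in policy:
            raise KeyError(f"policy undefined for state {state!r}")
        a = policy[state]
        return actions[a] if isinstance(a, (int, np.integer)) else a
    a = policy[STATE_INDEX[state]]
    return actions[int(a)] if not isinstance(a, str) else a


def optimal_pathway(
    start: str,
    policy,
    transitions: TransitionModel,
    max_cycles: int = 13,
) -> Pathway:
    """Most-probable state sequence under the greedy policy from ``start``.

    Follows each state's policy action to its most probable successor until
    reaching non-risk, lung-cancer occurrence, a stationary state or the
    cycle budget; ties in the successor break toward lower risk.  ``policy``
    is a dict {state: action} or an index array over all states.
    """
    if start not in RISK_STATES:
        raise ValueError(f"start must be a risk state, got {start!r}")
    path = [start]
    acts: list[str] = []
    visited = {start}
    s = start
    for _ in range(max_cycles):
        if s in (RISK_STATES[-1], LUNG_CANCER):
            break
        a = _policy_action(policy, s, transitions.actions)
        p = transitions.row(s, a)
        best = p.max()
        candidates = np.flatnonzero(np.isclose(p, best))
        # ties break toward lower risk: prefer ladder states closest to non
        ladder = [c for c in candidates if c < len(RISK_STATES)]
        nxt_idx = int(max(ladder)) if ladder else int(candidates[0])
        nxt = ALL_STATES[nxt_idx]
        if nxt == s or nxt in visited:
            break
        path.append(nxt)
        acts.append(a)
        visited.add(nxt)
        s = nxt
    # keep the longest direction-consistent prefix
    for end in range(len(path), 0, -1):
        try:
            return Pathway.from_states(path[:end], tuple(acts[: end - 1]) or None)
        except ValueError:
            continue
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class IncidenceResult:
    stratum: str
    incidence_before: float  # per 100,000
    incidence_after: float
    decline_pct: float


def incidence_decline(before: float, after: float) -> float:
    """Percent decline 100·(before − after)/before, to 2 decimals."""
    if before <= 0:
        raise ValueError("baseline incidence must be positive")
    if after < 0:
        raise ValueError("post-transfer incidence cannot be negative")
    return round(100.0 * (before - after) / before, 2)


def simulate_incidence_trend(
    policy,
    transitions: TransitionModel,
    hazards: dict[str, float],
    cycles: int,
    n_subjects: int,
    seed: int = 0,
    start_strata: tuple[str, ...] = RISK_STATES,
) -> pd.DataFrame:
    """Monte-Carlo lung-cancer incidence trend per starting stratum.

    Each cycle a subject first draws a lung-cancer event from the hazard of
    its current state, then (event-free) moves along the ladder according to
    the policy action's transition row renormalized over the four risk
    states.  Returns cumulative events per 100,000 starting subjects by
    cycle and stratum.  Under a maintenance policy the trend has closed form
    100000·(1 − (1−h)^cycle).
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    rng = np.random.default_rng(seed)
    h = np.array([hazards[s] for s in RISK_STATES])
    # per-state most relevant row under the policy, renormalized on the ladder
    move = np.zeros((len(RISK_STATES), len(RISK_STATES)))
    for si, s in enumerate(RISK_STATES):
        a = _policy_action(policy, s, transitions.actions)
        row = transitions.row(s, a)[: len(RISK_STATES)]
        move[si] = row / row.sum()
    cum_move = np.cumsum(move, axis=1)

    rows = []
    for stratum in start_strata:
        states = np.full(n_subjects, STATE_INDEX[stratum])
        active = np.ones(n_subjects, dtype=bool)
        cum_events = 0
        for cycle in range(1, cycles + 1):
            u = rng.random(n_subjects)
            event = active & (u < h[states])
            cum_events += int(event.sum())
            active &= ~event
            idx = np.flatnonzero(active)
            if idx.size:
                u2 = rng.random(idx.size)
                states[idx] = (u2[:, None] >= cum_move[states[idx]]).sum(axis=1)
            rows.append(
                {
                    "start_stratum": stratum,
                    "cycle": cycle,
                    "cumulative_events": cum_events,
                    "incidence_per_100k": 1e5 * cum_events / n_subjects,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SurvivalCurve:
    """Product-limit estimate S(t) with the underlying risk/event tallies."""

    times: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    survival: np.ndarray
    endpoint: str = "lung-cancer incidence survival"

    def at(self, t: float) -> float:
        """S(t): right-continuous step-function lookup (S(0) = 1)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
                "survival": self.survival,
            }
        )


def km_curve(
    times: np.ndarray, events: np.ndarray, endpoint: str = "lung-cancer incidence survival"
) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator S(t) = ∏_{t_i ≤ t} (1 − d_i/n_i).

    ``events`` flags whether the endpoint occurred at ``times`` (0 =
    right-censored); censored subjects leave the risk set after their time.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.shape != e.shape:
        raise ValueError("times and events must have equal length")
    if (t < 0).any():
        raise ValueError("negative time")
    if not np.isin(e, (0.0, 1.0)).all():
        raise ValueError("event flags must be binary")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq = np.unique(t)
    n = len(t)
    n_risk = np.empty(len(uniq), dtype=int)
    n_event = np.empty(len(uniq), dtype=int)
    surv = np.empty(len(uniq))
    s = 1.0
    for i, ti in enumerate(uniq):
        at_risk = n - np.searchsorted(t, ti, side="left")
        d = int(e[t == ti].sum())
        n_risk[i] = at_risk
        n_event[i] = d
        if at_risk > 0:
            s *= 1.0 - d / at_risk
        surv[i] = s
    return SurvivalCurve(times=uniq, n_risk=n_risk, n_event=n_event, survival=surv,
                         endpoint=endpoint)


def extract_survival(
    records: pd.DataFrame, endpoint: str = "incidence", wave_interval_years: int = 2
) -> pd.DataFrame:
    """Per-person time (years from first wave) and event flag for an endpoint.

    Endpoints: "incidence" (time to first lung-cancer event), "overall"
    (time to death from any cause), "lung_cancer_death" (death with a
    lung-cancer event); otherwise censored at the last observed wave.
    Includes each person's baseline stratum column when present.
    """
    if endpoint not in ("incidence", "overall", "lung_cancer_death"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    df = records.sort_values(["person_id", "wave_index"], kind="stable")
    rows = []
    for pid, g in df.groupby("person_id", sort=False):
        w0 = g["wave_index"].iloc[0]
        lc = g[g["lung_cancer_event"].astype(bool)]
        death = g[g["death_event"].astype(bool)]
        if endpoint == "incidence":
            hit = lc
        elif endpoint == "overall":
            hit = death
        else:
            hit = death[death["lung_cancer_event"].astype(bool)] if len(death) else death
        if len(hit):
            t = (hit["wave_index"].iloc[0] - w0) * wave_interval_years
            ev = 1
        else:
            t = (g["wave_index"].iloc[-1] - w0) * wave_interval_years
            ev = 0
        row = {"person_id": pid, "time": float(t), "event": ev}
        if "stratum" in g.columns:
            row["stratum"] = g["stratum"].iloc[0]
        elif "latent_state" in g.columns:
            row["stratum"] = g["latent_state"].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows)


_AGE_BINS = ((-np.inf, 45.0, "<=45"), (45.0, 65.0, "45-65"), (65.0, np.inf, ">65"))
_EDU_BINS = ((0, 3, "0-3"), (4, 6, "4-6"), (7, 9, "7-9"), (10, 12, "10-12"),
             (13, 16, "13-16"), (17, np.inf, ">=17"))


def baseline_table(
    records: pd.DataFrame, variables: list[str] | None = None
) -> pd.DataFrame:
    """Baseline characteristics: level counts and percentages to 2 decimals.

    Uses each person's first observed wave.  Numeric age (derived from
    calendar and birth year) and education are binned to the conventional
    reporting groups; missing values are reported as their own level.
    Percentages are 100·n/N of the table's person count.
    """
    df = records
    if "wave_index" in df.columns and "person_id" in df.columns:
        first = df.groupby("person_id", sort=False)["wave_index"].transform("min")
        df = df[df["wave_index"] == first]
    df = df.copy()
    if "calendar_year" in df.columns and "birth_year" in df.columns:
        age = pd.to_numeric(df["calendar_year"], errors="coerce") - pd.to_numeric(
            df["birth_year"], errors="coerce"
        )
        df["age_group"] = [
            next((lbl for lo, hi, lbl in _AGE_BINS if lo < a <= hi), np.nan)
            if pd.notna(a)
            else np.nan
            for a in age
        ]
    if "education_years" in df.columns:
        edu = pd.to_numeric(df["education_years"], errors="coerce")
        df["education_group"] = [
            next((lbl for lo, hi, lbl in _EDU_BINS if lo <= e <= hi), np.nan)
            if pd.notna(e)
            else np.nan
            for e in edu
        ]
    if variables is None:
        variables = [
            v
            for v in ("age_group", "gender", "marital_status", "education_group")
            if v in df.columns
        ]
    N = len(df)
    rows = []
    for var in variables:
        col = df[var].astype(object).where(df[var].notna(), "missing")
        counts = col.value_counts(dropna=False)
        if isinstance(df[var].dtype, pd.CategoricalDtype):
            # declared-but-unobserved levels are reported as 0 (0.00)
            levels = list(df[var].cat.categories)
            if "missing" in counts.index and "missing" not in levels:
                levels.append("missing")
            counts = counts.reindex(levels, fill_value=0)
        for level, n in counts.items():
            rows.append(
                {
                    "variable": var,
                    "level": level,
                    "n": int(n),
                    "pct": round(100.0 * n / N, 2) if N else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["variable", "level", "n", "pct"])
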