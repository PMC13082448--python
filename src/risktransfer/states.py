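"""Shared vocabulary for lung-cancer risk states and transfer actions.

The model stratifies subjects into four ordered risk states — high, medium,
low and non-risk — plus one absorbing state for lung-cancer occurrence.
Transfer actions are the behavioural interventions that can move a subject
between risk states over one biennial follow-up cycle: maintaining current
behaviour, extending the duration of smoking cessation, or reducing smoking
frequency.
"""

from __future__ import annotations

RISK_STATES: tuple[str, ...] = ("high", "medium", "low", "non")
LUNG_CANCER: str = "lung_cancer"
ALL_STATES: tuple[str, ...] = RISK_STATES + (LUNG_CANCER,)

STATE_INDEX: dict[str, int] = {s: i for i, s in enumerate(ALL_STATES)}
N_RISK_STATES: int = len(RISK_STATES)
N_STATES: int = len(ALL_STATES)

#: Transfer actions: risk maintenance, three cessation-extension targets and
#: three frequency reductions.
ACTIONS: tuple[str, ...] = (
    "maintain",
    "extend_cessation_1y",
    "extend_cessation_3y",
    "extend_cessation_5y",
    "reduce_freq_everyday_to_someday",
    "reduce_freq_someday_to_quit",
    "reduce_freq_everyday_to_quit",
)
ACTION_INDEX: dict[str, int] = {a: i for i, a in enumerate(ACTIONS)}


def risk_level(state: str) -> int:
    """Ordinal position of a risk state: 0 = high risk ... 3 = non-risk.

    Raises ``ValueError`` for the absorbing lung-cancer state, which has no
    position on the risk ladder.
    """
    if state not in RISK_STATES:
        raise ValueError(f"{state!r} is not a ladder risk state")
    return RISK_STATES.index(state)


def is_improvement(state: str, next_state: str) -> bool:
    """True when the move goes down the risk ladder (toward non-risk)."""
    if state not in RISK_STATES or next_state not in RISK_STATES:
        return False
    return risk_level(next_state) > risk_level(state)
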