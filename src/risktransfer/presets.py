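"""Named cohort-generator presets for the study conditions.

``default_config`` mirrors the observational setting (biennial waves from
1992, risk maintenance as the data-generating behaviour, hazards on the
scale of the reported per-100,000 incidences).  ``separable_config``
strengthens the state-conditional covariate separation so the latent
stratum is recoverable from covariates.  ``recovery_config`` removes
events and randomizes behaviour so every (state, action) transition cell
accumulates counts for estimator-recovery checks.  ``hrs_scale_config``
matches the HRS cohort scale (12,543 persons over 15 waves).
"""

from __future__ import annotations

import numpy as np

from .cohort import CohortConfig, CovariateProfile, default_transitions
from .states import N_STATES

__all__ = [
    "default_config",
    "separable_config",
    "recovery_config",
    "hrs_scale_config",
]


def default_config(seed: int = 0, n_subjects: int = 2000, n_waves: int = 8) -> CohortConfig:
    return CohortConfig(n_subjects=n_subjects, n_waves=n_waves, seed=seed)


def _pad(rows: list[list[float]]) -> np.ndarray:
    mat = np.zeros((N_STATES, N_STATES))
    mat[:4, :4] = np.asarray(rows)
    mat[4, 4] = 1.0
    return mat


def separable_config(seed: int = 7, n_subjects: int = 3000, n_waves: int = 6) -> CohortConfig:
    """Sticky risk states with strongly state-separated covariates."""
    sticky = {
        a: _pad(
            [
                [0.92, 0.05, 0.02, 0.01],
                [0.04, 0.90, 0.04, 0.02],
                [0.01, 0.04, 0.90, 0.05],
                [0.01, 0.02, 0.05, 0.92],
            ]
        )
        for a in ("maintain",)
    }
    profile = CovariateProfile(
        smoke_now_p=(0.95, 0.65, 0.30, 0.02),
        smoke_ever_extra_p=(0.03, 0.15, 0.25, 0.20),
        lung_disease_p=(0.90, 0.50, 0.12, 0.01),
        vigorous_p=(0.03, 0.25, 0.65, 0.95),
        drinking_p=(0.85, 0.60, 0.30, 0.05),
        prevention_p=(0.05, 0.30, 0.70, 0.95),
        cancer_history_p=(0.45, 0.18, 0.05, 0.005),
        bmi_mean=(32.5, 28.8, 25.5, 22.5),
        bmi_sd=(1.3, 1.3, 1.3, 1.3),
    )
    return CohortConfig(
        n_subjects=n_subjects,
        n_waves=n_waves,
        seed=seed,
        true_transitions=sticky,
        initial_state_probs=(0.25, 0.25, 0.25, 0.25),
        covariates=profile,
    )


def recovery_config(
    seed: int = 11, n_subjects: int = 20_000, n_waves: int = 8
) -> CohortConfig:
    """Event-free cohort with uniform random behaviour over three actions,
    tuned so every (state, action) cell collects many transitions."""
    transitions = {
        "maintain": _pad(
            [
                [0.70, 0.20, 0.07, 0.03],
                [0.15, 0.60, 0.18, 0.07],
                [0.05, 0.15, 0.62, 0.18],
                [0.02, 0.08, 0.20, 0.70],
            ]
        ),
        "extend_cessation_5y": _pad(
            [
                [0.30, 0.45, 0.18, 0.07],
                [0.05, 0.35, 0.45, 0.15],
                [0.02, 0.08, 0.40, 0.50],
                [0.01, 0.04, 0.10, 0.85],
            ]
        ),
        "reduce_freq_everyday_to_quit": _pad(
            [
                [0.50, 0.30, 0.15, 0.05],
                [0.10, 0.50, 0.30, 0.10],
                [0.05, 0.12, 0.55, 0.28],
                [0.03, 0.07, 0.15, 0.75],
            ]
        ),
    }
    return CohortConfig(
        n_subjects=n_subjects,
        n_waves=n_waves,
        seed=seed,
        true_transitions=transitions,
        state_hazards={"high": 0.0, "medium": 0.0, "low": 0.0, "non": 0.0},
        death_hazard={"high": 0.0, "medium": 0.0, "low": 0.0, "non": 0.0, "lung_cancer": 0.0},
        initial_state_probs=(0.25, 0.25, 0.25, 0.25),
        behavior_policy="uniform",
    )


def hrs_scale_config(seed: int = 0) -> CohortConfig:
    """HRS-scale preset: 12,543 persons followed biennially 1992–2020."""
    return CohortConfig(
        n_subjects=12_543, n_waves=15, seed=seed, true_transitions=default_transitions()
    )
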