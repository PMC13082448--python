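"""Shared fixtures: small cohorts and the heavier pipeline artifacts.

Session scope keeps the expensive stages (separable-cohort stratification,
recovery-cohort estimation) computed once for all tests that need them.
"""

from __future__ import annotations

import numpy as np
import pytest

import risktransfer as rt
from risktransfer.presets import recovery_config, separable_config
from risktransfer.stratifier import DNNTrainConfig, train_dnn


@pytest.fixture(scope="session")
def small_cohort() -> rt.Cohort:
    return rt.generate_cohort(rt.CohortConfig(n_subjects=300, n_waves=6, seed=1))


@pytest.fixture(scope="session")
def recovery_fit():
    """Event-free cohort with uniform behaviour and its estimated transitions."""
    cfg = recovery_config(seed=11, n_subjects=20_000, n_waves=8)
    cohort = rt.generate_cohort(cfg)
    model = rt.estimate_transitions(
        cohort.records, smoothing=0.5, actions=cfg.action_list
    )
    return cfg, cohort, model


@pytest.fixture(scope="session")
def separable_stratification():
    """Separable-preset pipeline: impute → split → train → stratify."""
    cfg = separable_config(seed=7)
    cohort = rt.generate_cohort(cfg)
    fm = rt.build_feature_matrix(cohort, label="latent_state")
    fm, converged = rt.impute(fm)
    train, test = rt.split(fm, (0.7, 0.3), seed=7)
    params, log = train_dnn(train.X, train.y, DNNTrainConfig(target="ordinal"))
    scores = rt.forward(params, test.X)
    strata = rt.stratify_scores(scores)
    true = np.asarray(rt.RISK_STATES, dtype=object)[test.y]
    return {
        "config": cfg,
        "converged": converged,
        "params": params,
        "log": log,
        "scores": scores,
        "predicted": strata,
        "true": true,
    }


@pytest.fixture(scope="session")
def risk_env_fit():
    """Default-dynamics cohort under uniform behaviour, estimated environment,
    and the exact value-iteration solution."""
    cfg = rt.CohortConfig(n_subjects=8000, n_waves=10, seed=2, behavior_policy="uniform")
    cohort = rt.generate_cohort(cfg)
    model = rt.estimate_transitions(cohort.records, smoothing=0.5, actions=cfg.action_list)
    env = rt.build_env(model, rt.RewardSpec(), horizon=14)
    from risktransfer.dqn import value_iteration

    q_star, pi_star = value_iteration(env, gamma=0.95, tol=1e-10)
    return cfg, cohort, model, env, q_star, pi_star
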