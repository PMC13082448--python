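"""Pathway catalog, optimal-pathway walk, incidence arithmetic, trend
simulation, Kaplan-Meier estimation and baseline tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import risktransfer as rt
from risktransfer.dqn import value_iteration
from risktransfer.mdp import RewardSpec, TransitionModel
from risktransfer.pathways import (
    Pathway,
    baseline_table,
    enumerate_pathways,
    extract_survival,
    incidence_decline,
    km_curve,
    optimal_pathway,
    simulate_incidence_trend,
)
from risktransfer.states import LUNG_CANCER, N_STATES, RISK_STATES


# --- pathway taxonomy -------------------------------------------------------


def test_catalog_cardinalities():
    catalog = enumerate_pathways()
    by_dir = {}
    for p in catalog:
        by_dir.setdefault(p.direction, []).append(p)
    assert len(by_dir["improvement"]) == 6
    assert len(by_dir["deterioration"]) == 10
    assert len(by_dir["maintenance"]) == 4
    assert len(catalog) == 20


def test_catalog_contains_named_pathways():
    seqs = {p.states for p in enumerate_pathways()}
    assert ("high", "medium", "low", "non") in seqs
    assert ("high", "low", "non") in seqs
    assert ("non", "low", "medium", "high") in seqs
    assert ("medium", LUNG_CANCER) in seqs
    for s in RISK_STATES:
        assert (s,) in seqs


def test_catalog_max_length_truncates():
    short = enumerate_pathways(max_length=2)
    assert all(len(p.states) <= 2 for p in short)
    with pytest.raises(ValueError):
        enumerate_pathways(max_length=0)


def test_direction_classification_and_validation():
    assert Pathway.from_states(("high", "low")).direction == "improvement"
    assert Pathway.from_states(("low", "high")).direction == "deterioration"
    assert Pathway.from_states(("low", LUNG_CANCER)).direction == "deterioration"
    assert Pathway.from_states(("medium",)).direction == "maintenance"
    with pytest.raises(ValueError, match="mixed"):
        Pathway.from_states(("high", "low", "medium"))
    with pytest.raises(ValueError, match="absorbing"):
        Pathway.from_states((LUNG_CANCER, "high", LUNG_CANCER))
    with pytest.raises(ValueError, match="inconsistent"):
        Pathway(states=("high", "low"), direction="deterioration")


# --- optimal pathway --------------------------------------------------------


def test_optimal_pathway_improvement_dominant_environment(risk_env_fit):
    """When improvement actions dominate, the high-risk optimum is the full
    descending chain."""
    _, _, model, env, _, pi_star = risk_env_fit
    path = optimal_pathway("high", pi_star, model)
    assert path.states == ("high", "medium", "low", "non")
    assert path.direction == "improvement"
    assert optimal_pathway("medium", pi_star, model).states == ("medium", "low", "non")
    assert optimal_pathway("low", pi_star, model).states == ("low", "non")


def test_optimal_pathway_from_non_risk_is_singleton(risk_env_fit):
    _, _, model, _, _, pi_star = risk_env_fit
    path = optimal_pathway("non", pi_star, model)
    assert path.states == ("non",)
    assert path.direction == "maintenance"


def test_optimal_pathway_adversarial_rewards_prefer_maintenance(risk_env_fit):
    """With improvement penalized, the exact solver maintains the stratum."""
    _, _, model, _, _, _ = risk_env_fit
    spec = RewardSpec(improvement_per_level=-2.0, deterioration_per_level=-3.0,
                      maintenance=0.0, lung_cancer=-10.0)
    env = rt.build_env(model, spec, horizon=14)
    _, pi = value_iteration(env, gamma=0.95, tol=1e-10)
    path = optimal_pathway("medium", pi, model)
    assert path.direction == "maintenance"


def test_optimal_pathway_requires_policy_for_state(risk_env_fit):
    _, _, model, _, _, _ = risk_env_fit
    with pytest.raises(KeyError, match="undefined"):
        optimal_pathway("high", {"low": "maintain"}, model)


# --- incidence arithmetic ---------------------------------------------------


def test_incidence_decline_reported_pairs():
    assert incidence_decline(1060.38, 336.78) == 68.24
    assert incidence_decline(671.20, 289.13) == 56.92


def test_incidence_decline_no_change_and_errors():
    assert incidence_decline(500.0, 500.0) == 0.0
    with pytest.raises(ValueError):
        incidence_decline(0.0, 10.0)
    with pytest.raises(ValueError):
        incidence_decline(10.0, -1.0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.floats(min_value=1e-3, max_value=1e5),
    st.floats(min_value=0.0, max_value=1e5),
    st.floats(min_value=1e-3, max_value=1e3),
)
def test_incidence_decline_scale_invariant(before, after, k):
    assert incidence_decline(k * before, k * after) == pytest.approx(
        incidence_decline(before, after), abs=0.011
    )


# --- trend simulation -------------------------------------------------------


def _identity_maintenance_model():
    probs = {}
    for i, s in enumerate(RISK_STATES):
        row = np.zeros(N_STATES)
        row[i] = 1.0
        probs[(s, "maintain")] = row
    return TransitionModel(probabilities=probs, actions=("maintain",))


MAINTAIN_POLICY = {s: "maintain" for s in RISK_STATES}


def test_trend_zero_hazards_zero_everywhere():
    model = _identity_maintenance_model()
    out = simulate_incidence_trend(
        MAINTAIN_POLICY, model, {s: 0.0 for s in RISK_STATES}, cycles=5,
        n_subjects=500, seed=1
    )
    assert (out["incidence_per_100k"] == 0.0).all()


def test_trend_seeded_reproducibility_and_input_validation():
    model = _identity_maintenance_model()
    h = {"high": 0.02, "medium": 0.01, "low": 0.005, "non": 0.001}
    a = simulate_incidence_trend(MAINTAIN_POLICY, model, h, 5, 1000, seed=3)
    b = simulate_incidence_trend(MAINTAIN_POLICY, model, h, 5, 1000, seed=3)
    pd.testing.assert_frame_equal(a, b)
    with pytest.raises(ValueError):
        simulate_incidence_trend(MAINTAIN_POLICY, model, h, 0, 1000, seed=3)
    with pytest.raises(ValueError):
        simulate_incidence_trend(MAINTAIN_POLICY, model, h, 5, 0, seed=3)


def test_trend_improvement_policy_beats_maintenance(risk_env_fit):
    cfg, _, model, env, _, pi_star = risk_env_fit
    n = 20_000
    maintain = simulate_incidence_trend(
        MAINTAIN_POLICY, model, cfg.state_hazards, 10, n, seed=4
    )
    improve = simulate_incidence_trend(
        pi_star, model, cfg.state_hazards, 10, n, seed=4
    )
    for s in ("high", "medium", "low"):
        final_m = maintain.query("start_stratum == @s and cycle == 10")[
            "incidence_per_100k"
        ].iloc[0]
        final_i = improve.query("start_stratum == @s and cycle == 10")[
            "incidence_per_100k"
        ].iloc[0]
        assert final_i < final_m


def test_trend_monte_carlo_error_halves_with_quadrupled_n():
    model = _identity_maintenance_model()
    h = {"high": 0.02, "medium": 0.02, "low": 0.02, "non": 0.02}

    def sd_of_final(n, seeds):
        vals = [
            simulate_incidence_trend(MAINTAIN_POLICY, model, h, 5, n, seed=s)
            .query("start_stratum == 'high' and cycle == 5")["incidence_per_100k"]
            .iloc[0]
            for s in seeds
        ]
        return np.std(vals)

    sd_small = sd_of_final(500, range(25))
    sd_large = sd_of_final(2000, range(25, 50))
    ratio = sd_small / sd_large
    assert 1.2 <= ratio <= 3.5  # theoretical ratio 2


# --- Kaplan-Meier -----------------------------------------------------------


def test_km_no_events_survival_one():
    curve = km_curve(np.array([1.0, 2.0, 3.0]), np.array([0, 0, 0]))
    assert (curve.survival == 1.0).all()
    assert curve.at(0.0) == 1.0


def test_km_no_censoring_equals_empirical_fraction():
    times = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
    events = np.ones(5)
    curve = km_curve(times, events)
    for t in (1.0, 2.0, 3.0, 5.0):
        assert curve.at(t) == pytest.approx(np.mean(times > t))


def test_km_textbook_example_hand_product_limit():
    times = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
    events = np.array([1.0, 1.0, 1.0, 0.0, 1.0, 0.0])
    curve = km_curve(times, events)
    assert curve.at(1.0) == pytest.approx(5 / 6)
    assert curve.at(2.0) == pytest.approx(5 / 6 * (1 - 2 / 5))
    assert curve.at(3.0) == pytest.approx(0.5)
    assert curve.at(4.0) == pytest.approx(0.25)
    assert curve.at(5.0) == pytest.approx(0.25)


def test_km_all_censored_at_common_time_is_one():
    curve = km_curve(np.full(8, 4.0), np.zeros(8))
    assert (curve.survival == 1.0).all()


def test_km_agrees_with_lifelines_on_random_data():
    import lifelines

    rng = np.random.default_rng(9)
    times = rng.exponential(5.0, size=200).round(1)
    events = (rng.random(200) < 0.7).astype(float)
    curve = km_curve(times, events)
    kmf = lifelines.KaplanMeierFitter().fit(times, events)
    for t in np.unique(times):
        ref = float(kmf.survival_function_.loc[t].iloc[0])
        assert curve.at(t) == pytest.approx(ref, abs=1e-10)


def test_km_validates_inputs():
    with pytest.raises(ValueError, match="negative"):
        km_curve(np.array([-1.0]), np.array([1.0]))
    with pytest.raises(ValueError, match="binary"):
        km_curve(np.array([1.0]), np.array([0.4]))


def test_extract_survival_times_and_flags():
    rows = []
    for w in range(4):
        rows.append({"person_id": "a", "wave_index": w,
                     "lung_cancer_event": w >= 2, "death_event": False,
                     "latent_state": "high"})
    for w in range(3):
        rows.append({"person_id": "b", "wave_index": w,
                     "lung_cancer_event": False, "death_event": w == 2,
                     "latent_state": "low"})
    df = pd.DataFrame(rows)
    inc = extract_survival(df, "incidence")
    assert inc.set_index("person_id").loc["a", ["time", "event"]].tolist() == [4.0, 1]
    assert inc.set_index("person_id").loc["b", ["time", "event"]].tolist() == [4.0, 0]
    ov = extract_survival(df, "overall")
    assert ov.set_index("person_id").loc["b", ["time", "event"]].tolist() == [4.0, 1]


# --- baseline table ---------------------------------------------------------


def test_baseline_table_counts_and_percentages():
    df = pd.DataFrame(
        {
            "gender": ["female"] * 6 + ["male"] * 3 + [np.nan],
        }
    )
    out = baseline_table(df, variables=["gender"]).set_index("level")
    assert out.loc["female", "n"] == 6
    assert out.loc["female", "pct"] == 60.0
    assert out.loc["missing", "pct"] == 10.0


def test_baseline_table_age_binning_from_years():
    df = pd.DataFrame(
        {
            "calendar_year": [1992] * 4,
            "birth_year": [1952, 1930, 1950, np.nan],  # ages 40, 62, 42, missing
        }
    )
    out = baseline_table(df, variables=["age_group"]).set_index("level")
    assert out.loc["<=45", "n"] == 2
    assert out.loc["45-65", "n"] == 1
    assert out.loc["missing", "n"] == 1


def test_baseline_table_reports_empty_declared_level():
    df = pd.DataFrame(
        {"stratum": pd.Categorical(["high", "high", "low"],
                                   categories=["high", "medium", "low"])}
    )
    out = baseline_table(df, variables=["stratum"]).set_index("level")
    assert out.loc["medium", "n"] == 0
    assert out.loc["medium", "pct"] == 0.0


def test_baseline_table_uses_first_wave_only(small_cohort):
    out = baseline_table(small_cohort.records)
    by_var = out.groupby("variable")["n"].sum()
    assert (by_var == small_cohort.n_subjects).all()
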