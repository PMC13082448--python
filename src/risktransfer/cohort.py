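"""Synthetic longitudinal cohort generator with known risk-state dynamics.

Emulates biennial follow-up survey data (HRS-like or CHARLS-like coding
dialects): each subject carries demographic and behavioural covariates, a
latent four-level lung-cancer risk state that evolves as a Markov chain
modulated by smoking-related actions, and state-dependent lung-cancer and
death events.  Because the generating transition matrices and hazards are
known, every downstream stage (stratification, transition estimation,
policy learning, trend simulation) can be tested for parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .states import ACTIONS, ALL_STATES, LUNG_CANCER, N_STATES, RISK_STATES

__all__ = [
    "CohortConfig",
    "Cohort",
    "CovariateProfile",
    "CohortConfigError",
    "generate_cohort",
    "inject_missingness",
    "emit_dialect",
    "default_transitions",
    "MASKABLE_COLUMNS",
    "HRS_CODES",
    "CHARLS_CODES",
    "EDUCATION_CATEGORY_YEARS",
]


class CohortConfigError(ValueError):
    """Raised when a cohort configuration field is invalid."""


MARITAL_LEVELS = (
    "married",
    "married_spouse_absent",
    "partnered",
    "separated",
    "divorced",
    "widowed",
    "never_married",
)
MARITAL_PROBS = (0.776, 0.005, 0.030, 0.025, 0.086, 0.049, 0.029)

SMOKING_FREQUENCY_LEVELS = ("everyday", "someday", "quit", "never")
CESSATION_LEVELS = ("<1 month", "1 year", "3 years", ">5 years", "not-applicable")

#: Covariate columns eligible for missing-completely-at-random masking.
#: Identifiers, ground-truth state and event flags are never masked.
MASKABLE_COLUMNS = (
    "birth_year",
    "gender",
    "marital_status",
    "bmi",
    "education_years",
    "smoke_ever",
    "smoke_now",
    "smoking_frequency",
    "cessation_duration",
    "vigorous_activity",
    "drinking",
    "prevention_behavior",
    "cancer_history",
    "lung_disease",
)


@dataclass(frozen=True)
class CovariateProfile:
    """State-conditional covariate distributions, indexed high→medium→low→non.

    Smoking intensity and lung-disease prevalence must be monotone in the
    latent state (heavier at high risk) so that covariates carry signal
    about the state they were generated from.
    """

    smoke_now_p: tuple[float, ...] = (0.75, 0.50, 0.25, 0.05)
    smoke_ever_extra_p: tuple[float, ...] = (0.15, 0.20, 0.25, 0.20)
    lung_disease_p: tuple[float, ...] = (0.40, 0.22, 0.10, 0.02)
    vigorous_p: tuple[float, ...] = (0.15, 0.30, 0.50, 0.70)
    drinking_p: tuple[float, ...] = (0.60, 0.45, 0.35, 0.25)
    prevention_p: tuple[float, ...] = (0.25, 0.40, 0.55, 0.75)
    cancer_history_p: tuple[float, ...] = (0.20, 0.12, 0.06, 0.02)
    bmi_mean: tuple[float, ...] = (29.5, 28.0, 26.5, 25.0)
    bmi_sd: tuple[float, ...] = (4.0, 4.0, 4.0, 4.0)

    def validate(self) -> None:
        for name in ("smoke_now_p", "lung_disease_p"):
            vals = getattr(self, name)
            if list(vals) != sorted(vals, reverse=True):
                raise CohortConfigError(f"covariates.{name} must be non-increasing in state")
        for name in (
            "smoke_now_p",
            "smoke_ever_extra_p",
            "lung_disease_p",
            "vigorous_p",
            "drinking_p",
            "prevention_p",
            "cancer_history_p",
        ):
            vals = getattr(self, name)
            if len(vals) != 4 or any(not 0.0 <= v <= 1.0 for v in vals):
                raise CohortConfigError(f"covariates.{name} must be 4 probabilities")


def default_transitions() -> dict[str, np.ndarray]:
    """Per-action 5×5 row-stochastic matrices over (high, medium, low, non, lung-cancer).

    Risk maintenance is sticky with mild drift; cessation-extension and
    frequency-reduction actions shift probability mass down the risk ladder,
    more strongly for longer cessation / larger frequency drops, and shrink
    the direct transition into the absorbing lung-cancer state.
    """
    m = {
        "maintain": [
            [0.820, 0.100, 0.030, 0.010, 0.040],
            [0.120, 0.740, 0.090, 0.030, 0.020],
            [0.030, 0.100, 0.750, 0.110, 0.010],
            [0.010, 0.030, 0.120, 0.838, 0.002],
        ],
        "extend_cessation_1y": [
            [0.650, 0.230, 0.070, 0.020, 0.030],
            [0.080, 0.600, 0.230, 0.075, 0.015],
            [0.020, 0.060, 0.640, 0.272, 0.008],
            [0.008, 0.020, 0.080, 0.890, 0.002],
        ],
        "extend_cessation_3y": [
            [0.500, 0.330, 0.110, 0.035, 0.025],
            [0.060, 0.450, 0.350, 0.128, 0.012],
            [0.015, 0.050, 0.500, 0.429, 0.006],
            [0.006, 0.015, 0.060, 0.917, 0.002],
        ],
        "extend_cessation_5y": [
            [0.250, 0.460, 0.200, 0.080, 0.010],
            [0.030, 0.280, 0.470, 0.214, 0.006],
            [0.008, 0.035, 0.330, 0.624, 0.003],
            [0.004, 0.008, 0.040, 0.947, 0.001],
        ],
        "reduce_freq_everyday_to_someday": [
            [0.680, 0.210, 0.060, 0.020, 0.030],
            [0.090, 0.620, 0.210, 0.065, 0.015],
            [0.022, 0.070, 0.650, 0.250, 0.008],
            [0.008, 0.022, 0.085, 0.883, 0.002],
        ],
        "reduce_freq_someday_to_quit": [
            [0.550, 0.300, 0.100, 0.025, 0.025],
            [0.065, 0.500, 0.310, 0.113, 0.012],
            [0.016, 0.055, 0.550, 0.372, 0.007],
            [0.006, 0.016, 0.065, 0.911, 0.002],
        ],
        "reduce_freq_everyday_to_quit": [
            [0.385, 0.410, 0.130, 0.060, 0.015],
            [0.050, 0.380, 0.400, 0.162, 0.008],
            [0.013, 0.050, 0.440, 0.492, 0.005],
            [0.005, 0.013, 0.055, 0.925, 0.002],
        ],
    }
    out: dict[str, np.ndarray] = {}
    for action, rows in m.items():
        mat = np.zeros((N_STATES, N_STATES))
        mat[:4, :] = np.asarray(rows)
        mat[4, 4] = 1.0  # lung cancer is absorbing
        out[action] = mat
    return out


@dataclass
class CohortConfig:
    """Configuration of the synthetic-cohort generator.

    ``true_transitions`` holds one 5×5 row-stochastic matrix per action over
    (high, medium, low, non, lung-cancer); the lung-cancer row must be a unit
    vector on itself.  ``state_hazards`` adds an extra per-cycle lung-cancer
    probability per risk state on top of any absorbing-column mass in the
    matrices; ``death_hazard`` gives the per-cycle death probability per
    state (death is censoring-with-flag, not a sixth MDP state).
    """

    n_subjects: int = 1000
    n_waves: int = 8
    wave_interval_years: int = 2
    baseline_year: int = 1992
    seed: int = 0
    true_transitions: dict[str, np.ndarray] = field(default_factory=default_transitions)
    state_hazards: dict[str, float] = field(
        default_factory=lambda: {"high": 0.0106, "medium": 0.0067, "low": 0.0033, "non": 0.0003}
    )
    death_hazard: dict[str, float] = field(
        default_factory=lambda: {
            "high": 0.030,
            "medium": 0.022,
            "low": 0.016,
            "non": 0.012,
            "lung_cancer": 0.250,
        }
    )
    missingness_rate: float = 0.0
    dialect: str = "hrs"
    initial_state_probs: tuple[float, ...] = (0.15, 0.25, 0.30, 0.30)
    #: Data-generating behaviour policy: "maintain", "uniform", or a callable
    #: ``(rng, state_indices, wave) -> action indices`` over the action list.
    behavior_policy: str | Callable = "maintain"
    covariates: CovariateProfile = field(default_factory=CovariateProfile)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise CohortConfigError("n_subjects must be >= 1")
        if self.n_waves < 2:
            raise CohortConfigError("n_waves must be >= 2")
        if self.wave_interval_years < 1:
            raise CohortConfigError("wave_interval_years must be >= 1")
        if not 0.0 <= self.missingness_rate < 1.0:
            raise CohortConfigError("missingness_rate must lie in [0, 1)")
        if self.dialect not in ("hrs", "charls"):
            raise CohortConfigError(f"dialect must be 'hrs' or 'charls', got {self.dialect!r}")
        if not self.true_transitions:
            raise CohortConfigError("true_transitions must contain at least one action")
        for action, mat in self.true_transitions.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (N_STATES, N_STATES):
                raise CohortConfigError(f"true_transitions[{action!r}] must be 5x5")
            if (mat < 0).any():
                raise CohortConfigError(f"true_transitions[{action!r}] has negative entries")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-12):
                raise CohortConfigError(f"true_transitions[{action!r}] rows must sum to 1")
            lc = np.zeros(N_STATES)
            lc[4] = 1.0
            if not np.array_equal(mat[4], lc):
                raise CohortConfigError(
                    f"true_transitions[{action!r}]: lung-cancer row must be absorbing"
                )
        for s in RISK_STATES:
            if s not in self.state_hazards:
                raise CohortConfigError(f"state_hazards missing state {s!r}")
            if not 0.0 <= self.state_hazards[s] <= 1.0:
                raise CohortConfigError(f"state_hazards[{s!r}] must lie in [0, 1]")
            if s not in self.death_hazard:
                raise CohortConfigError(f"death_hazard missing state {s!r}")
        probs = np.asarray(self.initial_state_probs, dtype=float)
        if probs.shape != (4,) or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise CohortConfigError("initial_state_probs must be 4 probabilities summing to 1")
        if isinstance(self.behavior_policy, str) and self.behavior_policy not in (
            "maintain",
            "uniform",
        ):
            raise CohortConfigError(
                f"behavior_policy must be 'maintain', 'uniform' or a callable, "
                f"got {self.behavior_policy!r}"
            )
        self.covariates.validate()

    @property
    def action_list(self) -> tuple[str, ...]:
        return tuple(self.true_transitions)

    def effective_matrix(self, action: str) -> np.ndarray:
        """Ground-truth per-cycle transition law with state hazards folded in.

        Row s (non-absorbing) is ``(1 - h_s) * P[a][s] + h_s * e_lc``: the
        extra hazard fires first, otherwise the chain follows the matrix.
        """
        base = np.asarray(self.true_transitions[action], dtype=float)
        out = base.copy()
        for i, s in enumerate(RISK_STATES):
            h = self.state_hazards[s]
            out[i] = (1.0 - h) * base[i]
            out[i, 4] += h
        return out

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["true_transitions"] = {
            a: np.asarray(m).tolist() for a, m in self.true_transitions.items()
        }
        d["behavior_policy"] = (
            self.behavior_policy if isinstance(self.behavior_policy, str) else "<callable>"
        )
        return d


@dataclass
class Cohort:
    """Long-format cohort: one row per subject per follow-up wave."""

    records: pd.DataFrame
    config: CohortConfig

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_subjects(self) -> int:
        return self.records["person_id"].nunique()


def _bucket_cessation(duration_years: np.ndarray) -> np.ndarray:
    """Discretize cessation duration (years) into the survey answer levels.

    Half-open brackets: [0,1) → "<1 month" (quit within the current wave),
    [1,3) → "1 year", [3,5) → "3 years", [5,∞) → ">5 years".
    """
    out = np.full(duration_years.shape, CESSATION_LEVELS[0], dtype=object)
    out[duration_years >= 1] = "1 year"
    out[duration_years >= 3] = "3 years"
    out[duration_years >= 5] = ">5 years"
    return out


def generate_cohort(config: CohortConfig) -> Cohort:
    """Simulate a longitudinal cohort under the configured dynamics.

    Latent risk states evolve by the per-action effective transition law
    (matrix plus extra hazard) under the configured behaviour policy;
    covariates are drawn from state-conditional distributions each wave;
    lung-cancer occurrence freezes the latent state and sets a monotone
    event flag; death ends the record sequence at the wave it is recorded.
    Fully reproducible given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    cov = config.covariates
    actions = config.action_list
    eff = {a: config.effective_matrix(a) for a in actions}
    # cumulative rows for inverse-CDF sampling
    eff_cum = {a: np.cumsum(m, axis=1) for a, m in eff.items()}

    person_ids = np.array([f"P{i:06d}" for i in range(n)])
    birth_year = config.baseline_year - rng.integers(50, 81, size=n)
    gender = np.where(rng.random(n) < 0.5366, "female", "male")
    marital = rng.choice(
        MARITAL_LEVELS, size=n, p=np.asarray(MARITAL_PROBS) / sum(MARITAL_PROBS)
    )
    education = np.clip(np.rint(rng.normal(12.0, 3.0, size=n)), 0, 17).astype(int)

    state = rng.choice(4, size=n, p=np.asarray(config.initial_state_probs, dtype=float))
    alive = np.ones(n, dtype=bool)
    has_lc = np.zeros(n, dtype=bool)
    smoke_ever = np.zeros(n, dtype=bool)
    # wave of last "smoking now" report; -1 means quit before baseline
    last_smoke_wave = np.full(n, -1, dtype=int)

    frames: list[pd.DataFrame] = []
    for w in range(config.n_waves):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        s = state[idx]
        p_now = np.asarray(cov.smoke_now_p)[s]
        smoke_now = rng.random(idx.size) < p_now
        extra_ever = rng.random(idx.size) < np.asarray(cov.smoke_ever_extra_p)[s]
        smoke_ever[idx] |= smoke_now | extra_ever
        ever = smoke_ever[idx]
        last_smoke_wave[idx[smoke_now]] = w

        freq = np.full(idx.size, "never", dtype=object)
        freq[ever & ~smoke_now] = "quit"
        everyday = smoke_now & (rng.random(idx.size) < 0.7)
        freq[smoke_now] = "someday"
        freq[everyday] = "everyday"

        cess = np.full(idx.size, "not-applicable", dtype=object)
        former = ever & ~smoke_now
        dur = (w - last_smoke_wave[idx[former]]) * config.wave_interval_years
        cess[former] = _bucket_cessation(dur.astype(float))

        dying = np.zeros(idx.size, dtype=bool)  # filled below for next wave
        frames.append(
            pd.DataFrame(
                {
                    "person_id": person_ids[idx],
                    "wave_index": w,
                    "calendar_year": config.baseline_year + w * config.wave_interval_years,
                    "birth_year": birth_year[idx],
                    "gender": gender[idx],
                    "marital_status": marital[idx],
                    "bmi": np.round(
                        rng.normal(np.asarray(cov.bmi_mean)[s], np.asarray(cov.bmi_sd)[s]), 2
                    ),
                    "education_years": education[idx],
                    "smoke_ever": ever,
                    "smoke_now": smoke_now,
                    "smoking_frequency": freq,
                    "cessation_duration": cess,
                    "vigorous_activity": rng.random(idx.size) < np.asarray(cov.vigorous_p)[s],
                    "drinking": rng.random(idx.size) < np.asarray(cov.drinking_p)[s],
                    "prevention_behavior": rng.random(idx.size)
                    < np.asarray(cov.prevention_p)[s],
                    "cancer_history": has_lc[idx]
                    | (rng.random(idx.size) < np.asarray(cov.cancer_history_p)[s]),
                    "lung_disease": rng.random(idx.size) < np.asarray(cov.lung_disease_p)[s],
                    "latent_state": np.asarray(RISK_STATES, dtype=object)[s],
                    "action": "",
                    "lung_cancer_event": has_lc[idx],
                    "death_event": dying,
                }
            )
        )

        if w == config.n_waves - 1:
            break

        # behaviour policy for the transition w -> w+1
        if callable(config.behavior_policy):
            act_idx = np.asarray(config.behavior_policy(rng, state[idx], w))
        elif config.behavior_policy == "uniform":
            act_idx = rng.integers(0, len(actions), size=idx.size)
        else:
            act_idx = np.zeros(idx.size, dtype=int)
            if "maintain" in actions:
                act_idx[:] = actions.index("maintain")
        frames[-1]["action"] = np.asarray(actions, dtype=object)[act_idx]

        # latent-state step for subjects not yet diagnosed
        u = rng.random(idx.size)
        new_state = state[idx].copy()
        new_lc = np.zeros(idx.size, dtype=bool)
        for ai, a in enumerate(actions):
            sel = (act_idx == ai) & ~has_lc[idx]
            if not sel.any():
                continue
            rows = eff_cum[a][state[idx[sel]]]
            nxt = (u[sel, None] >= rows).sum(axis=1)
            new_lc[sel] = nxt == 4
            new_state[sel] = np.where(nxt == 4, state[idx[sel]], nxt)
        has_lc[idx] |= new_lc
        state[idx] = new_state

        # death between waves, recorded at the next wave then censored
        dh = np.array([config.death_hazard[s_] for s_ in RISK_STATES])
        p_death = np.where(
            has_lc[idx], config.death_hazard.get(LUNG_CANCER, 0.25), dh[state[idx]]
        )
        dies = rng.random(idx.size) < p_death
        if dies.any():
            dead_idx = idx[dies]
            s_d = state[dead_idx]
            frames.append(
                pd.DataFrame(
                    {
                        "person_id": person_ids[dead_idx],
                        "wave_index": w + 1,
                        "calendar_year": config.baseline_year
                        + (w + 1) * config.wave_interval_years,
                        "birth_year": birth_year[dead_idx],
                        "gender": gender[dead_idx],
                        "marital_status": marital[dead_idx],
                        "bmi": np.nan,
                        "education_years": education[dead_idx],
                        "smoke_ever": smoke_ever[dead_idx],
                        "smoke_now": False,
                        "smoking_frequency": "quit",
                        "cessation_duration": "not-applicable",
                        "vigorous_activity": False,
                        "drinking": False,
                        "prevention_behavior": False,
                        "cancer_history": has_lc[dead_idx],
                        "lung_disease": False,
                        "latent_state": np.asarray(RISK_STATES, dtype=object)[s_d],
                        "action": "",
                        "lung_cancer_event": has_lc[dead_idx],
                        "death_event": True,
                    }
                )
            )
            alive[dead_idx] = False

    records = pd.concat(frames, ignore_index=True)
    records = records.sort_values(["person_id", "wave_index"], kind="stable").reset_index(
        drop=True
    )
    return Cohort(records=records, config=config)


def inject_missingness(cohort: Cohort, rate: float, seed: int) -> Cohort:
    """Mask covariate cells missing-completely-at-random at the given rate.

    Identifiers, wave indices, latent states and event flags are never
    masked.  The mask is a deterministic function of ``seed``.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("missingness rate must lie in [0, 1)")
    records = cohort.records.copy()
    if rate == 0.0:
        return Cohort(records=records, config=cohort.config)
    rng = np.random.default_rng(seed)
    cols = [c for c in MASKABLE_COLUMNS if c in records.columns]
    mask = rng.random((len(records), len(cols))) < rate
    for j, c in enumerate(cols):
        col = records[c]
        if col.dtype == bool or pd.api.types.is_integer_dtype(col):
            records[c] = col.astype(object)
        records.loc[mask[:, j], c] = np.nan
    return Cohort(records=records, config=cohort.config)


# --- dialect emission -------------------------------------------------------

#: Canonical column → survey code, HRS-like dialect.
HRS_CODES = {
    "person_id": "PN",
    "wave_index": "WAVE",
    "calendar_year": "YEAR",
    "birth_year": "RABYEAR",
    "gender": "RAGENDER",
    "marital_status": "R1MSTAT",
    "bmi": "R1BMI",
    "education_years": "RAEDYRS",
    "smoke_ever": "R1SMOKEV",
    "smoke_now": "R2SMOKEN",
    "smoking_frequency": "R1SMOKEF",
    "cessation_duration": "R1CESSDU",
    "vigorous_activity": "R1VGACTF",
    "drinking": "R1DRINK",
    "prevention_behavior": "R1CHOLST",
    "cancer_history": "R1CANCRE",
    "lung_disease": "R1LUNGE",
    "lung_cancer_event": "LUNGCA",
    "death_event": "DEATH",
}

#: CHARLS-like dialect: person id "ID", measured BMI "R1MBMI", categorical
#: education "RAEDUC_C", categorical activity code, and no cholesterol
#: prevention column.
CHARLS_CODES = {
    **HRS_CODES,
    "person_id": "ID",
    "bmi": "R1MBMI",
    "education_years": "RAEDUC_C",
    "vigorous_activity": "R1VGACT_C",
}
del CHARLS_CODES["prevention_behavior"]

GENDER_CODES = {"male": 1, "female": 2}
MARITAL_CODES = {lvl: i + 1 for i, lvl in enumerate(MARITAL_LEVELS)}

#: CHARLS-like education categories with the canonical years assigned on
#: harmonization (the illiterate level anchors at 0 years).
EDUCATION_CATEGORY_YEARS = {
    "no formal education illiterate": 0,
    "primary school": 6,
    "middle school": 9,
    "high school": 12,
    "vocational school": 15,
    "college and above": 16,
}
_EDU_BINS = ((0, "no formal education illiterate"), (1, "primary school"),
             (7, "middle school"), (10, "high school"), (13, "vocational school"),
             (16, "college and above"))


def _years_to_category(years: float) -> str:
    cat = _EDU_BINS[0][1]
    for lo, name in _EDU_BINS:
        if years >= lo:
            cat = name
    return cat


def emit_dialect(cohort: Cohort, dialect: str, path: str | Path | None = None) -> pd.DataFrame:
    """Render the cohort as a survey extract in one coding dialect.

    HRS-like tables code education in years ("RAEDYRS"); CHARLS-like tables
    code it as categories ("RAEDUC_C") and omit the cholesterol-prevention
    column.  The hidden ``latent_state`` is never emitted.  When ``path`` is
    given the table is written as CSV with a ``<path>.truth.json`` sidecar
    holding the generating configuration.
    """
    if dialect not in ("hrs", "charls"):
        raise ValueError(f"unknown dialect {dialect!r}")
    codes = HRS_CODES if dialect == "hrs" else CHARLS_CODES
    df = cohort.records.copy()

    def _recode(col: pd.Series, mapping: dict) -> pd.Series:
        return col.map(lambda v: mapping.get(v, v) if pd.notna(v) else v)

    df["gender"] = _recode(df["gender"], GENDER_CODES)
    df["marital_status"] = _recode(df["marital_status"], MARITAL_CODES)
    if dialect == "charls":
        df["education_years"] = df["education_years"].map(
            lambda v: _years_to_category(float(v)) if pd.notna(v) else v
        )
    for c in ("smoke_ever", "smoke_now", "vigorous_activity", "drinking",
              "prevention_behavior", "cancer_history", "lung_disease",
              "lung_cancer_event", "death_event"):
        df[c] = df[c].map(lambda v: int(v) if pd.notna(v) else v)

    out = df[[c for c in codes]].rename(columns=codes)
    if path is not None:
        path = Path(path)
        out.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".truth.json")
        sidecar.write_text(json.dumps(cohort.config.to_jsonable(), indent=1, sort_keys=True))
    return out
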