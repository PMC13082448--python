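"""Dialect harmonization and the preprocessing chain.

Maps HRS-like / CHARLS-like survey extracts onto one canonical schema, then
prepares model inputs: cessation-duration derivation from smoking reports,
mean-initialized iterative linear-regression imputation, SVD denoising,
SMOTE class balancing (training split only) and person-level train/test
splitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from importlib import resources as importlib_resources
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.exceptions import ConvergenceWarning
from sklearn.impute import IterativeImputer
from sklearn.linear_model import LinearRegression
from sklearn.neighbors import NearestNeighbors

from .cohort import (
    CESSATION_LEVELS,
    EDUCATION_CATEGORY_YEARS,
    GENDER_CODES,
    MARITAL_CODES,
    MARITAL_LEVELS,
    SMOKING_FREQUENCY_LEVELS,
    Cohort,
    _bucket_cessation,
)
from .states import RISK_STATES

__all__ = [
    "VariableMap",
    "FeatureMatrix",
    "load_variable_map",
    "harmonize",
    "derive_cessation",
    "build_feature_matrix",
    "impute",
    "svd_denoise",
    "smote_balance",
    "split",
    "N_FEATURES",
]

#: Width of the encoded feature matrix: a 27-column current-wave block
#: (age, BMI, education, sex, 7 marital levels, smoking ever/now, 4 frequency
#: levels, 5 cessation levels, activity, drinking, prevention, cancer
#: history, lung disease), the same block lagged one wave, plus the wave
#: index and normalized calendar year.
N_FEATURES = 56


@dataclass(frozen=True)
class VariableMap:
    """Canonical-name ↔ dialect-code correspondence with recoding rules."""

    entries: tuple[dict, ...]

    def __post_init__(self) -> None:
        names = [e["canonical"] for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("canonical names must be unique")
        for e in self.entries:
            if not (e.get("hrs") or e.get("charls")):
                raise ValueError(f"entry {e['canonical']!r} has no dialect code")

    def code_to_canonical(self, dialect: str) -> dict[str, str]:
        return {
            e[dialect]: e["canonical"] for e in self.entries if e.get(dialect) is not None
        }

    def recode_rule(self, canonical: str, dialect: str) -> str:
        for e in self.entries:
            if e["canonical"] == canonical:
                return e.get(f"recode_{dialect}", e.get("recode", "identity"))
        raise KeyError(canonical)


def load_variable_map() -> VariableMap:
    text = (
        importlib_resources.files("risktransfer.resources")
        .joinpath("variable_map.json")
        .read_text()
    )
    return VariableMap(entries=tuple(json.loads(text)["entries"]))


_GENDER_DECODE = {v: k for k, v in GENDER_CODES.items()}
_MARITAL_DECODE = {v: k for k, v in MARITAL_CODES.items()}


def _decode(col: pd.Series, rule: str) -> pd.Series:
    if rule == "identity":
        return col
    if rule == "gender_code":
        return col.map(lambda v: _GENDER_DECODE.get(int(v), v) if pd.notna(v) else v)
    if rule == "marital_code":
        return col.map(lambda v: _MARITAL_DECODE.get(int(v), v) if pd.notna(v) else v)
    if rule == "int_bool":
        return col.map(lambda v: bool(int(v)) if pd.notna(v) else v)
    if rule == "education_category":
        return col.map(lambda v: EDUCATION_CATEGORY_YEARS.get(v, v) if pd.notna(v) else v)
    raise ValueError(f"unknown recode rule {rule!r}")


def harmonize(
    table: pd.DataFrame | str | Path,
    dialect: str,
    variable_map: VariableMap | None = None,
) -> Cohort:
    """Map a dialect survey extract onto the canonical cohort schema.

    CHARLS-like education categories become years (the illiterate category
    anchors at 0 years); coded sex/marital levels become canonical labels;
    columns absent from the dialect (cholesterol prevention in CHARLS-like
    tables) stay absent rather than being imputed here.  Unknown columns
    raise a warning and are dropped; a missing person-id column is an error.
    """
    if dialect not in ("hrs", "charls"):
        raise ValueError(f"unknown dialect {dialect!r}")
    vmap = variable_map or load_variable_map()
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    codes = vmap.code_to_canonical(dialect)
    id_code = codes and {v: k for k, v in codes.items()}["person_id"]
    if len(table.columns) and id_code not in table.columns:
        raise ValueError(f"mandatory person-id column {id_code!r} missing")
    unknown = [c for c in table.columns if c not in codes]
    if unknown:
        warnings.warn(f"ignoring unknown columns {unknown}", stacklevel=2)
    out = {}
    for code, canonical in codes.items():
        if code in table.columns:
            out[canonical] = _decode(table[code], vmap.recode_rule(canonical, dialect))
    records = pd.DataFrame(out)
    if len(records):
        records = records.sort_values(["person_id", "wave_index"], kind="stable").reset_index(
            drop=True
        )
    return Cohort(records=records, config=None)


def derive_cessation(cohort: Cohort, wave_interval_years: int = 2) -> Cohort:
    """Fill ``cessation_duration`` from the smoking-ever / smoking-now reports.

    For an ever-smoker observed not smoking at wave w', duration is
    ``(w' − w) × interval`` years, where w is the last wave reporting
    current smoking (ever-smokers never observed smoking are treated as
    having quit one interval before baseline).  Durations discretize into
    half-open brackets [0,1) → "<1 month", [1,3) → "1 year", [3,5) →
    "3 years", [5,∞) → ">5 years"; current and never smokers are
    not-applicable.  Contradictory rows (smoking now without smoking ever)
    are repaired to smoke_ever=True with a warning.
    """
    df = cohort.records.copy()
    now = df["smoke_now"].map(lambda v: bool(v) if pd.notna(v) else False).to_numpy()
    ever = df["smoke_ever"].map(lambda v: bool(v) if pd.notna(v) else False).to_numpy()
    contradictory = now & ~ever
    if contradictory.any():
        warnings.warn(
            f"repaired {int(contradictory.sum())} rows reporting smoking now "
            "without smoking ever",
            stacklevel=2,
        )
        ever = ever | now
        df["smoke_ever"] = df["smoke_ever"].astype(object)
        df.loc[contradictory, "smoke_ever"] = True

    wave = df["wave_index"].to_numpy(dtype=float)
    smoke_wave = np.where(now, wave, -1.0)
    last_smoke = (
        pd.Series(smoke_wave).groupby(df["person_id"].to_numpy(), sort=False).cummax()
    ).to_numpy()
    duration = (wave - last_smoke) * wave_interval_years

    cess = np.full(len(df), "not-applicable", dtype=object)
    former = ever & ~now
    cess[former] = _bucket_cessation(duration[former])
    df["cessation_duration"] = cess
    return Cohort(records=df, config=cohort.config)


# --- feature encoding -------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Encoded per-wave design matrix with ids, labels and a missingness mask."""

    X: np.ndarray
    columns: tuple[str, ...]
    ids: pd.DataFrame
    y: np.ndarray | None = None
    mask: np.ndarray | None = None  # True where the cell was missing pre-imputation

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("X width must match the column manifest")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=list(self.columns))


def _onehot(col: pd.Series, levels: tuple[str, ...], prefix: str) -> pd.DataFrame:
    out = {}
    isna = col.isna()
    for lvl in levels:
        v = (col == lvl).astype(float)
        v[isna] = np.nan
        out[f"{prefix}_{lvl}"] = v
    return pd.DataFrame(out)


def _to_float(col: pd.Series) -> pd.Series:
    return col.map(lambda v: float(v) if pd.notna(v) else np.nan)


def _wave_block(df: pd.DataFrame, prefix: str = "") -> pd.DataFrame:
    blocks = [
        pd.DataFrame(
            {
                f"{prefix}age": _to_float(df["calendar_year"]) - _to_float(df["birth_year"]),
                f"{prefix}bmi": _to_float(df["bmi"]),
                f"{prefix}education_years": _to_float(df["education_years"]),
                f"{prefix}female": _to_float(df["gender"].map(
                    lambda v: v == "female" if pd.notna(v) else np.nan
                )),
            }
        ),
        _onehot(df["marital_status"], MARITAL_LEVELS, f"{prefix}marital").set_axis(
            df.index
        ),
        pd.DataFrame(
            {
                f"{prefix}smoke_ever": _to_float(df["smoke_ever"]),
                f"{prefix}smoke_now": _to_float(df["smoke_now"]),
            }
        ),
        _onehot(df["smoking_frequency"], SMOKING_FREQUENCY_LEVELS, f"{prefix}freq").set_axis(
            df.index
        ),
        _onehot(df["cessation_duration"], CESSATION_LEVELS, f"{prefix}cess").set_axis(
            df.index
        ),
        pd.DataFrame(
            {
                f"{prefix}vigorous_activity": _to_float(df["vigorous_activity"]),
                f"{prefix}drinking": _to_float(df["drinking"]),
                # structurally absent in the CHARLS-like dialect: a constant
                # zero channel, distinct from item nonresponse (NaN)
                f"{prefix}prevention_behavior": _to_float(df["prevention_behavior"])
                if "prevention_behavior" in df.columns
                else 0.0,
                f"{prefix}cancer_history": _to_float(df["cancer_history"]),
                f"{prefix}lung_disease": _to_float(df["lung_disease"]),
            },
            index=df.index,
        ),
    ]
    return pd.concat(blocks, axis=1)


def build_feature_matrix(cohort: Cohort, label: str | None = "latent_state") -> FeatureMatrix:
    """Encode a canonical cohort into the 56-column numeric design matrix.

    Columns: the current-wave block, the same block from the previous wave
    of the same person (first waves reuse their own values), plus the wave
    index and a normalized calendar year.  Labels: ``"latent_state"`` (the
    hidden risk level, synthetic cohorts only), ``"event"`` (lung-cancer
    occurrence at or after the current wave) or ``None``.
    """
    df = cohort.records.reset_index(drop=True)
    cur = _wave_block(df)
    prev_rows = df.groupby("person_id", sort=False).shift(1)
    prev_rows = prev_rows.where(prev_rows.notna(), df)  # first wave: reuse current
    lag = _wave_block(prev_rows, prefix="prev_")
    year = _to_float(df["calendar_year"])
    extra = pd.DataFrame(
        {
            "wave_index": _to_float(df["wave_index"]),
            "calendar_year_norm": (year - year.min())
            / max(float(year.max() - year.min()), 1.0),
        }
    )
    full = pd.concat([cur, lag, extra], axis=1)
    assert full.shape[1] == N_FEATURES

    y: np.ndarray | None = None
    if label == "latent_state":
        y = df["latent_state"].map(RISK_STATES.index).to_numpy()
    elif label == "event":
        ev = df["lung_cancer_event"].astype(bool).astype(int)
        y = (
            ev.iloc[::-1]
            .groupby(df["person_id"].iloc[::-1].to_numpy(), sort=False)
            .cummax()
            .iloc[::-1]
            .to_numpy()
        )
    elif label is not None:
        raise ValueError(f"unknown label {label!r}")

    X = full.to_numpy(dtype=float)
    return FeatureMatrix(
        X=X,
        columns=tuple(full.columns),
        ids=df[["person_id", "wave_index"]].copy(),
        y=y,
        mask=np.isnan(X),
    )


# --- preprocessing steps ----------------------------------------------------


def impute(
    matrix: FeatureMatrix, max_iter: int = 10, tol: float = 1e-3
) -> tuple[FeatureMatrix, bool]:
    """Mean-initialized iterative linear-regression imputation.

    Missing cells start at their column mean and are then re-predicted by a
    linear regression of each incomplete column on the others until the
    largest change falls below ``tol`` or ``max_iter`` rounds are reached.
    Observed cells are never altered.  Returns the completed matrix and a
    convergence flag.
    """
    X = matrix.X
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        bad = [matrix.columns[j] for j in np.flatnonzero(all_missing)]
        raise ValueError(f"columns entirely missing: {bad}")
    if not np.isnan(X).any():
        return replace(matrix, X=X.copy()), True
    imp = IterativeImputer(
        estimator=LinearRegression(),
        initial_strategy="mean",
        max_iter=max_iter,
        tol=tol,
        sample_posterior=False,
        random_state=0,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        filled = imp.fit_transform(X)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    out = X.copy()
    out[np.isnan(X)] = filled[np.isnan(X)]
    return replace(matrix, X=out), converged


def svd_denoise(matrix: FeatureMatrix, rank: int | str = "auto") -> FeatureMatrix:
    """Replace the standardized feature block by its best rank-r approximation.

    ``rank="auto"`` keeps the smallest rank retaining 95% of the squared
    singular-value mass.  Labels, ids and the missingness mask are untouched.
    """
    X = matrix.X
    if np.isnan(X).any():
        raise ValueError("impute before denoising: matrix contains missing cells")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    if rank == "auto":
        mass = np.cumsum(s**2) / max(float((s**2).sum()), 1e-300)
        rank = int(np.searchsorted(mass, 0.95) + 1)
    rank = int(rank)
    if rank <= 0:
        raise ValueError("rank must be positive")
    if rank > min(X.shape):
        raise ValueError(f"rank {rank} exceeds min(n, p) = {min(X.shape)}")
    Z_r = (U[:, :rank] * s[:rank]) @ Vt[:rank]
    return replace(matrix, X=Z_r * sd + mu)


def smote_balance(matrix: FeatureMatrix, k: int = 5, seed: int = 0) -> FeatureMatrix:
    """Oversample minority classes to the majority count via SMOTE.

    Each synthetic row is a convex combination of a minority row and one of
    its k nearest minority neighbours (Euclidean).  Original rows are
    preserved verbatim; synthetic rows carry person_id "synthetic" so they
    can never leak into person-level splits.  Apply to the training split
    only.
    """
    if matrix.y is None:
        raise ValueError("smote_balance requires labels")
    if np.isnan(matrix.X).any():
        raise ValueError("impute before SMOTE: matrix contains missing cells")
    y = np.asarray(matrix.y)
    classes, counts = np.unique(y, return_counts=True)
    majority = counts.max()
    rng = np.random.default_rng(seed)
    new_X: list[np.ndarray] = []
    new_y: list[np.ndarray] = []
    for cls, cnt in zip(classes, counts):
        need = majority - cnt
        if need == 0:
            continue
        if cnt < k + 1:
            raise ValueError(
                f"minority class {cls!r} has {cnt} rows < k+1={k + 1}; use a smaller k"
            )
        Xc = matrix.X[y == cls]
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, neigh = nn.kneighbors(Xc)  # first neighbour is the point itself
        base = rng.integers(0, cnt, size=need)
        pick = neigh[base, rng.integers(1, k + 1, size=need)]
        gap = rng.random((need, 1))
        new_X.append(Xc[base] + gap * (Xc[pick] - Xc[base]))
        new_y.append(np.full(need, cls, dtype=y.dtype))
    if not new_X:
        return replace(matrix, X=matrix.X.copy(), y=y.copy())
    X_out = np.vstack([matrix.X] + new_X)
    y_out = np.concatenate([y] + new_y)
    n_syn = X_out.shape[0] - matrix.n
    ids_out = pd.concat(
        [
            matrix.ids,
            pd.DataFrame({"person_id": ["synthetic"] * n_syn, "wave_index": [-1] * n_syn}),
        ],
        ignore_index=True,
    )
    mask_out = None
    if matrix.mask is not None:
        mask_out = np.vstack(
            [matrix.mask, np.zeros((n_syn, matrix.X.shape[1]), dtype=bool)]
        )
    return FeatureMatrix(X=X_out, columns=matrix.columns, ids=ids_out, y=y_out, mask=mask_out)


def split(
    data: Cohort | FeatureMatrix, fractions: tuple[float, float] = (0.7, 0.3), seed: int = 0
):
    """Person-level disjoint random split: all waves of a person go one way."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if isinstance(data, Cohort):
        persons = data.records["person_id"].to_numpy()
    else:
        persons = data.ids["person_id"].to_numpy()
    unique = np.unique(persons)
    rng = np.random.default_rng(seed)
    order = rng.permutation(unique)
    n_first = int(round(fractions[0] * len(unique)))
    if n_first == 0 or n_first == len(unique):
        raise ValueError("split would leave one side empty")
    first = set(order[:n_first])
    in_first = np.array([p in first for p in persons])

    def _take(keep: np.ndarray):
        if isinstance(data, Cohort):
            return Cohort(records=data.records[keep].reset_index(drop=True), config=data.config)
        return FeatureMatrix(
            X=data.X[keep],
            columns=data.columns,
            ids=data.ids[keep].reset_index(drop=True),
            y=None if data.y is None else data.y[keep],
            mask=None if data.mask is None else data.mask[keep],
        )

    return _take(in_first), _take(~in_first)
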