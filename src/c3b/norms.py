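"""Regression-based demographic norms and adjusted z-scores.

Raw scores on cognitive tests depend strongly on age, education, sex and
race.  Instead of stratified lookup tables, each test's normative model is
a linear regression of the raw score on those demographics, and a
subject's performance is expressed as

    adjusted z = (raw - predicted) / RMSE

where ``predicted`` is the regression's demographic prediction and RMSE is
the residual standard deviation of the normative fit, so z has mean 0 and
SD 1 in the normative population.

Two parametric forms are used.  The PST model carries a quadratic age term
centered at 50.26714; the VMT model carries a quadratic spline term
``max(0, age - 71)^2`` that activates only above the age-71 knot (plus no
sex term).  Indicator coding is male=1/female=0 and African-American=1/
non-AA=0; negative sex/race coefficients therefore encode worse expected
performance for males and for African-Americans, matching the normative
narrative.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "AGE_RANGE",
    "PST_AGE_CENTER",
    "VMT_AGE_KNOT",
    "Demographics",
    "NormativeModel",
    "FitResult",
    "BasisSpec",
    "PST_BASIS",
    "VMT_BASIS",
    "LINEAR_AGE_BASIS",
    "SingularDesignError",
    "ExtrapolationWarning",
    "nonlinear_age_term",
    "predicted_score",
    "adjusted_z",
    "z_from_predicted",
    "fit_normative_model",
    "select_model",
    "builtin_models",
    "load_models",
]

AGE_RANGE = (18.0, 89.0)
PST_AGE_CENTER = 50.26714
VMT_AGE_KNOT = 71.0


class SingularDesignError(ValueError):
    """The regression design matrix is rank deficient."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(
            "singular design matrix; offending columns: " + ", ".join(self.columns)
        )


class ExtrapolationWarning(UserWarning):
    """Demographics fall outside the normative sample's supported range."""


@dataclass(frozen=True)
class Demographics:
    """Predictor record: age in years, education in years, sex (male=1,
    female=0), race (African-American=1, non-AA=0)."""

    age: float
    education: float
    sex: int = 0
    race: int = 0

    def __post_init__(self) -> None:
        if self.education < 0:
            raise ValueError("education must be >= 0")
        if self.sex not in (0, 1) or self.race not in (0, 1):
            raise ValueError("sex and race must be 0/1 indicators")
        if not AGE_RANGE[0] <= self.age <= AGE_RANGE[1]:
            warnings.warn(
                f"age {self.age} outside the normative range {AGE_RANGE}; "
                "predictions are extrapolations",
                ExtrapolationWarning,
                stacklevel=2,
            )

    @property
    def extrapolated(self) -> bool:
        return not AGE_RANGE[0] <= self.age <= AGE_RANGE[1]


@dataclass(frozen=True)
class NormativeModel:
    """A fitted normative coefficient set for one test.

    ``beta_sex`` is ``None`` for models without a sex term (the VMT).
    ``age_constant`` is the centering constant of the quadratic age basis
    (PST) or the spline knot (VMT), per ``nonlinear_basis``.
    """

    test_id: str
    intercept: float
    beta_age: float
    beta_nonlinear_age: float
    beta_education: float
    beta_race: float
    rmse: float
    nonlinear_basis: str  # "quadratic_centered" | "knot_spline"
    age_constant: float
    beta_sex: float | None = None
    coefficient_set_id: str = "custom"

    def __post_init__(self) -> None:
        if self.rmse <= 0:
            raise ValueError("rmse must be > 0")
        if self.nonlinear_basis not in ("quadratic_centered", "knot_spline"):
            raise ValueError(f"unknown nonlinear basis {self.nonlinear_basis!r}")


@dataclass(frozen=True)
class FitResult:
    model: NormativeModel
    adjusted_r2: float
    standard_errors: Mapping[str, float]
    n: int
    basis_name: str = ""


def _nonlinear_basis_value(basis: str, constant: float, age) -> np.ndarray | float:
    age = np.asarray(age, dtype=float) if np.ndim(age) else float(age)
    if basis == "quadratic_centered":
        return (age - constant) ** 2
    if basis == "knot_spline":
        return np.maximum(0.0, age - constant) ** 2 if np.ndim(age) else max(0.0, age - constant) ** 2
    raise ValueError(f"unknown nonlinear basis {basis!r}")


def nonlinear_age_term(test_id: str, age: float) -> float:
    """Nonlinear age basis of the published models.

    PST: ``(age - 50.26714)^2``; VMT: ``max(0, age - 71)^2`` (zero at or
    below the knot).
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    tid = test_id.upper()
    if tid == "PST":
        return float(_nonlinear_basis_value("quadratic_centered", PST_AGE_CENTER, age))
    if tid == "VMT":
        return float(_nonlinear_basis_value("knot_spline", VMT_AGE_KNOT, age))
    raise ValueError(f"unknown test_id {test_id!r}")


def predicted_score(model: NormativeModel, demo: Demographics) -> float:
    """Demographically predicted raw score under ``model``."""
    pred = (
        model.intercept
        + model.beta_age * demo.age
        + model.beta_nonlinear_age
        * _nonlinear_basis_value(model.nonlinear_basis, model.age_constant, demo.age)
        + model.beta_education * demo.education
        + model.beta_race * demo.race
    )
    if model.beta_sex is not None:
        pred += model.beta_sex * demo.sex
    return float(pred)


def adjusted_z(raw: float, model: NormativeModel, demo: Demographics) -> float:
    """Demographically adjusted z-score: (raw - predicted) / RMSE."""
    return z_from_predicted(raw, predicted_score(model, demo), model.rmse)


def z_from_predicted(raw: float, predicted: float, rmse: float) -> float:
    """Adjusted z from an already-computed predicted score."""
    if rmse <= 0:
        raise ValueError("rmse must be > 0")
    return (raw - predicted) / rmse


# ---------------------------------------------------------------------------
# Norm fitting


@dataclass(frozen=True)
class BasisSpec:
    """A candidate regression basis for norm fitting.

    ``nonlinear_basis`` of ``None`` drops the nonlinear age column (pure
    linear-age model); ``include_sex`` controls the sex indicator column.
    """

    name: str
    nonlinear_basis: str | None
    age_constant: float = 0.0
    include_sex: bool = True

    @property
    def column_names(self) -> list[str]:
        cols = ["const", "age"]
        if self.nonlinear_basis is not None:
            cols.append("nonlinear_age")
        cols.append("education")
        if self.include_sex:
            cols.append("sex")
        cols.append("race")
        return cols

    def design_matrix(self, cohort: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(index=cohort.index)
        X["const"] = 1.0
        X["age"] = cohort["age"].astype(float)
        if self.nonlinear_basis is not None:
            X["nonlinear_age"] = _nonlinear_basis_value(
                self.nonlinear_basis, self.age_constant, cohort["age"].to_numpy(float)
            )
        X["education"] = cohort["education"].astype(float)
        if self.include_sex:
            X["sex"] = cohort["sex"].astype(float)
        X["race"] = cohort["race"].astype(float)
        return X


PST_BASIS = BasisSpec(
    name="pst_quadratic_age",
    nonlinear_basis="quadratic_centered",
    age_constant=PST_AGE_CENTER,
    include_sex=True,
)
VMT_BASIS = BasisSpec(
    name="vmt_knot71_spline",
    nonlinear_basis="knot_spline",
    age_constant=VMT_AGE_KNOT,
    include_sex=False,
)
LINEAR_AGE_BASIS = BasisSpec(name="linear_age", nonlinear_basis=None, include_sex=False)


def _singular_columns(X: pd.DataFrame) -> list[str]:
    """Name the columns that fail to add rank, scanning left to right."""
    bad: list[str] = []
    cols: list[str] = []
    rank = 0
    for c in X.columns:
        cand = X[cols + [c]].to_numpy(float)
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            rank = r
            cols.append(c)
        else:
            bad.append(c)
    return bad


def fit_normative_model(
    cohort: pd.DataFrame,
    form: BasisSpec,
    score_column: str,
    test_id: str = "custom",
) -> FitResult:
    """Least-squares fit of a normative basis on a cohort table.

    ``cohort`` needs columns ``age, education, sex, race`` and the raw
    score column.  The reported RMSE is the residual SD with denominator
    ``n - p`` — the quantity used as the z-score denominator.
    """
    if len(cohort) < 30:
        raise ValueError("norm fitting requires n >= 30")
    X = form.design_matrix(cohort)
    y = cohort[score_column].astype(float)
    if np.linalg.matrix_rank(X.to_numpy(float)) < X.shape[1]:
        raise SingularDesignError(_singular_columns(X))
    res = sm.OLS(y, X).fit()
    rmse = float(np.sqrt(res.scale))  # sqrt(SSR / (n - p))
    model = NormativeModel(
        test_id=test_id,
        intercept=float(res.params["const"]),
        beta_age=float(res.params["age"]),
        beta_nonlinear_age=float(res.params.get("nonlinear_age", 0.0)),
        beta_education=float(res.params["education"]),
        beta_sex=float(res.params["sex"]) if form.include_sex else None,
        beta_race=float(res.params["race"]),
        rmse=rmse if rmse > 0 else np.finfo(float).tiny,
        nonlinear_basis=form.nonlinear_basis or "quadratic_centered",
        age_constant=form.age_constant,
        coefficient_set_id=f"fit:{form.name}",
    )
    return FitResult(
        model=model,
        adjusted_r2=float(res.rsquared_adj),
        standard_errors={k: float(v) for k, v in res.bse.items()},
        n=int(res.nobs),
        basis_name=form.name,
    )


def select_model(
    cohort: pd.DataFrame,
    candidates: Iterable[BasisSpec],
    score_column: str,
    test_id: str = "custom",
) -> FitResult:
    """Fit every candidate basis and keep the best by adjusted R-squared.

    Ties are broken toward the basis with fewer coefficients.
    """
    fits: list[tuple[float, int, FitResult]] = []
    errors: list[str] = []
    for spec in candidates:
        try:
            fit = fit_normative_model(cohort, spec, score_column, test_id=test_id)
        except SingularDesignError as e:
            errors.append(f"{spec.name}: {e}")
            continue
        fits.append((fit.adjusted_r2, -len(spec.column_names), fit))
    if not fits:
        raise SingularDesignError(["all candidates singular: " + "; ".join(errors)])
    fits.sort(key=lambda t: (t[0], t[1]))
    return fits[-1][2]


# ---------------------------------------------------------------------------
# Published coefficient sets


def load_models(path) -> dict[str, NormativeModel]:
    """Load a coefficient-set config (JSON) into NormativeModel objects."""
    with open(path) as fh:
        cfg = json.load(fh)
    return _models_from_config(cfg)


def _models_from_config(cfg: Mapping) -> dict[str, NormativeModel]:
    set_id = cfg.get("coefficient_set_id", "custom")
    out: dict[str, NormativeModel] = {}
    for m in cfg["models"]:
        out[m["test_id"]] = NormativeModel(
            test_id=m["test_id"],
            intercept=m["intercept"],
            beta_age=m["beta_age"],
            beta_nonlinear_age=m["beta_nonlinear_age"],
            beta_education=m["beta_education"],
            beta_sex=m["beta_sex"],
            beta_race=m["beta_race"],
            rmse=m["rmse"],
            nonlinear_basis=m["nonlinear_basis"],
            age_constant=m["age_constant"],
            coefficient_set_id=set_id,
        )
    return out


def builtin_models() -> dict[str, NormativeModel]:
    """The published PST and VMT normative coefficient sets.

    PST: quadratic age centered at 50.26714, RMSE 8.958.  VMT: age-71 knot
    spline, no sex term, RMSE 12.879.
    """
    cfg = json.loads(
        resources.files("c3b").joinpath("data/coefficients.json").read_text()
    )
    return _models_from_config(cfg)
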