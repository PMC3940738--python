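"""Earnings and missed-workday regressions on worker microdata.

Household earnings are modelled by ordinary least squares on the
functional-limitations score with age-group dummies; missed workdays by a
negative-binomial (NB2) regression with a log link on the same design.
Fitted models are evaluated at the pooled-trial functional scores for the
surgical and nonsurgical arms to produce a per-age-group productivity
table: predicted annual earnings, predicted missed days, and the dollar
value of missed days (days x arm-specific earnings per workday).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .params import (
    AGE_GROUPS,
    AGE_WEIGHTS,
    ValidationError,
    default_productivity_table,
)

__all__ = [
    "EarningsModel",
    "MissedDaysModel",
    "fit_earnings_model",
    "fit_missed_days_model",
    "predict_productivity",
    "build_productivity_table",
]

_REFERENCE_GROUP = AGE_GROUPS[0]


def _design(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + score + age dummies (reference = first group)."""
    cols = [np.ones(len(df)), df["functional_score"].to_numpy(dtype=float)]
    names = ["intercept", "functional_score"]
    present = [g for g in AGE_GROUPS[1:] if (df["age_group"] == g).any()]
    for g in present:
        cols.append((df["age_group"] == g).to_numpy(dtype=float))
        names.append(g)
    return np.column_stack(cols), names


@dataclass(frozen=True)
class EarningsModel:
    """OLS earnings model: intercept + slope*score + age offsets (USD)."""

    intercept: float
    score_coefficient: float
    age_offsets: Mapping[str, float]
    residual_sd: float
    score_se: float = float("nan")  # standard error of the score coefficient

    def predict(self, score: float, age_group: str) -> float:
        if age_group not in self.age_offsets:
            raise ValidationError(f"age_group: unknown group {age_group!r}")
        if not 0.0 <= score <= 1.0:
            raise ValidationError(f"score: must lie in [0, 1], got {score}")
        return (self.intercept + self.age_offsets[age_group]
                + self.score_coefficient * score)

    def to_json(self) -> str:
        return json.dumps({
            "model": "earnings_ols",
            "intercept": self.intercept,
            "score_coefficient": self.score_coefficient,
            "age_offsets": dict(self.age_offsets),
            "residual_sd": self.residual_sd,
            "score_se": self.score_se,
        }, indent=2)


@dataclass(frozen=True)
class MissedDaysModel:
    """NB2 missed-workday model with log link; dispersion k, Var = mu + mu^2/k."""

    log_intercept: float
    score_coefficient: float
    age_offsets: Mapping[str, float]
    dispersion: float
    score_se: float = float("nan")
    converged: bool = True
    log_likelihood: float = float("nan")

    def predict(self, score: float, age_group: str) -> float:
        if age_group not in self.age_offsets:
            raise ValidationError(f"age_group: unknown group {age_group!r}")
        if not 0.0 <= score <= 1.0:
            raise ValidationError(f"score: must lie in [0, 1], got {score}")
        return float(np.exp(self.log_intercept + self.age_offsets[age_group]
                            + self.score_coefficient * score))

    def to_json(self) -> str:
        return json.dumps({
            "model": "missed_days_nb2",
            "log_intercept": self.log_intercept,
            "score_coefficient": self.score_coefficient,
            "age_offsets": dict(self.age_offsets),
            "dispersion": self.dispersion,
            "score_se": self.score_se,
            "converged": self.converged,
            "log_likelihood": self.log_likelihood,
        }, indent=2)


def _offsets_from(names: list[str], coefs: np.ndarray) -> dict[str, float]:
    offsets = {g: 0.0 for g in AGE_GROUPS}
    for name, c in zip(names, coefs):
        if name in offsets:
            offsets[name] = float(c)
    return offsets


def fit_earnings_model(records: pd.DataFrame) -> EarningsModel:
    """Ordinary least squares of household earnings on score + age dummies."""
    df = records
    if df["functional_score"].nunique() < 2:
        raise ValidationError("records: need >= 2 distinct functional scores")
    X, names = _design(df)
    if len(df) < X.shape[1]:
        raise ValidationError("records: need at least as many observations as parameters")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    res = sm.OLS(df["household_earnings"].to_numpy(dtype=float), X).fit()
    saturated = res.df_resid <= 0  # exact interpolation, e.g. two points
    return EarningsModel(
        intercept=float(res.params[0]),
        score_coefficient=float(res.params[1]),
        age_offsets=_offsets_from(names, res.params),
        residual_sd=0.0 if saturated else float(np.sqrt(res.scale)),
        score_se=float("nan") if saturated else float(res.bse[1]),
    )


def fit_missed_days_model(records: pd.DataFrame, maxiter: int = 200) -> MissedDaysModel:
    """Maximum-likelihood NB2 regression of missed workdays (log link)."""
    df = records
    y = df["missed_workdays"].to_numpy(dtype=float)
    if np.any(y < 0):
        raise ValidationError("records: missed_workdays must be non-negative")
    if not np.any(y > 0):
        raise ValidationError("records: all counts are zero; a log-link mean "
                              "of 0 is not representable")
    X, names = _design(df)
    if len(df) <= X.shape[1]:
        raise ValidationError("records: need more observations than parameters")
    model = sm.NegativeBinomial(y, X, loglike_method="nb2")
    res = model.fit(disp=False, maxiter=maxiter)
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged:
        grad = np.linalg.norm(model.score(res.params))
        raise ValidationError(
            f"missed-days fit did not converge in {maxiter} iterations "
            f"(last gradient norm {grad:.3g})")
    alpha = float(res.params[-1])  # statsmodels alpha = 1/k
    return MissedDaysModel(
        log_intercept=float(res.params[0]),
        score_coefficient=float(res.params[1]),
        age_offsets=_offsets_from(names, res.params[:-1]),
        dispersion=float(1.0 / alpha) if alpha > 0 else float("inf"),
        score_se=float(res.bse[1]),
        converged=converged,
        log_likelihood=float(res.llf),
    )


def predict_productivity(earnings_model: EarningsModel,
                         missed_days_model: MissedDaysModel,
                         score_surgical: float,
                         score_nonsurgical: float,
                         age_group: str,
                         workdays_per_year: float = 240.0) -> dict[str, float]:
    """One productivity-table row: predictions at the two arm scores.

    Missed-day dollar value uses the arm-specific predicted earnings per
    workday; change columns are nonsurgical-minus-surgical for missed-day
    values (a reduction is a benefit) and surgical-minus-nonsurgical for
    earnings, so positive change always means surgery is favourable.
    """
    earn_s = earnings_model.predict(score_surgical, age_group)
    earn_n = earnings_model.predict(score_nonsurgical, age_group)
    days_s = missed_days_model.predict(score_surgical, age_group)
    days_n = missed_days_model.predict(score_nonsurgical, age_group)
    val_s = days_s * earn_s / workdays_per_year
    val_n = days_n * earn_n / workdays_per_year
    return {
        "score_surgical": score_surgical,
        "score_nonsurgical": score_nonsurgical,
        "earnings_surgical": earn_s,
        "earnings_nonsurgical": earn_n,
        "earnings_change": earn_s - earn_n,
        "missed_days_surgical": days_s,
        "missed_days_nonsurgical": days_n,
        "missed_days_reduction": days_n - days_s,
        "missed_value_surgical": val_s,
        "missed_value_nonsurgical": val_n,
        "missed_value_change": val_n - val_s,
    }


def build_productivity_table(earnings_model: EarningsModel,
                             missed_days_model: MissedDaysModel,
                             scores: pd.DataFrame | None = None,
                             age_weights: Mapping[str, float] | None = None,
                             workdays_per_year: float = 240.0) -> pd.DataFrame:
    """Per-age productivity rows plus the age-weighted summary row.

    ``scores`` supplies per-group arm scores (columns score_surgical,
    score_nonsurgical, indexed by age group, with a ``weighted`` row giving
    the pooled arm scores); the packaged trial scores are the default.  The
    weighted row averages per-group predictions evaluated at the pooled
    scores over the age distribution.
    """
    weights = dict(age_weights if age_weights is not None else AGE_WEIGHTS)
    if scores is None:
        scores = default_productivity_table()[["score_surgical", "score_nonsurgical"]]
    rows = {}
    for g in weights:
        rows[g] = predict_productivity(
            earnings_model, missed_days_model,
            float(scores.loc[g, "score_surgical"]),
            float(scores.loc[g, "score_nonsurgical"]),
            g, workdays_per_year)
    s_w = float(scores.loc["weighted", "score_surgical"])
    n_w = float(scores.loc["weighted", "score_nonsurgical"])
    pooled = {
        g: predict_productivity(earnings_model, missed_days_model,
                                s_w, n_w, g, workdays_per_year)
        for g in weights
    }
    weighted = {k: sum(weights[g] * pooled[g][k] for g in weights)
                for k in next(iter(pooled.values()))}
    weighted["score_surgical"], weighted["score_nonsurgical"] = s_w, n_w
    rows["weighted"] = weighted
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "age_group"
    df.insert(0, "weight", [weights.get(g, 1.0) for g in df.index])
    return df
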