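"""Logistic-regression associations between serum biomarkers and CRC.

Albumin, uric acid and neutrophil count are modelled against the cumulative
CRC event flag, continuously and by sex-pooled biomarker quartile (Q1
reference), adjusted for the Model-3 covariate set.  Odds ratios with Wald
confidence intervals; separation and non-convergence produce explicit
failure results.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .scoring import DegenerateDistributionError, ScoredCohort, quartile_labels
from .survival import (
    ETHNICITY_LEVELS,
    MODEL_COVARIATES,
    QUARTILES,
    _frame,
    separating_indicators,
)

BIOMARKERS = ("albumin", "uric_acid", "neutrophils")


@dataclass
class LogisticResult:
    """Summary of one exposure term from a logistic fit."""

    term: str
    or_: float
    ci_low: float
    ci_high: float
    p: float
    n_used: int
    n_events: int
    outcome: str
    covariates: tuple[str, ...]
    status: str = "ok"
    message: str = ""

    @property
    def failed(self) -> bool:
        return self.status != "ok"


def _failure(term: str, outcome: str, covariates, message: str) -> LogisticResult:
    return LogisticResult(
        term=term,
        or_=float("nan"),
        ci_low=float("nan"),
        ci_high=float("nan"),
        p=float("nan"),
        n_used=0,
        n_events=0,
        outcome=outcome,
        covariates=tuple(covariates),
        status="failed",
        message=message,
    )


def _expand(df: pd.DataFrame, covariates) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        if cov == "ethnicity":
            for level in ETHNICITY_LEVELS[1:]:
                cols[f"ethnicity_{level}"] = (df["ethnicity"] == level).astype(float)
        else:
            cols[cov] = df[cov].astype(float)
    return pd.DataFrame(cols, index=df.index)


def _fit_terms(
    df: pd.DataFrame,
    exposure_cols: list[str],
    outcome: str,
    covariates,
) -> list[LogisticResult]:
    needed = list(exposure_cols) + [c for c in covariates if c != "ethnicity"]
    if "ethnicity" in covariates:
        needed.append("ethnicity")
    sub = df[needed + [outcome]].dropna()
    y = sub[outcome].astype(int)
    # center exposures, standardize covariates: exposure ORs are per raw
    # unit and unaffected, but the optimizer sees a well-scaled design
    expo = sub[exposure_cols].astype(float)
    expo = expo - expo.mean()
    zcov = _expand(sub, covariates)
    zcov = zcov.loc[:, zcov.nunique() > 1]
    zcov = zcov.drop(columns=separating_indicators(zcov, y))
    if not zcov.empty:
        zcov = (zcov - zcov.mean()) / zcov.std()
    X = pd.concat([expo, zcov], axis=1)
    for c in exposure_cols:
        if X[c].nunique() < 2:
            return [
                _failure(t, outcome, covariates, f"exposure {c!r} is constant")
                for t in exposure_cols
            ]
    X = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate fits handled below
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", False):
            raise RuntimeError("maximum-likelihood fit did not converge")
        params, conf, pvals = fit.params, fit.conf_int(), fit.pvalues
    except (RuntimeError, np.linalg.LinAlgError, ValueError, Exception) as exc:
        # statsmodels raises PerfectSeparationError (subclass of Exception)
        return [_failure(t, outcome, covariates, str(exc)) for t in exposure_cols]
    out = []
    for term in exposure_cols:
        out.append(
            LogisticResult(
                term=term,
                or_=float(np.exp(params[term])),
                ci_low=float(np.exp(conf.loc[term, 0])),
                ci_high=float(np.exp(conf.loc[term, 1])),
                p=float(pvals[term]),
                n_used=int(len(sub)),
                n_events=int(y.sum()),
                outcome=outcome,
                covariates=tuple(covariates),
            )
        )
    return out


def fit_logistic(
    scored: ScoredCohort | pd.DataFrame,
    exposure: str,
    form: str = "continuous",
    outcome: str = "crc",
    model_id: int | None = 3,
) -> list[LogisticResult]:
    """Logistic fit for a biomarker (or OBS) against the CRC flag.

    ``form="continuous"`` returns one OR per unit of the exposure;
    ``form="quartile"`` categorizes the exposure at its sex-pooled sample
    quartiles and returns Q2/Q3/Q4 ORs against Q1.  ``model_id=None`` fits
    the exposure alone (no covariates).
    """
    df = _frame(scored)
    covariates = MODEL_COVARIATES[model_id] if model_id is not None else ()
    if form == "continuous":
        return _fit_terms(df, [exposure], outcome, covariates)
    if form != "quartile":
        raise ValueError("form must be 'continuous' or 'quartile'")
    try:
        labels, _ = quartile_labels(df[exposure])
    except DegenerateDistributionError as exc:
        return [
            _failure(f"{exposure}_{q}", outcome, covariates, str(exc))
            for q in QUARTILES[1:]
        ]
    work = df[labels.notna()].copy()
    dummies = []
    for q in QUARTILES[1:]:
        col = f"{exposure}_{q}"
        work[col] = (labels.loc[work.index] == q).astype(float)
        dummies.append(col)
    return _fit_terms(work, dummies, outcome, covariates)


def biomarker_associations(
    scored: ScoredCohort | pd.DataFrame,
    biomarkers: tuple[str, ...] = BIOMARKERS,
    outcome: str = "crc",
    model_id: int = 3,
) -> pd.DataFrame:
    """Continuous + quartile logistic fits for each biomarker (tidy frame)."""
    rows = []
    for marker in biomarkers:
        for form in ("continuous", "quartile"):
            for r in fit_logistic(scored, marker, form=form, outcome=outcome, model_id=model_id):
                rows.append(
                    {
                        "biomarker": marker,
                        "form": form,
                        "term": r.term,
                        "or": round(r.or_, 3) if math.isfinite(r.or_) else r.or_,
                        "ci_low": round(r.ci_low, 3)
                        if math.isfinite(r.ci_low)
                        else r.ci_low,
                        "ci_high": round(r.ci_high, 3)
                        if math.isfinite(r.ci_high)
                        else r.ci_high,
                        "p": r.p,
                        "n_used": r.n_used,
                        "n_events": r.n_events,
                        "status": r.status,
                    }
                )
    return pd.DataFrame(rows)
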