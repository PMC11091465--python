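"""Cox proportional-hazards models for the OBS-CRC association.

Three nested covariate sets are used throughout:

* Model 1: age, ethnicity (indicator contrasts, European reference),
  education score, Townsend deprivation index
* Model 2: Model 1 + daily dietary energy intake
* Model 3: Model 2 + plasma CRP + NSAIDs use

The exposure enters either continuously (HR per OBS unit) or as quartile
indicators with Q1 as the reference.  Fits are complete-case on the model
variables; the time scale is years since study entry; ties are handled with
the Breslow approximation (lifelines' convention).  Degenerate fits
(no events, constant exposure, non-convergence) return an explicit failure
result rather than a silent number.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from scipy import stats

from .components import ComponentSpec
from .scoring import ScoredCohort, quartile_labels

MODEL_COVARIATES = {
    1: ("age", "ethnicity", "education", "tdi"),
    2: ("age", "ethnicity", "education", "tdi", "energy_intake"),
    3: ("age", "ethnicity", "education", "tdi", "energy_intake", "crp", "nsaids"),
}
ETHNICITY_LEVELS = ("European", "Mixed-race", "Asian", "African", "Chinese", "Others")
QUARTILES = ("Q1", "Q2", "Q3", "Q4")


class ModelFitError(RuntimeError):
    """A model could not be estimated (degenerate data or non-convergence)."""


@dataclass(frozen=True)
class ModelSpec:
    """One Cox analysis: nesting level, exposure form, outcome, subgroup."""

    model_id: int = 3
    exposure: str = "obs_total"
    exposure_form: str = "continuous"  # or "quartile"
    outcome: str = "crc"
    subgroup: str | None = None  # pandas query expression
    subgroup_label: str | None = None

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_COVARIATES:
            raise ValueError(f"model_id must be one of {sorted(MODEL_COVARIATES)}")
        if self.exposure_form not in ("continuous", "quartile"):
            raise ValueError("exposure_form must be 'continuous' or 'quartile'")

    @property
    def covariates(self) -> tuple[str, ...]:
        return MODEL_COVARIATES[self.model_id]

    @property
    def label(self) -> str:
        return self.subgroup_label or self.subgroup or "overall"


@dataclass
class CoxResult:
    """Summary of one exposure term from a proportional-hazards fit."""

    term: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n_used: int
    n_events: int
    model_id: int
    outcome: str
    subgroup: str
    p_trend: float | None = None
    status: str = "ok"
    message: str = ""

    @property
    def failed(self) -> bool:
        return self.status != "ok"


def _failure(spec: ModelSpec, term: str, message: str) -> CoxResult:
    return CoxResult(
        term=term,
        hr=float("nan"),
        ci_low=float("nan"),
        ci_high=float("nan"),
        p=float("nan"),
        n_used=0,
        n_events=0,
        model_id=spec.model_id,
        outcome=spec.outcome,
        subgroup=spec.label,
        status="failed",
        message=message,
    )


def _frame(scored: ScoredCohort | pd.DataFrame) -> pd.DataFrame:
    return scored.data if isinstance(scored, ScoredCohort) else scored


def _design(
    df: pd.DataFrame, spec: ModelSpec, exposure_cols: list[str]
) -> pd.DataFrame:
    """Complete-case design frame: exposure, covariates, duration, event."""
    needed = set(exposure_cols) | {"follow_up", spec.outcome}
    needed |= set(spec.covariates)
    missing = needed - set(df.columns)
    if missing:
        raise KeyError(f"columns absent from cohort: {sorted(missing)}")
    sub = df[sorted(needed, key=list(df.columns).index)].dropna()
    cols = {}
    for c in exposure_cols:
        cols[c] = sub[c].astype(float)
    for cov in spec.covariates:
        if cov == "ethnicity":
            for level in ETHNICITY_LEVELS[1:]:  # European = reference
                cols[f"ethnicity_{level}"] = (sub["ethnicity"] == level).astype(float)
        else:
            cols[cov] = sub[cov].astype(float)
    cols["follow_up"] = sub["follow_up"].astype(float)
    cols["event"] = sub[spec.outcome].astype(int)
    return pd.DataFrame(cols, index=sub.index)


def separating_indicators(
    X: pd.DataFrame, y: pd.Series, exclude: tuple[str, ...] = ()
) -> list[str]:
    """Binary covariate columns whose carriers have all-0 or all-1 outcomes.

    Such indicators (typically sparse category dummies at small n) drive
    quasi-separation: their ML coefficient diverges.  They carry no usable
    contrast and are dropped from adjustment sets.
    """
    out = []
    for c in X.columns:
        if c in exclude:
            continue
        vals = X[c].dropna().unique()
        if not set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
            continue
        carriers = y[X[c] == 1]
        if len(carriers) == 0 or carriers.sum() in (0, len(carriers)):
            out.append(c)
    return out


def _fit_design(design: pd.DataFrame, exposure_cols: list[str]) -> CoxPHFitter:
    """Fit lifelines Cox model, dropping degenerate covariate columns."""
    n_events = int(design["event"].sum())
    if len(design) == 0 or n_events < 1:
        raise ModelFitError(f"no usable events (n={len(design)}, events={n_events})")
    for c in exposure_cols:
        if design[c].nunique() < 2:
            raise ModelFitError(f"exposure {c!r} is constant; coefficient inestimable")
    drop = set(
        separating_indicators(
            design.drop(columns=["follow_up", "event"]),
            design["event"],
            exclude=tuple(exposure_cols),
        )
    )
    keep = [
        c
        for c in design.columns
        if c in ("follow_up", "event")
        or c in exposure_cols
        or (design[c].nunique() > 1 and c not in drop)
    ]
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            # sparse-event fits warn about wide steps; hard failures raise
            warnings.simplefilter("ignore")
            cph.fit(
                design[keep],
                duration_col="follow_up",
                event_col="event",
                show_progress=False,
            )
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
        raise ModelFitError(f"Cox fit failed: {exc}") from exc
    return cph


def _extract(
    cph: CoxPHFitter, term: str, spec: ModelSpec, design: pd.DataFrame
) -> CoxResult:
    row = cph.summary.loc[term]
    return CoxResult(
        term=term,
        hr=float(row["exp(coef)"]),
        ci_low=float(row["exp(coef) lower 95%"]),
        ci_high=float(row["exp(coef) upper 95%"]),
        p=float(row["p"]),
        n_used=int(len(design)),
        n_events=int(design["event"].sum()),
        model_id=spec.model_id,
        outcome=spec.outcome,
        subgroup=spec.label,
    )


def _subset(df: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    return df.query(spec.subgroup) if spec.subgroup else df


def fit_cox(scored: ScoredCohort | pd.DataFrame, spec: ModelSpec) -> list[CoxResult]:
    """Fit one nested Cox model; one result per exposure term.

    Continuous form returns a single HR per OBS unit; quartile form returns
    Q2/Q3/Q4 HRs against Q1 and attaches the P-for-trend to each.
    """
    df = _subset(_frame(scored), spec)
    if spec.exposure_form == "continuous":
        design = _design(df, spec, [spec.exposure])
        try:
            cph = _fit_design(design, [spec.exposure])
            return [_extract(cph, spec.exposure, spec, design)]
        except ModelFitError as exc:
            return [_failure(spec, spec.exposure, str(exc))]

    quart_col = f"{spec.exposure}_quartile" if spec.exposure != "obs_total" else "obs_quartile"
    if quart_col not in df.columns:
        raise KeyError(f"quartile column {quart_col!r} absent; categorize first")
    dummies = [f"{spec.exposure}_{q}" for q in QUARTILES[1:]]
    work = df.copy()
    for q, col in zip(QUARTILES[1:], dummies):
        work[col] = (work[quart_col] == q).astype(float)
    work = work[work[quart_col].notna()]
    try:
        design = _design(work, spec, dummies)
        cph = _fit_design(design, dummies)
    except ModelFitError as exc:
        return [_failure(spec, c, str(exc)) for c in dummies]
    try:
        trend = p_for_trend(work, spec, quart_col=quart_col)
    except ModelFitError:
        trend = None
    results = []
    for col in dummies:
        res = _extract(cph, col, spec, design)
        res.p_trend = trend
        results.append(res)
    return results


def p_for_trend(
    scored: ScoredCohort | pd.DataFrame, spec: ModelSpec, quart_col: str = "obs_quartile"
) -> float:
    """Wald p for the quartile index (1-4) entered as a single covariate."""
    df = _subset(_frame(scored), spec)
    if quart_col not in df.columns:
        raise KeyError(f"quartile column {quart_col!r} absent; categorize first")
    work = df[df[quart_col].notna()].copy()
    work["quartile_index"] = work[quart_col].cat.codes.astype(float) + 1.0
    design = _design(work, spec, ["quartile_index"])
    cph = _fit_design(design, ["quartile_index"])
    return float(cph.summary.loc["quartile_index", "p"])


def leave_one_out(
    scored: ScoredCohort,
    specs: list[ComponentSpec] | None = None,
    model: ModelSpec | None = None,
) -> pd.DataFrame:
    """Refit the continuous model once per excluded component.

    For each component c the exposure becomes ``obs_total - score_c`` (range
    0-42) and the row is labelled "OBS without <c>".  Per-row failures are
    recorded, never raised.
    """
    specs = scored.components if specs is None else specs
    model = ModelSpec(model_id=3) if model is None else model
    rows = []
    for comp in specs:
        work = scored.data.copy()
        work["obs_without"] = work["obs_total"] - work[comp.score_column]
        res = fit_cox(work, replace(model, exposure="obs_without"))[0]
        rows.append(
            {
                "excluded": comp.name,
                "label": f"OBS without {comp.name}",
                "hr": res.hr,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p": res.p,
                "n_used": res.n_used,
                "n_events": res.n_events,
                "status": res.status,
                "message": res.message,
            }
        )
    return pd.DataFrame(rows)


def subscore_analysis(
    scored: ScoredCohort | pd.DataFrame,
    model: ModelSpec | None = None,
) -> dict[str, CoxResult]:
    """Continuous fits for the lifestyle and dietary sub-scores."""
    model = ModelSpec(model_id=3) if model is None else model
    out = {}
    for sub in ("obs_lifestyle", "obs_diet"):
        out[sub] = fit_cox(scored, replace(model, exposure=sub))[0]
    return out


def hr_to_risk_reduction(hr: float) -> float:
    """Percent risk reduction implied by a hazard ratio: (1 - HR) x 100.

    Rounded to one decimal; negative when HR > 1.
    """
    if not math.isfinite(hr) or hr <= 0:
        raise ValueError(f"hazard ratio must be positive and finite, got {hr}")
    return round((1.0 - hr) * 100.0, 1)


# --- descriptive baseline table -------------------------------------------

CONTINUOUS_BASELINE = (
    "obs_total",
    "age",
    "tdi",
    "education",
    "bmi",
    "crp",
    "energy_intake",
    "albumin",
    "uric_acid",
    "neutrophils",
)
CATEGORICAL_BASELINE = ("sex", "ethnicity", "nsaids", "crc")


def baseline_table(
    scored: ScoredCohort | pd.DataFrame,
    continuous: tuple[str, ...] = CONTINUOUS_BASELINE,
    categorical: tuple[str, ...] = CATEGORICAL_BASELINE,
) -> pd.DataFrame:
    """Descriptive statistics by OBS quartile with rank-based / chi-square p.

    Continuous variables: mean (SD) per quartile, Kruskal-Wallis p (the
    k-sample generalization of the rank-sum test).  Categorical variables:
    n (%) per level per quartile, chi-square p; a single-level variable gets
    a not-applicable p.  Missing counts are reported per variable.
    """
    df = _frame(scored)
    if "obs_quartile" not in df.columns:
        raise KeyError("obs_quartile absent; categorize quartiles first")
    groups = {q: df[df["obs_quartile"] == q] for q in QUARTILES}
    rows = []

    def fmt_mean(s: pd.Series) -> str:
        return f"{s.mean():.1f} ({s.std():.1f})" if s.notna().any() else ""

    for var in continuous:
        if var not in df.columns:
            continue
        samples = [g[var].dropna() for g in groups.values()]
        try:
            nonempty = [s for s in samples if len(s) > 0]
            p = (
                float(stats.kruskal(*nonempty).pvalue)
                if len(nonempty) >= 2
                else float("nan")
            )
        except ValueError:  # all values identical
            p = float("nan")
        rows.append(
            {
                "variable": var,
                "level": "mean (SD)",
                "overall": fmt_mean(df[var]),
                **{q: fmt_mean(groups[q][var]) for q in QUARTILES},
                "missing": int(df[var].isna().sum()),
                "p_value": p,
            }
        )
    for var in categorical:
        if var not in df.columns:
            continue
        levels = pd.unique(df[var].dropna())
        counts = np.array(
            [[int((groups[q][var] == lv).sum()) for q in QUARTILES] for lv in levels]
        )
        if len(levels) < 2 or (counts.sum(axis=1) > 0).sum() < 2:
            p = float("nan")
        else:
            keep = counts[:, counts.sum(axis=0) > 0]
            p = float(stats.chi2_contingency(keep[keep.sum(axis=1) > 0]).pvalue)
        for i, lv in enumerate(levels):
            denom = {q: max(int(groups[q][var].notna().sum()), 1) for q in QUARTILES}
            all_n = max(int(df[var].notna().sum()), 1)
            rows.append(
                {
                    "variable": var,
                    "level": str(lv),
                    "overall": f"{int((df[var] == lv).sum())} "
                    f"({100.0 * (df[var] == lv).sum() / all_n:.1f}%)",
                    **{
                        q: f"{counts[i, j]} ({100.0 * counts[i, j] / denom[q]:.1f}%)"
                        for j, q in enumerate(QUARTILES)
                    },
                    "missing": int(df[var].isna().sum()),
                    "p_value": p if i == 0 else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def results_to_frame(results: list[CoxResult]) -> pd.DataFrame:
    """Tidy one-row-per-term frame (HR/CI rounded to 3 decimals for report)."""
    rows = []
    for r in results:
        rows.append(
            {
                "outcome": r.outcome,
                "model_id": r.model_id,
                "subgroup": r.subgroup,
                "term": r.term,
                "hr": round(r.hr, 3) if math.isfinite(r.hr) else r.hr,
                "ci_low": round(r.ci_low, 3) if math.isfinite(r.ci_low) else r.ci_low,
                "ci_high": round(r.ci_high, 3)
                if math.isfinite(r.ci_high)
                else r.ci_high,
                "p": r.p,
                "p_trend": r.p_trend,
                "n_used": r.n_used,
                "n_events": r.n_events,
                "status": r.status,
                "message": r.message,
            }
        )
    return pd.DataFrame(rows)
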