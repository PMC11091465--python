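"""Oxidative balance score construction.

Pipeline: derive composite exposures (meat, vegetable, physical activity),
estimate sex-stratified cut-points, assign per-component 0/1/2 scores, sum
into the total OBS and its dietary / lifestyle sub-scores, and categorize
the total into sample quartiles.

Scoring rules
-------------
* ``tertile`` components: cut-points are the 1/3 and 2/3 sample quantiles of
  non-missing values in the sex stratum (linear interpolation between order
  statistics, the "type 7" convention).  Antioxidants score 0 below the lower
  cut, 1 in the middle, 2 at or above the upper cut; pro-oxidants are the
  mirror image (2 - antioxidant score).
* ``abstention_binary`` components (smoking, alcohol, meat): a raw value of
  exactly 0 (non-consumption) scores 2; consumers at or below the consumer
  median score 1, above it 0.

Missing raw values propagate to missing scores; participants with any
missing component score are dropped (complete-case) and tallied in an
exclusion log.  Sex stratification applies to cut-point *estimation* only:
scores from both strata are pooled into a single analysis cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .components import ComponentSpec, default_components

TERTILE_PROBS = (1.0 / 3.0, 2.0 / 3.0)
QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


class SchemaError(KeyError):
    """A required raw column is absent from the cohort table."""


class EstimationError(ValueError):
    """Too little data in a stratum to estimate cut-points."""


class DegenerateDistributionError(ValueError):
    """Score distribution too degenerate to categorize."""


@dataclass(frozen=True)
class TertileCuts:
    lower: float
    upper: float
    n: int


@dataclass(frozen=True)
class AbstentionCuts:
    split: float  # consumer median
    n: int  # stratum sample size (consumers + abstainers)


@dataclass
class CutpointSet:
    """Cut-points per (component, stratum).

    ``stratify`` is ``"sex"`` (strata taken from the cohort's sex column) or
    ``"none"`` (single stratum ``"all"``).
    """

    stratify: str
    cuts: dict[tuple[str, str], TertileCuts | AbstentionCuts] = field(
        default_factory=dict
    )

    def get(self, component: str, stratum: str):
        key = (component, stratum if self.stratify == "sex" else "all")
        try:
            return self.cuts[key]
        except KeyError:
            raise EstimationError(
                f"no cut-points for component {component!r}, stratum {stratum!r}"
            ) from None


@dataclass
class ScoredCohort:
    """Cohort with per-component scores, OBS totals and quartile labels."""

    data: pd.DataFrame
    components: list[ComponentSpec]
    cutpoints: CutpointSet
    exclusions: dict
    quartile_edges: tuple[float, float, float] | None = None


def derive_composites(
    cohort: pd.DataFrame, specs: list[ComponentSpec] | None = None
) -> pd.DataFrame:
    """Add composite exposure columns (sum-combined components).

    meat = beef + lamb + pork; vegetable = raw + cooked vegetables;
    physical_activity = light + moderate + vigorous weekly MET-minutes.
    A missing addend makes the composite missing.
    """
    specs = default_components() if specs is None else specs
    out = cohort.copy()
    for spec in specs:
        if spec.combine != "sum":
            continue
        missing = [c for c in spec.source_columns if c not in out.columns]
        if missing:
            raise SchemaError(
                f"composite {spec.name!r}: missing source columns {missing}"
            )
        # plain sum: NaN in any addend propagates to the composite
        out[spec.name] = sum(out[c] for c in spec.source_columns)
    return out


def _strata(cohort: pd.DataFrame, stratify: str) -> dict[str, pd.Series]:
    if stratify == "none":
        return {"all": pd.Series(True, index=cohort.index)}
    if stratify == "sex":
        if "sex" not in cohort.columns:
            raise SchemaError("sex column required for sex-stratified cut-points")
        return {
            str(level): cohort["sex"] == level
            for level in pd.unique(cohort["sex"].dropna())
        }
    raise ValueError(f"unknown stratification {stratify!r}")


def compute_cutpoints(
    cohort: pd.DataFrame,
    specs: list[ComponentSpec] | None = None,
    stratify: str = "sex",
) -> CutpointSet:
    """Estimate per-component, per-stratum cut-points from non-missing values."""
    specs = default_components() if specs is None else specs
    cuts = CutpointSet(stratify=stratify)
    for spec in specs:
        if spec.column not in cohort.columns:
            raise SchemaError(f"component {spec.name!r}: column {spec.column!r} absent")
        for stratum, mask in _strata(cohort, stratify).items():
            values = cohort.loc[mask, spec.column].dropna().to_numpy(dtype=float)
            if spec.rule == "tertile":
                if values.size < 3:
                    raise EstimationError(
                        f"component {spec.name!r}, stratum {stratum!r}: "
                        f"{values.size} non-missing values, need >= 3 for tertiles"
                    )
                lower, upper = np.quantile(values, TERTILE_PROBS)
                if lower == upper:
                    warnings.warn(
                        f"component {spec.name!r}, stratum {stratum!r}: tied "
                        f"tertile boundaries ({lower}); bins will be unbalanced",
                        stacklevel=2,
                    )
                cuts.cuts[(spec.name, stratum)] = TertileCuts(
                    lower=float(lower), upper=float(upper), n=int(values.size)
                )
            else:  # abstention_binary
                consumers = values[values > 0]
                if consumers.size < 1:
                    raise EstimationError(
                        f"component {spec.name!r}, stratum {stratum!r}: "
                        "no consumers to estimate the abstention split point"
                    )
                cuts.cuts[(spec.name, stratum)] = AbstentionCuts(
                    split=float(np.median(consumers)), n=int(values.size)
                )
    return cuts


def _score_values(
    values: np.ndarray, spec: ComponentSpec, cp: TertileCuts | AbstentionCuts
) -> np.ndarray:
    """Vectorized 0/1/2 scoring; NaN in -> NaN out."""
    out = np.full(values.shape, np.nan)
    ok = ~np.isnan(values)
    v = values[ok]
    if spec.rule == "tertile":
        anti = np.where(v < cp.lower, 0.0, np.where(v < cp.upper, 1.0, 2.0))
        out[ok] = anti if spec.polarity == "antioxidant" else 2.0 - anti
    else:
        out[ok] = np.where(v == 0, 2.0, np.where(v <= cp.split, 1.0, 0.0))
    return out


def score_component(
    value: float, spec: ComponentSpec, cuts: CutpointSet, stratum: str
) -> float:
    """Score a single raw value; returns 0/1/2 or NaN for missing input."""
    cp = cuts.get(spec.name, stratum)
    return float(_score_values(np.asarray([value], dtype=float), spec, cp)[0])


def score_cohort(
    cohort: pd.DataFrame,
    specs: list[ComponentSpec] | None = None,
    stratify: str = "sex",
    cutpoints: CutpointSet | None = None,
) -> ScoredCohort:
    """Score every component, sum OBS totals, drop incomplete participants.

    Returns a :class:`ScoredCohort` whose ``data`` holds integer columns
    ``score_<component>``, ``obs_total``, ``obs_diet`` and ``obs_lifestyle``,
    and whose ``exclusions`` log counts dropped rows per component.
    """
    specs = default_components() if specs is None else specs
    df = derive_composites(cohort, specs)
    if cutpoints is None:
        cutpoints = compute_cutpoints(df, specs, stratify=stratify)

    strata = _strata(df, cutpoints.stratify)
    score_cols = {}
    for spec in specs:
        col = np.full(len(df), np.nan)
        for stratum, mask in strata.items():
            cp = cutpoints.get(spec.name, stratum)
            vals = df.loc[mask, spec.column].to_numpy(dtype=float)
            col[mask.to_numpy()] = _score_values(vals, spec, cp)
        score_cols[spec.score_column] = col

    scores = pd.DataFrame(score_cols, index=df.index)
    complete = scores.notna().all(axis=1)
    missing_by_component = {
        spec.name: int(scores[spec.score_column].isna().sum()) for spec in specs
    }
    exclusions = {
        "n_input": int(len(df)),
        "n_retained": int(complete.sum()),
        "n_excluded": int((~complete).sum()),
        "missing_by_component": missing_by_component,
    }
    if not complete.any():
        raise EstimationError("no participant has a complete set of component scores")

    data = df.loc[complete].copy()
    scores = scores.loc[complete].astype(np.int64)
    for c in scores.columns:
        data[c] = scores[c]
    diet = [s.score_column for s in specs if s.category == "dietary"]
    life = [s.score_column for s in specs if s.category == "lifestyle"]
    data["obs_diet"] = scores[diet].sum(axis=1)
    data["obs_lifestyle"] = scores[life].sum(axis=1)
    data["obs_total"] = data["obs_diet"] + data["obs_lifestyle"]
    return ScoredCohort(
        data=data, components=specs, cutpoints=cutpoints, exclusions=exclusions
    )


def quartile_labels(
    values: pd.Series, edges: tuple[float, float, float] | None = None
) -> tuple[pd.Series, tuple[float, float, float]]:
    """Assign Q1-Q4 by sample quartiles, left-closed right-open intervals.

    Q1: value < p25; Q2: p25 <= value < p50; Q3: p50 <= value < p75;
    Q4: value >= p75 (closed at the observed maximum).  ``edges`` may be
    supplied to replicate a fixed categorization.
    """
    x = values.to_numpy(dtype=float)
    finite = x[~np.isnan(x)]
    if edges is None:
        if np.unique(finite).size < 4:
            raise DegenerateDistributionError(
                "fewer than 4 distinct values; quartiles undefined"
            )
        edges = tuple(float(e) for e in np.percentile(finite, [25, 50, 75]))
    idx = (
        (x[:, None] >= np.asarray(edges)[None, :]).sum(axis=1)
    )  # 0..3, NaN handled below
    labels = pd.Series(
        pd.Categorical.from_codes(
            np.where(np.isnan(x), -1, idx).astype(int),
            categories=list(QUARTILE_LABELS),
            ordered=True,
        ),
        index=values.index,
    )
    return labels, edges


def categorize_quartiles(
    scored: ScoredCohort, edges: tuple[float, float, float] | None = None
) -> ScoredCohort:
    """Add an ``obs_quartile`` column to a scored cohort (Q1 lowest OBS)."""
    labels, used_edges = quartile_labels(scored.data["obs_total"], edges=edges)
    scored.data["obs_quartile"] = labels
    scored.quartile_edges = used_edges
    return scored
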