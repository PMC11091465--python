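"""OBS scoring: composites, cut-points, 0/1/2 assignment, quartiles.

The brute-force oracle used here re-implements tertile/abstention scoring
by explicit sorting and interpolation, independently of the package's
vectorized path.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxbalance.components import ComponentSpec, default_components
from oxbalance.scoring import (
    DegenerateDistributionError,
    EstimationError,
    SchemaError,
    categorize_quartiles,
    compute_cutpoints,
    derive_composites,
    quartile_labels,
    score_cohort,
    score_component,
)
from conftest import random_raw_cohort

# --- independent oracle ----------------------------------------------------


def oracle_quantile(values, p):
    """Linear interpolation between order statistics (explicit sort)."""
    x = sorted(values)
    h = p * (len(x) - 1)
    lo = math.floor(h)
    hi = math.ceil(h)
    return x[lo] + (h - lo) * (x[hi] - x[lo])


def oracle_score(value, spec, stratum_values):
    """Score one value against its stratum by direct sort-and-assign."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    clean = [v for v in stratum_values if not math.isnan(v)]
    if spec.rule == "tertile":
        lower = oracle_quantile(clean, 1 / 3)
        upper = oracle_quantile(clean, 2 / 3)
        if value < lower:
            anti = 0
        elif value < upper:
            anti = 1
        else:
            anti = 2
        return anti if spec.polarity == "antioxidant" else 2 - anti
    consumers = sorted(v for v in clean if v > 0)
    k = len(consumers)
    split = (
        consumers[k // 2]
        if k % 2
        else (consumers[k // 2 - 1] + consumers[k // 2]) / 2
    )
    if value == 0:
        return 2
    return 1 if value <= split else 0


# --- composites ------------------------------------------------------------


def test_composites_arithmetic_and_zero():
    df = pd.DataFrame(
        {
            "beef": [1.0, 0.0],
            "lamb": [2.0, 0.0],
            "pork": [3.0, 0.0],
            "raw_vegetables": [0.0, 1.5],
            "cooked_vegetables": [0.0, 2.5],
            "met_light": [10.0, 0.0],
            "met_moderate": [20.0, 0.0],
            "met_vigorous": [30.0, 5.0],
        }
    )
    out = derive_composites(df)
    assert out["meat"].tolist() == [6.0, 0.0]
    assert out["vegetable"].tolist() == [0.0, 4.0]
    assert out["physical_activity"].tolist() == [60.0, 5.0]


def test_composite_missing_propagation_all_patterns():
    """Any missing addend makes the composite missing (all 8 patterns)."""
    rows = []
    for pattern in range(8):
        rows.append(
            {
                "beef": np.nan if pattern & 1 else 1.0,
                "lamb": np.nan if pattern & 2 else 2.0,
                "pork": np.nan if pattern & 4 else 3.0,
            }
        )
    df = pd.DataFrame(rows)
    for c in ("raw_vegetables", "cooked_vegetables", "met_light", "met_moderate", "met_vigorous"):
        df[c] = 1.0
    out = derive_composites(df)
    for pattern in range(8):
        expect_missing = pattern != 0
        assert np.isnan(out.loc[pattern, "meat"]) == expect_missing


def test_composite_missing_source_column_is_schema_error():
    with pytest.raises(SchemaError):
        derive_composites(pd.DataFrame({"beef": [1.0], "lamb": [2.0]}))


# --- cut-points ------------------------------------------------------------


def _one_component(name="tea", **kwargs):
    base = dict(
        name=name,
        category="lifestyle",
        polarity="antioxidant",
        rule="tertile",
        source_columns=(name,),
    )
    base.update(kwargs)
    return ComponentSpec(**base)


def test_tertile_boundaries_match_sorting_oracle():
    df = pd.DataFrame({"tea": np.arange(1.0, 10.0)})
    cuts = compute_cutpoints(df, [_one_component()], stratify="none")
    cp = cuts.get("tea", "all")
    assert cp.lower == pytest.approx(oracle_quantile(df["tea"], 1 / 3))
    assert cp.upper == pytest.approx(oracle_quantile(df["tea"], 2 / 3))
    assert (cp.lower, cp.upper) == pytest.approx((11 / 3, 19 / 3), abs=0.01)


def test_abstention_split_is_consumer_median():
    df = pd.DataFrame({"alcohol": [2.0, 4.0, 6.0, 8.0, 0.0, 0.0]})
    spec = _one_component("alcohol", rule="abstention_binary", polarity="prooxidant")
    cuts = compute_cutpoints(df, [spec], stratify="none")
    assert cuts.get("alcohol", "all").split == 5.0


def test_degenerate_constant_distribution_warns_single_bin():
    df = pd.DataFrame({"tea": [7.0] * 10})
    spec = _one_component()
    with pytest.warns(UserWarning, match="tied"):
        cuts = compute_cutpoints(df, [spec], stratify="none")
    cp = cuts.get("tea", "all")
    assert cp.lower == cp.upper == 7.0
    assert score_component(7.0, spec, cuts, "all") == 2  # v >= upper


def test_insufficient_stratum_data_names_component():
    df = pd.DataFrame({"tea": [1.0, 2.0], "sex": ["female", "female"]})
    with pytest.raises(EstimationError, match="tea"):
        compute_cutpoints(df, [_one_component()], stratify="sex")


# --- component scoring -----------------------------------------------------


def test_score_component_rules():
    df = pd.DataFrame({"x": [5.0, 15.0, 25.0] * 3 + [10.0]})
    anti = _one_component("x")
    cuts = compute_cutpoints(df, [anti], stratify="none")
    cuts.cuts[("x", "all")] = type(cuts.get("x", "all"))(lower=10.0, upper=20.0, n=10)
    pro = _one_component("x", polarity="prooxidant")
    assert score_component(25.0, anti, cuts, "all") == 2
    assert score_component(25.0, pro, cuts, "all") == 0
    assert score_component(10.0, anti, cuts, "all") == 1  # boundary: left-closed
    assert math.isnan(score_component(float("nan"), anti, cuts, "all"))


def test_smoking_abstention_scores_two():
    df = pd.DataFrame({"smoking": [0.0, 0.0, 3.0, 8.0, 12.0]})
    spec = _one_component("smoking", rule="abstention_binary", polarity="prooxidant")
    cuts = compute_cutpoints(df, [spec], stratify="none")
    assert score_component(0.0, spec, cuts, "all") == 2
    assert score_component(3.0, spec, cuts, "all") == 1  # below consumer median
    assert score_component(12.0, spec, cuts, "all") == 0


@settings(max_examples=100, derandomize=True)
@given(
    lower=st.floats(0, 50),
    width=st.floats(0.1, 50),
    v1=st.floats(0, 120),
    delta=st.floats(0, 50),
)
def test_monotonicity_and_polarity_duality(lower, width, v1, delta):
    """Antioxidant scores never decrease in the raw value; pro-oxidant is 2-s."""
    from oxbalance.scoring import CutpointSet, TertileCuts

    cuts = CutpointSet(stratify="none")
    cuts.cuts[("x", "all")] = TertileCuts(lower=lower, upper=lower + width, n=10)
    anti = _one_component("x")
    pro = _one_component("x", polarity="prooxidant")
    s1 = score_component(v1, anti, cuts, "all")
    s2 = score_component(v1 + delta, anti, cuts, "all")
    assert s2 >= s1
    assert score_component(v1, pro, cuts, "all") == 2 - s1


# --- whole-cohort scoring --------------------------------------------------


def test_cohort_scores_match_bruteforce_oracle():
    rng = np.random.default_rng(2024)
    specs = default_components()
    raw = derive_composites(random_raw_cohort(rng, 40), specs)
    scored = score_cohort(raw, specs, stratify="sex")
    for spec in specs:
        for idx, row in scored.data.iterrows():
            stratum_values = raw.loc[raw["sex"] == row["sex"], spec.column].tolist()
            expect = oracle_score(row[spec.column], spec, stratum_values)
            assert row[spec.score_column] == expect, (spec.name, idx)
    # totals are the sums of the parts, on every row
    score_cols = [s.score_column for s in specs]
    assert (scored.data[score_cols].sum(axis=1) == scored.data["obs_total"]).all()
    assert (
        scored.data["obs_diet"] + scored.data["obs_lifestyle"]
        == scored.data["obs_total"]
    ).all()
    assert scored.data["obs_total"].between(0, 44).all()
    assert scored.data["obs_diet"].between(0, 34).all()
    assert scored.data["obs_lifestyle"].between(0, 10).all()


def test_antioxidant_maximal_participant_scores_44():
    rng = np.random.default_rng(5)
    specs = default_components()
    raw = random_raw_cohort(rng, 30)
    for spec in specs:  # push row 0 to the antioxidant-maximal end
        for src in spec.source_columns:
            if spec.rule == "abstention_binary":
                raw.loc[0, src] = 0.0
            elif spec.polarity == "antioxidant":
                raw.loc[0, src] = raw[src].max() * 2
            else:
                raw.loc[0, src] = raw[src].min() / 2
    scored = score_cohort(raw, specs, stratify="none")
    top = scored.data.loc[scored.data["participant_id"] == 0].iloc[0]
    assert top["obs_total"] == 44


def test_constant_cohort_gives_identical_totals():
    specs = default_components()
    rng = np.random.default_rng(1)
    raw = random_raw_cohort(rng, 12)
    for col in raw.columns:
        if col not in ("participant_id", "sex"):
            raw[col] = 3.0
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scored = score_cohort(raw, specs, stratify="none")
    assert scored.data["obs_total"].nunique() == 1


def test_missing_component_drops_participant_and_logs():
    rng = np.random.default_rng(9)
    raw = random_raw_cohort(rng, 30)
    raw.loc[3, "tea"] = np.nan
    scored = score_cohort(raw, stratify="none")
    assert scored.exclusions["n_excluded"] == 1
    assert scored.exclusions["missing_by_component"]["tea"] == 1
    assert 3 not in scored.data.index


def test_row_order_never_changes_scores():
    rng = np.random.default_rng(11)
    raw = random_raw_cohort(rng, 50)
    scored = score_cohort(raw, stratify="sex")
    shuffled = raw.sample(frac=1.0, random_state=4)
    scored_shuffled = score_cohort(shuffled, stratify="sex")
    merged = scored.data.set_index("participant_id")[["obs_total"]].join(
        scored_shuffled.data.set_index("participant_id")[["obs_total"]],
        rsuffix="_shuffled",
    )
    assert (merged["obs_total"] == merged["obs_total_shuffled"]).all()


# --- quartiles -------------------------------------------------------------


def test_quartile_interval_conventions():
    """Left-closed right-open intervals; the last interval is closed."""
    s = pd.Series([4, 19, 21, 22, 26, 41])
    labels, _ = quartile_labels(s, edges=(19, 22, 26))
    assert labels.tolist() == ["Q1", "Q2", "Q2", "Q3", "Q4", "Q4"]


def test_quartile_group_sizes_conserve_count(scored_default):
    counts = scored_default.data["obs_quartile"].value_counts()
    assert int(counts.sum()) == len(scored_default.data)
    assert set(counts.index) == {"Q1", "Q2", "Q3", "Q4"}


def test_quartiles_require_four_distinct_values():
    with pytest.raises(DegenerateDistributionError):
        quartile_labels(pd.Series([1.0, 1.0, 2.0, 2.0, 3.0]))
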