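"""Geographic assignment and county/state panel aggregation.

Turns raw event tables (bookmarks, recipes, user locations) into the
county-year and state-year panels the longitudinal models consume: users are
assigned to counties by exact gazetteer match, bookmarked-recipe nutrition is
averaged per geographic unit and year, the composite FSA score is computed on
the mean nutrient profile, census obesity is joined, and sparsely observed
county-years (fewer than 30 distinct users by default) are dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fsa import DEFAULT_THRESHOLDS, NUTRIENTS, BandThresholds, NutrientProfile, fsa_score

__all__ = [
    "AssignmentResult",
    "assign_geography",
    "gazetteer_from_geography",
    "aggregate_panel",
    "filter_min_users",
    "recompute_state_panel",
    "dataset_summary",
    "load_preaggregated",
    "PANEL_COLUMNS",
    "SUMMARY_COLUMNS",
]

logger = logging.getLogger(__name__)

MEAN_COLUMNS = {
    "fat": "mean_fat",
    "saturated_fat": "mean_satfat",
    "sugar": "mean_sugar",
    "sodium": "mean_sodium",
}

PANEL_COLUMNS = [
    "state_id",
    "county_id",
    "year",
    "year_centered",
    "n_users",
    "n_bookmarks",
    "mean_fat",
    "mean_satfat",
    "mean_sugar",
    "mean_sodium",
    "fsa_score_of_means",
    "obesity",
    "has_census",
]

SUMMARY_COLUMNS = [
    "Year",
    "Num. Users",
    "Num. Bookmarks",
    "Num. Recipes",
    "Num. Counties",
    "Num. States",
]


class ConfigurationError(ValueError):
    pass


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class AssignmentResult:
    """User-to-geography assignment plus an exclusion summary."""

    assignments: pd.DataFrame  # user_id, county_id, state_id
    n_input: int
    n_assigned: int
    n_unmatched: int


def gazetteer_from_geography(geography: pd.DataFrame) -> pd.DataFrame:
    """Build a (label, county_id, state_id) gazetteer from a geography table."""
    counties = geography.loc[geography["level"] == "county"]
    return pd.DataFrame(
        {
            "label": counties["name"].to_numpy(),
            "county_id": counties["id"].astype(int).to_numpy(),
            "state_id": counties["parent_id"].astype(int).to_numpy(),
        }
    )


def assign_geography(users: pd.DataFrame, gazetteer: pd.DataFrame) -> AssignmentResult:
    """Assign each user to a county and state by exact location-label match.

    Users whose label does not match any gazetteer entry are excluded and
    counted; duplicate gazetteer labels are a configuration error because
    they would make assignment ambiguous.
    """
    if gazetteer["label"].duplicated().any():
        dupes = gazetteer.loc[gazetteer["label"].duplicated(), "label"].unique()
        raise ConfigurationError(f"duplicate gazetteer labels: {list(dupes)[:10]}")
    merged = users[["id", "location"]].merge(
        gazetteer, how="left", left_on="location", right_on="label"
    )
    matched = merged["county_id"].notna()
    assignments = (
        merged.loc[matched, ["id", "county_id", "state_id"]]
        .rename(columns={"id": "user_id"})
        .astype({"county_id": int, "state_id": int})
        .reset_index(drop=True)
    )
    result = AssignmentResult(
        assignments=assignments,
        n_input=len(users),
        n_assigned=int(matched.sum()),
        n_unmatched=int((~matched).sum()),
    )
    logger.info(
        "assigned %d/%d users to counties (%d unmatched excluded)",
        result.n_assigned,
        result.n_input,
        result.n_unmatched,
    )
    return result


def _mean_profile_scores(panel: pd.DataFrame, thresholds: BandThresholds) -> pd.Series:
    scores = [
        fsa_score(
            NutrientProfile(
                fat=row.mean_fat,
                saturated_fat=min(row.mean_satfat, row.mean_fat),
                sugar=row.mean_sugar,
                sodium=row.mean_sodium,
            ),
            thresholds,
        )
        for row in panel.itertuples()
    ]
    return pd.Series(scores, index=panel.index, dtype=int)


def _aggregate_level(
    events: pd.DataFrame,
    geo_col: str,
    weighting: str,
    fsa_on_means: bool,
    thresholds: BandThresholds,
) -> pd.DataFrame:
    keys = [geo_col, "year"]
    base = events.groupby(keys).agg(
        n_users=("user_id", "nunique"), n_bookmarks=("user_id", "size")
    )

    if weighting == "bookmark":
        weighted = events
    elif weighting == "recipe":
        weighted = events.drop_duplicates(subset=[*keys, "recipe_id"])
    elif weighting == "user":
        per_user = events.groupby([*keys, "user_id"])[list(NUTRIENTS)].mean().reset_index()
        weighted = per_user
    else:
        raise ConfigurationError(
            f"unknown weighting {weighting!r}; expected bookmark, recipe, or user"
        )
    means = weighted.groupby(keys)[list(NUTRIENTS)].mean().rename(columns=MEAN_COLUMNS)
    panel = base.join(means).reset_index()

    if fsa_on_means:
        panel["fsa_score_of_means"] = _mean_profile_scores(panel, thresholds)
    else:
        per_recipe = events.copy()
        score = np.zeros(len(per_recipe))
        for name in NUTRIENTS:
            low, high = thresholds.cuts[name]
            a = per_recipe[name].to_numpy(dtype=float)
            if thresholds.inclusive_low:
                score += 1 + (a > low).astype(int) + (a > high).astype(int)
            else:
                score += 1 + (a >= low).astype(int) + (a >= high).astype(int)
        per_recipe["_score"] = score
        panel["fsa_score_of_means"] = (
            per_recipe.groupby(keys)["_score"].mean().to_numpy()
        )
    return panel


def aggregate_panel(
    bookmarks: pd.DataFrame,
    recipes: pd.DataFrame,
    assignments: pd.DataFrame,
    census: pd.DataFrame | None = None,
    *,
    weighting: str = "bookmark",
    fsa_on_means: bool = True,
    thresholds: BandThresholds = DEFAULT_THRESHOLDS,
    year_origin: int = 2004,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate bookmark events to county-year and state-year panels.

    Per county-year (and state-year): the number of distinct bookmarking
    users, the number of bookmark events, the mean of each per-100 g nutrient
    over events (``weighting="bookmark"``, the default; ``"recipe"`` counts
    each distinct recipe once, ``"user"`` averages per user first), and the
    FSA score of the mean nutrient profile.  Census obesity, when given, is
    joined on geographic id and year; rows without census coverage are kept
    with ``has_census=False``.

    Bookmarks whose user has no assignment, or whose recipe lacks a complete
    nutrient profile, are dropped with a logged count.
    """
    for col in ("user_id", "recipe_id", "year"):
        if col not in bookmarks.columns:
            raise InputError(f"bookmark table lacks column {col!r}")

    events = bookmarks.merge(assignments, on="user_id", how="left")
    n_no_geo = int(events["county_id"].isna().sum())
    events = events.dropna(subset=["county_id"])

    recipe_cols = recipes[["id", *NUTRIENTS]].rename(columns={"id": "recipe_id"})
    events = events.merge(recipe_cols, on="recipe_id", how="left")
    n_no_nutrition = int(events[list(NUTRIENTS)].isna().any(axis=1).sum())
    events = events.dropna(subset=list(NUTRIENTS))
    if n_no_geo or n_no_nutrition:
        logger.info(
            "dropped %d bookmarks without user assignment and %d without full nutrition",
            n_no_geo,
            n_no_nutrition,
        )
    events = events.astype({"county_id": int, "state_id": int})

    county = _aggregate_level(events, "county_id", weighting, fsa_on_means, thresholds)
    county_state = assignments.drop_duplicates("county_id").set_index("county_id")["state_id"]
    county.insert(0, "state_id", county["county_id"].map(county_state).astype(int))
    state = _aggregate_level(events, "state_id", weighting, fsa_on_means, thresholds)
    state.insert(1, "county_id", pd.array([pd.NA] * len(state), dtype="Int64"))

    for panel in (county, state):
        panel.insert(
            list(panel.columns).index("year") + 1, "year_centered", panel["year"] - year_origin
        )

    county = _join_census(county, census, on="county_id")
    state = _join_census_state(state, census)
    return county[PANEL_COLUMNS], state[PANEL_COLUMNS]


def _join_census(panel: pd.DataFrame, census: pd.DataFrame | None, on: str) -> pd.DataFrame:
    if census is None:
        panel["obesity"] = np.nan
        panel["has_census"] = False
        return panel
    c = census[[on, "year", "obesity"]].drop_duplicates(subset=[on, "year"])
    extra_years = set(c["year"]) - set(panel["year"])
    if extra_years:
        warnings.warn(
            f"census years outside the panel are ignored: {sorted(extra_years)}", stacklevel=3
        )
    panel = panel.merge(c, on=[on, "year"], how="left")
    panel["has_census"] = panel["obesity"].notna()
    return panel


def _join_census_state(state_panel: pd.DataFrame, census: pd.DataFrame | None) -> pd.DataFrame:
    if census is None:
        state_panel["obesity"] = np.nan
        state_panel["has_census"] = False
        return state_panel
    # state obesity = unweighted mean of the state's county values per year
    state_obesity = census.groupby(["state_id", "year"])["obesity"].mean().reset_index()
    return _join_census(state_panel, state_obesity, on="state_id")


def filter_min_users(
    county_panel: pd.DataFrame, min_users: int = 30
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop county-years with fewer than ``min_users`` distinct users.

    The threshold is inclusive: a county-year with exactly ``min_users``
    users survives.  The filter is applied per county-year, so an unbalanced
    panel (counties present only in some years) is permitted.  State-year
    rows are recomputed from the surviving county rows.
    """
    if not isinstance(min_users, (int, np.integer)) or min_users < 1:
        raise ConfigurationError(f"min_users must be an integer >= 1, got {min_users!r}")
    kept = county_panel.loc[county_panel["n_users"] >= min_users].reset_index(drop=True)
    if kept.empty:
        warnings.warn(
            f"no county-year has at least {min_users} users; filtered panel is empty",
            stacklevel=2,
        )
    return kept, recompute_state_panel(kept)


def recompute_state_panel(county_panel: pd.DataFrame) -> pd.DataFrame:
    """Rebuild the state-year panel from county-year rows.

    Counts are summed (each user resides in exactly one county); nutrient
    means are combined weighted by bookmark counts, matching event-level
    aggregation; the FSA score is recomputed on the combined mean profile;
    state obesity is the unweighted mean of county obesity.
    """
    if county_panel.empty:
        return pd.DataFrame(columns=PANEL_COLUMNS)
    cp = county_panel.copy()
    for col in MEAN_COLUMNS.values():
        cp[f"_w_{col}"] = cp[col] * cp["n_bookmarks"]
    g = cp.groupby(["state_id", "year"])
    state = g.agg(
        year_centered=("year_centered", "first"),
        n_users=("n_users", "sum"),
        n_bookmarks=("n_bookmarks", "sum"),
        obesity=("obesity", "mean"),
        has_census=("has_census", "any"),
    )
    for col in MEAN_COLUMNS.values():
        state[col] = g[f"_w_{col}"].sum() / state["n_bookmarks"]
    state = state.reset_index()
    state["county_id"] = pd.array([pd.NA] * len(state), dtype="Int64")
    state["fsa_score_of_means"] = _mean_profile_scores(state, DEFAULT_THRESHOLDS)
    return state[PANEL_COLUMNS]


def dataset_summary(
    county_panel: pd.DataFrame,
    bookmarks: pd.DataFrame,
    assignments: pd.DataFrame,
) -> pd.DataFrame:
    """Per-year descriptive statistics over the surviving county-years.

    One row per year with distinct users, bookmark events, distinct recipes,
    counties, and states, restricted to bookmark events falling in a
    county-year that survived filtering.  A user bookmarking in one year is
    counted once for that year regardless of how many recipes they saved.
    """
    if county_panel.empty:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    events = bookmarks.merge(assignments, on="user_id", how="inner")
    surviving = county_panel[["county_id", "year"]].drop_duplicates()
    events = events.merge(surviving, on=["county_id", "year"], how="inner")
    g = events.groupby("year")
    summary = pd.DataFrame(
        {
            "Year": sorted(events["year"].unique()),
            "Num. Users": g["user_id"].nunique().to_numpy(),
            "Num. Bookmarks": g.size().to_numpy(),
            "Num. Recipes": g["recipe_id"].nunique().to_numpy(),
            "Num. Counties": g["county_id"].nunique().to_numpy(),
            "Num. States": g["state_id"].nunique().to_numpy(),
        }
    )
    return summary[SUMMARY_COLUMNS]


_PREAGG_ALIASES = {
    "county": "county_id",
    "state": "state_id",
    "fat": "mean_fat",
    "saturated_fat": "mean_satfat",
    "satfat": "mean_satfat",
    "sugar": "mean_sugar",
    "sodium": "mean_sodium",
    "fsa": "fsa_score_of_means",
    "fsa_score": "fsa_score_of_means",
}


def load_preaggregated(
    source,  # path or DataFrame
    *,
    year_origin: int = 2004,
    thresholds: BandThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Ingest a pre-aggregated panel CSV directly into panel form.

    Accepts a county/state-year table of averaged nutrients plus obesity (the
    shape of a deposited per-geography dataset), normalises column names,
    derives ``year_centered``, and computes the FSA score of the mean profile
    when absent.  Aggregation is bypassed entirely.
    """
    df = pd.read_csv(source) if not isinstance(source, pd.DataFrame) else source.copy()
    df = df.rename(columns={c: _PREAGG_ALIASES.get(c, c) for c in df.columns})
    required = ["state_id", "year", "obesity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"pre-aggregated panel lacks columns: {missing}")
    if "county_id" not in df.columns:
        df["county_id"] = pd.array([pd.NA] * len(df), dtype="Int64")
    df["year_centered"] = df["year"].astype(int) - year_origin
    for col in ("n_users", "n_bookmarks"):
        if col not in df.columns:
            df[col] = pd.array([pd.NA] * len(df), dtype="Int64")
    if "fsa_score_of_means" not in df.columns:
        df["fsa_score_of_means"] = _mean_profile_scores(df, thresholds)
    df["has_census"] = df["obesity"].notna()
    return df[[c for c in PANEL_COLUMNS if c in df.columns]]
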