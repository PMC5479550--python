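"""Synthetic study world: nested geography, users, recipes, bookmarks, census.

Emulates, at desk scale, the structure of a bookmarking corpus from a large
online recipe community joined to county-level obesity surveillance:

* counties nested in states, each user residing in exactly one county;
* recipes with right-skewed (log-normal) per-100 g nutrient amounts;
* yearly bookmark events (2004-2012 by default) whose recipe choice is tilted
  by a latent county "taste" shift, so counties differ systematically in the
  nutrition of what they bookmark;
* a census-style obesity panel generated from a three-level linear growth
  model — fixed intercept, year slope and nutrition coefficients; correlated
  random intercept/slope at the state level and at the county-within-state
  level; i.i.d. Gaussian residuals.

Every generator is deterministic given its configuration and seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "WorldConfig",
    "TrueParams",
    "SimulatedEffects",
    "World",
    "generate_world",
    "generate_bookmarks",
    "generate_obesity_panel",
    "simulate_panel",
]


class ConfigurationError(ValueError):
    """Raised when a generator configuration field is invalid."""


class InputError(ValueError):
    """Raised when generator inputs (tables) are missing or inconsistent."""


def _default_locations() -> dict[str, float]:
    # Log-scale medians per 100 g: g for fat/sat-fat/sugar, mg for sodium.
    return {"fat": 9.0, "saturated_fat": 3.0, "sugar": 8.0, "sodium": 350.0}


def _default_scales() -> dict[str, float]:
    return {"fat": 0.6, "saturated_fat": 0.7, "sugar": 0.9, "sodium": 0.5}


@dataclass(frozen=True)
class WorldConfig:
    """Configuration of the synthetic study world.

    Defaults give a desk-scale world (8 states x 5 counties, ~40 users per
    county, 3000 recipes, 20 bookmarks per user-year over 2004-2012) with
    the nested structure and right-skewed nutrient distributions the
    analysis assumes.

    Parameters
    ----------
    users_per_county_mean, users_per_county_dispersion
        Mean and negative-binomial dispersion (gamma shape) of the per-county
        user count; every county receives at least one user.
    nutrient_locations, nutrient_scales
        Per-nutrient log-normal median and log-scale sigma of per-100 g
        amounts (sodium in mg).
    bookmark_rate
        Expected bookmark events per user per year (Poisson).
    taste_heterogeneity
        Standard deviation of the latent county taste shift; a county with
        shift d bookmarks recipes with probability proportional to
        exp(d * z_r), where z_r is the recipe's standardised "unhealthiness"
        axis (mean of the standardised log amounts of the four nutrients).
        Positive shifts tilt a county toward recipes high in all four
        nutrients, shifting the location of every nutrient among its
        bookmarks and making nutrition fixed effects identifiable.
    missing_rate
        Probability that a county-year is dropped from the census panel,
        to mimic unbalanced real-world coverage.
    """

    n_states: int = 8
    counties_per_state: int = 5
    users_per_county_mean: float = 40.0
    users_per_county_dispersion: float = 8.0
    n_recipes: int = 3000
    year_start: int = 2004
    year_end: int = 2012
    nutrient_locations: Mapping[str, float] = field(default_factory=_default_locations)
    nutrient_scales: Mapping[str, float] = field(default_factory=_default_scales)
    bookmark_rate: float = 20.0
    taste_heterogeneity: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_states", "counties_per_state", "n_recipes"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ConfigurationError(f"{name} must be an integer >= 1, got {value!r}")
        if self.year_end < self.year_start:
            raise ConfigurationError(
                f"year range is empty: {self.year_start}..{self.year_end}"
            )
        if not self.users_per_county_mean > 0:
            raise ConfigurationError("users_per_county_mean must be > 0")
        if not self.users_per_county_dispersion > 0:
            raise ConfigurationError("users_per_county_dispersion must be > 0")
        if not self.bookmark_rate > 0:
            raise ConfigurationError("bookmark_rate must be > 0")
        if self.taste_heterogeneity < 0:
            raise ConfigurationError("taste_heterogeneity must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        from .fsa import NUTRIENTS

        for name in NUTRIENTS:
            if name not in self.nutrient_locations or name not in self.nutrient_scales:
                raise ConfigurationError(f"nutrient distribution for {name!r} not configured")
            if not self.nutrient_locations[name] > 0:
                raise ConfigurationError(f"nutrient location for {name!r} must be > 0")
            if not self.nutrient_scales[name] > 0:
                raise ConfigurationError(f"nutrient scale for {name!r} must be > 0")

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)


def _default_coefficients() -> dict[str, float]:
    return {"mean_fat": 0.19, "mean_sugar": 0.08}


@dataclass(frozen=True)
class TrueParams:
    """Generative parameters of the three-level obesity growth model.

    Units: obesity in percentage points; ``year_slope`` in %/year on the
    centred year; each nutrition coefficient in % per unit of its covariate.
    Variances are in squared percentage points (slope variances per year^2).
    Defaults mirror typical county-level US obesity surveillance magnitudes:
    ~25% prevalence in the base year rising ~0.3%/year, large between-county
    and between-state intercept spread, small slope spread, residual near 1.
    """

    intercept: float = 25.0
    year_slope: float = 0.30
    nutrition_coefficients: Mapping[str, float] = field(default_factory=_default_coefficients)
    state_intercept_var: float = 5.0
    state_slope_var: float = 0.04
    state_cov: float = -0.05
    county_intercept_var: float = 9.0
    county_slope_var: float = 0.09
    county_cov: float = -0.25
    residual_var: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "state_intercept_var",
            "state_slope_var",
            "county_intercept_var",
            "county_slope_var",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not self.residual_var > 0:
            raise ConfigurationError("residual_var must be > 0")
        for cov, v1, v2 in (
            ("state_cov", self.state_intercept_var, self.state_slope_var),
            ("county_cov", self.county_intercept_var, self.county_slope_var),
        ):
            if abs(getattr(self, cov)) > math.sqrt(v1 * v2) + 1e-12:
                raise ConfigurationError(f"|{cov}| exceeds sqrt of its variance product")

    def state_cov_matrix(self) -> np.ndarray:
        return np.array(
            [[self.state_intercept_var, self.state_cov], [self.state_cov, self.state_slope_var]]
        )

    def county_cov_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.county_intercept_var, self.county_cov],
                [self.county_cov, self.county_slope_var],
            ]
        )


@dataclass(frozen=True)
class SimulatedEffects:
    """Latent random-effect realisations returned by the census generator.

    ``state_effects``: one row per state (state_id, intercept, slope);
    ``county_effects``: one row per county (county_id, state_id, intercept,
    slope).  Used for parameter- and effect-recovery checks.
    """

    state_effects: pd.DataFrame
    county_effects: pd.DataFrame


class World(NamedTuple):
    geography: pd.DataFrame
    users: pd.DataFrame
    recipes: pd.DataFrame


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def generate_world(config: WorldConfig) -> World:
    """Generate geography, users, and recipes.

    County ids are FIPS-like: ``state_id * 1000 + county_index``, so county
    uniqueness across states is structural.  Each user carries its county id
    and a human-readable county-name location label (for the gazetteer
    matching path).  Recipe nutrient amounts are log-normal per nutrient;
    saturated fat is truncated at the recipe's fat content.
    """
    rng = _rng(config.seed, 0)

    states = pd.DataFrame(
        {
            "id": np.arange(1, config.n_states + 1),
            "name": [f"State{s:02d}" for s in range(1, config.n_states + 1)],
            "level": "state",
            "parent_id": pd.array([pd.NA] * config.n_states, dtype="Int64"),
        }
    )
    county_state = np.repeat(states["id"].to_numpy(), config.counties_per_state)
    county_idx = np.tile(np.arange(1, config.counties_per_state + 1), config.n_states)
    county_ids = county_state * 1000 + county_idx
    counties = pd.DataFrame(
        {
            "id": county_ids,
            "name": [f"County{c:05d}" for c in county_ids],
            "level": "county",
            "parent_id": pd.array(county_state, dtype="Int64"),
        }
    )
    geography = pd.concat([states, counties], ignore_index=True)

    k = config.users_per_county_dispersion
    m = config.users_per_county_mean
    n_users = rng.negative_binomial(k, k / (k + m), size=len(county_ids))
    n_users = np.maximum(n_users, 1)
    user_county = np.repeat(county_ids, n_users)
    county_names = dict(zip(counties["id"], counties["name"]))
    users = pd.DataFrame(
        {
            "id": np.arange(1, user_county.size + 1),
            "county_id": user_county,
            "location": [county_names[c] for c in user_county],
        }
    )

    cols: dict[str, np.ndarray] = {"id": np.arange(1, config.n_recipes + 1)}
    cols["servings"] = rng.integers(1, 13, size=config.n_recipes)
    from .fsa import NUTRIENTS

    for name in NUTRIENTS:
        mu = math.log(config.nutrient_locations[name])
        sigma = config.nutrient_scales[name]
        cols[name] = rng.lognormal(mu, sigma, size=config.n_recipes)
    # enforce sat-fat <= fat recipe-wise
    cols["saturated_fat"] = np.minimum(cols["saturated_fat"], cols["fat"])
    recipes = pd.DataFrame(cols)[["id", "servings", *NUTRIENTS]]

    return World(geography=geography, users=users, recipes=recipes)


def generate_bookmarks(
    world: World, config: WorldConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate bookmark events and the county taste shifts that drove them.

    Each user produces Poisson(``bookmark_rate``) bookmarks per year.  Within
    a county with taste shift d, recipes are chosen with probability
    proportional to exp(d * z_r), where z_r is the recipe's standardised
    unhealthiness axis (mean of the standardised log per-100 g amounts of the
    four nutrients).  Positive shifts tilt the county toward recipes high in
    fat, saturated fat, sugar and sodium alike, so county mean nutrition (and
    the FSA score of the means) varies between counties and nutrition fixed
    effects are identifiable downstream.

    Returns
    -------
    (bookmarks, taste_shifts)
        ``bookmarks``: columns user_id, recipe_id, year.
        ``taste_shifts``: columns county_id, taste_shift.
    """
    if len(world.users) == 0:
        raise InputError("user table is empty")
    if len(world.recipes) == 0:
        raise InputError("recipe table is empty")
    rng = _rng(config.seed, 1)

    counties = world.geography.loc[world.geography["level"] == "county", "id"].to_numpy()
    shifts = rng.normal(0.0, config.taste_heterogeneity, size=counties.size)
    taste_shifts = pd.DataFrame({"county_id": counties, "taste_shift": shifts})
    shift_by_county = dict(zip(counties, shifts))

    from .fsa import NUTRIENTS

    z_parts = []
    for name in NUTRIENTS:
        logged = np.log(world.recipes[name].to_numpy(dtype=float) + 1e-9)
        z_parts.append((logged - logged.mean()) / max(logged.std(), 1e-12))
    z_health = np.mean(z_parts, axis=0)
    z_health = (z_health - z_health.mean()) / max(z_health.std(), 1e-12)
    recipe_ids = world.recipes["id"].to_numpy()

    years = np.array(list(config.years))
    user_ids = world.users["id"].to_numpy()
    user_county = world.users["county_id"].to_numpy()

    counts = rng.poisson(config.bookmark_rate, size=(user_ids.size, years.size))
    total = counts.sum(axis=1)
    ev_user = np.repeat(user_ids, total)
    ev_county = np.repeat(user_county, total)
    ev_year = np.repeat(np.tile(years, user_ids.size), counts.ravel())

    order = np.argsort(ev_county, kind="stable")
    ev_user, ev_county, ev_year = ev_user[order], ev_county[order], ev_year[order]
    ev_recipe = np.empty(ev_user.size, dtype=recipe_ids.dtype)
    boundaries = np.searchsorted(ev_county, counties, side="left")
    ends = np.searchsorted(ev_county, counties, side="right")
    for c, start, stop in zip(counties, boundaries, ends):
        if stop == start:
            continue
        w = np.exp(shift_by_county[c] * z_health)
        w /= w.sum()
        ev_recipe[start:stop] = rng.choice(recipe_ids, size=stop - start, p=w)

    bookmarks = pd.DataFrame({"user_id": ev_user, "recipe_id": ev_recipe, "year": ev_year})
    bookmarks = bookmarks.sort_values(["user_id", "year", "recipe_id"], kind="stable")
    return bookmarks.reset_index(drop=True), taste_shifts


def generate_obesity_panel(
    geography: pd.DataFrame,
    county_covariates: pd.DataFrame,
    params: TrueParams,
    seed: int,
    year_origin: int | None = None,
) -> tuple[pd.DataFrame, SimulatedEffects]:
    """Generate a census-style obesity panel from the three-level growth model.

    One observation is emitted per row of ``county_covariates`` (columns:
    ``county_id``, ``year``, plus every covariate named in
    ``params.nutrition_coefficients``).  For year t (centred at
    ``year_origin``), county i in state j::

        obesity_tij = intercept + year_slope * t + sum_k coef_k * x_k
                      + u0_j + u1_j * t + r0_ij + r1_ij * t + eps_tij

    with (u0, u1) and (r0, r1) zero-mean bivariate Gaussians with the
    configured (co)variances and eps ~ N(0, residual_var).  Values are not
    clipped to [0, 100]; a warning is emitted if any fall outside.

    Returns the census table (county_id, state_id, year, obesity) and the
    drawn random effects for recovery testing.
    """
    counties = geography.loc[geography["level"] == "county", ["id", "parent_id"]]
    parent = dict(zip(counties["id"].astype(int), counties["parent_id"].astype(int)))

    cov = county_covariates.copy()
    required = ["county_id", "year", *params.nutrition_coefficients]
    missing_cols = [c for c in required if c not in cov.columns]
    if missing_cols:
        raise InputError(f"covariate table lacks columns: {missing_cols}")
    bad = cov[required].isna().any(axis=1)
    if bad.any():
        offenders = cov.loc[bad, ["county_id", "year"]].to_records(index=False).tolist()
        raise InputError(f"missing covariate values for county-years: {offenders[:20]}")
    unknown = set(cov["county_id"].astype(int)) - set(parent)
    if unknown:
        raise InputError(f"covariate county ids not in geography: {sorted(unknown)[:20]}")

    if year_origin is None:
        year_origin = int(cov["year"].min())
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))

    state_ids = np.sort(counties["parent_id"].astype(int).unique())
    county_ids = np.sort(counties["id"].astype(int).unique())
    u = rng.multivariate_normal(np.zeros(2), params.state_cov_matrix(), size=state_ids.size)
    r = rng.multivariate_normal(np.zeros(2), params.county_cov_matrix(), size=county_ids.size)
    state_effects = pd.DataFrame(
        {"state_id": state_ids, "intercept": u[:, 0], "slope": u[:, 1]}
    )
    county_effects = pd.DataFrame(
        {
            "county_id": county_ids,
            "state_id": [parent[c] for c in county_ids],
            "intercept": r[:, 0],
            "slope": r[:, 1],
        }
    )

    u_map = {s: (u[k, 0], u[k, 1]) for k, s in enumerate(state_ids)}
    r_map = {c: (r[k, 0], r[k, 1]) for k, c in enumerate(county_ids)}

    cid = cov["county_id"].astype(int).to_numpy()
    sid = np.array([parent[c] for c in cid])
    t = cov["year"].astype(int).to_numpy() - year_origin
    mean = params.intercept + params.year_slope * t
    for name, coef in params.nutrition_coefficients.items():
        mean = mean + coef * cov[name].to_numpy(dtype=float)
    u0 = np.array([u_map[s][0] for s in sid])
    u1 = np.array([u_map[s][1] for s in sid])
    r0 = np.array([r_map[c][0] for c in cid])
    r1 = np.array([r_map[c][1] for c in cid])
    eps = rng.normal(0.0, math.sqrt(params.residual_var), size=len(cov))
    obesity = mean + u0 + u1 * t + r0 + r1 * t + eps

    if (obesity < 0).any() or (obesity > 100).any():
        warnings.warn(
            "simulated obesity values fall outside [0, 100]; the growth model is "
            "linear-Gaussian and does not clip",
            stacklevel=2,
        )

    census = pd.DataFrame(
        {"county_id": cid, "state_id": sid, "year": cov["year"].astype(int).to_numpy(),
         "obesity": obesity}
    ).sort_values(["county_id", "year"]).reset_index(drop=True)
    return census, SimulatedEffects(state_effects=state_effects, county_effects=county_effects)


def simulate_panel(
    params: TrueParams,
    n_states: int = 50,
    counties_per_state: int = 6,
    years: Iterable[int] = range(2004, 2013),
    seed: int = 0,
    covariate_means: Mapping[str, float] | None = None,
    covariate_between_sd: float = 2.0,
    covariate_within_sd: float = 0.8,
    missing_rate: float = 0.0,
) -> tuple[pd.DataFrame, SimulatedEffects]:
    """Simulate a model-ready county-year panel directly from the growth model.

    A convenience wrapper for estimation studies that bypasses the bookmark
    layer: covariates named in ``params.nutrition_coefficients`` are drawn as
    a county-level mean (between-county sd ``covariate_between_sd``) plus
    yearly noise (``covariate_within_sd``), then obesity is generated by
    :func:`generate_obesity_panel`.  Returns a panel with columns county_id,
    state_id, year, year_centered, the covariates, and obesity.
    """
    years = list(years)
    if covariate_means is None:
        covariate_means = {name: 10.0 for name in params.nutrition_coefficients}
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(3,)))

    state_ids = np.arange(1, n_states + 1)
    county_ids = np.concatenate([s * 1000 + np.arange(1, counties_per_state + 1)
                                 for s in state_ids])
    geography = pd.DataFrame(
        {
            "id": np.concatenate([state_ids, county_ids]),
            "name": [f"State{s:02d}" for s in state_ids]
            + [f"County{c:05d}" for c in county_ids],
            "level": ["state"] * state_ids.size + ["county"] * county_ids.size,
            "parent_id": pd.array(
                [pd.NA] * state_ids.size + list(county_ids // 1000), dtype="Int64"
            ),
        }
    )

    grid = pd.DataFrame(
        [(c, y) for c in county_ids for y in years], columns=["county_id", "year"]
    )
    for name in params.nutrition_coefficients:
        base = rng.normal(covariate_means[name], covariate_between_sd, size=county_ids.size)
        base_map = dict(zip(county_ids, base))
        grid[name] = grid["county_id"].map(base_map) + rng.normal(
            0.0, covariate_within_sd, size=len(grid)
        )
    if missing_rate > 0:
        keep = rng.random(len(grid)) >= missing_rate
        grid = grid.loc[keep].reset_index(drop=True)

    census, effects = generate_obesity_panel(
        geography, grid, params, seed=seed, year_origin=min(years)
    )
    panel = census.merge(grid, on=["county_id", "year"], how="left")
    panel["year_centered"] = panel["year"] - min(years)
    return panel, effects
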