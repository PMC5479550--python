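"""End-to-end orchestration: config, stages, artifacts, report rendering.

Runs the full study on a synthetic world (or user-supplied CSVs): score
recipes, aggregate bookmarks to county/state-year panels, apply the
minimum-user filter, build the descriptive summary, compute correlation
matrices, fit the model sequence, and write every artifact plus a run
manifest.  Identical config + seed reproduces every artifact bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregate import (
    aggregate_panel,
    assign_geography,
    dataset_summary,
    filter_min_users,
    gazetteer_from_geography,
)
from .correlate import correlation_matrix
from .fsa import BandThresholds, score_table
from .mlm import ComparisonTable, information_criteria, run_model_sequence
from .synth import TrueParams, WorldConfig, generate_bookmarks, generate_obesity_panel, generate_world

__all__ = ["PipelineConfig", "run_pipeline", "render_comparison", "PipelineError"]

logger = logging.getLogger(__name__)

CSV_FLOAT_FORMAT = "%.6g"

CORRELATION_VARIABLES = [
    "n_bookmarks",
    "year",
    "mean_fat",
    "mean_satfat",
    "mean_sugar",
    "mean_sodium",
    "fsa_score_of_means",
    "obesity",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Declarative configuration of one end-to-end run."""

    world: WorldConfig = field(default_factory=WorldConfig)
    true_params: TrueParams = field(default_factory=TrueParams)
    thresholds: BandThresholds = field(default_factory=BandThresholds)
    min_users: int = 30
    weighting: str = "bookmark"
    correlation_method: str = "spearman"
    model_method: str = "REML"
    variance_structure: str = "correlated"
    seed: int = 0
    out_dir: str = "artifacts"
    verbosity: str = "INFO"

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self, seed=seed, world=dataclasses.replace(self.world, seed=seed)
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "world" in raw:
            kwargs["world"] = WorldConfig(**raw["world"])
        if "true_params" in raw:
            kwargs["true_params"] = TrueParams(**raw["true_params"])
        if "thresholds" in raw:
            cuts = {k: tuple(v) for k, v in raw["thresholds"].get("cuts", {}).items()}
            base = dict(BandThresholds().cuts)
            base.update(cuts)
            kwargs["thresholds"] = BandThresholds(
                cuts=base, inclusive_low=raw["thresholds"].get("inclusive_low", True)
            )
        for key in (
            "min_users", "weighting", "correlation_method", "model_method",
            "variance_structure", "seed", "out_dir", "verbosity",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        config = cls(**kwargs)
        if "seed" in raw and "world" in raw and "seed" not in raw["world"]:
            config = config.with_seed(raw["seed"])
        return config

    def to_manifest(self) -> dict:
        return {
            "world": dataclasses.asdict(self.world),
            "true_params": dataclasses.asdict(self.true_params),
            "thresholds": {
                "cuts": {k: list(v) for k, v in self.thresholds.cuts.items()},
                "inclusive_low": self.thresholds.inclusive_low,
            },
            "min_users": self.min_users,
            "weighting": self.weighting,
            "correlation_method": self.correlation_method,
            "model_method": self.model_method,
            "variance_structure": self.variance_structure,
            "seed": self.seed,
        }


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=CSV_FLOAT_FORMAT)


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return ""


VC_ROWS = [
    ("Var: county:State (Intercept)", "county_intercept_var"),
    ("Var: State (Intercept)", "state_intercept_var"),
    ("Var: Residual", "residual_var"),
    ("Var: County:State Year", "county_slope_var"),
    ("Cov: County:State (Intercept) Year", "county_cov"),
    ("Var: State Year", "state_slope_var"),
    ("Cov: State (Intercept) Year", "state_cov"),
]

FIXED_ROWS = [
    ("(Intercept)", "intercept"),
    ("Year", "year_centered"),
    ("FSA score", "fsa_score_of_means"),
    ("Fat/100g", "mean_fat"),
    ("Sugar/100g", "mean_sugar"),
    ("Sat. fat/100g", "mean_satfat"),
    ("Sodium/100g", "mean_sodium"),
]


def render_comparison(comparison: ComparisonTable) -> tuple[str, pd.DataFrame]:
    """Render a fitted-model comparison as aligned text and a tidy table.

    Rows: variance components, then fixed effects as ``estimate (se)`` with
    significance stars (*** p<0.001, * p<0.05), then AIC/BIC/log-likelihood,
    observation and group counts.  Columns follow fitting order.
    """
    if not comparison.fits:
        raise ValueError("comparison table has no fits")
    labels = comparison.labels
    rows: list[tuple[str, list[str]]] = []

    def fmt(value: float) -> str:
        return f"{value:.2f}"

    rows.append(("Variance Components", ["" for _ in labels]))
    for title, attr in VC_ROWS:
        cells = []
        any_present = False
        for f in comparison.fits:
            c = f.components
            has_slope = f.spec is not None and (
                "year" in f.spec.county_random or "year" in f.spec.state_random
            )
            relevant = attr in ("county_intercept_var", "state_intercept_var", "residual_var") \
                or has_slope
            if c is None or (not relevant) or (f.spec and f.spec.is_null
                                               and attr != "residual_var"):
                cells.append("")
                any_present = any_present or False
            else:
                cells.append(fmt(getattr(c, attr)))
                any_present = True
        if any_present:
            rows.append((title, cells))

    rows.append(("Fixed Effects", ["" for _ in labels]))
    for title, term in FIXED_ROWS:
        if not any(term in f.fixed_effects for f in comparison.fits):
            continue
        cells = []
        for f in comparison.fits:
            if term in f.fixed_effects:
                p = f.fixed_pvalues()[term]
                cells.append(f"{fmt(f.fixed_effects[term])}{_stars(p)} ({fmt(f.fixed_se[term])})")
            else:
                cells.append("")
        rows.append((title, cells))

    crit = comparison.criteria.set_index("label")
    rows.append(("AIC", [fmt(crit.loc[lb, "AIC"]) for lb in labels]))
    rows.append(("BIC", [fmt(crit.loc[lb, "BIC"]) for lb in labels]))
    rows.append(("Log Likelihood", [fmt(crit.loc[lb, "loglik"]) for lb in labels]))
    rows.append(("Num. obs.", [str(f.n) for f in comparison.fits]))
    rows.append(("Num. groups: county:state", [str(f.n_counties) for f in comparison.fits]))
    rows.append(("Num. groups: state", [str(f.n_states) for f in comparison.fits]))

    tidy = pd.DataFrame(
        {"row": [r[0] for r in rows],
         **{label: [r[1][i] for r in rows] for i, label in enumerate(labels)}}
    )
    width0 = max(len(r[0]) for r in rows) + 2
    widths = [max(12, max(len(r[1][i]) for r in rows) + 2, len(labels[i]) + 2)
              for i in range(len(labels))]
    lines = ["".ljust(width0) + "".join(lb.rjust(w) for lb, w in zip(labels, widths))]
    for title, cells in rows:
        lines.append(title.ljust(width0) + "".join(c.rjust(w) for c, w in zip(cells, widths)))
    lines.append("")
    lines.append("Note: *** p < 0.001, * p < 0.05; standard errors in parentheses.")
    for lrt in comparison.lrt_rows:
        lines.append(
            f"LRT {lrt['nested']} vs {lrt['full']}: chi2({lrt['df']}) = "
            f"{lrt['statistic']:.2f}, p = {lrt['p']:.3g}"
        )
    return "\n".join(lines) + "\n", tidy


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write artifacts to ``config.out_dir``.

    Artifact order: scored recipes; raw county/state panels; filtered panels;
    per-year summary; correlation matrices; model comparison (CSV + aligned
    text) and fit JSONs; a manifest recording config, seed, and versions.
    A stage failure raises :class:`PipelineError` naming the stage, leaving a
    ``FAILED`` marker beside the partial artifacts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))

    stage = "simulate"
    t0 = time.time()
    try:
        world = generate_world(config.world)
        bookmarks, taste = generate_bookmarks(world, config.world)
        logger.info("[%s] %.1fs", stage, time.time() - t0)

        stage = "score"
        scored = score_table(world.recipes, config.thresholds)
        _write_csv(scored, out / "recipes_scored.csv")

        stage = "aggregate"
        gazetteer = gazetteer_from_geography(world.geography)
        assignment = assign_geography(world.users, gazetteer)
        county_raw, _ = aggregate_panel(
            bookmarks,
            world.recipes,
            assignment.assignments,
            census=None,
            weighting=config.weighting,
            thresholds=config.thresholds,
            year_origin=config.world.year_start,
        )
        census, _effects = generate_obesity_panel(
            world.geography,
            county_raw[["county_id", "year", "mean_fat", "mean_sugar"]],
            config.true_params,
            seed=config.seed,
            year_origin=config.world.year_start,
        )
        county_raw, state_raw = aggregate_panel(
            bookmarks,
            world.recipes,
            assignment.assignments,
            census=census,
            weighting=config.weighting,
            thresholds=config.thresholds,
            year_origin=config.world.year_start,
        )
        _write_csv(county_raw, out / "panel_county_raw.csv")
        _write_csv(state_raw, out / "panel_state_raw.csv")

        stage = "filter"
        county_panel, state_panel = filter_min_users(county_raw, config.min_users)
        _write_csv(county_panel, out / "panel_county.csv")
        _write_csv(state_panel, out / "panel_state.csv")
        summary = dataset_summary(county_panel, bookmarks, assignment.assignments)
        _write_csv(summary, out / "summary_by_year.csv")

        stage = "correlate"
        for level, panel in (("county", county_panel), ("state", state_panel)):
            if panel.empty:
                continue
            matrix = correlation_matrix(
                panel, CORRELATION_VARIABLES, method=config.correlation_method, level=level
            )
            _write_csv(matrix.rho, out / f"correlations_{level}_rho.csv", index=True)
            _write_csv(matrix.p, out / f"correlations_{level}_p.csv", index=True)
            annotated = matrix.rho.round(3).astype(str) + matrix.stars
            _write_csv(annotated, out / f"correlations_{level}_annotated.csv", index=True)

        stage = "fit"
        if county_panel.empty:
            raise PipelineError(
                "fit: panel is empty after the minimum-user filter "
                f"(min_users={config.min_users}); no observations to model"
            )
        comparison = run_model_sequence(
            county_panel,
            method=config.model_method,
            variance_structure=config.variance_structure,
            year_origin=config.world.year_start,
        )
        text, tidy = render_comparison(comparison)
        (out / "models_comparison.txt").write_text(text)
        _write_csv(tidy, out / "models_comparison.csv")
        fits_json = {
            label: f.to_dict() for label, f in zip(comparison.labels, comparison.fits)
        }
        fits_json["lrt"] = comparison.lrt_rows
        (out / "fits.json").write_text(json.dumps(fits_json, indent=2, sort_keys=True))

        stage = "manifest"
        manifest = {
            "config": config.to_manifest(),
            "versions": {
                "nutripanel": __version__,
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    marker = out / "FAILED"
    if marker.exists():
        marker.unlink()
    logger.info("pipeline complete in %.1fs -> %s", time.time() - t0, out)
    return out
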