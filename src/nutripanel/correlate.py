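"""Exploratory correlation matrices with significance annotation.

Pairwise Spearman (default) or Pearson correlations between panel variables
at county or state level, with per-pair sample sizes, p-values, and star
annotations (*** p<0.001, ** p<0.01, * p<0.05 by default).  Spearman
p-values are exact-permutation when the pair has at most ``exact_max_n``
complete observations and asymptotic otherwise; an optional
Benjamini-Hochberg correction is available (none is applied by default).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CorrelationMatrix", "correlation_matrix", "assign_stars"]

DEFAULT_STAR_LEVELS: tuple[tuple[float, str], ...] = (
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
)


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric correlation matrix bundle for one geographic level."""

    variables: tuple[str, ...]
    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    stars: pd.DataFrame
    method: str
    level: str
    star_levels: tuple[tuple[float, str], ...] = field(default=DEFAULT_STAR_LEVELS)


def assign_stars(
    p: float, star_levels: tuple[tuple[float, str], ...] = DEFAULT_STAR_LEVELS
) -> str:
    """Star annotation for a p-value under ordered (threshold, symbol) tiers."""
    if np.isnan(p):
        return ""
    for threshold, symbol in sorted(star_levels):
        if p < threshold:
            return symbol
    return ""


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p-value for the Spearman coefficient.

    Enumerates all n! orderings of y and counts permutations whose |rho| is
    at least the observed |rho|.  Only feasible for small n.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rho_obs = _pearson(rx, ry)
    perms = np.array(list(itertools.permutations(ry)))
    rx_c = rx - rx.mean()
    p_c = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (p_c**2).sum(axis=1))
    rho_perm = p_c @ rx_c / np.where(denom == 0, np.nan, denom)
    return float(np.mean(np.abs(rho_perm) >= abs(rho_obs) - 1e-12))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return np.nan
    return float(a @ b / denom)


def _pair_stats(
    x: np.ndarray, y: np.ndarray, method: str, exact_max_n: int
) -> tuple[float, float, int]:
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        return np.nan, np.nan, n
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan, n  # constant input: coefficient undefined
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
        if n <= exact_max_n:
            p = _exact_spearman_p(x, y)
    elif method == "pearson":
        rho, p = stats.pearsonr(x, y)
    else:
        raise ValidationError(f"unknown method {method!r}; expected spearman or pearson")
    return float(rho), float(p), n


def correlation_matrix(
    panel: pd.DataFrame,
    variables: list[str],
    method: str = "spearman",
    level: str = "county",
    *,
    star_levels: tuple[tuple[float, str], ...] = DEFAULT_STAR_LEVELS,
    benjamini_hochberg: bool = False,
    exact_max_n: int = 9,
) -> CorrelationMatrix:
    """Pairwise correlation matrix over complete pairs of panel variables.

    Each pair uses its complete observations; a pair with fewer than 3 is
    reported as undefined (NaN) rather than fabricated.  The matrix is
    symmetric with unit diagonal.  ``benjamini_hochberg=True`` applies an FDR
    adjustment to the off-diagonal p-values before starring.
    """
    unknown = [v for v in variables if v not in panel.columns]
    if unknown:
        raise ValidationError(f"variables not in panel: {unknown}")
    if method not in ("spearman", "pearson"):
        raise ValidationError(f"unknown method {method!r}; expected spearman or pearson")
    k = len(variables)
    rho = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    cols = {v: panel[v].to_numpy(dtype=float) for v in variables}
    for v in variables:
        n[variables.index(v), variables.index(v)] = int(np.isfinite(cols[v]).sum())
    for i, j in itertools.combinations(range(k), 2):
        r_ij, p_ij, n_ij = _pair_stats(cols[variables[i]], cols[variables[j]], method, exact_max_n)
        rho[i, j] = rho[j, i] = r_ij
        p[i, j] = p[j, i] = p_ij
        n[i, j] = n[j, i] = n_ij

    if benjamini_hochberg:
        iu = np.triu_indices(k, 1)
        raw = p[iu]
        valid = ~np.isnan(raw)
        adjusted = raw.copy()
        adjusted[valid] = stats.false_discovery_control(raw[valid], method="bh")
        p[iu] = adjusted
        p.T[iu] = adjusted

    idx = list(variables)
    stars = pd.DataFrame(
        [[assign_stars(p[i, j], star_levels) if i != j else "" for j in range(k)]
         for i in range(k)],
        index=idx,
        columns=idx,
    )
    return CorrelationMatrix(
        variables=tuple(variables),
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
        stars=stars,
        method=method,
        level=level,
        star_levels=star_levels,
    )
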