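"""Three-level longitudinal linear mixed models of obesity prevalence.

The model: repeated yearly observations t of counties i nested in states j,

    obesity_tij = beta' x_tij + z_tij' r_ij + z_tij' u_j + eps_tij

with x the fixed-effect covariates (intercept, centred year, nutrition
variables), z the random-effect covariates (intercept and optionally the
centred year slope), r_ij ~ N(0, G_county) the county-within-state effects,
u_j ~ N(0, G_state) the state effects, and eps ~ N(0, sigma^2) i.i.d.
G matrices are either fully correlated (2x2 with intercept-slope covariance)
or diagonal ("independent").

Estimation maximises the ML or REML objective over the relative covariance
factors (Cholesky parameterisation of G/sigma^2); for each candidate the
fixed effects and residual variance are profiled out by generalised least
squares, exploiting independence across states to work with per-state
marginal covariance blocks.  :func:`dense_loglik` evaluates the same
marginal Gaussian (restricted) log-density by building each state's full
covariance matrix explicitly, serving as the slow correctness oracle.

REML uses the restricted likelihood without the |X'X| constant, the lme4
convention; ML and REML log-likelihoods are therefore directly comparable
with lme4's.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular

__all__ = [
    "FIXED_TERMS",
    "ModelSpec",
    "VarianceComponents",
    "Design",
    "FitResult",
    "ComparisonTable",
    "build_design",
    "dense_loglik",
    "fit",
    "information_criteria",
    "likelihood_ratio_test",
    "icc",
    "icc_from_components",
    "pseudo_r2",
    "run_model_sequence",
]

logger = logging.getLogger(__name__)

FIXED_TERMS = (
    "intercept",
    "year_centered",
    "fsa_score_of_means",
    "mean_fat",
    "mean_sugar",
    "mean_satfat",
    "mean_sodium",
)
RANDOM_TERMS = ("intercept", "year")

LOG_VAR_FLOOR = -15.0  # log relative-sd floor treated as a boundary (variance -> 0)


class ValidationError(ValueError):
    pass


class InputError(ValueError):
    pass


class NumericalError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one three-level mixed model.

    ``fixed`` lists fixed-effect terms (must include ``intercept``);
    ``county_random`` / ``state_random`` list random terms per level, each a
    subset of ``("intercept", "year")``.  A random ``year`` slope requires
    the fixed ``year_centered`` term.  ``variance_structure="correlated"``
    estimates an intercept-slope covariance per level; ``"independent"``
    constrains it to zero.  Empty random terms at both levels give the
    single-level (OLS) null baseline.
    """

    fixed: tuple[str, ...] = ("intercept",)
    county_random: tuple[str, ...] = ("intercept",)
    state_random: tuple[str, ...] = ("intercept",)
    variance_structure: str = "correlated"
    method: str = "REML"
    outcome: str = "obesity"
    year_origin: int = 2004

    def __post_init__(self) -> None:
        if "intercept" not in self.fixed:
            raise ValidationError("fixed terms must include the intercept")
        unknown = [t for t in self.fixed if t not in FIXED_TERMS]
        if unknown:
            raise ValidationError(f"unknown fixed terms: {unknown}")
        for name, terms in (("county_random", self.county_random),
                            ("state_random", self.state_random)):
            bad = [t for t in terms if t not in RANDOM_TERMS]
            if bad:
                raise ValidationError(f"unknown {name} terms: {bad}")
            if "year" in terms and "intercept" not in terms:
                raise ValidationError(f"{name}: a random slope requires a random intercept")
            if "year" in terms and "year_centered" not in self.fixed:
                raise ValidationError(
                    f"{name}: random year slope requires the fixed year_centered term"
                )
        if self.variance_structure not in ("correlated", "independent"):
            raise ValidationError("variance_structure must be 'correlated' or 'independent'")
        if self.method not in ("ML", "REML"):
            raise ValidationError("method must be 'ML' or 'REML'")

    @property
    def is_null(self) -> bool:
        return not self.county_random and not self.state_random

    def n_theta(self) -> int:
        total = 0
        for terms in (self.county_random, self.state_random):
            q = len(terms)
            if q == 0:
                continue
            total += q if self.variance_structure == "independent" else q * (q + 1) // 2
        return total

    def k(self) -> int:
        """Free-parameter count: fixed effects + (co)variance parameters + residual."""
        return len(self.fixed) + self.n_theta() + 1


@dataclass(frozen=True)
class VarianceComponents:
    """Variance/covariance components on the outcome scale."""

    county_intercept_var: float = 0.0
    county_slope_var: float = 0.0
    county_cov: float = 0.0
    state_intercept_var: float = 0.0
    state_slope_var: float = 0.0
    state_cov: float = 0.0
    residual_var: float = 1.0

    def __post_init__(self) -> None:
        for name in ("county_intercept_var", "county_slope_var",
                     "state_intercept_var", "state_slope_var"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not self.residual_var > 0:
            raise ValidationError("residual_var must be > 0")
        for cov, v1, v2 in (
            ("county_cov", self.county_intercept_var, self.county_slope_var),
            ("state_cov", self.state_intercept_var, self.state_slope_var),
        ):
            if abs(getattr(self, cov)) > math.sqrt(v1 * v2) + 1e-8:
                raise ValidationError(f"|{cov}| exceeds sqrt of its variance product")

    def county_matrix(self, terms: Sequence[str]) -> np.ndarray:
        return _g_matrix(self.county_intercept_var, self.county_slope_var,
                         self.county_cov, terms)

    def state_matrix(self, terms: Sequence[str]) -> np.ndarray:
        return _g_matrix(self.state_intercept_var, self.state_slope_var,
                         self.state_cov, terms)


def _g_matrix(iv: float, sv: float, cov: float, terms: Sequence[str]) -> np.ndarray:
    if len(terms) == 2:
        return np.array([[iv, cov], [cov, sv]])
    if terms == ("intercept",) or list(terms) == ["intercept"]:
        return np.array([[iv]])
    if len(terms) == 0:
        return np.zeros((0, 0))
    raise ValidationError(f"unsupported random terms {terms!r}")


@dataclass
class _CountyBlock:
    label: int
    rows: slice  # local to the state block
    Z: np.ndarray


@dataclass
class _StateBlock:
    label: int
    rows: slice  # into the global row order
    X: np.ndarray
    y: np.ndarray
    Z_state: np.ndarray
    counties: list[_CountyBlock]


@dataclass
class Design:
    """Model-ready arrays: response, fixed design, nested grouping blocks."""

    spec: ModelSpec
    y: np.ndarray
    X: np.ndarray
    fixed_names: tuple[str, ...]
    states: list[_StateBlock]
    county_labels: list[int]
    n_dropped: int

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_counties(self) -> int:
        return len(self.county_labels)


def build_design(panel: pd.DataFrame, spec: ModelSpec) -> Design:
    """Assemble response, fixed-effect matrix, and nested grouping blocks.

    The year column is centred at ``spec.year_origin``; rows missing any
    required field are dropped with a logged count; rows are ordered by
    state, then county, then year so that each state's observations form one
    contiguous block and each county's a contiguous sub-block.
    """
    df = panel.copy()
    if "year_centered" not in df.columns:
        if "year" not in df.columns:
            raise InputError("panel lacks both year_centered and year columns")
        df["year_centered"] = df["year"].astype(int) - spec.year_origin

    needed = [spec.outcome, "county_id", "state_id", "year_centered"]
    needed += [t for t in spec.fixed if t != "intercept" and t != "year_centered"]
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise InputError(f"panel lacks columns required by the model: {missing_cols}")

    before = len(df)
    df = df.dropna(subset=needed)
    n_dropped = before - len(df)
    if n_dropped:
        logger.info("dropped %d panel rows with missing model fields", n_dropped)
    if df.empty:
        raise InputError("empty design: no complete panel rows for the requested model")

    nesting = df.groupby("county_id")["state_id"].nunique()
    multi = nesting[nesting > 1]
    if len(multi):
        raise InputError(f"counties mapped to more than one state: {list(multi.index)[:10]}")

    df = df.sort_values(["state_id", "county_id", "year_centered"], kind="stable")
    y = df[spec.outcome].to_numpy(dtype=float)
    columns = []
    for term in spec.fixed:
        if term == "intercept":
            columns.append(np.ones(len(df)))
        else:
            columns.append(df[term].to_numpy(dtype=float))
    X = np.column_stack(columns)
    for name, col in zip(spec.fixed, columns):
        if name != "intercept" and float(np.std(col)) == 0.0:
            raise InputError(
                f"fixed-effect covariate {name!r} is constant in the panel; "
                "the model is not identifiable"
            )
    t = df["year_centered"].to_numpy(dtype=float)
    state_ids = df["state_id"].to_numpy()
    county_ids = df["county_id"].to_numpy()

    def z_cols(terms: Sequence[str], tt: np.ndarray) -> np.ndarray:
        cols = []
        if "intercept" in terms:
            cols.append(np.ones(tt.size))
        if "year" in terms:
            cols.append(tt)
        return np.column_stack(cols) if cols else np.zeros((tt.size, 0))

    states: list[_StateBlock] = []
    county_labels: list[int] = []
    start = 0
    for sid in pd.unique(state_ids):
        mask = state_ids == sid
        m = int(mask.sum())
        rows = slice(start, start + m)
        tt = t[rows]
        counties: list[_CountyBlock] = []
        local = county_ids[rows]
        cstart = 0
        for cid in pd.unique(local):
            cm = int((local == cid).sum())
            crows = slice(cstart, cstart + cm)
            counties.append(
                _CountyBlock(label=int(cid), rows=crows,
                             Z=z_cols(spec.county_random, tt[crows]))
            )
            county_labels.append(int(cid))
            cstart += cm
        states.append(
            _StateBlock(
                label=int(sid),
                rows=rows,
                X=X[rows],
                y=y[rows],
                Z_state=z_cols(spec.state_random, tt),
                counties=counties,
            )
        )
        start += m

    return Design(
        spec=spec,
        y=y,
        X=X,
        fixed_names=tuple(spec.fixed),
        states=states,
        county_labels=county_labels,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# Relative-covariance (theta) parameterisation


def _theta_slices(spec: ModelSpec) -> tuple[slice, slice]:
    def size(terms: tuple[str, ...]) -> int:
        q = len(terms)
        if q == 0:
            return 0
        return q if spec.variance_structure == "independent" else q * (q + 1) // 2

    nc = size(spec.county_random)
    ns = size(spec.state_random)
    return slice(0, nc), slice(nc, nc + ns)


def _psi_from_theta(theta: np.ndarray, terms: tuple[str, ...], structure: str) -> np.ndarray:
    """Relative covariance Psi = G / sigma^2 from unconstrained parameters.

    q=1: theta = (a,), Psi = [[e^{2a}]].  q=2 correlated: theta = (a, b, c)
    with Cholesky L = [[e^a, 0], [b, e^c]]; independent: theta = (a, c).
    """
    q = len(terms)
    if q == 0:
        return np.zeros((0, 0))
    if q == 1:
        return np.array([[math.exp(2.0 * theta[0])]])
    if structure == "independent":
        L = np.diag([math.exp(theta[0]), math.exp(theta[1])])
    else:
        L = np.array([[math.exp(theta[0]), 0.0], [theta[1], math.exp(theta[2])]])
    return L @ L.T


def _theta_from_psi(psi: np.ndarray, structure: str) -> np.ndarray:
    q = psi.shape[0]
    if q == 0:
        return np.zeros(0)
    if q == 1:
        return np.array([0.5 * math.log(max(psi[0, 0], 1e-12))])
    if structure == "independent":
        return np.array([0.5 * math.log(max(psi[0, 0], 1e-12)),
                         0.5 * math.log(max(psi[1, 1], 1e-12))])
    L = np.linalg.cholesky(psi + 1e-12 * np.eye(2))
    return np.array([math.log(L[0, 0]), L[1, 0], math.log(L[1, 1])])


def _profiled_objective(theta: np.ndarray, design: Design, method: str):
    """Profiled -2*log-likelihood and GLS by-products at relative covariance theta.

    Returns (neg2ll, beta_hat, sigma2_hat, XtWiX, logdet_W).
    """
    spec = design.spec
    c_slice, s_slice = _theta_slices(spec)
    psi_c = _psi_from_theta(theta[c_slice], spec.county_random, spec.variance_structure)
    psi_s = _psi_from_theta(theta[s_slice], spec.state_random, spec.variance_structure)

    n, p = design.n, design.p
    C = np.zeros((p + 1, p + 1))
    logdet = 0.0
    for st in design.states:
        m = st.y.size
        W = np.eye(m)
        if psi_s.size:
            W += st.Z_state @ psi_s @ st.Z_state.T
        if psi_c.size:
            for cb in st.counties:
                W[cb.rows, cb.rows] += cb.Z @ psi_c @ cb.Z.T
        try:
            L = np.linalg.cholesky(W)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"marginal covariance not positive definite: {exc}") from exc
        logdet += 2.0 * float(np.log(np.diag(L)).sum())
        A = solve_triangular(L, np.column_stack([st.X, st.y]), lower=True)
        C += A.T @ A

    XtWiX = C[:p, :p]
    XtWiy = C[:p, p]
    ytWiy = C[p, p]
    try:
        cf = cho_factor(XtWiX)
        beta = cho_solve(cf, XtWiy)
        logdet_xtwix = 2.0 * float(np.log(np.diag(cf[0])).sum())
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"singular fixed-effect crossproduct: {exc}") from exc
    rss = max(float(ytWiy - XtWiy @ beta), 1e-300)

    if method == "ML":
        sigma2 = rss / n
        neg2ll = n * math.log(2.0 * math.pi * sigma2) + logdet + n
    else:
        dof = n - p
        if dof <= 0:
            raise NumericalError("REML requires n > number of fixed effects")
        sigma2 = rss / dof
        neg2ll = dof * math.log(2.0 * math.pi * sigma2) + logdet + logdet_xtwix + dof
    return neg2ll, beta, sigma2, XtWiX, logdet


def dense_loglik(
    beta: np.ndarray | Sequence[float],
    components: VarianceComponents,
    design: Design,
    method: str = "ML",
) -> float:
    """Marginal Gaussian (restricted) log-likelihood by explicit dense covariance.

    Builds each state's full marginal covariance V_j = sigma^2 I +
    Zc Gc Zc' + Zs Gs Zs' explicitly and sums the exact log-densities; the
    REML variant uses the Harville restricted likelihood (which does not
    depend on ``beta``).  This is the slow correctness oracle for
    :func:`fit`, not a fitting routine.
    """
    spec = design.spec
    beta = np.asarray(beta, dtype=float)
    if beta.size != design.p:
        raise ValidationError(f"beta has {beta.size} entries, design expects {design.p}")
    Gc = components.county_matrix(spec.county_random)
    Gs = components.state_matrix(spec.state_random)
    sigma2 = components.residual_var

    if method not in ("ML", "REML"):
        raise ValidationError("method must be 'ML' or 'REML'")

    n, p = design.n, design.p
    logdet_V = 0.0
    quad = 0.0
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    resid_quads = []
    for st in design.states:
        m = st.y.size
        V = sigma2 * np.eye(m)
        if Gs.size:
            V += st.Z_state @ Gs @ st.Z_state.T
        if Gc.size:
            for cb in st.counties:
                V[cb.rows, cb.rows] += cb.Z @ Gc @ cb.Z.T
        sign, ld = np.linalg.slogdet(V)
        if sign <= 0:
            raise NumericalError(
                f"state {st.label}: covariance not positive definite "
                f"(cond={np.linalg.cond(V):.2e})"
            )
        logdet_V += ld
        try:
            cf = cho_factor(V)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(
                f"state {st.label}: covariance factorisation failed "
                f"(cond={np.linalg.cond(V):.2e})"
            ) from exc
        ViX = cho_solve(cf, st.X)
        Viy = cho_solve(cf, st.y)
        XtViX += st.X.T @ ViX
        XtViy += st.X.T @ Viy
        r = st.y - st.X @ beta
        quad += float(r @ cho_solve(cf, r))
        resid_quads.append((st, cf))

    if method == "ML":
        return -0.5 * (n * math.log(2.0 * math.pi) + logdet_V + quad)

    beta_gls = np.linalg.solve(XtViX, XtViy)
    quad_r = 0.0
    for st, cf in resid_quads:
        r = st.y - st.X @ beta_gls
        quad_r += float(r @ cho_solve(cf, r))
    sign, logdet_xvx = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise NumericalError("X'V^-1X not positive definite")
    return -0.5 * ((n - p) * math.log(2.0 * math.pi) + logdet_V + logdet_xvx + quad_r)


@dataclass
class FitResult:
    """Estimates and diagnostics of one fitted model."""

    spec: ModelSpec | None = None
    fixed_effects: dict[str, float] = field(default_factory=dict)
    fixed_se: dict[str, float] = field(default_factory=dict)
    components: VarianceComponents | None = None
    loglik: float = np.nan
    method: str = "REML"
    k: int = 0
    n: int = 0
    n_counties: int = 0
    n_states: int = 0
    converged: bool = False
    boundary: bool = False
    theta: np.ndarray | None = None
    design: Design | None = field(default=None, repr=False)
    group_effects: dict[str, pd.DataFrame] | None = field(default=None, repr=False)

    def fixed_pvalues(self) -> dict[str, float]:
        """Wald z-test p-values for the fixed effects."""
        out = {}
        for name, est in self.fixed_effects.items():
            se = self.fixed_se[name]
            z = est / se if se > 0 else np.inf
            out[name] = float(2.0 * stats.norm.sf(abs(z)))
        return out

    def to_dict(self) -> dict:
        return {
            "fixed": list(self.spec.fixed) if self.spec else [],
            "county_random": list(self.spec.county_random) if self.spec else [],
            "state_random": list(self.spec.state_random) if self.spec else [],
            "method": self.method,
            "fixed_effects": self.fixed_effects,
            "fixed_se": self.fixed_se,
            "variance_components": {
                f: getattr(self.components, f)
                for f in (
                    "county_intercept_var", "county_slope_var", "county_cov",
                    "state_intercept_var", "state_slope_var", "state_cov",
                    "residual_var",
                )
            } if self.components else {},
            "loglik": self.loglik,
            "k": self.k,
            "n": self.n,
            "n_counties": self.n_counties,
            "n_states": self.n_states,
            "converged": self.converged,
            "boundary": self.boundary,
        }


def _heuristic_theta_init(design: Design) -> np.ndarray:
    """Variance-partition starting values on the relative-covariance scale.

    Partitions OLS residual variance into between-state, between-county and
    within-county parts from group means, and starts slope variances small.
    """
    spec = design.spec
    X, y = design.X, design.y
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    total = max(float(resid.var()), 1e-8)

    state_means = np.array([resid[st.rows].mean() for st in design.states])
    county_means = []
    for st in design.states:
        r = resid[st.rows]
        for cb in st.counties:
            county_means.append(r[cb.rows].mean())
    county_means = np.array(county_means)

    v_state = max(float(state_means.var()), 0.05 * total)
    v_county = max(float(county_means.var()) - v_state, 0.05 * total)
    v_resid = max(total - v_state - v_county, 0.1 * total)

    def level_theta(terms: tuple[str, ...], v_int: float) -> list[float]:
        if not terms:
            return []
        rel = max(v_int / v_resid, 1e-4)
        if len(terms) == 1:
            return [0.5 * math.log(rel)]
        slope_rel = max(0.01 * rel, 1e-4)
        if spec.variance_structure == "independent":
            return [0.5 * math.log(rel), 0.5 * math.log(slope_rel)]
        return [0.5 * math.log(rel), 0.0, 0.5 * math.log(slope_rel)]

    return np.array(
        level_theta(spec.county_random, v_county) + level_theta(spec.state_random, v_state)
    )


def _fit_null(design: Design, method: str) -> FitResult:
    """OLS baseline (no random effects) with the matching Gaussian likelihood."""
    X, y = design.X, design.y
    n, p = design.n, design.p
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    if method == "ML":
        sigma2 = rss / n
        ll = -0.5 * (n * math.log(2.0 * math.pi * sigma2) + n)
    else:
        sigma2 = rss / (n - p)
        _, ldx = np.linalg.slogdet(X.T @ X)
        # Harville with V = s2*I: -2ll = (n-p)ln(2*pi*s2) + log|X'X| + (n-p),
        # matching the profiled REML convention of the mixed fitter (W = I)
        ll = -0.5 * ((n - p) * math.log(2.0 * math.pi * sigma2) + ldx + (n - p))
    cov_beta = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov_beta))
    spec = design.spec
    return FitResult(
        spec=spec,
        fixed_effects=dict(zip(design.fixed_names, map(float, beta))),
        fixed_se=dict(zip(design.fixed_names, map(float, se))),
        components=VarianceComponents(residual_var=sigma2),
        loglik=float(ll),
        method=method,
        k=p + 1,
        n=n,
        n_counties=design.n_counties,
        n_states=design.n_states,
        converged=True,
        boundary=False,
        theta=np.zeros(0),
        design=design,
    )


def fit(spec: ModelSpec, panel: pd.DataFrame | Design) -> FitResult:
    """Fit a three-level mixed model by profiled ML or REML.

    Optimises the profiled objective over the relative-covariance Cholesky
    parameters with a deterministic variance-partition start (plus a neutral
    fallback start); fixed effects and the residual variance are recovered by
    generalised least squares at the optimum.  Variance estimates on the
    0 boundary are reported as 0 with ``boundary=True``; a non-converged
    optimisation returns the best iterate flagged ``converged=False``.
    """
    if isinstance(panel, Design):
        same = (
            panel.spec.fixed == spec.fixed
            and panel.spec.county_random == spec.county_random
            and panel.spec.state_random == spec.state_random
            and panel.spec.variance_structure == spec.variance_structure
        )
        if not same:
            raise ValidationError("design was built for a structurally different spec")
        design = replace(panel, spec=spec)
    else:
        design = build_design(panel, spec)

    if spec.is_null:
        return _fit_null(design, spec.method)

    if spec.county_random and design.n_counties < 2:
        raise ValidationError("county random effects require >= 2 counties")
    if spec.state_random and design.n_states < 2:
        raise ValidationError("state random effects require >= 2 states")
    if "year" in spec.county_random:
        distinct = max(
            len(np.unique(cb.Z[:, 1])) for st in design.states for cb in st.counties
        )
        if distinct < 2:
            raise ValidationError(
                "random year slope requires >= 2 distinct years within some group"
            )
    if "year" in spec.state_random:
        distinct = max(len(np.unique(st.Z_state[:, 1])) for st in design.states)
        if distinct < 2:
            raise ValidationError(
                "random year slope requires >= 2 distinct years within some state"
            )

    def objective(theta: np.ndarray) -> float:
        try:
            return _profiled_objective(theta, design, spec.method)[0]
        except NumericalError:
            return 1e12

    starts = [_heuristic_theta_init(design)]
    starts.append(np.zeros(spec.n_theta()))

    best = None
    converged = False
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
            converged = bool(res.success)
        elif res.success and abs(res.fun - best.fun) <= 1e-6:
            converged = True
    # polish with a simplex pass if gradient-based optimisation struggled
    if not converged:
        res = optimize.minimize(
            objective, best.x, method="Nelder-Mead",
            options={"maxiter": 2000, "fatol": 1e-10, "xatol": 1e-8},
        )
        if res.fun <= best.fun + 1e-9:
            best = res
            converged = bool(res.success)

    theta = np.asarray(best.x, dtype=float)
    neg2ll, beta, sigma2, XtWiX, _ = _profiled_objective(theta, design, spec.method)
    ll = -0.5 * neg2ll

    c_slice, s_slice = _theta_slices(spec)
    psi_c = _psi_from_theta(theta[c_slice], spec.county_random, spec.variance_structure)
    psi_s = _psi_from_theta(theta[s_slice], spec.state_random, spec.variance_structure)

    boundary = False

    def extract(psi: np.ndarray, terms: tuple[str, ...]) -> tuple[float, float, float]:
        nonlocal boundary
        if psi.size == 0:
            return 0.0, 0.0, 0.0
        iv = sigma2 * psi[0, 0]
        sv = sigma2 * psi[1, 1] if psi.shape[0] == 2 else 0.0
        cov = sigma2 * psi[0, 1] if psi.shape[0] == 2 else 0.0
        # snap near-zero boundary estimates to exactly zero
        if psi[0, 0] < math.exp(2 * LOG_VAR_FLOOR) * 1e6:
            iv, cov = 0.0, 0.0
            boundary = True
        if psi.shape[0] == 2 and psi[1, 1] < math.exp(2 * LOG_VAR_FLOOR) * 1e6:
            sv, cov = 0.0, 0.0
            boundary = True
        return iv, sv, cov

    civ, csv_, ccov = extract(psi_c, spec.county_random)
    siv, ssv, scov = extract(psi_s, spec.state_random)
    components = VarianceComponents(
        county_intercept_var=civ, county_slope_var=csv_, county_cov=ccov,
        state_intercept_var=siv, state_slope_var=ssv, state_cov=scov,
        residual_var=sigma2,
    )

    cov_beta = sigma2 * np.linalg.inv(XtWiX)
    se = np.sqrt(np.diag(cov_beta))

    if not converged:
        logger.warning("mixed-model optimisation did not converge; returning best iterate")

    return FitResult(
        spec=spec,
        fixed_effects=dict(zip(design.fixed_names, map(float, beta))),
        fixed_se=dict(zip(design.fixed_names, map(float, se))),
        components=components,
        loglik=float(ll),
        method=spec.method,
        k=spec.k(),
        n=design.n,
        n_counties=design.n_counties,
        n_states=design.n_states,
        converged=converged,
        boundary=boundary,
        theta=theta,
        design=design,
    )


def predict_group_effects(result: FitResult) -> dict[str, pd.DataFrame]:
    """Empirical best predictions (BLUPs) of the state and county deviations."""
    if result.design is None or result.components is None:
        raise ValidationError("fit result lacks the design needed for prediction")
    design = result.design
    spec = design.spec
    Gc = result.components.county_matrix(spec.county_random)
    Gs = result.components.state_matrix(spec.state_random)
    sigma2 = result.components.residual_var
    beta = np.array([result.fixed_effects[n] for n in design.fixed_names])

    state_rows, county_rows = [], []
    for st in design.states:
        m = st.y.size
        V = sigma2 * np.eye(m)
        if Gs.size:
            V += st.Z_state @ Gs @ st.Z_state.T
        if Gc.size:
            for cb in st.counties:
                V[cb.rows, cb.rows] += cb.Z @ Gc @ cb.Z.T
        cf = cho_factor(V)
        r = st.y - st.X @ beta
        Vir = cho_solve(cf, r)
        if Gs.size:
            u = Gs @ st.Z_state.T @ Vir
            state_rows.append({"state_id": st.label,
                               **dict(zip(spec.state_random, map(float, u)))})
        if Gc.size:
            for cb in st.counties:
                b = Gc @ cb.Z.T @ Vir[cb.rows]
                county_rows.append({"county_id": cb.label, "state_id": st.label,
                                    **dict(zip(spec.county_random, map(float, b)))})
    return {
        "state": pd.DataFrame(state_rows),
        "county": pd.DataFrame(county_rows),
    }


def information_criteria(result: FitResult) -> tuple[float, float]:
    """AIC = -2 LL + 2k and BIC = -2 LL + k ln(n)."""
    if result.k == 0 and result.loglik == 0:
        return 0.0, 0.0
    aic = -2.0 * result.loglik + 2.0 * result.k
    bic = -2.0 * result.loglik + result.k * math.log(result.n) if result.n else np.nan
    return float(aic), float(bic)


def _is_nested(nested: ModelSpec, full: ModelSpec) -> bool:
    return (
        set(nested.fixed) <= set(full.fixed)
        and set(nested.county_random) <= set(full.county_random)
        and set(nested.state_random) <= set(full.state_random)
    )


def likelihood_ratio_test(
    nested: FitResult, full: FitResult, *, refit_ml: bool = True
) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested against a fuller model.

    Returns (statistic, df, p) with statistic = 2 (LL_full - LL_nested) and a
    chi-squared reference with df = k_full - k_nested.  When the two fits
    differ in fixed effects and were estimated by REML, both are re-fitted
    with ML automatically (REML likelihoods are not comparable across fixed
    structures).
    """
    if nested.spec is None or full.spec is None:
        raise ValidationError("both fits must carry their model spec")
    if not _is_nested(nested.spec, full.spec):
        raise ValidationError("models are not nested; likelihood-ratio test undefined")
    if nested.n != full.n:
        raise ValidationError("fits use different data (observation counts differ)")

    fixed_differ = set(nested.spec.fixed) != set(full.spec.fixed)
    ll_nested, ll_full = nested.loglik, full.loglik
    k_nested, k_full = nested.k, full.k
    if fixed_differ and refit_ml:
        if nested.method != "ML":
            refit = fit(replace(nested.spec, method="ML"), nested.design)
            ll_nested, k_nested = refit.loglik, refit.k
        if full.method != "ML":
            refit = fit(replace(full.spec, method="ML"), full.design)
            ll_full, k_full = refit.loglik, refit.k

    statistic = 2.0 * (ll_full - ll_nested)
    if statistic < -1e-4:
        raise NumericalError(
            f"negative LRT statistic ({statistic:.6g}); the full-model optimiser "
            "likely failed to reach its optimum"
        )
    statistic = max(statistic, 0.0)
    df = k_full - k_nested
    if df < 0:
        raise ValidationError("the 'full' model has fewer parameters than the nested one")
    if df == 0:
        # identical parameterisations: the test is degenerate
        return float(statistic), 0, 1.0
    p = float(stats.chi2.sf(statistic, df))
    return float(statistic), int(df), p


def icc_from_components(
    county_var: float, state_var: float, residual_var: float
) -> dict[str, float]:
    """Intraclass correlations of a two-grouping random-intercept model.

    ICC_county:state = (county + state) / (county + state + residual) is the
    variance share of geography as a whole; ICC_state = state / total is the
    share of the state level alone.
    """
    total = county_var + state_var + residual_var
    if total == 0:
        return {"county:state": float("nan"), "state": float("nan")}
    return {
        "county:state": (county_var + state_var) / total,
        "state": state_var / total,
    }


def icc(result: FitResult) -> dict[str, float]:
    """Per-level intraclass correlations from an unconditional-means fit."""
    if result.spec is not None and (
        "year" in result.spec.county_random or "year" in result.spec.state_random
    ):
        raise ValidationError("ICC is defined for random-intercept-only models")
    c = result.components
    return icc_from_components(c.county_intercept_var, c.state_intercept_var, c.residual_var)


def pseudo_r2(base: FitResult, extended: FitResult) -> float:
    """Proportional reduction in residual variance from base to extended model."""
    r0 = base.components.residual_var
    r1 = extended.components.residual_var
    if r0 == 0:
        raise ValidationError("base residual variance is zero; reduction undefined")
    if base.n and extended.n and base.n != extended.n:
        raise ValidationError("fits use different data (observation counts differ)")
    return float((r0 - r1) / r0)


@dataclass
class ComparisonTable:
    """Ordered model fits with pairwise LRTs and information criteria."""

    labels: list[str]
    fits: list[FitResult]
    lrt_rows: list[dict]
    criteria: pd.DataFrame  # columns: label, AIC, BIC, loglik, k, n

    def fit_by_label(self, label: str) -> FitResult:
        return self.fits[self.labels.index(label)]


MODEL_SEQUENCE_SPECS: dict[str, ModelSpec] = {
    "Null": ModelSpec(fixed=("intercept",), county_random=(), state_random=(), method="ML"),
    "Model 1": ModelSpec(fixed=("intercept",)),
    "Model 2": ModelSpec(
        fixed=("intercept", "year_centered"),
        county_random=("intercept", "year"),
        state_random=("intercept", "year"),
    ),
    "Model 3": ModelSpec(
        fixed=("intercept", "year_centered", "fsa_score_of_means"),
        county_random=("intercept", "year"),
        state_random=("intercept", "year"),
    ),
    "Model 4": ModelSpec(
        fixed=("intercept", "year_centered", "mean_fat", "mean_sugar"),
        county_random=("intercept", "year"),
        state_random=("intercept", "year"),
    ),
}


def run_model_sequence(
    panel: pd.DataFrame,
    method: str = "REML",
    variance_structure: str = "correlated",
    year_origin: int = 2004,
) -> ComparisonTable:
    """Fit the standard model-building sequence and compare the fits.

    Model 1: unconditional means (random intercepts per county-within-state
    and state).  Model 2: unconditional growth (adds fixed and random year
    slopes at both levels).  Model 3: Model 2 + FSA-score fixed effect.
    Model 4: Model 2 + fat and sugar fixed effects.  A single-intercept OLS
    null baseline is fitted first and tested against Model 1.

    Likelihood-ratio tests are computed for nested pairs only — Null vs
    Model 1, Model 1 vs 2, Model 2 vs 3, and Model 2 vs 4; Models 3 and 4
    are non-nested siblings (one swaps the FSA score for fat + sugar), so
    they are compared by information criteria instead.
    """
    labels = list(MODEL_SEQUENCE_SPECS)
    fits: list[FitResult] = []
    for label in labels:
        spec = replace(
            MODEL_SEQUENCE_SPECS[label],
            method=method,
            variance_structure=variance_structure,
            year_origin=year_origin,
        )
        fits.append(fit(spec, panel))

    by = dict(zip(labels, fits))
    lrt_rows = []
    for a, b in (("Null", "Model 1"), ("Model 1", "Model 2"),
                 ("Model 2", "Model 3"), ("Model 2", "Model 4")):
        statistic, df, p = likelihood_ratio_test(by[a], by[b])
        lrt_rows.append({"nested": a, "full": b, "statistic": statistic, "df": df, "p": p})

    criteria = pd.DataFrame(
        [
            {
                "label": label,
                "AIC": information_criteria(f)[0],
                "BIC": information_criteria(f)[1],
                "loglik": f.loglik,
                "k": f.k,
                "n": f.n,
            }
            for label, f in zip(labels, fits)
        ]
    )
    return ComparisonTable(labels=labels, fits=fits, lrt_rows=lrt_rows, criteria=criteria)
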