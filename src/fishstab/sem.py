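"""Piecewise structural equation models with directed-separation tests.

A path model is a DAG over annual indicator series.  Each endogenous
variable is fitted as a linear sub-model on its parents, either with
iid errors (OLS) or with AR(1) errors estimated by exact maximum
likelihood (small annual samples make two-step feasible-GLS unstable).
Overall fit is evaluated by testing the model's implied conditional
independencies (the basis set) and combining their p-values with
Fisher's C = -2 sum ln(p_i), compared against chi-square with 2k df.

Standardized coefficients are beta_std = beta * sd(x)/sd(y) on the
modeled (possibly transformed) scales; for a single-predictor iid
sub-model beta_std equals the Pearson correlation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as opt
import scipy.stats as st
import statsmodels.api as sm

from .errors import CollinearityError, NonStationaryError, ValidationError

#: Two-sided significance threshold used to flag paths in reports.
PATH_ALPHA = 0.10

#: p-values of exactly zero are clamped here before taking logs.
P_CLAMP = 1e-300


# ---------------------------------------------------------------------------
# AR(p) generalized least squares by exact maximum likelihood
# ---------------------------------------------------------------------------

def _pacf_to_ar(pacf: np.ndarray) -> np.ndarray:
    """Map partial autocorrelations in (-1, 1) to stationary AR coefficients."""
    a = np.array([], dtype=float)
    for k, r in enumerate(pacf, start=1):
        new = np.empty(k)
        new[k - 1] = r
        if k > 1:
            new[: k - 1] = a - r * a[::-1]
        a = new
    return a


def _ar_corr(phi: np.ndarray, nlags: int) -> np.ndarray:
    """Autocorrelations rho_0..rho_nlags of a stationary AR(p) process."""
    p = len(phi)
    # Yule-Walker system for gamma_0..gamma_p with unit innovation variance
    m = np.eye(p + 1)
    for k in range(p + 1):
        for i, f in enumerate(phi, start=1):
            m[k, abs(k - i)] -= f
    rhs = np.zeros(p + 1)
    rhs[0] = 1.0
    gam = np.linalg.solve(m, rhs)
    g = list(gam)
    for k in range(p + 1, nlags + 1):
        g.append(sum(phi[i - 1] * g[k - i] for i in range(1, p + 1)))
    g = np.array(g[: nlags + 1])
    return g / g[0]


@dataclass
class SubmodelFit:
    """One fitted linear sub-model (response on its parents)."""

    response: str
    predictors: tuple[str, ...]
    params: pd.Series            # includes "const"
    bse: pd.Series
    pvalues: pd.Series
    nobs: int
    df_resid: int
    error_structure: str         # "iid" | "ar1"
    rho: float | None            # AR(1) coefficient (None for iid)
    sigma2: float
    loglik: float
    resid: np.ndarray
    sd_y: float                  # SD of the modeled response
    sd_x: pd.Series              # SDs of the modeled predictors

    @property
    def resid_lag1_autocorr(self) -> float:
        r = self.resid - self.resid.mean()
        if len(r) < 3 or (r ** 2).sum() == 0:
            return 0.0
        return float((r[1:] * r[:-1]).sum() / (r ** 2).sum())


def _gls_profile(y: np.ndarray, X: np.ndarray, corr: np.ndarray):
    """Profile GLS quantities for a fixed error correlation matrix."""
    L = sla.cholesky(corr, lower=True)
    yw = sla.solve_triangular(L, y, lower=True)
    Xw = sla.solve_triangular(L, X, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    return beta, Xw, rss, logdet


def fit_gls_ar(
    y: np.ndarray,
    X: np.ndarray,
    names: Sequence[str],
    ar_order: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None, float, float, int]:
    """Linear model with AR(p) errors by exact Gaussian maximum likelihood.

    Returns (beta, cov_beta, phi_or_None, sigma2, loglik, df_resid),
    where ``phi`` is the vector of AR coefficients.
    The AR coefficients are parameterized through partial
    autocorrelations squashed by tanh, so every iterate is stationary;
    estimates pushed against the boundary raise
    :class:`NonStationaryError`.  Coefficient covariance uses the GLS
    form with the (n - p) residual-degrees-of-freedom variance.
    """
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise CollinearityError("rank-deficient design matrix")
    if n < k + ar_order + 1:
        raise ValidationError(
            f"need at least {k + ar_order + 1} complete observations, got {n}")

    if ar_order == 0:
        corr = np.eye(n)
        beta, Xw, rss, _ = _gls_profile(y, X, corr)
        phi = None
    else:
        def negloglik(z):
            pacf = np.tanh(np.atleast_1d(z))
            phi = _pacf_to_ar(pacf)
            corr = sla.toeplitz(_ar_corr(phi, n - 1))
            try:
                _, _, rss_, logdet = _gls_profile(y, X, corr)
            except np.linalg.LinAlgError:
                return 1e12
            s2 = max(rss_ / n, 1e-300)
            return 0.5 * (n * math.log(2 * math.pi * s2) + logdet + n)

        if ar_order == 1:
            res = opt.minimize_scalar(negloglik, bounds=(-5.0, 5.0),
                                      method="bounded")
            z_hat = np.array([res.x])
        else:
            res = opt.minimize(negloglik, np.zeros(ar_order),
                               method="Nelder-Mead",
                               options={"xatol": 1e-8, "fatol": 1e-10})
            z_hat = np.atleast_1d(res.x)
        pacf = np.tanh(z_hat)
        if np.any(np.abs(pacf) > 0.999):
            raise NonStationaryError(
                "AR estimate at the stationarity boundary (|pacf| ~ 1)")
        phi = _pacf_to_ar(pacf)
        corr = sla.toeplitz(_ar_corr(phi, n - 1))
        beta, Xw, rss, _ = _gls_profile(y, X, corr)

    df_resid = n - k
    sigma2 = rss / df_resid if df_resid > 0 else float("nan")
    cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
    s2_ml = max(rss / n, 1e-300)
    if ar_order == 0:
        logdet = 0.0
    else:
        L = sla.cholesky(corr, lower=True)
        logdet = 2.0 * float(np.log(np.diag(L)).sum())
    loglik = -0.5 * (n * math.log(2 * math.pi * s2_ml) + logdet + n)
    return beta, cov, phi, float(sigma2), float(loglik), df_resid


def fit_submodel(
    response: str,
    predictors: Sequence[str],
    data: pd.DataFrame,
    error_structure: str = "iid",
    transform: str = "none",
) -> SubmodelFit:
    """Fit one sub-model: ``response ~ predictors`` with iid or AR(1) errors.

    ``transform="log"`` models ln(response); standardization downstream
    then operates on the log scale.  Rows must already be complete cases
    ordered by year.
    """
    if error_structure not in ("iid", "ar1"):
        raise ValidationError(f"unknown error structure {error_structure!r}")
    y = data[response].to_numpy(dtype=float)
    if transform == "log":
        if np.any(y <= 0):
            raise ValidationError(
                f"log transform of {response} requires positive values")
        y = np.log(y)
    elif transform != "none":
        raise ValidationError(f"unknown transform {transform!r}")

    X = np.column_stack(
        [np.ones(len(y))] + [data[p].to_numpy(dtype=float) for p in predictors])
    names = ["const", *predictors]
    ar_order = 1 if error_structure == "ar1" else 0

    if error_structure == "iid":
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise CollinearityError("rank-deficient design matrix")
        ols = sm.OLS(y, X).fit()
        beta, cov = ols.params, ols.cov_params()
        rho, sigma2, loglik = None, float(ols.scale), float(ols.llf)
        df_resid = int(ols.df_resid)
    else:
        beta, cov, phi, sigma2, loglik, df_resid = fit_gls_ar(
            y, X, names, ar_order=ar_order)
        rho = float(phi[0]) if phi is not None else None

    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * st.t.sf(np.abs(tvals), df_resid)
    resid = y - X @ beta
    sd_x = pd.Series({p: float(np.std(data[p].to_numpy(dtype=float), ddof=1))
                      for p in predictors})
    return SubmodelFit(
        response=response, predictors=tuple(predictors),
        params=pd.Series(beta, index=names), bse=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names), nobs=len(y),
        df_resid=df_resid, error_structure=error_structure, rho=rho,
        sigma2=sigma2, loglik=loglik, resid=resid,
        sd_y=float(np.std(y, ddof=1)), sd_x=sd_x)


def standardize(coef: float, sd_x: float, sd_y: float) -> float:
    """Standardized coefficient beta_std = beta * sd(x) / sd(y)."""
    if sd_y == 0:
        raise ValidationError("response SD is zero: cannot standardize")
    return coef * sd_x / sd_y


# ---------------------------------------------------------------------------
# Path-model specification and the directed-separation basis set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Claim:
    """One implied conditional independence: x independent of y given `given`.

    ``y`` is the claim's dependent variable: the test regresses y on
    its conditioning set plus x and reads the p-value on x.
    """

    x: str
    y: str
    given: tuple[str, ...]


@dataclass
class PathModelSpec:
    """Declared DAG of annual indicators plus per-response fitting options."""

    variables: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    error_structure: Mapping[str, str] = field(default_factory=dict)
    transform: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        vs = set(self.variables)
        for a, b in self.edges:
            if a not in vs or b not in vs:
                raise ValidationError(f"edge {a}->{b} uses undeclared variable")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("path model must be acyclic")
        for v in list(self.error_structure) + list(self.transform):
            if v not in vs:
                raise ValidationError(f"options refer to undeclared variable {v}")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.edges)
        return g

    def endogenous(self) -> list[str]:
        g = self.graph()
        return [v for v in self.variables if g.in_degree(v) > 0]

    def error_for(self, v: str) -> str:
        return self.error_structure.get(v, "iid")

    def transform_for(self, v: str) -> str:
        return self.transform.get(v, "none")

    @classmethod
    def from_dict(cls, d: Mapping) -> "PathModelSpec":
        edges = []
        for e in d.get("edges", []):
            if isinstance(e, str):
                a, b = [s.strip() for s in e.split("->")]
            else:
                a, b = e
            edges.append((a, b))
        return cls(
            variables=tuple(d["variables"]),
            edges=tuple(edges),
            error_structure=dict(d.get("error", {})),
            transform=dict(d.get("transform", {})),
        )


def basis_set(spec: PathModelSpec) -> list[Claim]:
    """Independence claims implied by the DAG (the d-separation basis set).

    For every non-adjacent ordered pair (u, v) with v endogenous and v
    not an ancestor of u, the claim is

        u  _||_  v  |  parents(v) U (parents(u) & ancestors(v)).

    Unordered pairs are deduplicated keeping the claim whose dependent
    variable is endogenous (topologically later, then lexicographic, as
    the tie-break); claims between two exogenous variables are excluded.
    """
    g = spec.graph()
    order = {v: i for i, v in enumerate(nx.lexicographical_topological_sort(g))}
    anc = {v: nx.ancestors(g, v) for v in g}
    candidates: dict[frozenset, Claim] = {}

    for u, v in itertools.permutations(g.nodes, 2):
        if g.has_edge(u, v) or g.has_edge(v, u):
            continue
        if g.in_degree(v) == 0:      # v must be endogenous
            continue
        if v in anc[u]:              # v must not be an ancestor of u
            continue
        cond = set(g.predecessors(v)) | (set(g.predecessors(u)) & anc[v])
        claim = Claim(x=u, y=v, given=tuple(sorted(cond)))
        key = frozenset((u, v))
        prev = candidates.get(key)
        if prev is None:
            candidates[key] = claim
        else:
            # deterministic preference: later dependent in topological order
            if (order[claim.y], claim.y) > (order[prev.y], prev.y):
                candidates[key] = claim
    return sorted(candidates.values(), key=lambda c: (c.y, c.x))


def fishers_c(pvalues: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's C = -2 sum ln(p_i), df = 2k, and its chi-square tail p.

    An empty claim set (saturated model) returns (0, 0, 1) by
    convention.  Zero p-values are clamped at 1e-300.
    """
    k = len(pvalues)
    if k == 0:
        return 0.0, 0, 1.0
    ps = np.clip(np.asarray(pvalues, dtype=float), P_CLAMP, 1.0)
    c = float(-2.0 * np.log(ps).sum())
    df = 2 * k
    return c, df, float(st.chi2.sf(c, df))


# ---------------------------------------------------------------------------
# Full piecewise fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathEstimate:
    response: str
    predictor: str
    coef: float
    beta_std: float
    se: float
    pvalue: float
    significant: bool    # two-sided p < 0.1


@dataclass
class SemFit:
    spec: PathModelSpec
    estimates: list[PathEstimate]
    submodels: dict[str, SubmodelFit]
    claims: list[Claim]
    claim_pvalues: list[float]
    fisher_c: float
    df: int
    pvalue: float
    dropped_years: list

    def estimates_table(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.estimates])

    def to_dict(self) -> dict:
        return {
            "edges": [f"{a} -> {b}" for a, b in self.spec.edges],
            "estimates": [e.__dict__ for e in self.estimates],
            "claims": [
                {"x": c.x, "y": c.y, "given": list(c.given), "p": p}
                for c, p in zip(self.claims, self.claim_pvalues)
            ],
            "fisher_c": self.fisher_c,
            "df": self.df,
            "pvalue": self.pvalue,
            "dropped_years": list(self.dropped_years),
            "diagnostics": {
                v: {"rho": f.rho,
                    "resid_lag1_autocorr": f.resid_lag1_autocorr}
                for v, f in self.submodels.items()
            },
        }


def fit_sem(spec: PathModelSpec, data: pd.DataFrame) -> SemFit:
    """Fit every sub-model, test every basis-set claim, assemble the SemFit.

    ``data`` has one row per year (index = year) and one column per
    declared variable.  Rows with a missing value in any declared
    variable are dropped (complete-case deletion) and reported in
    ``dropped_years``.  Each claim is tested by adding its independent
    variable to the dependent variable's conditional regression, fitted
    with the dependent variable's declared error structure.
    """
    cols = list(spec.variables)
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValidationError(f"data lacks declared variables: {missing}")
    sub = data.loc[:, cols].sort_index()
    complete = sub.dropna()
    dropped = [ix for ix in sub.index if ix not in complete.index]

    g = spec.graph()
    submodels: dict[str, SubmodelFit] = {}
    estimates: list[PathEstimate] = []
    for v in spec.endogenous():
        parents = sorted(g.predecessors(v))
        fit = fit_submodel(v, parents, complete,
                           error_structure=spec.error_for(v),
                           transform=spec.transform_for(v))
        submodels[v] = fit
        for p in parents:
            coef = float(fit.params[p])
            estimates.append(PathEstimate(
                response=v, predictor=p, coef=coef,
                beta_std=standardize(coef, float(fit.sd_x[p]), fit.sd_y),
                se=float(fit.bse[p]), pvalue=float(fit.pvalues[p]),
                significant=bool(fit.pvalues[p] < PATH_ALPHA)))

    claims = basis_set(spec)
    claim_ps: list[float] = []
    for c in claims:
        fit = fit_submodel(c.y, [*c.given, c.x], complete,
                           error_structure=spec.error_for(c.y),
                           transform=spec.transform_for(c.y))
        claim_ps.append(float(fit.pvalues[c.x]))

    c_stat, df, p = fishers_c(claim_ps)
    return SemFit(spec=spec, estimates=estimates, submodels=submodels,
                  claims=claims, claim_pvalues=claim_ps,
                  fisher_c=c_stat, df=df, pvalue=p, dropped_years=dropped)
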