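"""Interannual trend models with autocorrelation-robust errors.

Trends in annual ecological and fishery indicators are fitted as linear
or quadratic functions of (centered) year, with iid, AR(1) or AR(2)
error structures estimated by exact maximum likelihood.  The quadratic
form is a lightweight surrogate for a penalized smoother: only the
direction and significance of a trend feed downstream interpretation.
A trend is flagged for display when its p-value is below 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .errors import ValidationError
from .sem import fit_gls_ar

#: Display threshold for trend inclusion.
TREND_ALPHA = 0.10


@dataclass
class TrendFit:
    """Fitted interannual trend for one indicator series."""

    name: str
    form: str                 # "linear" | "quadratic"
    ar_order: int
    years: np.ndarray
    coef: pd.Series           # const, year[, year2]; year is centered
    se: pd.Series
    pvalues: pd.Series
    phi: np.ndarray | None    # AR coefficients (None for iid)
    sigma2: float
    loglik: float
    fitted: np.ndarray
    ci_halfwidth: np.ndarray  # 95% pointwise CI on the mean trend
    include: bool             # any trend term with p < 0.1

    @property
    def slope_pvalue(self) -> float:
        return float(self.pvalues["year"])


def _design(years: np.ndarray, form: str) -> tuple[np.ndarray, list[str]]:
    t = years - years.mean()
    if form == "linear":
        return np.column_stack([np.ones_like(t), t]), ["const", "year"]
    if form == "quadratic":
        return (np.column_stack([np.ones_like(t), t, t ** 2]),
                ["const", "year", "year2"])
    raise ValidationError(f"unknown trend form {form!r}")


def fit_trend(
    years,
    values,
    form: str = "linear",
    ar_order: int = 1,
) -> TrendFit:
    """Fit one trend model by ML and return coefficients, CIs and the p<0.1 flag."""
    years = np.asarray(years, dtype=float)
    y = np.asarray(values, dtype=float)
    if ar_order not in (0, 1, 2):
        raise ValidationError("ar_order must be 0, 1 or 2")
    keep = np.isfinite(y) & np.isfinite(years)
    years, y = years[keep], y[keep]
    order = np.argsort(years)
    years, y = years[order], y[order]

    X, names = _design(years, form)
    beta, cov, phi, sigma2, loglik, df_resid = fit_gls_ar(
        y, X, names, ar_order=ar_order)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * st.t.sf(np.abs(tvals), df_resid)

    fitted = X @ beta
    tcrit = st.t.ppf(0.975, df_resid)
    half = tcrit * np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))

    trend_terms = [n for n in names if n != "const"]
    pseries = pd.Series(pvals, index=names)
    include = bool((pseries[trend_terms] < TREND_ALPHA).any())
    return TrendFit(
        name="", form=form, ar_order=ar_order, years=years,
        coef=pd.Series(beta, index=names), se=pd.Series(se, index=names),
        pvalues=pseries, phi=phi, sigma2=sigma2, loglik=loglik,
        fitted=fitted, ci_halfwidth=half, include=include)


def trend_table(fits: dict[str, TrendFit]) -> pd.DataFrame:
    """Summarize a set of named trend fits as a flat table."""
    rows = []
    for name, f in fits.items():
        rows.append({
            "series": name, "form": f.form, "ar_order": f.ar_order,
            "slope": float(f.coef["year"]), "slope_se": float(f.se["year"]),
            "slope_p": f.slope_pvalue,
            "rho1": float(f.phi[0]) if f.phi is not None else np.nan,
            "include": f.include,
        })
    return pd.DataFrame(rows)
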