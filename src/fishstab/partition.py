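"""Within-year stability-asynchrony partitioning.

For a species x month matrix of biomass or harvest, the aggregate
(portfolio or community) stability

    S_agg = mu_R / sigma_R                       (inverse CV of monthly totals)

factors exactly as

    S_agg = phi * S_bar,        phi = SAE * CPE,

where ``S_bar = mu_R / sum_i sigma_i`` is the inverse of the
share-weighted average species CV, asynchrony ``phi = sum_i sigma_i /
sigma_R >= 1``, the statistical averaging effect ``SAE = sum_i sigma_i /
sqrt(sum_i sigma_i^2)`` lies in [1, sqrt(n)], and the compensation
effect ``CPE = sqrt(sum_i sigma_i^2) / sigma_R`` exceeds 1 when species
covary negatively (CPE is the inverse square-rooted variance ratio).

All SDs use the sample (T-1) denominator; with five months per year the
denominator choice is numerically consequential for the S quantities,
though the dimensionless ratios are nearly invariant to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import MonthlyPanel
from .errors import DegenerateSeriesError

#: Relative tolerance at which the multiplicative identities are asserted.
IDENTITY_RTOL = 1e-10


@dataclass(frozen=True)
class TemporalStats:
    """Per-species and aggregate temporal moments of one panel."""

    species: tuple[str, ...]
    mu: np.ndarray        # per-species temporal means
    sigma: np.ndarray     # per-species sample SDs
    cv: np.ndarray        # sigma/mu (NaN where mu = 0)
    mu_R: float           # mean of the monthly totals
    sigma_R: float        # sample SD of the monthly totals
    n: int
    T: int

    @property
    def sum_sigma(self) -> float:
        return float(self.sigma.sum())

    @property
    def sum_sigma_sq_root(self) -> float:
        """sqrt(sum_i sigma_i^2): portfolio SD under independent fluctuations."""
        return float(np.sqrt((self.sigma ** 2).sum()))


@dataclass(frozen=True)
class StabilityDecomposition:
    """The six partitioned quantities for one panel (all dimensionless)."""

    s_agg: float
    s_bar: float
    phi: float
    sae: float
    cpe: float
    layer: str
    stats: TemporalStats


def _as_matrix(panel) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(panel, MonthlyPanel):
        return panel.values, panel.species
    x = np.atleast_2d(np.asarray(panel, dtype=float))
    return x, tuple(f"sp{i}" for i in range(x.shape[0]))


def temporal_stats(panel) -> TemporalStats:
    """Compute per-species means/SDs and the aggregate-series moments.

    Accepts a :class:`~fishstab.dataio.MonthlyPanel` or a plain
    n x T array.  Raises :class:`DegenerateSeriesError` when every
    species SD is zero or the aggregate mean is zero.
    """
    x, species = _as_matrix(panel)
    n, T = x.shape
    if T < 2:
        raise DegenerateSeriesError("need at least two time points",
                                    code="zero-variance")
    mu = x.mean(axis=1)
    sigma = x.std(axis=1, ddof=1)
    totals = x.sum(axis=0)
    mu_R = float(totals.mean())
    sigma_R = float(totals.std(ddof=1))
    if not np.any(sigma > 0):
        raise DegenerateSeriesError(
            "all species series are constant (every sigma_i = 0)",
            code="zero-variance")
    if mu_R <= 0:
        raise DegenerateSeriesError(
            "aggregate temporal mean is zero", code="zero-mean")
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mu > 0, sigma / np.where(mu > 0, mu, 1.0), np.nan)
    return TemporalStats(species=species, mu=mu, sigma=sigma, cv=cv,
                         mu_R=mu_R, sigma_R=sigma_R, n=n, T=T)


def portfolio_stability(total_series) -> float:
    """Inverse CV (mu/sigma) of a summed monthly series.

    This is S_Portfolio (or S_Community when applied to community
    biomass).  A constant series has infinite stability and raises a
    zero-variance error instead of returning a number.
    """
    y = np.asarray(total_series, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise DegenerateSeriesError("need a 1-D series of length >= 2",
                                    code="zero-variance")
    mu = float(y.mean())
    sd = float(y.std(ddof=1))
    if sd == 0:
        raise DegenerateSeriesError("series is constant (SD = 0)",
                                    code="zero-variance")
    if mu <= 0:
        raise DegenerateSeriesError("series mean is zero", code="zero-mean")
    return mu / sd


def species_stability_bar(stats: TemporalStats) -> float:
    """Inverse of the share-weighted average species CV.

    ``(sum_i CV_i * mu_i / mu_R)^{-1}``, which reduces algebraically to
    ``mu_R / sum_i sigma_i``; species with sigma_i = 0 contribute zero
    to the weighted average but still count in mu_R.
    """
    ss = stats.sum_sigma
    if ss == 0:
        raise DegenerateSeriesError("sum of species SDs is zero",
                                    code="zero-variance")
    return stats.mu_R / ss


def asynchrony(stats: TemporalStats) -> float:
    """phi = sum_i sigma_i / sigma_R; >= 1, equal to 1 under perfect synchrony."""
    if stats.sigma_R == 0:
        raise DegenerateSeriesError(
            "aggregate series is constant while species fluctuate "
            "(perfect compensation)", code="perfect-compensation")
    return stats.sum_sigma / stats.sigma_R


def sae(stats: TemporalStats) -> float:
    """Statistical averaging effect, sum sigma_i / sqrt(sum sigma_i^2) in [1, sqrt(n)]."""
    denom = stats.sum_sigma_sq_root
    if denom == 0:
        raise DegenerateSeriesError("sum of species SDs is zero",
                                    code="zero-variance")
    return stats.sum_sigma / denom


def cpe(stats: TemporalStats) -> float:
    """Compensation effect, sqrt(sum sigma_i^2) / sigma_R.

    Values above 1 indicate greater aggregate stability than expected if
    species fluctuated independently (negative covariances).
    """
    if stats.sigma_R == 0:
        raise DegenerateSeriesError(
            "aggregate series is constant while species fluctuate "
            "(perfect compensation)", code="perfect-compensation")
    return stats.sum_sigma_sq_root / stats.sigma_R


def decompose(panel, layer: str = "harvest") -> StabilityDecomposition:
    """Compute all six quantities and assert the multiplicative identities.

    ``layer`` labels the hierarchy level ("species" for community
    biomass, "harvest" for the fishing portfolio) and is carried through
    to output tables.
    """
    try:
        stats = temporal_stats(panel)
        s_agg = stats.mu_R / stats.sigma_R if stats.sigma_R > 0 else None
        if s_agg is None:
            raise DegenerateSeriesError(
                "aggregate series is constant while species fluctuate "
                "(perfect compensation)", code="perfect-compensation")
        s_bar = species_stability_bar(stats)
        phi = asynchrony(stats)
        sae_v = sae(stats)
        cpe_v = cpe(stats)
    except DegenerateSeriesError as err:
        raise DegenerateSeriesError(f"[layer={layer}] {err}",
                                    code=err.code) from None

    assert abs(s_agg - phi * s_bar) <= IDENTITY_RTOL * abs(s_agg), \
        "S_agg = phi * S_bar identity violated"
    assert abs(phi - sae_v * cpe_v) <= IDENTITY_RTOL * abs(phi), \
        "phi = SAE * CPE identity violated"
    assert phi >= 1 - 1e-12, "phi below its theoretical lower bound"
    assert 1 - 1e-12 <= sae_v <= np.sqrt(stats.n) + 1e-12, "SAE outside [1, sqrt(n)]"

    return StabilityDecomposition(
        s_agg=float(s_agg), s_bar=float(s_bar), phi=float(phi),
        sae=float(sae_v), cpe=float(cpe_v), layer=layer, stats=stats)
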