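"""Annual harvest-portfolio indicators.

Region-year scalar indices built from monthly harvest, value and trip
records: the seasonal harvest ratio (SHR), harvest-weighted timing,
a cross-species effort index, portfolio yield/value totals, portfolio
harvest stability at the survey-month (short) and 12-month (long)
resolutions, value stability, and the cumulative-yield species
selection rule.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import DEFAULT_SURVEY_MONTHS, MonthlyPanel
from .errors import DegenerateSeriesError
from .partition import portfolio_stability


@dataclass
class AnnualIndicators:
    """Scalar indicator set for one region-year.

    ``None`` marks an indicator whose defining ratio was degenerate for
    that year (e.g., constant monthly totals); batch tables encode these
    as empty cells with a paired flag column.
    """

    region: str
    year: int
    shr: float | None = None
    mean_harvest_month: dict[str, float] | None = None
    effort_index: float | None = None
    portfolio_yield: float = 0.0
    portfolio_value: float = 0.0
    s_portfolio_s: float | None = None
    s_portfolio_l: float | None = None
    value_stability: float | None = None


def seasonal_harvest_ratio(
    monthly_totals: Mapping[int, float],
    closure_months: Sequence[int],
    survey_months: Sequence[int] = DEFAULT_SURVEY_MONTHS,
) -> float:
    """Mean monthly harvest inside the closure window over the mean outside it.

    Both windows are restricted to survey months (the primary fishing
    season).  High values mean other stocks compensated for the closed
    fishery during the closure.
    """
    surv = [m for m in survey_months if m in monthly_totals]
    inside = [monthly_totals[m] for m in surv if m in set(closure_months)]
    outside = [monthly_totals[m] for m in surv if m not in set(closure_months)]
    if not inside or not outside:
        raise DegenerateSeriesError(
            "closure and open windows must both intersect the survey months",
            code="zero-denominator")
    denom = float(np.mean(outside))
    if denom == 0:
        raise DegenerateSeriesError("open-season mean harvest is zero",
                                    code="zero-denominator")
    return float(np.mean(inside)) / denom


def mean_harvest_month(
    monthly_harvest: Mapping[int, float],
    months: Sequence[int] | None = None,
) -> float:
    """Average month of harvest, weighted by monthly harvest mass.

    ``months`` restricts the index to a sub-grid (e.g., survey months to
    match the temporal resolution of the compensation indices); default
    uses every month present.
    """
    if months is None:
        months = sorted(monthly_harvest)
    h = np.array([monthly_harvest.get(m, 0.0) for m in months], dtype=float)
    m = np.array(list(months), dtype=float)
    total = h.sum()
    if total <= 0:
        raise DegenerateSeriesError("zero total harvest: timing undefined",
                                    code="undefined-timing")
    return float((m * h).sum() / total)


def effort_index(
    trips: Mapping[str, Mapping[int, float]],
    survey_months: Sequence[int] = DEFAULT_SURVEY_MONTHS,
    per_month: bool = False,
) -> float | None:
    """Combined annual trips index across species.

    Per species, trips are summed over the survey months; the index is
    the unweighted mean of those species totals.  ``per_month=True``
    switches to the mean of monthly trip counts instead of species
    totals (an alternative reading of "averaging the total number of
    trips for each species").  Returns ``None`` when no species has trip
    data (a missing-indicator flag, not an error).
    """
    sm = set(survey_months)
    totals = []
    for sp, by_month in trips.items():
        vals = [v for m, v in by_month.items() if m in sm]
        if not vals:
            continue
        totals.append(np.mean(vals) if per_month else np.sum(vals))
    if not totals:
        return None
    return float(np.mean(totals))


def portfolio_totals(
    harvest_panel: MonthlyPanel, value_panel: MonthlyPanel
) -> tuple[float, float]:
    """Annual portfolio yield (kg) and value (USD): sums over species and months."""
    return float(harvest_panel.values.sum()), float(value_panel.values.sum())


def _safe_stability(series) -> float | None:
    try:
        return portfolio_stability(series)
    except DegenerateSeriesError:
        return None


def portfolio_stability_short_long(
    harvest_panel_12: MonthlyPanel,
    survey_months: Sequence[int] = DEFAULT_SURVEY_MONTHS,
) -> tuple[float | None, float | None]:
    """(S_Portfolio,S, S_Portfolio,L): inverse CV of monthly total harvest.

    The short form uses only the survey months (matching the biomass
    indices); the long form uses all months present in the panel.
    Degenerate windows yield ``None``.
    """
    short = harvest_panel_12.subset_months(survey_months)
    return (_safe_stability(short.totals()),
            _safe_stability(harvest_panel_12.totals()))


def value_stability(value_panel_12: MonthlyPanel) -> float | None:
    """Inverse CV of summed monthly harvest value across all 12 months."""
    return _safe_stability(value_panel_12.totals())


def select_top_species(
    total_yields: Mapping[str, float], cutoff: float = 0.90
) -> list[str]:
    """Species forming the top ``cutoff`` share of cumulative multi-year yield.

    Yields are ranked descending (alphabetical tie-break); species are
    included in rank order until the cumulative share first reaches the
    cutoff, and the crossing species is kept.
    """
    items = sorted(total_yields.items(), key=lambda kv: (-kv[1], kv[0]))
    grand = sum(v for _, v in items)
    if grand <= 0:
        return []
    selected, cum = [], 0.0
    for sp, v in items:
        selected.append(sp)
        cum += v / grand
        if cum >= cutoff - 1e-12:
            break
    return selected


def annual_indicators(
    region: str,
    year: int,
    harvest_panel_12: MonthlyPanel,
    value_panel_12: MonthlyPanel,
    trips: Mapping[str, Mapping[int, float]] | None,
    closure_months: Sequence[int],
    survey_months: Sequence[int] = DEFAULT_SURVEY_MONTHS,
) -> AnnualIndicators:
    """Assemble the full indicator set for one region-year."""
    totals12 = dict(zip(harvest_panel_12.months, harvest_panel_12.totals()))
    out = AnnualIndicators(region=region, year=year)

    try:
        out.shr = seasonal_harvest_ratio(totals12, closure_months, survey_months)
    except DegenerateSeriesError:
        out.shr = None

    timing: dict[str, float] = {}
    for i, sp in enumerate(harvest_panel_12.species):
        by_month = dict(zip(harvest_panel_12.months, harvest_panel_12.values[i]))
        try:
            timing[sp] = mean_harvest_month(by_month)
        except DegenerateSeriesError:
            pass
    out.mean_harvest_month = timing or None

    out.effort_index = effort_index(trips, survey_months) if trips else None
    out.portfolio_yield, out.portfolio_value = portfolio_totals(
        harvest_panel_12, value_panel_12)
    out.s_portfolio_s, out.s_portfolio_l = portfolio_stability_short_long(
        harvest_panel_12, survey_months)
    out.value_stability = value_stability(value_panel_12)
    return out


def indicators_table(rows: Sequence[AnnualIndicators]) -> pd.DataFrame:
    """Flatten indicator records to a region-year table with flag columns."""
    recs = []
    for r in rows:
        d = asdict(r)
        d.pop("mean_harvest_month")
        recs.append(d)
    df = pd.DataFrame(recs)
    for col in ("shr", "effort_index", "s_portfolio_s", "s_portfolio_l",
                "value_stability"):
        df[f"{col}_missing"] = df[col].isna()
    return df
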