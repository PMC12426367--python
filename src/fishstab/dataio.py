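"""Tidy-long record IO, validation, and reshaping to monthly panels.

The canonical interchange format is a long CSV with one row per
(region, year, month, species, quantity_kind) holding a single
non-negative value.  ``quantity_kind`` distinguishes biomass indices,
harvest mass, dockside value and trip counts so that synthetic and real
data flow through identical code paths.

Zero is a legitimate value (e.g., harvest during a closure); a missing
row is *not* an implicit zero, and panel construction refuses gaps.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IncompletePanelError, ValidationError

logger = logging.getLogger("fishstab")

#: Accepted measurement kinds for the ``quantity_kind`` column.
QUANTITY_KINDS = ("biomass_kg", "harvest_kg", "value_usd", "trips")

#: Canonical column order of the long format.
LONG_COLUMNS = ("region", "year", "month", "species", "quantity_kind", "value")

#: ChesMMAP-style survey months (March, May, July, September, November).
DEFAULT_SURVEY_MONTHS = (3, 5, 7, 9, 11)


# ---------------------------------------------------------------------------
# Long records
# ---------------------------------------------------------------------------

def validate_long(records: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format frame and return it with canonical dtypes.

    Raises :class:`ValidationError` naming the offending rows for
    malformed months/years, negative values, unknown quantity kinds, or
    duplicated keys.  Columns beyond the canonical six are dropped (with
    a logged count).
    """
    missing = [c for c in LONG_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    extra = [c for c in records.columns if c not in LONG_COLUMNS]
    if extra:
        logger.info("ignoring %d unknown column(s): %s", len(extra), extra)
    df = records.loc[:, list(LONG_COLUMNS)].copy()

    for col, kind in (("year", "year"), ("month", "month")):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() | (coerced != coerced.round())
        if bad.any():
            raise ValidationError(
                f"malformed {kind} in rows {list(df.index[bad])[:10]}"
            )
        df[col] = coerced.astype(int)

    bad_month = ~df["month"].between(1, 12)
    if bad_month.any():
        raise ValidationError(
            f"month outside 1..12 in rows {list(df.index[bad_month])[:10]}"
        )

    bad_kind = ~df["quantity_kind"].isin(QUANTITY_KINDS)
    if bad_kind.any():
        raise ValidationError(
            f"unknown quantity_kind in rows {list(df.index[bad_kind])[:10]}"
        )

    values = pd.to_numeric(df["value"], errors="coerce")
    bad_val = values.isna() | (values < 0)
    if bad_val.any():
        raise ValidationError(
            f"negative or non-numeric value in rows {list(df.index[bad_val])[:10]}"
        )
    df["value"] = values.astype(float)

    key_cols = ["region", "year", "month", "species", "quantity_kind"]
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        offenders = df.loc[dup, key_cols].drop_duplicates().head(5)
        raise ValidationError(
            "duplicate keys:\n" + offenders.to_string(index=False)
        )
    return df


def read_long(path) -> pd.DataFrame:
    """Read and validate a long CSV (header row names the six fields)."""
    df = pd.read_csv(path)
    out = validate_long(df)
    logger.info("read %d valid records from %s", len(out), path)
    return out


def write_long(records: pd.DataFrame, path) -> None:
    """Write validated long records to CSV (inverse of :func:`read_long`)."""
    validate_long(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Monthly panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonthlyPanel:
    """Species x month matrix of one quantity for one region-year.

    ``values[i, j]`` is the value for ``species[i]`` in ``months[j]``.
    """

    region: str
    year: int
    quantity_kind: str
    species: tuple[str, ...]
    months: tuple[int, ...]
    values: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.values, dtype=float)
        if x.shape != (len(self.species), len(self.months)):
            raise ValidationError(
                f"panel shape {x.shape} does not match "
                f"{len(self.species)} species x {len(self.months)} months"
            )
        if len(self.months) < 2:
            raise ValidationError("a panel needs at least two months")
        if np.any(x < 0) or not np.all(np.isfinite(x)):
            raise ValidationError("panel values must be finite and non-negative")
        object.__setattr__(self, "values", x)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_months(self) -> int:
        return len(self.months)

    def totals(self) -> np.ndarray:
        """Monthly totals summed across species (the aggregate series)."""
        return self.values.sum(axis=0)

    def subset_months(self, months: Sequence[int]) -> "MonthlyPanel":
        keep = [m for m in self.months if m in set(months)]
        idx = [self.months.index(m) for m in keep]
        return MonthlyPanel(
            self.region, self.year, self.quantity_kind,
            self.species, tuple(keep), self.values[:, idx],
        )

    def to_long(self) -> pd.DataFrame:
        rows = [
            (self.region, self.year, m, sp, self.quantity_kind,
             self.values[i, j])
            for i, sp in enumerate(self.species)
            for j, m in enumerate(self.months)
        ]
        return pd.DataFrame(rows, columns=list(LONG_COLUMNS))


def to_panel(
    records: pd.DataFrame,
    region: str,
    year: int,
    quantity_kind: str,
    months: Sequence[int],
    species: Sequence[str] | None = None,
) -> MonthlyPanel:
    """Assemble a :class:`MonthlyPanel` from long records.

    Every (species, month) cell must be present; gaps raise
    :class:`IncompletePanelError` listing the missing combinations.
    """
    df = records
    sel = (
        (df["region"] == region)
        & (df["year"] == year)
        & (df["quantity_kind"] == quantity_kind)
        & (df["month"].isin(list(months)))
    )
    sub = df.loc[sel]
    if species is None:
        species = sorted(sub["species"].unique())
    species = list(species)
    months = list(months)

    pivot = sub.drop_duplicates(
        subset=["species", "month"]).pivot(
        index="species", columns="month", values="value")
    gaps: list[tuple[str, int]] = []
    x = np.empty((len(species), len(months)))
    for i, sp in enumerate(species):
        for j, m in enumerate(months):
            try:
                v = pivot.at[sp, m]
            except KeyError:
                v = np.nan
            if pd.isna(v):
                gaps.append((sp, m))
            else:
                x[i, j] = v
    if gaps:
        raise IncompletePanelError(
            f"incomplete panel for {region} {year} {quantity_kind}: "
            f"missing {gaps[:10]}" + (" ..." if len(gaps) > 10 else ""),
            gaps=gaps,
        )
    return MonthlyPanel(region, year, quantity_kind, tuple(species),
                        tuple(months), x)


# ---------------------------------------------------------------------------
# Closure calendars
# ---------------------------------------------------------------------------

@dataclass
class ClosureCalendar:
    """Month-resolved fishery closures plus the survey-month grid.

    ``closed`` maps (region, species) to the set of closed months.  A
    month counts as closed when at least 15 of its days fall inside a
    closure date range, so short partial-month closures (e.g., a
    January 1-15 closure) do not mask a whole month.
    """

    closed: dict[tuple[str, str], frozenset[int]] = field(default_factory=dict)
    survey_months: tuple[int, ...] = DEFAULT_SURVEY_MONTHS

    def __post_init__(self):
        if not self.survey_months:
            raise ValidationError("survey_months must be non-empty")
        for months in self.closed.values():
            if not set(months) <= set(range(1, 13)):
                raise ValidationError("closed months must lie in 1..12")

    def closed_months(self, region: str, species: str) -> frozenset[int]:
        return self.closed.get((region, species), frozenset())

    @classmethod
    def from_ranges(
        cls,
        ranges: Mapping[tuple[str, str], Iterable[tuple[tuple[int, int], tuple[int, int]]]],
        survey_months: Sequence[int] = DEFAULT_SURVEY_MONTHS,
        min_days: int = 15,
    ) -> "ClosureCalendar":
        """Build a calendar from (start, end) (month, day) date ranges.

        Ranges may wrap the year boundary (e.g., December 8 - April 15).
        Day counts use a non-leap year.
        """
        closed: dict[tuple[str, str], frozenset[int]] = {}
        for key, rr in ranges.items():
            days_closed = np.zeros(13, dtype=int)
            for (m0, d0), (m1, d1) in rr:
                start = _dt.date(2001, m0, d0)
                end = _dt.date(2001, m1, d1)
                if end >= start:
                    spans = [(start, end)]
                else:  # wraps the new year
                    spans = [(start, _dt.date(2001, 12, 31)),
                             (_dt.date(2001, 1, 1), end)]
                for s, e in spans:
                    d = s
                    while d <= e:
                        days_closed[d.month] += 1
                        d += _dt.timedelta(days=1)
            months = frozenset(
                m for m in range(1, 13) if days_closed[m] >= min(
                    min_days, calendar.monthrange(2001, m)[1])
            )
            closed[key] = months
        return cls(closed=closed, survey_months=tuple(survey_months))


# ---------------------------------------------------------------------------
# CPI deflation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeflatorSeries:
    """Monthly price index (e.g., CPI-U) used to express values in real terms."""

    index: Mapping[tuple[int, int], float]
    base: tuple[int, int]

    def __post_init__(self):
        if any(v <= 0 for v in self.index.values()):
            raise ValidationError("price-index values must be positive")
        if self.base not in self.index:
            raise ValidationError(f"base period {self.base} not in deflator")

    def factor(self, year: int, month: int) -> float:
        try:
            return self.index[self.base] / self.index[(year, month)]
        except KeyError:
            raise ValidationError(
                f"deflator has no entry for period ({year}, {month})"
            ) from None


def deflate(records: pd.DataFrame, deflator: DeflatorSeries) -> pd.DataFrame:
    """Convert ``value_usd`` records to real terms in the deflator's base period.

    Deflation is monthly: each record is scaled by
    ``index(base) / index(year, month)``.  Non-value records pass through
    unchanged.
    """
    df = validate_long(records).copy()
    is_val = df["quantity_kind"] == "value_usd"
    if is_val.any():
        factors = np.array([
            deflator.factor(int(y), int(m))
            for y, m in zip(df.loc[is_val, "year"], df.loc[is_val, "month"])
        ])
        df.loc[is_val, "value"] = df.loc[is_val, "value"].to_numpy() * factors
    return df
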