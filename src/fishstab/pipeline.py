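"""End-to-end orchestration: simulate/ingest -> indices -> partition ->
indicators -> SEM -> trends -> report.

The pipeline consumes long records (synthetic or file-based; the two
are interchangeable) and produces per-region-year decomposition tables,
annual indicator tables, piecewise SEM fits and interannual trends.
Species and harvest layers are always partitioned on the same
survey-month grid so that their asynchrony components are comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import dataio, indices, partition, synthetic, trends as trends_mod
from .errors import DegenerateSeriesError, FishstabError, IncompletePanelError
from .sem import PathModelSpec, SemFit, fit_sem

logger = logging.getLogger("fishstab")

PARTITION_COLUMNS = ("layer", "region", "year", "s_agg", "s_bar", "phi",
                     "sae", "cpe", "n", "T", "degenerate_flag")

#: Default path models, mirroring a two-SEM-per-region layout: SEM 1
#: links community and portfolio asynchrony components (plus the
#: closure-diversification index in MD and the effort pathway in VA);
#: SEM 2 links portfolio stability and economic variables.
DEFAULT_SEMS: dict[str, list[dict]] = {
    "MD": [
        {
            "name": "sem1_asynchrony",
            "variables": ["shr", "sae_species", "cpe_species",
                          "sae_harvest", "cpe_harvest"],
            "edges": ["shr -> cpe_harvest", "shr -> sae_harvest",
                      "cpe_species -> cpe_harvest",
                      "sae_species -> sae_harvest"],
        },
        {
            "name": "sem2_economics",
            "variables": ["s_portfolio_s", "s_portfolio_l",
                          "value_stability", "portfolio_yield",
                          "portfolio_value"],
            "edges": ["s_portfolio_s -> s_portfolio_l",
                      "s_portfolio_l -> value_stability",
                      "value_stability -> portfolio_value",
                      "portfolio_yield -> portfolio_value"],
        },
    ],
    "VA": [
        {
            "name": "sem1_asynchrony",
            "variables": ["sae_species", "cpe_species", "effort_index",
                          "sae_harvest", "cpe_harvest", "s_bar_harvest"],
            "edges": ["sae_species -> cpe_species",
                      "sae_species -> cpe_harvest",
                      "cpe_species -> cpe_harvest",
                      "sae_species -> effort_index",
                      "effort_index -> s_bar_harvest",
                      "sae_species -> sae_harvest"],
        },
        {
            "name": "sem2_economics",
            "variables": ["s_portfolio_s", "s_portfolio_l",
                          "value_stability", "portfolio_yield",
                          "portfolio_value"],
            "edges": ["s_portfolio_s -> s_portfolio_l",
                      "s_portfolio_l -> value_stability",
                      "s_portfolio_l -> portfolio_yield",
                      "value_stability -> portfolio_value",
                      "portfolio_yield -> portfolio_value"],
        },
    ],
}


def decompose_records(
    records: pd.DataFrame,
    quantity_kind: str,
    layer: str,
    survey_months: Sequence[int] = dataio.DEFAULT_SURVEY_MONTHS,
    species: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Partition every region-year panel of one quantity kind.

    Degenerate panels produce a flagged row with empty metric cells
    rather than aborting the batch.
    """
    rows = []
    sub = records[records["quantity_kind"] == quantity_kind]
    for (region, year), _ in sub.groupby(["region", "year"], sort=True):
        try:
            panel = dataio.to_panel(records, region, int(year), quantity_kind,
                                    survey_months, species)
            d = partition.decompose(panel, layer=layer)
            rows.append((layer, region, int(year), d.s_agg, d.s_bar, d.phi,
                         d.sae, d.cpe, d.stats.n, d.stats.T, ""))
        except DegenerateSeriesError as err:
            rows.append((layer, region, int(year), np.nan, np.nan, np.nan,
                         np.nan, np.nan, np.nan, np.nan, err.code))
    return pd.DataFrame(rows, columns=list(PARTITION_COLUMNS))


def annual_table(
    records: pd.DataFrame,
    region: str,
    closures: Mapping[str, frozenset[int]] | None = None,
    survey_months: Sequence[int] = dataio.DEFAULT_SURVEY_MONTHS,
    species: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One row per year: partition components of both layers + indicators.

    ``species`` restricts the portfolio; by default the cumulative-yield
    90% rule selects it from the harvest records.  The closure window
    for the seasonal harvest ratio is the union of closed months across
    species (empty -> SHR missing).
    """
    closures = closures or {}
    sub = records[records["region"] == region]
    if species is None:
        totals = (sub[sub["quantity_kind"] == "harvest_kg"]
                  .groupby("species")["value"].sum().to_dict())
        species = indices.select_top_species(totals)
    species = list(species)
    closure_months = sorted(set().union(*closures.values())) if closures else []

    parts = pd.concat([
        decompose_records(sub, "biomass_kg", "species", survey_months, species),
        decompose_records(sub, "harvest_kg", "harvest", survey_months, species),
    ], ignore_index=True)
    wide = parts.pivot(index="year", columns="layer")
    out = pd.DataFrame(index=wide.index)
    for layer in ("species", "harvest"):
        if ("s_agg", layer) not in wide.columns:
            continue
        for metric in ("s_agg", "s_bar", "phi", "sae", "cpe"):
            out[f"{metric}_{layer}"] = wide[(metric, layer)]

    years = sorted(sub.loc[sub["quantity_kind"] == "harvest_kg", "year"].unique())
    ind_rows = []
    for year in years:
        h12 = dataio.to_panel(sub, region, int(year), "harvest_kg",
                              range(1, 13), species)
        v12 = dataio.to_panel(sub, region, int(year), "value_usd",
                              range(1, 13), species)
        tr = sub[(sub["year"] == year) & (sub["quantity_kind"] == "trips")
                 & (sub["species"].isin(species))]
        trips = {
            sp: dict(zip(grp["month"].astype(int), grp["value"]))
            for sp, grp in tr.groupby("species")
        } or None
        ind_rows.append(indices.annual_indicators(
            region, int(year), h12, v12, trips, closure_months, survey_months))
    ind = indices.indicators_table(ind_rows).set_index("year").drop(
        columns=["region"])
    return out.join(ind, how="outer")


@dataclass
class RunConfig:
    """Single-run configuration (usually loaded from YAML)."""

    scenario: str = "md_closure"
    seed: int = 0
    years: int = 17
    survey_months: tuple[int, ...] = dataio.DEFAULT_SURVEY_MONTHS
    sems: list[dict] = field(default_factory=list)   # empty -> region default
    trend_series: list[str] = field(
        default_factory=lambda: ["sae_species", "cpe_species", "sae_harvest",
                                 "cpe_harvest", "s_portfolio_l"])
    trend_form: str = "linear"
    trend_ar_order: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise FishstabError(f"unknown config keys: {sorted(unknown)}")
        if "survey_months" in d:
            d["survey_months"] = tuple(d["survey_months"])
        return cls(**d)

    def digest(self) -> str:
        blob = yaml.safe_dump(
            {k: list(v) if isinstance(v, tuple) else v
             for k, v in self.__dict__.items()}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline for one scenario and write the run directory.

    Stage failures abort with the stage name and offending region-year.
    Returns a dict with the in-memory products and the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario = synthetic.preset(config.scenario, seed=config.seed)
    if config.years != scenario.years:
        from dataclasses import replace
        scenario = replace(scenario, years=config.years)

    logger.info("stage 1: simulate (%s, seed=%d)", config.scenario, config.seed)
    sim = synthetic.simulate(scenario, config.seed)
    records = sim.records
    dataio.write_long(records, outdir / "records.csv")
    sim.hauls.to_csv(outdir / "hauls.csv", index=False)

    logger.info("stage 2-3: biomass indices and partitioning")
    try:
        annual = annual_table(records, scenario.region,
                              closures=scenario.closures,
                              survey_months=config.survey_months)
    except IncompletePanelError as err:
        raise FishstabError(f"stage partition failed: {err}") from err
    annual.to_csv(outdir / "annual_table.csv")

    parts = pd.concat([
        decompose_records(records, "biomass_kg", "species",
                          config.survey_months),
        decompose_records(records, "harvest_kg", "harvest",
                          config.survey_months),
    ], ignore_index=True)
    parts.to_csv(outdir / "partition.csv", index=False)

    logger.info("stage 5: piecewise SEMs")
    sem_specs = config.sems or DEFAULT_SEMS.get(scenario.region, [])
    sem_fits: dict[str, SemFit] = {}
    path_rows = []
    for spec_d in sem_specs:
        name = spec_d.get("name", "sem")
        spec = PathModelSpec.from_dict(spec_d)
        fit = fit_sem(spec, annual)
        sem_fits[name] = fit
        with open(outdir / f"sem_{name}.json", "w") as fh:
            json.dump(fit.to_dict(), fh, indent=2)
        t = fit.estimates_table()
        t.insert(0, "sem", name)
        path_rows.append(t)
    if path_rows:
        pd.concat(path_rows, ignore_index=True).to_csv(
            outdir / "sem_paths.csv", index=False)

    logger.info("stage 6: interannual trends")
    tfits = {}
    for series in config.trend_series:
        if series not in annual.columns:
            continue
        vals = annual[series]
        try:
            tfits[series] = trends_mod.fit_trend(
                annual.index.to_numpy(), vals.to_numpy(),
                form=config.trend_form, ar_order=config.trend_ar_order)
        except FishstabError as err:
            logger.warning("trend fit skipped for %s: %s", series, err)
    ttable = trends_mod.trend_table(tfits)
    ttable.to_csv(outdir / "trends.csv", index=False)

    manifest = {
        "scenario": config.scenario,
        "seed": config.seed,
        "config_hash": config.digest(),
        "region": scenario.region,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()
                          and p.name != "manifest.json"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {"records": records, "annual": annual, "partition": parts,
            "sems": sem_fits, "trends": tfits, "manifest": manifest}
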