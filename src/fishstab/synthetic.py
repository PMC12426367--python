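"""Synthetic Chesapeake-style data: community biomass, trawl surveys,
harvests, values and trips.

The generator emulates a two-region estuarine demersal-finfish system:
3-5 species per region with sinusoidal within-year (migration-driven)
biomass cycles, multiplicative interannual trends concentrated in a
dominant species, a stratified random trawl survey observed with
compound Poisson-gamma (Tweedie) noise over five survey months per
year, and a monthly fishery in which effort is reallocated across open
species (gravity/ideal-free switching) under seasonal closures.

Every generator is a pure function of (config, seed): rerunning with
the same arguments is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.optimize as opt

from .dataio import DEFAULT_SURVEY_MONTHS, LONG_COLUMNS
from .errors import ValidationError

#: Stream ids keeping the community, survey and fishery RNGs independent.
_STREAM_COMMUNITY, _STREAM_SURVEY, _STREAM_HARVEST = 11, 23, 37


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesParams:
    """Biology and fishery parameters for one species.

    baseline
        Mean monthly biomass (kg) in year 1.
    amplitude
        Fractional within-year sinusoidal variation, in [0, 1).
    phase
        Seasonal phase in radians; biomass peaks where
        sin(2*pi*month/12 - phase) = 1.
    trend
        Multiplicative per-year biomass factor (> 0).
    catchability
        Harvest rate per unit effort share.
    price
        Ex-vessel price, USD/kg.
    """

    baseline: float
    amplitude: float = 0.3
    phase: float = 0.0
    trend: float = 1.0
    catchability: float = 0.02
    price: float = 1.0

    def __post_init__(self):
        if not (0 <= self.amplitude < 1):
            raise ValidationError("amplitude must lie in [0, 1)")
        if self.trend <= 0:
            raise ValidationError("trend factor must be positive")
        if self.price < 0:
            raise ValidationError("price must be non-negative")


@dataclass(frozen=True)
class SurveyDesign:
    """Stratified random survey layout (three depth strata)."""

    stratum_areas: Mapping[int, float] = field(
        default_factory=lambda: {1: 400.0, 2: 300.0, 3: 300.0})
    hauls_per_stratum: int = 5
    swept_km2: float = 0.05


@dataclass(frozen=True)
class EffortModel:
    """Monthly effort allocation across open species.

    Effort shares are proportional to
    (catchability * biomass * price) ** elasticity, renormalized among
    open species; elasticity 0 gives fixed equal shares and high values
    give strong switching.  In months where a closure is in force, total
    effort is scaled by a per-year participation factor drawn uniformly
    from ``closure_participation`` (fishers differ from year to year in
    how much they redirect effort to the open stocks).
    """

    total_effort: float = 1.0
    elasticity: float = 1.0
    closure_participation: tuple[float, float] = (1.0, 1.0)
    trips_scale: float = 200.0
    harvest_noise_cv: float = 0.15
    trip_noise_cv: float = 0.10


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete specification of one synthetic region scenario."""

    name: str
    region: str
    species: Mapping[str, SpeciesParams]
    closures: Mapping[str, frozenset[int]] = field(default_factory=dict)
    years: int = 17
    start_year: int = 2002
    survey_months: tuple[int, ...] = DEFAULT_SURVEY_MONTHS
    tweedie_power: float = 1.5
    tweedie_phi: float = 2.0
    effort: EffortModel = field(default_factory=EffortModel)
    design: SurveyDesign = field(default_factory=SurveyDesign)
    #: Per-year uniform range scaling species' phase offsets from their
    #: common mean phase (1 keeps the configured phases; values toward 0
    #: synchronize the community).  Drives year-to-year variation in
    #: seasonal compensation.
    phase_dispersion: tuple[float, float] = (1.0, 1.0)
    #: Deterministic (start, end) multiplier on the phase-dispersion
    #: factor, interpolated linearly across years: an end value below
    #: the start synchronizes seasonal dynamics over the study period
    #: (timing shifts accompanying community decline).
    phase_dispersion_trend: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if not (1 < self.tweedie_power < 2):
            raise ValidationError("Tweedie power must lie in (1, 2)")
        if self.tweedie_phi <= 0:
            raise ValidationError("Tweedie dispersion must be positive")


# ---------------------------------------------------------------------------
# Community biomass
# ---------------------------------------------------------------------------

def _phase_factors(config: ScenarioConfig, seed: int) -> np.ndarray:
    rng = np.random.default_rng([seed, _STREAM_COMMUNITY])
    lo, hi = config.phase_dispersion
    t0, t1 = config.phase_dispersion_trend
    trend = np.linspace(t0, t1, config.years)
    return trend * rng.uniform(lo, hi, size=config.years)


def gen_community(config: ScenarioConfig, seed: int | None = None) -> pd.DataFrame:
    """True monthly biomass for all species, years and 12 months.

    biomass(s, y, m) = baseline * trend**(y-1)
                       * (1 + amplitude * sin(2*pi*m/12 - phase_eff)),
    truncated at zero, where phase_eff contracts each species' phase
    toward the community mean phase by the year's phase-dispersion
    factor.  Deterministic given (config, seed).
    """
    seed = config.seed if seed is None else seed
    u = _phase_factors(config, seed)
    phases = np.array([sp.phase for sp in config.species.values()])
    phase0 = float(phases.mean())
    months = np.arange(1, 13)
    rows = []
    for y in range(config.years):
        for name, sp in config.species.items():
            phase_eff = phase0 + (sp.phase - phase0) * u[y]
            level = sp.baseline * sp.trend ** y
            b = level * (1 + sp.amplitude * np.sin(2 * np.pi * months / 12
                                                   - phase_eff))
            b = np.clip(b, 0.0, None)
            for m, v in zip(months, b):
                rows.append((config.region, config.start_year + y, int(m),
                             name, "biomass_kg", float(v)))
    return pd.DataFrame(rows, columns=list(LONG_COLUMNS))


# ---------------------------------------------------------------------------
# Tweedie sampling and the trawl survey
# ---------------------------------------------------------------------------

def rtweedie(rng: np.random.Generator, mu, p: float, phi: float) -> np.ndarray:
    """Compound Poisson-gamma (Tweedie) draws with mean mu, Var = phi * mu**p.

    Exact simulation: N ~ Poisson(lambda) with
    lambda = mu**(2-p) / (phi*(2-p)); the draw is a Gamma with shape
    N*alpha and scale theta, where alpha = (2-p)/(p-1) and
    theta = phi*(p-1)*mu**(p-1).  N = 0 gives an exact zero.
    """
    mu = np.asarray(mu, dtype=float)
    if not (1 < p < 2):
        raise ValidationError("Tweedie power must lie in (1, 2)")
    out = np.zeros_like(mu)
    pos = mu > 0
    lam = mu[pos] ** (2 - p) / (phi * (2 - p))
    alpha = (2 - p) / (p - 1)
    theta = phi * (p - 1) * mu[pos] ** (p - 1)
    n = rng.poisson(lam)
    draw = np.zeros_like(lam)
    nz = n > 0
    draw[nz] = rng.gamma(shape=n[nz] * alpha, scale=theta[nz])
    out[pos] = draw
    return out


def gen_trawl_survey(config: ScenarioConfig,
                     biomass: pd.DataFrame | None = None,
                     seed: int | None = None) -> pd.DataFrame:
    """Simulate stratified random hauls for every survey month.

    Density is uniform within the region (biomass / total area); each
    haul's catch is Tweedie-distributed around density * swept area.
    """
    seed = config.seed if seed is None else seed
    if biomass is None:
        biomass = gen_community(config, seed)
    rng = np.random.default_rng([seed, _STREAM_SURVEY])
    areas = dict(sorted(config.design.stratum_areas.items()))
    total_area = sum(areas.values())
    nh = config.design.hauls_per_stratum
    b = (biomass[biomass["month"].isin(config.survey_months)]
         .sort_values(["year", "month", "species"], kind="stable"))

    strata = np.repeat(list(areas), nh)                  # one survey-month block
    side = np.repeat([np.sqrt(a) for a in areas.values()], nh)
    k = len(strata)                                      # hauls per block
    nblk = len(b)
    dens = np.repeat(b["value"].to_numpy(dtype=float) / total_area, k)
    mu = dens * config.design.swept_km2
    catch = rtweedie(rng, mu, config.tweedie_power, config.tweedie_phi)
    xy = rng.uniform(0, 1, size=(nblk * k, 2)) * np.tile(side, nblk)[:, None]
    return pd.DataFrame({
        "station": np.arange(1, nblk * k + 1),
        "x": xy[:, 0], "y": xy[:, 1],
        "stratum": np.tile(strata, nblk),
        "year": np.repeat(b["year"].to_numpy(), k),
        "month": np.repeat(b["month"].to_numpy(), k),
        "species": np.repeat(b["species"].to_numpy(), k),
        "catch_kg": catch,
        "swept_km2": config.design.swept_km2,
    })


def survey_biomass_indices(config: ScenarioConfig,
                           hauls: pd.DataFrame) -> pd.DataFrame:
    """Design-based biomass index for every species-year-month in the hauls.

    Vectorized equivalent of applying
    :func:`fishstab.survey.stratified_index` per species-month.
    """
    df = hauls.copy()
    df["dens"] = df["catch_kg"] / df["swept_km2"]
    df["area"] = df["stratum"].map(dict(config.design.stratum_areas))
    per_stratum = (df.groupby(["year", "month", "species", "stratum"])
                   .agg(mean_dens=("dens", "mean"), area=("area", "first"))
                   .reset_index())
    per_stratum["contrib"] = per_stratum["area"] * per_stratum["mean_dens"]
    idx = (per_stratum.groupby(["year", "month", "species"])["contrib"]
           .sum().reset_index())
    out = pd.DataFrame({
        "region": config.region,
        "year": idx["year"].astype(int),
        "month": idx["month"].astype(int),
        "species": idx["species"],
        "quantity_kind": "biomass_kg",
        "value": idx["contrib"].astype(float),
        "se": np.nan,
    })
    return out


# ---------------------------------------------------------------------------
# Harvest, value and trips
# ---------------------------------------------------------------------------

def gen_harvest(config: ScenarioConfig,
                biomass: pd.DataFrame | None = None,
                seed: int | None = None) -> pd.DataFrame:
    """Monthly harvest (kg), value (USD) and trips for every species.

    Effort is allocated among open species by the gravity rule of the
    effort model; closed species-months receive exactly zero harvest and
    zero targeted trips.  Harvest noise is multiplicative lognormal.
    Returns one long frame holding the three quantity kinds.
    """
    seed = config.seed if seed is None else seed
    if biomass is None:
        biomass = gen_community(config, seed)
    rng = np.random.default_rng([seed, _STREAM_HARVEST])
    em = config.effort
    species = list(config.species)
    q = np.array([config.species[s].catchability for s in species])
    price = np.array([config.species[s].price for s in species])

    lo, hi = em.closure_participation
    participation = rng.uniform(lo, hi, size=config.years)
    any_closure_month = set().union(*config.closures.values()) \
        if config.closures else set()

    bwide = biomass.pivot_table(index=["year", "month"], columns="species",
                                values="value", aggfunc="first")
    rows = []
    for y in range(config.years):
        year = config.start_year + y
        for m in range(1, 13):
            b = bwide.loc[(year, m), species].to_numpy(dtype=float)
            open_mask = np.array(
                [m not in config.closures.get(s, frozenset()) for s in species])
            effort = em.total_effort
            if m in any_closure_month:
                effort *= participation[y]
            weights = np.zeros(len(species))
            if open_mask.any():
                grav = np.where(open_mask, (q * b * price) ** em.elasticity, 0.0)
                if grav.sum() > 0:
                    weights = grav / grav.sum()
                else:
                    weights = open_mask / open_mask.sum()
            h_noise = rng.lognormal(-0.5 * np.log(1 + em.harvest_noise_cv ** 2),
                                    np.sqrt(np.log(1 + em.harvest_noise_cv ** 2)),
                                    size=len(species))
            t_noise = rng.lognormal(-0.5 * np.log(1 + em.trip_noise_cv ** 2),
                                    np.sqrt(np.log(1 + em.trip_noise_cv ** 2)),
                                    size=len(species))
            harvest = q * b * weights * effort * h_noise
            trips = np.round(em.trips_scale * effort * weights * t_noise)
            for i, s in enumerate(species):
                rows.append((config.region, year, m, s, "harvest_kg",
                             float(harvest[i])))
                rows.append((config.region, year, m, s, "value_usd",
                             float(harvest[i] * price[i])))
                rows.append((config.region, year, m, s, "trips",
                             float(trips[i])))
    return pd.DataFrame(rows, columns=list(LONG_COLUMNS))


@dataclass
class SimulatedData:
    """Bundle of the generated tables for one scenario run."""

    config: ScenarioConfig
    seed: int
    biomass_true: pd.DataFrame
    hauls: pd.DataFrame
    biomass_index: pd.DataFrame   # long records, quantity_kind = biomass_kg
    fishery: pd.DataFrame         # long records: harvest_kg / value_usd / trips

    @property
    def records(self) -> pd.DataFrame:
        """All long records (biomass indices + fishery) in one frame."""
        idx = self.biomass_index.loc[:, list(LONG_COLUMNS)]
        return pd.concat([idx, self.fishery], ignore_index=True)


def simulate(config: ScenarioConfig, seed: int | None = None) -> SimulatedData:
    """Run the full generator chain for one scenario."""
    seed = config.seed if seed is None else seed
    biomass = gen_community(config, seed)
    hauls = gen_trawl_survey(config, biomass, seed)
    index = survey_biomass_indices(config, hauls)
    fishery = gen_harvest(config, biomass, seed)
    return SimulatedData(config=config, seed=seed, biomass_true=biomass,
                         hauls=hauls, biomass_index=index, fishery=fishery)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def decade_decline_factor(target_decline: float, years: int = 17,
                          split: int = 9) -> float:
    """Per-year multiplicative factor realizing a decade-on-decade decline.

    Solves for g such that the mean of g**(y-1) over years split+1..years
    is (1 - target_decline) times its mean over years 1..split.
    """
    if not (0 < target_decline < 1):
        raise ValidationError("target decline must lie in (0, 1)")

    def ratio(g):
        t = g ** np.arange(years)
        return t[split:].mean() / t[:split].mean() - (1 - target_decline)

    return float(opt.brentq(ratio, 1e-6, 1.0 - 1e-12))


_MONTH = 2 * np.pi / 12   # radians per month


def _balanced_catchabilities(species: Mapping[str, SpeciesParams],
                             scale: float) -> dict[str, SpeciesParams]:
    """Set catchabilities q_s = scale / sqrt(baseline_s * price_s).

    Under the gravity effort rule with unit elasticity this makes
    realized harvest shares proportional to biomass shares (the
    documented regional composition), instead of letting effort
    concentrate entirely on the most valuable stock.
    """
    return {
        s: replace(p, catchability=scale / np.sqrt(p.baseline * p.price))
        for s, p in species.items()
    }


def preset(name: str, seed: int = 0) -> ScenarioConfig:
    """Named scenario configurations.

    - ``synchronous_null``: species share one seasonal phase; species
      and harvest dynamics are synchronous (phi ~ 1).
    - ``va_compensation``: dispersed migration phases with year-varying
      dispersion, so seasonal compensation among species drives harvest
      compensation.
    - ``md_closure``: a March-May closure of the dominant (striped-bass-
      like) stock; year-varying closure-season participation drives the
      seasonal harvest ratio and harvest compensation.
    - ``va_decline``: dispersed phases plus decade-scale declines
      (92%/77%/51%) concentrated in the dominant species, raising the
      evenness of species variances while lowering portfolio stability.
    """
    md_species_raw = {
        "striped bass": SpeciesParams(baseline=554_372, amplitude=0.35,
                                      phase=7 * _MONTH, price=5.47),
        "white perch": SpeciesParams(baseline=162_971, amplitude=0.30,
                                     phase=5 * _MONTH, price=1.64),
        "Atlantic croaker": SpeciesParams(baseline=77_677, amplitude=0.40,
                                          phase=6 * _MONTH, price=1.37),
        "channel catfish": SpeciesParams(baseline=87_480, amplitude=0.25,
                                         phase=6 * _MONTH, price=1.22),
        "gizzard shad": SpeciesParams(baseline=54_250, amplitude=0.30,
                                      phase=4 * _MONTH, price=0.32),
    }
    va_species_raw = {
        "Atlantic croaker": SpeciesParams(baseline=1_489_750, amplitude=0.50,
                                          phase=6 * _MONTH, price=1.49),
        "spot": SpeciesParams(baseline=554_203, amplitude=0.50,
                              phase=9 * _MONTH, price=2.22),
        "striped bass": SpeciesParams(baseline=304_782, amplitude=0.70,
                                      phase=3 * _MONTH, price=5.12),
    }
    md_species = _balanced_catchabilities(md_species_raw, scale=250.0)
    va_species = _balanced_catchabilities(va_species_raw, scale=300.0)

    if name == "synchronous_null":
        sync = {s: replace(p, phase=6 * _MONTH, amplitude=0.4)
                for s, p in va_species.items()}
        return ScenarioConfig(name=name, region="VA", species=sync, seed=seed)

    if name == "va_compensation":
        return ScenarioConfig(
            name=name, region="VA", species=va_species,
            phase_dispersion=(0.25, 1.0), seed=seed)

    if name == "md_closure":
        return ScenarioConfig(
            name=name, region="MD", species=md_species,
            closures={"striped bass": frozenset({3, 4, 5})},
            effort=EffortModel(closure_participation=(0.2, 1.0)),
            seed=seed)

    if name == "va_decline":
        declines = {"Atlantic croaker": 0.92, "spot": 0.77,
                    "striped bass": 0.51}
        amplitudes = {"Atlantic croaker": 0.60, "spot": 0.45,
                      "striped bass": 0.45}
        sp = {s: replace(p, trend=decade_decline_factor(declines[s]),
                         amplitude=amplitudes[s])
              for s, p in va_species.items()}
        return ScenarioConfig(
            name=name, region="VA", species=sp,
            phase_dispersion_trend=(1.0, 0.1), seed=seed)

    raise ValidationError(f"unknown preset {name!r}")
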