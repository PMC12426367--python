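# fishstab

Stability–asynchrony partitioning for multi-species fishery harvest
portfolios and the fish communities that support them.

`fishstab` is aimed at quantitative fisheries ecologists who want to ask:
how much of the within-year stability of a region's total harvest (or a
community's total biomass) comes from the *statistical averaging* of
independently fluctuating stocks, and how much from *compensation* —
different stocks peaking at different times? It implements the full
chain from monthly landings/survey records to partitioned stability
components, annual portfolio indicators, piecewise structural equation
models over those indicators, and autocorrelation-robust interannual
trends, together with a synthetic estuarine-fishery generator
(Chesapeake-Bay-style: 3–5 demersal species, five survey months per
year, 17 years, seasonal closures) so the entire analysis runs without
any external data.

## The partitioning

For one region-year, let `x_i(t)` be the monthly harvest (or biomass) of
species `i = 1..n` over months `t = 1..T`, with per-species temporal
mean `μ_i` and sample SD `σ_i`, and let `μ_R`, `σ_R` be the mean and SD
of the monthly totals. Then

- **Aggregate (portfolio) stability** `S = μ_R / σ_R` — the inverse CV
  of total monthly harvest;
- **Species-level stability** `S̄ = (Σ_i CV_i · μ_i/μ_R)⁻¹ = μ_R / Σ_i σ_i`
  — the inverse of the share-weighted average species CV;
- **Asynchrony** `ϕ = Σ_i σ_i / σ_R ≥ 1`, with `ϕ = 1` iff all species
  fluctuate in perfect synchrony;
- **Statistical averaging effect** `SAE = Σ_i σ_i / √(Σ_i σ_i²) ∈ [1, √n]`,
  growing with richness and variance evenness;
- **Compensation effect** `CPE = √(Σ_i σ_i²) / σ_R`, the inverse
  square-rooted variance ratio; `CPE > 1` means negative covariances
  stabilize the total beyond independence.

These satisfy the exact multiplicative identities `S = ϕ·S̄` and
`ϕ = SAE·CPE`, which the implementation asserts on every decomposition.
Around the partitioning sit the portfolio indicators — the seasonal
harvest ratio (closure-window mean harvest over open-window mean),
harvest-weighted mean month of harvest, a cross-species trips index,
annual yield/value totals, and inverse-CV stabilities of harvest and
value at survey-month and 12-month resolutions — plus piecewise SEMs
(linear sub-models with iid or AR(1)-ML errors, d-separation basis sets,
Fisher's `C = −2Σln pᵢ` against χ² with 2k df) and GLS trend models.

## Worked example

Partition one Maryland-style harvest year over the five survey months
(March–November, odd months). Striped bass is closed March–May; white
perch compensates:

```python
import numpy as np
import fishstab as fs

panel = fs.MonthlyPanel(
    "MD", 2012, "harvest_kg", ("striped bass", "white perch"),
    (3, 5, 7, 9, 11),
    np.array([[0.0, 0.0, 52.1, 61.8, 47.9],
              [21.4, 25.0, 9.6, 8.2, 10.3]]) * 1e3)

d = fs.decompose(panel, layer="harvest")
totals = dict(zip(panel.months, panel.totals()))
shr = fs.seasonal_harvest_ratio(totals, closure_months={3, 4, 5})
```

This prints:

```
S_agg = 2.109
S_bar = 1.254
phi   = 1.681
SAE   = 1.218
CPE   = 1.381
SHR   = 0.367
```

Read: total harvest is 2.1× more stable (inverse CV) than the average
stock (`S_agg = ϕ·S̄ = 1.681 × 1.254`), and most of that asynchrony gain
comes from compensation (`CPE = 1.381 > 1`: perch harvests rise exactly
when bass harvests are forced to zero) rather than statistical averaging
(`SAE = 1.218` of a possible `√2 ≈ 1.414`). The seasonal harvest ratio
0.367 says closure-season harvests run at ~37% of the open-season mean.

The same analysis runs end-to-end on synthetic scenarios from the shell:

```sh
fishstab run --seed 1 --out runs/md_closure
fishstab simulate --scenario va_decline --seed 1 --out records.csv
```

`run` writes the simulated records, design-based biomass indices,
per-year decomposition table, annual indicators, SEM fits (JSON + path
table), trend table and a manifest (config hash + seed) for exact
reruns. Presets `synchronous_null`, `va_compensation`, `md_closure` and
`va_decline` generate communities with, respectively, synchronous
dynamics, migration-driven compensation, a March–May closure of the
dominant stock, and decade-scale declines concentrated in the dominant
species.

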