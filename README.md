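# ballastrisk

Ballast-water discharge hindcasting and invasion-risk ranking for shipping
networks.

Commercial vessels carry ballast water for trim and stability and discharge
it — along with any entrained coastal organisms — when they load cargo.
Discharged ballast is a primary pathway for marine bioinvasions, and
biosecurity agencies need to know **which shipping routes and marine
ecoregions carry the most propagule pressure**. Direct ballast measurements
are typically available only for a short census window, while voyage records
span decades; this package reconstructs (hindcasts) discharge over the full
shipping history from vessel geometry alone and converts it into relative
invasion risk.

It is written for quantitative ecologists and biosecurity analysts. Because
real voyage/ballast datasets are usually confidential, the package ships a
first-class synthetic-data generator with known ground truth, so the entire
analysis chain is testable offline; the same machinery accepts real tables
with the documented CSV schemas.

## The models

**Vessel geometry.** Deadweight tonnage is reconstructed from vessel length
via the naval-architecture "cube root format",

    DWT = L³ · ρ · C_B · C_D / ((L/B)² · (B/H)),

with defaults C_D = 0.8, C_B = 0.75, L/B = 6.5, B/H = 2.2, ρ = 1.025.
Ballast capacity is 30% of DWT. Records with length ∉ (0, 345] m or
discharge > 120% of DWT are curated out.

**Discharge models.** For tankers, container ships and "other" vessels,
per-voyage discharge is multiple linear regression on calculated ballast
capacity and destination-port purpose, with candidate predictor sets ranked
by BIC. Bulk carriers are multi-modal (minimal / partial / full / heavy
ballast regimes), so their discharge follows a K-component mixture of linear
regressions,

    yᵢ ~ β₁ⱼ + β₂ⱼ xᵢ + N(0, σⱼ²)  with probability pⱼ,

fitted by EM; K ∈ {1..5} is chosen by AIC, AIC3 and MDL and validated by
repeated random-subsampling cross-validation.

**Propagule pressure.** Organism density in a tank decays exponentially,
D(t) = D(0)·e^(−λt) (defaults D(0) = 2113.489 organisms/m³, λ = 0.161/day).
Mid-ocean ballast-water exchange at proportion p of a voyage of duration T,
retaining a fraction r of organisms, gives

    D(T) = D(0) · r · e^(−μ₁pT) · e^(−μ₂(1−p)T) = D(0) · r · e^(−λT),
    λ = μ₁p + μ₂(1−p).

Voyage durations come from geodesic shortest paths **over water** (a
visibility graph on ports and shoreline vertices, Dijkstra, 1 nm = 1
arc-minute, 15 knots). Per-voyage propagules = discharge volume × D(T);
routes and ecoregions are ranked by totals, with a sensitivity analysis over
λ ∈ [0.01, 0.50] (λ = 0 is the volume-only baseline).

## Worked example

```bash
ballastrisk run --seed 1 --out out/
```

runs the whole pipeline on the default synthetic world (8 ecoregions, 24
ports, 400 vessels, voyages 1999–2012) and prints, per stage, what it wrote.
Key numbers from `out/` at seed 1:

* `curation_report.csv` — 740 of 4402 ballast-voyage records rejected
  (16.8%; the generator injects corruption at rate 0.16).
* `hindcast_by_year.csv` — total hindcast discharge grows from 1.59×10⁶ m³
  (1999) to 3.15×10⁶ m³ (2012), a ratio of 1.98: traffic growth of 6%/yr
  roughly doubles annual discharge over 14 years.
* `provenance.csv` — 79.2% of ballast volume has an uptake port consistent
  with the voyage source (the generator's mismatch rate is 0.20), rising to
  81.0% at ecoregion level.
* `bulker_selection.csv` — per-K log-likelihood and AIC/AIC3/BIC/MDL for the
  bulker mixture; `models.json` holds the fitted parameters.
* `top_routes.csv` — the 20 busiest of 117 routes carry 52.4% of voyages,
  52.5% of discharge volume and 51.4% of propagules at λ = 0.161.
* `sensitivity_ranks.csv` — ecoregion rank trajectories across the λ grid;
  nearer sources rise in rank as λ grows.

Each subcommand (`simulate`, `curate`, `fit-linear`, `fit-mixture`,
`select`, `distances`, `hindcast`, `risk`, `sensitivity`, `rank`,
`validate`) also runs standalone on the CSV contracts; see `--help`.

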