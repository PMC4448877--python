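# Methods

This note documents the models implemented in `ballastrisk`, the synthetic
study conditions they are exercised under, the numerical choices, and what
the tests do and do not establish.

## Vessel geometry

Deadweight tonnage (DWT) — carrying capacity, not displacement — is
reconstructed from vessel length by rearranging the ship-design "cube root
format" L = [DWT·(L/B)²·(B/H)/(ρ·C_B·C_D)]^(1/3) into

    DWT(L) = L³ · ρ · C_B · C_D / ((L/B)² · (B/H)).

This grouping is the only rearrangement that makes DWT a linear function of
L³ with realistic magnitudes (a 225 m Panamax gives ≈ 75 kt). Defaults
C_D = 0.8, C_B = 0.75, L/B = 6.5, B/H = 2.2 and ρ = 1.025 are mid-range
values for the bulker/tanker/container fleet; a speed-dependent block
coefficient C_B = 1.23 − 0.395·V/√L is provided but not used by default.
Ballast capacity is 0.30·DWT, reported numerically in m³ without dividing
by ρ (seawater density makes the tonnes/m³ distinction ≤ 2.5%, well inside
model error); an `as_volume` flag applies the division.

Curation removes records with missing fields, length ≤ 0 m, length > 345 m,
or discharge > 1.2·DWT(L), in that order, each record counted once under
the first rule it violates. Length rules are applied before the discharge
rule because the discharge bound is only meaningful for a credible length.
Curation is idempotent, and "missing" is reported separately from
rule-based rejections.

## Discharge models

The modelling unit is the voyage: per-tank census events are summed to
voyage totals before fitting, because discharge behaviour is a per-journey
decision.

**Linear models (tankers, containers, other).** Ordinary least squares of
voyage discharge on calculated ballast capacity plus categorical covariates
(destination-port purpose, ports, ecoregions), solved exactly via the
normal equations (statsmodels OLS). Categorical factors enter as one-hot
offsets with the alphabetically first level as reference. The Gaussian
log-likelihood uses the MLE variance (RSS/n), and BIC = −2ℓ + k·ln n with
k counting coefficients plus one for σ. Candidate predictor sets are ranked
by BIC ascending with ties broken toward fewer parameters; candidates that
fail to fit (rank-deficient designs are refused, naming the collinear term)
are recorded as non-competing.

**Bulker mixture.** Bulkers discharge in regimes (near-zero, partial, full,
heavy ballast), so a single regression is misspecified. The model is a
K-component mixture of linear regressions on capacity with unequal
component variances, fitted by EM:

* E-step responsibilities from Gaussian log-densities via logsumexp;
  M-step per-component weighted least squares in closed form.
* Convergence when the relative log-likelihood gain ≤ 1e−8; max 1000
  iterations. The observed-data log-likelihood is asserted non-decreasing
  on every iteration (any decrease raises, as it indicates a numerical
  fault).
* Initialisation: two deterministic starts (hard assignment by K-quantile
  bins of y/x, which separates slope-differing components, and of pooled
  OLS residuals, which separates intercept shifts) plus random hard
  assignments up to `n_restarts` (default 10); best final log-likelihood
  wins. K = 1 bypasses EM and is exactly OLS.
* Degeneracy guards: component variances floored at 1e−6·sd(y); a restart
  is abandoned when a weight falls below 1/n or a variance sits at the
  floor for 10 consecutive iterations; it is an error if every restart
  degenerates.
* Components are reported sorted by slope, making the labelling
  deterministic and permutation-invariant.

Component count selection over K ∈ {1..5} uses AIC = −2ℓ + 2k,
AIC3 = −2ℓ + 3k, BIC = −2ℓ + k·ln n and MDL = −ℓ + (k/2)·ln n, all with
k = 4K − 1 free parameters (intercept, slope, σ per component, K−1
weights); MDL is taken in its BIC/2 form, the common convention for
mixture order selection. In repeated simulation at the default study
conditions, AIC3 and MDL recover the true K ≥ 98% of the time; AIC
overselects K+1 in roughly 10% of replicates — the textbook inconsistency
of AIC for order selection, worth knowing when interpreting its column in
the selection table. The pipeline's hindcast uses the AIC choice; on
mixture data one component more than the truth is harmless for prediction.

**Prediction.** The predictive mean is Σⱼ pⱼ(β₁ⱼ + β₂ⱼx), truncated below
at 0 and capped at 1.2·DWT when DWT is available (mirroring the curation
feasibility bound); the predictive variance follows the law of total
variance. Sample mode draws a component, then Gaussian noise, with the
same truncation. Unseen categorical levels at prediction time fall back to
the level-marginal (average) offset with a logged warning.

**Cross-validation.** Repeated random subsampling (default 70% train);
per-repeat held-out R² and total-discharge error (predicted − true), with
mixture predictions using the predictive mean. A caution established by
simulation here: for data genuinely generated by a constant-weight mixture,
the mixture's predictive mean is affine in x — the same family OLS fits —
so both predictors are unbiased for held-out totals and the mixture's
total-error advantage over a single-component model is small and
inconsistent (≈ 55–60% win rate, not a reliable ordering). A decisive CV
advantage for the mixture on real data is therefore evidence of genuine
misspecification of the linear model (regime structure, nonlinearity),
not something mixture data automatically produce.

## Hindcast

Fitted models are applied to every voyage in the shipping table: expected
discharge and predictive variance per voyage, after excluding (and
counting) voyages whose vessel fails the length checks. Vessels outside
the covariate range seen in the ballast census are extrapolated linearly —
the shipping fleet is wider than the census fleet, and this is flagged
rather than hidden. Aggregation by year/port/ecoregion/route sums
expectations exactly; variances are summed under voyage independence, the
simplest defensible contract (between-voyage behavioural correlation would
widen, not shift, the intervals). Sums over any complete partition equal
the grand total exactly; this is asserted in tests.

Provenance consistency is the volume-weighted proportion of census events
whose uptake port matches the voyage's source (or discharge matches the
destination), computed at port, ecoregion, or grouped-ecoregion resolution;
coarsening can only merge mismatches into matches, so the proportion is
monotone in resolution. The named real-world super-groups (South China Sea
group; Japan/Korea waters group) ship as a constant for use with real data.

## Over-water routing

Seaborne distance is the shortest path on a visibility graph whose nodes
are ports and shoreline polygon vertices, with edges between nodes whose
connecting segment does not cross land, weighted by spherical great-circle
distance (1 nm = 1 arc-minute; no ellipsoid — the error is far below model
uncertainty). The land test is planar in lon/lat: by default an exact
segment/polygon intersection via shapely, where an edge is blocked only if
it overlaps a polygon *interior* with positive length (touching a vertex or
running along a coast is allowed, so paths can hug shorelines); a
dense-sampling variant tests points every `sampling_step_nm` (default 5 nm)
and is conservative under refinement (a finer step never unblocks an
edge). Longitudes are normalised to (−180, 180]; polygons crossing the
antimeridian must be pre-split before input. Shortest paths are Dijkstra
(networkx); the port-pair distance matrix is computed once per world and
persisted. Durations are distance/(speed·24) at 15 knots (360 nm/day).

The tests verify the edge set against a brute-force, from-scratch planar
geometry oracle and Dijkstra against independent all-pairs and exhaustive
enumeration oracles. Exhaustive simple-path enumeration is combinatorially
explosive, so it runs on worlds of ≤ 10 nodes; the ≤ 50-node worlds are
checked against Floyd–Warshall instead, and the edge oracle runs at full
size everywhere.

## Propagule pressure and risk ranking

D(t) = D(0)e^(−λt) with defaults D(0) = 2113.489 organisms/m³ and
λ = 0.161/day (the unrounded value is stored). Ballast-water exchange is
instantaneous at proportion p of the voyage (default 0.5, mid-voyage;
per-event positions can override), retains a fraction r (default 1.0, i.e.
no assumed efficacy), and switches decay from μ₁ to μ₂, giving
D(T) = D(0)·r·e^(−μ₁pT)·e^(−μ₂(1−p)T) ≡ D(0)·r·e^(−λT) with
λ = μ₁p + μ₂(1−p). D(0) and r scale every total equally, so rankings are
invariant to both. Per-voyage propagules are **expected** discharge ×
arrival density (sampled discharge would add noise without changing
expected rankings). Ranking ties break by larger volume, then
alphabetical source id. The sensitivity analysis re-ranks source and
arrival ecoregions over 50 evenly spaced λ values on [0.01, 0.50]; λ = 0 is
admitted as the no-decay baseline, where propagule ranking provably equals
volume ranking. For equal-volume sources, the nearer source's propagule
share is non-decreasing in λ (e^(−λ(T₁−T₂)) is monotone); this is asserted
numerically over the grid. A secondary per-voyage mean-density statistic
is reported unweighted by volume.

## Synthetic study conditions

The generator emulates the structure of a national inbound-shipping and
ballast-census dataset; all defaults are fixed once as the study
conditions:

* **World:** 8 ecoregions (3 destination, 5 source), 3 ports each, 4
  star-convex islands in a 60°×50° ocean box; ports placed in water by
  rejection sampling. Port purposes follow the 11-category scheme with
  mining purposes (iron ore, coal) over-represented.
* **Fleet:** 400 vessels; type mix 45% bulker / 20% tanker / 15% container
  / 20% other; truncated-normal lengths per class (bulkers 225 ± 45 m,
  capped at 345 m, matching the curation cap).
* **Traffic:** gamma-distributed route intensities (concentration 0.5, so
  a few routes dominate), Poisson annual counts growing 6%/yr over
  1999–2012 — which doubles annual volume, the shape of the observed
  decade-scale trend. Mining-purpose destinations draw bulkers at 3× the
  base weight. The negative-binomial-like route-count model is a stand-in;
  no claim is made that real traffic follows it.
* **Bulker mixture truth:** weights (0.25, 0.40, 0.25, 0.10), intercepts
  (100, 500, 1000, 2000) m³, slopes (0.05, 0.35, 0.65, 0.95) m³/m³,
  σ = (400, 900, 1400, 1800) m³ — minimal, partial, full and heavy-ballast
  regimes with variance growing with discharge level.
* **Linear truths:** slopes 0.45/0.25/0.30 for tanker/container/other with
  purpose offsets and σ = 1200/800/600 m³.
* **Census:** 1 + Poisson(0.8) tanks per voyage with Dirichlet volume
  splits; BWE on 70% of tanks, exchange position Beta(8, 8) (mode 0.5);
  uptake-provenance mismatch rate 0.20 (giving ≈ 79% port-level volume
  consistency); corruption rate 0.16 (zero/overlong lengths or infeasible
  discharge), flagged internally so curation counts can be asserted
  exactly. Negative discharge draws are truncated to 0 and totals capped
  at 1.2·DWT at generation.

What the generator does **not** emulate: realistic coastline geometry,
seasonality, economic structure of trade flows, spatially correlated
provenance mismatches (mismatch ports are uniform, so ecoregion-level
consistency exceeds port-level by only a little, whereas real mismatches
are usually nearby), per-taxon decay variation, and post-census regulatory
behaviour change. Passing tests therefore demonstrate the correctness of
the machinery and estimators under known ground truth, not the realism of
any particular coefficient for a real fleet.

## Reproducibility and problem sizes

All randomness descends from one root seed via `numpy.random.SeedSequence`
spawning, one child per stage; identical configurations reproduce
byte-identical output files (asserted by digest and byte comparison). The
default pipeline world produces ≈ 4,400 census voyages and ≈ 11,000
shipping voyages and completes in seconds. Simulation studies in the test
suite use n = 5000 (mixture recovery and order selection, 100 replicates),
n = 2000 (BIC predictor-set selection, 100 replicates), n = 3000 (CV
ordering, 20 replicates), and 100 random archipelagos for the routing
oracle — sizes chosen to give stable Monte-Carlo rates on a single CPU.

## Known limitations

* The tonnes-vs-m³ convention treats 0.30·DWT as a volume; strict volumes
  differ by the density factor 1.025.
* The land test is planar in lon/lat; at high latitudes the chord sampled
  in lon/lat deviates from the great-circle track, so visibility is
  approximate away from the tropics and mid-latitudes.
* Predictive variances assume independent voyages and within-model
  Gaussian noise; parameter uncertainty of the fitted models is not
  propagated.
* Risk is transport-stage only: no environmental matching, survival,
  establishment or spread modelling, and no hull-biofouling pathway.
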