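"""Synthetic shipping world with known ground truth.

The original voyage and ballast census data behind this kind of biosecurity
analysis are confidential, so this module generates a self-consistent stand-in
world: island shorelines, ports grouped into marine ecoregions, a fleet of
four vessel classes, a multi-year voyage history with a traffic trend, and a
per-tank ballast census whose discharge volumes follow known type-specific
generative models (a K-component mixture of linear regressions on calculated
ballast capacity for bulkers; linear-plus-noise with destination-purpose
offsets for the other classes).  Because the generating parameters are known,
every downstream stage — curation, model fitting, hindcasting, provenance
checks, routing and risk ranking — can be tested offline against ground
truth.

All generators are deterministic given their configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import DesignCoefficients, DEFAULT_COEFFS, calc_dwt, calc_ballast_capacity

__all__ = [
    "PURPOSE_CATEGORIES",
    "MINING_PURPOSES",
    "VESSEL_TYPES",
    "Shoreline",
    "WorldConfig",
    "FleetConfig",
    "TrafficConfig",
    "MixtureParams",
    "LinearParams",
    "GroundTruth",
    "gen_world",
    "gen_fleet",
    "gen_voyages",
    "gen_ballast_census",
    "ballast_voyage_table",
]

#: the 11 broad port-purpose categories (primary makeup of traffic at a port)
PURPOSE_CATEGORIES = (
    "iron_ore",
    "coal",
    "tankers",
    "other_minerals",
    "timber",
    "grains",
    "sugar",
    "imports",
    "general_cargo",
    "variety",
    "unknown",
)

#: purposes indicating mining export traffic (preferred bulker destinations)
MINING_PURPOSES = frozenset({"iron_ore", "coal"})

VESSEL_TYPES = ("bulker", "tanker", "container", "other")


class Shoreline:
    """A collection of simple (non-self-intersecting) land polygons in lon/lat."""

    def __init__(self, polygons: Sequence[np.ndarray]):
        self.polygons = [np.asarray(p, dtype=float) for p in polygons]
        for p in self.polygons:
            if p.ndim != 2 or p.shape[1] != 2 or len(p) < 3:
                raise ValueError("each polygon must be an (k, 2) array with k >= 3")
        self._shapely = None

    def __len__(self) -> int:
        return len(self.polygons)

    def to_shapely(self):
        """The shoreline as a list of shapely Polygons (cached)."""
        if self._shapely is None:
            from shapely.geometry import Polygon

            self._shapely = [Polygon(p) for p in self.polygons]
        return self._shapely

    def contains(self, lon, lat) -> np.ndarray:
        """Vectorised strict-interior containment test against any polygon."""
        import shapely

        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        inside = np.zeros(lon.shape, dtype=bool)
        for poly in self.to_shapely():
            inside |= shapely.contains_xy(poly, lon, lat)
        return inside

    def to_geojson(self) -> dict:
        feats = []
        for i, p in enumerate(self.polygons):
            ring = [[float(x), float(y)] for x, y in p]
            if ring[0] != ring[-1]:
                ring.append(ring[0])
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {"island": i},
                }
            )
        return {"type": "FeatureCollection", "features": feats}

    def write_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh, sort_keys=True)

    @classmethod
    def from_geojson(cls, obj) -> "Shoreline":
        if not isinstance(obj, dict):
            with open(obj) as fh:
                obj = json.load(fh)
        polys = []
        for feat in obj["features"]:
            ring = feat["geometry"]["coordinates"][0]
            arr = np.asarray(ring, dtype=float)
            if np.allclose(arr[0], arr[-1]):
                arr = arr[:-1]
            polys.append(arr)
        return cls(polys)


@dataclass(frozen=True)
class WorldConfig:
    """Geography of the synthetic world.

    ``destination_fraction`` of the ecoregions play the role of the focal
    (arrival) coast; the remainder are foreign source ecoregions.  Port
    purposes are drawn from :data:`PURPOSE_CATEGORIES` with mining purposes
    over-represented, so that bulker traffic can concentrate on ore/coal
    export ports.
    """

    n_ecoregions: int = 8
    ports_per_ecoregion: int = 3
    n_islands: int = 4
    bbox: tuple[float, float, float, float] = (100.0, 160.0, -45.0, 5.0)
    seed: int = 0
    destination_fraction: float = 0.375
    purpose_weights: Mapping[str, float] | None = None
    island_radius_deg: tuple[float, float] = (1.0, 3.0)
    port_scatter_deg: float = 1.5
    max_place_tries: int = 500

    def __post_init__(self) -> None:
        if self.n_ecoregions < 2:
            raise ValueError("n_ecoregions must be at least 2")
        lon0, lon1, lat0, lat1 = self.bbox
        if lon1 <= lon0 or lat1 <= lat0:
            raise ValueError("bbox is degenerate")


#: default purpose weights: mining purposes over-represented
_DEFAULT_PURPOSE_WEIGHTS = {
    "iron_ore": 0.18,
    "coal": 0.15,
    "tankers": 0.10,
    "other_minerals": 0.08,
    "timber": 0.05,
    "grains": 0.08,
    "sugar": 0.04,
    "imports": 0.10,
    "general_cargo": 0.10,
    "variety": 0.08,
    "unknown": 0.04,
}


@dataclass(frozen=True)
class FleetConfig:
    """Fleet composition: class mix and per-class truncated-normal lengths (m)."""

    n_vessels: int = 400
    type_mix: tuple[float, float, float, float] = (0.45, 0.20, 0.15, 0.20)
    #: per type: (location, scale, lower, upper) of a truncated normal, metres
    length_params: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "bulker": (225.0, 45.0, 100.0, 345.0),
            "tanker": (185.0, 45.0, 60.0, 345.0),
            "container": (215.0, 55.0, 90.0, 345.0),
            "other": (110.0, 50.0, 30.0, 345.0),
        }
    )

    def __post_init__(self) -> None:
        if len(self.type_mix) != len(VESSEL_TYPES):
            raise ValueError("type_mix must have one entry per vessel type")
        if any(p < 0 for p in self.type_mix) or not np.isclose(sum(self.type_mix), 1.0):
            raise ValueError("type_mix must be a probability vector summing to 1")
        for t, (_, _, lo, hi) in self.length_params.items():
            if not (0 <= lo < hi <= 345.0):
                raise ValueError(f"length bounds for {t} must satisfy 0 <= lo < hi <= 345")


@dataclass(frozen=True)
class TrafficConfig:
    """Voyage-history structure.

    Route intensities are gamma-distributed with shape ``route_concentration``
    (small values make a few routes dominate, emulating heavy-tailed real
    traffic); annual voyage counts are Poisson with a multiplicative
    ``growth_rate`` trend.  Destinations with mining purposes draw bulkers
    preferentially (``bulker_mining_boost`` multiplies the bulker weight).
    """

    years: tuple[int, int] = (1999, 2012)
    base_intensity: float = 1.5
    growth_rate: float = 1.06
    route_concentration: float = 0.5
    bulker_mining_boost: float = 3.0

    def __post_init__(self) -> None:
        if self.base_intensity <= 0 or self.route_concentration <= 0:
            raise ValueError("intensities must be positive")
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be positive")
        if self.years[1] < self.years[0]:
            raise ValueError("year range must be non-empty")


@dataclass(frozen=True)
class MixtureParams:
    """Ground-truth K-component mixture of linear regressions."""

    weights: tuple[float, ...] = (0.25, 0.40, 0.25, 0.10)
    intercepts: tuple[float, ...] = (100.0, 500.0, 1000.0, 2000.0)
    slopes: tuple[float, ...] = (0.05, 0.35, 0.65, 0.95)
    sigmas: tuple[float, ...] = (400.0, 900.0, 1400.0, 1800.0)

    def __post_init__(self) -> None:
        k = len(self.weights)
        if not (len(self.intercepts) == len(self.slopes) == len(self.sigmas) == k):
            raise ValueError("mixture parameter tuples must share one length")
        if any(w <= 0 for w in self.weights) or not np.isclose(sum(self.weights), 1.0):
            raise ValueError("weights must be positive and sum to 1")
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("sigmas must be positive")

    @property
    def K(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class LinearParams:
    """Ground-truth linear discharge model: intercept + slope*capacity + purpose offset."""

    intercept: float = 300.0
    slope: float = 0.45
    sigma: float = 1200.0
    purpose_offsets: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters for the ballast census.

    Defaults: a 4-component bulker mixture spanning minimal to heavy-ballast
    discharge regimes; linear models for the other classes with destination
    purpose offsets; ballast-water exchange on ~70% of tanks with exchange
    position Beta(8, 8) (mode 0.5, mid-voyage); a 20% uptake-provenance
    mismatch rate (uptake port differing from the voyage source); and a 16%
    record-corruption rate to exercise curation.
    """

    bulker_mixture: MixtureParams = field(default_factory=MixtureParams)
    tanker: LinearParams = field(
        default_factory=lambda: LinearParams(
            300.0, 0.45, 1200.0, {"tankers": 2000.0, "imports": -400.0, "variety": 500.0}
        )
    )
    container: LinearParams = field(
        default_factory=lambda: LinearParams(
            200.0, 0.25, 800.0, {"imports": -300.0, "general_cargo": 400.0}
        )
    )
    other: LinearParams = field(
        default_factory=lambda: LinearParams(150.0, 0.30, 600.0, {"general_cargo": 250.0})
    )
    exchange_beta: tuple[float, float] = (8.0, 8.0)
    bwe_probability: float = 0.7
    provenance_mismatch_rate: float = 0.20
    corruption_rate: float = 0.16
    mean_extra_tanks: float = 0.8

    def __post_init__(self) -> None:
        for name in ("bwe_probability", "provenance_mismatch_rate", "corruption_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def linear_for(self, vessel_type: str) -> LinearParams:
        return {"tanker": self.tanker, "container": self.container, "other": self.other}[
            vessel_type
        ]


# ---------------------------------------------------------------------------
# world


def _random_island(rng: np.random.Generator, cfg: WorldConfig) -> np.ndarray:
    lon0, lon1, lat0, lat1 = cfg.bbox
    margin = 0.05
    cx = rng.uniform(lon0 + margin * (lon1 - lon0), lon1 - margin * (lon1 - lon0))
    cy = rng.uniform(lat0 + margin * (lat1 - lat0), lat1 - margin * (lat1 - lat0))
    r = rng.uniform(*cfg.island_radius_deg)
    k = int(rng.integers(6, 12))
    # jittered equally spaced angles keep every angular gap well below pi,
    # which guarantees the star polygon is simple (non-self-intersecting)
    angles = 2.0 * np.pi * (np.arange(k) + rng.uniform(0.0, 0.6, size=k)) / k
    radii = r * rng.uniform(0.5, 1.0, size=k)
    return np.column_stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)])


def _place_in_water(rng, shoreline: Shoreline, sampler, tries: int, what: str):
    for _ in range(tries):
        lon, lat = sampler()
        if not shoreline.contains(lon, lat)[0]:
            return float(lon), float(lat)
    raise ValueError(f"could not place {what} in water after {tries} tries")


def gen_world(config: WorldConfig) -> tuple[Shoreline, pd.DataFrame, pd.DataFrame]:
    """Generate shoreline, port table and ecoregion table.

    Returns ``(shoreline, ports, ecoregions)``; ports carry ``port_id``,
    coordinates, numeric ``ecoregion`` code and a ``purpose`` label, and are
    guaranteed to lie strictly in water.
    """
    rng = np.random.default_rng(config.seed)
    lon0, lon1, lat0, lat1 = config.bbox

    shoreline = Shoreline([_random_island(rng, config) for _ in range(config.n_islands)])

    # ecoregion centres in water, loosely separated
    centres = []
    min_sep = 0.15 * min(lon1 - lon0, lat1 - lat0)
    for i in range(config.n_ecoregions):
        def sample():
            return rng.uniform(lon0, lon1), rng.uniform(lat0, lat1)

        for attempt in range(config.max_place_tries):
            lon, lat = _place_in_water(rng, shoreline, sample, config.max_place_tries, "ecoregion centre")
            if all((lon - a) ** 2 + (lat - b) ** 2 >= min_sep**2 for a, b in centres):
                break
        centres.append((lon, lat))

    n_dest = max(1, int(round(config.destination_fraction * config.n_ecoregions)))
    dest_idx = set(rng.choice(config.n_ecoregions, size=n_dest, replace=False).tolist())

    eco_rows = []
    for i, (lon, lat) in enumerate(centres):
        code = 100 + i
        eco_rows.append(
            {
                "ecoregion": code,
                "name": f"ER{code}",
                "lon": lon,
                "lat": lat,
                "is_destination": i in dest_idx,
            }
        )
    ecoregions = pd.DataFrame(eco_rows)

    weights = dict(config.purpose_weights or _DEFAULT_PURPOSE_WEIGHTS)
    cats = list(PURPOSE_CATEGORIES)
    w = np.array([weights.get(c, 0.0) for c in cats], dtype=float)
    if w.sum() <= 0:
        raise ValueError("purpose weights must have positive mass")
    w = w / w.sum()

    port_rows = []
    pid = 0
    for _, eco in ecoregions.iterrows():
        for _ in range(config.ports_per_ecoregion):
            def sample():
                return (
                    np.clip(eco["lon"] + rng.normal(0, config.port_scatter_deg), lon0, lon1),
                    np.clip(eco["lat"] + rng.normal(0, config.port_scatter_deg), lat0, lat1),
                )

            lon, lat = _place_in_water(rng, shoreline, sample, config.max_place_tries, "port")
            purpose = cats[int(rng.choice(len(cats), p=w))]
            port_rows.append(
                {
                    "port_id": f"P{pid:03d}",
                    "lon": lon,
                    "lat": lat,
                    "ecoregion": int(eco["ecoregion"]),
                    "purpose": purpose,
                }
            )
            pid += 1
    ports = pd.DataFrame(port_rows)
    return shoreline, ports, ecoregions


# ---------------------------------------------------------------------------
# fleet


def gen_fleet(config: FleetConfig, seed: int = 0) -> pd.DataFrame:
    """Generate the vessel table: ``vessel_id``, ``vessel_type``, ``length_m``."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    types = rng.choice(len(VESSEL_TYPES), size=config.n_vessels, p=list(config.type_mix))
    lengths = np.empty(config.n_vessels)
    for ti, tname in enumerate(VESSEL_TYPES):
        mask = types == ti
        if not mask.any():
            continue
        loc, scale, lo, hi = config.length_params[tname]
        a, b = (lo - loc) / scale, (hi - loc) / scale
        lengths[mask] = stats.truncnorm.rvs(
            a, b, loc=loc, scale=scale, size=int(mask.sum()), random_state=rng
        )
    return pd.DataFrame(
        {
            "vessel_id": [f"V{i:04d}" for i in range(config.n_vessels)],
            "vessel_type": [VESSEL_TYPES[t] for t in types],
            "length_m": lengths,
        }
    )


# ---------------------------------------------------------------------------
# voyages


def gen_voyages(
    world: tuple[Shoreline, pd.DataFrame, pd.DataFrame],
    fleet: pd.DataFrame,
    config: TrafficConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate the voyage table over all (source, destination) routes.

    Sources are ports in non-destination ecoregions; destinations are ports in
    destination ecoregions.  Expected annual counts grow geometrically by
    ``growth_rate``; the vessel class drawn for each voyage is tilted toward
    bulkers when the destination port has a mining purpose.
    """
    _, ports, ecoregions = world
    rng = np.random.default_rng(seed)

    dest_codes = set(ecoregions.loc[ecoregions["is_destination"], "ecoregion"])
    dst_ports = ports[ports["ecoregion"].isin(dest_codes)].reset_index(drop=True)
    src_ports = ports[~ports["ecoregion"].isin(dest_codes)].reset_index(drop=True)
    if dst_ports.empty or src_ports.empty:
        raise ValueError("world must contain both source and destination ecoregions")

    base_mix = np.array(
        [
            (fleet["vessel_type"] == t).sum() / len(fleet)
            for t in VESSEL_TYPES
        ]
    )
    if not base_mix.any():
        raise ValueError("fleet is empty")
    vessels_by_type = {
        t: fleet.loc[fleet["vessel_type"] == t, "vessel_id"].to_numpy() for t in VESSEL_TYPES
    }
    all_vessels = fleet["vessel_id"].to_numpy()

    y0, y1 = config.years
    years = np.arange(y0, y1 + 1)
    eco_of = dict(zip(ports["port_id"], ports["ecoregion"]))
    purpose_of = dict(zip(ports["port_id"], ports["purpose"]))

    rows = []
    vid = 0
    for _, src in src_ports.iterrows():
        for _, dst in dst_ports.iterrows():
            lam = rng.gamma(
                config.route_concentration, config.base_intensity / config.route_concentration
            )
            mining = dst["purpose"] in MINING_PURPOSES
            mix = base_mix.copy()
            if mining:
                mix[0] *= config.bulker_mining_boost
            mix = mix / mix.sum()
            for year in years:
                count = rng.poisson(lam * config.growth_rate ** (year - y0))
                if count == 0:
                    continue
                tidx = rng.choice(len(VESSEL_TYPES), size=count, p=mix)
                for t in tidx:
                    tname = VESSEL_TYPES[t]
                    pool = vessels_by_type[tname]
                    if len(pool) == 0:
                        pool = all_vessels
                    vessel = pool[int(rng.integers(len(pool)))]
                    rows.append(
                        {
                            "voyage_id": f"J{vid:06d}",
                            "vessel_id": vessel,
                            "vessel_type": tname,
                            "year": int(year),
                            "source_port": src["port_id"],
                            "dest_port": dst["port_id"],
                            "source_ecoregion": int(eco_of[src["port_id"]]),
                            "dest_ecoregion": int(eco_of[dst["port_id"]]),
                            "dest_purpose": purpose_of[dst["port_id"]],
                        }
                    )
                    vid += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ballast census


def _draw_discharge(
    rng: np.random.Generator,
    vessel_type: str,
    capacity: np.ndarray,
    dwt: np.ndarray,
    purpose: pd.Series,
    truth: GroundTruth,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voyage total discharge draw; returns (volume, component index or -1)."""
    n = len(capacity)
    if vessel_type == "bulker":
        mix = truth.bulker_mixture
        comp = rng.choice(mix.K, size=n, p=list(mix.weights))
        mu = np.asarray(mix.intercepts)[comp] + np.asarray(mix.slopes)[comp] * capacity
        y = mu + rng.normal(0.0, np.asarray(mix.sigmas)[comp])
    else:
        lin = truth.linear_for(vessel_type)
        offs = purpose.map(lambda p: lin.purpose_offsets.get(p, 0.0)).to_numpy(float)
        y = lin.intercept + lin.slope * capacity + offs + rng.normal(0.0, lin.sigma, size=n)
        comp = np.full(n, -1)
    # discharge cannot be negative nor exceed the feasibility cap used in curation
    y = np.clip(y, 0.0, 1.2 * dwt)
    return y, comp


def gen_ballast_census(
    voyages: pd.DataFrame,
    vessels: pd.DataFrame,
    ground_truth: GroundTruth,
    seed: int = 0,
    ports: pd.DataFrame | None = None,
    coeffs: DesignCoefficients = DEFAULT_COEFFS,
) -> pd.DataFrame:
    """Generate per-tank ballast events for each voyage.

    Each voyage's total discharge is drawn from the type-specific ground-truth
    model on calculated ballast capacity, then split across 1+Poisson tanks.
    Exchange positions (proportion of voyage completed at BWE) are Beta
    draws with mode 0.5; a ``provenance_mismatch_rate`` fraction of events
    get an uptake port differing from the voyage source; a
    ``corruption_rate`` fraction of voyages are corrupted (zero/overlong
    length or infeasible discharge) after clean generation.  Corrupt and
    mismatched rows are flagged in ``_corrupt`` / ``_mismatch`` columns so
    tests can assert exact curation counts.
    """
    rng = np.random.default_rng(seed)
    df = voyages.drop(columns=["vessel_type", "length_m"], errors="ignore").merge(
        vessels[["vessel_id", "vessel_type", "length_m"]], on="vessel_id"
    )
    df = df.sort_values("voyage_id").reset_index(drop=True)
    dwt = calc_dwt(df["length_m"].to_numpy(), coeffs)
    capacity = calc_ballast_capacity(dwt, coeffs)

    totals = np.empty(len(df))
    comps = np.empty(len(df), dtype=int)
    for vtype in VESSEL_TYPES:
        mask = (df["vessel_type"] == vtype).to_numpy()
        if not mask.any():
            continue
        y, comp = _draw_discharge(
            rng, vtype, capacity[mask], dwt[mask], df.loc[mask, "dest_purpose"], ground_truth
        )
        totals[mask] = y
        comps[mask] = comp

    all_ports = (
        ports["port_id"].to_numpy() if ports is not None else
        np.unique(np.concatenate([df["source_port"].to_numpy(), df["dest_port"].to_numpy()]))
    )

    mismatch = rng.random(len(df)) < ground_truth.provenance_mismatch_rate
    corrupt = rng.random(len(df)) < ground_truth.corruption_rate
    corrupt_kind = rng.choice(
        ["zero_length", "max_length", "infeasible_discharge"], size=len(df)
    )
    n_tanks = 1 + rng.poisson(ground_truth.mean_extra_tanks, size=len(df))

    a, b = ground_truth.exchange_beta
    rows = []
    eid = 0
    for i in range(len(df)):
        row = df.iloc[i]
        length = float(row["length_m"])
        total = float(totals[i])
        if corrupt[i]:
            kind = corrupt_kind[i]
            if kind == "zero_length":
                length = 0.0
            elif kind == "max_length":
                length = float(346.0 + rng.uniform(0.0, 40.0))
            else:
                total = float((1.3 + rng.uniform(0.0, 0.5)) * dwt[i])
        uptake = row["source_port"]
        if mismatch[i]:
            others = all_ports[all_ports != row["source_port"]]
            uptake = str(others[int(rng.integers(len(others)))])
        k = int(n_tanks[i])
        shares = rng.dirichlet(np.ones(k))
        for j in range(k):
            has_bwe = rng.random() < ground_truth.bwe_probability
            rows.append(
                {
                    "event_id": f"E{eid:07d}",
                    "voyage_id": row["voyage_id"],
                    "vessel_id": row["vessel_id"],
                    "vessel_type": row["vessel_type"],
                    "year": int(row["year"]),
                    "tank_no": j,
                    "uptake_port": uptake,
                    "discharge_port": row["dest_port"],
                    "volume_m3": total * shares[j],
                    "exchange_position": float(rng.beta(a, b)) if has_bwe else np.nan,
                    "vessel_length_m": length,
                    "_component": int(comps[i]),
                    "_corrupt": bool(corrupt[i]),
                    "_mismatch": bool(mismatch[i]),
                }
            )
            eid += 1
    return pd.DataFrame(rows)


def sample_bulker_discharge(
    n: int,
    mixture: MixtureParams | None = None,
    seed: int = 0,
    length_params: tuple[float, float, float, float] = (225.0, 45.0, 100.0, 345.0),
    coeffs: DesignCoefficients = DEFAULT_COEFFS,
) -> pd.DataFrame:
    """Draw (capacity, discharge, component) directly from the bulker model.

    A convenience for parameter-recovery and model-selection studies: bulker
    lengths are drawn from the fleet truncated normal, converted to
    calculated ballast capacity, and discharge is drawn from the ground-truth
    mixture (negative draws truncated to 0, capped at 1.2 DWT).
    """
    from scipy import stats

    mixture = mixture or MixtureParams()
    rng = np.random.default_rng(seed)
    loc, scale, lo, hi = length_params
    a, b = (lo - loc) / scale, (hi - loc) / scale
    lengths = stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)
    dwt = calc_dwt(lengths, coeffs)
    capacity = calc_ballast_capacity(dwt, coeffs)
    comp = rng.choice(mixture.K, size=n, p=list(mixture.weights))
    mu = np.asarray(mixture.intercepts)[comp] + np.asarray(mixture.slopes)[comp] * capacity
    y = np.clip(mu + rng.normal(0.0, np.asarray(mixture.sigmas)[comp]), 0.0, 1.2 * dwt)
    return pd.DataFrame(
        {"length_m": lengths, "capacity_m3": capacity, "discharge_m3": y, "_component": comp}
    )


def sample_linear_discharge(
    n: int,
    params: LinearParams | None = None,
    seed: int = 0,
    length_params: tuple[float, float, float, float] = (185.0, 45.0, 60.0, 345.0),
    purposes: Sequence[str] = ("tankers", "imports", "variety", "coal", "grains", "unknown"),
    n_source_ports: int = 20,
    n_source_ecoregions: int = 8,
    coeffs: DesignCoefficients = DEFAULT_COEFFS,
) -> pd.DataFrame:
    """Draw voyage-level discharge from a ground-truth linear model.

    Discharge depends only on calculated ballast capacity and destination
    purpose; source ports and ecoregions are drawn independently so that
    they carry no signal — the configuration used to study predictor-set
    selection.  Negative draws are truncated to 0.
    """
    from scipy import stats

    params = params or LinearParams()
    rng = np.random.default_rng(seed)
    loc, scale, lo, hi = length_params
    a, b = (lo - loc) / scale, (hi - loc) / scale
    lengths = stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)
    capacity = calc_ballast_capacity(calc_dwt(lengths, coeffs), coeffs)
    purpose = rng.choice(list(purposes), size=n)
    offs = pd.Series(purpose).map(lambda p: params.purpose_offsets.get(p, 0.0)).to_numpy()
    y = params.intercept + params.slope * capacity + offs + rng.normal(0, params.sigma, n)
    port_eco = np.arange(n_source_ports) % n_source_ecoregions
    port = rng.integers(n_source_ports, size=n)
    return pd.DataFrame(
        {
            "capacity": capacity,
            "purpose": purpose,
            "source_port": [f"P{p:03d}" for p in port],
            "source_ecoregion": [int(port_eco[p]) for p in port],
            "discharge": np.maximum(y, 0.0),
        }
    )


def ballast_voyage_table(events: pd.DataFrame, voyages: pd.DataFrame | None = None,
                         coeffs: DesignCoefficients = DEFAULT_COEFFS) -> pd.DataFrame:
    """Aggregate tank events to one row per voyage (the modelling unit).

    Sums tank volumes to a per-voyage ``discharge_m3``, carries vessel length
    and type, and recomputes ``capacity_m3`` from length where the length is
    usable.  Optionally joins voyage covariates (destination purpose etc.).
    """
    g = events.groupby("voyage_id", sort=True)
    out = pd.DataFrame(
        {
            "voyage_id": g.size().index,
            "vessel_id": g["vessel_id"].first().to_numpy(),
            "vessel_type": g["vessel_type"].first().to_numpy(),
            "year": g["year"].first().to_numpy(),
            "length_m": g["vessel_length_m"].first().to_numpy(),
            "discharge_m3": g["volume_m3"].sum().to_numpy(),
        }
    )
    if "_corrupt" in events.columns:
        out["_corrupt"] = g["_corrupt"].first().to_numpy()
    ok = (out["length_m"] > 0) & (out["length_m"] <= 345.0)
    cap = np.full(len(out), np.nan)
    cap[ok.to_numpy()] = calc_ballast_capacity(
        calc_dwt(out.loc[ok, "length_m"].to_numpy(), coeffs), coeffs
    )
    out["capacity_m3"] = cap
    if voyages is not None:
        cols = [c for c in ("voyage_id", "source_port", "dest_port", "source_ecoregion",
                            "dest_ecoregion", "dest_purpose") if c in voyages.columns]
        out = out.merge(voyages[cols], on="voyage_id", how="left")
    return out
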