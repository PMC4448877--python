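"""Propagule pressure from hindcast discharge and voyage durations.

The density of viable organisms in a ballast tank is assumed to decay
exponentially with time at sea: ``D(t) = D(0) * exp(-lambda * t)`` with ``t``
in days.  Mid-ocean ballast-water exchange (BWE) at a proportion ``p``
through a voyage of duration ``T``, retaining a fraction ``r`` of propagules
and switching the decay rate from ``mu1`` (pre-exchange) to ``mu2``
(post-exchange), gives

    D(T) = D(0) * r * exp(-mu1*p*T) * exp(-mu2*(1-p)*T)
         = D(0) * r * exp(-lambda*T),   lambda = mu1*p + mu2*(1-p).

Propagule pressure for a voyage is its discharge volume times the arrival
density; route and ecoregion totals rank transport risk.  ``D(0)`` and ``r``
scale every total equally, so rankings are invariant to them.  A sensitivity
analysis re-ranks ecoregions across a grid of decay rates (default 50 values
on [0.01, 0.50]); ``lambda = 0`` is the no-decay baseline where ranking by
propagules coincides with ranking by discharge volume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .routing import voyage_duration_days

__all__ = [
    "DecayParams",
    "RiskResult",
    "density_at",
    "composite_lambda",
    "bwe_density",
    "propagule_pressure",
    "sensitivity_rank",
    "top_routes",
    "default_lambda_grid",
]


@dataclass(frozen=True)
class DecayParams:
    """Parameters of the exponential survival model with BWE.

    ``d0``: initial organism density (organisms per m^3); ``lam``: decay
    rate per day; ``mu1``/``mu2``: pre-/post-exchange decay rates (default to
    ``lam``); ``p_exchange``: proportion of the voyage completed when BWE
    occurs (mid-voyage by default); ``r``: proportion of propagules
    remaining after BWE.
    """

    d0: float = 2113.489
    lam: float = 0.161
    mu1: float | None = None
    mu2: float | None = None
    p_exchange: float = 0.5
    r: float = 1.0

    def __post_init__(self) -> None:
        if self.d0 < 0 or self.lam < 0:
            raise ValueError("d0 and lam must be non-negative")
        for name in ("mu1", "mu2"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.p_exchange <= 1.0:
            raise ValueError("p_exchange must lie in [0, 1]")
        if not 0.0 <= self.r <= 1.0:
            raise ValueError("r must lie in [0, 1]")

    @property
    def mu1_(self) -> float:
        return self.lam if self.mu1 is None else self.mu1

    @property
    def mu2_(self) -> float:
        return self.lam if self.mu2 is None else self.mu2

    def with_lambda(self, lam: float) -> "DecayParams":
        """Same parameters with a single decay rate ``lam`` throughout."""
        return replace(self, lam=lam, mu1=None, mu2=None)


def density_at(t_days, params: DecayParams = DecayParams()):
    """Organism density after ``t`` days without BWE: ``D0 * exp(-lam*t)``."""
    t = np.asarray(t_days, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = params.d0 * np.exp(-params.lam * t)
    return float(out) if np.isscalar(t_days) else out


def composite_lambda(mu1: float, mu2: float, p_exchange: float) -> float:
    """Effective decay rate under BWE: ``mu1*p + mu2*(1-p)``."""
    if mu1 < 0 or mu2 < 0:
        raise ValueError("decay rates must be non-negative")
    if not 0.0 <= p_exchange <= 1.0:
        raise ValueError("p_exchange must lie in [0, 1]")
    return mu1 * p_exchange + mu2 * (1.0 - p_exchange)


def bwe_density(T_days, params: DecayParams = DecayParams(), p_exchange=None):
    """Arrival density with BWE: ``D0 * r * exp(-mu1*p*T) * exp(-mu2*(1-p)*T)``.

    Identical to ``D0 * r * exp(-composite_lambda * T)``.  Reduces to
    :func:`density_at` when ``r=1`` and ``mu1 == mu2 == lam``.  A per-voyage
    exchange position may override ``params.p_exchange``.
    """
    T = np.asarray(T_days, dtype=float)
    if np.any(T < 0):
        raise ValueError("duration must be non-negative")
    p = params.p_exchange if p_exchange is None else np.asarray(p_exchange, dtype=float)
    if np.any(np.asarray(p) < 0) or np.any(np.asarray(p) > 1):
        raise ValueError("p_exchange must lie in [0, 1]")
    out = params.d0 * params.r * np.exp(-params.mu1_ * p * T) * np.exp(
        -params.mu2_ * (1.0 - p) * T
    )
    return float(out) if np.isscalar(T_days) and np.isscalar(p) else out


@dataclass
class RiskResult:
    """Route-level risk table plus ecoregion totals.

    ``route_risk`` has one row per (source, destination) port pair with
    distance, duration, voyage count, total discharge and propagule
    pressure; ``source_ecoregions`` / ``dest_ecoregions`` aggregate
    propagules by ecoregion; ``n_missing_distance`` counts voyages dropped
    for lack of a route distance.
    """

    route_risk: pd.DataFrame
    source_ecoregions: pd.DataFrame
    dest_ecoregions: pd.DataFrame
    n_missing_distance: int


def _as_distance_frame(distances) -> pd.DataFrame:
    if isinstance(distances, pd.DataFrame):
        return distances[["source_port", "dest_port", "distance_nm"]]
    rows = [
        {"source_port": s, "dest_port": d, "distance_nm": float(v)}
        for (s, d), v in distances.items()
    ]
    return pd.DataFrame(rows)


def propagule_pressure(
    hindcast_records: pd.DataFrame,
    distances,
    params: DecayParams = DecayParams(),
    speed_knots: float = 15.0,
) -> RiskResult:
    """Propagule pressure per route and per ecoregion.

    Per-voyage propagules = expected discharge volume x arrival density at
    the voyage duration (distance at ``speed_knots``); totals are summed per
    route and per source/arrival ecoregion.  Voyages on routes with no
    (finite) distance are excluded and counted.
    """
    dist = _as_distance_frame(distances)
    df = hindcast_records.merge(dist, on=["source_port", "dest_port"], how="left")
    missing = df["distance_nm"].isna() | ~np.isfinite(df["distance_nm"])
    n_missing = int(missing.sum())
    df = df.loc[~missing].copy()

    duration = voyage_duration_days(df["distance_nm"].to_numpy(), speed_knots)
    df["duration_days"] = duration
    df["propagules"] = df["expected_discharge_m3"].to_numpy() * bwe_density(duration, params)

    route = (
        df.groupby(["source_port", "dest_port"], sort=True)
        .agg(
            source_ecoregion=("source_ecoregion", "first"),
            dest_ecoregion=("dest_ecoregion", "first"),
            distance_nm=("distance_nm", "first"),
            duration_days=("duration_days", "first"),
            voyage_count=("propagules", "size"),
            total_discharge_m3=("expected_discharge_m3", "sum"),
            propagules=("propagules", "sum"),
        )
        .reset_index()
    )
    src = (
        df.groupby("source_ecoregion", sort=True)
        .agg(total_discharge_m3=("expected_discharge_m3", "sum"), propagules=("propagules", "sum"))
        .reset_index()
    )
    dst = (
        df.groupby("dest_ecoregion", sort=True)
        .agg(total_discharge_m3=("expected_discharge_m3", "sum"), propagules=("propagules", "sum"))
        .reset_index()
    )
    return RiskResult(route, src, dst, n_missing)


def default_lambda_grid(n: int = 50, lo: float = 0.01, hi: float = 0.50) -> np.ndarray:
    """Evenly spaced decay-rate grid for the sensitivity analysis."""
    return np.linspace(lo, hi, n)


def _rank(series: pd.Series, volumes: pd.Series, ids: pd.Series) -> np.ndarray:
    """Rank 1 = most propagules; ties break by larger volume then id."""
    order = np.lexsort((ids.astype(str).to_numpy(), -volumes.to_numpy(), -series.to_numpy()))
    ranks = np.empty(len(series), dtype=int)
    ranks[order] = np.arange(1, len(series) + 1)
    return ranks


def sensitivity_rank(
    hindcast_records: pd.DataFrame,
    distances,
    lambda_grid: Sequence[float] | None = None,
    params: DecayParams = DecayParams(),
    speed_knots: float = 15.0,
) -> pd.DataFrame:
    """Ecoregion rankings across a decay-rate grid.

    Returns a long table with columns ``lam``, ``role`` (source|arrival),
    ``ecoregion``, ``propagules``, ``total_discharge_m3`` and ``rank``
    (1 = most propagules), suitable for rank-trajectory plots.  ``lam=0``
    (no decay) is permitted and reproduces the volume-only ranking.
    """
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    if grid.size == 0:
        raise ValueError("lambda grid is empty")
    if np.any(grid < 0):
        raise ValueError("decay rates must be non-negative")
    rows = []
    for lam in grid:
        res = propagule_pressure(
            hindcast_records, distances, params.with_lambda(float(lam)), speed_knots
        )
        for role, table in (("source", res.source_ecoregions), ("arrival", res.dest_ecoregions)):
            ranks = _rank(table["propagules"], table["total_discharge_m3"], table.iloc[:, 0])
            for i, row in table.iterrows():
                rows.append(
                    {
                        "lam": float(lam),
                        "role": role,
                        "ecoregion": row.iloc[0],
                        "propagules": float(row["propagules"]),
                        "total_discharge_m3": float(row["total_discharge_m3"]),
                        "rank": int(ranks[i]),
                    }
                )
    return pd.DataFrame(rows)


_METRIC_COLS = {
    "voyages": "voyage_count",
    "volume": "total_discharge_m3",
    "propagules": "propagules",
}


def top_routes(route_risks: pd.DataFrame, metric: str = "propagules", n: int = 20):
    """Top-n routes by a metric, with the share of the grand total covered.

    Ties break deterministically: larger discharge volume first, then
    alphabetical source port id.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if metric not in _METRIC_COLS:
        raise ValueError(f"unknown metric {metric!r}; use one of {sorted(_METRIC_COLS)}")
    col = _METRIC_COLS[metric]
    order = np.lexsort(
        (
            route_risks["source_port"].astype(str).to_numpy(),
            -route_risks["total_discharge_m3"].to_numpy(),
            -route_risks[col].to_numpy(),
        )
    )
    ranked = route_risks.iloc[order].reset_index(drop=True)
    top = ranked.head(n).copy()
    total = float(route_risks[col].sum())
    share = float(top[col].sum()) / total if total > 0 else float("nan")
    return top, share
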