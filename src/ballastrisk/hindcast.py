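"""Hindcast ballast discharge over the full voyage history.

Fitted discharge models (one per vessel class) are applied to every voyage in
the shipping table, giving per-voyage expected discharge and predictive
variance; these are then aggregated by year, port, ecoregion or route.
Aggregation sums expectations exactly and variances under independence
across voyages, so any complete partition of the records conserves the grand
total.  The module also quantifies provenance consistency: the
volume-weighted proportion of ballast events whose uptake (or discharge)
location matches the voyage's source (or destination) at port, ecoregion, or
grouped-ecoregion resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .discharge import predict_discharge
from .geometry import (
    CurationRules,
    DesignCoefficients,
    DEFAULT_COEFFS,
    DEFAULT_RULES,
    calc_ballast_capacity,
    calc_dwt,
)

__all__ = [
    "HindcastResult",
    "ProvenanceResult",
    "hindcast_voyages",
    "aggregate",
    "provenance_consistency",
    "PROVENANCE_SUPER_GROUPS",
]

#: named ecoregion super-groups used when comparing provenance at the
#: "grouped" level on real-world data: the South China Sea group and the
#: Japan/Korea waters group.
PROVENANCE_SUPER_GROUPS: dict[str, str] = {
    "Gulf of Tonkin": "South China Sea group",
    "South China Sea Oceanic Islands": "South China Sea group",
    "Gulf of Thailand": "South China Sea group",
    "Southern Vietnam": "South China Sea group",
    "Sunda Shelf/Java Sea": "South China Sea group",
    "Malacca Strait": "South China Sea group",
    "Northeastern Honshu": "Japan/Korea waters group",
    "Sea of Japan": "Japan/Korea waters group",
    "Yellow Sea": "Japan/Korea waters group",
    "Central Kuroshio Current": "Japan/Korea waters group",
    "East China Sea": "Japan/Korea waters group",
}

_GROUP_KEYS = {
    "year": ["year"],
    "port": ["dest_port"],
    "source_port": ["source_port"],
    "ecoregion": ["dest_ecoregion"],
    "source_ecoregion": ["source_ecoregion"],
    "route": ["source_port", "dest_port"],
}


@dataclass
class HindcastResult:
    """Per-voyage hindcast records plus the count of voyages excluded by
    vessel-geometry checks."""

    records: pd.DataFrame
    n_excluded: int


def hindcast_voyages(
    voyage_table: pd.DataFrame,
    vessel_table: pd.DataFrame,
    models_by_type: Mapping[str, object],
    coeffs: DesignCoefficients = DEFAULT_COEFFS,
    rules: CurationRules = DEFAULT_RULES,
) -> HindcastResult:
    """Expected discharge and predictive variance for every voyage.

    Voyages whose vessel fails the length feasibility checks are excluded and
    counted.  A vessel type with no model in ``models_by_type`` raises
    ``KeyError`` naming the type.  Vessels outside the covariate range the
    models were fitted on are extrapolated linearly.
    """
    df = voyage_table.drop(columns=["vessel_type", "length_m"], errors="ignore").merge(
        vessel_table[["vessel_id", "vessel_type", "length_m"]], on="vessel_id", how="left"
    )
    missing_types = sorted(set(df["vessel_type"].dropna()) - set(models_by_type))
    if missing_types:
        raise KeyError(f"no discharge model for vessel types: {missing_types}")

    length = pd.to_numeric(df["length_m"], errors="coerce")
    ok = length.notna() & (length > rules.min_length_m) & (length <= rules.max_length_m)
    n_excluded = int((~ok).sum())
    df = df.loc[ok].reset_index(drop=True)

    dwt = calc_dwt(df["length_m"].to_numpy(float), coeffs)
    capacity = calc_ballast_capacity(dwt, coeffs)
    df = df.assign(capacity=capacity, _dwt=dwt)

    exp = np.empty(len(df))
    var = np.empty(len(df))
    for vtype, model in models_by_type.items():
        mask = (df["vessel_type"] == vtype).to_numpy()
        if not mask.any():
            continue
        sub = df.loc[mask]
        mean, v = predict_discharge(
            model,
            sub["capacity"].to_numpy(),
            mode="expected",
            dwt=sub["_dwt"].to_numpy(),
            frame=sub,
        )
        exp[mask] = mean
        var[mask] = v

    keep = [
        c
        for c in (
            "voyage_id",
            "vessel_id",
            "vessel_type",
            "year",
            "source_port",
            "dest_port",
            "source_ecoregion",
            "dest_ecoregion",
        )
        if c in df.columns
    ]
    records = df[keep].copy()
    records["expected_discharge_m3"] = exp
    records["predictive_variance_m6"] = var
    return HindcastResult(records=records, n_excluded=n_excluded)


def aggregate(records: pd.DataFrame, by: str) -> pd.DataFrame:
    """Group hindcast records and sum discharge, variance and voyage count.

    ``by`` is one of ``year``, ``port``, ``source_port``, ``ecoregion``,
    ``source_ecoregion`` or ``route``.  Output is ordered by key; sums over
    any complete partition equal the grand total exactly.
    """
    if by not in _GROUP_KEYS:
        raise ValueError(f"unknown grouping key {by!r}; use one of {sorted(_GROUP_KEYS)}")
    if records.empty:
        raise ValueError("records table is empty")
    keys = _GROUP_KEYS[by]
    g = records.groupby(keys, sort=True)
    out = g.agg(
        total_discharge_m3=("expected_discharge_m3", "sum"),
        total_variance_m6=("predictive_variance_m6", "sum"),
        voyage_count=("expected_discharge_m3", "size"),
    ).reset_index()
    return out


@dataclass
class ProvenanceResult:
    """Volume-weighted provenance consistency at a given spatial level."""

    proportion: float
    volume_consistent: float
    volume_total: float
    n_events: int
    n_excluded: int


def provenance_consistency(
    ballast_events: pd.DataFrame,
    voyage_table: pd.DataFrame,
    ports: pd.DataFrame | None = None,
    level: str = "port",
    side: str = "uptake",
    groups: Mapping | None = None,
) -> ProvenanceResult:
    """Volume-weighted proportion of ballast whose provenance is consistent.

    ``side="uptake"`` compares each event's uptake port against the voyage's
    source port (last port of call); ``side="discharge"`` compares the
    discharge port against the destination.  ``level`` raises the comparison
    from ports to ecoregions (requires ``ports`` with an ``ecoregion``
    column) or to grouped ecoregions (``groups`` maps ecoregion to
    super-group; ecoregions absent from the mapping stand alone;
    :data:`PROVENANCE_SUPER_GROUPS` covers the named real-world groups).
    Events referencing unknown ports are excluded and counted.
    """
    if side == "uptake":
        event_col, voyage_col = "uptake_port", "source_port"
    elif side == "discharge":
        event_col, voyage_col = "discharge_port", "dest_port"
    else:
        raise ValueError("side must be 'uptake' or 'discharge'")

    df = ballast_events.merge(
        voyage_table[["voyage_id", "source_port", "dest_port"]], on="voyage_id", how="left"
    )
    df = df[df[voyage_col].notna()]

    a = df[event_col].astype(str)
    b = df[voyage_col].astype(str)
    n_excluded = 0
    if level in ("ecoregion", "grouped"):
        if ports is None:
            raise ValueError("ecoregion-level comparison requires the ports table")
        eco = dict(zip(ports["port_id"].astype(str), ports["ecoregion"]))
        known = a.isin(eco) & b.isin(eco)
        n_excluded = int((~known).sum())
        df = df[known]
        a = a[known].map(eco)
        b = b[known].map(eco)
        if level == "grouped":
            mapping = groups if groups is not None else PROVENANCE_SUPER_GROUPS
            a = a.map(lambda e: mapping.get(e, e))
            b = b.map(lambda e: mapping.get(e, e))
    elif level != "port":
        raise ValueError("level must be 'port', 'ecoregion' or 'grouped'")

    vol = df["volume_m3"].to_numpy(float)
    match = (a.to_numpy() == b.to_numpy())
    total = float(vol.sum())
    consistent = float(vol[match].sum())
    return ProvenanceResult(
        proportion=consistent / total if total > 0 else float("nan"),
        volume_consistent=consistent,
        volume_total=total,
        n_events=int(len(df)),
        n_excluded=n_excluded,
    )
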