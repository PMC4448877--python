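"""Vessel geometry: deadweight tonnage from length, ballast capacity, and curation.

Deadweight tonnage (DWT) is reconstructed from vessel length through the naval
architecture "cube root format": at the design stage the length of a ship is
chosen as ``L = [DWT * (L/B)^2 * (B/H) / (rho * C_B * C_D)]^(1/3)``, where
``C_D`` is the deadweight coefficient (deadweight/displacement), ``C_B`` the
block coefficient, ``L/B`` the length/breadth ratio, ``B/H`` the breadth/draft
ratio and ``rho`` the density of saltwater.  Rearranged, DWT is a linear
function of ``L^3``, which lets a shipping record that carries only vessel
length be converted into a carrying capacity, and from there into a ballast
capacity (a fixed fraction of DWT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

__all__ = [
    "DesignCoefficients",
    "CurationRules",
    "CurationReport",
    "DEFAULT_COEFFS",
    "DEFAULT_RULES",
    "calc_dwt",
    "calc_block_coefficient",
    "calc_ballast_capacity",
    "curate",
]


@dataclass(frozen=True)
class DesignCoefficients:
    """Hull-form coefficients of the cube-root deadweight formula.

    Defaults are mid-range values for the dry-bulk / tanker / container fleet:
    ``c_d=0.8`` (deadweight coefficient), ``c_b=0.75`` (block coefficient),
    ``l_over_b=6.5``, ``b_over_h=2.2``, ``rho=1.025`` (saltwater density) and
    a ballast capacity equal to 30% of DWT.
    """

    c_d: float = 0.8
    c_b: float = 0.75
    l_over_b: float = 6.5
    b_over_h: float = 2.2
    rho: float = 1.025
    ballast_fraction: float = 0.30

    def __post_init__(self) -> None:
        for name in ("c_d", "c_b", "l_over_b", "b_over_h", "rho", "ballast_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class CurationRules:
    """Feasibility filters for ballast records.

    Records are removed when the vessel length is outside ``(min_length_m,
    max_length_m]`` or when the reported discharge exceeds
    ``max_discharge_fraction_of_dwt`` times the calculated DWT.
    """

    max_length_m: float = 345.0
    min_length_m: float = 0.0  # exclusive lower bound
    max_discharge_fraction_of_dwt: float = 1.20

    def __post_init__(self) -> None:
        if self.max_length_m <= self.min_length_m:
            raise ValueError("max_length_m must exceed min_length_m")
        if self.max_discharge_fraction_of_dwt <= 0:
            raise ValueError("max_discharge_fraction_of_dwt must be positive")


DEFAULT_COEFFS = DesignCoefficients()
DEFAULT_RULES = CurationRules()

#: rejection reasons, in the order the rules are applied
CURATION_REASONS = ("missing", "zero_length", "max_length", "infeasible_discharge")


def calc_dwt(length_m, coeffs: DesignCoefficients = DEFAULT_COEFFS):
    """Deadweight tonnage (t) from vessel length (m).

    ``DWT = L^3 * rho * C_B * C_D / ((L/B)^2 * (B/H))`` — exactly cubic in L.
    Accepts scalars or arrays; negative lengths raise ``ValueError``.
    """
    arr = np.asarray(length_m, dtype=float)
    if np.any(arr < 0):
        raise ValueError("vessel length must be non-negative")
    dwt = arr**3 * (coeffs.rho * coeffs.c_b * coeffs.c_d) / (
        coeffs.l_over_b**2 * coeffs.b_over_h
    )
    return float(dwt) if np.isscalar(length_m) else dwt


def calc_block_coefficient(speed_knots, length_m, a: float = 1.23, b: float = 0.395):
    """Block coefficient from design speed (knots) and length (m).

    ``C_B = a - b * V / sqrt(L)``.  Provided for completeness; the pipeline
    default fixes ``C_B = 0.75`` rather than deriving it per vessel.
    """
    arr = np.asarray(length_m, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("vessel length must be strictly positive")
    cb = a - b * np.asarray(speed_knots, dtype=float) / np.sqrt(arr)
    return float(cb) if np.isscalar(length_m) and np.isscalar(speed_knots) else cb


def calc_ballast_capacity(
    dwt_tonnes, coeffs: DesignCoefficients = DEFAULT_COEFFS, as_volume: bool = False
):
    """Ballast capacity from DWT, as ``ballast_fraction * DWT``.

    By default tonnes are reported numerically as m^3 (seawater density makes
    the distinction at most 2.5%); ``as_volume=True`` divides by ``rho`` to
    return a strict volume.
    """
    arr = np.asarray(dwt_tonnes, dtype=float)
    if np.any(arr < 0):
        raise ValueError("DWT must be non-negative")
    cap = coeffs.ballast_fraction * arr
    if as_volume:
        cap = cap / coeffs.rho
    return float(cap) if np.isscalar(dwt_tonnes) else cap


@dataclass
class CurationReport:
    """Per-rule rejection counts from :func:`curate`."""

    n_input: int
    counts: dict = field(default_factory=dict)

    @property
    def n_rejected(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def rejected_fraction(self) -> float:
        return self.n_rejected / self.n_input if self.n_input else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "count": int(self.counts.get(r, 0))} for r in CURATION_REASONS]
        rows.append({"rule": "total_rejected", "count": self.n_rejected})
        rows.append({"rule": "n_input", "count": self.n_input})
        return pd.DataFrame(rows)


def curate(
    ballast_voyages: pd.DataFrame,
    rules: CurationRules = DEFAULT_RULES,
    coeffs: DesignCoefficients = DEFAULT_COEFFS,
    length_col: str = "length_m",
    discharge_col: str = "discharge_m3",
) -> tuple[pd.DataFrame, CurationReport]:
    """Remove infeasible ballast-voyage records.

    Rules, applied in order (each record counted once, under the first rule it
    violates): missing length/discharge; length at or below the lower bound;
    length above the upper bound; discharge above
    ``max_discharge_fraction_of_dwt`` x calculated DWT.

    Returns the curated table (index preserved) and a :class:`CurationReport`.
    Idempotent: curating an already-curated table removes nothing.
    """
    for col in (length_col, discharge_col):
        if col not in ballast_voyages.columns:
            raise KeyError(f"required column {col!r} not present")

    df = ballast_voyages
    length = pd.to_numeric(df[length_col], errors="coerce")
    discharge = pd.to_numeric(df[discharge_col], errors="coerce")

    missing = length.isna() | discharge.isna()
    zero_length = ~missing & (length <= rules.min_length_m)
    max_length = ~missing & ~zero_length & (length > rules.max_length_m)
    ok_geom = ~(missing | zero_length | max_length)
    dwt = calc_dwt(length.where(ok_geom, other=0.0).to_numpy())
    infeasible = ok_geom & (
        discharge > rules.max_discharge_fraction_of_dwt * pd.Series(dwt, index=df.index)
    )

    report = CurationReport(
        n_input=len(df),
        counts={
            "missing": int(missing.sum()),
            "zero_length": int(zero_length.sum()),
            "max_length": int(max_length.sum()),
            "infeasible_discharge": int(infeasible.sum()),
        },
    )
    keep = ~(missing | zero_length | max_length | infeasible)
    return df.loc[keep].copy(), report
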