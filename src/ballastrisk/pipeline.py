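"""End-to-end reproducible pipeline: simulate -> curate -> fit -> distances ->
hindcast -> risk -> sensitivity -> rank.

All randomness flows from a single root seed, split deterministically per
stage, so re-running with the same configuration reproduces byte-identical
output files; a run manifest records the configuration hash and per-file
digests to make that checkable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .discharge import (
    cross_validate,
    model_to_json,
    select_linear_by_bic,
    select_mixture,
)
from .geometry import CurationRules, DesignCoefficients, curate
from .hindcast import aggregate, hindcast_voyages, provenance_consistency
from .risk import DecayParams, propagule_pressure, sensitivity_rank, top_routes
from .routing import build_water_graph, distance_table
from .synthetic import (
    FleetConfig,
    GroundTruth,
    TrafficConfig,
    WorldConfig,
    ballast_voyage_table,
    gen_ballast_census,
    gen_fleet,
    gen_voyages,
    gen_world,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "validate_tables",
           "stage_seeds", "DEFAULT_CANDIDATE_SETS"]

DEFAULT_CANDIDATE_SETS = (
    ("capacity",),
    ("capacity", "purpose"),
    ("capacity", "purpose", "source_ecoregion"),
    ("capacity", "purpose", "source_port"),
)


@dataclass
class PipelineConfig:
    """Complete run configuration; round-trips losslessly through YAML."""

    seed: int = 0
    world: WorldConfig = field(default_factory=WorldConfig)
    fleet: FleetConfig = field(default_factory=FleetConfig)
    traffic: TrafficConfig = field(default_factory=TrafficConfig)
    ground_truth: GroundTruth = field(default_factory=GroundTruth)
    coeffs: DesignCoefficients = field(default_factory=DesignCoefficients)
    rules: CurationRules = field(default_factory=CurationRules)
    candidate_sets: tuple = DEFAULT_CANDIDATE_SETS
    mixture_k_range: tuple[int, int] = (1, 5)
    em_restarts: int = 10
    cv_repeats: int = 10
    cv_train_fraction: float = 0.7
    speed_knots: float = 15.0
    decay: DecayParams = field(default_factory=DecayParams)
    lambda_grid_n: int = 50
    lambda_grid_range: tuple[float, float] = (0.01, 0.50)
    top_n_routes: int = 20

    def to_dict(self) -> dict:
        def conv(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {f.name: conv(getattr(v, f.name)) for f in dataclasses.fields(v)}
            if isinstance(v, (tuple, list)):
                return [conv(x) for x in v]
            if isinstance(v, dict):
                return {k: conv(x) for k, x in v.items()}
            if isinstance(v, np.generic):
                return v.item()
            return v

        return conv(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        from .synthetic import LinearParams, MixtureParams

        def tup(v):
            return tuple(v) if isinstance(v, list) else v

        kw = dict(d)
        if "world" in kw:
            w = dict(kw["world"])
            for k in ("bbox", "island_radius_deg"):
                if k in w:
                    w[k] = tup(w[k])
            kw["world"] = WorldConfig(**w)
        if "fleet" in kw:
            f = dict(kw["fleet"])
            if "type_mix" in f:
                f["type_mix"] = tup(f["type_mix"])
            if "length_params" in f:
                f["length_params"] = {k: tup(v) for k, v in f["length_params"].items()}
            kw["fleet"] = FleetConfig(**f)
        if "traffic" in kw:
            t = dict(kw["traffic"])
            if "years" in t:
                t["years"] = tup(t["years"])
            kw["traffic"] = TrafficConfig(**t)
        if "ground_truth" in kw:
            g = dict(kw["ground_truth"])
            if "bulker_mixture" in g:
                g["bulker_mixture"] = MixtureParams(
                    **{k: tup(v) for k, v in g["bulker_mixture"].items()}
                )
            for name in ("tanker", "container", "other"):
                if name in g:
                    g[name] = LinearParams(**g[name])
            if "exchange_beta" in g:
                g["exchange_beta"] = tup(g["exchange_beta"])
            kw["ground_truth"] = GroundTruth(**g)
        if "coeffs" in kw:
            kw["coeffs"] = DesignCoefficients(**kw["coeffs"])
        if "rules" in kw:
            kw["rules"] = CurationRules(**kw["rules"])
        if "decay" in kw:
            kw["decay"] = DecayParams(**kw["decay"])
        for k in ("candidate_sets",):
            if k in kw:
                kw[k] = tuple(tuple(c) for c in kw[k])
        for k in ("mixture_k_range", "lambda_grid_range"):
            if k in kw:
                kw[k] = tup(kw[k])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def stage_seeds(root_seed: int) -> dict[str, int]:
    """Deterministically derive one sub-seed (< 2^31) per pipeline stage."""
    names = ("world", "fleet", "voyages", "census", "fit", "cv")
    children = np.random.SeedSequence(root_seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, children)}


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    files: dict[str, str]
    warnings: int
    started: str
    finished: str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def run_pipeline(config: PipelineConfig, outdir) -> RunManifest:
    """Execute every stage and write stage outputs plus a run manifest.

    Stages: simulate the synthetic world and ballast census; curate; fit the
    per-type discharge models (BIC candidate selection for linear types,
    information-criterion K selection for the bulker mixture); compute
    over-water distances; hindcast discharge over the full voyage table;
    convert to propagule pressure; run the decay-rate sensitivity analysis;
    rank top routes.  Any stage error aborts with the stage name attached.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    seeds = stage_seeds(config.seed)
    files: dict[str, str] = {}
    n_warnings = 0

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        _write_csv(df, path)
        files[name] = _sha256(path)

    stage = "simulate"
    try:
        world_cfg = dataclasses.replace(config.world, seed=seeds["world"])
        world = gen_world(world_cfg)
        shoreline, ports, ecoregions = world
        fleet = gen_fleet(config.fleet, seeds["fleet"])
        voyages = gen_voyages(world, fleet, config.traffic, seeds["voyages"])
        events = gen_ballast_census(
            voyages, fleet, config.ground_truth, seeds["census"], ports=ports,
            coeffs=config.coeffs,
        )
        shoreline.write_geojson(outdir / "shoreline.geojson")
        files["shoreline.geojson"] = _sha256(outdir / "shoreline.geojson")
        emit("ports.csv", ports)
        emit("ecoregions.csv", ecoregions)
        emit("vessels.csv", fleet)
        emit("voyages.csv", voyages)
        emit("ballast_events.csv", events.drop(columns=[c for c in events.columns
                                                        if c.startswith("_")]))

        stage = "curate"
        bv = ballast_voyage_table(events, voyages, config.coeffs)
        curated, report = curate(bv, config.rules, config.coeffs)
        emit("ballast_voyages_curated.csv",
             curated.drop(columns=[c for c in curated.columns if c.startswith("_")]))
        emit("curation_report.csv", report.to_frame())

        stage = "fit"
        models: dict[str, object] = {}
        fit_tables = {}
        bulker = curated[curated["vessel_type"] == "bulker"]
        # cap K at what the sample size supports (n > 5*(3K-1) per K)
        k_lo, k_hi = config.mixture_k_range
        while k_hi > k_lo and len(bulker) <= 5 * (3 * k_hi - 1):
            k_hi -= 1
        if k_hi < config.mixture_k_range[1]:
            logger.warning("mixture K range capped at %d by sample size n=%d",
                           k_hi, len(bulker))
            n_warnings += 1
        sel = select_mixture(
            bulker["capacity_m3"].to_numpy(),
            bulker["discharge_m3"].to_numpy(),
            k_range=range(k_lo, k_hi + 1),
            seed=seeds["fit"],
            n_restarts=config.em_restarts,
        )
        models["bulker"] = sel.best("aic")
        fit_tables["bulker_selection"] = sel.table.assign(
            chosen_aic=sel.chosen["aic"], chosen_aic3=sel.chosen["aic3"],
            chosen_mdl=sel.chosen["mdl"],
        )
        for vtype in ("tanker", "container", "other"):
            sub = curated[curated["vessel_type"] == vtype]
            best, table = select_linear_by_bic(sub, config.candidate_sets)
            models[vtype] = best
            fit_tables[f"{vtype}_selection"] = table
        # validate the chosen bulker mixture against a single-component model
        chosen_k = models["bulker"].K
        n_train = int(round(config.cv_train_fraction * len(bulker)))
        if n_train > 5 * (3 * chosen_k - 1):
            cv_rows = []
            for label, spec in (("mixture", ("mixture", chosen_k)),
                                ("single_component", ("mixture", 1))):
                cv = cross_validate(spec, bulker, config.cv_train_fraction,
                                    config.cv_repeats, seed=seeds["cv"],
                                    n_restarts=config.em_restarts)
                cv_rows.append({"model": label, "K": spec[1], "cv_r2_mean": cv.r2_mean,
                                "cv_r2_sd": cv.r2_sd,
                                "cv_abs_total_error_mean": cv.abs_total_error_mean})
            emit("bulker_cv.csv", pd.DataFrame(cv_rows))
        else:
            logger.warning("skipping bulker CV: training split too small for K=%d",
                           chosen_k)
            n_warnings += 1
        emit("bulker_selection.csv", fit_tables["bulker_selection"])
        for vtype in ("tanker", "container", "other"):
            emit(f"{vtype}_selection.csv", fit_tables[f"{vtype}_selection"])
        with open(outdir / "models.json", "w") as fh:
            json.dump({t: model_to_json(m) for t, m in models.items()}, fh,
                      indent=2, sort_keys=True)
        files["models.json"] = _sha256(outdir / "models.json")

        stage = "distances"
        graph = build_water_graph(shoreline, ports)
        dists = distance_table(graph)
        emit("distances.csv", dists)

        stage = "hindcast"
        hc = hindcast_voyages(voyages, fleet, models, config.coeffs, config.rules)
        emit("hindcast.csv", hc.records)
        for by in ("year", "port", "ecoregion", "route"):
            emit(f"hindcast_by_{by}.csv", aggregate(hc.records, by))
        prov = provenance_consistency(events, voyages, ports, level="port")
        prov_eco = provenance_consistency(events, voyages, ports, level="ecoregion")
        emit("provenance.csv", pd.DataFrame([
            {"level": "port", "side": "uptake", "proportion": prov.proportion,
             "n_events": prov.n_events, "n_excluded": prov.n_excluded},
            {"level": "ecoregion", "side": "uptake", "proportion": prov_eco.proportion,
             "n_events": prov_eco.n_events, "n_excluded": prov_eco.n_excluded},
        ]))

        stage = "risk"
        risk = propagule_pressure(hc.records, dists, config.decay, config.speed_knots)
        emit("route_risk.csv", risk.route_risk)
        emit("ecoregion_sources.csv", risk.source_ecoregions)
        emit("ecoregion_arrivals.csv", risk.dest_ecoregions)
        n_warnings += 1 if risk.n_missing_distance else 0

        stage = "sensitivity"
        lo, hi = config.lambda_grid_range
        grid = np.linspace(lo, hi, config.lambda_grid_n)
        sens = sensitivity_rank(hc.records, dists, grid, config.decay, config.speed_knots)
        emit("sensitivity_ranks.csv", sens)

        stage = "rank"
        tops = []
        for metric in ("voyages", "volume", "propagules"):
            top, share = top_routes(risk.route_risk, metric, config.top_n_routes)
            top = top.assign(metric=metric, share_of_total=share)
            tops.append(top)
        emit("top_routes.csv", pd.concat(tops, ignore_index=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = RunManifest(
        config_hash=config.config_hash(),
        version=__version__,
        seed=config.seed,
        files=files,
        warnings=n_warnings,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# table validation

_REQUIRED = {
    "ports": ("port_id", "lon", "lat", "ecoregion", "purpose"),
    "ecoregions": ("ecoregion", "name", "lon", "lat"),
    "vessels": ("vessel_id", "vessel_type", "length_m"),
    "voyages": ("voyage_id", "vessel_id", "year", "source_port", "dest_port"),
    "events": ("event_id", "voyage_id", "uptake_port", "discharge_port", "volume_m3"),
}


@dataclass
class ValidationReport:
    issues: list[str]
    warnings: list[str]

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_tables(tables: dict[str, pd.DataFrame | str | Path]) -> ValidationReport:
    """Schema and referential-integrity checks across the pipeline tables.

    ``tables`` maps names (ports, ecoregions, vessels, voyages, events) to
    DataFrames or CSV paths; missing optional tables yield warnings, schema
    violations and dangling id references yield issues.
    """
    issues: list[str] = []
    warns: list[str] = []
    loaded: dict[str, pd.DataFrame] = {}
    for name, obj in tables.items():
        if isinstance(obj, (str, Path)):
            try:
                obj = pd.read_csv(obj)
            except Exception as exc:
                issues.append(f"{name}: unreadable ({exc})")
                continue
        loaded[name] = obj
        req = _REQUIRED.get(name, ())
        if obj.empty and req:
            warns.append(f"{name}: table is empty")
        for col in req:
            if col not in obj.columns:
                issues.append(f"{name}: missing required column {col!r}")

    def check_ref(child, col, parent, pcol):
        if child in loaded and parent in loaded:
            c, p = loaded[child], loaded[parent]
            if col in c.columns and pcol in p.columns:
                dangling = ~c[col].isin(set(p[pcol]))
                if dangling.any():
                    issues.append(
                        f"{child}.{col}: {int(dangling.sum())} rows reference "
                        f"unknown {parent}.{pcol}"
                    )

    check_ref("voyages", "vessel_id", "vessels", "vessel_id")
    check_ref("voyages", "source_port", "ports", "port_id")
    check_ref("voyages", "dest_port", "ports", "port_id")
    check_ref("events", "voyage_id", "voyages", "voyage_id")
    check_ref("ports", "ecoregion", "ecoregions", "ecoregion")
    return ValidationReport(issues=issues, warnings=warns)
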