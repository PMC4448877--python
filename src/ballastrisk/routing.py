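"""Over-water shortest-path distances between ports.

Seaborne distances are approximated as shortest paths on a visibility graph:
nodes are ports plus shoreline polygon vertices, and two nodes are joined
when the segment between them does not pass through the interior of any land
polygon.  Edge weights are spherical great-circle distances in nautical miles
(1 nm = 1 arc-minute of great circle).  Shortest paths are computed with
Dijkstra's algorithm, and distances convert to voyage durations at a fixed
cruising speed (15 knots by default, i.e. 360 nm per day).

The land test operates in lon/lat coordinates: by default an exact planar
segment/polygon intersection (an edge is blocked when the chord crosses a
polygon interior with positive length); a dense-sampling variant
(``method="sampled"``) tests points every ``sampling_step_nm`` along the
chord instead.  Longitudes are expected in (-180, 180]; polygons crossing
the antimeridian must be pre-split.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd

from .synthetic import Shoreline

__all__ = [
    "great_circle_nm",
    "build_water_graph",
    "shortest_path_nm",
    "distance_table",
    "voyage_duration_days",
    "normalize_lon",
]

EARTH_NM_PER_DEG = 60.0  # definition of the nautical mile


def normalize_lon(lon):
    """Normalise longitudes to (-180, 180]."""
    lon = np.asarray(lon, dtype=float)
    out = ((lon + 180.0) % 360.0) - 180.0
    out = np.where(out == -180.0, 180.0, out)
    return float(out) if np.isscalar(lon) or out.ndim == 0 else out


def great_circle_nm(a, b) -> float:
    """Spherical great-circle distance between two (lon, lat) points, nm."""
    lon1, lat1 = math.radians(a[0]), math.radians(a[1])
    lon2, lat2 = math.radians(b[0]), math.radians(b[1])
    s = math.sin((lat2 - lat1) / 2.0) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(
        (lon2 - lon1) / 2.0
    ) ** 2
    angle = 2.0 * math.asin(min(1.0, math.sqrt(s)))
    return math.degrees(angle) * EARTH_NM_PER_DEG


def _segment_blocked_exact(coords_a, coords_b, polygons) -> np.ndarray:
    """Exact planar test: chord passes through a polygon interior with
    positive length.  Touching a vertex or running along the boundary does
    not block, so paths may follow a coastline."""
    from shapely.geometry import LineString
    from shapely.prepared import prep

    n = len(coords_a)
    blocked = np.zeros(n, dtype=bool)
    prepared = [(prep(poly), poly, poly.boundary) for poly in polygons]
    for i in range(n):
        line = LineString([coords_a[i], coords_b[i]])
        for prepared_poly, poly, boundary in prepared:
            if not prepared_poly.intersects(line):
                continue
            interior_len = line.intersection(poly).length - line.intersection(boundary).length
            if interior_len > 1e-9:
                blocked[i] = True
                break
    return blocked


def _segment_blocked_sampled(coords_a, coords_b, polygons, step_nm: float) -> np.ndarray:
    """Dense-sampling land test: sample interior points of each chord every
    ``step_nm`` and flag strict containment in any polygon."""
    import shapely

    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    n = len(a)
    dists = np.array([great_circle_nm(a[i], b[i]) for i in range(n)])
    counts = np.maximum(2, np.ceil(dists / step_nm).astype(int) + 1)
    seg_idx = np.repeat(np.arange(n), counts)
    t = np.concatenate([np.linspace(0.0, 1.0, c + 2)[1:-1] for c in counts])
    px = a[seg_idx, 0] + t * (b[seg_idx, 0] - a[seg_idx, 0])
    py = a[seg_idx, 1] + t * (b[seg_idx, 1] - a[seg_idx, 1])
    inside = np.zeros(len(px), dtype=bool)
    for poly in polygons:
        inside |= shapely.contains_xy(poly, px, py)
    blocked = np.zeros(n, dtype=bool)
    np.add.at(blocked, seg_idx, inside)  # bool add == any
    return blocked


def build_water_graph(
    shoreline: Shoreline,
    ports: pd.DataFrame,
    sampling_step_nm: float = 5.0,
    method: str = "exact",
) -> nx.Graph:
    """Build the over-water visibility graph on ports and shoreline vertices.

    ``ports`` needs columns ``port_id``, ``lon``, ``lat``; every port must lie
    in water (a port strictly inside a land polygon raises ``ValueError``
    naming it).  ``method="exact"`` (default) uses a planar segment/polygon
    intersection test; ``method="sampled"`` tests points along the chord at
    ``sampling_step_nm`` spacing, which is conservative in the sense that
    refining the step never unblocks a blocked edge.
    """
    polygons = shoreline.to_shapely()

    in_land = shoreline.contains(ports["lon"].to_numpy(), ports["lat"].to_numpy())
    if in_land.any():
        bad = ports.loc[in_land, "port_id"].tolist()
        raise ValueError(f"ports inside land polygons: {bad}")

    pos: dict[str, tuple[float, float]] = {}
    for _, row in ports.iterrows():
        pos[str(row["port_id"])] = (float(row["lon"]), float(row["lat"]))
    for i, poly in enumerate(shoreline.polygons):
        for j, (x, y) in enumerate(poly):
            pos[f"shore_{i}_{j}"] = (float(x), float(y))

    nodes = list(pos)
    pairs = list(itertools.combinations(range(len(nodes)), 2))
    coords_a = [pos[nodes[i]] for i, _ in pairs]
    coords_b = [pos[nodes[j]] for _, j in pairs]
    if polygons and pairs:
        if method == "exact":
            blocked = _segment_blocked_exact(coords_a, coords_b, polygons)
        elif method == "sampled":
            blocked = _segment_blocked_sampled(coords_a, coords_b, polygons, sampling_step_nm)
        else:
            raise ValueError("method must be 'exact' or 'sampled'")
    else:
        blocked = np.zeros(len(pairs), dtype=bool)

    g = nx.Graph()
    for name, (x, y) in pos.items():
        g.add_node(name, lon=x, lat=y, is_port=not name.startswith("shore_"))
    for (i, j), blk in zip(pairs, blocked):
        if blk:
            continue
        d = great_circle_nm(pos[nodes[i]], pos[nodes[j]])
        if d > 0.0:
            g.add_edge(nodes[i], nodes[j], weight=d)
    return g


def shortest_path_nm(graph: nx.Graph, src_port: str, dst_port: str):
    """Shortest over-water distance (nm) and node path between two ports.

    Unreachable destinations are signalled by ``(inf, None)``; unknown node
    ids raise ``KeyError``.
    """
    for p in (src_port, dst_port):
        if p not in graph:
            raise KeyError(f"unknown port {p!r}")
    if src_port == dst_port:
        return 0.0, [src_port]
    try:
        dist, path = nx.single_source_dijkstra(graph, src_port, dst_port, weight="weight")
    except nx.NetworkXNoPath:
        return math.inf, None
    return float(dist), path


def distance_table(graph: nx.Graph, port_ids=None) -> pd.DataFrame:
    """All-pairs over-water distances between ports as a long DataFrame.

    Computed once per world (one Dijkstra sweep per port) and intended to be
    persisted alongside the port table.  Unreachable pairs get ``inf``.
    """
    if port_ids is None:
        port_ids = [n for n, d in graph.nodes(data=True) if d.get("is_port")]
    port_ids = list(port_ids)
    rows = []
    for src in port_ids:
        lengths = nx.single_source_dijkstra_path_length(graph, src, weight="weight")
        for dst in port_ids:
            if dst == src:
                continue
            rows.append(
                {
                    "source_port": src,
                    "dest_port": dst,
                    "distance_nm": float(lengths.get(dst, math.inf)),
                }
            )
    return pd.DataFrame(rows)


def voyage_duration_days(distance_nm, speed_knots: float = 15.0):
    """Voyage duration in days at constant speed: ``distance / (speed * 24)``."""
    if speed_knots <= 0:
        raise ValueError("speed must be positive")
    arr = np.asarray(distance_nm, dtype=float)
    if np.any(arr < 0):
        raise ValueError("distance must be non-negative")
    out = arr / (speed_knots * 24.0)
    return float(out) if np.isscalar(distance_nm) else out
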