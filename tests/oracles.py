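"""Independent brute-force oracles for the routing tests.

Pure-python computational geometry (no shapely) and exhaustive path
enumeration (no networkx), kept deliberately separate from the package so
that agreement is meaningful.
"""

import numpy as np


def point_in_polygon(px, py, poly) -> bool:
    """Strict-interior ray-casting test (boundary points excluded)."""
    n = len(poly)
    inside = False
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        # on-edge check: collinear and within bounding box
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        if abs(cross) < 1e-12 and min(x1, x2) - 1e-12 <= px <= max(x1, x2) + 1e-12 \
                and min(y1, y2) - 1e-12 <= py <= max(y1, y2) + 1e-12:
            return False
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


def _seg_params(a, b, c, d):
    """Intersection parameters (t, u) of segments a-b and c-d, or None."""
    r = (b[0] - a[0], b[1] - a[1])
    s = (d[0] - c[0], d[1] - c[1])
    denom = r[0] * s[1] - r[1] * s[0]
    if abs(denom) < 1e-15:
        return None
    t = ((c[0] - a[0]) * s[1] - (c[1] - a[1]) * s[0]) / denom
    u = ((c[0] - a[0]) * r[1] - (c[1] - a[1]) * r[0]) / denom
    if -1e-12 <= t <= 1 + 1e-12 and -1e-12 <= u <= 1 + 1e-12:
        return t, u
    return None


def segment_blocked(a, b, polygons) -> bool:
    """True when segment a-b passes through any polygon's interior with
    positive length: collect all crossing parameters with polygon edges and
    probe the midpoint of every sub-interval."""
    for poly in polygons:
        ts = [0.0, 1.0]
        n = len(poly)
        for i in range(n):
            hit = _seg_params(a, b, poly[i], poly[(i + 1) % n])
            if hit is not None:
                ts.append(min(1.0, max(0.0, hit[0])))
        ts = sorted(set(ts))
        for t0, t1 in zip(ts[:-1], ts[1:]):
            tm = 0.5 * (t0 + t1)
            px = a[0] + tm * (b[0] - a[0])
            py = a[1] + tm * (b[1] - a[1])
            if point_in_polygon(px, py, poly):
                return True
    return False


def enumerate_shortest_path(nodes, edges, src, dst):
    """Exhaustive simple-path enumeration; edges is {(u, v): weight}."""
    adj = {n: [] for n in nodes}
    for (u, v), w in edges.items():
        adj[u].append((v, w))
        adj[v].append((u, w))
    best = [np.inf]

    def walk(node, seen, acc):
        if acc >= best[0]:
            return
        if node == dst:
            best[0] = acc
            return
        for nxt, w in adj[node]:
            if nxt not in seen:
                walk(nxt, seen | {nxt}, acc + w)

    walk(src, {src}, 0.0)
    return best[0]


def floyd_warshall(nodes, edges):
    """All-pairs shortest distances by Floyd-Warshall."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for (u, v), w in edges.items():
        i, j = idx[u], idx[v]
        d[i, j] = min(d[i, j], w)
        d[j, i] = min(d[j, i], w)
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    return idx, d


def random_archipelago(rng, n_islands=None, n_ports=None, max_nodes=50):
    """A small random world in a ~4-degree box: star-convex islands plus
    ports placed in open water.  Returns (polygons, ports{name: (lon, lat)})."""
    if n_islands is None:
        n_islands = int(rng.integers(1, 4))
    if n_ports is None:
        n_ports = int(rng.integers(3, 8))
    polys = []
    for _ in range(n_islands):
        cx, cy = rng.uniform(-1.5, 1.5, size=2)
        k = int(rng.integers(5, 9))
        # jittered equally spaced angles -> gaps < pi -> simple polygon
        angles = 2 * np.pi * (np.arange(k) + rng.uniform(0.0, 0.6, k)) / k
        radii = rng.uniform(0.25, 0.7) * rng.uniform(0.5, 1.0, k)
        polys.append(np.column_stack([cx + radii * np.cos(angles),
                                      cy + radii * np.sin(angles)]))
    # cap total nodes
    while n_ports + sum(len(p) for p in polys) > max_nodes:
        polys.pop()
    ports = {}
    i = 0
    while len(ports) < n_ports:
        x, y = rng.uniform(-2.0, 2.0, size=2)
        if not any(point_in_polygon(x, y, p) for p in polys):
            ports[f"P{i:02d}"] = (x, y)
            i += 1
    return polys, ports
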