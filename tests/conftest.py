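"""Shared fixtures and independent oracle helpers.

Oracles here are deliberately naive (heap Dijkstra, recursive flood fill,
brute-force step-up) so they stay independent of the package's vectorised
implementations.
"""

import heapq

import numpy as np
import pytest

from tractstats import SkeletonMesh, generate_skeletons


@pytest.fixture(scope="session")
def skeletons_small():
    """Three small tracts (6x6 grids) for fast end-to-end tests."""
    return generate_skeletons(["CC", "IFO_L", "SLF_R"], resolution=6, seed=7)


@pytest.fixture(scope="session")
def cc_mesh(skeletons_small):
    return skeletons_small["CC"]


def flat_grid_mesh(n=3, spacing=1.0, half=1.0, name="CC"):
    """Planar z=0 grid sheet with +z normals; areas are exactly known."""
    xs, ys = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing,
                         indexing="ij")
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(n * n)])
    i, j = np.meshgrid(np.arange(n - 1), np.arange(n - 1), indexing="ij")
    v00 = (i * n + j).ravel()
    tris = np.concatenate([
        np.stack([v00, v00 + n, v00 + n + 1], axis=1),
        np.stack([v00, v00 + n + 1, v00 + 1], axis=1),
    ])
    normals = np.tile([0.0, 0.0, 1.0], (n * n, 1))
    return SkeletonMesh(name, verts, tris, normals, np.full(n * n, half))


# ---------------------------------------------------------------------------
# Independent oracles

def dijkstra_oracle(mesh, source):
    """Heap-based shortest path over the edge graph, written from scratch."""
    adj = {i: [] for i in range(mesh.n_vertices)}
    for a, b in mesh.edges():
        w = float(np.linalg.norm(mesh.vertices[a] - mesh.vertices[b]))
        adj[int(a)].append((int(b), w))
        adj[int(b)].append((int(a), w))
    dist = np.full(mesh.n_vertices, np.inf)
    dist[source] = 0.0
    heap = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist[u]:
            continue
        for v, w in adj[u]:
            if d + w < dist[v]:
                dist[v] = d + w
                heapq.heappush(heap, (dist[v], v))
    return dist


def flood_fill_oracle(mask, edges):
    """Brute-force connected components of the supra-threshold subgraph."""
    mask = np.asarray(mask, dtype=bool)
    adj = {}
    for a, b in edges:
        a, b = int(a), int(b)
        if mask[a] and mask[b]:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
    seen = set()
    comps = []
    for start in np.flatnonzero(mask):
        start = int(start)
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj.get(u, set()) - comp)
        seen |= comp
        comps.append(sorted(comp))
    return sorted(comps)


def bh_stepup_oracle(p, q):
    """Classical step-up rule: largest i with p_(i) <= i q / m, reject below."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject
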