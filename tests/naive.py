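"""Independent brute-force reference implementations of the clustering
metrics, written as plain double/triple loops straight from the defining
formulas.  Deliberately slow and structurally unrelated to the package code
so they can serve as oracles."""

from __future__ import annotations

import math

import numpy as np

EPS = 1e-6


def dist(p, q):
    return math.hypot(p[0] - q[0], p[1] - q[1])


def naive_ripley_score(points, area, radii):
    n = len(points)
    hits = 0
    for r in radii:
        count = 0
        for i in range(n):
            for j in range(n):
                if i != j and dist(points[i], points[j]) <= r:
                    count += 1
        K = area / n**2 * count
        if K - math.pi * r**2 > 0:
            hits += 1
    return 100.0 * hits / len(radii)


def naive_knn_edges(points, k):
    n = len(points)
    edges = set()
    for i in range(n):
        order = sorted(range(n), key=lambda j: (dist(points[i], points[j]), j))
        for j in order[1 : k + 1]:
            edges.add((min(i, j), max(i, j)))
    return sorted(edges)


def naive_assortativity(points, k):
    edges = naive_knn_edges(points, k)
    n = len(points)
    deg = [0.0] * n
    for i, j in edges:
        w = 1.0 / max(dist(points[i], points[j]), EPS) ** 2
        deg[i] += w
        deg[j] += w
    ends = [deg[i] for i, j in edges] + [deg[j] for i, j in edges]
    other = [deg[j] for i, j in edges] + [deg[i] for i, j in edges]
    mean = sum(ends) / len(ends)
    num = sum((a - mean) * (b - mean) for a, b in zip(ends, other))
    den = sum((a - mean) ** 2 for a in ends)
    if den < 1e-300 or max(deg) - min(deg) < 1e-12 * max(1.0, max(deg)):
        return 0.0
    return num / den


def naive_morans_per_axis(points, axis):
    n = len(points)
    vals = [p[axis] for p in points]
    mean = sum(vals) / n
    W = 0.0
    num = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            w = 1.0 / max(dist(points[i], points[j]), EPS) ** 2
            W += w
            num += w * (vals[i] - mean) * (vals[j] - mean)
    den = sum((v - mean) ** 2 for v in vals)
    return n / W * num / den


def naive_mnnd(points):
    n = len(points)
    total = 0.0
    for i in range(n):
        total += min(dist(points[i], points[j]) for j in range(n) if j != i)
    return total / n


def naive_dispersion(points):
    ds = [
        dist(points[i], points[j])
        for i in range(len(points))
        for j in range(i + 1, len(points))
    ]
    mean = sum(ds) / len(ds)
    var = sum((d - mean) ** 2 for d in ds) / len(ds)
    return var / mean


def weighted_modularity(points, edges, membership):
    """Q of a given partition on the 1/d^2-weighted graph (defining formula)."""
    n = len(points)
    W2 = 0.0  # 2m equivalent: total weight * 2
    w = {}
    for i, j in edges:
        w[(i, j)] = 1.0 / max(dist(points[i], points[j]), EPS) ** 2
        W2 += 2.0 * w[(i, j)]
    strength = [0.0] * n
    for (i, j), wij in w.items():
        strength[i] += wij
        strength[j] += wij
    Q = 0.0
    for i in range(n):
        for j in range(n):
            if membership[i] != membership[j]:
                continue
            a = w.get((min(i, j), max(i, j)), 0.0) if i != j else 0.0
            Q += a - strength[i] * strength[j] / W2
    return Q / W2
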