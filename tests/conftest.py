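"""Shared fixtures and oracles for the ervkit test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ervkit import SimulationParams, simulate_provirus

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """One modest provirus (short internal region) for structural tests."""
    return simulate_provirus(
        SimulationParams(
            ltr_length=300,
            internal_length=4000,
            backbone_length=10000,
            true_age=5e6,
            rate=5e-9,
            n_nonsense=2,
            n_frameshift=2,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def intact_sim():
    """A young, defect-free provirus."""
    return simulate_provirus(
        SimulationParams(
            ltr_length=300,
            internal_length=4000,
            backbone_length=10000,
            true_age=1e6,
            rate=5e-9,
            n_nonsense=0,
            n_frameshift=0,
            seed=4,
        )
    )


def random_contig(length: int, seed: int, gc: float = 0.42) -> str:
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random unrooted binary tree with positive branch lengths, as an
    independent oracle for neighbor joining.

    Returns (newick string, labels, path-distance matrix).
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    # adjacency over node ids; leaves 0..n-1
    next_id = n_taxa
    edges: dict[tuple[int, int], float] = {}
    nodes = list(range(n_taxa))

    def blen() -> float:
        return float(rng.uniform(0.1, 1.0))

    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]  # pop higher index first
        u = next_id
        next_id += 1
        edges[(a, u)] = blen()
        edges[(b, u)] = blen()
        nodes.remove(a)
        nodes.remove(b)
        nodes.append(u)
    center = next_id
    for a in nodes:
        edges[(a, center)] = blen()

    # path distances between leaves via BFS over the tree graph
    adj: dict[int, list[tuple[int, float]]] = {}
    for (a, b), w in edges.items():
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))
    m = np.zeros((n_taxa, n_taxa))
    for s in range(n_taxa):
        dist = {s: 0.0}
        stack = [s]
        while stack:
            v = stack.pop()
            for w, wt in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + wt
                    stack.append(w)
        for t in range(n_taxa):
            m[s, t] = dist[t]

    # newick for reference (rooted at center arbitrarily)
    def nwk(v: int, parent: int) -> str:
        kids = [w for w, _ in adj[v] if w != parent]
        if not kids:
            return labels[v]
        return "(" + ",".join(f"{nwk(w, v)}:{dict(adj[v])[w]}" for w in kids) + ")"

    return nwk(center, -1) + ";", labels, m
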