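"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use the most naive correct formulation
(exhaustive path enumeration, exhaustive subset sweeps, exhaustive DAG
enumeration) so they stay independent of the package's algorithms.
"""

from __future__ import annotations

from itertools import combinations, product

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from causalbn.bn_core import DAG, DiscreteDataset


# ---------------------------------------------------------------------------
# canonical treatment/outcome pathway fixture (synthetic reconstruction)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def pathway_graph():
    """Synthetic fixture of the canonical treatment-outcome pathway taxonomy.

    Measured nodes: a common cause C1; a collider C2 of two unmeasured causes
    (one of treatment, one of outcome); C3a, which transmits unmeasured
    confounding (T <- U1 -> C3a -> Y); a pure outcome cause C3b; a pure
    treatment cause C5; a second collider C6 whose adjustment opens a path
    through the unmeasured U3; and a mediator M1.
    """
    nodes = ["T", "Y", "C1", "C2", "C3a", "C3b", "C5", "C6", "M1", "U1", "U2", "U3"]
    edges = [
        ("C1", "T"), ("C1", "Y"),
        ("U1", "T"), ("U1", "C3a"), ("C3a", "Y"),
        ("U1", "C2"), ("U2", "C2"), ("U2", "Y"),
        ("U1", "C6"), ("U3", "C6"), ("U3", "Y"),
        ("C3b", "Y"), ("C5", "T"),
        ("T", "M1"), ("M1", "Y"),
        ("T", "Y"),
    ]
    return DAG(nodes, edges), {"U1", "U2", "U3"}


# ---------------------------------------------------------------------------
# random structures and data
# ---------------------------------------------------------------------------


def random_dag(rng: np.random.Generator, n_nodes: int, p_edge: float = 0.4) -> DAG:
    names = [f"v{i}" for i in range(n_nodes)]
    order = rng.permutation(n_nodes)
    edges = []
    for i, j in combinations(range(n_nodes), 2):
        if rng.random() < p_edge:
            a, b = order[i], order[j]
            edges.append((names[a], names[b]))
    return DAG(names, edges)


def sample_from_dag(
    dag: DAG, n: int, rng: np.random.Generator, strength: float = 0.35
) -> DiscreteDataset:
    """Binary ancestral sampling with +/- ``strength`` probability shifts."""
    codes: dict[str, np.ndarray] = {}
    for v in dag.topological_order():
        parents = sorted(dag.parents(v))
        base = 0.5
        logits = np.full(n, 0.0)
        for p in parents:
            sign = 1.0 if (hash((v, p)) % 2 == 0) else -1.0
            logits += sign * (codes[p] * 2 - 1)
        prob = np.clip(base + strength * np.tanh(logits), 0.05, 0.95)
        codes[v] = (rng.random(n) < prob).astype(np.int16)
    frame = pd.DataFrame(
        {v: pd.Categorical.from_codes(codes[v], categories=["0", "1"]) for v in dag.nodes}
    )
    return DiscreteDataset.from_frame(frame)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def dsep_path_enumeration(dag: DAG, x: str, y: str, given: set[str]) -> bool:
    """d-separation by brute-force enumeration of all simple paths."""
    an_z = set(given)
    for g in given:
        an_z |= dag.ancestors(g)
    und = nx.Graph()
    und.add_nodes_from(dag.nodes)
    und.add_edges_from(dag.edges)
    if x in given or y in given:
        return True
    for path in nx.all_simple_paths(und, x, y):
        blocked = False
        for i in range(1, len(path) - 1):
            prev, node, nxt = path[i - 1], path[i], path[i + 1]
            collider = dag.has_edge(prev, node) and dag.has_edge(nxt, node)
            if collider:
                if node not in an_z:
                    blocked = True
                    break
            elif node in given:
                blocked = True
                break
        if not blocked:
            return False
    return True


def backdoor_sets_bruteforce(
    dag: DAG, treatment: str, outcome: str, measured: list[str]
) -> list[set[str]]:
    """All minimal valid backdoor sets by plain subset sweep + networkx d-sep."""
    g = dag.to_networkx()
    for child in list(g.successors(treatment)):
        g.remove_edge(treatment, child)
    pool = [
        v
        for v in measured
        if v not in (treatment, outcome) and v not in nx.descendants(dag.to_networkx(), treatment)
    ]
    valid = []
    for size in range(len(pool) + 1):
        for z in combinations(sorted(pool), size):
            zs = set(z)
            if nx.is_d_separator(g, {treatment}, {outcome}, zs):
                valid.append(zs)
    minimal = [s for s in valid if not any(o < s for o in valid)]
    return sorted(minimal, key=lambda s: (len(s), sorted(s)))


def enumerate_all_dags(names: list[str]):
    """Yield every labeled DAG over ``names`` (543 of them for 4 nodes)."""
    pairs = list(combinations(names, 2))
    for directions in product((0, 1, 2), repeat=len(pairs)):
        edges = []
        for (a, b), d in zip(pairs, directions):
            if d == 1:
                edges.append((a, b))
            elif d == 2:
                edges.append((b, a))
        g = nx.DiGraph()
        g.add_nodes_from(names)
        g.add_edges_from(edges)
        if nx.is_directed_acyclic_graph(g):
            yield DAG(names, edges)
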