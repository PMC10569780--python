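"""Structure learning for discrete Bayesian networks under expert constraints.

Three algorithm families are provided, mirroring the constraint-based /
hybrid / exact score-based trichotomy used in causal-discovery practice:

* :func:`learn_constraint_based` — PC-stable skeleton discovery with
  v-structure orientation and Meek-rule propagation, extended with
  NPC-style bookkeeping of *ambiguous regions*: sets of interdependent
  uncertain links where the removal of one edge relied on conditioning on a
  node whose own link was removed for a symmetric reason.  Such regions are
  surfaced for explicit resolution instead of being silently discarded.
* :func:`learn_mmhc` — max-min parents-and-children candidate skeletons
  followed by score-based greedy hill climbing restricted to that skeleton.
* :func:`learn_sm_exact` — globally score-optimal DAG by dynamic programming
  over node subsets (best parent sets, best sinks, order reconstruction).

All learners honour a :class:`~causalbn.bn_core.ConstraintSet`: forbidden
edges are never produced, required edges are always present, and layer
orderings forbid upward edges.  Every learner is deterministic given the data
and configuration; ties are broken lexicographically on node names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np

from .bn_core import (
    DAG,
    ConstraintSet,
    DiscreteDataset,
    ci_test,
    score_family,
    validate_constraints,
)

__all__ = [
    "AmbiguousRegion",
    "LearnedStructure",
    "learn_constraint_based",
    "resolve_ambiguities",
    "default_priority_groups",
    "learn_mmhc",
    "learn_sm_exact",
    "learn_with_whitelist_retry",
]

Edge = frozenset  # undirected edge as a frozenset of two node names


@dataclass
class AmbiguousRegion:
    """A set of interdependent uncertain links awaiting resolution."""

    candidate_edges: set[frozenset[str]]
    dependency_note: str = ""

    def __post_init__(self) -> None:
        if len(self.candidate_edges) < 2:
            raise ValueError("an ambiguous region needs >= 2 candidate edges")


@dataclass
class LearnedStructure:
    """Result of a structure-learning run.

    ``graph`` is the fully directed output; ``skeleton`` the undirected edge
    set it was built from; ``ambiguous`` any unresolved regions (empty except
    for the NPC-like learner before :func:`resolve_ambiguities`).
    """

    graph: DAG
    skeleton: set[frozenset[str]]
    ambiguous: list[AmbiguousRegion]
    algorithm: str
    alpha: float | None
    score_kind: str | None
    resolution_log: list[str] = field(default_factory=list)
    constraints: ConstraintSet = field(default_factory=ConstraintSet)
    sepsets: dict[frozenset[str], set[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# PC-stable skeleton + NPC-style ambiguity bookkeeping
# ---------------------------------------------------------------------------


def _required_pairs(constraints: ConstraintSet) -> set[frozenset[str]]:
    return {frozenset(e) for e in constraints.required}


def _pc_skeleton(
    data: DiscreteDataset,
    constraints: ConstraintSet,
    alpha: float,
    test_kind: str,
    max_cond: int,
):
    names = sorted(data.names)
    required = _required_pairs(constraints)
    adj: dict[str, set[str]] = {v: set() for v in names}
    blocked_pairs: set[frozenset[str]] = set()
    for x, y in combinations(names, 2):
        if not constraints.allows(x, y) and not constraints.allows(y, x):
            blocked_pairs.add(Edge((x, y)))
            continue
        adj[x].add(y)
        adj[y].add(x)

    sepsets: dict[frozenset[str], set[str]] = {}
    removal_level: dict[frozenset[str], int] = {}
    for level in range(max_cond + 1):
        frozen = {v: sorted(adj[v]) for v in names}
        removals: list[tuple[str, str, set[str]]] = []
        any_candidate = False
        for x, y in combinations(names, 2):
            pair = Edge((x, y))
            if y not in adj[x] or pair in required:
                continue
            pools = []
            if len(frozen[x]) - 1 >= level:
                pools.append([z for z in frozen[x] if z != y])
            if len(frozen[y]) - 1 >= level:
                pools.append([z for z in frozen[y] if z != x])
            if not pools:
                continue
            any_candidate = True
            tried: set[frozenset[str]] = set()
            separated = None
            for pool in pools:
                for sub in combinations(pool, level):
                    key = frozenset(sub)
                    if key in tried:
                        continue
                    tried.add(key)
                    res = ci_test(data, x, y, sorted(sub), test_kind)
                    if res.degenerate:
                        continue
                    if res.p_value > alpha:
                        separated = set(sub)
                        break
                if separated is not None:
                    break
            if separated is not None:
                removals.append((x, y, separated))
        for x, y, sep in removals:
            adj[x].discard(y)
            adj[y].discard(x)
            sepsets[Edge((x, y))] = sep
            removal_level[Edge((x, y))] = level
        if not any_candidate:
            break

    skeleton = {Edge((x, y)) for x in names for y in adj[x] if x < y}
    # pairs never eligible for an edge: no sepset information
    for pair in blocked_pairs:
        sepsets.setdefault(pair, set())
    return skeleton, sepsets, removal_level, blocked_pairs


def _ambiguous_regions(
    sepsets: dict[frozenset[str], set[str]],
    removal_level: dict[frozenset[str], int],
) -> list[AmbiguousRegion]:
    """Group removed edges whose separations condition on each other's lost partner.

    Removals (X,Y | S1) and (X,Z | S2) are interdependent when Z is in S1 and
    Y is in S2: each independence statement leaned on the node whose own link
    to X was simultaneously judged absent, so neither removal is certain on
    its own.  Connected groups of such removals form one ambiguous region.
    """
    removed = sorted(removal_level, key=lambda e: tuple(sorted(e)))
    parent: dict[frozenset[str], frozenset[str]] = {e: e for e in removed}

    def find(e):
        while parent[e] != e:
            parent[e] = parent[parent[e]]
            e = parent[e]
        return e

    notes: list[str] = []
    for e1, e2 in combinations(removed, 2):
        shared = e1 & e2
        if len(shared) != 1:
            continue
        (x,) = shared
        (y,) = e1 - shared
        (z,) = e2 - shared
        if z in sepsets[e1] and y in sepsets[e2]:
            parent[find(e1)] = find(e2)
            notes.append(
                f"removal of {sorted(e1)} conditioned on {z}; "
                f"removal of {sorted(e2)} conditioned on {y}"
            )

    groups: dict[frozenset[str], set[frozenset[str]]] = {}
    for e in removed:
        groups.setdefault(find(e), set()).add(e)
    regions = []
    for members in sorted(groups.values(), key=lambda s: sorted(map(sorted, s))):
        if len(members) >= 2:
            note = "; ".join(n for n in notes if any(str(sorted(m)) in n for m in members))
            regions.append(AmbiguousRegion(set(members), note))
    return regions


# ---------------------------------------------------------------------------
# orientation: v-structures, Meek rules, layered fallback
# ---------------------------------------------------------------------------


class _PDAG:
    """Partially directed graph used during orientation."""

    def __init__(self, nodes: Sequence[str], skeleton: set[frozenset[str]]):
        self.nodes = sorted(nodes)
        self.undirected: set[frozenset[str]] = set(skeleton)
        self.directed: set[tuple[str, str]] = set()

    def adjacent(self, u: str, v: str) -> bool:
        return (
            Edge((u, v)) in self.undirected
            or (u, v) in self.directed
            or (v, u) in self.directed
        )

    def neighbors(self, v: str) -> set[str]:
        out = {next(iter(e - {v})) for e in self.undirected if v in e}
        out |= {b for a, b in self.directed if a == v}
        out |= {a for a, b in self.directed if b == v}
        return out

    def orient(self, u: str, v: str) -> bool:
        e = Edge((u, v))
        if e in self.undirected:
            self.undirected.discard(e)
            self.directed.add((u, v))
            return True
        return False

    def has_directed_path(self, u: str, v: str) -> bool:
        stack, seen = [u], set()
        while stack:
            w = stack.pop()
            for a, b in self.directed:
                if a == w and b not in seen:
                    if b == v:
                        return True
                    seen.add(b)
                    stack.append(b)
        return False


def _orient(
    skeleton: set[frozenset[str]],
    sepsets: dict[frozenset[str], set[str]],
    nodes: Sequence[str],
    constraints: ConstraintSet,
    log: list[str],
) -> DAG:
    pdag = _PDAG(nodes, skeleton)

    for u, v in sorted(constraints.required):
        if Edge((u, v)) in pdag.undirected:
            pdag.orient(u, v)

    def allowed(u: str, v: str) -> bool:
        return constraints.allows(u, v)

    # v-structures: x - z - y with x,y non-adjacent and z outside sepset(x,y)
    for z in pdag.nodes:
        nbrs = sorted(e for e in pdag.undirected if z in e)
        for e1, e2 in combinations(nbrs, 2):
            (x,) = e1 - {z}
            (y,) = e2 - {z}
            if pdag.adjacent(x, y):
                continue
            pair = Edge((x, y))
            if pair not in sepsets:
                continue
            if z not in sepsets[pair]:
                if allowed(x, z) and allowed(y, z):
                    pdag.orient(x, z)
                    pdag.orient(y, z)
                    log.append(f"v-structure {x} -> {z} <- {y}")

    _meek(pdag, allowed)

    # fallback: orient leftovers down the layer ordering, lexicographic in ties
    ranks = constraints.layers or {}
    while pdag.undirected:
        e = min(pdag.undirected, key=lambda s: tuple(sorted(s)))
        a, b = sorted(e)
        ra, rb = ranks.get(a, 0), ranks.get(b, 0)
        first = (a, b) if ra <= rb else (b, a)
        second = (first[1], first[0])
        for u, v in (first, second):
            if allowed(u, v) and not pdag.has_directed_path(v, u):
                pdag.orient(u, v)
                log.append(f"fallback orientation {u} -> {v}")
                break
        else:  # pragma: no cover - pathological orientation conflict
            pdag.undirected.discard(e)
            log.append(f"dropped unorientable edge {a} - {b}")
        _meek(pdag, allowed)

    dag = DAG(pdag.nodes)
    for u, v in sorted(pdag.directed):
        try:
            dag.add_edge(u, v)
        except ValueError:
            log.append(f"dropped cycle-inducing edge {u} -> {v}")
    return dag


def _meek(pdag: _PDAG, allowed: Callable[[str, str], bool]) -> None:
    """Meek rules R1-R4, constraint-aware, to a fixpoint."""
    changed = True
    while changed:
        changed = False
        for e in sorted(pdag.undirected, key=lambda s: tuple(sorted(s))):
            a, b = sorted(e)
            for u, v in ((a, b), (b, a)):
                if not allowed(u, v):
                    continue
                if _meek_applies(pdag, u, v):
                    pdag.orient(u, v)
                    changed = True
                    break
            if changed:
                break


def _meek_applies(pdag: _PDAG, u: str, v: str) -> bool:
    din = {a for a, b in pdag.directed if b == u}
    # R1: w -> u, w and v non-adjacent  =>  u -> v
    for w in din:
        if not pdag.adjacent(w, v):
            return True
    # R2: directed path u -> ... -> v of length 2  =>  u -> v
    for w in {b for a, b in pdag.directed if a == u}:
        if (w, v) in pdag.directed:
            return True
    # R3: u - w1, u - w2, w1 -> v, w2 -> v, w1,w2 non-adjacent  =>  u -> v
    into_v = {a for a, b in pdag.directed if b == v}
    linked = [w for w in into_v if Edge((u, w)) in pdag.undirected]
    for w1, w2 in combinations(sorted(linked), 2):
        if not pdag.adjacent(w1, w2):
            return True
    # R4: u - w, w -> z, z -> v, u - z, w,v non-adjacent  =>  u -> v
    for w in sorted(pdag.neighbors(u)):
        if Edge((u, w)) not in pdag.undirected:
            continue
        for z in {b for a, b in pdag.directed if a == w}:
            if (z, v) in pdag.directed and Edge((u, z)) in pdag.undirected:
                if not pdag.adjacent(w, v):
                    return True
    return False


def learn_constraint_based(
    data: DiscreteDataset,
    constraints: ConstraintSet | None = None,
    alpha: float = 0.05,
    test_kind: str = "G2",
    max_cond: int = 3,
) -> LearnedStructure:
    """NPC-like constraint-based learner (PC-stable + ambiguous regions).

    The skeleton is discovered with conditional-independence tests of
    increasing order restricted to current adjacency neighbourhoods;
    v-structures are oriented from separating sets, Meek rules propagate, and
    leftovers are oriented down the layer ordering.  Interdependent uncertain
    removals are reported as :class:`AmbiguousRegion` rather than silently
    dropped; apply :func:`resolve_ambiguities` to settle them.
    """
    constraints = constraints or ConstraintSet()
    if len(data.names) < 2:
        raise ValueError("need at least two variables")
    skeleton, sepsets, removal_level, _ = _pc_skeleton(
        data, constraints, alpha, test_kind, max_cond
    )
    regions = _ambiguous_regions(
        {e: s for e, s in sepsets.items() if e in removal_level}, removal_level
    )
    log: list[str] = []
    dag = _orient(skeleton, sepsets, data.names, constraints, log)
    return LearnedStructure(
        graph=dag,
        skeleton=skeleton,
        ambiguous=regions,
        algorithm="NPC-like",
        alpha=alpha,
        score_kind=None,
        resolution_log=log,
        constraints=constraints,
        sepsets=sepsets,
    )


def default_priority_groups(names: Sequence[str]) -> list[set[str]]:
    """Outcome nodes first (recurrence and survival), then treatment nodes."""
    outcome = {n for n in names if n.startswith(("surv_", "rec_"))}
    treatment = {n for n in names if n in ("treatment", "adj_therapy", "regimen")}
    return [outcome, treatment]


def resolve_ambiguities(
    structure: LearnedStructure,
    policy: Sequence[set[str]] | None = None,
) -> LearnedStructure:
    """Settle ambiguous regions by keeping one candidate edge per region.

    Within each region the kept edge is the one incident to the
    highest-priority node group (default: outcome nodes, then treatment
    nodes); ties and regions touching no prioritized group fall back to the
    lexicographically first edge.  Kept edges rejoin the skeleton and the
    graph is re-oriented; all choices are appended to the resolution log.
    """
    if not structure.ambiguous:
        return structure
    if policy is None:
        policy = default_priority_groups(structure.graph.nodes)

    log = list(structure.resolution_log)
    skeleton = set(structure.skeleton)
    for region in structure.ambiguous:
        candidates = sorted(region.candidate_edges, key=lambda e: tuple(sorted(e)))
        keep = None
        for group in policy:
            hits = [e for e in candidates if e & group]
            if hits:
                keep = hits[0]
                log.append(
                    f"region {sorted(map(sorted, candidates))}: kept "
                    f"{sorted(keep)} (priority group {sorted(group)})"
                )
                break
        if keep is None:
            keep = candidates[0]
            log.append(
                f"region {sorted(map(sorted, candidates))}: no prioritized "
                f"group touched; kept {sorted(keep)} (lexicographic fallback)"
            )
        skeleton.add(keep)

    dag = _orient(
        skeleton, structure.sepsets, structure.graph.nodes, structure.constraints, log
    )
    return LearnedStructure(
        graph=dag,
        skeleton=skeleton,
        ambiguous=[],
        algorithm=structure.algorithm,
        alpha=structure.alpha,
        score_kind=structure.score_kind,
        resolution_log=log,
        constraints=structure.constraints,
        sepsets=structure.sepsets,
    )


# ---------------------------------------------------------------------------
# MMHC: max-min parents-and-children + hill climbing
# ---------------------------------------------------------------------------


def _mmpc_one(
    data: DiscreteDataset,
    target: str,
    constraints: ConstraintSet,
    alpha: float,
    test_kind: str,
    max_cond: int,
) -> set[str]:
    names = sorted(n for n in data.names if n != target)
    required = {
        u for u, v in constraints.required if v == target
    } | {v for u, v in constraints.required if u == target}
    eligible = [
        n
        for n in names
        if constraints.allows(n, target) or constraints.allows(target, n)
    ]

    def max_p(x: str, cpc: list[str]) -> float:
        """Weakest association of x with target over subsets of the CPC."""
        worst = 0.0
        pools = [()]
        for size in range(1, min(max_cond, len(cpc)) + 1):
            pools.extend(combinations(cpc, size))
        for sub in pools:
            res = ci_test(data, x, target, sorted(sub), test_kind)
            if res.degenerate:
                continue
            worst = max(worst, res.p_value)
            if worst > alpha:
                break
        return worst

    cpc: list[str] = sorted(required)
    candidates = [n for n in eligible if n not in cpc]
    while True:
        best_x, best_p = None, alpha
        for x in candidates:
            p = max_p(x, cpc)
            if p < best_p or (best_x is not None and p == best_p and x < best_x):
                best_x, best_p = x, p
        if best_x is None:
            break
        cpc.append(best_x)
        candidates.remove(best_x)
    # backward: drop members separated given some subset of the others
    for x in sorted(cpc):
        if x in required:
            continue
        others = [c for c in cpc if c != x]
        if max_p(x, others) > alpha:
            cpc.remove(x)
    return set(cpc)


def _hill_climb(
    data: DiscreteDataset,
    allowed_pairs: set[frozenset[str]],
    constraints: ConstraintSet,
    score_kind: str,
    log: list[str],
) -> DAG:
    names = sorted(data.names)
    cache: dict[tuple[str, frozenset[str]], float] = {}

    def fam(child: str, parents: frozenset[str]) -> float:
        key = (child, parents)
        if key not in cache:
            cache[key] = score_family(data, child, sorted(parents), score_kind)
        return cache[key]

    dag = DAG(names)
    for u, v in sorted(constraints.required):
        dag.add_edge(u, v)

    eps = 1e-9
    while True:
        best: list = [eps, None]  # [delta, op]; strictly improving moves only

        def consider(delta: float, op: tuple) -> None:
            if delta > best[0] + eps or (
                best[1] is not None and abs(delta - best[0]) <= eps and op < best[1]
            ):
                best[0], best[1] = delta, op

        for u, v in ((a, b) for a in names for b in names if a != b):
            pv = frozenset(dag.parents(v))
            if dag.has_edge(u, v):
                if (u, v) in constraints.required:
                    continue
                consider(fam(v, pv - {u}) - fam(v, pv), ("delete", u, v))
                if constraints.allows(v, u):
                    dag.remove_edge(u, v)
                    cyclic = v in dag.descendants(u)
                    dag.add_edge(u, v, check_acyclic=False)
                    if not cyclic:
                        pu = frozenset(dag.parents(u))
                        delta = (
                            fam(v, pv - {u})
                            - fam(v, pv)
                            + fam(u, pu | {v})
                            - fam(u, pu)
                        )
                        consider(delta, ("reverse", u, v))
            else:
                if Edge((u, v)) not in allowed_pairs:
                    continue
                if dag.has_edge(v, u) or not constraints.allows(u, v):
                    continue
                if u in dag.descendants(v):
                    continue  # adding u->v would close a cycle
                consider(fam(v, pv | {u}) - fam(v, pv), ("add", u, v))
        if best[1] is None:
            break
        kind, u, v = best[1]
        if kind == "add":
            dag.add_edge(u, v)
        elif kind == "delete":
            dag.remove_edge(u, v)
        else:
            dag.remove_edge(u, v)
            dag.add_edge(v, u)
        log.append(f"hill-climb {kind} {u} -> {v} (delta {best[0]:.4f})")
    return dag


def learn_mmhc(
    data: DiscreteDataset,
    constraints: ConstraintSet | None = None,
    alpha: float = 0.05,
    score_kind: str = "BIC",
    test_kind: str = "G2",
    max_cond: int = 3,
) -> LearnedStructure:
    """Hybrid max-min hill-climbing learner.

    Stage 1 builds per-node candidate parent/child sets with the max-min
    heuristic at significance ``alpha`` (an edge survives only if each
    endpoint selects the other).  Stage 2 hill-climbs add/delete/reverse moves
    over edges permitted by both the candidate skeleton and the constraints,
    maximizing the decomposable score; deterministic lexicographic
    tie-breaking makes the run reproducible.
    """
    constraints = constraints or ConstraintSet()
    if len(data.names) < 2:
        raise ValueError("need at least two variables")
    cpcs = {
        t: _mmpc_one(data, t, constraints, alpha, test_kind, max_cond)
        for t in sorted(data.names)
    }
    skeleton = {
        Edge((x, y))
        for x in data.names
        for y in cpcs[x]
        if x in cpcs[y]
    }
    skeleton |= _required_pairs(constraints)
    log: list[str] = []
    dag = _hill_climb(data, skeleton, constraints, score_kind, log)
    return LearnedStructure(
        graph=dag,
        skeleton={Edge((u, v)) for u, v in dag.edges},
        ambiguous=[],
        algorithm="MMHC",
        alpha=alpha,
        score_kind=score_kind,
        resolution_log=log,
        constraints=constraints,
    )


# ---------------------------------------------------------------------------
# exact search by dynamic programming over node subsets
# ---------------------------------------------------------------------------


def learn_sm_exact(
    data: DiscreteDataset,
    constraints: ConstraintSet | None = None,
    score_kind: str = "BIC",
    max_parents: int = 4,
) -> LearnedStructure:
    """Globally optimal DAG by dynamic programming (Silander-Myllymaki style).

    Enumerates local scores for every admissible parent set (respecting
    forbidden/required edges and ``max_parents``), computes best parent sets
    per candidate pool and best sinks per node subset, and reconstructs the
    optimal ordering.  Exact but exponential in the variable count, hence the
    hard cap of 20 variables.
    """
    constraints = constraints or ConstraintSet()
    names = sorted(data.names)
    p = len(names)
    if p > 20:
        raise ValueError("exact search supports at most 20 variables")
    idx = {n: i for i, n in enumerate(names)}
    full = (1 << p) - 1

    required_parents = [0] * p
    for u, v in constraints.required:
        required_parents[idx[v]] |= 1 << idx[u]
    candidate = []
    for v in names:
        mask = 0
        for u in names:
            if u != v and constraints.allows(u, v):
                mask |= 1 << idx[u]
        mask |= required_parents[idx[v]]
        candidate.append(mask)

    # local scores for admissible parent sets
    neg = -np.inf
    bp_score = [np.full(1 << p, neg) for _ in range(p)]
    bp_choice = [np.zeros(1 << p, dtype=np.int64) for _ in range(p)]
    for vi, v in enumerate(names):
        req = required_parents[vi]
        pool = [i for i in range(p) if candidate[vi] >> i & 1]
        limit = max(max_parents, bin(req).count("1"))
        local: dict[int, float] = {}
        for size in range(limit + 1):
            for combo in combinations(pool, size):
                mask = 0
                for i in combo:
                    mask |= 1 << i
                if mask & req != req:
                    continue
                parents = [names[i] for i in combo]
                local[mask] = score_family(data, v, parents, score_kind)
        # best admissible parent set within each candidate pool, by subset DP
        sc = bp_score[vi]
        ch = bp_choice[vi]
        for mask, s in local.items():
            sc[mask] = s
            ch[mask] = mask
        for mask in range(1 << p):
            if mask & (1 << vi):
                continue
            m = mask
            while m:
                low = m & -m
                sub = mask ^ low
                if sc[sub] > sc[mask]:
                    sc[mask] = sc[sub]
                    ch[mask] = ch[sub]
                m ^= low
    # best sinks over subsets
    best = np.full(1 << p, neg)
    sink = np.full(1 << p, -1, dtype=np.int64)
    best[0] = 0.0
    for mask in range(1, 1 << p):
        m = mask
        while m:
            low = m & -m
            vi = low.bit_length() - 1
            rest = mask ^ low
            s = best[rest] + bp_score[vi][rest]
            if s > best[mask]:
                best[mask] = s
                sink[mask] = vi
            m ^= low
    if not np.isfinite(best[full]):
        raise ValueError("constraints admit no DAG within the parent-set limit")

    dag = DAG(names)
    mask = full
    while mask:
        vi = int(sink[mask])
        rest = mask ^ (1 << vi)
        pmask = int(bp_choice[vi][rest])
        for ui in range(p):
            if pmask >> ui & 1:
                dag.add_edge(names[ui], names[vi])
        mask = rest

    return LearnedStructure(
        graph=dag,
        skeleton={Edge((u, v)) for u, v in dag.edges},
        ambiguous=[],
        algorithm="SM-exact",
        alpha=None,
        score_kind=score_kind,
        resolution_log=[],
        constraints=constraints,
    )


# ---------------------------------------------------------------------------
# whitelist retry loop
# ---------------------------------------------------------------------------

_ALGORITHMS: dict[str, Callable[..., LearnedStructure]] = {}


def _register_algorithms() -> None:
    _ALGORITHMS.update(
        npc_like=lambda data, constraints, alpha, score_kind: resolve_ambiguities(
            learn_constraint_based(data, constraints, alpha)
        ),
        mmhc=lambda data, constraints, alpha, score_kind: learn_mmhc(
            data, constraints, alpha, score_kind
        ),
        sm_exact=lambda data, constraints, alpha, score_kind: learn_sm_exact(
            data, constraints, score_kind
        ),
    )


_register_algorithms()


def learn_with_whitelist_retry(
    data: DiscreteDataset,
    constraints: ConstraintSet | None = None,
    algorithm: str | Callable[..., LearnedStructure] = "npc_like",
    alpha: float = 0.05,
    score_kind: str = "BIC",
    max_iterations: int = 5,
) -> LearnedStructure:
    """Run a learner, whitelist the corrections of any blacklist violations, retry.

    Mirrors the manual workflow of adding the correctly directed counterpart
    of each misdirected edge to a minimal whitelist of enforced edges and
    repeating structure learning until the output is compliant (or the
    iteration cap is hit).
    """
    constraints = constraints or ConstraintSet()
    learner = _ALGORITHMS[algorithm] if isinstance(algorithm, str) else algorithm
    current = ConstraintSet(
        forbidden=set(constraints.forbidden),
        required=set(constraints.required),
        layers=dict(constraints.layers) if constraints.layers else None,
    )
    for iteration in range(1, max_iterations + 1):
        structure = learner(data, current, alpha, score_kind)
        violations = validate_constraints(structure.graph, current)
        if not violations:
            structure.resolution_log.append(
                f"whitelist retry converged after {iteration} run(s)"
            )
            return structure
        for u, v in sorted(structure.graph.edges):
            if (u, v) in current.forbidden and current.allows(v, u):
                current.required.add((v, u))
        current = ConstraintSet(
            forbidden=current.forbidden,
            required=current.required,
            layers=current.layers,
        )
    raise RuntimeError(
        f"structure learning did not satisfy constraints after {max_iterations} retries"
    )
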