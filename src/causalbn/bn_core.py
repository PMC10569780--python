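"""Discrete-data foundations for causal Bayesian-network analysis.

This module provides the substrate everything else builds on: categorical
datasets with missing values, directed acyclic graphs, conditional-independence
tests (Pearson chi-squared and G² likelihood-ratio), decomposable network
scores (BIC, BDeu), d-separation, and expert knowledge constraints expressed as
edge blacklists/whitelists or as ordered layers.

Missing values are handled by test-wise / family-wise complete-case deletion:
every statistic drops the records that have an NA in any of the variables it
touches.  This matches the administrative-censoring origin of the missingness
in discretized survival outcomes, where follow-up simply ended before the
horizon of a yearly outcome node.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from math import lgamma, log
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "Variable",
    "DiscreteDataset",
    "DAG",
    "ConstraintSet",
    "CITestResult",
    "NetworkScore",
    "ci_test",
    "score_family",
    "score_network",
    "d_separated",
    "constraints_from_layers",
    "validate_constraints",
    "write_dot",
    "read_dot",
    "write_graphml",
    "read_graphml",
    "write_constraints",
    "read_constraints",
]

NA = -1  # integer code marking a missing value


@dataclass(frozen=True)
class Variable:
    """A categorical variable: a name, its ordered levels, and an optional layer rank.

    The layer rank encodes expert temporal/causal ordering knowledge: rank 0 is
    the topmost layer and edges may only run from lower to higher (or equal)
    rank.
    """

    name: str
    levels: tuple[str, ...]
    layer: int | None = None

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"variable {self.name!r} needs >= 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"variable {self.name!r} has duplicate levels")
        if self.layer is not None and self.layer < 0:
            raise ValueError("layer rank must be non-negative")

    @property
    def cardinality(self) -> int:
        return len(self.levels)


class DiscreteDataset:
    """Records of categorical observations with missing values.

    Internally stores an ``(n, p)`` int16 code matrix where ``-1`` marks NA;
    level labels live on the :class:`Variable` objects.  Construct from a
    pandas DataFrame with :meth:`from_frame`.
    """

    def __init__(self, variables: Sequence[Variable], codes: np.ndarray):
        codes = np.asarray(codes, dtype=np.int16)
        if codes.ndim != 2 or codes.shape[1] != len(variables):
            raise ValueError("codes must be (n, p) with one column per variable")
        if codes.shape[0] < 1:
            raise ValueError("dataset needs at least one record")
        for j, v in enumerate(variables):
            col = codes[:, j]
            if col.max(initial=-1) >= v.cardinality or col.min(initial=0) < -1:
                raise ValueError(f"column {v.name!r} contains out-of-range codes")
        self.variables: tuple[Variable, ...] = tuple(variables)
        self.codes = codes
        self._index = {v.name: j for j, v in enumerate(self.variables)}
        if len(self._index) != len(self.variables):
            raise ValueError("duplicate variable names")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        levels: Mapping[str, Sequence[str]] | None = None,
        layers: Mapping[str, int] | None = None,
    ) -> "DiscreteDataset":
        """Build a dataset from a DataFrame of categorical/object columns.

        NaN/None/pd.NA become missing values.  ``levels`` fixes the level
        order per column; otherwise levels are the sorted observed labels.
        """
        variables: list[Variable] = []
        cols: list[np.ndarray] = []
        for name in df.columns:
            s = df[name]
            if isinstance(s.dtype, pd.CategoricalDtype) and levels is None:
                lv = tuple(str(x) for x in s.cat.categories)
            elif levels is not None and name in levels:
                lv = tuple(str(x) for x in levels[name])
            else:
                lv = tuple(sorted(str(x) for x in s.dropna().unique()))
            cat = pd.Categorical(s.astype(object).where(s.notna(), None), categories=lv)
            variables.append(
                Variable(str(name), lv, None if layers is None else layers.get(str(name)))
            )
            cols.append(cat.codes.astype(np.int16))
        return cls(variables, np.column_stack(cols))

    def to_frame(self) -> pd.DataFrame:
        data = {}
        for j, v in enumerate(self.variables):
            data[v.name] = pd.Categorical.from_codes(
                self.codes[:, j].astype(np.int64), categories=list(v.levels)
            )
        return pd.DataFrame(data)

    # -- access ------------------------------------------------------------

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def variable(self, name: str) -> Variable:
        return self.variables[self._index[name]]

    def column(self, name: str) -> np.ndarray:
        return self.codes[:, self._index[name]]

    def cardinality(self, name: str) -> int:
        return self.variables[self._index[name]].cardinality

    def select(self, names: Sequence[str]) -> "DiscreteDataset":
        idx = [self._index[n] for n in names]
        return DiscreteDataset([self.variables[i] for i in idx], self.codes[:, idx])


class DAG:
    """A directed acyclic graph over named nodes.

    Stores parent/child adjacency as dicts of sets; acyclicity is enforced on
    every mutation via :meth:`topological_order`.
    """

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]] = ()):
        self.nodes: list[str] = list(dict.fromkeys(nodes))
        self._parents: dict[str, set[str]] = {v: set() for v in self.nodes}
        self._children: dict[str, set[str]] = {v: set() for v in self.nodes}
        for u, v in edges:
            self.add_edge(u, v)

    # -- mutation ----------------------------------------------------------

    def add_edge(self, u: str, v: str, check_acyclic: bool = True) -> None:
        if u == v:
            raise ValueError("self-loops are not allowed")
        if u not in self._parents or v not in self._parents:
            raise KeyError(f"unknown node in edge ({u!r}, {v!r})")
        self._children[u].add(v)
        self._parents[v].add(u)
        if check_acyclic and self.topological_order() is None:
            self.remove_edge(u, v)
            raise ValueError(f"edge {u!r}->{v!r} would create a cycle")

    def remove_edge(self, u: str, v: str) -> None:
        self._children[u].discard(v)
        self._parents[v].discard(u)

    # -- queries -----------------------------------------------------------

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._children.get(u, ())

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {(u, v) for u, cs in self._children.items() for v in cs}

    def parents(self, v: str) -> set[str]:
        return set(self._parents[v])

    def children(self, v: str) -> set[str]:
        return set(self._children[v])

    def skeleton(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.edges}

    def topological_order(self) -> list[str] | None:
        """Kahn's algorithm; returns None when a cycle exists."""
        indeg = {v: len(self._parents[v]) for v in self.nodes}
        queue = sorted(v for v, d in indeg.items() if d == 0)
        order: list[str] = []
        while queue:
            v = queue.pop(0)
            order.append(v)
            for c in sorted(self._children[v]):
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        return order if len(order) == len(self.nodes) else None

    def _reach(self, start: str, adj: dict[str, set[str]]) -> set[str]:
        seen: set[str] = set()
        stack = [start]
        while stack:
            v = stack.pop()
            for w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return seen

    def ancestors(self, v: str) -> set[str]:
        return self._reach(v, self._parents)

    def descendants(self, v: str) -> set[str]:
        return self._reach(v, self._children)

    def copy(self) -> "DAG":
        return DAG(self.nodes, self.edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.DiGraph) -> "DAG":
        return cls(g.nodes, g.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DAG):
            return NotImplemented
        return set(self.nodes) == set(other.nodes) and self.edges == other.edges

    def __repr__(self) -> str:
        return f"DAG({len(self.nodes)} nodes, {len(self.edges)} edges)"


@dataclass
class ConstraintSet:
    """Expert knowledge constraints: forbidden edges, required edges, layers.

    ``layers`` maps node -> rank with rank 0 the topmost layer; an edge u->v is
    admissible iff rank(u) <= rank(v).  The pairwise prohibitions implied by
    layers are merged into ``forbidden`` by :func:`constraints_from_layers`.
    """

    forbidden: set[tuple[str, str]] = field(default_factory=set)
    required: set[tuple[str, str]] = field(default_factory=set)
    layers: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.forbidden = set(self.forbidden)
        self.required = set(self.required)
        if self.forbidden & self.required:
            raise ValueError("an edge cannot be both forbidden and required")
        if self.required:
            nodes = {n for e in self.required for n in e}
            DAG(nodes, self.required)  # raises on a cycle among required edges
        if self.layers is not None:
            implied = _layer_forbidden(self.layers)
            if self.required & implied:
                raise ValueError("a required edge contradicts the layer ordering")
            self.forbidden |= implied

    def allows(self, u: str, v: str) -> bool:
        return (u, v) not in self.forbidden

    @classmethod
    def empty(cls) -> "ConstraintSet":
        return cls()


@dataclass
class CITestResult:
    """Outcome of a conditional-independence test on discrete data.

    ``degenerate`` flags tests where no complete cases remained or a tested
    variable was constant; such results carry ``p_value = nan`` so callers
    cannot mistake them for evidence of independence.
    """

    statistic: float
    df: int
    p_value: float
    n_effective: int
    test_kind: str
    degenerate: bool = False


@dataclass
class NetworkScore:
    """Decomposable network score: total is the sum of per-family terms."""

    total: float
    per_family: dict[str, float]
    score_kind: str
    hyperparameters: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# counting helpers
# ---------------------------------------------------------------------------


def _complete_cases(data: DiscreteDataset, names: Sequence[str]) -> np.ndarray:
    cols = [data.column(n) for n in names]
    mask = np.ones(data.n, dtype=bool)
    for c in cols:
        mask &= c >= 0
    return mask


def _joint_counts(
    data: DiscreteDataset, names: Sequence[str], mask: np.ndarray
) -> np.ndarray:
    """Contingency counts over ``names`` (complete cases only), shape = cards."""
    cards = [data.cardinality(n) for n in names]
    flat = np.zeros(mask.sum(), dtype=np.int64)
    for n, card in zip(names, cards):
        flat = flat * card + data.column(n)[mask]
    counts = np.bincount(flat, minlength=int(np.prod(cards)))
    return counts.reshape(cards)


# ---------------------------------------------------------------------------
# conditional-independence tests
# ---------------------------------------------------------------------------


def ci_test(
    data: DiscreteDataset,
    x: str,
    y: str,
    given: Sequence[str] = (),
    test_kind: str = "G2",
) -> CITestResult:
    """Test X independent of Y given Z by a stratified chi-squared statistic.

    ``test_kind`` selects Pearson's X² or the G² likelihood-ratio statistic
    (default); both are referred to a chi-squared distribution with
    ``(|X|-1)(|Y|-1) * (number of non-empty Z strata)`` degrees of freedom.
    Records with an NA in any tested variable are dropped first.
    """
    given = list(given)
    if x == y or x in given or y in given:
        raise ValueError("x, y and the conditioning set must be distinct")
    if test_kind not in ("Pearson", "G2"):
        raise ValueError(f"unknown test_kind {test_kind!r}")

    names = [x, y, *given]
    mask = _complete_cases(data, names)
    n_eff = int(mask.sum())
    rx, ry = data.cardinality(x), data.cardinality(y)

    def _degenerate() -> CITestResult:
        return CITestResult(0.0, 1, float("nan"), n_eff, test_kind, degenerate=True)

    if n_eff == 0:
        return _degenerate()
    cx = data.column(x)[mask]
    cy = data.column(y)[mask]
    if cx.min() == cx.max() or cy.min() == cy.max():
        return _degenerate()

    if given:
        stratum = np.zeros(n_eff, dtype=np.int64)
        q = 1
        for z in given:
            stratum = stratum * data.cardinality(z) + data.column(z)[mask]
            q *= data.cardinality(z)
        tables = np.zeros((q, rx, ry), dtype=np.int64)
        np.add.at(tables, (stratum, cx, cy), 1)
    else:
        tables = np.zeros((1, rx, ry), dtype=np.int64)
        np.add.at(tables, (0, cx, cy), 1)

    stat = 0.0
    nonempty = 0
    for t in tables:
        nk = t.sum()
        if nk == 0:
            continue
        nonempty += 1
        row = t.sum(axis=1, keepdims=True)
        col = t.sum(axis=0, keepdims=True)
        expected = row * col / nk
        if test_kind == "Pearson":
            with np.errstate(divide="ignore", invalid="ignore"):
                contrib = np.where(expected > 0, (t - expected) ** 2 / expected, 0.0)
            stat += float(contrib.sum())
        else:
            obs = t[t > 0].astype(float)
            exp = expected[t > 0]
            stat += float(2.0 * np.sum(obs * np.log(obs / exp)))

    df = max((rx - 1) * (ry - 1) * nonempty, 1)
    p = float(chi2.sf(stat, df))
    return CITestResult(float(stat), int(df), p, n_eff, test_kind)


# ---------------------------------------------------------------------------
# decomposable scores
# ---------------------------------------------------------------------------


def score_family(
    data: DiscreteDataset,
    child: str,
    parents: Sequence[str],
    score_kind: str = "BIC",
    ess: float = 1.0,
) -> float:
    """Score one node family (child given its parent set); natural logs.

    BIC: maximized multinomial log-likelihood minus
    ``(ln n / 2) * (|child| - 1) * prod(|parent|)``, with family-wise
    complete-case deletion.  BDeu uses a uniform Dirichlet prior with
    equivalent sample size ``ess``.
    """
    parents = sorted(parents)
    if child in parents:
        raise ValueError("child cannot be its own parent")
    names = [child, *parents]
    mask = _complete_cases(data, names)
    n_eff = int(mask.sum())
    r = data.cardinality(child)
    q = int(np.prod([data.cardinality(p) for p in parents])) if parents else 1
    if n_eff == 0:
        return 0.0

    counts = _joint_counts(data, [*parents, child], mask).reshape(q, r)
    row = counts.sum(axis=1)

    if score_kind == "BIC":
        obs = counts[counts > 0].astype(float)
        rep = np.repeat(row, r).reshape(q, r)[counts > 0].astype(float)
        ll = float(np.sum(obs * np.log(obs / rep)))
        return ll - 0.5 * log(n_eff) * (r - 1) * q
    if score_kind == "BDeu":
        a_j = ess / q
        a_jk = ess / (q * r)
        score = 0.0
        for j in range(q):
            if row[j] == 0:
                continue
            score += lgamma(a_j) - lgamma(a_j + row[j])
            for k in range(r):
                if counts[j, k] > 0:
                    score += lgamma(a_jk + counts[j, k]) - lgamma(a_jk)
        return score
    raise ValueError(f"unknown score_kind {score_kind!r}")


def score_network(
    data: DiscreteDataset, dag: DAG, score_kind: str = "BIC", ess: float = 1.0
) -> NetworkScore:
    """Score a DAG as the sum of its family scores (decomposability)."""
    missing = [v for v in dag.nodes if v not in data.names]
    if missing:
        raise KeyError(f"nodes not in dataset: {missing}")
    per = {
        v: score_family(data, v, sorted(dag.parents(v)), score_kind, ess)
        for v in dag.nodes
    }
    hyper = {"ess": ess} if score_kind == "BDeu" else {}
    return NetworkScore(sum(per.values()), per, score_kind, hyper)


# ---------------------------------------------------------------------------
# d-separation
# ---------------------------------------------------------------------------


def d_separated(dag: DAG, x: str, y: str, given: Iterable[str] = ()) -> bool:
    """Decide whether ``given`` d-separates x and y in ``dag``.

    Reachability formulation: a path is blocked iff it contains a non-collider
    in the conditioning set, or a collider with no descendant (including
    itself) in the conditioning set.  Runs in O(V + E).
    """
    z = set(given)
    for node in (x, y, *z):
        if node not in dag._parents:
            raise KeyError(f"unknown node {node!r}")
    if x == y:
        raise ValueError("x and y must differ")

    # colliders are open iff they are in An(Z) (ancestor-of-or-in Z)
    an_z: set[str] = set(z)
    for g in z:
        an_z |= dag.ancestors(g)

    UP, DOWN = 0, 1  # UP: arrived from a child; DOWN: arrived from a parent
    visited: set[tuple[str, int]] = set()
    stack: list[tuple[str, int]] = [(x, UP)]
    while stack:
        v, d = stack.pop()
        if (v, d) in visited:
            continue
        visited.add((v, d))
        if v == y and v not in z:
            return False
        if d == UP and v not in z:
            for p in dag._parents[v]:
                stack.append((p, UP))
            for c in dag._children[v]:
                stack.append((c, DOWN))
        elif d == DOWN:
            if v not in z:
                for c in dag._children[v]:
                    stack.append((c, DOWN))
            if v in an_z:
                for p in dag._parents[v]:
                    stack.append((p, UP))
    return True


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------


def _layer_forbidden(layer_map: Mapping[str, int]) -> set[tuple[str, str]]:
    return {
        (u, v)
        for u, ru in layer_map.items()
        for v, rv in layer_map.items()
        if u != v and ru > rv
    }


def constraints_from_layers(layer_map: Mapping[str, int]) -> ConstraintSet:
    """Expand a layer ordering into the pairwise blacklist it implies.

    Rank 0 is the topmost layer; an edge u -> v is allowed iff
    ``rank(u) <= rank(v)``, so the blacklist contains exactly the ordered
    pairs pointing from a strictly lower (larger-rank) node to a higher one.
    """
    return ConstraintSet(forbidden=set(), layers=dict(layer_map))


def validate_constraints(dag: DAG, constraints: ConstraintSet) -> list[str]:
    """List every constraint violation; an empty list means compliant."""
    violations = []
    for u, v in sorted(dag.edges):
        if (u, v) in constraints.forbidden:
            violations.append(f"forbidden edge present: {u} -> {v}")
    for u, v in sorted(constraints.required):
        if not dag.has_edge(u, v):
            violations.append(f"required edge missing: {u} -> {v}")
    return violations


# ---------------------------------------------------------------------------
# input/output
# ---------------------------------------------------------------------------


def write_dot(dag: DAG, path: str) -> None:
    lines = ["digraph G {"]
    linked = {n for e in dag.edges for n in e}
    for v in dag.nodes:
        if v not in linked:
            lines.append(f'  "{v}";')
    for u, v in sorted(dag.edges):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


_DOT_EDGE = re.compile(r'"([^"]+)"\s*->\s*"([^"]+)"')
_DOT_NODE = re.compile(r'^\s*"([^"]+)"\s*;')


def read_dot(path: str) -> DAG:
    """Parse the plain node/edge DOT subset emitted by :func:`write_dot`."""
    nodes: list[str] = []
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            m = _DOT_EDGE.search(line)
            if m:
                edges.append((m.group(1), m.group(2)))
                nodes.extend(m.groups())
                continue
            m = _DOT_NODE.match(line)
            if m:
                nodes.append(m.group(1))
    return DAG(dict.fromkeys(nodes), edges)


def write_graphml(dag: DAG, path: str) -> None:
    nx.write_graphml(dag.to_networkx(), path)


def read_graphml(path: str) -> DAG:
    return DAG.from_networkx(nx.read_graphml(path))


def write_constraints(constraints: ConstraintSet, path: str) -> None:
    """Serialize constraints as a three-section text file."""
    lines = ["[forbidden]"]
    lines += [f"{u} -> {v}" for u, v in sorted(constraints.forbidden)]
    lines.append("[required]")
    lines += [f"{u} -> {v}" for u, v in sorted(constraints.required)]
    lines.append("[layers]")
    if constraints.layers:
        lines += [f"{n} {r}" for n, r in sorted(constraints.layers.items())]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_constraints(path: str) -> ConstraintSet:
    section = None
    forbidden: set[tuple[str, str]] = set()
    required: set[tuple[str, str]] = set()
    layers: dict[str, int] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("["):
                section = line.strip("[]").lower()
                continue
            if section in ("forbidden", "required"):
                u, _, v = (t.strip() for t in line.partition("->"))
                (forbidden if section == "forbidden" else required).add((u, v))
            elif section == "layers":
                name, rank = line.rsplit(None, 1)
                layers[name] = int(rank)
    # explicit pairs only; layer expansion merges in the constructor
    return ConstraintSet(
        forbidden=forbidden, required=required, layers=layers or None
    )
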