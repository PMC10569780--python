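"""Causal-role classification and adjustment-set construction.

Given a causal DAG, a treatment node and one or more outcome nodes, this
module formalizes "inspection of the graph": each measured pretreatment
variable is labelled by its causal role (confounder, indirect confounder,
mediator, collider risk, cause of treatment/outcome only, independent), and
adjustment sets are produced under the four classical criteria:

* pretreatment   — adjust for every measured pretreatment variable;
* common cause   — adjust for common causes of treatment and outcome;
* backdoor       — all minimal measured sets that block every backdoor path;
* disjunctive cause — measured causes of treatment or outcome (no mediators).

Unmeasured variables may be present in the graph (for ground-truth analyses);
they are excluded from every adjustment set and from role reports.

Role precedence is mediator > confounder > indirect_confounder >
collider_risk: adjusting for a mediator is the most severe error, so a node on
both a mediating and a confounding path is reported as a mediator and flagged
as dual-role.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .bn_core import DAG, d_separated

__all__ = [
    "CausalRole",
    "CausalRoleReport",
    "surgery",
    "classify_node",
    "adjustment_sets",
    "NoValidBackdoorSet",
    "treatment_outcome_association",
    "build_report",
]

ROLE_LABELS = (
    "confounder",
    "indirect_confounder",
    "mediator",
    "collider_risk",
    "cause_of_treatment_only",
    "cause_of_outcome_only",
    "independent",
)


@dataclass(frozen=True)
class CausalRole:
    label: str
    dual_role: bool = False  # also lies on a confounding path despite mediator label

    def __post_init__(self) -> None:
        if self.label not in ROLE_LABELS:
            raise ValueError(f"unknown causal role {self.label!r}")


class NoValidBackdoorSet(Exception):
    """No measured adjustment set blocks every backdoor path.

    Distinguishes "the empty set suffices" (a valid answer) from "adjustment
    is impossible with the measured variables" (this error), which arises for
    instance under an unmeasured common cause of treatment and outcome.
    """


def surgery(dag: DAG, treatment: str) -> DAG:
    """The backdoor graph: ``dag`` with the treatment's outgoing edges removed."""
    g = dag.copy()
    for child in dag.children(treatment):
        g.remove_edge(treatment, child)
    return g


def _measured(dag: DAG, unmeasured: set[str]) -> list[str]:
    return [v for v in dag.nodes if v not in unmeasured]


def _is_proper_backdoor_set(
    cut: DAG, treatment: str, outcome: str, z: set[str]
) -> bool:
    return d_separated(cut, treatment, outcome, z)


def classify_node(
    dag: DAG,
    node: str,
    treatment: str,
    outcomes: str | set[str],
    unmeasured: set[str] | None = None,
) -> CausalRole:
    """Classify one node's causal role relative to (treatment, outcomes).

    * mediator: on a directed path treatment -> ... -> outcome;
    * confounder: ancestor of treatment and of an outcome via a path avoiding
      treatment (a common cause, possibly indirect);
    * indirect_confounder: not a common cause, but a non-collider sitting on
      an open backdoor path (so adjusting for it blocks confounding that is
      otherwise transmitted through unmeasured variables);
    * collider_risk: conditioning on the node opens a backdoor path between
      treatment and an outcome that some valid measured adjustment blocked;
    * cause_of_treatment_only / cause_of_outcome_only / independent otherwise.
    """
    outcomes = {outcomes} if isinstance(outcomes, str) else set(outcomes)
    unmeasured = unmeasured or set()
    if node not in dag._parents:
        raise KeyError(f"unknown node {node!r}")
    if node == treatment or node in outcomes:
        raise ValueError("node must differ from treatment and outcomes")

    desc = dag.descendants(node)
    anc_t = dag.ancestors(treatment)
    causes_t = node in anc_t

    # mediator: node is a descendant of treatment and an ancestor of an outcome
    on_mediating_path = node in dag.descendants(treatment) and bool(desc & outcomes)

    # ancestor of an outcome via a path that avoids treatment entirely
    cut = dag.copy()
    for p in dag.parents(treatment):
        cut.remove_edge(p, treatment)
    for c in dag.children(treatment):
        cut.remove_edge(treatment, c)
    causes_y_bypassing_t = bool(cut.descendants(node) & outcomes)

    confounds = causes_t and causes_y_bypassing_t
    if on_mediating_path:
        return CausalRole("mediator", dual_role=confounds)
    if confounds:
        return CausalRole("confounder")

    bd = surgery(dag, treatment)
    measured = set(_measured(dag, unmeasured)) - {treatment} - outcomes

    # indirect confounder: non-collider on a backdoor path that is open given {}
    for y in outcomes:
        if _on_open_backdoor_path(bd, treatment, y, node):
            return CausalRole("indirect_confounder")

    # collider risk: adding the node to some valid measured set opens a path.
    # Conditioning can only open a collider the node descends from (or is),
    # so skip the subset sweep when that necessary condition fails.
    colliders = {v for v in bd.nodes if len(bd.parents(v)) >= 2}
    can_open = any(node == c or node in bd.descendants(c) for c in colliders)
    pool = sorted(measured - {node})
    if can_open:
        for y in outcomes:
            for size in range(len(pool) + 1):
                opened = False
                for z in combinations(pool, size):
                    zs = set(z)
                    if d_separated(bd, treatment, y, zs) and not d_separated(
                        bd, treatment, y, zs | {node}
                    ):
                        opened = True
                        break
                if opened:
                    return CausalRole("collider_risk")

    causes_y = any(y in desc for y in outcomes)
    if causes_t:
        return CausalRole("cause_of_treatment_only")
    if causes_y:
        return CausalRole("cause_of_outcome_only")
    return CausalRole("independent")


def _on_open_backdoor_path(bd: DAG, t: str, y: str, node: str) -> bool:
    """Is ``node`` on a backdoor path that is open given the empty set?

    Open given {} means the path has no colliders, so every vertex on it --
    the node included -- is a non-collider and adjusting for the node blocks
    that path.  Backdoor paths are exactly the t-y paths of the backdoor
    graph, since the treatment's outgoing edges have been removed.
    """
    und = nx.Graph()
    und.add_nodes_from(bd.nodes)
    und.add_edges_from(bd.edges)
    for path in nx.all_simple_paths(und, t, y):
        if node not in path[1:-1]:
            continue
        collider_free = all(
            not (bd.has_edge(path[i - 1], path[i]) and bd.has_edge(path[i + 1], path[i]))
            for i in range(1, len(path) - 1)
        )
        if collider_free:
            return True
    return False


def adjustment_sets(
    dag: DAG,
    treatment: str,
    outcome: str,
    criterion: str,
    unmeasured: set[str] | None = None,
) -> list[set[str]]:
    """Adjustment sets for (treatment, outcome) under a named criterion.

    ``pretreatment``, ``common_cause`` and ``disjunctive_cause`` each return a
    single set; ``backdoor`` returns every minimal measured set Z with
    treatment d-separated from outcome given Z in the backdoor graph,
    excluding descendants of the treatment.  Raises
    :class:`NoValidBackdoorSet` when no measured set works.
    """
    unmeasured = set(unmeasured or ())
    for v in (treatment, outcome):
        if v not in dag._parents:
            raise KeyError(f"unknown node {v!r}")
    measured = [
        v for v in _measured(dag, unmeasured) if v not in (treatment, outcome)
    ]

    if criterion == "pretreatment":
        pre = [v for v in measured if v not in dag.descendants(treatment)]
        return [set(pre)]

    anc_t = dag.ancestors(treatment)
    desc_t = dag.descendants(treatment)

    if criterion == "common_cause":
        cut = dag.copy()
        for p in dag.parents(treatment):
            cut.remove_edge(p, treatment)
        for c in dag.children(treatment):
            cut.remove_edge(treatment, c)
        common = {
            v
            for v in measured
            if v in anc_t and outcome in cut.descendants(v)
        }
        return [common]

    if criterion == "disjunctive_cause":
        anc_y = dag.ancestors(outcome)
        dis = {
            v
            for v in measured
            if (v in anc_t or v in anc_y) and v not in desc_t
        }
        return [dis]

    if criterion == "backdoor":
        bd = surgery(dag, treatment)
        pool = sorted(v for v in measured if v not in desc_t)
        valid: list[set[str]] = []
        for size in range(len(pool) + 1):
            for z in combinations(pool, size):
                zs = set(z)
                if any(v < zs for v in valid):
                    continue  # a subset is already valid: not minimal
                if _is_proper_backdoor_set(bd, treatment, outcome, zs):
                    valid.append(zs)
        if not valid:
            raise NoValidBackdoorSet(
                f"no measured set blocks every backdoor path from "
                f"{treatment!r} to {outcome!r}"
            )
        return sorted(valid, key=lambda s: (len(s), sorted(s)))

    raise ValueError(f"unknown criterion {criterion!r}")


def treatment_outcome_association(
    dag: DAG, treatment: str, outcomes: str | set[str]
) -> bool:
    """True iff treatment is d-connected (given nothing) to any outcome node."""
    outcomes = {outcomes} if isinstance(outcomes, str) else set(outcomes)
    return any(not d_separated(dag, treatment, y, set()) for y in outcomes)


@dataclass
class CausalRoleReport:
    """Per-variable roles plus adjustment sets per criterion.

    ``roles`` covers every measured node other than treatment/outcomes;
    ``adjustment_sets`` maps criterion name to a list of node sets (for the
    union-over-outcomes backdoor analysis, per-outcome detail is kept in
    ``per_outcome``).  Backdoor impossibility is recorded in ``notes``.
    """

    treatment: str
    outcomes: set[str]
    roles: dict[str, CausalRole]
    adjustment: dict[str, list[set[str]]]
    per_outcome: dict[str, dict[str, list[set[str]]]] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def confounders(self) -> set[str]:
        return {
            v
            for v, r in self.roles.items()
            if r.label in ("confounder", "indirect_confounder")
        }

    def to_dict(self) -> dict:
        return {
            "treatment": self.treatment,
            "outcomes": sorted(self.outcomes),
            "roles": {
                v: {"label": r.label, "dual_role": r.dual_role}
                for v, r in sorted(self.roles.items())
            },
            "adjustment_sets": {
                c: [sorted(s) for s in sets] for c, sets in self.adjustment.items()
            },
            "per_outcome": {
                y: {c: [sorted(s) for s in sets] for c, sets in d.items()}
                for y, d in self.per_outcome.items()
            },
            "notes": list(self.notes),
        }

    def summary(self) -> str:
        lines = [f"treatment: {self.treatment}", f"outcomes: {sorted(self.outcomes)}"]
        lines.append(f"{'node':<16} role")
        for v, r in sorted(self.roles.items()):
            flag = " (dual role)" if r.dual_role else ""
            lines.append(f"{v:<16} {r.label}{flag}")
        for c, sets in self.adjustment.items():
            lines.append(f"{c}: {[sorted(s) for s in sets]}")
        lines.extend(self.notes)
        return "\n".join(lines)


def build_report(
    dag: DAG,
    treatment: str,
    outcomes: str | set[str],
    unmeasured: set[str] | None = None,
) -> CausalRoleReport:
    """Classify every measured node and compute adjustment sets per criterion.

    With several outcome nodes, a variable counts as a confounder if it
    confounds *any* (treatment, outcome) pair; per-pair adjustment sets are
    retained under ``per_outcome``.
    """
    outcomes = {outcomes} if isinstance(outcomes, str) else set(outcomes)
    unmeasured = set(unmeasured or ())
    roles: dict[str, CausalRole] = {}
    for v in dag.nodes:
        if v == treatment or v in outcomes or v in unmeasured:
            continue
        roles[v] = classify_node(dag, v, treatment, outcomes, unmeasured)

    per_outcome: dict[str, dict[str, list[set[str]]]] = {}
    notes: list[str] = []
    merged: dict[str, list[set[str]]] = {}
    for y in sorted(outcomes):
        per_outcome[y] = {}
        for criterion in ("pretreatment", "common_cause", "backdoor", "disjunctive_cause"):
            try:
                sets = adjustment_sets(dag, treatment, y, criterion, unmeasured)
            except NoValidBackdoorSet as err:
                notes.append(str(err))
                sets = []
            per_outcome[y][criterion] = sets
    for criterion in ("pretreatment", "common_cause", "backdoor", "disjunctive_cause"):
        if criterion == "backdoor":
            # per-outcome minimal sets are unioned pairwise across outcomes
            merged[criterion] = _merge_backdoor(per_outcome)
        else:
            union: set[str] = set()
            for y in per_outcome:
                for s in per_outcome[y][criterion]:
                    union |= s
            merged[criterion] = [union]
    return CausalRoleReport(treatment, outcomes, roles, merged, per_outcome, notes)


def _merge_backdoor(per_outcome: dict[str, dict[str, list[set[str]]]]) -> list[set[str]]:
    outcome_sets = [d["backdoor"] for d in per_outcome.values() if d["backdoor"]]
    if len(outcome_sets) != len(per_outcome):
        return []  # at least one outcome had no valid measured set
    merged = [set()]
    for sets in outcome_sets:
        merged = [m | s for m in merged for s in sets]
    uniq: list[set[str]] = []
    for s in sorted(merged, key=lambda s: (len(s), sorted(s))):
        if not any(u <= s for u in uniq):
            uniq.append(s)
    return uniq
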