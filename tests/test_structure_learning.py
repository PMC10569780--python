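"""Structure learners: recovery, constraint compliance, exactness, determinism."""

import numpy as np
import pandas as pd
import pytest

from causalbn.bn_core import (
    DAG,
    ConstraintSet,
    DiscreteDataset,
    constraints_from_layers,
    score_network,
    validate_constraints,
)
from causalbn.structure_learning import (
    AmbiguousRegion,
    LearnedStructure,
    learn_constraint_based,
    learn_mmhc,
    learn_sm_exact,
    learn_with_whitelist_retry,
    resolve_ambiguities,
)
from conftest import enumerate_all_dags, random_dag, sample_from_dag


def independent_data(n=5000, k=3, seed=0):
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            f"v{i}": pd.Categorical.from_codes(
                rng.integers(0, 2, n).astype(np.int64), categories=["0", "1"]
            )
            for i in range(k)
        }
    )
    return DiscreteDataset.from_frame(frame)


def collider_data(n=10_000, seed=0):
    # A and B independent fair coins; P(C=1) = 0.15 + 0.35 A + 0.35 B gives a
    # v-structure whose marginal parent-child dependencies are decisive
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 2, n)
    b = rng.integers(0, 2, n)
    c = (rng.random(n) < 0.15 + 0.35 * a + 0.35 * b).astype(int)
    frame = pd.DataFrame(
        {
            k: pd.Categorical.from_codes(v.astype(np.int64), categories=["0", "1"])
            for k, v in {"A": a, "B": b, "C": c}.items()
        }
    )
    return DiscreteDataset.from_frame(frame)


class TestConstraintBased:
    def test_collider_identified(self):
        s = learn_constraint_based(collider_data())
        assert s.skeleton == {frozenset("AC"), frozenset("BC")}
        assert s.graph.edges == {("A", "C"), ("B", "C")}

    def test_independent_columns_empty_graph(self):
        s = learn_constraint_based(independent_data())
        assert s.graph.edges == set()
        assert s.ambiguous == []

    def test_required_edge_kept(self):
        c = ConstraintSet(required={("v0", "v1")})
        s = learn_constraint_based(independent_data(), c)
        assert ("v0", "v1") in s.graph.edges

    def test_single_variable_rejected(self):
        with pytest.raises(ValueError):
            learn_constraint_based(independent_data(k=1))


class TestResolveAmbiguities:
    def _structure(self, regions):
        nodes = ["grade", "surv_05y", "adj_therapy", "treatment", "A", "B"]
        return LearnedStructure(
            graph=DAG(nodes),
            skeleton=set(),
            ambiguous=regions,
            algorithm="NPC-like",
            alpha=0.05,
            score_kind=None,
        )

    def test_outcome_priority(self):
        region = AmbiguousRegion(
            {frozenset(("grade", "surv_05y")), frozenset(("grade", "adj_therapy"))}
        )
        out = resolve_ambiguities(self._structure([region]))
        assert frozenset(("grade", "surv_05y")) in out.skeleton
        assert frozenset(("grade", "adj_therapy")) not in out.skeleton
        assert out.ambiguous == []
        assert any("kept" in line for line in out.resolution_log)

    def test_treatment_second_tier(self):
        region = AmbiguousRegion({frozenset(("A", "treatment")), frozenset(("A", "B"))})
        out = resolve_ambiguities(self._structure([region]))
        assert frozenset(("A", "treatment")) in out.skeleton

    def test_no_priority_falls_back_lexicographically(self):
        region = AmbiguousRegion({frozenset(("A", "B")), frozenset(("B", "grade"))})
        out = resolve_ambiguities(
            self._structure([region]), policy=[{"surv_05y"}, {"treatment"}]
        )
        assert frozenset(("A", "B")) in out.skeleton
        assert any("fallback" in line for line in out.resolution_log)

    def test_empty_regions_identity(self):
        s = self._structure([])
        assert resolve_ambiguities(s) is s

    def test_region_needs_two_edges(self):
        with pytest.raises(ValueError):
            AmbiguousRegion({frozenset(("A", "B"))})


class TestMMHC:
    def test_chain_equivalence_class_score(self):
        rng = np.random.default_rng(2)
        chain = DAG(["A", "B", "C"], [("A", "B"), ("B", "C")])
        data = sample_from_dag(chain, 5000, rng)
        s = learn_mmhc(data)
        learned = score_network(data, s.graph).total
        truth = score_network(data, chain).total
        assert learned == pytest.approx(truth, abs=1e-6)

    def test_independent_columns_empty_graph(self):
        assert learn_mmhc(independent_data()).graph.edges == set()

    def test_blacklist_never_violated(self):
        rng = np.random.default_rng(4)
        forbidden = {(f"v{i}", "age") for i in range(4)}
        c = ConstraintSet(forbidden=forbidden)
        for rep in range(50):
            dag = random_dag(rng, 4)
            dag.nodes[0] = dag.nodes[0]  # names v0..v3
            data = sample_from_dag(dag, 400, rng)
            frame = data.to_frame().rename(columns={"v3": "age"})
            data = DiscreteDataset.from_frame(frame)
            s = learn_mmhc(data, c)
            assert all(v != "age" for _, v in s.graph.edges)

    def test_score_between_empty_and_exact(self):
        rng = np.random.default_rng(9)
        for rep in range(5):
            dag = random_dag(rng, 4)
            data = sample_from_dag(dag, 1000, rng)
            empty = score_network(data, DAG(data.names)).total
            mmhc = score_network(data, learn_mmhc(data).graph).total
            exact = score_network(data, learn_sm_exact(data).graph).total
            assert mmhc >= empty - 1e-9
            assert mmhc <= exact + 1e-9


class TestSMExact:
    def test_matches_exhaustive_enumeration_small(self):
        rng = np.random.default_rng(0)
        names = ["a", "b", "c", "d"]
        for rep in range(3):
            dag = random_dag(rng, 4)
            data = sample_from_dag(dag, 1000, rng)
            best = max(
                score_network(data, g).total
                for g in enumerate_all_dags(sorted(data.names))
            )
            got = score_network(data, learn_sm_exact(data).graph).total
            assert got == pytest.approx(best, abs=1e-9)

    def test_independent_columns_empty_graph(self):
        assert learn_sm_exact(independent_data(n=2000)).graph.edges == set()

    def test_required_edge_enforced(self):
        c = ConstraintSet(required={("v0", "v1")})
        s = learn_sm_exact(independent_data(n=2000), c)
        assert ("v0", "v1") in s.graph.edges

    def test_node_limit(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(
            {f"v{i}": ["0", "1"] * 2 for i in range(21)}
        )
        with pytest.raises(ValueError):
            learn_sm_exact(DiscreteDataset.from_frame(frame))

    def test_unmeasured_confounder_links_treatment_and_outcome(self):
        # hidden cause of both treatment and survival: the learner cannot
        # separate them, exhibiting the spurious-confounding risk of
        # score-based search under unmeasured confounding
        from causalbn.causal_id import treatment_outcome_association
        from causalbn.pipeline import default_constraints
        from causalbn.synthetic_cohort import (
            ScenarioConfig,
            apply_exclusions,
            discretize_outcomes,
            make_ground_truth,
            sample_cohort,
            simplify_node_set,
        )

        gt = make_ground_truth(ScenarioConfig("unmeasured_confounder", 10_000, 0))
        cohort, _ = apply_exclusions(sample_cohort(gt, 10_000, 0))
        ds = simplify_node_set(discretize_outcomes(cohort), "simplified")
        s = learn_sm_exact(ds, default_constraints())
        assert treatment_outcome_association(
            s.graph, "treatment", {"surv_05y"}
        )


class TestWhitelistRetry:
    def test_compliant_first_pass_identity(self):
        s = learn_with_whitelist_retry(independent_data(), algorithm="mmhc")
        assert s.graph.edges == set()
        assert any("converged after 1" in line for line in s.resolution_log)

    def test_misdirecting_stub_corrected_in_two_runs(self):
        calls = []

        def stub(data, constraints, alpha, score_kind):
            calls.append(1)
            nodes = ["sex", "age"]
            if ("sex", "age") in constraints.required:
                g = DAG(nodes, [("sex", "age")])
            else:
                g = DAG(nodes, [("age", "sex")])  # misdirected on first pass
            return LearnedStructure(
                g, {frozenset(nodes)}, [], "stub", alpha, None, [], constraints
            )

        c = constraints_from_layers({"sex": 0, "age": 1})
        s = learn_with_whitelist_retry(independent_data(), c, algorithm=stub)
        assert len(calls) == 2
        assert validate_constraints(s.graph, c) == []

    def test_nonconvergence_raises(self):
        def stubborn(data, constraints, alpha, score_kind):
            g = DAG(["sex", "age"], [("age", "sex")])
            return LearnedStructure(
                g, {frozenset(("sex", "age"))}, [], "stub", alpha, None, [], constraints
            )

        c = ConstraintSet(forbidden={("age", "sex"), ("sex", "age")})
        with pytest.raises(RuntimeError, match="retries"):
            learn_with_whitelist_retry(independent_data(), c, algorithm=stubborn)


class TestDeterminismAndCompliance:
    @pytest.mark.parametrize("algorithm", ["npc_like", "mmhc", "sm_exact"])
    def test_identical_runs_identical_output(self, algorithm):
        rng = np.random.default_rng(12)
        dag = random_dag(rng, 5)
        data = sample_from_dag(dag, 2000, rng)
        a = learn_with_whitelist_retry(data, algorithm=algorithm)
        b = learn_with_whitelist_retry(data, algorithm=algorithm)
        assert a.graph == b.graph
        assert a.skeleton == b.skeleton

    @pytest.mark.parametrize("algorithm", ["npc_like", "mmhc", "sm_exact"])
    def test_output_acyclic_and_compliant(self, algorithm):
        rng = np.random.default_rng(21)
        layers = {f"v{i}": i % 3 for i in range(5)}
        c = constraints_from_layers(layers)
        for rep in range(5):
            dag = random_dag(rng, 5)
            data = sample_from_dag(dag, 800, rng)
            s = learn_with_whitelist_retry(data, c, algorithm=algorithm)
            assert s.graph.topological_order() is not None
            assert validate_constraints(s.graph, c) == []
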