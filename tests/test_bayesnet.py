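"""Bayesian-network engine: estimation, exact inference, structure learning."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vdtsurv.bayesnet import (
    BayesianNetwork,
    CategoricalVariable,
    Cpt,
    Dag,
    classify,
    conditional_mutual_information,
    diagnostic_profile,
    fit_mle,
    joint_probability,
    learn_abn_structure,
    naive_network_from_spec,
    network_from_json,
    network_to_json,
    posterior,
    sensitivity,
)
from vdtsurv.cohort import (
    ATTRIBUTES,
    CLASS_LABELS,
    TRACKED_STATE,
    generate_cohort,
    records_to_dataframe,
)
from tests.oracles import (
    contingency_cmi,
    enumerate_posterior,
    naive_bayes_argmax,
    random_binary_network,
)


def two_node_chain(p_a1=0.4, p_b1_a1=0.75, p_b1_a0=0.25) -> BayesianNetwork:
    graph = Dag(nodes=frozenset({"a", "b"}), arcs=frozenset({("a", "b")}))
    variables = [CategoricalVariable("a", ("a0", "a1")), CategoricalVariable("b", ("b0", "b1"))]
    cpts = {
        "a": Cpt("a", (), ("a0", "a1"), {(): np.array([1 - p_a1, p_a1])}),
        "b": Cpt("b", ("a",), ("b0", "b1"), {
            ("a0",): np.array([1 - p_b1_a0, p_b1_a0]),
            ("a1",): np.array([1 - p_b1_a1, p_b1_a1]),
        }),
    }
    return BayesianNetwork(variables=variables, graph=graph, cpts=cpts)


def hand_three_node() -> BayesianNetwork:
    """target -> A, target -> B with asymmetric hand-picked parameters."""
    graph = Dag(
        nodes=frozenset({"t", "a", "b"}),
        arcs=frozenset({("t", "a"), ("t", "b")}),
    )
    variables = [
        CategoricalVariable("t", ("t0", "t1", "t2")),
        CategoricalVariable("a", ("a0", "a1")),
        CategoricalVariable("b", ("b0", "b1")),
    ]
    cpts = {
        "t": Cpt("t", (), ("t0", "t1", "t2"), {(): np.array([0.5, 0.3, 0.2])}),
        "a": Cpt("a", ("t",), ("a0", "a1"), {
            ("t0",): np.array([0.9, 0.1]),
            ("t1",): np.array([0.4, 0.6]),
            ("t2",): np.array([0.2, 0.8]),
        }),
        "b": Cpt("b", ("t",), ("b0", "b1"), {
            ("t0",): np.array([0.7, 0.3]),
            ("t1",): np.array([0.5, 0.5]),
            ("t2",): np.array([0.05, 0.95]),
        }),
    }
    return BayesianNetwork(variables=variables, graph=graph, cpts=cpts)


class TestFitMle:
    @pytest.fixture()
    def ab_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"a": ["a1", "a1", "a1", "a0"], "b": ["b1", "b1", "b0", "b0"]}
        )

    @pytest.fixture()
    def ab_graph(self):
        return Dag(nodes=frozenset({"a", "b"}), arcs=frozenset({("a", "b")}))

    def test_hand_counts(self, ab_graph, ab_frame):
        bn = fit_mle(ab_graph, ab_frame)
        assert bn.cpts["b"].prob("b1", ("a1",)) == pytest.approx(2 / 3)
        assert bn.cpts["a"].prob("a1", ()) == pytest.approx(3 / 4)

    def test_additive_smoothing(self, ab_graph, ab_frame):
        bn = fit_mle(ab_graph, ab_frame, smoothing=1.0)
        assert bn.cpts["b"].prob("b1", ("a1",)) == pytest.approx((2 + 1) / (3 + 2))

    def test_unobserved_combo_uniform(self, ab_graph, ab_frame):
        frame = ab_frame[ab_frame["a"] == "a1"]
        bn = fit_mle(ab_graph, frame, states={"a": ("a0", "a1"), "b": ("b0", "b1")})
        assert bn.cpts["b"].table[("a0",)] == pytest.approx([0.5, 0.5])

    def test_rejects_undeclared_states(self, ab_graph, ab_frame):
        with pytest.raises(ValueError, match="outside declared"):
            fit_mle(ab_graph, ab_frame, states={"a": ("a0",  "a1"), "b": ("b0", "bX")})


class TestJointProbability:
    def test_single_uniform_node(self):
        graph = Dag(nodes=frozenset({"x"}), arcs=frozenset())
        bn = BayesianNetwork(
            variables=[CategoricalVariable("x", ("x0", "x1"))],
            graph=graph,
            cpts={"x": Cpt("x", (), ("x0", "x1"), {(): np.array([0.5, 0.5])})},
        )
        assert joint_probability(bn, {"x": "x0"}) == 0.5

    def test_chain_product(self):
        bn = two_node_chain()
        assert joint_probability(bn, {"a": "a1", "b": "b1"}) == pytest.approx(0.3)

    def test_normalization_over_all_assignments(self):
        bn = hand_three_node()
        total = sum(
            joint_probability(bn, dict(zip(("t", "a", "b"), combo)))
            for combo in itertools.product(("t0", "t1", "t2"), ("a0", "a1"), ("b0", "b1"))
        )
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_partial_assignment_rejected(self):
        bn = two_node_chain()
        with pytest.raises(ValueError, match="missing"):
            joint_probability(bn, {"a": "a1"})


class TestPosterior:
    def test_no_evidence_returns_prior(self):
        bn = hand_three_node()
        assert posterior(bn, "t") == pytest.approx({"t0": 0.5, "t1": 0.3, "t2": 0.2})

    def test_matches_enumeration_on_hand_network(self):
        bn = hand_three_node()
        for ev in [{}, {"a": "a1"}, {"a": "a0", "b": "b1"}, {"t": "t2"}]:
            for query in bn.graph.nodes - set(ev):
                ve = posterior(bn, query, ev)
                brute = enumerate_posterior(bn, query, ev)
                for s in ve:
                    assert ve[s] == pytest.approx(brute[s], abs=1e-12)

    def test_query_in_evidence_rejected(self):
        bn = two_node_chain()
        with pytest.raises(ValueError, match="evidence"):
            posterior(bn, "a", {"a": "a1"})

    def test_zero_probability_evidence_rejected(self):
        bn = two_node_chain(p_a1=0.0)
        with pytest.raises(ValueError, match="zero"):
            posterior(bn, "b", {"a": "a1"})

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_elimination_equals_enumeration_on_random_networks(self, seed):
        rng = np.random.default_rng(seed)
        bn = random_binary_network(rng)
        names = sorted(bn.graph.nodes)
        n_ev = int(rng.integers(0, len(names)))
        ev_vars = list(rng.choice(names, size=n_ev, replace=False))
        evidence = {v: ("s0" if rng.random() < 0.5 else "s1") for v in ev_vars}
        query = next(n for n in names if n not in evidence)
        try:
            ve = posterior(bn, query, evidence)
        except ValueError:
            return  # zero-probability evidence; contract tested elsewhere
        brute = enumerate_posterior(bn, query, evidence)
        for s in ve:
            assert ve[s] == pytest.approx(brute[s], abs=1e-12)


class TestDiagnosticProfile:
    @pytest.mark.parametrize(
        "cls,attr,expected",
        [("none", "sleep", 0.1673), ("cardiovascular", "sex", 0.8140),
         ("musculoskeletal", "age_ge39", 0.7181)],
    )
    def test_paper_spec_network_returns_stored_conditionals(
        self, paper_spec, cls, attr, expected
    ):
        bn = naive_network_from_spec(paper_spec)
        assert diagnostic_profile(bn, cls)[attr] == pytest.approx(expected, abs=1e-12)

    def test_values_are_probabilities(self, paper_spec, small_cohort):
        dag = learn_abn_structure(small_cohort, cmi_threshold=0.01)
        bn = fit_mle(dag, small_cohort)
        for cls in CLASS_LABELS:
            for p in diagnostic_profile(bn, cls).values():
                assert 0.0 <= p <= 1.0

    def test_unknown_state_rejected(self, paper_spec):
        bn = naive_network_from_spec(paper_spec)
        with pytest.raises(ValueError, match="disorder state"):
            diagnostic_profile(bn, "rheumatic")


class TestClassify:
    def test_degenerate_prior_always_first_class(self, paper_spec):
        spec = paper_spec
        bn = naive_network_from_spec(spec)
        # force the prior onto the first class
        bn.cpts["disorder"].table[()] = np.array([1.0, 0, 0, 0, 0, 0])
        assert classify(bn, {"smoker": "yes"}) == "none"

    def test_exact_tie_breaks_by_state_order(self):
        graph = Dag(nodes=frozenset({"t", "a"}), arcs=frozenset({("t", "a")}))
        bn = BayesianNetwork(
            variables=[CategoricalVariable("t", ("t0", "t1")),
                       CategoricalVariable("a", ("a0", "a1"))],
            graph=graph,
            cpts={
                "t": Cpt("t", (), ("t0", "t1"), {(): np.array([0.5, 0.5])}),
                "a": Cpt("a", ("t",), ("a0", "a1"), {
                    ("t0",): np.array([0.3, 0.7]),
                    ("t1",): np.array([0.3, 0.7]),
                }),
            },
        )
        assert classify(bn, {"a": "a1"}, target="t") == "t0"

    def test_agrees_with_enumeration_argmax(self):
        bn = hand_three_node()
        for ev in [{"a": "a1"}, {"a": "a0", "b": "b1"}, {"b": "b0"}]:
            brute = enumerate_posterior(bn, "t", ev)
            expected = max(("t0", "t1", "t2"), key=lambda s: brute[s])
            assert classify(bn, ev, target="t") == expected


class TestSensitivity:
    def test_zero_delta_zero_change(self):
        bn = two_node_chain()
        assert sensitivity(bn, ("a", "a1"), 0.0, ("b", "b1")) == 0.0

    def test_disconnected_components_no_influence(self):
        graph = Dag(nodes=frozenset({"a", "b"}), arcs=frozenset())
        bn = BayesianNetwork(
            variables=[CategoricalVariable("a", ("a0", "a1")),
                       CategoricalVariable("b", ("b0", "b1"))],
            graph=graph,
            cpts={
                "a": Cpt("a", (), ("a0", "a1"), {(): np.array([0.4, 0.6])}),
                "b": Cpt("b", (), ("b0", "b1"), {(): np.array([0.7, 0.3])}),
            },
        )
        assert sensitivity(bn, ("a", "a1"), 0.1, ("b", "b1")) == pytest.approx(0.0, abs=1e-15)

    def test_two_node_closed_form(self):
        # d P(b1) / d P(a1) = P(b1|a1) - P(b1|a0), so change = delta * that slope
        bn = two_node_chain(p_a1=0.4, p_b1_a1=0.75, p_b1_a0=0.25)
        change = sensitivity(bn, ("a", "a1"), 0.1, ("b", "b1"))
        assert change == pytest.approx(0.1 * (0.75 - 0.25), abs=1e-12)

    def test_out_of_range_perturbation_rejected(self):
        bn = two_node_chain(p_a1=0.95)
        with pytest.raises(ValueError, match="outside"):
            sensitivity(bn, ("a", "a1"), 0.1, ("b", "b1"))

    def test_non_root_source_rejected(self):
        bn = two_node_chain()
        with pytest.raises(ValueError, match="root"):
            sensitivity(bn, ("b", "b1"), 0.1, ("a", "a1"))


class TestStructureLearning:
    def test_conditionally_independent_data_yields_naive_star(self, calibration_cohort):
        dag = learn_abn_structure(calibration_cohort, cmi_threshold=0.01)
        assert dag.arcs == frozenset(("disorder", a) for a in ATTRIBUTES)

    def test_planted_copy_recovered(self, paper_spec):
        records = generate_cohort(paper_spec, n=5_000, seed=9, coupling=("smoker", "alcohol"))
        dag = learn_abn_structure(records, cmi_threshold=0.01)
        assert ("smoker", "alcohol") in dag.arcs or ("alcohol", "smoker") in dag.arcs

    def test_structural_contract(self, small_cohort):
        dag = learn_abn_structure(small_cohort, cmi_threshold=0.0)
        star = {a for a in dag.arcs if a[0] == "disorder"}
        augmentation = dag.arcs - star
        assert len(star) == 7
        assert len(augmentation) <= 6  # a forest over 7 features
        # every feature has at most one feature parent
        for child in ATTRIBUTES:
            assert sum(1 for p, c in augmentation if c == child) <= 1

    def test_infinite_threshold_matches_independent_naive_bayes(self, paper_spec, small_cohort):
        dag = learn_abn_structure(small_cohort, cmi_threshold=math.inf)
        assert dag.arcs == frozenset(("disorder", a) for a in ATTRIBUTES)
        bn = fit_mle(dag, small_cohort)
        # oracle parameters = empirical frequencies, matching the MLE fit
        frame = records_to_dataframe(small_cohort)
        prior = (frame["disorder"].value_counts() / len(frame)).to_dict()
        prior = {c: prior.get(c, 0.0) for c in CLASS_LABELS}
        conds = {}
        for c in CLASS_LABELS:
            sub = frame[frame["disorder"] == c]
            for a in ATTRIBUTES:
                conds[(c, a)] = (
                    (sub[a] == TRACKED_STATE[a]).mean() if len(sub) else 0.5
                )
        probe = small_cohort[:200]
        expected = naive_bayes_argmax(
            probe, CLASS_LABELS, prior, conds, ATTRIBUTES, TRACKED_STATE
        )
        got = [
            classify(bn, {a: getattr(r, a) for a in ATTRIBUTES}) for r in probe
        ]
        assert got == expected

    def test_empty_records_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="empty"):
            learn_abn_structure(pd.DataFrame(columns=["disorder", "smoker"]))

    def test_unknown_target_rejected(self, small_cohort):
        with pytest.raises(KeyError, match="illness"):
            learn_abn_structure(small_cohort, target="illness")


class TestCmi:
    def test_matches_contingency_oracle(self, small_cohort):
        frame = records_to_dataframe(small_cohort)
        triples = list(zip(frame["disorder"], frame["smoker"], frame["alcohol"]))
        assert conditional_mutual_information(
            frame, "smoker", "alcohol", "disorder"
        ) == pytest.approx(contingency_cmi(triples), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_nonnegative_and_symmetric(self, seed):
        import pandas as pd

        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 120))
        frame = pd.DataFrame(
            {
                "x": rng.choice(["x0", "x1"], size=n),
                "y": rng.choice(["y0", "y1", "y2"], size=n),
                "z": rng.choice(["z0", "z1"], size=n),
            }
        )
        xy = conditional_mutual_information(frame, "x", "y", "z")
        yx = conditional_mutual_information(frame, "y", "x", "z")
        assert xy >= 0.0
        assert xy == pytest.approx(yx, abs=1e-12)

    def test_deterministic_copy_has_maximal_cmi(self, paper_spec):
        records = generate_cohort(paper_spec, n=5_000, seed=9, coupling=("smoker", "alcohol"))
        frame = records_to_dataframe(records)
        coupled = conditional_mutual_information(frame, "smoker", "alcohol", "disorder")
        for a, b in itertools.combinations(ATTRIBUTES, 2):
            if {a, b} == {"smoker", "alcohol"}:
                continue
            assert coupled > conditional_mutual_information(frame, a, b, "disorder")


class TestParameterRecovery:
    def test_mle_recovers_generating_network(self, paper_spec):
        records = generate_cohort(paper_spec, n=50_000, seed=13)
        dag = Dag(
            nodes=frozenset({"disorder", *ATTRIBUTES}),
            arcs=frozenset(("disorder", a) for a in ATTRIBUTES),
        )
        bn = fit_mle(dag, records)
        counts = {c: sum(r.disorder == c for r in records) for c in CLASS_LABELS}
        for cls in CLASS_LABELS:
            for attr in ATTRIBUTES:
                p = paper_spec.conditionals[(cls, attr)]
                est = bn.cpts[attr].prob(TRACKED_STATE[attr], (cls,))
                se = math.sqrt(p * (1 - p) / counts[cls])
                assert abs(est - p) <= 3 * se + 1e-12, (cls, attr)


def test_serialization_round_trip(paper_spec):
    bn = naive_network_from_spec(paper_spec)
    clone = network_from_json(network_to_json(bn))
    assert clone.graph.arcs == bn.graph.arcs
    post_a = posterior(bn, "disorder", {"smoker": "yes"})
    post_b = posterior(clone, "disorder", {"smoker": "yes"})
    assert post_a == pytest.approx(post_b, abs=1e-15)
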