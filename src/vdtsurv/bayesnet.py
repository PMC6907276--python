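"""Discrete Bayesian-network engine for disorder / risk-factor inference.

A network is the triplet (variables, DAG, conditional probability tables):
the joint distribution factorizes as the product over nodes of
P(node | parents).  The module provides

* augmented-naive-Bayes (ABN) structure learning: the disorder target is the
  common parent of every clinical attribute (the naive star), enriched with
  feature-feature arcs selected by conditional mutual information given the
  target, thinned to a maximum-weight spanning forest;
* maximum-likelihood CPT estimation from frequencies, with optional additive
  smoothing;
* exact inference by variable elimination (networks here have at most ~10
  nodes), supporting predictive (attributes -> disorder), diagnostic
  (disorder -> attributes) and intercausal reasoning through the same
  posterior computation;
* one-way sensitivity analysis: perturb a root prior, measure the induced
  change in a target posterior.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from vdtsurv.cohort import (
    ATTRIBUTES,
    ATTRIBUTE_STATES,
    CLASS_LABELS,
    DISORDER_VARIABLE,
    TRACKED_STATE,
    PopulationSpec,
    records_to_dataframe,
)

__all__ = [
    "CategoricalVariable",
    "Dag",
    "Cpt",
    "BayesianNetwork",
    "conditional_mutual_information",
    "learn_abn_structure",
    "fit_mle",
    "joint_probability",
    "posterior",
    "diagnostic_profile",
    "classify",
    "sensitivity",
    "naive_network_from_spec",
    "network_to_json",
    "network_from_json",
]


@dataclass(frozen=True)
class CategoricalVariable:
    """A named discrete variable with a fixed state order (used for tie-breaks)."""

    name: str
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.states) < 2:
            raise ValueError(f"variable {self.name!r} needs >= 2 states")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"variable {self.name!r} has duplicate states")


@dataclass(frozen=True)
class Dag:
    """Directed acyclic graph over named nodes."""

    nodes: frozenset[str]
    arcs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "arcs", frozenset(tuple(a) for a in self.arcs))
        for parent, child in self.arcs:
            if parent not in self.nodes or child not in self.nodes:
                raise ValueError(f"arc ({parent!r}, {child!r}) references undeclared node")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("graph contains a directed cycle")

    def parents(self, node: str) -> tuple[str, ...]:
        """Parents of ``node`` in sorted order (the canonical CPT parent order)."""
        return tuple(sorted(p for p, c in self.arcs if c == node))

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(c for p, c in self.arcs if p == node))


@dataclass
class Cpt:
    """Conditional probability table: one child-state distribution per parent combo.

    ``table`` maps a tuple of parent states (in ``parents`` order; the empty
    tuple for roots) to a probability vector over the child's states.
    """

    child: str
    parents: tuple[str, ...]
    states: tuple[str, ...]
    table: dict[tuple[str, ...], np.ndarray]

    def __post_init__(self) -> None:
        self.parents = tuple(self.parents)
        self.states = tuple(self.states)
        self.table = {tuple(k): np.asarray(v, dtype=float) for k, v in self.table.items()}
        for combo, dist in self.table.items():
            if dist.shape != (len(self.states),):
                raise ValueError(
                    f"CPT row {combo} for {self.child!r} has wrong length"
                )
            if abs(dist.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"CPT row {combo} for {self.child!r} sums to {dist.sum()!r}, not 1"
                )

    def prob(self, child_state: str, parent_states: tuple[str, ...]) -> float:
        return float(self.table[tuple(parent_states)][self.states.index(child_state)])


@dataclass
class BayesianNetwork:
    """The (variables, graph, CPTs) triplet."""

    variables: list[CategoricalVariable]
    graph: Dag
    cpts: dict[str, Cpt]

    def __post_init__(self) -> None:
        names = {v.name for v in self.variables}
        if names != set(self.graph.nodes):
            raise ValueError("variable list and graph nodes disagree")
        if set(self.cpts) != names:
            raise ValueError("exactly one CPT per node is required")
        for name, cpt in self.cpts.items():
            if cpt.parents != self.graph.parents(name):
                raise ValueError(
                    f"CPT parents {cpt.parents} for {name!r} != graph parents "
                    f"{self.graph.parents(name)}"
                )

    def variable(self, name: str) -> CategoricalVariable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(f"unknown variable {name!r}")


# ---------------------------------------------------------------------------
# structure learning
# ---------------------------------------------------------------------------

def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_dataframe(records)


def conditional_mutual_information(
    data: pd.DataFrame, x: str, y: str, given: str
) -> float:
    """CMI(X; Y | Z) in bits, from empirical frequencies.

    Non-negative and symmetric in (x, y); zero iff X and Y are conditionally
    independent in the empirical distribution.
    """
    n = len(data)
    if n == 0:
        raise ValueError("empty data")
    counts = data.groupby([given, x, y], observed=True).size()
    cmi = 0.0
    for z_val, sub in counts.groupby(level=0, observed=True):
        nz = sub.sum()
        p_z = nz / n
        joint = sub.droplevel(0) / nz  # P(x, y | z)
        px = joint.groupby(level=0, observed=True).sum()
        py = joint.groupby(level=1, observed=True).sum()
        for (xv, yv), p in joint.items():
            if p > 0:
                cmi += p_z * p * math.log2(p / (px[xv] * py[yv]))
    return max(cmi, 0.0)  # clip -0.0 from rounding


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {i: i for i in items}

    def find(self, a: str) -> str:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: str, b: str) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def learn_abn_structure(
    records,
    target: str = DISORDER_VARIABLE,
    cmi_threshold: float = 0.01,
) -> Dag:
    """Learn an augmented-naive-Bayes DAG.

    The target is the common parent of every feature (naive star).  Feature
    pairs with empirical CMI(Xi; Xj | target) above ``cmi_threshold`` compete
    for augmentation arcs; a maximum-weight spanning forest (Kruskal, ties
    broken by lexicographic pair order) keeps the structure a forest, and
    each tree is directed away from its lexicographically smallest member,
    so every feature has at most one feature parent.
    """
    data = _as_frame(records)
    if len(data) == 0:
        raise ValueError("empty record list")
    if target not in data.columns:
        raise KeyError(f"target {target!r} not among columns {list(data.columns)}")
    if cmi_threshold < 0:
        raise ValueError("cmi_threshold must be non-negative")

    features = sorted(c for c in data.columns if c != target)
    nodes = frozenset([target, *features])
    arcs = {(target, f) for f in features}

    weighted = []
    for a, b in itertools.combinations(features, 2):
        w = conditional_mutual_information(data, a, b, target)
        if w > cmi_threshold:
            weighted.append((w, (a, b)))
    # max-weight first; lexicographic pair order breaks weight ties
    weighted.sort(key=lambda item: (-item[0], item[1]))

    uf = _UnionFind(features)
    forest = nx.Graph()
    for _, (a, b) in weighted:
        if uf.union(a, b):
            forest.add_edge(a, b)

    for component in nx.connected_components(forest):
        root = min(component)
        for parent, child in nx.bfs_edges(forest.subgraph(component), root):
            arcs.add((parent, child))

    return Dag(nodes=nodes, arcs=frozenset(arcs))


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------

def fit_mle(
    graph: Dag,
    records,
    smoothing: float = 0.0,
    states: Mapping[str, Sequence[str]] | None = None,
) -> BayesianNetwork:
    """Maximum-likelihood CPT estimation from observed frequencies.

    Each row is ``(count + smoothing) / (row_total + smoothing * n_states)``.
    With zero smoothing an unobserved parent combination gets a uniform row
    (documented fallback).  ``states`` fixes state sets and their order; when
    omitted, known exam-record variables use their canonical state sets and
    anything else uses sorted observed values.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")
    data = _as_frame(records)
    missing = [n for n in graph.nodes if n not in data.columns]
    if missing:
        raise ValueError(f"records do not cover variables: {sorted(missing)}")

    def default_states(name: str) -> tuple[str, ...]:
        if name in ATTRIBUTE_STATES:
            return ATTRIBUTE_STATES[name]
        if name == DISORDER_VARIABLE:
            return CLASS_LABELS
        return tuple(sorted(data[name].unique()))

    state_of: dict[str, tuple[str, ...]] = {
        n: tuple(states[n]) if states is not None and n in states else default_states(n)
        for n in graph.nodes
    }
    for name, sts in state_of.items():
        bad = set(data[name].unique()) - set(sts)
        if bad:
            raise ValueError(
                f"variable {name!r} has record states outside declared set: {sorted(bad)}"
            )

    variables = [CategoricalVariable(n, state_of[n]) for n in sorted(graph.nodes)]
    cpts: dict[str, Cpt] = {}
    for node in graph.nodes:
        parents = graph.parents(node)
        child_states = state_of[node]
        k = len(child_states)
        table: dict[tuple[str, ...], np.ndarray] = {}
        if parents:
            grouped = data.groupby(list(parents), observed=True)[node]
            counts_by_combo = {
                (combo if isinstance(combo, tuple) else (combo,)): grp.value_counts()
                for combo, grp in grouped
            }
        else:
            counts_by_combo = {(): data[node].value_counts()}
        combos = (
            list(itertools.product(*(state_of[p] for p in parents))) if parents else [()]
        )
        for combo in combos:
            vc = counts_by_combo.get(combo)
            counts = np.array(
                [0.0 if vc is None else float(vc.get(s, 0)) for s in child_states]
            )
            total = counts.sum() + smoothing * k
            if total == 0:
                dist = np.full(k, 1.0 / k)  # unobserved combo, no smoothing
            else:
                dist = (counts + smoothing) / total
            table[combo] = dist
        cpts[node] = Cpt(child=node, parents=parents, states=child_states, table=table)

    return BayesianNetwork(variables=variables, graph=graph, cpts=cpts)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def joint_probability(bn: BayesianNetwork, assignment: Mapping[str, str]) -> float:
    """P(assignment) for a full assignment, via the factorization over parents."""
    if set(assignment) != set(bn.graph.nodes):
        missing = set(bn.graph.nodes) - set(assignment)
        raise ValueError(f"assignment must cover every variable; missing {sorted(missing)}")
    p = 1.0
    for node, cpt in bn.cpts.items():
        parent_states = tuple(assignment[q] for q in cpt.parents)
        p *= cpt.prob(assignment[node], parent_states)
    return p


class _Factor:
    """A non-negative table over a tuple of variables (axes in ``vars`` order)."""

    __slots__ = ("vars", "values")

    def __init__(self, variables: tuple[str, ...], values: np.ndarray):
        self.vars = variables
        self.values = values

    def multiply(self, other: "_Factor") -> "_Factor":
        merged = self.vars + tuple(v for v in other.vars if v not in self.vars)
        a = self._broadcast(merged)
        b = other._broadcast(merged)
        return _Factor(merged, a * b)

    def _broadcast(self, merged: tuple[str, ...]) -> np.ndarray:
        # move own axes into merged order, add singleton axes for absent vars
        perm = [self.vars.index(v) for v in merged if v in self.vars]
        arr = np.transpose(self.values, perm)
        shape = []
        i = 0
        for v in merged:
            if v in self.vars:
                shape.append(arr.shape[i])
                i += 1
            else:
                shape.append(1)
        return arr.reshape(shape)

    def sum_out(self, var: str) -> "_Factor":
        axis = self.vars.index(var)
        return _Factor(
            tuple(v for v in self.vars if v != var), self.values.sum(axis=axis)
        )


def _node_factor(bn: BayesianNetwork, node: str, evidence: Mapping[str, str]) -> _Factor:
    cpt = bn.cpts[node]
    axes = cpt.parents + (node,)
    cards = [len(bn.variable(v).states) for v in axes]
    values = np.empty(cards)
    for combo_idx in itertools.product(*(range(c) for c in cards[:-1])):
        combo = tuple(
            bn.variable(p).states[i] for p, i in zip(cpt.parents, combo_idx)
        )
        values[combo_idx] = cpt.table[combo]
    # condition on evidence by zeroing incompatible entries, then drop the axis
    factor = _Factor(axes, values)
    for var in axes:
        if var in evidence:
            states = bn.variable(var).states
            idx = states.index(evidence[var])
            axis = factor.vars.index(var)
            factor = _Factor(
                tuple(v for v in factor.vars if v != var),
                np.take(factor.values, idx, axis=axis),
            )
    return factor


def posterior(
    bn: BayesianNetwork,
    query: str,
    evidence: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Exact P(query | evidence) by variable elimination (min-degree order).

    Raises ``ValueError`` if the query is part of the evidence or if the
    evidence has probability zero under the network.
    """
    evidence = dict(evidence or {})
    if query in evidence:
        raise ValueError(f"query {query!r} appears in evidence")
    for var, state in evidence.items():
        if state not in bn.variable(var).states:
            raise ValueError(f"evidence state {state!r} invalid for {var!r}")
    bn.variable(query)  # raises on unknown query

    factors = [_node_factor(bn, node, evidence) for node in bn.graph.nodes]
    hidden = set(bn.graph.nodes) - {query} - set(evidence)

    while hidden:
        # min-degree: eliminate the variable whose product factor is smallest
        def cost(v: str) -> tuple[int, str]:
            involved_vars = set()
            for f in factors:
                if v in f.vars:
                    involved_vars.update(f.vars)
            return (len(involved_vars), v)  # name as deterministic tie-break

        var = min(hidden, key=cost)
        hidden.remove(var)
        involved = [f for f in factors if var in f.vars]
        rest = [f for f in factors if var not in f.vars]
        prod = involved[0]
        for f in involved[1:]:
            prod = prod.multiply(f)
        rest.append(prod.sum_out(var))
        factors = rest

    result = factors[0]
    for f in factors[1:]:
        result = result.multiply(f)
    values = result.values.reshape(-1)
    total = values.sum()
    if total <= 0.0:
        raise ValueError("evidence has probability zero under the network")
    dist = values / total
    return dict(zip(bn.variable(query).states, dist.tolist()))


def diagnostic_profile(
    bn: BayesianNetwork,
    disorder_state: str,
    disorder_var: str = DISORDER_VARIABLE,
    attributes: Sequence[str] | None = None,
) -> dict[str, float]:
    """Tracked-state posterior of every attribute given a disorder class.

    Diagnostic (effect -> cause direction) inference; on a network encoding
    the published population this reproduces a column of the published
    class-conditional frequency table.
    """
    if disorder_var not in bn.graph.nodes:
        raise KeyError(f"disorder variable {disorder_var!r} not in network")
    if disorder_state not in bn.variable(disorder_var).states:
        raise ValueError(f"unknown disorder state {disorder_state!r}")
    attrs = (
        list(attributes)
        if attributes is not None
        else [a for a in ATTRIBUTES if a in bn.graph.nodes]
    )
    profile = {}
    for attr in attrs:
        post = posterior(bn, attr, {disorder_var: disorder_state})
        tracked = TRACKED_STATE.get(attr, bn.variable(attr).states[0])
        profile[attr] = post[tracked]
    return profile


def classify(
    bn: BayesianNetwork,
    evidence: Mapping[str, str],
    target: str = DISORDER_VARIABLE,
) -> str:
    """Most probable target state given attribute evidence; ties break by state order."""
    post = posterior(bn, target, evidence)
    states = bn.variable(target).states
    probs = np.array([post[s] for s in states])
    return states[int(np.argmax(probs))]  # argmax takes the first maximum


def sensitivity(
    bn: BayesianNetwork,
    source: tuple[str, str],
    delta: float,
    target: tuple[str, str],
    evidence: Mapping[str, str] | None = None,
) -> float:
    """Signed change in P(target_state) when the source prior moves by ``delta``.

    The source must be a parentless node: its prior row is shifted by
    ``delta`` on the source state, with the remaining states renormalized
    proportionally, and the target posterior is recomputed.  Raises if the
    perturbed probabilities leave [0, 1].
    """
    src_var, src_state = source
    tgt_var, tgt_state = target
    if bn.graph.parents(src_var):
        raise ValueError(
            f"sensitivity source {src_var!r} must be a root (parentless) node"
        )
    cpt = bn.cpts[src_var]
    row = cpt.table[()].copy()
    i = cpt.states.index(src_state)
    new_p = row[i] + delta
    if not 0.0 <= new_p <= 1.0:
        raise ValueError(f"perturbed probability {new_p} outside [0, 1]")
    rest = 1.0 - row[i]
    new_row = row.copy()
    new_row[i] = new_p
    if rest > 0:
        scale = (1.0 - new_p) / rest
        for j in range(len(row)):
            if j != i:
                new_row[j] = row[j] * scale
    elif new_p != 1.0:
        raise ValueError("cannot renormalize: source state had probability 1")

    base = posterior(bn, tgt_var, evidence)[tgt_state]
    perturbed = BayesianNetwork(
        variables=list(bn.variables),
        graph=bn.graph,
        cpts={
            **bn.cpts,
            src_var: Cpt(src_var, (), cpt.states, {(): new_row}),
        },
    )
    return posterior(perturbed, tgt_var, evidence)[tgt_state] - base


# ---------------------------------------------------------------------------
# construction from a population spec; serialization
# ---------------------------------------------------------------------------

def naive_network_from_spec(spec: PopulationSpec) -> BayesianNetwork:
    """Naive-star network whose CPTs are set directly from generative parameters.

    The disorder class is the root with the class prior; every attribute is a
    child with its class-conditional tracked-state probabilities.  Diagnostic
    inference on this network returns the stored conditionals exactly.
    """
    spec.validate()
    nodes = frozenset([DISORDER_VARIABLE, *ATTRIBUTES])
    arcs = frozenset((DISORDER_VARIABLE, a) for a in ATTRIBUTES)
    graph = Dag(nodes=nodes, arcs=arcs)
    variables = [CategoricalVariable(DISORDER_VARIABLE, CLASS_LABELS)] + [
        CategoricalVariable(a, spec.attribute_states[a]) for a in ATTRIBUTES
    ]
    prior = np.array([spec.class_prior[c] for c in CLASS_LABELS])
    cpts = {
        DISORDER_VARIABLE: Cpt(DISORDER_VARIABLE, (), CLASS_LABELS, {(): prior / prior.sum()})
    }
    for attr in ATTRIBUTES:
        states = spec.attribute_states[attr]
        tracked_idx = states.index(TRACKED_STATE[attr])
        table = {}
        for c in CLASS_LABELS:
            p = spec.conditionals[(c, attr)]
            dist = np.empty(2)
            dist[tracked_idx] = p
            dist[1 - tracked_idx] = 1.0 - p
            table[(c,)] = dist
        cpts[attr] = Cpt(attr, (DISORDER_VARIABLE,), states, table)
    return BayesianNetwork(variables=variables, graph=graph, cpts=cpts)


def network_to_json(bn: BayesianNetwork) -> str:
    payload = {
        "variables": [{"name": v.name, "states": list(v.states)} for v in bn.variables],
        "arcs": sorted([list(a) for a in bn.graph.arcs]),
        "cpts": {
            name: {
                "parents": list(cpt.parents),
                "rows": [
                    {"parent_states": list(combo), "distribution": dist.tolist()}
                    for combo, dist in sorted(cpt.table.items())
                ],
            }
            for name, cpt in sorted(bn.cpts.items())
        },
    }
    return json.dumps(payload, indent=2)


def network_from_json(text: str) -> BayesianNetwork:
    payload = json.loads(text)
    variables = [
        CategoricalVariable(v["name"], tuple(v["states"])) for v in payload["variables"]
    ]
    nodes = frozenset(v.name for v in variables)
    arcs = frozenset(tuple(a) for a in payload["arcs"])
    graph = Dag(nodes=nodes, arcs=arcs)
    states_of = {v.name: v.states for v in variables}
    cpts = {
        name: Cpt(
            child=name,
            parents=tuple(entry["parents"]),
            states=states_of[name],
            table={
                tuple(row["parent_states"]): np.asarray(row["distribution"])
                for row in entry["rows"]
            },
        )
        for name, entry in payload["cpts"].items()
    }
    return BayesianNetwork(variables=variables, graph=graph, cpts=cpts)
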