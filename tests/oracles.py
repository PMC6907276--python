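"""Independent brute-force oracles used to cross-check the inference engine.

These deliberately share no code with vdtsurv.bayesnet beyond reading CPT
tables: posteriors are computed by full enumeration of the joint, CMI from an
explicit contingency table, and the naive-Bayes classifier from first
principles.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np

from vdtsurv.bayesnet import BayesianNetwork, CategoricalVariable, Cpt, Dag


def enumerate_posterior(bn: BayesianNetwork, query: str, evidence: dict[str, str]) -> dict[str, float]:
    """P(query | evidence) by summing the joint over every full assignment."""
    names = sorted(bn.graph.nodes)
    states = {v.name: v.states for v in bn.variables}
    acc = {s: 0.0 for s in states[query]}
    for combo in itertools.product(*(states[n] for n in names)):
        assignment = dict(zip(names, combo))
        if any(assignment[k] != v for k, v in evidence.items()):
            continue
        p = 1.0
        for node, cpt in bn.cpts.items():
            parent_states = tuple(assignment[q] for q in cpt.parents)
            p *= cpt.table[parent_states][cpt.states.index(assignment[node])]
        acc[assignment[query]] += p
    total = sum(acc.values())
    if total <= 0:
        raise ValueError("zero-probability evidence")
    return {s: v / total for s, v in acc.items()}


def contingency_cmi(triples: list[tuple[str, str, str]]) -> float:
    """CMI(X; Y | Z) in bits from raw (z, x, y) observations."""
    n = len(triples)
    c_zxy = Counter(triples)
    c_zx = Counter((z, x) for z, x, _ in triples)
    c_zy = Counter((z, y) for z, _, y in triples)
    c_z = Counter(z for z, _, _ in triples)
    cmi = 0.0
    for (z, x, y), k in c_zxy.items():
        p_xy_z = k / c_z[z]
        p_x_z = c_zx[(z, x)] / c_z[z]
        p_y_z = c_zy[(z, y)] / c_z[z]
        cmi += (c_z[z] / n) * p_xy_z * math.log2(p_xy_z / (p_x_z * p_y_z))
    return cmi


def naive_bayes_argmax(
    records, target_states, class_prior, conditionals, attributes, tracked
) -> list[str]:
    """Independent naive-Bayes MAP classifier from per-class Bernoulli parameters.

    ``conditionals[(cls, attr)]`` is P(attr = tracked state | cls).  Ties break
    by ``target_states`` order.
    """
    labels = []
    for r in records:
        best, best_score = None, -math.inf
        for cls in target_states:
            score = math.log(class_prior[cls]) if class_prior[cls] > 0 else -math.inf
            for attr in attributes:
                p = conditionals[(cls, attr)]
                hit = getattr(r, attr) == tracked[attr]
                q = p if hit else 1.0 - p
                score += math.log(q) if q > 0 else -math.inf
            if score > best_score:  # strict: first class wins ties
                best, best_score = cls, score
        labels.append(best)
    return labels


def random_binary_network(rng: np.random.Generator, max_nodes: int = 6) -> BayesianNetwork:
    """A random DAG over binary variables with Dirichlet CPT rows."""
    n = int(rng.integers(2, max_nodes + 1))
    names = [f"v{i}" for i in range(n)]
    order = list(rng.permutation(n))
    arcs = set()
    for i_pos in range(n):
        for j_pos in range(i_pos + 1, n):
            if rng.random() < 0.4:
                arcs.add((names[order[i_pos]], names[order[j_pos]]))
    graph = Dag(nodes=frozenset(names), arcs=frozenset(arcs))
    variables = [CategoricalVariable(name, ("s0", "s1")) for name in names]
    cpts = {}
    for name in names:
        parents = graph.parents(name)
        table = {}
        for combo in itertools.product(*(("s0", "s1") for _ in parents)):
            table[combo] = rng.dirichlet((1.0, 1.0))
        cpts[name] = Cpt(name, parents, ("s0", "s1"), table)
    return BayesianNetwork(variables=variables, graph=graph, cpts=cpts)
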