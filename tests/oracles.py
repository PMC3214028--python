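"""Independent reference implementations used to check the package.

Everything here is deliberately written from first principles (brute force,
closed forms, graph algorithms on networkx) and stays independent of the code
paths it validates.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np

BASES = "ACGT"


# ---------------------------------------------------------------------------
# substitution count pooling: brute force over every pair and site
# ---------------------------------------------------------------------------

def brute_force_pooled_counts(rows: list[str]) -> np.ndarray:
    F = np.zeros((4, 4))
    for r1, r2 in itertools.combinations(rows, 2):
        for a, b in zip(r1, r2):
            F[BASES.index(a), BASES.index(b)] += 1
            F[BASES.index(b), BASES.index(a)] += 1
    return F


# ---------------------------------------------------------------------------
# scalar TN93 closed form (independent of the vectorized implementation)
# ---------------------------------------------------------------------------

def tn93_scalar(row_i: str, row_j: str, pi: np.ndarray) -> float:
    """Closed-form TN93 distance with externally supplied base frequencies."""
    L = len(row_i)
    p1 = sum(1 for a, b in zip(row_i, row_j) if {a, b} == {"A", "G"}) / L
    p2 = sum(1 for a, b in zip(row_i, row_j) if {a, b} == {"C", "T"}) / L
    q = sum(1 for a, b in zip(row_i, row_j) if a != b) / L - p1 - p2
    piA, piC, piG, piT = pi
    piR, piY = piA + piG, piC + piT
    k1 = 2 * piA * piG / piR
    k2 = 2 * piC * piT / piY
    k3 = 2 * (piR * piY - piA * piG * piY / piR - piC * piT * piR / piY)
    w1 = 1 - p1 / k1 - q / (2 * piR)
    w2 = 1 - p2 / k2 - q / (2 * piY)
    w3 = 1 - q / (2 * piR * piY)
    if min(w1, w2, w3) <= 0:
        return math.nan
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def jc_distance(row_i: str, row_j: str) -> float:
    p = sum(1 for a, b in zip(row_i, row_j) if a != b) / len(row_i)
    return -0.75 * math.log(1 - 4 * p / 3)


# ---------------------------------------------------------------------------
# K2P sequence-pair simulation via the closed-form transition probabilities
# ---------------------------------------------------------------------------

_TRANSITION_OF = {"A": "G", "G": "A", "C": "T", "T": "C"}


def k2p_evolve(seq: str, t: float, kappa: float, rng: np.random.Generator) -> str:
    """Evolve under K2P (transition/transversion rate ratio kappa, unit mean
    rate) for time t, using the analytic substitution probabilities."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4 * beta * t)
    e2 = math.exp(-2 * (alpha + beta) * t)
    p_transition = 0.25 + 0.25 * e1 - 0.5 * e2
    p_each_transversion = 0.25 * (1 - e1)
    out = []
    for base in seq:
        u = rng.random()
        if u < p_transition:
            out.append(_TRANSITION_OF[base])
        elif u < p_transition + 2 * p_each_transversion:
            tv = [b for b in BASES if b != base and b != _TRANSITION_OF[base]]
            out.append(tv[0] if u < p_transition + p_each_transversion else tv[1])
        else:
            out.append(base)
    return "".join(out)


# ---------------------------------------------------------------------------
# tree -> networkx graph, path distances, brute-force PD and clades
# ---------------------------------------------------------------------------

def tree_to_graph(tree) -> nx.Graph:
    graph = nx.Graph()
    counter = itertools.count()

    def walk(node):
        label = node.name if node.is_tip else f"__internal_{next(counter)}"
        graph.add_node(label)
        for child in node.children:
            child_label = walk(child)
            graph.add_edge(label, child_label, length=child.length or 0.0)
        return label

    walk(tree.root)
    return graph


def path_distance_matrix(tree, tip_order: list[str]) -> np.ndarray:
    graph = tree_to_graph(tree)
    lengths = dict(nx.all_pairs_dijkstra_path_length(graph, weight="length"))
    n = len(tip_order)
    d = np.zeros((n, n))
    for i, a in enumerate(tip_order):
        for j, b in enumerate(tip_order):
            d[i, j] = lengths[a][b]
    return d


def pd_path_union(tree, subset: set[str]) -> float:
    """Faith's PD as the total length of the union of tip-to-tip paths."""
    graph = tree_to_graph(tree)
    edges = set()
    for a, b in itertools.combinations(sorted(subset), 2):
        path = nx.shortest_path(graph, a, b, weight="length")
        edges.update(frozenset(e) for e in zip(path, path[1:]))
    return sum(graph.edges[tuple(e)]["length"] for e in edges)


def all_clades(tree) -> set[frozenset[str]]:
    """Every side of every edge of the unrooted tree, plus the full tip set."""
    graph = tree_to_graph(tree)
    tips = {n for n in graph.nodes if not str(n).startswith("__internal_")}
    clades = {frozenset(tips)}
    for edge in list(graph.edges):
        length = graph.edges[edge]["length"]
        graph.remove_edge(*edge)
        comps = list(nx.connected_components(graph))
        graph.add_edge(*edge, length=length)
        for comp in comps:
            side = frozenset(comp & tips)
            if side:
                clades.add(side)
    return clades


def brute_force_zero_clusters(tree, ids: list[str], d: np.ndarray) -> set[frozenset[str]]:
    """Exhaustive search: for every tip, the largest clade containing it whose
    members are pairwise at distance exactly zero."""
    index = {s: i for i, s in enumerate(ids)}
    clades = sorted(all_clades(tree), key=len, reverse=True)

    def zero_diameter(group):
        return all(
            d[index[a], index[b]] == 0.0
            for a, b in itertools.combinations(sorted(group), 2)
        )

    result = set()
    for tip in ids:
        best = frozenset({tip})
        for clade in clades:
            if tip in clade and len(clade) > len(best) and zero_diameter(clade):
                best = clade
                break
        result.add(best)
    return result
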