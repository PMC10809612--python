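"""Independent oracles used across the test suite.

These deliberately avoid the package's dynamic-programming and
simulation code paths: exhaustive enumeration for parsimony, direct
recounts for distances, closed forms for population genetics.
"""

from __future__ import annotations

import itertools
import math

from mitoegt.parsimony import TIP_ADMISSIBLE, TransitionCostMatrix
from mitoegt.tree import Cladogram

_S = ("M", "N", "L")


def _edge_pair(costs: TransitionCostMatrix, a: str, b: str):
    return (costs.cost(a, b), 1 if (a == "M" and b == "N") else 0)


def brute_force_min(
    tree: Cladogram,
    tips: dict[str, str],
    costs: TransitionCostMatrix = TransitionCostMatrix(),
):
    """Exhaustive minimum over all internal labelings.

    Leaf states are minimised per leaf given the parent label, which is
    exact because the lexicographic order on (cost, transfers) is
    translation-invariant, so independent sums minimise separately.
    """
    internals = [nd for nd in tree.postorder() if not nd.is_leaf()]
    index = {nd: i for i, nd in enumerate(internals)}
    int_edges = [
        (index[nd.parent_node], index[nd])
        for nd in internals
        if nd.parent_node is not None
    ]
    leaf_mins = []  # (parent index, {parent state: best pair})
    for nd in tree.leaves():
        adm = TIP_ADMISSIBLE[tips[nd.taxon.label]]
        table = {
            a: min(_edge_pair(costs, a, b) for b in adm) for a in _S
        }
        leaf_mins.append((index[nd.parent_node], table))
    root_i = index[tree.root]

    best = (math.inf, 0)
    for labeling in itertools.product(_S, repeat=len(internals)):
        if tree.has_stem:
            c, t = _edge_pair(costs, "M", labeling[root_i])
        else:
            c, t = 0.0, 0
        for pi, ci in int_edges:
            dc, dt = _edge_pair(costs, labeling[pi], labeling[ci])
            c += dc
            t += dt
        for pi, table in leaf_mins:
            dc, dt = table[labeling[pi]]
            c += dc
            t += dt
        if (c, t) < best:
            best = (c, t)
    cost, transfers = best
    losses = round((cost - costs.c_t * transfers) / costs.c_l)
    return cost, transfers, losses


def random_topology(labels, rng, polytomy_prob=0.25) -> str:
    """Random rooted topology over the labels, polytomies allowed."""

    def build(group):
        if len(group) == 1:
            return group[0]
        n_parts = 2
        if len(group) > 2 and rng.random() < polytomy_prob:
            n_parts = int(rng.integers(3, len(group) + 1))
        # random surjective assignment of members to parts
        while True:
            assign = rng.integers(0, n_parts, size=len(group))
            if len(set(assign.tolist())) == n_parts:
                break
        parts = [
            [g for g, a in zip(group, assign) if a == k]
            for k in range(n_parts)
        ]
        return "(" + ",".join(build(p) for p in parts) + ")"

    labels = list(labels)
    return build(labels) + ";"


def count_maximal_nd_subtrees(tree: Cladogram, tips: dict[str, str]) -> int:
    """Number of maximal subtrees whose leaves are all N or D.

    Computed bottom-up directly from tip states, with no reference to
    the parsimony machinery.
    """
    all_nd = {}
    for nd in tree.postorder():
        if nd.is_leaf():
            all_nd[nd] = tips[nd.taxon.label] in ("N", "D")
        else:
            all_nd[nd] = all(all_nd[c] for c in nd.child_nodes())
    count = 0
    for nd in tree.preorder():
        parent = nd.parent_node
        if all_nd[nd] and (parent is None or not all_nd[parent]):
            count += 1
    return count


def wf_neutral_fixation(initial_count: int, n_pop: int) -> float:
    """Neutral Wright–Fisher fixation probability = initial frequency."""
    return initial_count / n_pop


def haploid_diffusion_fixation(s_cost: float, n_pop: int, p0: float) -> float:
    """Diffusion fixation probability for a deleterious haploid allele.

    ``s_cost`` is the fitness cost (w = 1 - s); for one initial copy
    this is (1 - e^{2s}) / (1 - e^{2Ns}).
    """
    if s_cost == 0:
        return p0
    num = 1.0 - math.exp(2 * n_pop * s_cost * p0)
    den = 1.0 - math.exp(2 * n_pop * s_cost)
    return num / den
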