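"""Asymmetric (Dollo-like) parsimony for mitochondrion-to-nucleus transfer.

Each gene is a three-state character on the species cladogram:

* ``M`` — encoded in the mitochondrial genome (ancestral),
* ``N`` — encoded in the nuclear genome (derived, via transfer),
* ``L`` — lost.

Transfer is treated as irreversible: functional relocation back into
the mitochondrial genome is essentially unobserved in nature, so the
cost matrix forbids ``N→M``, ``L→M`` and ``L→N`` outright.  Allowed
transitions are the transfer ``M→N`` (cost ``c_t``) and the losses
``M→L`` and ``N→L`` (cost ``c_l`` each).

The dynamic program is Sankoff's: each node carries a per-state value,
children of a node (any number — polytomies are legal) combine by
summation, and an edge contributes the transition cost between parent
and child states.  Values are *pairs* ``(cost, transfers)`` ordered
lexicographically, so the program returns, among all minimum-cost
ancestral labelings, the one with the fewest transfers — reported
counts therefore carry "at least this many independent transfers"
semantics.  A virtual stem edge above the root is pinned to the
ancestral state ``M`` (the last eukaryotic common ancestor was
mitochondrion-encoded for every gene considered), so a transfer shared
by all sampled taxa is counted once, on the stem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .matrix import GeneStateMatrix
from .tree import Cladogram

_INTERNAL_STATES = ("M", "N", "L")
STEM_EDGE = "stem"

#: admissible internal states per observed tip symbol
TIP_ADMISSIBLE: dict[str, tuple[str, ...]] = {
    "M": ("M",),
    "N": ("N",),
    "L": ("L",),
    # a dual tip demonstrates that a transfer has occurred
    "D": ("N",),
    # unknown tips are free: absence of evidence is not loss
    "?": ("M", "N", "L"),
}


class ParsimonyError(ValueError):
    pass


@dataclass(frozen=True)
class TransitionCostMatrix:
    """Costs of state changes along one edge; irreversible moves are infinite."""

    c_t: float = 1.0  # transfer M -> N
    c_l: float = 1.0  # loss  M -> L  or  N -> L

    def __post_init__(self):
        if not (self.c_t > 0 and self.c_l > 0):
            raise ParsimonyError("finite costs must be positive")

    def cost(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        if a == "M" and b == "N":
            return self.c_t
        if b == "L" and a in ("M", "N"):
            return self.c_l
        return math.inf

    def scaled(self, factor: float) -> "TransitionCostMatrix":
        return TransitionCostMatrix(self.c_t * factor, self.c_l * factor)


@dataclass
class EventReconstruction:
    """Minimal-event explanation of one gene's tip states."""

    cost: float
    transfers: int
    losses: int
    #: representative per-edge event map: (edge id, "transfer" | "loss")
    events: list[tuple[str, str]] = field(default_factory=list)
    #: True when any lexicographic tie was broken during backtrace
    ambiguous: bool = False
    #: True when any tip was dual (D): both copies retained
    has_dual: bool = False
    #: representative ancestral state per node id
    node_states: dict[str, str] = field(default_factory=dict)


def _tip_value(state: str):
    try:
        adm = TIP_ADMISSIBLE[state]
    except KeyError:
        raise ParsimonyError(f"unknown tip state {state!r}")
    return {s: (0.0, 0) if s in adm else (math.inf, 0) for s in _INTERNAL_STATES}


def _edge_value(costs: TransitionCostMatrix, a: str, b: str):
    c = costs.cost(a, b)
    return (c, 1 if (a == "M" and b == "N") else 0)


def _add(u, v):
    return (u[0] + v[0], u[1] + v[1])


def _node_vectors(
    tree: Cladogram,
    tip_assignment: Mapping[str, str],
    costs: TransitionCostMatrix,
) -> dict:
    """Postorder Sankoff pass; returns per-node (cost, transfers) vectors."""
    vec: dict = {}
    for nd in tree.postorder():
        if nd.is_leaf():
            label = nd.taxon.label
            if label not in tip_assignment:
                raise ParsimonyError(f"leaf {label!r} has no tip assignment")
            vec[nd] = _tip_value(tip_assignment[label])
        else:
            node_vec = {}
            for a in _INTERNAL_STATES:
                total = (0.0, 0)
                for child in nd.child_nodes():
                    best = min(
                        _add(_edge_value(costs, a, b), vec[child][b])
                        for b in _INTERNAL_STATES
                    )
                    total = _add(total, best)
                node_vec[a] = total
            vec[nd] = node_vec
    return vec


def sankoff_min_cost(
    tree: Cladogram,
    tip_assignment: Mapping[str, str],
    costs: TransitionCostMatrix = TransitionCostMatrix(),
) -> tuple[float, int, int]:
    """Minimum total cost, minimum transfers among minimum-cost labelings,
    and the associated loss count.

    The stem edge (present on cladograms with ``has_stem``) fixes the
    state above the root to ``M``.
    """
    vec = _node_vectors(tree, tip_assignment, costs)
    root_vec = vec[tree.root]
    if tree.has_stem:
        best = min(
            _add(_edge_value(costs, "M", s), root_vec[s])
            for s in _INTERNAL_STATES
        )
    else:
        best = min(root_vec[s] for s in _INTERNAL_STATES)
    cost, transfers = best
    assert math.isfinite(cost), "root value must be finite for this cost matrix"
    losses = round((cost - costs.c_t * transfers) / costs.c_l)
    return cost, transfers, losses


def reconstruct_events(
    tree: Cladogram,
    tip_assignment: Mapping[str, str],
    costs: TransitionCostMatrix = TransitionCostMatrix(),
) -> EventReconstruction:
    """Backtrace one representative minimum-(cost, transfers) labeling.

    Ties between states are broken by the preference order
    ``M > N > L`` and flagged via ``ambiguous``.
    """
    vec = _node_vectors(tree, tip_assignment, costs)
    root_vec = vec[tree.root]
    ambiguous = False
    events: list[tuple[str, str]] = []
    node_states: dict[str, str] = {}

    def pick(options: dict[str, tuple]) -> tuple[str, bool]:
        best = min(options.values())
        winners = [s for s in _INTERNAL_STATES if options[s] == best]
        return winners[0], len(winners) > 1

    if tree.has_stem:
        opts = {
            s: _add(_edge_value(costs, "M", s), root_vec[s])
            for s in _INTERNAL_STATES
        }
    else:
        opts = dict(root_vec)
    root_state, tie = pick(opts)
    ambiguous |= tie
    if tree.has_stem and root_state != "M":
        events.append((STEM_EDGE, "transfer" if root_state == "N" else "loss"))

    assign = {tree.root: root_state}
    for nd in tree.preorder():
        a = assign[nd]
        node_states[nd.edge_id] = a
        for child in nd.child_nodes():
            copts = {
                b: _add(_edge_value(costs, a, b), vec[child][b])
                for b in _INTERNAL_STATES
            }
            b, tie = pick(copts)
            ambiguous |= tie
            assign[child] = b
            if b != a:
                if a == "M" and b == "N":
                    events.append((child.edge_id, "transfer"))
                elif b == "L":
                    events.append((child.edge_id, "loss"))
                else:  # pragma: no cover - forbidden by cost matrix
                    raise AssertionError("forbidden transition in backtrace")

    transfers = sum(1 for _, e in events if e == "transfer")
    losses = sum(1 for _, e in events if e == "loss")
    cost = costs.c_t * transfers + costs.c_l * losses
    # sanity: the representative must achieve the DP optimum
    opt_cost, opt_t, opt_l = sankoff_min_cost(tree, tip_assignment, costs)
    assert (cost, transfers) == (opt_cost, opt_t), "backtrace lost optimality"
    has_dual = any(tip_assignment[l] == "D" for l in tree.leaf_labels)
    return EventReconstruction(
        cost=cost,
        transfers=transfers,
        losses=losses,
        events=events,
        ambiguous=ambiguous,
        has_dual=has_dual,
        node_states=node_states,
    )


def count_transfers_matrix(
    tree: Cladogram,
    matrix: GeneStateMatrix,
    costs: TransitionCostMatrix = TransitionCostMatrix(),
) -> pd.DataFrame:
    """Per-gene minimal transfer/loss counts plus state percentages.

    The tree is pruned to the matrix taxa before inference.  Percentages
    are taken over taxa with a determinate state (not ``?``); dual
    (``D``) taxa count toward ``pct_N`` — a transfer has demonstrably
    occurred — so the three percentages sum to 100.
    """
    if not matrix.genes:
        raise ParsimonyError("empty gene set")
    pruned = tree.pruned_to(matrix.taxa)
    rows = []
    for gene in matrix.genes:
        tips = matrix.states[gene].to_dict()
        rec = reconstruct_events(pruned, tips, costs)
        col = matrix.states[gene]
        observed = col[col != "?"]
        n_obs = len(observed)
        pct = lambda k: 100.0 * k / n_obs if n_obs else float("nan")
        rows.append(
            {
                "gene": gene,
                "transfers": rec.transfers,
                "losses": rec.losses,
                "ambiguous": rec.ambiguous,
                "pct_M": pct((observed == "M").sum()),
                "pct_N": pct(((observed == "N") | (observed == "D")).sum()),
                "pct_L": pct((observed == "L").sum()),
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def replacement_events(
    tree: Cladogram,
    matrix: GeneStateMatrix,
    gene_set: Sequence[str],
    costs: TransitionCostMatrix = TransitionCostMatrix(),
    replacement_marker: Optional[Mapping[str, bool]] = None,
) -> tuple[int, list[tuple[str, str]]]:
    """Count independent losses/replacements of a whole gene module.

    The gene set (canonically the four bacteria-derived cytochrome *c*
    maturation ``ccm`` genes) collapses to one synthetic character per
    taxon: ``M`` if any member gene is still mitochondrion-encoded
    (``M`` or ``D``), otherwise ``L`` — or ``N`` when an optional
    replacement marker (e.g. a nuclear cytochrome *c* heme lyase) is
    present in that taxon.  Taxa whose member states are all ``?`` stay
    ``?``.  The usual irreversible DP then counts the independent
    module-level events; the returned count is transfers + losses of
    the collapsed character.
    """
    if not gene_set:
        raise ParsimonyError("gene_set must be non-empty")
    sub = matrix.subset_genes(list(gene_set))
    collapsed: dict[str, str] = {}
    for taxon in sub.taxa:
        row = sub.states.loc[taxon]
        if ((row == "M") | (row == "D")).any():
            collapsed[taxon] = "M"
        elif (row == "?").all():
            collapsed[taxon] = "?"
        elif replacement_marker is not None and replacement_marker.get(
            taxon, False
        ):
            collapsed[taxon] = "N"
        else:
            collapsed[taxon] = "L"
    pruned = tree.pruned_to(sub.taxa)
    rec = reconstruct_events(pruned, collapsed, costs)
    return rec.transfers + rec.losses, rec.events
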