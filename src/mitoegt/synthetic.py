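"""Synthetic data: trees, irreversibly evolved gene-state matrices, and
noisy presequence-predictor call tables.

This module is the stand-in for the real 86-taxon census.  It emulates
the processes the census is subject to:

* per-gene evolution down the species tree as a continuous-time Markov
  chain on ``{M, N, L}`` whose generator allows only ``M→N`` (transfer),
  ``M→L`` and ``N→L`` (loss) — never the reverse;
* branch-specific *burst* multipliers on the transfer rate, mimicking
  episodic spurts of relocation on particular lineages;
* imperfect detection for transcriptome-only taxa (a truly encoded gene
  recorded as lost);
* per-predictor sensitivity/specificity noise on presequence calls.

The ground truth (every simulated event, in order, per edge) is
returned alongside the observable matrix so inference can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional

import dendropy
import numpy as np
import pandas as pd

from .matrix import GeneStateMatrix
from .rng import RngLike, as_rng
from .tree import Cladogram


@dataclass(frozen=True)
class EvolveParams:
    """Rates and noise settings of the synthetic gene-state process.

    Rates are events per unit branch length.  ``burst_edges`` name the
    child-end node identifiers of edges on which the transfer rate is
    multiplied by ``burst_multiplier``.  ``detection_failure_prob`` is
    the probability that a truly encoded (M or N) gene is recorded as
    ``L`` in a transcriptome-evidence taxon; ``record_unknown`` emits
    ``?`` instead of ``L`` for such failures.  ``dwell_rate``, when
    set, routes transfers through the dual state ``D`` with an
    exponential dwell time before the mitochondrial copy is lost
    (``M→D→N``); by default dual retention is off, as it is rare in
    nature.
    """

    rate_transfer: float = 0.15
    rate_loss_m: float = 0.10
    rate_loss_n: float = 0.05
    burst_edges: frozenset = frozenset()
    burst_multiplier: float = 1.0
    n_genes: int = 20
    detection_failure_prob: float = 0.05
    transcriptome_fraction: float = 0.5
    record_unknown: bool = False
    dwell_rate: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if min(self.rate_transfer, self.rate_loss_m, self.rate_loss_n) < 0:
            raise ValueError("rates must be >= 0")
        if self.burst_multiplier < 1:
            raise ValueError("burst_multiplier must be >= 1")
        if not 0 <= self.detection_failure_prob <= 1:
            raise ValueError("detection_failure_prob must be in [0, 1]")
        if not 0 <= self.transcriptome_fraction <= 1:
            raise ValueError("transcriptome_fraction must be in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.dwell_rate is not None and self.dwell_rate <= 0:
            raise ValueError("dwell_rate must be positive when set")


@dataclass
class TrueEventLog:
    """Ground-truth events per gene: ordered (edge id, event type) pairs."""

    events: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def n_transfers(self, gene: str) -> int:
        return sum(1 for _, e in self.events.get(gene, []) if e == "transfer")

    def n_losses(self, gene: str) -> int:
        return sum(1 for _, e in self.events.get(gene, []) if e == "loss")

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for gene, evs in self.events.items():
                fh.write(
                    json.dumps({"gene": gene, "events": [list(e) for e in evs]})
                    + "\n"
                )

    @classmethod
    def from_jsonl(cls, path) -> "TrueEventLog":
        events = {}
        with open(path) as fh:
            for line in fh:
                rec = json.loads(line)
                events[rec["gene"]] = [tuple(e) for e in rec["events"]]
        return cls(events)


# ----------------------------------------------------------------------
# trees
def generate_tree(
    n_taxa: int,
    mode: str = "yule",
    seed: RngLike = None,
    birth_rate: float = 1.0,
    branch_length: float = 1.0,
) -> Cladogram:
    """Random or regular rooted binary tree with branch lengths.

    ``yule`` grows a pure-birth tree (rate ``birth_rate``) until
    ``n_taxa`` extant tips, ultrametric by construction.  ``balanced``
    builds the most balanced binary topology with every branch of
    length ``branch_length``.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if mode == "balanced":
        return _balanced_tree(n_taxa, branch_length)
    if mode == "yule":
        return _yule_tree_n(n_taxa, birth_rate, as_rng(seed))
    raise ValueError(f"unknown tree mode {mode!r}")


def yule_tree_fixed_time(
    birth_rate: float, max_time: float, seed: RngLike = None
) -> Cladogram:
    """Pure-birth tree grown for a fixed time from the root split.

    Starting from 2 lineages at time 0, each extant lineage splits at
    rate ``birth_rate``; the expected tip count at time ``t`` is
    ``2 * exp(birth_rate * t)``.  May return a 2-leaf cherry if no
    split occurs.
    """
    rng = as_rng(seed)
    root = _Bud(None)
    active = [_Bud(root), _Bud(root)]
    root.children = list(active)
    t = 0.0
    for b in active:
        b.birth = 0.0
    while True:
        wait = rng.exponential(1.0 / (birth_rate * len(active)))
        if t + wait >= max_time:
            break
        t += wait
        idx = rng.integers(len(active))
        parent = active.pop(int(idx))
        parent.length = t - parent.birth
        kids = [_Bud(parent), _Bud(parent)]
        for k in kids:
            k.birth = t
        parent.children = kids
        active.extend(kids)
    for b in active:
        b.length = max_time - b.birth
    return _buds_to_cladogram(root)


def _yule_tree_n(n_taxa: int, birth_rate: float, rng) -> Cladogram:
    root = _Bud(None)
    active = [_Bud(root), _Bud(root)]
    root.children = list(active)
    t = 0.0
    for b in active:
        b.birth = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = rng.integers(len(active))
        parent = active.pop(int(idx))
        parent.length = t - parent.birth
        kids = [_Bud(parent), _Bud(parent)]
        for k in kids:
            k.birth = t
        parent.children = kids
        active.extend(kids)
    # extend all tips to just before the (unrealised) next split
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    for b in active:
        b.length = t_end - b.birth
    return _buds_to_cladogram(root)


class _Bud:
    __slots__ = ("parent", "children", "birth", "length")

    def __init__(self, parent):
        self.parent = parent
        self.children = []
        self.birth = 0.0
        self.length = 0.0


def _buds_to_cladogram(root: _Bud) -> Cladogram:
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    counter = [0]

    def build(bud: _Bud, node: dendropy.Node):
        if not bud.children:
            counter[0] += 1
            node.taxon = taxon_ns.new_taxon(label=f"t{counter[0]}")
        for kid in bud.children:
            child = dendropy.Node()
            child.edge.length = kid.length
            node.add_child(child)
            build(kid, child)

    build(root, tree.seed_node)
    tree.is_rooted = True
    return Cladogram(tree)


def _balanced_tree(n_taxa: int, branch_length: float) -> Cladogram:
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    labels = [f"t{i + 1}" for i in range(n_taxa)]

    def build(node, lo, hi):
        if hi - lo == 1:
            node.taxon = taxon_ns.new_taxon(label=labels[lo])
            return
        mid = (lo + hi + 1) // 2
        for a, b in ((lo, mid), (mid, hi)):
            child = dendropy.Node()
            child.edge.length = branch_length
            node.add_child(child)
            build(child, a, b)

    build(tree.seed_node, 0, n_taxa)
    tree.is_rooted = True
    return Cladogram(tree)


# ----------------------------------------------------------------------
# gene-state evolution
def evolve_gene_states(
    tree: Cladogram,
    params: EvolveParams,
    evidence: Optional[Mapping[str, str]] = None,
    rng: RngLike = None,
) -> tuple[GeneStateMatrix, TrueEventLog]:
    """Evolve ``n_genes`` independent characters down the tree.

    Each gene starts in state ``M`` above the root and follows the
    irreversible continuous-time chain along every edge; burst edges
    multiply the transfer rate.  Detection noise is applied last, to
    tip states of transcriptome-evidence taxa.  Returns the observable
    matrix and the ground-truth event log.
    """
    if not tree.has_branch_lengths:
        raise ValueError("evolve_gene_states requires branch lengths")
    rng = as_rng(rng if rng is not None else params.seed)
    leaf_labels = tree.leaf_labels
    if evidence is None:
        is_tr = rng.random(len(leaf_labels)) < params.transcriptome_fraction
        evidence = {
            lab: ("transcriptome" if flag else "genome")
            for lab, flag in zip(leaf_labels, is_tr)
        }

    genes = [f"g{i + 1}" for i in range(params.n_genes)]
    log = TrueEventLog({g: [] for g in genes})
    tip_states = {g: {} for g in genes}

    for gene in genes:
        state_at = {tree.root: _evolve_root_state()}
        for nd in tree.preorder():
            if nd is tree.root:
                continue
            start = state_at[nd.parent_node]
            end, evs = _evolve_edge(
                start, nd.edge.length, nd.edge_id, params, rng
            )
            log.events[gene].extend(evs)
            state_at[nd] = end
        for lf in tree.leaves():
            tip_states[gene][lf.taxon.label] = state_at[lf]

    df = pd.DataFrame(
        {g: pd.Series(tip_states[g]) for g in genes}
    ).loc[leaf_labels]

    # detection noise: truly encoded genes unrecorded in transcriptome taxa
    q = params.detection_failure_prob
    if q > 0:
        miss_symbol = "?" if params.record_unknown else "L"
        for taxon in leaf_labels:
            if evidence[taxon] != "transcriptome":
                continue
            for g in genes:
                if df.at[taxon, g] in ("M", "N", "D") and rng.random() < q:
                    df.at[taxon, g] = miss_symbol
    return GeneStateMatrix(df, evidence=evidence), log


def _evolve_root_state() -> str:
    # the ancestral (LECA) state of every modelled gene is mitochondrial
    return "M"


def _evolve_edge(state, length, edge_id, params, rng):
    """Jump-chain simulation of one edge; returns (end state, events)."""
    rt = params.rate_transfer
    if edge_id in params.burst_edges:
        rt *= params.burst_multiplier
    events = []
    t = 0.0
    while True:
        if state == "M":
            out = rt + params.rate_loss_m
        elif state == "D":
            out = params.dwell_rate
        elif state == "N":
            out = params.rate_loss_n
        else:  # L absorbing
            return state, events
        if out <= 0:
            return state, events
        t += rng.exponential(1.0 / out)
        if t >= length:
            return state, events
        if state == "M":
            if rng.random() < rt / out:
                events.append((edge_id, "transfer"))
                state = "D" if params.dwell_rate is not None else "N"
            else:
                events.append((edge_id, "loss"))
                state = "L"
        elif state == "D":
            state = "N"  # mito copy decays; completes the transfer
        elif state == "N":
            events.append((edge_id, "loss"))
            state = "L"


def expected_transfer_count(tree: Cladogram, params: EvolveParams) -> float:
    """Analytic expected number of transfer events for one gene.

    The gene is still ``M`` at distance x into an edge with probability
    ``P(M at edge start) * exp(-(r_t' + r_lm) x)`` where rates are the
    edge's effective ones; integrating the transfer intensity along
    every edge gives the Poisson-process expectation used as an oracle
    for the stochastic simulator.
    """
    rlm = params.rate_loss_m
    total = 0.0
    p_m_at = {tree.root: 1.0}
    for nd in tree.preorder():
        if nd is tree.root:
            continue
        rt = params.rate_transfer
        if nd.edge_id in params.burst_edges:
            rt *= params.burst_multiplier
        out = rt + rlm
        p0 = p_m_at[nd.parent_node]
        L = nd.edge.length
        if out > 0:
            total += p0 * (rt / out) * (1.0 - np.exp(-out * L))
            p_m_at[nd] = p0 * np.exp(-out * L)
        else:
            p_m_at[nd] = p0
    return total


# ----------------------------------------------------------------------
# predictor calls
def generate_predictor_calls(
    truth: Mapping[str, bool],
    tools: Mapping[str, tuple[float, float]],
    seed: RngLike = None,
) -> pd.DataFrame:
    """Per-tool presequence calls with given sensitivity/specificity.

    For a protein that truly carries a presequence the tool calls
    positive with probability ``sensitivity``; for one that does not,
    it calls positive with probability ``1 - specificity``.
    """
    rng = as_rng(seed)
    for tool, (sens, spec) in tools.items():
        if not (0 <= sens <= 1 and 0 <= spec <= 1):
            raise ValueError(f"tool {tool!r}: sens/spec must be in [0, 1]")
    proteins = list(truth)
    t = np.array([bool(truth[p]) for p in proteins])
    data = {}
    for tool, (sens, spec) in tools.items():
        p_call = np.where(t, sens, 1.0 - spec)
        data[tool] = rng.random(len(proteins)) < p_call
    return pd.DataFrame(data, index=proteins).astype("boolean")
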