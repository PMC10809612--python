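"""Clustering of taxa by gene retention/loss/transfer patterns, and
Coulson-style per-group summary tables.

The distance between two taxa is the Hamming proportion over genes
observed (state ≠ ``?``) in *both* taxa, with the dual state ``D``
its own category.  Agglomeration uses average linkage; ties in the
minimum inter-cluster distance are broken by the lexicographic order
of cluster representatives (the smallest member name), so results are
independent of input order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .matrix import GeneStateMatrix
from .tree import Cladogram


class ClusteringError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ClusteringError("distance matrix shape mismatch")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0):
            raise ClusteringError("distance matrix must be symmetric with zero diagonal")
        if (v < 0).any() or not np.isfinite(v).all():
            raise ClusteringError("distances must be finite and non-negative")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)


def taxa_with_data(matrix: GeneStateMatrix) -> list[str]:
    """Taxa with at least one observed (non-``?``) gene state.

    Mirrors the census practice of excluding species without nuclear
    genomic or transcriptomic data before clustering.
    """
    mask = (matrix.states != "?").any(axis=1)
    return matrix.states.index[mask].tolist()


def pattern_distance(matrix: GeneStateMatrix) -> DistanceMatrix:
    """Pairwise Hamming distance over co-observed genes.

    A pair with no co-observed genes gets distance 1 with a warning.
    """
    taxa = matrix.taxa
    if len(taxa) < 2:
        raise ClusteringError("need at least 2 taxa")
    arr = matrix.states.to_numpy(dtype="U1")
    obs = arr != "?"
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            m = both.sum()
            if m == 0:
                warnings.warn(
                    f"taxa {taxa[i]!r} and {taxa[j]!r} share no observed "
                    "genes; distance set to 1"
                )
                d[i, j] = d[j, i] = 1.0
            else:
                d[i, j] = d[j, i] = (arr[i, both] != arr[j, both]).mean()
    return DistanceMatrix(list(taxa), d)


def hierarchical_cluster(distmat: DistanceMatrix) -> Cladogram:
    """Average-linkage agglomeration; returns a dendrogram as a cladogram
    with heights encoded as branch lengths.

    Merge heights are the average-linkage distances; a child's branch
    length is its parent's height minus its own.
    """
    n = len(distmat.taxa)
    d = {(i, j): distmat.values[i, j] for i in range(n) for j in range(i + 1, n)}
    size = {i: 1 for i in range(n)}
    rep = {i: distmat.taxa[i] for i in range(n)}
    height = {i: 0.0 for i in range(n)}
    nodes = {}
    taxon_ns = dendropy.TaxonNamespace()
    for i, t in enumerate(distmat.taxa):
        nd = dendropy.Node()
        nd.taxon = taxon_ns.new_taxon(label=t)
        nodes[i] = nd
    active = set(range(n))
    next_id = n

    def dist(i, j):
        return d[(i, j) if i < j else (j, i)]

    while len(active) > 1:
        best = min(
            ((dist(i, j), tuple(sorted((rep[i], rep[j]))), (i, j))
             for i in active for j in active if i < j),
        )
        h, _, (i, j) = best
        parent = dendropy.Node()
        for k in (i, j):
            nodes[k].edge.length = max(h - height[k], 0.0)
            parent.add_child(nodes[k])
        new = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            dk = (size[i] * dist(k, i) + size[j] * dist(k, j)) / (
                size[i] + size[j]
            )
            d[(min(k, new), max(k, new))] = dk
        active -= {i, j}
        active.add(new)
        nodes[new] = parent
        size[new] = size[i] + size[j]
        rep[new] = min(rep[i], rep[j])
        height[new] = h

    root_id = active.pop()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node = nodes[root_id]
    tree.is_rooted = True
    return Cladogram(tree, has_stem=False)


@dataclass
class GroupSummary:
    """Per-group per-gene state tallies and identical-pattern sectors."""

    #: rows indexed by (group, gene); count and fraction per state
    table: pd.DataFrame
    #: group -> list of (pattern tuple, multiplicity, member taxa)
    sectors: dict[str, list[tuple[tuple, int, list[str]]]] = field(
        default_factory=dict
    )


def summarize_groups(
    matrix: GeneStateMatrix, group_map: Mapping[str, str]
) -> GroupSummary:
    """Tally states per (group, gene) and unify identical row patterns.

    Fractions are over taxa with an observed state for the gene, so
    the M/N/L/D fractions sum to 1 where any state was observed.
    """
    unmapped = set(matrix.taxa) - set(group_map)
    if unmapped:
        raise ClusteringError(f"unmapped taxa: {sorted(unmapped)}")
    groups = pd.Series({t: group_map[t] for t in matrix.taxa})
    rows = []
    sectors: dict[str, list[tuple[tuple, int, list[str]]]] = {}
    for group, members in groups.groupby(groups).groups.items():
        sub = matrix.states.loc[list(members)]
        for gene in matrix.genes:
            col = sub[gene]
            counts = {s: int((col == s).sum()) for s in "MNLD?"}
            n_obs = len(col) - counts["?"]
            row = {"group": group, "gene": gene, "n_taxa": len(col)}
            for s in "MNLD?":
                row[f"count_{s}"] = counts[s]
            for s in "MNLD":
                row[f"frac_{s}"] = counts[s] / n_obs if n_obs else np.nan
            rows.append(row)
        pats: dict[tuple, list[str]] = {}
        for taxon in members:
            pats.setdefault(tuple(sub.loc[taxon]), []).append(taxon)
        sectors[group] = [
            (pat, len(taxa), taxa) for pat, taxa in pats.items()
        ]
    table = pd.DataFrame(rows).set_index(["group", "gene"])
    return GroupSummary(table=table, sectors=sectors)
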