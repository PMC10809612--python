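"""Rooted cladograms for gene-content evolution.

A :class:`Cladogram` is a thin, validated wrapper around a rooted
``dendropy.Tree``.  Polytomies are permitted, branch lengths are optional
(parsimony ignores them; the synthetic evolver requires them), and an
optional virtual *stem edge* above the root carries the ancestral
mitochondrion-encoded state so that events shared by all taxa are
countable as single events.

Every node carries a stable identifier (``node.edge_id`` on the wrapped
dendropy nodes): leaves use their taxon label, internal nodes use their
Newick label when present and otherwise an auto-assigned ``n<k>`` in
postorder.  Edges are referred to by the identifier of their child node.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional

import dendropy


class CladogramError(ValueError):
    """Raised when a tree violates the cladogram invariants."""


class Cladogram:
    """Rooted species tree with unique leaf labels and stable edge ids.

    Parameters
    ----------
    tree:
        A rooted ``dendropy.Tree``.  The instance takes ownership.
    has_stem:
        Whether a virtual stem edge above the root exists for event
        placement (the stem carries the fixed ancestral state).
    """

    def __init__(self, tree: dendropy.Tree, has_stem: bool = True):
        self._tree = tree
        self.has_stem = bool(has_stem)
        self._validate()
        self._assign_edge_ids()

    # ------------------------------------------------------------------
    # construction
    @classmethod
    def from_newick(cls, newick: str, has_stem: bool = True) -> "Cladogram":
        """Parse a Newick string (comments in ``[]`` stripped by the reader)."""
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error classes
            raise CladogramError(_describe_parse_error(newick, exc)) from exc
        tree.is_rooted = True
        return cls(tree, has_stem=has_stem)

    def to_newick(self) -> str:
        """Serialise to one-line Newick, preserving child order."""
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            suppress_edge_lengths=not self.has_branch_lengths,
        )
        return s.strip() + ("\n" if not s.strip().endswith("\n") else "")

    def copy(self) -> "Cladogram":
        return Cladogram(dendropy.Tree(self._tree), has_stem=self.has_stem)

    # ------------------------------------------------------------------
    # accessors
    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def root(self) -> dendropy.Node:
        return self._tree.seed_node

    def leaves(self) -> list[dendropy.Node]:
        return list(self._tree.leaf_node_iter())

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def has_branch_lengths(self) -> bool:
        return all(
            nd.edge.length is not None
            for nd in self._tree.preorder_node_iter()
            if nd.parent_node is not None
        )

    @property
    def total_length(self) -> float:
        """Sum of branch lengths (0.0 if lengths absent)."""
        return sum(
            nd.edge.length or 0.0
            for nd in self._tree.preorder_node_iter()
            if nd.parent_node is not None
        )

    def postorder(self) -> Iterator[dendropy.Node]:
        return self._tree.postorder_node_iter()

    def preorder(self) -> Iterator[dendropy.Node]:
        return self._tree.preorder_node_iter()

    def node_by_edge_id(self, edge_id: str) -> dendropy.Node:
        for nd in self._tree.preorder_node_iter():
            if nd.edge_id == edge_id:
                return nd
        raise KeyError(f"no node with edge id {edge_id!r}")

    # ------------------------------------------------------------------
    # manipulation
    def pruned_to(self, taxa: Iterable[str]) -> "Cladogram":
        """Return a copy restricted to the given leaf labels.

        Unifurcations created by pruning are suppressed (their branch
        lengths are summed), so the result is again a valid cladogram.
        """
        keep = set(taxa)
        missing = keep - set(self.leaf_labels)
        if missing:
            raise CladogramError(
                f"taxa absent from tree: {sorted(missing)}"
            )
        t = dendropy.Tree(self._tree)
        t.retain_taxa_with_labels(sorted(keep))
        t.suppress_unifurcations()
        # pruning can leave the root with a single child
        while len(t.seed_node.child_nodes()) == 1:
            child = t.seed_node.child_nodes()[0]
            t.seed_node = child
            child.parent_node = None
        return Cladogram(t, has_stem=self.has_stem)

    # ------------------------------------------------------------------
    # internals
    def _validate(self) -> None:
        labels = []
        for lf in self._tree.leaf_node_iter():
            if lf.taxon is None or not (lf.taxon.label or "").strip():
                raise CladogramError("leaf with empty or missing label")
            labels.append(lf.taxon.label)
        if len(labels) < 2:
            raise CladogramError("cladogram requires at least 2 leaves")
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise CladogramError(f"duplicate leaf labels: {sorted(dupes)}")
        for nd in self._tree.preorder_node_iter():
            kids = nd.child_nodes()
            if kids and len(kids) < 2:
                raise CladogramError(
                    "internal node with a single child (unifurcation)"
                )
            if nd.parent_node is not None and nd.edge.length is not None:
                if nd.edge.length < 0:
                    raise CladogramError(
                        f"negative branch length {nd.edge.length}"
                    )

    def _assign_edge_ids(self) -> None:
        counter = 0
        for nd in self._tree.postorder_node_iter():
            if nd.is_leaf():
                nd.edge_id = nd.taxon.label
            elif nd.label:
                nd.edge_id = str(nd.label)
            else:
                nd.edge_id = f"n{counter}"
                counter += 1


def _describe_parse_error(newick: str, exc: Exception) -> str:
    pos = ""
    line = getattr(exc, "line_num", None)
    col = getattr(exc, "col_num", None)
    if line is not None and col is not None:
        # byte offset assuming the reported line/column (1-based)
        lines = newick.split("\n")
        offset = sum(len(l) + 1 for l in lines[: line - 1]) + max(col - 1, 0)
        pos = f" at byte offset {offset} (line {line}, column {col})"
    return f"malformed Newick{pos}: {exc}"
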