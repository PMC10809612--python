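"""Gene-state matrices: which genome encodes each gene in each taxon.

States follow the gene-content census coding:

========  ==============================================
``M``     encoded in the mitochondrial genome
``N``     encoded in the nuclear genome (transferred)
``L``     lost, or not detected
``D``     dual: both mitochondrial and nuclear copies
``?``     unknown / no data
========  ==============================================

``L`` deliberately conflates loss with non-detection: for taxa whose
nuclear data come from a transcriptome only, an undetected gene may
simply not have been expressed.  The per-taxon ``evidence`` flag
(``genome`` vs ``transcriptome``) records which taxa are exposed to
that failure mode.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd

STATES = ("M", "N", "L", "D", "?")
EVIDENCE = ("genome", "transcriptome")


class MatrixError(ValueError):
    """Raised on gene-state matrix invariant violations."""


class GeneStateMatrix:
    """Taxa x genes matrix of genomic-location states.

    Parameters
    ----------
    states:
        DataFrame indexed by taxon, one column per gene, cells in
        ``{M, N, L, D, ?}``.
    evidence:
        Optional mapping taxon -> ``genome`` | ``transcriptome``;
        defaults to ``genome`` for every taxon.
    """

    def __init__(
        self,
        states: pd.DataFrame,
        evidence: Optional[Mapping[str, str]] = None,
    ):
        states = states.astype(str)
        if states.index.has_duplicates:
            dup = states.index[states.index.duplicated()].tolist()
            raise MatrixError(f"duplicate taxa: {dup}")
        if states.columns.has_duplicates:
            dup = states.columns[states.columns.duplicated()].tolist()
            raise MatrixError(f"duplicate genes: {dup}")
        bad = ~states.isin(STATES)
        if bad.to_numpy().any():
            r, c = next(zip(*bad.to_numpy().nonzero()))
            raise MatrixError(
                f"unknown state symbol {states.iloc[r, c]!r} at "
                f"taxon {states.index[r]!r}, gene {states.columns[c]!r}"
            )
        self.states = states
        if evidence is None:
            ev = pd.Series("genome", index=states.index)
        else:
            ev = pd.Series({t: evidence.get(t, "genome") for t in states.index})
            ev = ev.reindex(states.index)
        bad_ev = ev[~ev.isin(EVIDENCE)]
        if len(bad_ev):
            raise MatrixError(
                f"invalid evidence value {bad_ev.iloc[0]!r} for taxon "
                f"{bad_ev.index[0]!r} (expected one of {EVIDENCE})"
            )
        self.evidence = ev

    # ------------------------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return self.states.index.tolist()

    @property
    def genes(self) -> list[str]:
        return self.states.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.states.shape

    def state(self, taxon: str, gene: str) -> str:
        return self.states.at[taxon, gene]

    def subset_taxa(self, taxa: Sequence[str]) -> "GeneStateMatrix":
        return GeneStateMatrix(
            self.states.loc[list(taxa)],
            self.evidence.loc[list(taxa)].to_dict(),
        )

    def subset_genes(self, genes: Sequence[str]) -> "GeneStateMatrix":
        missing = set(genes) - set(self.genes)
        if missing:
            raise MatrixError(f"genes absent from matrix: {sorted(missing)}")
        return GeneStateMatrix(
            self.states[list(genes)], self.evidence.to_dict()
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneStateMatrix):
            return NotImplemented
        return self.states.equals(other.states) and self.evidence.equals(
            other.evidence
        )

    def __repr__(self) -> str:
        nt, ng = self.shape
        return f"GeneStateMatrix({nt} taxa x {ng} genes)"
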