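"""k-of-n consensus over mitochondrial-presequence predictor calls.

The census rule: a presequence is considered valid when at least two
of the three predictors (MitoFates, TargetP, TPpred3) call it.  This
module implements the general ``k``-of-``n`` rule over a call table;
the predictors themselves are external.  Missing calls shrink the
denominator rather than counting as negative, and a protein whose
missing calls could still change its verdict is flagged indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .matrix import GeneStateMatrix


class ConsensusError(ValueError):
    pass


@dataclass
class ConsensusResult:
    """Per-protein consensus verdicts.

    ``table`` columns: ``n_positive``, ``n_missing``, ``verdict``
    (count of positive non-missing calls ≥ k), ``indeterminate``
    (verdict is negative but the missing calls could have reached k).
    """

    table: pd.DataFrame
    k: int
    tools: list[str]


def consensus_calls(calls: pd.DataFrame, k: int = 2) -> ConsensusResult:
    """Apply the ≥ k-of-n rule to a protein × tool boolean call table.

    ``calls`` uses pandas nullable booleans; ``pd.NA`` marks a missing
    call.
    """
    n_tools = calls.shape[1]
    if n_tools < 1:
        raise ConsensusError("need at least one tool")
    if not 1 <= k <= n_tools:
        raise ConsensusError(f"k={k} out of range for {n_tools} tools")
    calls = calls.astype("boolean")
    n_pos = calls.fillna(False).sum(axis=1).astype(int)
    n_missing = calls.isna().sum(axis=1).astype(int)
    verdict = n_pos >= k
    indeterminate = (~verdict) & (n_pos + n_missing >= k)
    table = pd.DataFrame(
        {
            "n_positive": n_pos,
            "n_missing": n_missing,
            "verdict": verdict,
            "indeterminate": indeterminate,
        }
    )
    return ConsensusResult(table=table, k=k, tools=calls.columns.tolist())


def annotate_matrix_with_mts(
    matrix: GeneStateMatrix, consensus: ConsensusResult
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join consensus verdicts onto the gene-state matrix.

    Consensus proteins must be keyed by ``(taxon, gene)`` (a pandas
    MultiIndex).  Returns a long table (taxon, gene, state, mts) and a
    cross-tab of location state × MTS verdict — the table behind the
    observation that mitochondrion-encoded versions lack detectable
    presequences.
    """
    idx = consensus.table.index
    if not isinstance(idx, pd.MultiIndex) or idx.nlevels != 2:
        raise ConsensusError(
            "consensus must be keyed by a (taxon, gene) MultiIndex"
        )
    known = {(t, g) for t in matrix.taxa for g in matrix.genes}
    bad = [key for key in idx if key not in known]
    if bad:
        raise ConsensusError(f"consensus keys absent from matrix: {bad[:5]}")
    long = matrix.states.stack()
    long.index.names = ["taxon", "gene"]
    long = long.rename("state").to_frame()
    mts = consensus.table["verdict"]
    mts.index.names = ["taxon", "gene"]
    long["mts"] = (
        mts.astype("boolean").reindex(long.index).fillna(False).astype(bool)
    )
    crosstab = pd.crosstab(long["state"], long["mts"])
    return long.reset_index(), crosstab
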