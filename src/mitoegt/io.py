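"""File formats: Newick trees and TSV gene-state / predictor-call tables."""

from __future__ import annotations

import os
from typing import Union

import pandas as pd

from .matrix import EVIDENCE, GeneStateMatrix, MatrixError
from .tree import Cladogram, CladogramError

PathLike = Union[str, os.PathLike]

_EVIDENCE_COL = "evidence"


def read_newick(path: PathLike, has_stem: bool = True) -> Cladogram:
    """Read a rooted cladogram from a Newick file.

    Quoted and unquoted labels are accepted, polytomies are preserved,
    ``[...]`` comments are stripped, and branch lengths are retained
    when present.
    """
    with open(path) as fh:
        text = fh.read()
    return Cladogram.from_newick(text, has_stem=has_stem)


def write_newick(tree: Cladogram, path: PathLike) -> None:
    """Write a cladogram as Newick, preserving input child order."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick())


def read_state_matrix(path: PathLike) -> GeneStateMatrix:
    """Read a taxa-rows x gene-columns TSV of location states.

    The header row names the genes; the first column holds taxon names;
    an optional ``evidence`` column (``genome``/``transcriptome``) may
    follow the taxon column.  Cells must be in ``{M, N, L, D, ?}``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    df.index = df.index.astype(str)
    if df.index.isna().any() or df.isna().to_numpy().any():
        raise MatrixError(f"{path}: ragged or incomplete rows")
    evidence = None
    if _EVIDENCE_COL in df.columns:
        evidence = df[_EVIDENCE_COL].to_dict()
        df = df.drop(columns=[_EVIDENCE_COL])
    return GeneStateMatrix(df, evidence=evidence)


def write_state_matrix(
    matrix: GeneStateMatrix, path: PathLike, include_evidence: bool = True
) -> None:
    df = matrix.states.copy()
    if include_evidence:
        df.insert(0, _EVIDENCE_COL, matrix.evidence)
    df.to_csv(path, sep="\t", index_label="taxon")


def read_predictor_table(path: PathLike) -> pd.DataFrame:
    """Read a protein x predictor boolean call table.

    Cells are ``1``/``0``/``true``/``false`` (case-insensitive); an
    empty cell or ``NA`` marks a missing call and is kept as missing
    rather than defaulted to negative.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    mapping = {
        "1": True, "0": False,
        "true": True, "false": False,
        "t": True, "f": False,
    }

    def conv(x):
        if x is None or (isinstance(x, float) and pd.isna(x)) or pd.isna(x):
            return pd.NA
        key = str(x).strip().lower()
        if key in ("", "na", "nan"):
            return pd.NA
        if key not in mapping:
            raise MatrixError(f"{path}: unparseable call {x!r}")
        return mapping[key]

    return df.map(conv).astype("boolean")


def write_predictor_table(table: pd.DataFrame, path: PathLike) -> None:
    out = table.map(
        lambda v: "" if pd.isna(v) else ("1" if bool(v) else "0")
    )
    out.to_csv(path, sep="\t", index_label="protein")
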