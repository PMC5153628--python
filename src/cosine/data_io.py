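"""Reading, writing and validation of interaction and similarity matrices.

The on-disk dialect is the tab-delimited adjacency table used by the public
Yamanishi gold-standard distributions: a header row of chemical identifiers,
a first column of target identifiers, and a "0"/"1" body (similarity tables
carry floats instead).  Real gold-standard files drop in unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input table (ragged rows, non-binary cells, non-square)."""


class ValidationError(ValueError):
    """Structurally parseable input violating a dataset invariant."""


class AlignmentError(ValueError):
    """Identifier sets cannot be reconciled between matrices."""


@dataclass
class InteractionDataset:
    """Binary protein-chemical interaction matrix with identifiers.

    ``R[i, j] = 1`` records a verified interaction between target
    ``target_ids[i]`` and chemical ``chemical_ids[j]``; 0 is ambiguous
    (no interaction, or simply untested) -- the one-class setting.
    """

    target_ids: list[str]
    chemical_ids: list[str]
    R: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        m, n = self.R.shape
        if m < 1 or n < 1:
            raise ValidationError("interaction matrix must be at least 1x1")
        if len(self.target_ids) != m or len(self.chemical_ids) != n:
            raise ValidationError(
                f"identifier counts ({len(self.target_ids)}, {len(self.chemical_ids)}) "
                f"do not match matrix shape {self.R.shape}"
            )
        for axis_name, ids in (("target", self.target_ids), ("chemical", self.chemical_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if ids.count(x) > 1})
                raise ValidationError(f"duplicate {axis_name} identifiers: {dupes}")
        bad = ~np.isin(self.R, (0.0, 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary entry {self.R[i, j]!r} at target {self.target_ids[i]!r}, "
                f"chemical {self.chemical_ids[j]!r}"
            )

    @property
    def n_targets(self) -> int:
        return self.R.shape[0]

    @property
    def n_chemicals(self) -> int:
        return self.R.shape[1]

    def copy(self) -> "InteractionDataset":
        return InteractionDataset(list(self.target_ids), list(self.chemical_ids), self.R.copy())


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise similarity scores in [0, 1] with unit diagonal.

    Typical sources: normalized Smith-Waterman alignment scores between
    protein sequences, or Tanimoto scores between chemical fingerprints.
    """

    ids: list[str]
    S: np.ndarray
    validate: bool = True

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        k = len(self.ids)
        if self.S.shape != (k, k):
            raise ValidationError(f"similarity matrix shape {self.S.shape} != ({k}, {k})")
        if len(set(self.ids)) != k:
            raise ValidationError("duplicate identifiers in similarity matrix")
        if self.validate:
            if not np.isfinite(self.S).all():
                raise ValidationError("non-finite similarity entries")
            if not np.allclose(self.S, self.S.T, atol=1e-9):
                raise ValidationError("similarity matrix not symmetric within 1e-9")
            if (self.S < 0).any() or (self.S > 1).any():
                raise ValidationError("similarity entries outside [0, 1]")

    def copy(self) -> "SimilarityMatrix":
        return SimilarityMatrix(list(self.ids), self.S.copy())


def _standardize_similarity(ids: Sequence[str], S: np.ndarray, source: str = "") -> SimilarityMatrix:
    """Symmetrize as (S + S^T)/2, clip to [0, 1] with a warning, force unit diagonal."""
    S = np.asarray(S, dtype=float)
    if not np.isfinite(S).all():
        raise ValidationError(f"non-finite similarity values{' in ' + source if source else ''}")
    if not np.allclose(S, S.T, atol=1e-9):
        logger.info("symmetrizing asymmetric similarity matrix %s as (S + S^T)/2", source)
    S = (S + S.T) / 2.0
    n_clip = int(((S < 0) | (S > 1)).sum())
    if n_clip:
        warnings.warn(
            f"{n_clip} similarity entries outside [0, 1] were clipped{' in ' + source if source else ''}",
            stacklevel=3,
        )
        S = np.clip(S, 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(list(ids), S)


def load_interaction_matrix(path, dialect: str = "rows_are_targets") -> InteractionDataset:
    """Read a tab-delimited 0/1 adjacency table.

    Parameters
    ----------
    path : file path
        Table with identifier header row and identifier first column.
    dialect : {"rows_are_targets", "rows_are_chemicals"}
        Orientation of the file; output is always targets x chemicals.
    """
    if dialect not in ("rows_are_targets", "rows_are_chemicals"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if df.isna().any().any():
        raise FormatError(f"ragged or missing cells in {path}")
    try:
        body = df.astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
    row_ids = [str(x) for x in df.index]
    col_ids = [str(x) for x in df.columns]
    bad = ~np.isin(body, (0.0, 1.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"non-binary cell {body[i, j]!r} at row {row_ids[i]!r}, column {col_ids[j]!r} in {path}"
        )
    if dialect == "rows_are_chemicals":
        body = body.T
        row_ids, col_ids = col_ids, row_ids
    return InteractionDataset(target_ids=row_ids, chemical_ids=col_ids, R=body)


def save_interaction_matrix(data: InteractionDataset, path) -> None:
    df = pd.DataFrame(data.R.astype(int), index=data.target_ids, columns=data.chemical_ids)
    df.to_csv(path, sep="\t")


def load_similarity_matrix(path, id_order: Optional[Sequence[str]] = None) -> SimilarityMatrix:
    """Read a square tab-delimited similarity table and standardize it.

    The matrix is symmetrized as (S + S^T)/2, values outside [0, 1] are
    clipped with a warning, and the diagonal is forced to 1.  When
    ``id_order`` is given, rows/columns are reordered to it.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    row_ids = [str(x) for x in df.index]
    col_ids = [str(x) for x in df.columns]
    if len(row_ids) != len(col_ids) or set(row_ids) != set(col_ids):
        raise FormatError(f"similarity table in {path} is not square with matching identifiers")
    # realign columns to row order before any numeric step
    df = df.loc[row_ids, row_ids]
    sim = _standardize_similarity(row_ids, df.to_numpy(dtype=float), source=str(path))
    if id_order is not None:
        sim = reorder_similarity(sim, id_order)
    return sim


def save_similarity_matrix(sim: SimilarityMatrix, path) -> None:
    pd.DataFrame(sim.S, index=sim.ids, columns=sim.ids).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def reorder_similarity(sim: SimilarityMatrix, id_order: Sequence[str]) -> SimilarityMatrix:
    """Subset/reorder a similarity matrix to ``id_order`` (must be a subset of its ids)."""
    pos = {identifier: k for k, identifier in enumerate(sim.ids)}
    missing = [x for x in id_order if x not in pos]
    if missing:
        raise AlignmentError(f"identifiers absent from similarity matrix: {missing}")
    idx = np.array([pos[x] for x in id_order], dtype=int)
    return SimilarityMatrix(list(id_order), sim.S[np.ix_(idx, idx)])


def align_datasets(
    interactions: InteractionDataset,
    target_sim: SimilarityMatrix,
    chem_sim: SimilarityMatrix,
) -> tuple[InteractionDataset, SimilarityMatrix, SimilarityMatrix]:
    """Reconcile identifier order across the three inputs.

    Similarity matrices are subset and reordered to the interaction dataset's
    identifier order; extra similarity entries are dropped.  A target or
    chemical without a similarity row is a hard error, because the
    weighted-profile cold-start step needs similarities for every entity.
    """
    M = reorder_similarity(target_sim, interactions.target_ids)
    N = reorder_similarity(chem_sim, interactions.chemical_ids)
    return interactions, M, N
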