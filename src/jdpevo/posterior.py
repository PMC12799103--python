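"""Per-cell alignment confidence and the >0.5 column filter.

Before tree inference, every alignment position gets a forward-backward
posterior confidence against the profile the alignment was built on, and
columns whose mean residue confidence does not exceed a threshold (default
0.5, strictly) are dropped.

Cell semantics: a residue in a *match* column carries the posterior
probability that it is emitted by that column's match state.  A residue in
a non-match (insert) column carries its total insert-state posterior
divided by the width of the insert slot — the columns of an unalignable
region are mutually non-identifiable, so confidence is diluted across the
slot.  Gap cells carry the delete-state posterior of the column's match
state (or NaN in a non-match column); they are excluded from column means
unless ``include_gap_cells`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hmm import ProfileHMM, posterior_decode
from .io import GAP, AlignmentBlock, decode_pp_code

__all__ = ["CellPosterior", "compute_cell_posteriors", "filter_columns"]


@dataclass
class CellPosterior:
    """Per (row, column) posterior confidences; NaN marks not-applicable."""

    values: np.ndarray  # (n_rows, n_columns)
    is_residue: np.ndarray  # boolean mask of residue cells

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _column_roles(model: ProfileHMM, ncols: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-column match-state index (-1 for insert columns) and the width of
    the insert slot each non-match column belongs to."""
    state_of = np.full(ncols, -1, dtype=np.int64)
    for k, c in enumerate(model.match_column_map):
        state_of[c] = k
    slot_width = np.zeros(ncols, dtype=np.int64)
    c = 0
    while c < ncols:
        if state_of[c] >= 0:
            c += 1
            continue
        j = c
        while j < ncols and state_of[j] < 0:
            j += 1
        slot_width[c:j] = j - c
        c = j
    return state_of, slot_width


def compute_cell_posteriors(
    model: ProfileHMM,
    aln: AlignmentBlock,
    trust_pp: bool = False,
) -> CellPosterior:
    """Forward-backward confidence for every cell of an alignment.

    Requires the alignment's columns to correspond to the model via its
    ``match_column_map`` (i.e. the model was built from this alignment or
    one with identical columns).  With ``trust_pp``, an existing Stockholm
    PP annotation is decoded instead of recomputing.
    """
    nrow, ncol = aln.n_rows, aln.column_count
    is_res = np.array([[c != GAP for c in row] for row in aln.matrix])
    if trust_pp:
        if aln.pp is None:
            raise ValueError("trust_pp requested but alignment has no PP lines")
        vals = np.full((nrow, ncol), np.nan)
        for r in range(nrow):
            for c in range(ncol):
                if is_res[r, c]:
                    vals[r, c] = decode_pp_code(aln.pp[r][c])
        return CellPosterior(vals, is_res)

    if model.match_column_map.max() >= ncol:
        raise ValueError(
            f"model columns (up to {model.match_column_map.max()}) incompatible "
            f"with alignment of {ncol} columns"
        )
    state_of, slot_width = _column_roles(model, ncol)
    vals = np.full((nrow, ncol), np.nan)
    for r in range(nrow):
        rec = aln.degapped(r)
        post = posterior_decode(model, rec)
        i = 0
        for c in range(ncol):
            if is_res[r, c]:
                k = state_of[c]
                if k >= 0:
                    vals[r, c] = post.p_match[i, k]
                else:
                    vals[r, c] = post.p_insert[i] / slot_width[c]
                i += 1
            else:
                k = state_of[c]
                vals[r, c] = post.p_delete[k] if k >= 0 else np.nan
    return CellPosterior(vals, is_res)


def filter_columns(
    aln: AlignmentBlock,
    pp: CellPosterior,
    threshold: float = 0.5,
    include_gap_cells: bool = False,
) -> tuple[AlignmentBlock, list[int]]:
    """Keep columns whose mean cell posterior strictly exceeds ``threshold``.

    By default the mean runs over residue cells only; all-gap columns are
    always dropped.  Returns the filtered block and the retained column
    indices.  Row order is preserved.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0,1]")
    if pp.shape != (aln.n_rows, aln.column_count):
        raise ValueError("posterior dimensions do not match alignment")
    retained: list[int] = []
    for c in range(aln.column_count):
        res_mask = pp.is_residue[:, c]
        if not res_mask.any():
            continue
        cells = pp.values[:, c] if include_gap_cells else pp.values[res_mask, c]
        cells = cells[~np.isnan(cells)]
        if cells.size and cells.mean() > threshold:
            retained.append(c)
    matrix = ["".join(row[c] for c in retained) for row in aln.matrix]
    new_pp = (
        ["".join(row[c] for c in retained) for row in aln.pp]
        if aln.pp is not None else None
    )
    return AlignmentBlock(list(aln.rows), matrix, new_pp), retained
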