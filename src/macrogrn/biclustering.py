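"""Cheng-Church delta-biclustering on expression matrices.

A bicluster is a subset of rows (genes) and columns (samples or strains)
whose mean squared residue

    H(I, J) = (1 / |I||J|) * sum_{i in I, j in J}
              (a_ij - a_iJ - a_Ij + a_IJ)^2

is at most delta, where a_iJ / a_Ij / a_IJ are the row, column and overall
means of the submatrix.  H is zero exactly for matrices of the additive
form a_ij = r_i + c_j (constant matrices included), so low-H submatrices
are sets of genes that shift together across the selected conditions.

Discovery follows the classical greedy scheme: multiple node deletion
(drop every row/column whose mean residue exceeds alpha * H) while the
matrix is large, single node deletion (drop the single worst row or
column) until H <= delta, then node addition (re-admit rows/columns whose
mean residue does not exceed H).  The found bicluster is masked with
seeded uniform noise over the matrix range and the search repeats, which
makes multi-bicluster discovery reproducible via the seed.  The original
algorithm's "mirror-image" (inverted row) addition is not implemented.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .containers import Bicluster
from .exceptions import UsageError

#: matrices smaller than this along an axis skip multiple node deletion
MULTIPLE_DELETION_MIN = 100


def _residue_stats(sub: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """H(I,J) plus per-row and per-column mean squared residues."""
    row_means = sub.mean(axis=1, keepdims=True)
    col_means = sub.mean(axis=0, keepdims=True)
    overall = sub.mean()
    res = sub - row_means - col_means + overall
    sq = res ** 2
    return float(sq.mean()), sq.mean(axis=1), sq.mean(axis=0)


def mean_squared_residue(
    matrix: pd.DataFrame,
    rows: Sequence[str] | None = None,
    cols: Sequence[str] | None = None,
) -> float:
    """Mean squared residue H(I, J) of a submatrix.

    ``rows``/``cols`` are label subsets of the matrix index/columns; both
    default to the full axis.  Empty subsets are a usage error.
    """
    row_labels = list(matrix.index if rows is None else rows)
    col_labels = list(matrix.columns if cols is None else cols)
    if not row_labels or not col_labels:
        raise UsageError("mean_squared_residue needs non-empty row and column sets")
    sub = matrix.loc[row_labels, col_labels].to_numpy(dtype=float)
    return _residue_stats(sub)[0]


def _single_node_deletion(
    data: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    delta: float,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Remove the worst row or column while H > delta.

    Returns the surviving index arrays and the trace of H values observed
    before each deletion (non-increasing by the deletion lemma: removing
    the row/column of maximal mean residue cannot increase H).
    """
    trace: list[float] = []
    while True:
        sub = data[np.ix_(rows, cols)]
        h, row_res, col_res = _residue_stats(sub)
        trace.append(h)
        if h <= delta:
            break
        if len(rows) <= 1 and len(cols) <= 1:
            break
        best_row = float(row_res.max()) if len(rows) > 1 else -np.inf
        best_col = float(col_res.max()) if len(cols) > 1 else -np.inf
        if best_row >= best_col:
            rows = np.delete(rows, int(np.argmax(row_res)))
        else:
            cols = np.delete(cols, int(np.argmax(col_res)))
    return rows, cols, trace


def _multiple_node_deletion(
    data: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    delta: float,
    alpha: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Batch-remove rows/columns with mean residue > alpha * H."""
    while True:
        sub = data[np.ix_(rows, cols)]
        h, row_res, col_res = _residue_stats(sub)
        if h <= delta:
            break
        changed = False
        if len(rows) > MULTIPLE_DELETION_MIN:
            keep = row_res <= alpha * h
            if keep.sum() >= 2 and not keep.all():
                rows = rows[keep]
                changed = True
        sub = data[np.ix_(rows, cols)]
        h, row_res, col_res = _residue_stats(sub)
        if h > delta and len(cols) > MULTIPLE_DELETION_MIN:
            keep = col_res <= alpha * h
            if keep.sum() >= 2 and not keep.all():
                cols = cols[keep]
                changed = True
        if not changed:
            break
    return rows, cols


def _node_addition(
    data: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    delta: float,
    n_rows_total: int,
    n_cols_total: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Re-admit columns then rows whose mean residue does not exceed H.

    A round of additions is reverted if it pushes H above delta (the
    classical lemma guarantees it cannot, but masking noise elsewhere in
    the matrix makes a guard cheap insurance).
    """
    while True:
        sub = data[np.ix_(rows, cols)]
        h = _residue_stats(sub)[0]
        row_means = sub.mean(axis=1)
        overall = sub.mean()
        added = False

        out_cols = np.setdiff1d(np.arange(n_cols_total), cols, assume_unique=False)
        if out_cols.size:
            cand = data[np.ix_(rows, out_cols)]
            col_means = cand.mean(axis=0)
            res = cand - row_means[:, None] - col_means[None, :] + overall
            cand_score = (res ** 2).mean(axis=0)
            admit = out_cols[cand_score <= h]
            if admit.size:
                new_cols = np.sort(np.concatenate([cols, admit]))
                if _residue_stats(data[np.ix_(rows, new_cols)])[0] <= delta:
                    cols = new_cols
                    added = True
                    sub = data[np.ix_(rows, cols)]
                    h = _residue_stats(sub)[0]
                    row_means = sub.mean(axis=1)
                    overall = sub.mean()

        out_rows = np.setdiff1d(np.arange(n_rows_total), rows, assume_unique=False)
        if out_rows.size:
            cand = data[np.ix_(out_rows, cols)]
            col_means = sub.mean(axis=0)
            res = cand - cand.mean(axis=1, keepdims=True) - col_means[None, :] + overall
            cand_score = (res ** 2).mean(axis=1)
            admit = out_rows[cand_score <= h]
            if admit.size:
                new_rows = np.sort(np.concatenate([rows, admit]))
                if _residue_stats(data[np.ix_(new_rows, cols)])[0] <= delta:
                    rows = new_rows
                    added = True

        if not added:
            break
    return rows, cols


def cheng_church(
    matrix: pd.DataFrame,
    delta: float | None = None,
    alpha: float = 1.2,
    n_biclusters: int = 1,
    seed: int = 0,
    return_traces: bool = False,
):
    """Greedy delta-bicluster discovery.

    Parameters
    ----------
    matrix:
        Genes x samples (or genes x strains) DataFrame of finite values.
    delta:
        MSR ceiling for reported biclusters.  Defaults to 10% of the full
        matrix's MSR, a scale-free choice usable on z-scored input.
    alpha:
        Multiple-deletion aggressiveness (> 1).
    n_biclusters:
        Maximum number of biclusters to report; discovery stops early when
        a round yields a degenerate (single row/column) bicluster.
    seed:
        Seeds the uniform masking noise, making repeated discovery
        deterministic.
    return_traces:
        Also return, per bicluster, the H trace of the single-deletion
        phase (used to assert deletion monotonicity).

    Returns a list of :class:`Bicluster` (with ``return_traces`` a tuple
    ``(biclusters, traces)``), each with |rows| >= 2 and |cols| >= 2 and
    ``msr <= delta``, in discovery order.
    """
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise UsageError("matrix contains non-finite values")
    if delta is None:
        delta = 0.1 * _residue_stats(values)[0]
    if delta < 0:
        raise UsageError("delta must be >= 0")
    if alpha <= 1:
        raise UsageError("alpha must be > 1")
    if n_biclusters < 1:
        raise UsageError("n_biclusters must be >= 1")

    rng = np.random.default_rng([seed, 47])
    data = values.copy()
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        hi = lo + 1.0  # degenerate constant matrix; mask range is arbitrary
    n_rows, n_cols = data.shape

    biclusters: list[Bicluster] = []
    traces: list[list[float]] = []
    for _ in range(n_biclusters):
        rows = np.arange(n_rows)
        cols = np.arange(n_cols)
        rows, cols = _multiple_node_deletion(data, rows, cols, delta, alpha)
        rows, cols, trace = _single_node_deletion(data, rows, cols, delta)
        rows, cols = _node_addition(data, rows, cols, delta, n_rows, n_cols)
        if len(rows) < 2 or len(cols) < 2:
            break
        # report against the *original* matrix: after masking, a round that
        # strayed into masked cells no longer certifies a real bicluster
        msr = _residue_stats(values[np.ix_(rows, cols)])[0]
        if msr <= delta:
            biclusters.append(
                Bicluster(
                    rows=tuple(matrix.index[rows]),
                    cols=tuple(matrix.columns[cols]),
                    msr=float(msr),
                )
            )
            traces.append(trace)
        data[np.ix_(rows, cols)] = rng.uniform(lo, hi, size=(len(rows), len(cols)))
    if return_traces:
        return biclusters, traces
    return biclusters


def write_bicluster_table(biclusters: Sequence[Bicluster], path) -> None:
    """TSV with one row per bicluster member: (bicluster_id, axis, member_id, msr)."""
    with open(path, "w") as fh:
        fh.write("bicluster_id\taxis\tmember_id\tmsr\n")
        for k, bc in enumerate(biclusters, start=1):
            for r in bc.rows:
                fh.write(f"{k}\trow\t{r}\t{bc.msr:.10g}\n")
            for c in bc.cols:
                fh.write(f"{k}\tcol\t{c}\t{bc.msr:.10g}\n")
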