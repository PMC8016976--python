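"""Weighted co-expression network analysis.

The pipeline follows the WGCNA recipe: a soft-thresholded adjacency
``a_ij = |cor(i, j)|^beta`` (unsigned by default; a signed variant
``((1 + cor)/2)^beta`` is available), soft connectivity ``k_i = sum_j
a_ij``, the unsigned topological overlap measure

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij   = sum_u a_iu * a_uj,

average-linkage hierarchical clustering on the dissimilarity 1 - TOM with
a height-scan tree cut for module detection, and an edge export threshold
chosen so the thresholded network has a requested mean degree.  The
soft-threshold power is picked as the smallest power whose scale-free fit
index reaches a target.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import CoexpressionNetwork
from .exceptions import UsageError, ValidationError
from .topology import powerlaw_fit_r2

UNASSIGNED_MODULE = "grey"
DEFAULT_FIT_TARGET = 0.68
DEFAULT_MIN_MODULE_SIZE = 30
DEFAULT_TARGET_MEAN_DEGREE = 15.0


def _correlation(log_matrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation across samples, constant genes dropped."""
    if log_matrix.shape[1] < 4:
        raise UsageError("co-expression analysis needs at least 4 samples")
    sds = log_matrix.std(axis=1, ddof=1)
    constant = sds == 0
    if constant.any():
        warnings.warn(
            f"excluding {int(constant.sum())} constant gene(s) from the "
            "correlation matrix",
            stacklevel=3,
        )
    sub = log_matrix.loc[~constant]
    if sub.shape[0] < 2:
        raise UsageError("need at least 2 non-constant genes")
    corr = np.corrcoef(sub.to_numpy(dtype=float))
    if not np.isfinite(corr).all():
        i, j = np.argwhere(~np.isfinite(corr))[0]
        raise ValidationError(
            f"non-finite correlation between {sub.index[i]!r} and {sub.index[j]!r}"
        )
    corr = np.clip(corr, -1.0, 1.0)
    return pd.DataFrame(corr, index=sub.index, columns=sub.index)


def adjacency_from_correlation(
    corr: pd.DataFrame, power: int, signed: bool = False
) -> pd.DataFrame:
    if power < 1:
        raise UsageError("soft-threshold power must be >= 1")
    base = np.abs(corr.to_numpy()) if not signed else (1.0 + corr.to_numpy()) / 2.0
    adj = base ** power
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(adj, index=corr.index, columns=corr.columns)


def pick_soft_threshold(
    log_matrix: pd.DataFrame,
    powers: Sequence[int] = tuple(range(1, 21)),
    target_fit: float = DEFAULT_FIT_TARGET,
    n_bins: int = 10,
    signed_fit: bool = True,
    signed_network: bool = False,
) -> tuple[int, pd.DataFrame]:
    """Scale-free fit index per candidate power; choose the first to reach
    the target, else the argmax with a warning.

    The fit index is the R^2 of log10(frequency) on log10(connectivity)
    over binned soft connectivities, multiplied by -sign(slope) so an
    upward-sloping (non-scale-free) connectivity distribution is
    penalized rather than rewarded; ``signed_fit=False`` gives the raw
    R^2.
    """
    if not len(powers):
        raise UsageError("powers must be non-empty")
    corr = _correlation(log_matrix)
    records = []
    for beta in powers:
        adj = adjacency_from_correlation(corr, beta, signed=signed_network)
        k = adj.to_numpy().sum(axis=0)
        try:
            r2, slope = powerlaw_fit_r2(k, n_bins=n_bins)
        except UsageError:
            r2, slope = np.nan, np.nan
        fit = -np.sign(slope) * r2 if (signed_fit and np.isfinite(slope)) else r2
        records.append(
            {"power": beta, "fit": fit, "r2": r2, "slope": slope, "mean_k": k.mean()}
        )
    table = pd.DataFrame(records)
    ok = table["fit"] >= target_fit
    if ok.any():
        chosen = int(table.loc[ok, "power"].iloc[0])
    else:
        chosen = int(table.loc[table["fit"].idxmax(), "power"])
        warnings.warn(
            f"no power reaches scale-free fit {target_fit}; "
            f"using argmax power {chosen}",
            stacklevel=2,
        )
    return chosen, table


def build_adjacency_tom(
    log_matrix: pd.DataFrame, power: int, signed: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Soft-thresholded adjacency and its topological overlap matrix.

    TOM is symmetric, lies in [0, 1], and has unit diagonal.
    """
    corr = _correlation(log_matrix)
    adj = adjacency_from_correlation(corr, power, signed=signed)
    a = adj.to_numpy()
    k = a.sum(axis=0)
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return adj, pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def _recursive_gap_split(
    d: np.ndarray, indices: np.ndarray, min_gap: float, min_size: int
) -> list[np.ndarray]:
    """Split a cluster at a merge-height gap, recursively.

    Average-linkage merge heights of a homogeneous cluster form a dense
    ramp; distinct sub-modules announce themselves as a gap between the
    within-module merges and the join that glues them together.  Cutting
    inside a gap and recursing into the parts handles hierarchies whose
    cross-module joins happen at staggered heights, where no single
    global cut separates every module.  Among candidate gaps of at least
    ``min_gap``, the cut that keeps the most genes in clusters of at
    least ``min_size`` wins (ties toward the larger gap), so a spurious
    low-height gap that would shatter the cluster into fragments loses to
    the true module boundary.  A cluster with no qualifying gap is left
    whole.
    """
    if indices.size < 3:
        return [indices]
    sub = d[np.ix_(indices, indices)]
    z = linkage(squareform(sub, checks=False), method="average")
    heights = np.unique(z[:, 2])
    if heights.size < 2:
        return [indices]
    gaps = np.diff(heights)
    candidates = np.flatnonzero(gaps >= min_gap)
    if candidates.size == 0:
        return [indices]
    if candidates.size > 50:  # widest gaps only, for very deep dendrograms
        candidates = candidates[np.argsort(gaps[candidates])[::-1][:50]]
    best_key: tuple[int, float] | None = None
    best_labels: np.ndarray | None = None
    for k in candidates:
        cut = float((heights[k] + heights[k + 1]) / 2.0)
        labels = fcluster(z, t=cut, criterion="distance")
        if labels.max() < 2:
            continue
        sizes = np.bincount(labels)[1:]
        assigned = int(sizes[sizes >= min_size].sum())
        key = (assigned, float(gaps[k]))
        if best_key is None or key > best_key:
            best_key, best_labels = key, labels
    if best_labels is None:
        return [indices]
    out: list[np.ndarray] = []
    for lab in range(1, best_labels.max() + 1):
        part = indices[best_labels == lab]
        if part.size:
            out.extend(_recursive_gap_split(d, part, min_gap, min_size))
    return out


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    min_gap: float = 0.05,
) -> pd.Series:
    """Module labels from average-linkage clustering of 1 - TOM.

    The dendrogram is decomposed by recursive gap cutting (see
    :func:`_recursive_gap_split`); resulting clusters below
    ``min_module_size`` genes fall into the reserved "grey" label.
    ``min_gap`` is the smallest merge-height gap (on the 0-1
    dissimilarity scale) treated as a real module boundary — smaller gaps
    are indistinguishable from the height jitter inside a homogeneous
    cluster.  Modules are named M1, M2, ... in decreasing size order,
    ties broken by the lexicographically smallest member, so labels are
    deterministic.
    """
    if min_module_size < 2:
        raise UsageError("min_module_size must be >= 2")
    t = tom.to_numpy(dtype=float)
    if t.shape[0] != t.shape[1]:
        raise UsageError("TOM must be square")
    if not np.allclose(t, t.T, atol=1e-8):
        raise ValidationError("TOM must be symmetric")
    n = t.shape[0]
    if n == 1:
        label = "M1" if min_module_size <= 1 else UNASSIGNED_MODULE
        return pd.Series([label], index=tom.index, name="module")

    d = np.clip(1.0 - (t + t.T) / 2.0, 0.0, None)
    np.fill_diagonal(d, 0.0)
    clusters = _recursive_gap_split(d, np.arange(n), min_gap, min_module_size)

    members = [sorted(tom.index[c]) for c in clusters]
    valid = [m for m in members if len(m) >= min_module_size]
    valid.sort(key=lambda m: (-len(m), m[0]))
    out = pd.Series(UNASSIGNED_MODULE, index=tom.index, name="module")
    for i, m in enumerate(valid):
        out.loc[m] = f"M{i + 1}"
    return out


def coexpression_edges(
    adjacency: pd.DataFrame,
    edge_threshold: float | None = None,
    target_mean_degree: float = DEFAULT_TARGET_MEAN_DEGREE,
) -> CoexpressionNetwork:
    """Threshold the adjacency into an explicit edge list.

    With ``edge_threshold=None`` the threshold is chosen per run so the
    exported network has approximately ``target_mean_degree`` edges per
    node.  Connectivity is always reported from the full (unthresholded)
    adjacency.
    """
    a = adjacency.to_numpy(dtype=float)
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = a[iu]
    if edge_threshold is None:
        m_target = int(round(n * target_mean_degree / 2.0))
        m_target = max(1, min(m_target, vals.size))
        threshold = float(np.sort(vals)[::-1][m_target - 1])
        threshold = min(max(threshold, np.nextafter(0.0, 1.0)), 1.0)
    else:
        if not 0.0 < edge_threshold <= 1.0:
            raise UsageError("edge_threshold must lie in (0, 1]")
        threshold = float(edge_threshold)
    keep = vals >= threshold
    genes = adjacency.index.to_numpy()
    edges = pd.DataFrame(
        {
            "gene_a": genes[iu[0][keep]],
            "gene_b": genes[iu[1][keep]],
            "weight": vals[keep],
        }
    ).sort_values(["gene_a", "gene_b"], kind="stable", ignore_index=True)
    connectivity = pd.Series(a.sum(axis=0), index=adjacency.index, name="connectivity")
    return CoexpressionNetwork(edges=edges, connectivity=connectivity, threshold=threshold)
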