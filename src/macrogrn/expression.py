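"""Expression-level analysis: thresholding, differential expression,
variable-gene k-means, and PCA.

All statistics operate on log2(TPM + pseudocount).  A gene counts as
expressed when its replicate-mean TPM reaches the threshold (default 10)
in at least one strain.  Differential expression uses a Welch t-test on
the log2 scale with Benjamini-Hochberg FDR control and a fold-change gate:
a gene is called up when fdr < alpha and log2FC > c, down when fdr < alpha
and log2FC < -c, otherwise ns.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix
from .exceptions import UsageError

DEFAULT_TPM_THRESHOLD = 10.0
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_DE_ALPHA = 0.05
DEFAULT_DE_FC = 2.0


def normalize_expression(
    m: ExpressionMatrix,
    tpm_threshold: float = DEFAULT_TPM_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Filter lowly expressed genes and return the log2 matrix.

    A gene is retained iff its mean TPM within at least one strain reaches
    ``tpm_threshold``.  Returns the filtered matrix and
    ``log2(TPM + pseudocount)`` over the retained genes.  Applying the
    filter twice is a no-op.
    """
    means = m.strain_means()
    keep = means.max(axis=1) >= tpm_threshold
    if not keep.any():
        warnings.warn("all genes fall below the expression threshold", stacklevel=2)
    filtered = ExpressionMatrix(m.values.loc[keep].copy(), dict(m.sample_to_strain))
    log_matrix = np.log2(filtered.values + pseudocount)
    return filtered, log_matrix


def differential_expression(
    log_matrix: pd.DataFrame,
    sample_to_strain: Mapping[str, str],
    strain_a: str,
    strain_b: str,
    alpha: float = DEFAULT_DE_ALPHA,
    fc_cut: float = DEFAULT_DE_FC,
) -> pd.DataFrame:
    """Per-gene Welch t-test between two strains on log2 values.

    log2FC is mean(strain_a) - mean(strain_b), so swapping the strains
    negates fold changes and swaps up/down calls while p-values are
    unchanged.  Returns a DataFrame indexed by gene with columns
    ``log2fc``, ``p_value``, ``fdr``, ``call``.
    """
    cols_a = [s for s in log_matrix.columns if sample_to_strain.get(s) == strain_a]
    cols_b = [s for s in log_matrix.columns if sample_to_strain.get(s) == strain_b]
    for strain, cols in ((strain_a, cols_a), (strain_b, cols_b)):
        if len(cols) < 2:
            raise UsageError(
                f"strain {strain!r} has {len(cols)} replicate(s); "
                "differential expression needs at least 2"
            )
    a = log_matrix[cols_a].to_numpy()
    b = log_matrix[cols_b].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        result = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(result.pvalue, dtype=float)
    # degenerate rows (zero variance in both groups): identical means are a
    # certain null, different means a certain difference
    degenerate = ~np.isfinite(p)
    p[degenerate & (log2fc == 0)] = 1.0
    p[degenerate & (log2fc != 0)] = 0.0
    fdr = multipletests(p, method="fdr_bh")[1]
    call = np.full(len(p), "ns", dtype=object)
    call[(fdr < alpha) & (log2fc > fc_cut)] = "up"
    call[(fdr < alpha) & (log2fc < -fc_cut)] = "down"
    return pd.DataFrame(
        {"log2fc": log2fc, "p_value": p, "fdr": fdr, "call": call},
        index=log_matrix.index,
    )


def variable_gene_kmeans(
    log_matrix: pd.DataFrame,
    n_top: int = 6000,
    k: int = 9,
    seed: int = 0,
) -> pd.Series:
    """K-means over the ``n_top`` most variable genes (log-scale variance).

    Rows are z-scored before clustering; zero-variance rows among the top
    set are excluded with a warning.  Deterministic given ``seed`` (10
    restarts, best inertia).
    """
    if k < 2:
        raise UsageError("k must be >= 2")
    if n_top > log_matrix.shape[0]:
        raise UsageError(
            f"n_top={n_top} exceeds the number of genes ({log_matrix.shape[0]})"
        )
    variances = log_matrix.var(axis=1, ddof=1)
    top = variances.sort_values(ascending=False, kind="stable").index[:n_top]
    sub = log_matrix.loc[top]
    sds = sub.std(axis=1, ddof=1)
    zero_var = sds == 0
    if zero_var.any():
        warnings.warn(
            f"excluding {int(zero_var.sum())} zero-variance gene(s) before z-scoring",
            stacklevel=2,
        )
        sub = sub.loc[~zero_var]
        sds = sds[~zero_var]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sds, axis=0)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(z.to_numpy())
    out = pd.Series(labels, index=sub.index, name="cluster")
    kept = [g for g in log_matrix.index if g in out.index]
    return out.loc[kept]  # input gene order


def pca_scores(log_matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample coordinates and explained-variance fractions via SVD.

    The matrix is centered per gene; fractions are non-increasing and sum
    to 1.  Component signs are fixed so the largest-magnitude loading of
    each component is positive.
    """
    if log_matrix.shape[1] < 2:
        raise UsageError("PCA needs at least 2 samples")
    x = log_matrix.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign convention
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
    scores = (vt * s[:, None]).T  # samples x components
    total = (s ** 2).sum()
    frac = (s ** 2) / total if total > 0 else np.zeros_like(s)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=log_matrix.columns, columns=cols), frac
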