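"""Group statistics and transcriptome overviews.

Group comparisons mirror the source analyses: Welch two-sample t-tests for
bracketed pairs and classical one-way ANOVA across conditions, with the
mouse (whole-mount metrics) or the image (culture metrics) as the unit of
analysis.  The transcriptome overview runs PCA and average-linkage
hierarchical clustering (correlation distance) on log2(TPM + 1) of the
top-variance genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = ["two_sample_t", "one_way_anova", "transcriptome_overview", "TranscriptomeOverview"]


def two_sample_t(a, b) -> tuple[float, float]:
    """Welch (unequal-variance) two-sided t-test; returns (t, p).

    Degenerate zero-variance inputs are handled by the limiting case: t = 0
    and p = 1 when the means coincide, else p -> 0 (flagged in the log).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        logger.warning("zero variance in both groups; p from limiting case")
        same = np.isclose(a.mean(), b.mean())
        return (0.0, 1.0) if same else (np.inf if a.mean() > b.mean() else -np.inf, 0.0)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def one_way_anova(groups: list) -> tuple[float, float]:
    """Classical one-way ANOVA across >= 2 groups; returns (F, p)."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if all(a.var(ddof=1) == 0 for a in arrays):
        if np.isclose(np.ptp([a.mean() for a in arrays]), 0):
            logger.warning("all groups identical; F = 0, p = 1")
            return 0.0, 1.0
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


@dataclass
class TranscriptomeOverview:
    """PCA coordinates plus hierarchical-clustering order for samples."""

    coordinates: pd.DataFrame  # samples x PCs
    explained_variance_ratio: np.ndarray
    dendrogram_order: list[str]
    linkage_matrix: np.ndarray = field(repr=False)


def transcriptome_overview(
    tpm: pd.DataFrame,
    n_top_genes: int = 2000,
    n_components: int = 2,
) -> TranscriptomeOverview:
    """PCA + hierarchical clustering of samples from a TPM matrix.

    Expression is log2(TPM + 1); the ``n_top_genes`` highest-variance genes
    are kept (all genes, with a warning, when fewer exist).  Samples are
    clustered with average linkage on correlation distance.  Deterministic
    for a given input.
    """
    if tpm.shape[1] < 3:
        raise ValueError("transcriptome overview needs >= 3 samples")
    logx = np.log2(tpm + 1.0)
    variances = logx.var(axis=1)
    if n_top_genes < len(variances):
        keep = variances.nlargest(n_top_genes).index
    else:
        if n_top_genes > len(variances):
            logger.warning(
                "requested %d top genes but only %d available; using all",
                n_top_genes,
                len(variances),
            )
        keep = variances.index
    x = logx.loc[keep].T.to_numpy()  # samples x genes
    n_comp = min(n_components, min(x.shape) - 1)
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(x - x.mean(axis=0))
    coord_df = pd.DataFrame(
        coords, index=tpm.columns, columns=[f"PC{i + 1}" for i in range(n_comp)]
    )
    dist = pdist(x, metric="correlation")
    lm = linkage(dist, method="average")
    order = [tpm.columns[i] for i in leaves_list(lm)]
    return TranscriptomeOverview(
        coordinates=coord_df,
        explained_variance_ratio=pca.explained_variance_ratio_,
        dendrogram_order=order,
        linkage_matrix=lm,
    )
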