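"""Bulk RNA-seq normalization and differential expression.

Two DEG procedures operate on a gene-by-sample integer count matrix:

* a sample-level Poisson comparison of two libraries (the Audic–Claverie
  test on uniquely mapped read counts), used with the thresholds
  ``|log2FC| >= 0.4`` and ``FDR <= 0.001``;
* a group-level negative-binomial Wald test (median-of-ratios size factors,
  pooled moment dispersion, delta-method standard errors), used with
  ``|log2FC| >= 0.4`` and adjusted p ("Qvalue") ``<= 0.05``.

This module is a transparent re-implementation of both procedures: no
dispersion shrinkage, no independent filtering, so DEG counts from shrinkage-
based packages are reproduced only approximately.  Multiple testing is
Benjamini–Hochberg throughout.  Gene symbols are matched case-insensitively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "tpm",
    "size_factors",
    "ac_poisson_test",
    "nb_wald_test",
    "bh_fdr",
    "call_degs",
    "DEGTable",
]

#: Pseudo-mean added to group means before the log2 ratio, in normalized
#: counts; bounds fold changes for zero-count groups and keeps the log2FC
#: antisymmetric under contrast reversal.
PSEUDO_MEAN = 0.5

DISPERSION_FLOOR = 1e-8

DEFAULT_LFC_MIN = 0.4
DEFAULT_FDR_MAX_SAMPLE = 0.001
DEFAULT_FDR_MAX_GROUP = 0.05


@dataclass
class DEGTable:
    """Per-gene differential-expression results for one named contrast.

    ``table`` columns: ``gene, log2fc, p, adj`` (log2fc positive when higher
    in ``group_a``).
    """

    group_a: str
    group_b: str
    table: pd.DataFrame = field(repr=False)

    @property
    def contrast(self) -> str:
        return f"{self.group_a} vs {self.group_b}"

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["contrast"] = self.contrast
        out.to_csv(path, index=False)


def _as_count_frame(counts) -> pd.DataFrame:
    df = pd.DataFrame(counts)
    if (df.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    lowered = df.index.str.lower() if df.index.dtype == object else df.index
    if pd.Index(lowered).has_duplicates:
        raise ValueError("gene symbols must be unique after case-normalization")
    return df


def tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: length-normalized rates scaled to 1e6 per sample."""
    counts = _as_count_frame(counts)
    gene_lengths = pd.Series(gene_lengths)
    missing = counts.index.difference(gene_lengths.index)
    if len(missing):
        raise ValueError(f"missing gene lengths for: {sorted(missing)}")
    lengths = gene_lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    rate = counts.div(lengths, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For genes expressed in every sample, each sample's factor is the median
    ratio of its counts to the per-gene geometric mean across samples.
    """
    counts = _as_count_frame(counts).astype(float)
    expressed = (counts > 0).all(axis=1)
    if not expressed.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; consider a pseudo-reference fallback"
        )
    sub = counts.loc[expressed]
    geo_mean = np.exp(np.log(sub).mean(axis=1))
    ratios = sub.div(geo_mean, axis=0)
    return pd.Series(ratios.median(axis=0), index=counts.columns, name="size_factor")


def ac_poisson_test(x_a: int, x_b: int, n_a: float, n_b: float) -> float:
    """Two-sided Audic–Claverie Poisson test for one gene in two libraries.

    Under a flat prior on the common Poisson rate, the count in library B
    given ``x_a`` reads in library A (library sizes ``n_a``, ``n_b``) follows
    the posterior predictive
    ``P(y | x) = (n_b/n_a)^y (x+y)! / (x! y! (1 + n_b/n_a)^(x+y+1))``,
    a negative binomial with size ``x_a + 1`` and success probability
    ``n_a / (n_a + n_b)``.  The two-sided p doubles the smaller tail at the
    observed ``x_b`` (both tails include the observation), capped at 1.
    """
    if x_a < 0 or x_b < 0:
        raise ValueError("counts must be >= 0")
    if n_a <= 0 or n_b <= 0:
        raise ValueError("library sizes must be > 0")
    dist = sps.nbinom(x_a + 1, n_a / (n_a + n_b))
    lower = dist.cdf(x_b)
    upper = dist.sf(x_b - 1)  # P(Y >= x_b)
    return float(min(1.0, 2.0 * min(lower, upper)))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _moment_dispersion(norm_counts: np.ndarray, inv_sf: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Pooled method-of-moments NB dispersion per gene.

    With normalized counts y = k/s, Var(y) = mu/s + alpha*mu^2, so within a
    group  alpha ~ (s2 - mu * mean(1/s)) / mu^2; estimates are averaged over
    groups and floored.
    """
    n_genes = norm_counts.shape[0]
    alphas = np.zeros(n_genes)
    n_used = np.zeros(n_genes)
    for idx in groups:
        y = norm_counts[:, idx]
        mu = y.mean(axis=1)
        s2 = y.var(axis=1, ddof=1)
        c = inv_sf[idx].mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (s2 - mu * c) / mu**2
        ok = mu > 0
        alphas[ok] += np.clip(a[ok], 0.0, None)
        n_used[ok] += 1
    out = np.full(n_genes, DISPERSION_FLOOR)
    nz = n_used > 0
    out[nz] = np.maximum(alphas[nz] / n_used[nz], DISPERSION_FLOOR)
    return out


def nb_wald_test(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    contrast: tuple[str, str],
    group_col: str = "group",
) -> DEGTable:
    """Group-level NB Wald test between two sample groups.

    Counts are normalized by median-of-ratios size factors; per-gene group
    means and a pooled moment dispersion give a delta-method standard error
    for the difference of log mean expressions.  The Wald statistic is
    referred to a t distribution with ``n_a + n_b - 2`` df (a finite-sample
    reference; the normal limit is anticonservative at the few-replicate
    group sizes this test targets), two-sided, BH-adjusted.

    ``contrast = (group_a, group_b)``; log2fc > 0 means higher in group_a.
    """
    counts = _as_count_frame(counts)
    if not counts.columns.equals(pd.Index(meta.index)):
        meta = meta.loc[counts.columns]
    group_a, group_b = contrast
    idx_a = np.flatnonzero((meta[group_col] == group_a).to_numpy())
    idx_b = np.flatnonzero((meta[group_col] == group_b).to_numpy())
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("each contrast group needs >= 2 samples")

    sf = size_factors(counts).to_numpy()
    mat = counts.to_numpy(dtype=float)
    norm = mat / sf
    inv_sf = 1.0 / sf
    alpha = _moment_dispersion(norm, inv_sf, [idx_a, idx_b])

    ya, yb = norm[:, idx_a], norm[:, idx_b]
    mu_a, mu_b = ya.mean(axis=1), yb.mean(axis=1)
    log2fc = np.log2((mu_a + PSEUDO_MEAN) / (mu_b + PSEUDO_MEAN))

    # Var(mean of normalized counts) by the NB model, then delta method on log.
    var_ma = (mu_a * inv_sf[idx_a].mean() + alpha * mu_a**2) / len(idx_a)
    var_mb = (mu_b * inv_sf[idx_b].mean() + alpha * mu_b**2) / len(idx_b)
    se = np.sqrt(var_ma / (mu_a + PSEUDO_MEAN) ** 2 + var_mb / (mu_b + PSEUDO_MEAN) ** 2)
    diff = np.log(mu_a + PSEUDO_MEAN) - np.log(mu_b + PSEUDO_MEAN)
    df_t = len(idx_a) + len(idx_b) - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = diff / se
    p = 2.0 * sps.t.sf(np.abs(z), df_t)

    allzero = (mu_a == 0) & (mu_b == 0)
    p[allzero] = 1.0
    log2fc[allzero] = 0.0
    p[~np.isfinite(p)] = 1.0

    table = pd.DataFrame(
        {
            "gene": counts.index,
            "log2fc": log2fc,
            "p": p,
            "adj": bh_fdr(p),
            "all_zero": allzero,
        }
    ).reset_index(drop=True)
    return DEGTable(group_a=str(group_a), group_b=str(group_b), table=table)


def call_degs(
    table: DEGTable | pd.DataFrame,
    lfc_min: float = DEFAULT_LFC_MIN,
    adj_max: float = DEFAULT_FDR_MAX_GROUP,
) -> pd.DataFrame:
    """Genes passing ``|log2fc| >= lfc_min`` and ``adj <= adj_max``.

    Returns the filtered rows with a ``direction`` column ("up" when log2fc
    is positive in the contrast's first group, else "down").
    """
    if lfc_min < 0 or adj_max < 0:
        raise ValueError("thresholds must be >= 0")
    df = table.table if isinstance(table, DEGTable) else table
    hits = df[(df["log2fc"].abs() >= lfc_min) & (df["adj"] <= adj_max)].copy()
    hits["direction"] = np.where(hits["log2fc"] > 0, "up", "down")
    return hits.reset_index(drop=True)


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a genes-by-samples count table (first column = gene symbol)."""
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    return _as_count_frame(df)


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")
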