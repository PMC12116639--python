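"""Count normalization, negative-binomial Wald differential expression and
the abundance / selection filters.

Normalization follows the standard bulk RNA-seq conventions: median-of-ratios
size factors, reads-per-million (RPM) for small-RNA counts, and FPKM for
gene counts.  Differential expression is a deliberately simple NB-Wald test:
per-feature method-of-moments dispersion (floored), a 0.5 pseudocount on
group means, a normal reference for the Wald z, and Benjamini-Hochberg FDR.
Exact parity with heavyweight DE packages is not a goal; the test is
validated by simulation calibration (type-I error and effect recovery under
planted truth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FilterThresholds",
    "size_factors",
    "to_rpm",
    "to_fpkm",
    "bh_fdr",
    "nb_wald_de",
    "select_abundant",
    "select_top_expressed",
    "de_feature_sets",
]


@dataclass
class FilterThresholds:
    """Selection thresholds of the analysis.

    de_fdr: BH FDR cut for differential expression (0.05).
    min_fold: minimum fold change required for genes to count as DE (2).
    min_mean_rpm: isomiR abundance floor, mean RPM over all samples (100).
    cum_fraction: cumulative share of total isomiR expression retained (0.95).
    top_genes: size of the expressed-gene universe (10,000).
    top_regulated: length of the up/down gene lists fed to TF analysis (500).
    fold_applies_to_isomirs: whether the 2-fold rule also gates isomiRs
        (off by default: abundance-filtered isomiRs need only pass the FDR cut).
    """

    de_fdr: float = 0.05
    min_fold: float = 2.0
    min_mean_rpm: float = 100.0
    cum_fraction: float = 0.95
    top_genes: int = 10_000
    top_regulated: int = 500
    fold_applies_to_isomirs: bool = False

    def validate(self) -> None:
        if not (0 < self.cum_fraction <= 1):
            raise ValueError("cum_fraction must lie in (0, 1]")
        if min(self.de_fdr, self.min_fold, self.min_mean_rpm) <= 0:
            raise ValueError("thresholds must be positive")
        if min(self.top_genes, self.top_regulated) < 1:
            raise ValueError("top-N thresholds must be >= 1")


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    s_j = median over features of count_ij / geometric-mean_i, the median
    taken over features with nonzero counts in every sample.
    """
    c = counts.to_numpy(dtype=float)
    all_nonzero = (c > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("size factors undefined: no feature has nonzero counts in all samples")
    sub = c[all_nonzero]
    geomean = np.exp(np.log(sub).mean(axis=1))
    sf = np.median(sub / geomean[:, None], axis=0)
    return pd.Series(sf, index=counts.columns, name="size_factor")


def to_rpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads per million: each column rescaled to sum to 1e6."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("zero column total: RPM undefined")
    return counts / totals * 1e6


def to_fpkm(size_normalized_counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """FPKM from size-factor-normalized counts and transcript lengths (nt).

    fpkm_ij = n_ij / (length_i / 1e3) / (column_sum_j / 1e6), with the
    column sum taken over the size-normalized counts before length scaling.
    """
    missing = size_normalized_counts.index.difference(gene_lengths.index)
    if len(missing):
        raise ValueError(f"missing gene lengths for {len(missing)} genes, e.g. {missing[0]}")
    lengths = gene_lengths.reindex(size_normalized_counts.index).astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    depth = size_normalized_counts.sum(axis=0) / 1e6
    per_kb = size_normalized_counts.div(lengths / 1e3, axis=0)
    return per_kb.div(depth, axis=1)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# --------------------------------------------------------------------------
# differential expression
# --------------------------------------------------------------------------

def _moderate_dispersion(
    alpha: np.ndarray, base_mean: np.ndarray, resid_df: int, prior_df: float
) -> np.ndarray:
    """Shrink per-feature MoM dispersions toward a fitted mean trend.

    The trend alpha(mu) = a0 + a1/mu is fit by least squares over features
    with a positive raw estimate (one robustness pass discarding gross
    outliers); log-dispersions are then averaged with the trend using
    residual vs prior degrees of freedom.  With a dozen samples the raw
    per-feature estimate is far too noisy to plug into a Wald SE; borrowing
    strength across features is what keeps the test calibrated.
    """
    ok = (alpha > 0) & (base_mean > 0) & np.isfinite(alpha)
    if ok.sum() < 10:
        return alpha
    x = np.column_stack([np.ones(ok.sum()), 1.0 / base_mean[ok]])
    y = alpha[ok]
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    keep = np.abs(resid) < 3.0 * (np.median(np.abs(resid)) / 0.6745 + 1e-12)
    if keep.sum() >= 10:
        coef, *_ = np.linalg.lstsq(x[keep], y[keep], rcond=None)
    coef = np.maximum(coef, 0.0)
    trend = coef[0] + coef[1] / np.maximum(base_mean, 1e-8)
    trend = np.maximum(trend, 1e-8)
    w = resid_df / (resid_df + prior_df)
    return np.exp(w * np.log(np.maximum(alpha, 1e-8)) + (1 - w) * np.log(trend))


def nb_wald_de(
    counts: pd.DataFrame,
    groups: pd.Series,
    sf: pd.Series | None = None,
    pseudocount: float = 0.5,
    dispersion_floor: float = 1e-8,
    dispersion_prior_df: float = 20.0,
    reference_group: str | None = None,
) -> pd.DataFrame:
    """Two-group NB Wald differential expression.

    log2FC is group2 vs group1 (group1 = ``reference_group`` or the group of
    the first sample).  Per feature: size-normalized group means, pooled
    method-of-moments dispersion (floored, then shrunk toward a fitted
    mean-dispersion trend with ``dispersion_prior_df`` prior degrees of
    freedom), delta-method SE of the log2 mean difference under
    Var(K/s) = mu/s + alpha*mu^2, normal two-sided Wald p, and BH q over
    all tested features.  Set ``dispersion_prior_df=0`` to disable the
    moderation.

    Returns a DataFrame indexed by feature with columns baseMean, log2FC,
    SE, pvalue, qvalue.
    """
    groups = groups.reindex(counts.columns)
    levels = [reference_group] if reference_group else []
    for g in groups:
        if g not in levels:
            levels.append(g)
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    g1, g2 = levels
    idx1 = (groups == g1).to_numpy()
    idx2 = (groups == g2).to_numpy()
    n1, n2 = int(idx1.sum()), int(idx2.sum())
    if min(n1, n2) < 2:
        raise ValueError("each group needs >= 2 samples")

    if sf is None:
        sf = size_factors(counts)
    s = sf.reindex(counts.columns).to_numpy(dtype=float)
    norm = counts.to_numpy(dtype=float) / s

    m1 = norm[:, idx1].mean(axis=1)
    m2 = norm[:, idx2].mean(axis=1)
    base_mean = norm.mean(axis=1)
    lfc = np.log2((m2 + pseudocount) / (m1 + pseudocount))

    v1 = norm[:, idx1].var(axis=1, ddof=1)
    v2 = norm[:, idx2].var(axis=1, ddof=1)
    pooled_var = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    inv_s_mean = float(np.mean(1.0 / s))
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - base_mean * inv_s_mean) / np.square(base_mean)
    alpha = np.where(np.isfinite(alpha), alpha, dispersion_floor)
    if dispersion_prior_df > 0:
        alpha = _moderate_dispersion(alpha, base_mean, n1 + n2 - 2, dispersion_prior_df)
    alpha = np.maximum(alpha, dispersion_floor)

    sum_inv_s1 = float(np.sum(1.0 / s[idx1]))
    sum_inv_s2 = float(np.sum(1.0 / s[idx2]))
    var_m1 = m1 * sum_inv_s1 / n1**2 + alpha * m1**2 / n1
    var_m2 = m2 * sum_inv_s2 / n2**2 + alpha * m2**2 / n2
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt(
        var_m1 / (ln2sq * (m1 + pseudocount) ** 2)
        + var_m2 / (ln2sq * (m2 + pseudocount) ** 2)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 0.0, 1.0)
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": lfc,
            "SE": se,
            "pvalue": p,
            "qvalue": bh_fdr(p),
        },
        index=counts.index,
    )


def de_feature_sets(
    de: pd.DataFrame, thresholds: FilterThresholds, apply_fold: bool = True
) -> dict[str, list[str]]:
    """Partition DE results into up/down/all significant feature lists."""
    sig = de["qvalue"] < thresholds.de_fdr
    if apply_fold:
        sig &= de["log2FC"].abs() > np.log2(thresholds.min_fold)
    up = de.index[sig & (de["log2FC"] > 0)]
    down = de.index[sig & (de["log2FC"] < 0)]
    return {"up": sorted(up), "down": sorted(down), "all": sorted(de.index[sig])}


# --------------------------------------------------------------------------
# selection filters
# --------------------------------------------------------------------------

def select_abundant(rpm: pd.DataFrame, thresholds: FilterThresholds | None = None) -> list[str]:
    """Abundant-isomiR selection: RPM floor, then cumulative-share prefix.

    Step 1 keeps isomiRs with mean RPM (all samples pooled) above
    ``min_mean_rpm``.  Step 2 ranks them by mean RPM descending (ties by
    label) and keeps the smallest prefix whose cumulative share of the
    *total* mean RPM over all isomiRs reaches ``cum_fraction``.
    """
    thresholds = thresholds or FilterThresholds()
    thresholds.validate()
    if rpm.shape[0] == 0:
        raise ValueError("empty RPM matrix")
    means = rpm.mean(axis=1)
    total = float(means.sum())
    kept = means[means > thresholds.min_mean_rpm]
    ranked = kept.sort_index().sort_values(ascending=False, kind="stable")
    cum = ranked.cumsum() / total
    n_sel = int(np.searchsorted(cum.to_numpy(), thresholds.cum_fraction) + 1)
    return list(ranked.index[: min(n_sel, len(ranked))])


def select_top_expressed(fpkm: pd.DataFrame, n: int) -> list[str]:
    """The n most expressed genes by mean FPKM (ties broken by label)."""
    if n > fpkm.shape[0]:
        raise ValueError("n exceeds the number of genes")
    means = fpkm.mean(axis=1)
    ranked = means.sort_index().sort_values(ascending=False, kind="stable")
    return list(ranked.index[:n])
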