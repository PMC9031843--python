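"""Normalization, expression filters, and tumor-vs-normal differential expression.

Counts are normalized to FPKM, then two filters mirror the screening stage:
a variance filter on the interquartile range of log2 expression and a
presence filter requiring non-zero expression in a strict majority fraction
of samples. Differential expression uses the two-sided Mann-Whitney U test
(exact enumeration for small groups) with a median-based log2 fold change
and Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, ExpressionError

# log2 transforms throughout use pseudocount 1; quartiles use linear
# interpolation (type 7), since neither convention is standardized upstream.
PSEUDOCOUNT = 1.0
EXACT_MAX_GROUP = 8


def fpkm_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM[f, s] = counts[f, s] * 1e9 / (length[f] * libsize[s]) where
    libsize is the per-sample column sum of raw counts.
    """
    if "length" not in counts.feature_meta.columns:
        raise ExpressionError("FPKM requires a 'length' column in feature_meta")
    lengths = counts.feature_meta["length"]
    missing = lengths.index[lengths.isna() | (lengths <= 0)].tolist()
    if missing:
        raise ExpressionError(f"features without a valid length: {missing}")
    libsize = counts.values.sum(axis=0)
    if (libsize <= 0).any():
        bad = libsize.index[libsize <= 0].tolist()
        raise ExpressionError(f"samples with zero library size: {bad}")
    fpkm = counts.values * 1e9
    fpkm = fpkm.div(lengths.astype(float), axis=0).div(libsize, axis=1)
    return ExpressionMatrix(fpkm, counts.feature_meta.copy(), counts.sample_meta.copy())


def log2iqr(matrix: ExpressionMatrix) -> pd.Series:
    """Interquartile range of log2(x + 1) per feature across all samples."""
    logx = np.log2(matrix.values.to_numpy(dtype=float) + PSEUDOCOUNT)
    q25, q75 = np.percentile(logx, [25, 75], axis=1)
    return pd.Series(q75 - q25, index=matrix.values.index, name="log2iqr")


def log2iqr_filter(matrix: ExpressionMatrix, threshold: float = 0.5) -> list[str]:
    """Feature ids whose log2-scale IQR is strictly above ``threshold``."""
    iqr = log2iqr(matrix)
    return iqr.index[iqr > threshold].tolist()


def presence_fraction(matrix: ExpressionMatrix) -> pd.Series:
    frac = (matrix.values > 0).mean(axis=1)
    frac.name = "presence_fraction"
    return frac


def presence_filter(matrix: ExpressionMatrix, fraction: float = 0.70) -> list[str]:
    """Feature ids expressed (> 0) in strictly more than ``fraction`` of samples."""
    frac = presence_fraction(matrix)
    return frac.index[frac > fraction].tolist()


def mann_whitney_p(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration of all group labelings when both groups have at most
    eight observations (correct under ties, since mid-ranks are enumerated);
    otherwise the normal approximation with tie correction and continuity
    correction. Clamped to [0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    n1, n2 = x.size, y.size
    if n1 <= EXACT_MAX_GROUP and n2 <= EXACT_MAX_GROUP:
        ranks = stats.rankdata(np.concatenate([x, y]))
        u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
        mu = n1 * n2 / 2
        dev = abs(u_obs - mu)
        hits = total = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                hits += 1
        return hits / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(min(res.pvalue, 1.0))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q(i) = min_{j >= i} (m * p(j) / j) over the ascending order, clamped
    to <= 1; the original input order is preserved.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def differential_expression(
    matrix: ExpressionMatrix, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-feature tumor-vs-normal differential expression table.

    logFC is the difference of group medians of log2(x + 1); p is the
    two-sided Mann-Whitney U p-value; q is BH-adjusted across all tested
    features. The returned table also carries the filter statistics
    (log2iqr, presence_fraction) and a ``significant`` flag at q < alpha.
    """
    tumor = matrix.samples_in("tumor")
    normal = matrix.samples_in("normal")
    if len(tumor) < 2 or len(normal) < 2:
        raise ExpressionError(
            f"need >= 2 samples per group, got tumor={len(tumor)} normal={len(normal)}"
        )
    logx = np.log2(matrix.values + PSEUDOCOUNT)
    lt = logx[tumor].to_numpy()
    ln = logx[normal].to_numpy()
    logfc = np.median(lt, axis=1) - np.median(ln, axis=1)
    raw_t = matrix.values[tumor].to_numpy()
    raw_n = matrix.values[normal].to_numpy()
    pvals = np.array(
        [mann_whitney_p(raw_t[i], raw_n[i]) for i in range(matrix.n_features)]
    )
    out = pd.DataFrame(
        {
            "feature_id": matrix.values.index,
            "rna_class": matrix.feature_meta["rna_class"].to_numpy(),
            "logFC": logfc,
            "p": pvals,
            "q": bh_adjust(pvals),
            "log2iqr": log2iqr(matrix).to_numpy(),
            "presence_fraction": presence_fraction(matrix).to_numpy(),
        }
    )
    out["significant"] = out["q"] < alpha
    return out
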