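"""Sign-constrained Spearman correlation screening across RNA classes.

The ceRNA model predicts that a sponged miRNA is negatively correlated with
both its lncRNA and mRNA partners while the two partners are positively
correlated with each other. This module computes tie-corrected Spearman
coefficients for every cross-class feature pair, adjusts p-values within
each pair-type family (miRNA-lncRNA, miRNA-mRNA, lncRNA-mRNA), and retains
pairs that meet the family's sign/magnitude cutoff at the FDR level.

Default cutoffs: rho <= -0.33 for miRNA-containing pairs and rho >= 0.4
for lncRNA-mRNA pairs, both inclusive, with q < 0.05.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .expression import ExpressionMatrix

PAIR_TYPES = ("miRNA-lncRNA", "miRNA-mRNA", "lncRNA-mRNA")
EXACT_MAX_N = 8

CUTOFF_MI = -0.33
CUTOFF_LNC_MRNA = 0.4
ALPHA = 0.05


class ConstantInputError(ValueError):
    """Spearman correlation is undefined for a constant vector."""


def _t_approx_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return 2.0 * stats.t.sf(abs(t), df=n - 2)


def spearman(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rho with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks. For n <= 8 the p-value is
    exact, from full enumeration of the n! pairings of the rank vectors;
    for larger n it uses the t approximation
    t = rho * sqrt((n - 2) / (1 - rho^2)) with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    n = x.size
    if n < 4:
        raise ValueError(f"need n >= 4 samples, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_MAX_N:
        # permuting y permutes its mid-ranks, so enumerate permutations of ry
        perms = np.array(list(itertools.permutations(ry)))
        pc = perms - perms.mean(axis=1, keepdims=True)
        xc = rx - rx.mean()
        denom = np.linalg.norm(pc, axis=1) * np.linalg.norm(xc)
        rho_perm = pc @ xc / denom
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    else:
        p = _t_approx_p(rho, n)
    return rho, p


def _rank_standardize(values: np.ndarray) -> np.ndarray:
    """Row-wise mid-ranks, centered and scaled to unit norm.

    Rows with zero rank variance (constant features) come back as NaN rows.
    """
    ranks = stats.rankdata(values, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(ranks, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(norm > 0, ranks / norm, np.nan)


def pairwise_screen(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    pair_type: str,
    cutoff_mi: float = CUTOFF_MI,
    cutoff_lnc_mrna: float = CUTOFF_LNC_MRNA,
    alpha: float = ALPHA,
    two_sided_lnc_mrna: bool = False,
) -> pd.DataFrame:
    """Screen all cross pairs of two matrices for one pair-type family.

    Computes Spearman rho and the t-approximation p-value for every
    (feature_a, feature_b) pair, BH-adjusts within the family, and keeps
    pairs passing the family rule: rho <= ``cutoff_mi`` for miRNA-lncRNA
    and miRNA-mRNA, rho >= ``cutoff_lnc_mrna`` for lncRNA-mRNA (or
    |rho| >= cutoff when ``two_sided_lnc_mrna``), each at q < ``alpha``.
    Constant features are excluded (their correlation is undefined).
    """
    if pair_type not in PAIR_TYPES:
        raise ValueError(f"pair_type must be one of {PAIR_TYPES}")
    ids_a = set(matrix_a.values.columns)
    ids_b = set(matrix_b.values.columns)
    if ids_a != ids_b:
        diff = sorted(ids_a ^ ids_b)
        raise ValueError(f"sample sets differ; symmetric difference: {diff}")
    vb = matrix_b.values[matrix_a.values.columns]  # align order
    n = matrix_a.n_samples
    if n < 4:
        raise ValueError(f"need n >= 4 shared samples, got {n}")

    ra = _rank_standardize(matrix_a.values.to_numpy(dtype=float))
    rb = _rank_standardize(vb.to_numpy(dtype=float))
    keep_a = ~np.isnan(ra[:, 0])
    keep_b = ~np.isnan(rb[:, 0])
    ia = matrix_a.values.index[keep_a]
    ib = vb.index[keep_b]
    rho = ra[keep_a] @ rb[keep_b].T
    rho = np.clip(rho, -1.0, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)

    class_a = matrix_a.feature_meta["rna_class"].iloc[0] if matrix_a.n_features else ""
    class_b = matrix_b.feature_meta["rna_class"].iloc[0] if matrix_b.n_features else ""
    pairs = pd.DataFrame(
        {
            "id_a": np.repeat(ia, len(ib)),
            "class_a": class_a,
            "id_b": np.tile(ib, len(ia)),
            "class_b": class_b,
            "rho": rho.ravel(),
            "p": p.ravel(),
        }
    )
    pairs["q"] = bh_adjust(pairs["p"].to_numpy()) if len(pairs) else []
    pairs["pair_type"] = pair_type
    pairs["n_samples"] = n

    if pair_type in ("miRNA-lncRNA", "miRNA-mRNA"):
        sign_ok = pairs["rho"] <= cutoff_mi
    elif two_sided_lnc_mrna:
        sign_ok = pairs["rho"].abs() >= cutoff_lnc_mrna
    else:
        sign_ok = pairs["rho"] >= cutoff_lnc_mrna
    kept = pairs[sign_ok & (pairs["q"] < alpha)].reset_index(drop=True)
    return kept.sort_values(["id_a", "id_b"], kind="stable").reset_index(drop=True)
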