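"""Preranked gene-set enrichment analysis.

The enrichment score (ES) is the signed maximum deviation of a weighted
Kolmogorov-Smirnov running sum over the ranked gene list: walking down the
ranking, the sum rises by |metric|^p / sum(|metric|^p over the set) at set
members ("hits") and falls by 1 / (N - k) at non-members. Significance
comes from a gene-label permutation null (random sets of the same size
drawn from the ranked universe), the standard choice when only a ranking
is available; NES normalizes ES by the mean |ES| of same-signed
permutations, and q-values are BH-adjusted across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import bh_adjust

MIN_SET_SIZE = 5
MAX_SET_SIZE = 500


@dataclass
class RankedList:
    """Gene ids ordered by a ranking metric, best (most positive) first.

    Ties are broken deterministically: by metric descending, then by gene
    id ascending. Ids must be unique.
    """

    ids: list[str]
    metrics: np.ndarray

    @classmethod
    def from_table(cls, table: pd.DataFrame, id_col: str = "feature_id",
                   metric_col: str = "logFC") -> "RankedList":
        if table[id_col].duplicated().any():
            raise ValueError("ranked list requires unique gene ids")
        ordered = table.sort_values(
            [metric_col, id_col], ascending=[False, True], kind="stable"
        )
        return cls(ordered[id_col].tolist(),
                   ordered[metric_col].to_numpy(dtype=float))

    def __len__(self) -> int:
        return len(self.ids)


def _running_sum(abs_metrics: np.ndarray, hit: np.ndarray, weight: float) -> np.ndarray:
    w = abs_metrics**weight * hit
    total = w.sum()
    if total == 0:  # degenerate all-zero metrics in the set: unweighted KS
        w = hit.astype(float)
        total = w.sum()
    n_miss = hit.size - int(hit.sum())
    p_hit = np.cumsum(w) / total
    p_miss = np.cumsum(~hit) / n_miss if n_miss else np.zeros(hit.size)
    return p_hit - p_miss


def enrichment_score(
    ranked: RankedList, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """ES and the full running sum for one gene set.

    Raises if the set does not intersect the ranking.
    """
    members = set(gene_set)
    hit = np.fromiter((g in members for g in ranked.ids), bool, len(ranked))
    if not hit.any():
        raise ValueError("gene set has empty intersection with the ranked list")
    running = _running_sum(np.abs(ranked.metrics), hit, weight)
    es = float(running[np.argmax(np.abs(running))])
    return es, running


def _es_only(abs_w: np.ndarray, hit: np.ndarray, n_miss_inv: float) -> float:
    w = abs_w * hit
    total = w.sum()
    if total == 0:
        w = hit.astype(float)
        total = w.sum()
    running = np.cumsum(w / total - (~hit) * n_miss_inv)
    return float(running[np.argmax(np.abs(running))])


def gsea_permutation(
    ranked: RankedList,
    gene_sets: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
    min_size: int = MIN_SET_SIZE,
    max_size: int = MAX_SET_SIZE,
) -> pd.DataFrame:
    """Permutation GSEA over a GMT-style dict of gene sets.

    p = (1 + #{|ES_perm| >= |ES|}) / (n_perm + 1); NES = ES divided by the
    mean |ES_perm| of permutations with the same sign. Sets smaller than
    ``min_size`` (after intersection) or larger than ``max_size`` are
    skipped with a warning. Deterministic for a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("need n_perm >= 100")
    rng = np.random.default_rng(seed)
    universe = ranked.ids
    index = {g: i for i, g in enumerate(universe)}
    n = len(universe)
    abs_w = np.abs(ranked.metrics) ** weight

    rows = []
    for set_id in sorted(gene_sets):
        members = [g for g in gene_sets[set_id] if g in index]
        k = len(members)
        if k < min_size or k > max_size:
            warnings.warn(
                f"{set_id}: size {k} outside [{min_size}, {max_size}], skipped"
            )
            continue
        hit = np.zeros(n, dtype=bool)
        hit[[index[g] for g in members]] = True
        n_miss_inv = 1.0 / (n - k) if n > k else 0.0
        es = _es_only(abs_w, hit, n_miss_inv)
        es_perm = np.empty(n_perm)
        for b in range(n_perm):
            perm_hit = np.zeros(n, dtype=bool)
            perm_hit[rng.choice(n, size=k, replace=False)] = True
            es_perm[b] = _es_only(abs_w, perm_hit, n_miss_inv)
        p = (1 + np.sum(np.abs(es_perm) >= abs(es))) / (n_perm + 1)
        same_sign = es_perm[np.sign(es_perm) == np.sign(es)]
        nes = es / np.mean(np.abs(same_sign)) if same_sign.size else np.nan
        rows.append(
            {"set_id": set_id, "size": k, "ES": es, "NES": nes, "p": p}
        )
    out = pd.DataFrame(rows, columns=["set_id", "size", "ES", "NES", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = []
    return out


def read_gmt(path) -> dict[str, list[str]]:
    """GMT reader: tab-separated lines of set id, description, members."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for set_id in sets:
            fh.write("\t".join([set_id, description, *sets[set_id]]) + "\n")
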