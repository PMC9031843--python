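"""Relative-expression arithmetic for qPCR validation (ddCt method).

Threshold cycles (Ct) are normalized against reference genes: B2M for
mRNA/lncRNA targets, the arithmetic mean of the RNU48 and RNU6 Ct values
for miRNA targets. For each matched tumor/normal tissue pair,
ddCt = dCt_tumor - dCt_normal and the relative expression is 2^(-ddCt)
(amplification efficiency fixed at 2). The per-target log2 fold change is
the median of -ddCt over pairs; group differences are tested on the dCt
distributions with the two-sided Mann-Whitney U test (a paired Wilcoxon
signed-rank alternative is available), with BH adjustment across targets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust, mann_whitney_p

MIRNA_REFERENCES = ("RNU48", "RNU6")
DEFAULT_REFERENCE = "B2M"
CT_MAX = 45.0


def delta_ct(ct_target: float, ct_refs: dict[str, float], rna_class: str) -> float:
    """Reference-normalized Ct for one measurement.

    mRNA/lncRNA targets normalize against B2M; miRNA targets against the
    arithmetic mean of the RNU48 and RNU6 cycles.
    """
    if rna_class == "miRNA":
        missing = [r for r in MIRNA_REFERENCES
                   if r not in ct_refs or pd.isna(ct_refs[r])]
        if missing:
            raise ValueError(f"missing miRNA reference genes: {missing}")
        ref = float(np.mean([ct_refs[r] for r in MIRNA_REFERENCES]))
    else:
        if DEFAULT_REFERENCE not in ct_refs or pd.isna(ct_refs[DEFAULT_REFERENCE]):
            raise ValueError(f"missing reference gene {DEFAULT_REFERENCE}")
        ref = float(ct_refs[DEFAULT_REFERENCE])
    return float(ct_target) - ref


def _row_delta_ct(row: pd.Series) -> float:
    refs = {
        c[3:]: row[c] for c in row.index if c.startswith("ct_") and c != "ct_target"
    }
    return delta_ct(row["ct_target"], refs, row["target_class"])


def relative_expression(
    table: pd.DataFrame, paired_test: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pair fold changes and a per-target summary from a Ct table.

    Expects the wide Ct layout (columns pair_id, target_id, target_class,
    condition, ct_target, ct_<reference>...). Returns ``(per_pair,
    summary)``: per pair, ddCt = dCt_tumor - dCt_normal, fold = 2^(-ddCt)
    and log2 fold change -ddCt; per target, the median logFC, the
    Mann-Whitney p on tumor-vs-normal dCt (Wilcoxon signed-rank on paired
    differences when ``paired_test``), and BH q across targets. Pairs
    missing either condition are excluded with a warning.
    """
    bad_ct = table["ct_target"].le(0) | table["ct_target"].gt(CT_MAX)
    if bad_ct.any():
        raise ValueError(f"{int(bad_ct.sum())} Ct values outside (0, {CT_MAX}]")
    work = table.copy()
    work["delta_ct"] = work.apply(_row_delta_ct, axis=1)

    wide = work.pivot_table(
        index=["target_id", "target_class", "pair_id"],
        columns="condition",
        values="delta_ct",
        aggfunc="first",
    ).reset_index()
    unpaired = wide["tumor"].isna() | wide["normal"].isna()
    if unpaired.any():
        warnings.warn(f"{int(unpaired.sum())} unpaired rows excluded")
        wide = wide[~unpaired]
    wide["ddct"] = wide["tumor"] - wide["normal"]
    wide["fold"] = 2.0 ** (-wide["ddct"])
    wide["logFC"] = -wide["ddct"]
    per_pair = wide.rename(
        columns={"tumor": "delta_ct_tumor", "normal": "delta_ct_normal"}
    )[["target_id", "target_class", "pair_id",
       "delta_ct_tumor", "delta_ct_normal", "ddct", "fold", "logFC"]]

    rows = []
    for (target, cls), grp in per_pair.groupby(["target_id", "target_class"],
                                               sort=True):
        dt = grp["delta_ct_tumor"].to_numpy()
        dn = grp["delta_ct_normal"].to_numpy()
        if len(grp) < 2:  # a single pair cannot support a group test
            p = np.nan
        elif paired_test:
            diff = dt - dn
            p = 1.0 if np.allclose(diff, 0) else float(
                stats.wilcoxon(diff).pvalue)
        else:
            p = mann_whitney_p(dt, dn)
        rows.append(
            {
                "target_id": target,
                "target_class": cls,
                "logFC": float(np.median(grp["logFC"])),
                "p": p,
                "n_pairs": len(grp),
            }
        )
    summary = pd.DataFrame(rows)
    summary["q"] = np.nan
    if len(summary):
        tested = summary["p"].notna()
        if tested.any():
            summary.loc[tested, "q"] = bh_adjust(summary.loc[tested, "p"].to_numpy())
    return per_pair, summary
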