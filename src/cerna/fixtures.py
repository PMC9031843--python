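"""Packaged worked-example data.

Transcribed from the published ovarian-cancer validation cohort: the
significant correlation-pair lists (rho values, adjusted p < 0.05) and the
miR-203a canonical binding-site calls for the correlated lncRNAs/mRNAs.
These drive the worked example: assembling the pair lists yields 16
triplets (15 with miR-203a, 1 with miR-148a), and the binding-site filter
reduces them to the lncRNAs OIP5-AS1/MLK7-AS1 and mRNAs c-MET/ZEB1/ZEB2.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

# mature hsa-miR-203a-3p (the predominant mature strand)
MIR203A_SEQUENCE = "GUGAAAUGUUUAGGACCACUAG"


def _read(name: str) -> pd.DataFrame:
    with resources.files("cerna.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def ovarian_pairs() -> dict[str, pd.DataFrame]:
    """The three published pair lists keyed by pair type."""
    table = _read("ovarian_pairs.tsv")
    return {pt: grp.reset_index(drop=True) for pt, grp in table.groupby("pair_type")}


def ovarian_sites() -> pd.DataFrame:
    """Published miR-203a site-type calls for the correlated transcripts."""
    return _read("ovarian_sites.tsv")
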