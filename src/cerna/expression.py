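"""Expression-matrix container and TSV round-trip.

The pipeline operates on features x samples matrices of non-negative
expression values (raw counts or FPKM) with two metadata tables: one per
feature (RNA class, transcript length) and one per sample (tumor/normal
condition, optional pair id for matched tumor/normal tissue pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

RNA_CLASSES = ("miRNA", "lncRNA", "mRNA")
CONDITIONS = ("tumor", "normal")


class ExpressionError(ValueError):
    """Invalid expression matrix or metadata."""


@dataclass
class ExpressionMatrix:
    """Features x samples expression values with feature/sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, columns are sample ids,
        non-negative numeric entries (counts or FPKM).
    feature_meta
        DataFrame indexed by feature id with columns ``rna_class``
        (one of miRNA/lncRNA/mRNA) and optionally ``length`` (nt,
        required for FPKM normalization).
    sample_meta
        DataFrame indexed by sample id with column ``condition``
        (tumor/normal) and optionally ``pair_id``.
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ExpressionError(f"duplicate feature ids: {dup}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ExpressionError(f"duplicate sample ids: {dup}")
        if not self.values.index.equals(self.feature_meta.index):
            raise ExpressionError("feature_meta index does not match values index")
        if not self.values.columns.equals(pd.Index(self.sample_meta.index)):
            raise ExpressionError("sample_meta index does not match values columns")
        if "rna_class" not in self.feature_meta.columns:
            raise ExpressionError("feature_meta requires an 'rna_class' column")
        bad = set(self.feature_meta["rna_class"]) - set(RNA_CLASSES)
        if bad:
            raise ExpressionError(f"unknown RNA classes: {sorted(bad)}")
        if "condition" not in self.sample_meta.columns:
            raise ExpressionError("sample_meta requires a 'condition' column")
        bad = set(self.sample_meta["condition"]) - set(CONDITIONS)
        if bad:
            raise ExpressionError(f"unknown sample conditions: {sorted(bad)}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ExpressionError("expression values must be numeric")
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ExpressionError("expression values must be finite and non-negative")
        if "length" in self.feature_meta.columns:
            lengths = self.feature_meta["length"].dropna()
            if (lengths <= 0).any():
                raise ExpressionError("feature lengths must be > 0")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in(self, condition: str) -> list[str]:
        mask = self.sample_meta["condition"] == condition
        return self.sample_meta.index[mask].tolist()

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        ids = [f for f in self.values.index if f in set(feature_ids)]
        return ExpressionMatrix(
            self.values.loc[ids], self.feature_meta.loc[ids], self.sample_meta.copy()
        )

    def subset_class(self, rna_class: str) -> "ExpressionMatrix":
        keep = self.feature_meta.index[self.feature_meta["rna_class"] == rna_class]
        return self.subset_features(keep)

    # -- TSV i/o ---------------------------------------------------------------

    def to_tsv(self, expr_path, samples_path, header_lines: list[str] | None = None) -> None:
        """Write expression and sample-metadata TSVs.

        Feature metadata travels as extra columns (``rna_class``, ``length``)
        after ``feature_id`` in the expression file. ``header_lines`` are
        written as ``#``-prefixed provenance comments.
        """
        out = self.feature_meta.copy()
        out.insert(0, "feature_id", out.index)
        table = pd.concat([out.reset_index(drop=True),
                           self.values.reset_index(drop=True)], axis=1)
        _write_tsv(table, expr_path, header_lines)
        smeta = self.sample_meta.copy()
        smeta.insert(0, "sample_id", smeta.index)
        _write_tsv(smeta.reset_index(drop=True), samples_path, header_lines)

    @classmethod
    def from_tsv(cls, expr_path, samples_path) -> "ExpressionMatrix":
        table = pd.read_csv(expr_path, sep="\t", comment="#")
        if "feature_id" not in table.columns:
            raise ExpressionError(f"{expr_path}: missing 'feature_id' column")
        table = table.set_index("feature_id")
        meta_cols = [c for c in ("rna_class", "length") if c in table.columns]
        feature_meta = table[meta_cols]
        values = table.drop(columns=meta_cols)
        smeta = pd.read_csv(samples_path, sep="\t", comment="#").set_index("sample_id")
        return cls(values, feature_meta, smeta.loc[values.columns])


def _write_tsv(df: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    """Read a pipeline TSV, skipping provenance comment lines."""
    return pd.read_csv(path, sep="\t", comment="#")
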