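"""Expression-matrix container and TSV I/O.

An :class:`ExpressionMatrix` wraps a genes × samples :class:`pandas.DataFrame`
plus per-sample annotation (a condition label for static two-condition data,
or an ordered time point for time courses).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "read_expression_tsv", "read_design_tsv"]


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with sample annotations.

    ``values`` is indexed by gene id (rows) and sample id (columns);
    ``sample_annotation`` maps each sample id to its condition label or time
    point.  Values must be finite and gene ids unique.
    """

    values: pd.DataFrame
    sample_annotation: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        for s in self.values.columns:
            self.sample_annotation.setdefault(s, None)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def submatrix(self, genes: Sequence[str]) -> pd.DataFrame:
        present = [g for g in genes if g in self.values.index]
        return self.values.loc[present]

    def write_tsv(self, path: str | Path, header: str | None = None) -> None:
        with Path(path).open("w") as fh:
            if header:
                for line in header.splitlines():
                    fh.write(f"# {line}\n")
            self.values.to_csv(fh, sep="\t", index_label="gene")


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV: header row = sample ids, first column = gene id.

    Leading ``#`` comment lines are skipped.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return ExpressionMatrix(values=df)


def read_design_tsv(path: str | Path) -> pd.DataFrame:
    """Read a sample-design TSV with columns sample, condition[, replicate]."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"design file needs columns {sorted(required)}")
    return df
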