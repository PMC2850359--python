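"""In-memory containers and TSV I/O for expression matrices and metadata.

All tabular files are plain TSV with missing values written as ``NA``.
The expression table has ``gene_id`` as its first column and one column per
sample; the sample sheet carries the :class:`~dielbfc.design.SampleDesign`
fields one row per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import SampleDesign

NA = "NA"


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with an implicit missing-value mask.

    ``values`` is a float DataFrame indexed by gene id with one column per
    sample id (NaN marks missing entries); ``samples`` carries the per-sample
    metadata in column order.
    """

    values: pd.DataFrame
    samples: list[SampleDesign]

    def __post_init__(self) -> None:
        sample_ids = [s.sample_id for s in self.samples]
        if list(self.values.columns) != sample_ids:
            raise ValueError("expression columns do not match sample sheet order")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where the value is missing."""
        return self.values.isna()

    def subset(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        """Row subset preserving the given order."""
        return ExpressionMatrix(self.values.loc[list(gene_ids)].copy(), list(self.samples))

    def backgrounds(self) -> np.ndarray:
        return np.array([s.background for s in self.samples], dtype=float)

    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.samples], dtype=float)

    def tods(self) -> np.ndarray:
        return np.array([s.tod for s in self.samples], dtype=float)

    def kinetics(self) -> np.ndarray:
        return np.array([s.kinetic for s in self.samples], dtype=int)


@dataclass
class TruthLabels:
    """Ground-truth gene labels emitted by the simulator.

    ``table`` columns: gene_id, gene_class (rhythmic | arrhythmic | unexpressed),
    true_cluster (int or NA), phase_h (hours or NA), amplitude (peak-to-trough
    delta-log2; 0 for unexpressed genes).
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def classes(self) -> pd.Series:
        return self.table.set_index("gene_id")["gene_class"]

    def true_clusters(self) -> pd.Series:
        return self.table.set_index("gene_id")["true_cluster"]


# ---------------------------------------------------------------------------
# TSV round-trips


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    out = m.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", na_rep=NA, float_format="%.6f")


def write_sample_sheet(samples: Sequence[SampleDesign], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "kinetic": [s.kinetic for s in samples],
            "tod": [s.tod for s in samples],
            "t": [s.t for s in samples],
            "light": [int(s.light) for s in samples],
            "background": [s.background for s in samples],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_truth(truth: TruthLabels, path: str | Path) -> None:
    truth.table.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_sample_sheet(path: str | Path) -> list[SampleDesign]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "kinetic", "tod", "t", "light", "background"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return [
        SampleDesign(
            sample_id=str(r.sample_id),
            kinetic=int(r.kinetic),
            tod=float(r.tod),
            t=float(r.t),
            light=bool(int(r.light)),
            background=float(r.background),
        )
        for r in df.itertuples(index=False)
    ]


def read_expression(path: str | Path, samples: Sequence[SampleDesign]) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene_id", na_values=[NA])
    return ExpressionMatrix(df, list(samples))


def read_truth(path: str | Path) -> TruthLabels:
    return TruthLabels(pd.read_csv(path, sep="\t", na_values=[NA]))
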