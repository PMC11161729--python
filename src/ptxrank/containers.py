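"""Core data containers and TSV input/output.

The pipeline moves three tabular objects between stages:

* :class:`CountMatrix` — a protein × sample abundance table with a layer tag
  distinguishing raw spectral counts, normalized counts and MS1 intensities.
* a *sample annotation* table (one row per sample: cohort, histological
  subtype, treatment arm, recurrence-free survival, event flag, tumour cell
  percentage, and the derived response group).
* a *protein metadata* table (molecular weight in kDa and unique-peptide
  counts per cohort).

All on-disk artifacts are plain TSV with a header row; matrices carry the
protein identifier in the first column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

RAW_SC = "raw_sc"
NORMALIZED_SC = "normalized_sc"
INTENSITY = "intensity"

_LAYERS = (RAW_SC, NORMALIZED_SC, INTENSITY)

SAMPLE_COLUMNS = [
    "sample_id",
    "cohort",
    "subtype",
    "treatment",
    "rfs_months",
    "event",
    "tcp",
]

PROTEIN_COLUMNS = ["protein_id", "mw_kda", "peptides_discovery", "peptides_validation"]


@dataclass
class CountMatrix:
    """Protein × sample abundance matrix.

    Parameters
    ----------
    data
        DataFrame indexed by protein id with sample ids as columns. Values
        must be non-negative and finite.
    layer
        One of ``raw_sc``, ``normalized_sc`` or ``intensity``.
    """

    data: pd.DataFrame
    layer: str = RAW_SC

    def __post_init__(self) -> None:
        if self.layer not in _LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {_LAYERS}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate protein ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        values = self.data.to_numpy()
        if not np.isfinite(values).all() or (values < 0).any():
            raise ValueError("matrix values must be finite and non-negative")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids) -> "CountMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return replace(self, data=self.data.loc[:, list(sample_ids)])

    def subset_proteins(self, protein_ids) -> "CountMatrix":
        missing = [p for p in protein_ids if p not in self.data.index]
        if missing:
            raise KeyError(f"unknown protein ids: {missing}")
        return replace(self, data=self.data.loc[list(protein_ids)])

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "protein_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, layer: str = RAW_SC) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(data=df, layer=layer)


def read_samples(path) -> pd.DataFrame:
    """Read a sample-annotation TSV, validating the required columns."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table missing columns: {missing}")
    return df


def read_proteins(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    missing = [c for c in PROTEIN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"protein table missing columns: {missing}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
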