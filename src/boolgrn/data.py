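"""In-memory containers for count data and binary state matrices.

The pipeline's entry point is a gene x sample integer count matrix with a
two-group design (control "ND" vs treated "HFD").  Counts live in a pandas
DataFrame (genes in rows, samples in columns); condition labels ride along as
a pandas Series indexed by sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CONTROL = "ND"
TREATED = "HFD"


@dataclass
class CountMatrix:
    """Gene x sample counts plus per-sample condition labels."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    condition: pd.Series  # sample -> {"ND", "HFD"}

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        self.condition = self.condition.reindex(self.counts.columns)
        if self.condition.isna().any():
            raise ValueError("every sample needs a condition label")
        bad = set(self.condition.unique()) - {CONTROL, TREATED}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, condition: str) -> list[str]:
        return list(self.condition.index[self.condition == condition])

    def subset_genes(self, genes: list[str]) -> "CountMatrix":
        missing = [g for g in genes if g not in self.counts.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return CountMatrix(self.counts.loc[genes].copy(), self.condition.copy())

    # -- disk round trip ------------------------------------------------

    def write(self, path, meta: dict | None = None) -> None:
        """Write counts as TSV plus a sidecar ``<path>.json`` with labels."""
        path = Path(path)
        self.counts.to_csv(path, sep="\t", index_label="gene")
        sidecar = {"condition": self.condition.to_dict()}
        if meta:
            sidecar.update(meta)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1)
        )

    @classmethod
    def read(cls, path) -> "CountMatrix":
        path = Path(path)
        counts = pd.read_csv(path, sep="\t", index_col="gene")
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        condition = pd.Series(sidecar["condition"])
        return cls(counts, condition)


def write_binary_states(states: pd.DataFrame, path) -> None:
    """Write a gene x sample 0/1 matrix as TSV."""
    states.astype(int).to_csv(path, sep="\t", index_label="gene")


def read_binary_states(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    vals = df.to_numpy()
    if not np.isin(vals, [0, 1]).all():
        raise ValueError("binary state matrix must contain only 0/1")
    return df.astype(int)
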