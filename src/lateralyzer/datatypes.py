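"""Core data containers: counts, sample metadata, log-scale expression.

All tabular I/O is plain TSV so that datasets round-trip through text files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

SIDES = ("L", "R")
SEXES = ("M", "F")


@dataclass
class CountMatrix:
    """Gene-by-sample matrix of non-negative integer read counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples), integer dtype
    lib_sizes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample IDs")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
            if self.lib_sizes.shape != (len(self.sample_ids),):
                raise ValueError("lib_sizes length must equal number of samples")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, keep: np.ndarray) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return CountMatrix(
            gene_ids=[self.gene_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            counts=self.counts[idx, :],
            lib_sizes=self.lib_sizes.copy(),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return CountMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            counts=self.counts[:, idx],
            lib_sizes=None,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        counts = df.to_numpy()
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError(f"{path}: counts are not integers")
            counts = counts.astype(np.int64)
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            counts=counts,
        )


@dataclass
class SampleSheet:
    """Per-sample metadata: individual, side, structure, age, sex."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "individual", "side", "structure", "age_pcw", "sex")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        tab = self.table
        if tab["sample_id"].duplicated().any():
            raise ValueError("duplicate sample IDs in sample sheet")
        bad_side = set(tab["side"]) - set(SIDES)
        if bad_side:
            raise ValueError(f"side values must be L/R, got {sorted(bad_side)}")
        bad_sex = set(tab["sex"]) - set(SEXES)
        if bad_sex:
            raise ValueError(f"sex values must be M/F, got {sorted(bad_sex)}")
        if (tab["age_pcw"] <= 0).any():
            raise ValueError("ages must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def for_structure(self, structure: str) -> "SampleSheet":
        sub = self.table[self.table["structure"] == structure].reset_index(drop=True)
        return SampleSheet(sub)

    @property
    def structures(self) -> list[str]:
        return list(dict.fromkeys(self.table["structure"]))

    def check_paired(self) -> None:
        """Require exactly one L and one R sample per individual."""
        for ind, grp in self.table.groupby("individual", sort=False):
            sides = sorted(grp["side"])
            if sides != ["L", "R"]:
                raise ValueError(
                    f"individual {ind!r} is not a complete L/R pair (sides: {sides})"
                )

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleSheet":
        tab = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "individual": str})
        return cls(tab)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample matrix of log2-CPM values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match gene/sample IDs")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")
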