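"""Cross-structure synthesis: Jaccard overlap of lateralized gene sets."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gsea import GseaResultList


def jaccard(a: set, b: set) -> float:
    """|a & b| / |a | b|, with 0 for two empty sets (declared convention)."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


@dataclass
class LateralizedSetList:
    """Gene sets enriched on one side of one structure at an FDR threshold."""

    structure: str
    side: str  # L or R
    names: set[str]
    threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.side not in ("L", "R"):
            raise ValueError("side must be 'L' or 'R'")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        self.names = set(self.names)


def lateralized_sets(
    results: GseaResultList, structure: str, threshold: float = 0.05
) -> tuple[LateralizedSetList, LateralizedSetList]:
    """Split enriched sets by side.

    The ranked list is ordered by the side t-value with positive = higher
    right-sided expression, so positive-NES sets are right-enriched and
    negative-NES sets left-enriched.
    """
    right = {r.name for r in results if r.fdr < threshold and r.nes > 0}
    left = {r.name for r in results if r.fdr < threshold and r.nes < 0}
    return (
        LateralizedSetList(structure, "L", left, threshold),
        LateralizedSetList(structure, "R", right, threshold),
    )


@dataclass
class OverlapReport:
    matrices: dict[str, pd.DataFrame]  # side -> structures x structures
    summary: pd.DataFrame  # per side: mean off-diagonal Jaccard

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        for side, mat in self.matrices.items():
            mat.to_csv(f"{prefix}_jaccard_{side}.tsv", sep="\t")
        self.summary.to_csv(f"{prefix}_jaccard_summary.tsv", sep="\t", index=False)


def overlap_matrix(lists: list[LateralizedSetList]) -> OverlapReport:
    """Side-stratified pairwise Jaccard matrices across structures."""
    if len(lists) < 2:
        raise ValueError("need at least 2 lateralized set lists")
    thresholds = {l.threshold for l in lists}
    if len(thresholds) > 1:
        raise ValueError(f"mixed FDR thresholds across lists: {sorted(thresholds)}")
    matrices: dict[str, pd.DataFrame] = {}
    summary_rows = []
    for side in ("L", "R"):
        side_lists = [l for l in lists if l.side == side]
        if not side_lists:
            continue
        structures = [l.structure for l in side_lists]
        if len(set(structures)) != len(structures):
            raise ValueError(f"duplicate structures on side {side}")
        m = len(side_lists)
        mat = np.zeros((m, m))
        for i in range(m):
            for j in range(m):
                if i == j:
                    mat[i, j] = 1.0 if side_lists[i].names else 0.0
                else:
                    mat[i, j] = jaccard(side_lists[i].names, side_lists[j].names)
        df = pd.DataFrame(mat, index=structures, columns=structures)
        df.index.name = "structure"
        matrices[side] = df
        off_diag = mat[~np.eye(m, dtype=bool)]
        summary_rows.append(
            {
                "side": side,
                "n_structures": m,
                "mean_offdiag_jaccard": float(off_diag.mean()) if m > 1 else np.nan,
            }
        )
    return OverlapReport(matrices, pd.DataFrame(summary_rows))
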