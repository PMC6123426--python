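"""Side-age correlation: which side leads the shared developmental program.

The statistic is the Pearson correlation, over genes, between the paired
left/right t-values and the age t-values.  With the sign conventions used
throughout (side t positive = higher on the right; age t positive =
increases with age), a positive correlation means the right side is ahead
of the left on the trajectory both sides follow.

Genes are generally not independent observations, so the nominal Pearson
p-value is biased; direction calls therefore require the sign-flip
permutation p-value (see :mod:`lateralyzer.permutation`), not the nominal
one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .de import DEResult


@dataclass
class AsynchronyReport:
    structure: str
    n_genes: int
    r: float
    nominal_p: float
    direction: str  # right-leads / left-leads / none
    permutation_p: float | None = None
    caveat: str = "genes non-independent; nominal p biased"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "structure": [self.structure],
                "n_genes": [self.n_genes],
                "r": [self.r],
                "nominal_p": [self.nominal_p],
                "permutation_p": [self.permutation_p],
                "direction": [self.direction],
                "caveat": [self.caveat],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def shared_t_values(
    side_de: DEResult, age_de: DEResult
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Intersect the two analyses' genes; the sample sets may differ."""
    age_t = dict(zip(age_de.gene_ids, age_de.t_values))
    genes = [g for g in side_de.gene_ids if g in age_t]
    side_t = np.array(
        [t for g, t in zip(side_de.gene_ids, side_de.t_values) if g in age_t]
    )
    return genes, side_t, np.array([age_t[g] for g in genes])


def side_age_correlation(
    side_de: DEResult,
    age_de: DEResult,
    structure: str = "",
    permutation_p: float | None = None,
    alpha: float = 0.05,
) -> AsynchronyReport:
    """Pearson r between side and age t-values over shared genes.

    The direction call uses the permutation p when supplied; without one no
    direction is called, whatever the nominal p says.
    """
    genes, side_t, age_t = shared_t_values(side_de, age_de)
    if len(genes) < 3:
        raise ValueError(f"only {len(genes)} shared genes; need >= 3")
    if np.std(side_t) == 0 or np.std(age_t) == 0:
        raise ValueError("zero variance in t-values; correlation undefined")
    r, p = stats.pearsonr(side_t, age_t)
    direction = "none"
    if permutation_p is not None and permutation_p < alpha:
        direction = "right-leads" if r > 0 else "left-leads"
    return AsynchronyReport(
        structure=structure,
        n_genes=len(genes),
        r=float(r),
        nominal_p=float(p),
        direction=direction,
        permutation_p=permutation_p,
    )


def scatter_report(
    side_de: DEResult,
    age_de: DEResult,
    out_prefix: str | Path,
    structure: str = "",
) -> pd.DataFrame:
    """Write the per-gene (side t, age t) table and the scatter figure.

    X axis: left-right t-value (positive = higher right-sided expression);
    Y axis: age t-value (positive = increases with age).
    """
    genes, side_t, age_t = shared_t_values(side_de, age_de)
    if len(genes) == 0:
        raise ValueError("zero shared genes between side and age analyses")
    table = pd.DataFrame({"gene_id": genes, "side_t": side_t, "age_t": age_t})
    out_prefix = Path(out_prefix)
    table.to_csv(f"{out_prefix}_side_age_t.tsv", sep="\t", index=False)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(side_t, age_t, s=4, alpha=0.4, linewidths=0)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.axvline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("left-right t-value (positive = higher right)")
    ax.set_ylabel("age t-value (positive = increases with age)")
    if structure:
        ax.set_title(structure)
    fig.tight_layout()
    fig.savefig(f"{out_prefix}_side_age_scatter.png", dpi=150)
    plt.close(fig)
    return table
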