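"""Bespoke permutation nulls for the laterality analysis.

Two schemes:

* left/right sign flips: every way of swapping (or not) the L and R samples
  of each individual.  The all-flipped assignment only mirrors the
  all-unflipped one, so with the first individual held unflipped there are
  exactly ``2^(n-1)`` distinct assignments, the true data being the
  all-unflipped one.  For every assignment the paired side contrast, the
  gene-set enrichment count and the side-age correlation are recomputed;
  the age contrast is flip-invariant and computed once.
* t-value randomization: the observed side t-values are randomly reassigned
  to genes before enrichment, which preserves the score distribution but
  destroys gene-set coherence.

Empirical p-values use the add-one estimator
``(1 + #{perm >= obs}) / (1 + #perm)`` and can therefore never be zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CountMatrix, SampleSheet
from .de import DEResult, side_contrast
from .gsea import GeneSetCollection, RankedList, gsea_preranked

ENUMERATION_CAP = 20


@dataclass(frozen=True)
class FlipAssignment:
    """Per-individual flip bits; bit 1 = that individual's L/R swapped."""

    bits: tuple[int, ...]

    @property
    def n(self) -> int:
        return len(self.bits)

    @property
    def n_unflipped(self) -> int:
        return self.n - sum(self.bits)

    @property
    def similarity(self) -> float:
        """max(k, n-k)/n with k the unflipped count; 1 for the true data
        and for its global mirror."""
        k = self.n_unflipped
        return max(k, self.n - k) / self.n

    @property
    def is_identity(self) -> bool:
        return sum(self.bits) == 0

    def label(self) -> str:
        return "".join(str(b) for b in self.bits)


def enumerate_flips(
    individuals,
    cap: int = ENUMERATION_CAP,
    monte_carlo: int | None = None,
    seed: int = 0,
) -> list[FlipAssignment]:
    """All 2^(n-1) flip assignments (first individual fixed unflipped).

    Beyond ``cap`` individuals, exhaustive enumeration must be replaced by
    seeded Monte-Carlo subsampling via ``monte_carlo=<n_draws>``; the
    identity assignment is always included first.
    """
    individuals = list(individuals)
    n = len(individuals)
    if n < 2:
        raise ValueError("need at least 2 individuals to flip")
    if n > cap:
        if monte_carlo is None:
            raise ValueError(
                f"{n} individuals would need 2^{n - 1} assignments; pass "
                f"monte_carlo=<n_draws> to subsample"
            )
        rng = np.random.default_rng(seed)
        out = [FlipAssignment(bits=(0,) * n)]
        seen = {out[0].bits}
        while len(out) < monte_carlo:
            bits = (0, *map(int, rng.integers(0, 2, size=n - 1)))
            if bits not in seen:
                seen.add(bits)
                out.append(FlipAssignment(bits=bits))
        return out
    return [
        FlipAssignment(bits=(0, *((code >> i) & 1 for i in range(n - 1))))
        for code in range(2 ** (n - 1))
    ]


def apply_flips(sheet: SampleSheet, assignment: FlipAssignment) -> SampleSheet:
    """Swap the L/R labels of flipped individuals."""
    tab = sheet.table.copy()
    individuals = list(dict.fromkeys(tab["individual"]))
    if len(individuals) != assignment.n:
        raise ValueError(
            f"assignment covers {assignment.n} individuals, sheet has "
            f"{len(individuals)}"
        )
    flipped = {ind for ind, b in zip(individuals, assignment.bits) if b}
    mask = tab["individual"].isin(flipped)
    tab.loc[mask, "side"] = tab.loc[mask, "side"].map({"L": "R", "R": "L"})
    return SampleSheet(tab)


def _empirical_p(observed: float, null_values: np.ndarray) -> float:
    return float((1 + np.sum(null_values >= observed)) / (1 + len(null_values)))


@dataclass
class PermutationSummary:
    table: pd.DataFrame  # assignment, similarity, r, n_sets_fdr
    observed_r: float
    p_abs_r: float
    observed_set_count: int | None = None
    p_set_count: float | None = None
    fdr_threshold: float = 0.25

    @property
    def n_assignments(self) -> int:
        return len(self.table)

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def plot_r_vs_similarity(self, path: str | Path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(self.table["similarity"], self.table["r"], s=12, alpha=0.6)
        obs = self.table[self.table["is_identity"]]
        ax.scatter(obs["similarity"], obs["r"], s=30, color="red", label="observed")
        ax.set_xlabel("similarity to true assignment")
        ax.set_ylabel("side-age correlation r")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def flip_pipeline(
    counts: CountMatrix,
    sheet: SampleSheet,
    sets: GeneSetCollection | None,
    flips: list[FlipAssignment] | None = None,
    age_de: DEResult | None = None,
    age_counts: CountMatrix | None = None,
    age_sheet: SampleSheet | None = None,
    fdr_threshold: float = 0.25,
    n_perm: int = 200,
    min_size: int = 15,
    max_size: int = 500,
    seed: int = 0,
    use_weights: bool = True,
) -> PermutationSummary:
    """Re-run side DE (+ optional GSEA) and the side-age correlation for
    every flip assignment.

    The age contrast is invariant under L/R flips, so it is supplied (or
    computed once from ``age_counts``/``age_sheet``) and reused.
    """
    sheet.check_paired()
    individuals = list(dict.fromkeys(sheet.table["individual"]))
    if flips is None:
        flips = enumerate_flips(individuals)
    if age_de is None:
        from .de import age_contrast

        if age_counts is None:
            age_counts, age_sheet = counts, sheet
        elif age_sheet is None:
            raise ValueError("age_counts requires age_sheet")
        age_de = age_contrast(age_counts, age_sheet)
    age_t = dict(zip(age_de.gene_ids, age_de.t_values))

    rows = []
    run_gsea = sets is not None and len(sets) > 0
    for assignment in flips:
        flipped_sheet = apply_flips(sheet, assignment)
        try:
            de = side_contrast(counts, flipped_sheet, use_weights=use_weights)
        except ValueError as exc:
            raise ValueError(
                f"side DE failed for flip assignment {assignment.label()}: {exc}"
            ) from exc
        shared = [g for g in de.gene_ids if g in age_t]
        side_t = np.array(
            [t for g, t in zip(de.gene_ids, de.t_values) if g in age_t]
        )
        r, _ = stats.pearsonr(side_t, np.array([age_t[g] for g in shared]))
        row = {
            "assignment": assignment.label(),
            "similarity": assignment.similarity,
            "is_identity": assignment.is_identity,
            "r": float(r),
        }
        if run_gsea:
            results = gsea_preranked(
                de.ranked_list(), sets, n_perm=n_perm, min_size=min_size,
                max_size=max_size, seed=seed,
            )
            row["n_sets_fdr"] = sum(res.fdr < fdr_threshold for res in results)
        rows.append(row)

    table = pd.DataFrame(rows)
    obs = table[table["is_identity"]]
    if len(obs) != 1:
        raise ValueError("expected exactly one identity assignment")
    observed_r = float(obs["r"].iloc[0])
    null = table[~table["is_identity"]]
    p_abs_r = _empirical_p(abs(observed_r), np.abs(null["r"].to_numpy()))
    observed_count = p_count = None
    if run_gsea:
        observed_count = int(obs["n_sets_fdr"].iloc[0])
        p_count = _empirical_p(observed_count, null["n_sets_fdr"].to_numpy())
    return PermutationSummary(
        table=table,
        observed_r=observed_r,
        p_abs_r=p_abs_r,
        observed_set_count=observed_count,
        p_set_count=p_count,
        fdr_threshold=fdr_threshold,
    )


@dataclass
class TValueRandomization:
    observed_count: int
    null_counts: list[int]
    ratio: float
    fdr_threshold: float = 0.25

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rep": ["observed", *range(1, len(self.null_counts) + 1)],
                "n_sets_fdr": [self.observed_count, *self.null_counts],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def tvalue_randomization(
    side_de: DEResult,
    sets: GeneSetCollection,
    n_reps: int = 10,
    seed: int = 0,
    fdr_threshold: float = 0.25,
    n_perm: int = 500,
    min_size: int = 15,
    max_size: int = 500,
) -> TValueRandomization:
    """Observed enrichment count vs counts after shuffling t-values across
    genes; the ratio quantifies how much set-level signal exceeds chance."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    genes = side_de.gene_ids
    scores = side_de.t_values

    def count_enriched(ranked: RankedList, gsea_seed: int) -> int:
        results = gsea_preranked(
            ranked, sets, n_perm=n_perm, min_size=min_size, max_size=max_size,
            seed=gsea_seed,
        )
        return sum(res.fdr < fdr_threshold for res in results)

    observed = count_enriched(RankedList.from_scores(genes, scores), seed)
    rng = np.random.default_rng(seed)
    null_counts = []
    for _ in range(n_reps):
        shuffled = [genes[i] for i in rng.permutation(len(genes))]
        null_counts.append(
            count_enriched(RankedList.from_scores(shuffled, scores), seed)
        )
    mean_null = float(np.mean(null_counts))
    if mean_null > 0:
        ratio = observed / mean_null
    else:
        ratio = float("inf") if observed > 0 else 1.0
    return TValueRandomization(
        observed_count=observed,
        null_counts=null_counts,
        ratio=ratio,
        fdr_threshold=fdr_threshold,
    )
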