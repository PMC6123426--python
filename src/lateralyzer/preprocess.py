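"""Normalization, expression filtering and sample-level quality control.

QC mirrors the usual bulk RNA-seq recipe for paired designs: log2-CPM
normalization, a minimum-expression filter (gene kept when at least
``min_libraries`` libraries have at least ``min_reads`` reads), sex
confirmation from XIST / EIF1AY / KDM5D expression, and classical
(Torgerson) MDS with per-dimension association tests and a
median + c*MAD outlier rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CountMatrix, ExpressionMatrix, SampleSheet

DEFAULT_SEX_MARKERS = ("XIST", "EIF1AY", "KDM5D")


def log2_cpm(counts: CountMatrix, prior_count: float = 0.5) -> ExpressionMatrix:
    """log2((count + prior) / (lib_size + 2*prior) * 1e6)."""
    if np.any(counts.lib_sizes <= 0):
        bad = [s for s, l in zip(counts.sample_ids, counts.lib_sizes) if l <= 0]
        raise ValueError(f"zero library size for samples: {bad}")
    lib = counts.lib_sizes + 2.0 * prior_count
    values = np.log2((counts.counts + prior_count) / lib[None, :] * 1.0e6)
    return ExpressionMatrix(
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        values=values,
    )


def filter_expressed(
    counts: CountMatrix, min_reads: int = 5, min_libraries: int = 3
) -> CountMatrix:
    """Keep genes with >= min_reads in at least min_libraries samples.

    Library sizes are preserved from the unfiltered matrix so that CPM
    values stay on the original sequencing-depth scale.
    """
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    if min_libraries < 1:
        raise ValueError("min_libraries must be >= 1")
    if min_libraries > counts.n_samples:
        raise ValueError(
            f"min_libraries={min_libraries} exceeds number of samples "
            f"({counts.n_samples})"
        )
    keep = (counts.counts >= min_reads).sum(axis=1) >= min_libraries
    return counts.subset_genes(keep)


def merge_samples(counts: CountMatrix, groups: dict[str, list[str]]) -> CountMatrix:
    """Sum integer counts of split libraries into one column per group."""
    known = set(counts.sample_ids)
    col = {s: j for j, s in enumerate(counts.sample_ids)}
    merged_ids, merged_cols = [], []
    used: set[str] = set()
    for new_id, members in groups.items():
        missing = [m for m in members if m not in known]
        if missing:
            raise ValueError(f"unknown samples in merge group {new_id!r}: {missing}")
        merged_ids.append(new_id)
        merged_cols.append(counts.counts[:, [col[m] for m in members]].sum(axis=1))
        used.update(members)
    for s in counts.sample_ids:
        if s not in used:
            merged_ids.append(s)
            merged_cols.append(counts.counts[:, col[s]])
    return CountMatrix(
        gene_ids=list(counts.gene_ids),
        sample_ids=merged_ids,
        counts=np.column_stack(merged_cols),
    )


# ---------------------------------------------------------------------------
# sex confirmation
# ---------------------------------------------------------------------------


def confirm_sex(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    markers: tuple[str, str, str] = DEFAULT_SEX_MARKERS,
    xist_threshold: float = 2.0,
    y_threshold: float = 1.0,
) -> pd.DataFrame:
    """Infer sex from marker expression and compare with the annotation.

    Female: XIST above threshold and both Y markers below threshold.
    Male: the reverse. Anything else (or absent markers) is indeterminate.
    """
    xist, y1, y2 = markers
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    have_markers = all(m in gene_pos for m in markers)
    rows = []
    annotated = dict(zip(sheet.table["sample_id"], sheet.table["sex"]))
    for j, sample in enumerate(expr.sample_ids):
        if not have_markers:
            rows.append(
                {
                    "sample_id": sample,
                    "xist": np.nan,
                    "y1": np.nan,
                    "y2": np.nan,
                    "inferred_sex": "indeterminate",
                    "annotated_sex": annotated.get(sample, ""),
                    "status": "indeterminate",
                }
            )
            continue
        x = expr.values[gene_pos[xist], j]
        a = expr.values[gene_pos[y1], j]
        b = expr.values[gene_pos[y2], j]
        if x > xist_threshold and a < y_threshold and b < y_threshold:
            inferred = "F"
        elif x <= xist_threshold and a >= y_threshold and b >= y_threshold:
            inferred = "M"
        else:
            inferred = "indeterminate"
        ann = annotated.get(sample, "")
        if inferred == "indeterminate":
            status = "indeterminate"
        else:
            status = "pass" if inferred == ann else "fail"
        rows.append(
            {
                "sample_id": sample,
                "xist": x,
                "y1": a,
                "y2": b,
                "inferred_sex": inferred,
                "annotated_sex": ann,
                "status": status,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# classical MDS QC
# ---------------------------------------------------------------------------


@dataclass
class MdsQcResult:
    coords: pd.DataFrame  # samples x dimensions
    eigenvalues: np.ndarray
    dimension_tests: pd.DataFrame
    outliers: pd.DataFrame

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.coords.to_csv(f"{prefix}_mds_coords.tsv", sep="\t")
        self.dimension_tests.to_csv(f"{prefix}_mds_tests.tsv", sep="\t", index=False)
        self.outliers.to_csv(f"{prefix}_outliers.tsv", sep="\t", index=False)


def classical_mds(dist: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson MDS: double-center the squared distances, eigendecompose."""
    n = dist.shape[0]
    d2 = dist**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = min(k, n)
    coords = np.zeros((n, k))
    for d in range(k):
        if evals[d] > 0:
            v = evecs[:, d] * np.sqrt(evals[d])
            # deterministic sign: largest-magnitude loading positive
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            coords[:, d] = v
    return coords, evals[:k]


def _top_variance_rows(values: np.ndarray, n_top: int) -> np.ndarray:
    variances = values.var(axis=1)
    if len(variances) <= n_top:
        return np.arange(len(variances))
    return np.sort(np.argsort(variances)[::-1][:n_top])


def mds_qc(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    k_dims: int = 8,
    n_top_genes: int = 500,
    outlier_mad: float = 5.0,
) -> MdsQcResult:
    """MDS coordinates, per-dimension association tests, outlier flags."""
    n = expr.n_samples
    if n < 3:
        raise ValueError("mds_qc requires at least 3 samples")
    if k_dims > n:
        warnings.warn(
            f"k_dims={k_dims} exceeds {n} samples; reduced to {n}", stacklevel=2
        )
        k_dims = n

    rows = _top_variance_rows(expr.values, n_top_genes)
    x = expr.values[rows, :].T  # samples x genes
    dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    coords, evals = classical_mds(dist, k_dims)
    k_dims = coords.shape[1]

    meta = sheet.table.set_index("sample_id").loc[expr.sample_ids]
    tests = _dimension_tests(coords, meta, k_dims)
    outliers = _outlier_flags(coords, meta, expr.sample_ids, outlier_mad)
    coords_df = pd.DataFrame(
        coords,
        index=pd.Index(expr.sample_ids, name="sample_id"),
        columns=[f"dim{d + 1}" for d in range(k_dims)],
    )
    return MdsQcResult(coords_df, evals, tests, outliers)


def _dimension_tests(coords: np.ndarray, meta: pd.DataFrame, k: int) -> pd.DataFrame:
    sex = meta["sex"].to_numpy()
    side = meta["side"].to_numpy()
    age = meta["age_pcw"].to_numpy(dtype=float)
    individual = meta["individual"].to_numpy()

    # pair L and R columns by individual for the paired side test
    pairs: list[tuple[int, int]] = []
    by_ind: dict[str, dict[str, int]] = {}
    for i, (ind, sd) in enumerate(zip(individual, side)):
        by_ind.setdefault(ind, {})[sd] = i
    for ind, sides in by_ind.items():
        if set(sides) == {"L", "R"}:
            pairs.append((sides["L"], sides["R"]))

    recs = []
    for d in range(k):
        v = coords[:, d]
        rec: dict[str, float | int] = {"dimension": d + 1}
        male, female = v[sex == "M"], v[sex == "F"]
        if len(male) >= 2 and len(female) >= 2:
            t, p = stats.ttest_ind(male, female)
            rec.update(sex_t=t, sex_p=p)
        else:
            rec.update(sex_t=np.nan, sex_p=np.nan)
        if len(pairs) >= 2:
            left = v[[i for i, _ in pairs]]
            right = v[[j for _, j in pairs]]
            t, p = stats.ttest_rel(right, left)
            rec.update(side_t=t, side_p=p)
        else:
            rec.update(side_t=np.nan, side_p=np.nan)
        if len(np.unique(age)) >= 3 and np.std(v) > 0:
            r, p = stats.pearsonr(v, age)
            rec.update(age_r=r, age_p=p)
        else:
            rec.update(age_r=np.nan, age_p=np.nan)
        recs.append(rec)
    df = pd.DataFrame(recs)
    for col in ("sex_p", "side_p", "age_p"):
        df[col + "_bonf"] = np.minimum(df[col] * k, 1.0)
    return df


def _outlier_flags(
    coords: np.ndarray,
    meta: pd.DataFrame,
    sample_ids: list[str],
    c: float,
) -> pd.DataFrame:
    structure = meta["structure"].to_numpy()
    dist = np.full(len(sample_ids), np.nan)
    threshold = np.full(len(sample_ids), np.nan)
    for st in np.unique(structure):
        idx = np.flatnonzero(structure == st)
        centroid = coords[idx].mean(axis=0)
        d = np.sqrt(((coords[idx] - centroid) ** 2).sum(axis=1))
        med = np.median(d)
        mad = np.median(np.abs(d - med))
        dist[idx] = d
        threshold[idx] = med + c * mad
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "structure": structure,
            "centroid_distance": dist,
            "threshold": threshold,
            "outlier": dist > threshold,
        }
    )
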