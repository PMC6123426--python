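"""Preranked weighted gene-set enrichment, implemented from first principles.

The statistic is the classic running-sum enrichment score: walking down a
ranked gene list, set members increment the sum by their weighted score
share and non-members decrement it by ``1/(N - N_hit)``; the ES is the
signed extremum.  The null model is gene-set randomization — random
same-size draws of positions from the ranked list — which is the only null
available for preranked input.  NES, nominal p, FWER and FDR follow the
standard normalization/tail-ratio recipe:

* ``NES = ES / mean(|null ES| of the same sign)`` per set;
* nominal p: fraction of the set's same-sign null ES values strictly more
  extreme than the observed ES;
* FWER p: fraction of permutations whose most extreme same-sign normalized
  null ES (over all sets, using the shared per-permutation draw) is
  strictly more extreme than the observed NES;
* FDR q: within each sign class, ratio of (fraction of pooled null NES at
  least as extreme) to (fraction of observed NES at least as extreme),
  clipped to [0, 1].
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------


@dataclass
class GeneSet:
    name: str
    description: str
    genes: list[str]

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g, None)
        self.genes = list(seen)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate set names: {dupes}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def names(self) -> list[str]:
        return [s.name for s in self.sets]

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s in self.sets:
                fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


@dataclass
class RankedList:
    """Gene IDs with scores, ordered descending (ties broken by gene ID)."""

    genes: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("ranked-list scores must be finite")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be in descending order")

    @classmethod
    def from_scores(cls, genes, scores) -> "RankedList":
        scores = np.asarray(scores, dtype=float)
        order = sorted(range(len(genes)), key=lambda i: (-scores[i], genes[i]))
        return cls([genes[i] for i in order], scores[order])

    def __len__(self) -> int:
        return len(self.genes)

    def write_rnk(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for g, s in zip(self.genes, self.scores):
                fh.write(f"{g}\t{float(s)!r}\n")


@dataclass
class GseaResult:
    name: str
    size: int
    es: float
    nes: float
    p: float
    fwer: float
    fdr: float
    leading_edge: list[str] = field(default_factory=list)


class GseaResultList(list):
    """List of GseaResult with the size-filtered set names attached."""

    def __init__(self, results=(), filtered=()):
        super().__init__(results)
        self.filtered: list[str] = list(filtered)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [r.name for r in self],
                "size": [r.size for r in self],
                "es": [r.es for r in self],
                "nes": [r.nes for r in self],
                "p": [r.p for r in self],
                "fwer": [r.fwer for r in self],
                "fdr": [r.fdr for r in self],
                "leading_edge": [",".join(r.leading_edge) for r in self],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# enrichment score
# ---------------------------------------------------------------------------


def _running_sum(positions: np.ndarray, weights: np.ndarray, n: int) -> np.ndarray:
    """Running enrichment sum over all n list positions.

    positions: sorted member positions; weights: |score|^p at every position.
    """
    k = len(positions)
    hit_w = weights[positions]
    # correctly-rounded sum: the ES extremum can sit on an exact tie between
    # a hit peak and a miss trough, where a 1-ulp denominator difference
    # would flip the reported sign
    denom = math.fsum(hit_w)
    if denom == 0.0:
        raise ValueError(
            "all member scores are zero: weighted hit normalization undefined"
        )
    if n == k:
        steps = np.zeros(n)
    else:
        steps = np.full(n, -1.0 / (n - k))
    steps[positions] = hit_w / denom
    return np.cumsum(steps)


def enrichment_score(
    ranked: RankedList,
    gene_set: GeneSet | list[str],
    weight_p: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted running-sum enrichment score for one set.

    Returns (ES, running sum over all positions, leading-edge genes).
    """
    members = gene_set.genes if isinstance(gene_set, GeneSet) else list(gene_set)
    index = {g: i for i, g in enumerate(ranked.genes)}
    positions = np.sort([index[g] for g in members if g in index])
    if len(positions) == 0:
        raise ValueError("gene set has no genes in the ranked list")
    n = len(ranked)
    weights = np.abs(ranked.scores) ** weight_p
    running = _running_sum(positions, weights, n)
    ext = int(np.argmax(np.abs(running)))
    es = float(running[ext])
    if es >= 0:
        lead = [ranked.genes[i] for i in positions if i <= ext]
    else:
        lead = [ranked.genes[i] for i in positions if i > ext]
    return es, running, lead


def _es_only(positions: np.ndarray, weights: np.ndarray, n: int) -> float:
    running = _running_sum(positions, weights, n)
    return float(running[np.argmax(np.abs(running))])


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------


def gsea_preranked(
    ranked: RankedList,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    min_size: int = 15,
    max_size: int = 500,
    weight_p: float = 1.0,
    seed: int = 0,
) -> GseaResultList:
    """Run preranked GSEA over a collection; see module docstring for the
    exact NES / p / FWER / FDR definitions."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = len(ranked)
    index = {g: i for i, g in enumerate(ranked.genes)}

    surviving: list[tuple[GeneSet, np.ndarray]] = []
    filtered: list[str] = []
    for s in sets:
        pos = np.sort([index[g] for g in s.genes if g in index])
        if min_size <= len(pos) <= max_size:
            surviving.append((s, pos))
        else:
            filtered.append(s.name)
    if filtered:
        logger.info("size filter [%d, %d] excluded %d sets", min_size, max_size,
                    len(filtered))
    if not surviving:
        warnings.warn("no gene sets survive the size filter", stacklevel=2)
        return GseaResultList([], filtered)

    weights = np.abs(ranked.scores) ** weight_p
    m = len(surviving)
    obs_es = np.empty(m)
    leading: list[list[str]] = []
    for i, (s, pos) in enumerate(surviving):
        es, _, lead = enrichment_score(ranked, s, weight_p)
        obs_es[i] = es
        leading.append(lead)

    # same-size random member draws; one shared permutation per iteration so
    # null ES values are coupled across sets within a permutation (for FWER)
    rng = np.random.default_rng(seed)
    sizes = np.array([len(pos) for _, pos in surviving])
    null_es = np.empty((m, n_perm))
    for j in range(n_perm):
        perm = rng.permutation(n)
        for i, k in enumerate(sizes):
            pos = np.sort(perm[:k])
            null_es[i, j] = _es_only(pos, weights, n)

    nes, null_nes = _normalize(obs_es, null_es)
    nominal_p = _nominal_p(obs_es, null_es)
    # the family-wise error of a set is by definition at least its own
    # nominal error; clamp to keep that guarantee under finite sampling
    fwer = np.maximum(_fwer(nes, null_nes, n_perm), nominal_p)
    fdr = _fdr(nes, null_nes)

    results = [
        GseaResult(
            name=s.name,
            size=int(sizes[i]),
            es=float(obs_es[i]),
            nes=float(nes[i]),
            p=float(nominal_p[i]),
            fwer=float(fwer[i]),
            fdr=float(fdr[i]),
            leading_edge=leading[i],
        )
        for i, (s, _) in enumerate(surviving)
    ]
    return GseaResultList(results, filtered)


def _sign_means(null_es: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-set mean of positive null ES and of |negative null ES|."""
    pos = np.where(null_es > 0, null_es, np.nan)
    neg = np.where(null_es < 0, -null_es, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        pos_mean = np.nanmean(pos, axis=1)
        neg_mean = np.nanmean(neg, axis=1)
    return pos_mean, neg_mean


def _normalize(obs_es: np.ndarray, null_es: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pos_mean, neg_mean = _sign_means(null_es)

    def norm(es: np.ndarray, pm: np.ndarray, nm: np.ndarray) -> np.ndarray:
        out = np.zeros_like(es)
        up = es >= 0
        with np.errstate(invalid="ignore", divide="ignore"):
            out[up] = es[up] / pm[up]
            out[~up] = es[~up] / nm[~up]
        return np.where(np.isfinite(out), out, 0.0)

    nes = norm(obs_es, pos_mean, neg_mean)
    null_nes = norm(
        null_es,
        np.broadcast_to(pos_mean[:, None], null_es.shape),
        np.broadcast_to(neg_mean[:, None], null_es.shape),
    )
    return nes, null_nes


def _nominal_p(obs_es: np.ndarray, null_es: np.ndarray) -> np.ndarray:
    # fraction of same-sign nulls strictly more extreme: a null draw that
    # merely ties the observed ES (e.g. it drew the same members) does not
    # count against it
    p = np.empty(len(obs_es))
    for i, es in enumerate(obs_es):
        if es >= 0:
            same = null_es[i][null_es[i] > 0]
            p[i] = np.sum(same > es) / len(same) if len(same) else 0.0
        else:
            same = null_es[i][null_es[i] < 0]
            p[i] = np.sum(same < es) / len(same) if len(same) else 0.0
    return p


def _fwer(nes: np.ndarray, null_nes: np.ndarray, n_perm: int) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        perm_max = np.max(np.where(null_nes > 0, null_nes, 0.0), axis=0)
        perm_min = np.min(np.where(null_nes < 0, null_nes, 0.0), axis=0)
    fwer = np.empty(len(nes))
    for i, v in enumerate(nes):
        if v >= 0:
            fwer[i] = np.sum(perm_max > v) / n_perm
        else:
            fwer[i] = np.sum(perm_min < v) / n_perm
    return fwer


def _fdr(nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """Pooled tail-ratio FDR, computed within each sign class."""
    pooled = null_nes.ravel()
    pooled_pos = pooled[pooled > 0]
    pooled_neg = pooled[pooled < 0]
    obs_pos = nes[nes >= 0]
    obs_neg = nes[nes < 0]
    q = np.empty(len(nes))
    for i, v in enumerate(nes):
        if v >= 0:
            num = np.mean(pooled_pos >= v) if len(pooled_pos) else 0.0
            den = np.mean(obs_pos >= v) if len(obs_pos) else 1.0
        else:
            num = np.mean(pooled_neg <= v) if len(pooled_neg) else 0.0
            den = np.mean(obs_neg <= v) if len(obs_neg) else 1.0
        q[i] = min(1.0, num / den) if den > 0 else 0.0
    return q


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a set are dropped (first occurrence kept)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene"
                )
            sets.append(GeneSet(name=parts[0], description=parts[1], genes=parts[2:]))
    return GeneSetCollection(sets)


def read_rnk(path: str | Path) -> RankedList:
    """Read a two-column RNK file and re-sort descending (ties: by gene ID)."""
    genes: list[str] = []
    scores: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            try:
                score = float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric score {parts[1]!r}") from exc
            genes.append(parts[0])
            scores.append(score)
    return RankedList.from_scores(genes, np.asarray(scores))
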