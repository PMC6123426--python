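"""Synthetic paired left/right RNA-seq datasets with known laterality structure.

The generative model: each gene has a baseline log2 abundance, an optional
linear age slope (log2 units per week), and a side offset applied with
opposite sign to the left and right samples of an individual.  The side
offset couples to the age slope through an asynchrony parameter ``delta``
(weeks): a gene whose expression rises with age is shifted up on the leading
side exactly as if that side were ``delta/2`` weeks older, and down on the
lagging side by the same amount, so the individual's nominal age stays the
midpoint.  Counts are negative binomial with mean/variance m + phi*m^2;
``phi = 0`` degenerates to Poisson.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import CountMatrix, SampleSheet
from .gsea import GeneSet, GeneSetCollection

MARKER_GENES = ("XIST", "EIF1AY", "KDM5D")

# marker log2 relative abundance by sex (XIST female-high, Y genes male-only)
_XIST_ON, _XIST_OFF = 6.0, -6.0
_Y_ON, _Y_OFF = 4.0, -20.0


@dataclass
class SimulationConfig:
    n_individuals: int = 6
    n_genes: int = 2000
    age_range: tuple[float, float] = (7.5, 13.0)
    frac_age_genes: float = 0.3
    slope_sd: float = 0.5
    asynchrony_delta: float = 0.0
    side_noise_sd: float = 0.05
    dispersion: float = 0.1
    lib_size_mean: float = 5.0e5
    lib_size_cv: float = 0.2
    n_sets: int = 50
    set_size_range: tuple[int, int] = (15, 100)
    frac_coherent_sets: float = 0.5
    sex_ratio: float = 0.5
    structure: str = "structure1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.n_individuals, (int, np.integer)) or isinstance(
            self.n_individuals, bool
        ):
            raise TypeError("n_individuals must be an integer")
        if not isinstance(self.n_genes, (int, np.integer)) or isinstance(
            self.n_genes, bool
        ):
            raise TypeError("n_genes must be an integer")
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        lo, hi = self.age_range
        if hi < lo:
            raise ValueError(f"empty age range: {self.age_range}")
        if not 0.0 <= self.frac_age_genes <= 1.0:
            raise ValueError("frac_age_genes must be in [0, 1]")
        if not 0.0 <= self.frac_coherent_sets <= 1.0:
            raise ValueError("frac_coherent_sets must be in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        smin, smax = self.set_size_range
        if smin < 2 or smax > self.n_genes or smin > smax:
            raise ValueError(
                f"set sizes must lie within [2, n_genes={self.n_genes}], "
                f"got {self.set_size_range}"
            )
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("age_range", "set_size_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruth:
    """Per-gene generative parameters of one simulated dataset."""

    gene_ids: list[str]
    baseline_log2: np.ndarray  # mu_g
    age_slope: np.ndarray  # a_g, log2 per week
    side_offset: np.ndarray  # delta_g, added for right, subtracted for left
    delta: float  # injected asynchrony, weeks (positive = right leads)
    coherent_sets: dict[str, int] = field(default_factory=dict)  # name -> +1/-1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "baseline_log2": self.baseline_log2,
                "age_slope": self.age_slope,
                "side_offset": self.side_offset,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _gene_ids(n_genes: int) -> list[str]:
    width = len(str(n_genes))
    n_plain = n_genes - len(MARKER_GENES)
    ids = [f"G{i + 1:0{width}d}" for i in range(n_plain)]
    ids.extend(MARKER_GENES)
    return ids


def simulate_dataset(
    config: SimulationConfig,
    truth: GroundTruth | None = None,
) -> tuple[CountMatrix, SampleSheet, GroundTruth]:
    """Draw one paired L/R count dataset.

    Passing a ``truth`` from a previous call reuses its gene-level parameters
    (baselines, slopes, side offsets), so several "structures" can share
    their expression programs while ages, sexes, library sizes and counts
    are redrawn.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    g = config.n_genes
    gene_ids = _gene_ids(g) if truth is None else list(truth.gene_ids)
    n_plain = g - len(MARKER_GENES)

    # gene-level parameters (drawn even when reusing truth, to keep the
    # downstream RNG stream identical between linked simulations)
    # sd kept moderate: a heavier tail lets single genes dominate a library,
    # and their count noise then shifts every other gene's CPM
    mu = rng.normal(3.0, 1.5, size=g)
    n_age = int(round(config.frac_age_genes * g))
    order = rng.permutation(n_plain)
    slopes = np.zeros(g)
    if n_age > 0:
        chosen = order[: min(n_age, n_plain)]
        slopes[chosen] = rng.normal(0.0, config.slope_sd, size=len(chosen))
        if n_age > n_plain:  # frac ~ 1: spill onto the marker genes
            extra = n_age - n_plain
            slopes[n_plain : n_plain + extra] = rng.normal(
                0.0, config.slope_sd, size=extra
            )
    noise = rng.normal(0.0, config.side_noise_sd, size=g) if config.side_noise_sd > 0 else np.zeros(g)
    side_offset = slopes * config.asynchrony_delta / 2.0 + noise

    if truth is not None:
        mu = truth.baseline_log2
        slopes = truth.age_slope
        side_offset = truth.side_offset

    # individuals: evenly spaced ages, sexes by ratio (shuffled)
    lo, hi = config.age_range
    ages = np.linspace(lo, hi, n)
    age_mid = (lo + hi) / 2.0  # baselines are abundances at the mid age
    n_male = int(round(config.sex_ratio * n))
    sexes = np.array(["M"] * n_male + ["F"] * (n - n_male))
    sexes = sexes[rng.permutation(n)]

    sigma2 = np.log1p(config.lib_size_cv**2)
    lib = rng.lognormal(
        mean=np.log(config.lib_size_mean) - sigma2 / 2.0,
        sigma=np.sqrt(sigma2),
        size=2 * n,
    )

    individuals = [f"E{i + 1:02d}" for i in range(n)]
    rows = []
    log2_expr = np.empty((g, 2 * n))
    for i in range(n):
        for k, (side, s) in enumerate((("L", -1.0), ("R", +1.0))):
            j = 2 * i + k
            x = mu + slopes * (ages[i] - age_mid) + s * side_offset
            # reserved sex markers override any age/side program
            if sexes[i] == "F":
                x[-3] = _XIST_ON
                x[-2] = _Y_OFF
                x[-1] = _Y_OFF
            else:
                x[-3] = _XIST_OFF
                x[-2] = _Y_ON
                x[-1] = _Y_ON
            log2_expr[:, j] = x
            rows.append(
                {
                    "sample_id": f"{individuals[i]}_{side}",
                    "individual": individuals[i],
                    "side": side,
                    "structure": config.structure,
                    "age_pcw": ages[i],
                    "sex": sexes[i],
                }
            )

    rel = np.exp2(log2_expr)
    mean = lib[None, :] * rel / rel.sum(axis=0, keepdims=True)
    counts = _draw_counts(rng, mean, config.dispersion)

    cm = CountMatrix(
        gene_ids=gene_ids,
        sample_ids=[r["sample_id"] for r in rows],
        counts=counts,
    )
    sheet = SampleSheet(pd.DataFrame(rows))
    out_truth = GroundTruth(
        gene_ids=gene_ids,
        baseline_log2=mu,
        age_slope=slopes,
        side_offset=side_offset,
        delta=config.asynchrony_delta,
    )
    if truth is not None:
        out_truth.coherent_sets = dict(truth.coherent_sets)
    return cm, sheet, out_truth


def nb_mean_matrix(config: SimulationConfig, truth: GroundTruth, ages: np.ndarray,
                   lib_sizes: np.ndarray, sexes: np.ndarray) -> np.ndarray:
    """Expected count matrix for given design — the simulator's mean formula,
    exposed so tests can check simulated marginals against it."""
    n = len(ages)
    g = len(truth.gene_ids)
    age_mid = (config.age_range[0] + config.age_range[1]) / 2.0
    log2_expr = np.empty((g, 2 * n))
    for i in range(n):
        for k, s in enumerate((-1.0, +1.0)):
            x = (truth.baseline_log2 + truth.age_slope * (ages[i] - age_mid)
                 + s * truth.side_offset)
            if sexes[i] == "F":
                x[-3], x[-2], x[-1] = _XIST_ON, _Y_OFF, _Y_OFF
            else:
                x[-3], x[-2], x[-1] = _XIST_OFF, _Y_ON, _Y_ON
            log2_expr[:, 2 * i + k] = x
    rel = np.exp2(log2_expr)
    return lib_sizes[None, :] * rel / rel.sum(axis=0, keepdims=True)


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0.0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = 1.0 / (1.0 + phi * mean)
    return rng.negative_binomial(r, p)


def simulate_gene_sets(config: SimulationConfig, truth: GroundTruth) -> GeneSetCollection:
    """Build a gene-set collection matched to a simulation's ground truth.

    A fraction ``frac_coherent_sets`` of sets are "coherent": drawn from the
    genes with the most positive (UP sets) or most negative (DOWN sets) age
    slopes, so with a nonzero asynchrony delta these are lateralized by
    construction.  The remaining sets are uniform draws.
    """
    smin, smax = config.set_size_range
    if smax > config.n_genes:
        raise ValueError("set_size_range exceeds n_genes")
    rng = np.random.default_rng([config.seed, 1003])
    n_coherent = int(round(config.frac_coherent_sets * config.n_sets))
    slopes = np.asarray(truth.age_slope)
    g = len(truth.gene_ids)
    gene_arr = np.asarray(truth.gene_ids)
    pool_size = max(smax, g // 4)

    sets: list[GeneSet] = []
    truth.coherent_sets = {}
    width = len(str(config.n_sets))
    for m in range(config.n_sets):
        size = int(rng.integers(smin, smax + 1))
        if m < n_coherent:
            direction = +1 if m % 2 == 0 else -1
            ranked = np.argsort(-direction * slopes, kind="stable")
            pool = ranked[: max(size, pool_size)]
            members = gene_arr[rng.choice(pool, size=size, replace=False)]
            tag = "UP" if direction > 0 else "DOWN"
            name = f"COHERENT_{tag}_{m + 1:0{width}d}"
            desc = f"coherent age-program set ({tag.lower()})"
            truth.coherent_sets[name] = direction
        else:
            members = gene_arr[rng.choice(g, size=size, replace=False)]
            name = f"RANDOM_{m + 1:0{width}d}"
            desc = "uniform random set"
        sets.append(GeneSet(name=name, description=desc, genes=list(members)))
    return GeneSetCollection(sets)


def write_dataset(
    out_dir: str | Path,
    counts: CountMatrix,
    sheet: SampleSheet,
    truth: GroundTruth,
    gene_sets: GeneSetCollection | None = None,
    config: SimulationConfig | None = None,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts.write_tsv(out / "counts.tsv")
    sheet.write_tsv(out / "samples.tsv")
    truth.write_tsv(out / "ground_truth.tsv")
    if gene_sets is not None:
        gene_sets.write_gmt(out / "gene_sets.gmt")
    if config is not None:
        config.to_yaml(out / "config.yaml")
    if truth.coherent_sets:
        with open(out / "coherent_sets.json", "w") as fh:
            json.dump(truth.coherent_sets, fh, indent=1)
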