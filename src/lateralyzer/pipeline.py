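"""End-to-end driver: QC -> filter -> DE -> GSEA -> asynchrony -> permutations
-> cross-structure overlap, for simulated or file-based inputs.

Every stage is a pure function of (inputs, config, seed); the whole output
tree is reproducible bit-identically under a fixed config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .asynchrony import scatter_report, side_age_correlation
from .datatypes import CountMatrix, SampleSheet
from .de import age_contrast, side_contrast
from .gsea import GeneSetCollection, gsea_preranked, read_gmt
from .overlap import lateralized_sets, overlap_matrix
from .permutation import flip_pipeline, tvalue_randomization
from .preprocess import confirm_sex, filter_expressed, log2_cpm, mds_qc
from .simulate import SimulationConfig, simulate_dataset, simulate_gene_sets

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, annotated with stage name and structure."""


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 1
    # simulation mode: n_structures datasets sharing one gene program
    simulate: dict | None = None
    n_structures: int = 1
    # file mode: list of {name, counts, samples, gmt}
    inputs: list[dict] = field(default_factory=list)
    min_reads: int = 5
    min_libraries: int = 3
    gsea_min_size: int = 15
    gsea_max_size: int = 500
    gsea_n_perm: int = 500
    fdr_enriched: float = 0.05
    fdr_permutation: float = 0.25
    k_dims: int = 8
    outlier_mad: float = 5.0
    run_flip_gsea: bool = False
    flip_gsea_n_perm: int = 100
    tvalue_reps: int = 10
    make_figures: bool = False

    def __post_init__(self) -> None:
        for name in ("min_reads", "min_libraries", "gsea_min_size",
                     "gsea_max_size", "gsea_n_perm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("fdr_enriched", "fdr_permutation"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.simulate is None and not self.inputs:
            raise ValueError("config needs either a 'simulate' block or 'inputs'")
        for item in self.inputs:
            for key in ("counts", "samples"):
                path = Path(item[key])
                if not path.exists():
                    raise FileNotFoundError(f"input file missing: {path}")
            if "gmt" in item and not Path(item["gmt"]).exists():
                raise FileNotFoundError(f"gene-set file missing: {item['gmt']}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class StructureResult:
    name: str
    side_de: object
    age_de: object
    side_gsea: object
    age_gsea: object
    asynchrony: object
    flip_summary: object
    tvalue: object


def _load_structures(config: PipelineConfig):
    """Yield (name, counts, sheet, gene_sets) per structure."""
    if config.simulate is not None:
        base = dict(config.simulate)
        base.setdefault("seed", config.seed)
        truth = None
        sets = None
        for i in range(config.n_structures):
            params = dict(base)
            params["structure"] = f"structure{i + 1}"
            params["seed"] = base["seed"] + i
            sim_config = SimulationConfig(**params)
            counts, sheet, new_truth = simulate_dataset(sim_config, truth=truth)
            if truth is None:
                truth = new_truth  # later structures share the gene program
                sets = simulate_gene_sets(sim_config, truth)
            yield params["structure"], counts, sheet, sets
    else:
        for item in config.inputs:
            counts = CountMatrix.read_tsv(item["counts"])
            sheet = SampleSheet.read_tsv(item["samples"])
            sets = read_gmt(item["gmt"]) if "gmt" in item else None
            yield item["name"], counts, sheet, sets


def _stage(structure: str, stage: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(
                    f"stage {stage!r} failed for structure {structure!r}: {exc}"
                ) from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    out_root = Path(config.out_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    logger.info("lateralyzer %s pipeline, seed=%d", __version__, config.seed)

    results: dict[str, StructureResult] = {}
    lat_lists = []
    summary_rows = []
    for name, counts, sheet, sets in _load_structures(config):
        out = out_root / name
        out.mkdir(exist_ok=True)
        sheet = sheet.for_structure(name) if name in sheet.structures else sheet

        with _stage(name, "qc"):
            expr_all = log2_cpm(counts)
            sex_report = confirm_sex(expr_all, sheet)
            sex_report.to_csv(out / "sex_check.tsv", sep="\t", index=False)
            qc = mds_qc(expr_all, sheet, k_dims=config.k_dims,
                        outlier_mad=config.outlier_mad)
            qc.write(out / "qc")

        with _stage(name, "filter"):
            filtered = filter_expressed(counts, config.min_reads,
                                        config.min_libraries)

        with _stage(name, "side_de"):
            side_de = side_contrast(filtered, sheet)
            side_de.write_tsv(out / "side_de.tsv")
            side_de.write_rnk(out / "side.rnk")

        with _stage(name, "age_de"):
            age_de = age_contrast(filtered, sheet)
            age_de.write_tsv(out / "age_de.tsv")
            age_de.write_rnk(out / "age.rnk")

        side_gsea = age_gsea = None
        if sets is not None:
            with _stage(name, "gsea"):
                side_gsea = gsea_preranked(
                    side_de.ranked_list(), sets, n_perm=config.gsea_n_perm,
                    min_size=config.gsea_min_size, max_size=config.gsea_max_size,
                    seed=config.seed,
                )
                side_gsea.write_tsv(out / "side_gsea.tsv")
                age_gsea = gsea_preranked(
                    age_de.ranked_list(), sets, n_perm=config.gsea_n_perm,
                    min_size=config.gsea_min_size, max_size=config.gsea_max_size,
                    seed=config.seed,
                )
                age_gsea.write_tsv(out / "age_gsea.tsv")

        with _stage(name, "permutations"):
            flip = flip_pipeline(
                filtered, sheet,
                sets if (config.run_flip_gsea and sets is not None) else None,
                age_de=age_de,
                fdr_threshold=config.fdr_permutation,
                n_perm=config.flip_gsea_n_perm,
                min_size=config.gsea_min_size,
                max_size=config.gsea_max_size,
                seed=config.seed,
            )
            flip.write_tsv(out / "flip_permutations.tsv")
            if config.make_figures:
                flip.plot_r_vs_similarity(out / "r_vs_similarity.png")
            tval = None
            if sets is not None:
                tval = tvalue_randomization(
                    side_de, sets, n_reps=config.tvalue_reps, seed=config.seed,
                    fdr_threshold=config.fdr_permutation,
                    n_perm=config.gsea_n_perm,
                    min_size=config.gsea_min_size,
                    max_size=config.gsea_max_size,
                )
                tval.write_tsv(out / "tvalue_randomization.tsv")

        with _stage(name, "asynchrony"):
            report = side_age_correlation(
                side_de, age_de, structure=name, permutation_p=flip.p_abs_r
            )
            report.write_tsv(out / "asynchrony.tsv")
            if config.make_figures:
                scatter_report(side_de, age_de, out / name, structure=name)

        if side_gsea is not None:
            left, right = lateralized_sets(side_gsea, name, config.fdr_enriched)
            lat_lists.extend([left, right])
            top_left = _top_sets(side_gsea, "L", config.fdr_enriched)
            top_right = _top_sets(side_gsea, "R", config.fdr_enriched)
        else:
            top_left = top_right = ""

        leading = {"right-leads": "right", "left-leads": "left", "none": "none"}
        summary_rows.append(
            {
                "structure": name,
                "n_pairs": sheet.table["individual"].nunique(),
                "n_genes_tested": len(side_de.table),
                "side_age_r": report.r,
                "permutation_p": report.permutation_p,
                "leading_side": leading[report.direction],
                "top_sets_left": top_left,
                "top_sets_right": top_right,
                "tvalue_ratio": tval.ratio if tval is not None else float("nan"),
            }
        )
        results[name] = StructureResult(
            name, side_de, age_de, side_gsea, age_gsea, report, flip, tval
        )

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out_root / "summary.tsv", sep="\t", index=False)
    overlap = None
    if len({l.structure for l in lat_lists}) >= 2:
        overlap = overlap_matrix(lat_lists)
        overlap.write(out_root / "overlap")
    return {"structures": results, "summary": summary, "overlap": overlap}


def _top_sets(gsea_results, side: str, threshold: float, k: int = 2) -> str:
    """Top-k enriched sets per side, by |NES| among FDR-passing sets."""
    if side == "R":
        passing = [r for r in gsea_results if r.fdr < threshold and r.nes > 0]
    else:
        passing = [r for r in gsea_results if r.fdr < threshold and r.nes < 0]
    passing.sort(key=lambda r: (-abs(r.nes), r.name))
    return ",".join(r.name for r in passing[:k])
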