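"""End-to-end orchestration: gene scoring -> modules -> enrichment -> permutation.

`run_pipeline` is the in-memory core used by the tests and the acceptance
script; `run_igea` wraps it with file I/O, checkpointing each stage as TSV so
stages can be inspected or re-run independently.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .enrichment import EnrichmentResult, enrich_all
from .gene_scoring import (
    GeneQtMatrix,
    map_snps_to_genes,
    read_gene_qt_matrix,
    significant_pairs,
    write_gene_qt_matrix,
)
from .io import read_expression_matrix, read_gene_annotation, read_snp_associations
from .modules import STRATEGIES, ExpressionMatrix, GsBcModule, build_modules, preprocess_expression
from .permutation import (
    DEFAULT_SEED,
    DegenerateNullError,
    PermutationEvaluation,
    evaluate_permutations,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineParams", "PipelineConfig", "PipelineError", "run_pipeline", "run_igea"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineParams:
    """Numeric knobs of the analysis, with the standard defaults."""

    window_bp: int = 20_000
    threshold: float = 1.0e-5
    min_gs: int = 10
    max_gs: int = 200
    min_bc: int = 2
    top_fraction: float = 0.2
    strategies: tuple[str, ...] = STRATEGIES
    alpha: float = 0.05
    correction_scope: str = "per_strategy"  # or "union"
    n_perm: int = 50
    seed: int = DEFAULT_SEED
    perm_mode: str = "rows"
    run_permutation: bool = True

    def __post_init__(self) -> None:
        if self.correction_scope not in ("per_strategy", "union"):
            raise ValueError(f"unknown correction scope {self.correction_scope!r}")
        unknown = set(self.strategies) - set(STRATEGIES)
        if unknown:
            raise ValueError(f"unknown strategies {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """File-level configuration for a full run (CLI `igea run`)."""

    expression: str
    out_dir: str
    snps: str | None = None
    snp_dialect: str = "long_tsv"
    genes: str | None = None
    gene_format: str = "tsv_1based"
    gene_scores: str | None = None
    sample_map: str | None = None
    probe_map: str | None = None
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        params = PipelineParams(**doc.pop("params", {}))
        return cls(params=params, **doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(
    expression: ExpressionMatrix,
    gene_qt: GeneQtMatrix,
    params: PipelineParams | None = None,
) -> dict:
    """Run module construction, enrichment and permutation on in-memory inputs.

    Returns a dict with the constructed objects (``modules``, ``selections``,
    ``enrichment``, ``permutation``) and a JSON-serializable ``report`` of
    every count the analysis produces.
    """
    params = params or PipelineParams()

    with _stage("module_construction"):
        built = build_modules(
            expression,
            min_gs=params.min_gs,
            max_gs=params.max_gs,
            min_bc=params.min_bc,
            top_fraction=params.top_fraction,
        )
    selections: dict[str, list[GsBcModule]] = built["selections"]

    with _stage("igea_enrichment"):
        sig = significant_pairs(gene_qt, params.threshold)
        enrichment: dict[str, list[EnrichmentResult]] = {}
        if params.correction_scope == "union":
            union: dict[str, GsBcModule] = {}
            for s in params.strategies:
                for m in selections[s]:
                    union.setdefault(m.module_id, m)
            union_results = {
                r.module_id: r
                for r in (
                    enrich_all(list(union.values()), gene_qt, sig, alpha=params.alpha)
                    if union
                    else []
                )
            }
            for s in params.strategies:
                enrichment[s] = [union_results[m.module_id] for m in selections[s]]
        else:
            for s in params.strategies:
                enrichment[s] = (
                    enrich_all(selections[s], gene_qt, sig, alpha=params.alpha)
                    if selections[s]
                    else []
                )

    permutation: dict[str, PermutationEvaluation | None] = {}
    if params.run_permutation:
        with _stage("permutation_evaluation"):
            for i, s in enumerate(params.strategies):
                if not selections[s]:
                    logger.warning("strategy %s selected no modules; skipping", s)
                    permutation[s] = None
                    continue
                try:
                    permutation[s] = evaluate_permutations(
                        selections[s],
                        gene_qt,
                        threshold=params.threshold,
                        alpha=params.alpha,
                        n_perm=params.n_perm,
                        seed=params.seed + i,
                        mode=params.perm_mode,
                    )
                except DegenerateNullError:
                    logger.warning(
                        "strategy %s: degenerate permutation null, p undefined", s
                    )
                    permutation[s] = None

    n_sig = {
        s: sum(1 for r in enrichment[s] if r.significant) for s in params.strategies
    }
    report = {
        "N_G": gene_qt.n_genes,
        "N_B": gene_qt.n_qts,
        "N": gene_qt.universe_size,
        "n_significant_pairs": sig.count,
        "threshold": params.threshold,
        **built["counts"],
        "n_significant_modules": n_sig,
        "n_tests": {
            s: (enrichment[s][0].n_tests if enrichment[s] else 0)
            for s in params.strategies
        },
        "permutation": {
            s: (
                None
                if permutation.get(s) is None
                else {
                    "n_perm": permutation[s].n_perm,
                    "prop_orig": permutation[s].prop_orig,
                    "mu_perm": permutation[s].mu_perm,
                    "sigma_perm": permutation[s].sigma_perm,
                    "t_stat": permutation[s].t_stat,
                    "p_value": permutation[s].p_value,
                }
            )
            for s in permutation
        },
        "params": dataclasses.asdict(params),
    }
    assert report["N"] == report["N_G"] * report["N_B"]
    return {
        "gene_sets": built["gene_sets"],
        "circuits": built["circuits"],
        "modules": built["modules"],
        "selections": selections,
        "significant_pairs": sig,
        "enrichment": enrichment,
        "permutation": permutation,
        "report": report,
    }


def write_module_tables(result: dict, out_dir: str | Path, prefix: str = "modules") -> None:
    """Checkpoint modules and memberships as TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "module_id": m.module_id,
            "gs_id": m.gene_set.gs_id,
            "bc_id": m.circuit.bc_id,
            "n_genes": m.n_genes,
            "n_rois": m.n_rois,
            "z_gene": m.z_gene,
            "z_roi": m.z_roi,
            "selected_by": ",".join(sorted(m.selected_by)),
        }
        for m in result["modules"]
    ]
    pd.DataFrame(rows).to_csv(out / f"{prefix}.tsv", sep="\t", index=False)
    gs_rows = [
        {"gs_id": gs.gs_id, "gene_id": g}
        for gs in result["gene_sets"]
        for g in gs.gene_ids
    ]
    pd.DataFrame(gs_rows).to_csv(out / f"{prefix}_gs_members.tsv", sep="\t", index=False)
    bc_rows = [
        {"bc_id": bc.bc_id, "roi_id": r}
        for bc in result["circuits"]
        for r in bc.roi_ids
    ]
    pd.DataFrame(bc_rows).to_csv(out / f"{prefix}_bc_members.tsv", sep="\t", index=False)


def write_enrichment_tables(result: dict, out_dir: str | Path) -> None:
    """Checkpoint per-strategy enrichment results as TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_id = {m.module_id: m for m in result["modules"]}
    for s, results in result["enrichment"].items():
        rows = [
            {
                "module_id": r.module_id,
                "bc_id": by_id[r.module_id].circuit.bc_id,
                "n_rois": by_id[r.module_id].n_rois,
                "gs_id": by_id[r.module_id].gene_set.gs_id,
                "n_genes": by_id[r.module_id].n_genes,
                "N": r.N,
                "n": r.n,
                "m": r.m,
                "k": r.k,
                "p_raw": r.p_raw,
                "p_corrected": r.p_corrected,
                "significant": r.significant,
                "testable": r.testable,
                "selected_by": ",".join(sorted(by_id[r.module_id].selected_by)),
            }
            for r in results
        ]
        pd.DataFrame(rows).to_csv(out / f"enrichment_{s}.tsv", sep="\t", index=False)


def run_igea(config: PipelineConfig) -> dict:
    """Full file-to-file run: read inputs, execute all stages, write outputs.

    Gene scores come either from a precomputed gene x QT TSV
    (``config.gene_scores``) or from SNP summary statistics plus a gene
    annotation. Returns the report dict (also written to ``report.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _stage("io_formats"):
        for label, p in (
            ("expression", config.expression),
            ("snps", config.snps),
            ("genes", config.genes),
            ("gene_scores", config.gene_scores),
        ):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} input not found: {p}")
        raw = read_expression_matrix(
            config.expression,
            row_kind="probe" if config.probe_map else "gene",
            col_kind="sample" if config.sample_map else "roi",
        )
        sample_map = _read_two_column_map(config.sample_map) if config.sample_map else None
        probe_map = _read_two_column_map(config.probe_map) if config.probe_map else None

    with _stage("module_construction"):
        if sample_map or probe_map:
            expression = preprocess_expression(raw, sample_map, probe_map)
        else:
            expression = preprocess_expression(raw)

    with _stage("gene_scoring"):
        if config.gene_scores:
            gene_qt = read_gene_qt_matrix(config.gene_scores)
        else:
            if not (config.snps and config.genes):
                raise ValueError("need either gene_scores or both snps and genes inputs")
            snps = read_snp_associations(config.snps, dialect=config.snp_dialect)
            genes = read_gene_annotation(config.genes, format=config.gene_format)
            gene_qt = map_snps_to_genes(snps, genes, window_bp=config.params.window_bp)
        write_gene_qt_matrix(gene_qt, out / "gene_qt.tsv")

    result = run_pipeline(expression, gene_qt, config.params)
    write_module_tables(result, out)
    write_enrichment_tables(result, out)
    report = dict(result["report"])
    report["config"] = config.to_dict()
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return result


def _read_two_column_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (from, to)")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
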