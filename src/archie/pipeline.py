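"""End-to-end analysis pipeline: summary statistics in, significant components out.

The pipeline mirrors the standard workflow: load the trans-eQTL summary
table, apply the trans-distance and expressed-gene filters, whiten with
reference LD and co-expression estimates, extract sparse components, and test
them against the competitive null built from variants of other traits.  Every
stochastic step draws from a named seed so a run is reconstructible from its
logged configuration alone.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .reference_correlation import (
    estimate_coexpression,
    estimate_ld,
    build_w,
    read_dosage_tsv,
    read_expression_tsv,
)
from .scca_core import SparsityConfig, fit_components
from .significance import (
    check_resamples,
    competitive_null_ensemble,
    component_pvalues,
    select_significant,
)
from .summary_io import filter_trans, intersect_expressed, load_summary

logger = logging.getLogger("archie")

__all__ = ["RunConfig", "run_pipeline"]


class SeedMap(BaseModel):
    model_config = ConfigDict(extra="forbid")
    analysis: int = 0
    null: int = 1


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are fatal."""

    model_config = ConfigDict(extra="forbid")

    summary: Path
    variant_meta: Path
    gene_meta: Path
    genotype_reference: Path
    expression_reference: Path
    phenotype: Path | None = None
    trait: str = ""
    expressed_genes: Path | None = None
    n_study: int = 0
    c_u: float | None = None  # None = automatic budget
    c_v: float | None = None
    K: int = 2
    M: int = 200
    B: int = 1000
    alpha: float = 0.05
    window_bp: int = 5_000_000
    ld_shrinkage: float = 0.0
    coexpr_shrinkage: float = 0.1
    eigen_floor: float = Field(default=1e-6, gt=0)
    z_map: str = "t_to_r"
    seeds: SeedMap = SeedMap()
    output_dir: Path = Path("archie_run")

    def validate_paths(self) -> None:
        for name in ("summary", "variant_meta", "gene_meta", "genotype_reference", "expression_reference"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")


def _write_components(path: Path, comps, variant_ids, gene_ids) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("component\telement_type\tid\tloading\n")
        for k, comp in enumerate(comps, start=1):
            for i in comp.selected_variants:
                fh.write(f"{k}\tvariant\t{variant_ids[i]}\t{comp.u[i]:.10g}\n")
            for j in comp.selected_genes:
                fh.write(f"{k}\tgene\t{gene_ids[j]}\t{comp.v[j]:.10g}\n")


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute the full analysis; returns the report dict written to disk.

    Writes ``components.tsv``, ``report.json``, ``null_q2.tsv`` and
    ``run.log`` under ``config.output_dir``; partial outputs are removed if a
    stage fails.
    """
    if isinstance(config, dict):
        config = RunConfig(**config)
    config.validate_paths()
    check_resamples(config.M, config.alpha)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    stages: dict[str, float] = {}

    def stage(name: str) -> None:
        stages[name] = round(time.time() - t0, 3)
        logger.info("stage %s done at %.3fs", name, stages[name])

    try:
        logger.info("config: %s", config.model_dump_json())
        summary = load_summary(
            config.summary, config.variant_meta, config.gene_meta, n_study=config.n_study
        )
        summary = filter_trans(summary, window_bp=config.window_bp)
        if config.expressed_genes is not None:
            expressed = {
                line.strip()
                for line in Path(config.expressed_genes).read_text().splitlines()
                if line.strip()
            }
            summary = intersect_expressed(summary, expressed)
        stage("load_filter")

        labels = summary.variants["trait_label"].to_numpy()
        trait = config.trait or labels[0]
        obs_rows = np.flatnonzero(labels == trait)
        if obs_rows.size == 0:
            raise ValueError(f"no variants labeled with trait {trait!r}")
        observed = summary.take_variants(obs_rows)

        dosages, dosage_ids = read_dosage_tsv(config.genotype_reference)
        expr, expr_gene_ids = read_expression_tsv(config.expression_reference)
        dpos = {v: i for i, v in enumerate(dosage_ids)}
        epos = {g: j for j, g in enumerate(expr_gene_ids)}
        missing_v = [v for v in observed.variant_ids if v not in dpos]
        if missing_v:
            raise ValueError(f"variants missing from genotype reference: {missing_v[:5]}")
        missing_g = [g for g in summary.gene_ids if g not in epos]
        if missing_g:
            raise ValueError(f"genes missing from expression reference: {missing_g[:5]}")

        ld = estimate_ld(
            dosages[:, [dpos[v] for v in observed.variant_ids]],
            config.ld_shrinkage,
            ids=observed.variant_ids,
            eigen_floor=config.eigen_floor,
        )
        coexpr = estimate_coexpression(
            expr[:, [epos[g] for g in observed.gene_ids]],
            config.coexpr_shrinkage,
            ids=observed.gene_ids,
            eigen_floor=config.eigen_floor,
        )
        W = build_w(observed, ld, coexpr, z_map=config.z_map)
        stage("build_w")

        cfg = SparsityConfig(c_u=config.c_u, c_v=config.c_v)
        comps = fit_components(W, config.K, cfg, seed=config.seeds.analysis)
        stage("fit")

        p_obs, g_obs = observed.shape
        nulls = competitive_null_ensemble(
            summary,
            p=p_obs,
            g=g_obs,
            M=config.M,
            K=len(comps),
            cfg=cfg,
            exclude_traits={trait},
            expression_ref=expr[:, [epos[g] for g in summary.gene_ids]],
            dosage_ref=dosages[:, [dpos[v] for v in summary.variant_ids if v in dpos]]
            if all(v in dpos for v in summary.variant_ids)
            else None,
            coexpr_shrinkage=config.coexpr_shrinkage,
            ld_shrinkage=config.ld_shrinkage,
            z_map=config.z_map,
            seed=config.seeds.null,
        )
        result = component_pvalues(comps.q2, nulls)
        L = select_significant(result, config.alpha)
        stage("significance")

        comp_path = out / "components.tsv"
        _write_components(comp_path, comps, observed.variant_ids, observed.gene_ids)
        written.append(comp_path)
        null_path = out / "null_q2.tsv"
        np.savetxt(null_path, nulls.null_q2, delimiter="\t", fmt="%.10g")
        written.append(null_path)

        report = {
            "trait": str(trait),
            "n_variants": int(p_obs),
            "n_genes": int(g_obs),
            "q2": [float(q) for q in comps.q2],
            "p_values": [float(p) for p in result.p_values],
            "p_values_readable": result.describe(),
            "alpha": config.alpha,
            "L": int(L),
            "M": config.M,
            "seeds": config.seeds.model_dump(),
            "provenance": {k: str(v) for k, v in W.provenance.items()},
            "config": json.loads(config.model_dump_json()),
            "stage_seconds": stages,
        }
        report_path = out / "report.json"
        report_path.write_text(json.dumps(report, indent=2))
        written.append(report_path)
        logger.info("done: L=%d of K=%d components significant", L, len(comps))
        return report
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
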