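"""Synthetic end-to-end fixture bundle.

``make_fixtures`` emits a small but complete set of inputs emulating a real
analysis: a 100-variant x 500-gene trans-eQTL summary table in which the 20
variants of one trait share a planted rank-one association with 30 target
genes (a second 20-variant trait carries pure noise, and 60 background
variants span 60 distinct traits for competitive-null draws), reference
dosage and expression panels, a cohort whose phenotype is generated through
the planted trans-architecture, and the frozen network presets.  Everything
is written as plain TSV/JSON so the bundle round-trips through the loaders.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .netsim import PRESETS, build_network
from .summary_io import SummaryMatrix, write_summary
from .ties import compute_ties

__all__ = ["make_fixtures", "FIXTURE_SHAPE"]

FIXTURE_SHAPE = (100, 500)  # variants x genes
N_TRAIT = 20          # variants labeled with the signal trait
N_SIGNAL_VARIANTS = 8  # subset of trait variants actually driving the module
N_NULL_TRAIT = 20      # pure-noise trait ("trait_null")
N_TARGET_GENES = 30
SIGNAL_SCALE = 8.0  # per-entry Z inflation along the planted rank-one pattern
N_REF = 200
N_COHORT = 800
N_STUDY = 5000


def _planted_summary(rng: np.random.Generator) -> tuple[SummaryMatrix, np.ndarray, np.ndarray]:
    p, g = FIXTURE_SHAPE
    Z = rng.standard_normal((p, g))
    u = np.abs(rng.normal(1.0, 0.2, size=N_SIGNAL_VARIANTS))
    w = np.abs(rng.normal(1.0, 0.2, size=N_TARGET_GENES))
    u /= np.abs(u).mean()
    w /= np.abs(w).mean()
    Z[:N_SIGNAL_VARIANTS, :N_TARGET_GENES] += SIGNAL_SCALE * np.outer(u, w)

    traits = (
        ["trait_signal"] * N_TRAIT
        + ["trait_null"] * N_NULL_TRAIT
        + [f"trait_bg{i:02d}" for i in range(p - N_TRAIT - N_NULL_TRAIT)]
    )
    mafs = rng.uniform(0.1, 0.4, size=p)
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{i:05d}" for i in range(p)],
            "chromosome": "1",
            "position": (np.arange(p) + 1) * 100_000,
            "maf": mafs,
            "trait_label": traits,
        }
    )
    genes = pd.DataFrame(
        {
            "gene_id": [f"ENSG{j:05d}" for j in range(g)],
            "chromosome": [str(2 + (j % 21)) for j in range(g)],
            "tss": (np.arange(g) + 1) * 50_000,
        }
    )
    summary = SummaryMatrix(Z=Z, variants=variants, genes=genes, n_study=N_STUDY)
    return summary, u, w


def make_fixtures(seed: int, out) -> dict[str, Path]:
    """Write the fixture bundle under ``out``; returns the emitted paths."""
    out = Path(out)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out}: {exc}") from exc
    if not out.is_dir():
        raise OSError(f"fixture path {out} is not a writable directory")
    rng = np.random.default_rng(seed)
    summary, _, _ = _planted_summary(rng)
    p, g = summary.shape
    paths: dict[str, Path] = {}

    paths["summary"] = out / "summary.tsv"
    write_summary(summary, paths["summary"])
    paths["variant_meta"] = out / "variants.tsv"
    summary.variants.to_csv(paths["variant_meta"], sep="\t", index=False)
    paths["gene_meta"] = out / "genes.tsv"
    summary.genes.to_csv(paths["gene_meta"], sep="\t", index=False)

    mafs = summary.variants["maf"].to_numpy()
    ref_dos = rng.binomial(2, mafs, size=(N_REF, p)).astype(float)
    pd.DataFrame(ref_dos, columns=summary.variant_ids).rename_axis("sample").to_csv(
        out / "dosages_ref.tsv", sep="\t"
    )
    paths["genotype_reference"] = out / "dosages_ref.tsv"

    ref_expr = rng.standard_normal((N_REF, g))
    pd.DataFrame(
        ref_expr.T, index=pd.Index(summary.gene_ids, name="gene_id"),
        columns=[f"s{i}" for i in range(N_REF)],
    ).to_csv(out / "expression_ref.tsv", sep="\t")
    paths["expression_reference"] = out / "expression_ref.tsv"

    # independent cohort with a phenotype mediated by the planted targets
    cohort_dos = rng.binomial(2, mafs, size=(N_COHORT, p)).astype(float)
    target_Z = summary.Z[:, :N_TARGET_GENES]
    ties = compute_ties(target_Z, cohort_dos, mafs).scores
    burden = ties[:, :N_TARGET_GENES].mean(axis=1)
    burden = (burden - burden.mean()) / burden.std()
    y = np.sqrt(0.2) * burden + np.sqrt(0.8) * rng.standard_normal(N_COHORT)
    pd.DataFrame(cohort_dos, columns=summary.variant_ids).rename_axis("sample").to_csv(
        out / "cohort_dosages.tsv", sep="\t"
    )
    paths["cohort_dosages"] = out / "cohort_dosages.tsv"
    pd.DataFrame({"sample": np.arange(N_COHORT), "value": y}).to_csv(
        out / "phenotype.tsv", sep="\t", index=False
    )
    paths["phenotype"] = out / "phenotype.tsv"

    nets = {}
    for preset in PRESETS:
        n_snps = 10 if preset == "global_null" else 40
        net = build_network(preset, seed=seed, n_snps=n_snps)
        nets[preset] = {
            "preset": preset,
            "n_snps": net.n_snps,
            "cis_genes": net.cis_genes,
            "downstream_genes": net.downstream_genes,
            "edges": net.edges,
            "cis_blocks": {k: v.tolist() for k, v in net.cis_blocks.items()},
        }
    paths["networks"] = out / "networks.json"
    paths["networks"].write_text(json.dumps(nets, indent=2))
    return paths
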