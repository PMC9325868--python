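"""Causal-network simulation engine and evaluation harness.

Cohorts are generated from a linear structural equation model: independent
SNPs (blocks of five per local *cis* gene) drive cis-gene expression, and a
weighted acyclic gene-gene network propagates those effects to nine
downstream genes.  Effect sizes are calibrated analytically so that the
average cis heritability sits in 20-22% and the average SNP-explained
(trans) heritability of the downstream genes in 10-14%; every gene has unit
total variance.  A global-null preset severs all SNP-gene paths: downstream
genes 1-4 are exogenous standard Gaussians and genes 5-9 draw 20-30% of
their variance from those upstream genes, giving realistic inter-gene
correlation with exactly zero SNP association.

On top of the generator sit the evaluation harnesses: per-pair trans-eQTL
mapping, familywise type-I error under the global null for both the pairwise
mapping and the aggregative sparse-CCA test, matched-calibration power by
network layer, and gene-selection sensitivity/specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._utils import as_rng, spawn_seeds
from .reference_correlation import CorrelationMatrix, build_w, estimate_coexpression
from .scca_core import SparsityConfig, batched_component_q2, fit_component, fit_components
from .significance import check_resamples
from .summary_io import SummaryMatrix

__all__ = [
    "CausalNetworkSpec",
    "SimulatedCohort",
    "MetricsReport",
    "PRESETS",
    "simulate_genotypes",
    "build_network",
    "calibrate_effects",
    "simulate_expression",
    "simulate_cohort",
    "map_trans_eqtl",
    "estimate_type1",
    "estimate_power",
    "selection_metrics",
]

#: frozen preset adjacencies. Downstream genes are "g1".."g9"; cis mediators
#: "c1".."c8". sparse: each downstream gene has at most 2 parents; dense: at
#: least 4; master_regulator: one hub mediates everything; global_null: no cis
#: genes at all, g5-g9 driven only by the exogenous g1-g4.
PRESETS: dict[str, dict[str, list[str]]] = {
    "global_null": {
        "g5": ["g1", "g2"],
        "g6": ["g2", "g3"],
        "g7": ["g3", "g4"],
        "g8": ["g1", "g4"],
        "g9": ["g2", "g4"],
    },
    "sparse": {
        "g1": ["c1"],
        "g2": ["c2"],
        "g3": ["c3", "c4"],
        "g4": ["c5"],
        "g5": ["c6", "c7"],
        "g6": ["c8", "g1"],
        "g7": ["g2"],
        "g8": ["g3", "c2"],
        "g9": ["g5"],
    },
    # dense: every downstream gene has four cis-mediator parents (rotating so
    # all mediators are used); genes 6-9 are additionally driven by an earlier
    # downstream gene, giving the network a second regulatory layer
    "dense": {
        **{f"g{i}": [f"c{1 + (i - 1 + k) % 8}" for k in range(4)] for i in range(1, 6)},
        **{f"g{i}": [f"g{i - 5}"] + [f"c{1 + (i - 1 + k) % 8}" for k in range(4)] for i in range(6, 10)},
    },
    "master_regulator": {
        "g1": ["c1", "c2", "c3", "c4", "c5", "c6", "c7", "c8"],
        **{f"g{i}": ["g1"] for i in range(2, 10)},
    },
}

CIS_H2_RANGE = (0.20, 0.22)
TRANS_H2_RANGE = (0.10, 0.14)
UPSTREAM_SHARE_RANGE = (0.20, 0.30)
SNPS_PER_CIS = 5


@dataclass
class CausalNetworkSpec:
    """SNP -> cis gene -> downstream gene linear SEM with calibration targets."""

    preset: str
    n_snps: int
    cis_genes: list[str]
    downstream_genes: list[str]
    cis_blocks: dict[str, np.ndarray]          # cis gene -> SNP indices (5 each)
    cis_effects: dict[str, np.ndarray]         # cis gene -> raw/calibrated effects
    edges: dict[str, dict[str, float]]         # child -> {parent: weight}
    cis_h2_targets: dict[str, float]
    upstream_share_targets: dict[str, float]   # global_null per-gene targets
    trans_h2_target: float = 0.12              # midpoint of TRANS_H2_RANGE
    noise_sd: dict[str, float] | None = None
    calibrated: bool = False
    seed: int = 0

    @property
    def genes(self) -> list[str]:
        return self.cis_genes + self.downstream_genes

    def graph(self) -> nx.DiGraph:
        dag = nx.DiGraph()
        dag.add_nodes_from(self.genes)
        for child, parents in self.edges.items():
            for parent, w in parents.items():
                dag.add_edge(parent, child, weight=w)
        return dag

    def topological_genes(self) -> list[str]:
        dag = self.graph()
        if not nx.is_directed_acyclic_graph(dag):
            raise ValueError("gene network contains a cycle")
        order = list(nx.topological_sort(dag))
        return sorted(self.genes, key=order.index)

    def total_snp_effects(self) -> dict[str, np.ndarray]:
        """Total (path-summed) effect of each standardized SNP on each gene."""
        totals: dict[str, np.ndarray] = {}
        for gene in self.topological_genes():
            t = np.zeros(self.n_snps)
            if gene in self.cis_effects:
                t[self.cis_blocks[gene]] += self.cis_effects[gene]
            for parent, w in self.edges.get(gene, {}).items():
                t += w * totals[parent]
            totals[gene] = t
        return totals

    def analytic_h2(self) -> tuple[dict[str, float], dict[str, float]]:
        """(cis gene -> cis h2, downstream gene -> SNP-explained trans h2).

        With standardized independent SNPs and unit-variance genes, each
        gene's SNP-explained variance is the squared L2 norm of its total
        path-effect vector.
        """
        totals = self.total_snp_effects()
        cis = {gene: float(totals[gene] @ totals[gene]) for gene in self.cis_genes}
        trans = {gene: float(totals[gene] @ totals[gene]) for gene in self.downstream_genes}
        return cis, trans


def build_network(preset: str, seed: int = 0, n_snps: int = 40) -> CausalNetworkSpec:
    """Instantiate a preset topology with seed-drawn raw weights and targets.

    Edge existence is fixed per preset; edge weights, cis effect directions
    and the per-gene heritability targets are drawn from the seed.  The
    returned network is uncalibrated: run :func:`calibrate_effects` before
    simulating expression.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    rng = np.random.default_rng(seed)
    adjacency = PRESETS[preset]
    downstream = [f"g{i}" for i in range(1, 10)]
    if preset == "global_null":
        cis_genes: list[str] = []
        cis_blocks: dict[str, np.ndarray] = {}
        cis_effects: dict[str, np.ndarray] = {}
    else:
        n_cis = 8
        if n_snps < n_cis * SNPS_PER_CIS:
            raise ValueError(f"preset {preset!r} needs at least {n_cis * SNPS_PER_CIS} SNPs")
        cis_genes = [f"c{i}" for i in range(1, n_cis + 1)]
        cis_blocks = {
            gene: np.arange(i * SNPS_PER_CIS, (i + 1) * SNPS_PER_CIS)
            for i, gene in enumerate(cis_genes)
        }
        cis_effects = {gene: rng.standard_normal(SNPS_PER_CIS) for gene in cis_genes}
    # each gene reads one dominant regulator (the first listed parent) plus
    # weaker secondary edges, so modules stay distinct while edges are many
    edges = {
        child: {
            parent: float(rng.choice([-1.0, 1.0]) * (1.0 if k == 0 else rng.uniform(0.2, 0.35)))
            for k, parent in enumerate(parents)
        }
        for child, parents in adjacency.items()
    }
    cis_h2_targets = {gene: float(rng.uniform(*CIS_H2_RANGE)) for gene in cis_genes}
    upstream_targets = {
        child: float(rng.uniform(*UPSTREAM_SHARE_RANGE)) for child in adjacency
    }
    net = CausalNetworkSpec(
        preset=preset,
        n_snps=n_snps,
        cis_genes=cis_genes,
        downstream_genes=downstream,
        cis_blocks=cis_blocks,
        cis_effects=cis_effects,
        edges=edges,
        cis_h2_targets=cis_h2_targets,
        upstream_share_targets=upstream_targets,
        seed=seed,
    )
    if not nx.is_directed_acyclic_graph(net.graph()):
        raise ValueError(f"preset {preset!r} adjacency is not acyclic")
    return net


def _systematic_variances(net: CausalNetworkSpec, noise_sd: dict[str, float]) -> dict[str, float]:
    """Pre-noise variance of each gene, by propagating SNP and noise loadings."""
    order = net.topological_genes()
    idx = {gene: i for i, gene in enumerate(order)}
    totals: dict[str, np.ndarray] = {}
    noise_load: dict[str, np.ndarray] = {}
    out: dict[str, float] = {}
    for gene in order:
        t = np.zeros(net.n_snps)
        nl = np.zeros(len(order))
        if gene in net.cis_effects:
            t[net.cis_blocks[gene]] += net.cis_effects[gene]
        for parent, w in net.edges.get(gene, {}).items():
            t += w * totals[parent]
            nl += w * noise_load[parent]
        out[gene] = float(t @ t + nl @ nl)
        nl[idx[gene]] = noise_sd.get(gene, 0.0)
        totals[gene] = t
        noise_load[gene] = nl
    return out


def calibrate_effects(net: CausalNetworkSpec) -> CausalNetworkSpec:
    """Rescale effects analytically to meet the heritability targets.

    For the mediated presets, each cis effect vector is scaled so the gene's
    cis h2 equals its drawn target in 20-22%, then a single multiplier on all
    gene-gene weights is solved for (scalar root find on the closed-form path
    variance) so the average downstream trans h2 equals the 12% midpoint of
    the 10-14% band.  For the global null, each downstream gene's incoming
    weights are scaled so its upstream-explained variance share matches the
    drawn 20-30% target, and the SNP -> gene total effect is exactly zero by
    construction.  Finally residual standard deviations are set so every gene
    has unit total variance; an infeasible gene (systematic variance >= 1)
    raises an error naming it.
    """
    dag = net.graph()
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("gene network contains a cycle")
    net = replace(
        net,
        cis_effects={k: v.copy() for k, v in net.cis_effects.items()},
        edges={c: dict(ps) for c, ps in net.edges.items()},
    )

    for gene, b in net.cis_effects.items():
        norm = np.linalg.norm(b)
        if norm == 0:
            raise ValueError(f"cis gene {gene!r} has an all-zero effect vector")
        net.cis_effects[gene] = b * np.sqrt(net.cis_h2_targets[gene]) / norm

    if net.preset == "global_null":
        # per-gene exact scaling of incoming weights to the upstream-share target
        order = net.topological_genes()
        noise_sd: dict[str, float] = {}
        for gene in order:
            parents = net.edges.get(gene, {})
            if parents:
                share = _systematic_variances(net, noise_sd)[gene]
                if share <= 0:
                    raise ValueError(f"gene {gene!r} has zero upstream variance")
                scale = np.sqrt(net.upstream_share_targets[gene] / share)
                net.edges[gene] = {p: w * scale for p, w in parents.items()}
            sys_var = _systematic_variances(net, noise_sd)[gene]
            if sys_var >= 1.0 - 1e-9:
                raise ValueError(f"gene {gene!r} infeasible: systematic variance {sys_var:.3f} >= 1")
            noise_sd[gene] = float(np.sqrt(1.0 - sys_var))
    else:
        # unit-L2 incoming weight vectors: the seed sets directions, a single
        # global multiplier (solved below) sets the mediation strength
        base_edges = {}
        for child, ps in net.edges.items():
            norm = np.linalg.norm(list(ps.values()))
            if norm == 0:
                raise ValueError(f"gene {child!r} has an all-zero incoming weight vector")
            base_edges[child] = {p: w / norm for p, w in ps.items()}

        def avg_trans_h2(kappa: float) -> float:
            net.edges = {c: {p: w * kappa for p, w in ps.items()} for c, ps in base_edges.items()}
            _, trans = net.analytic_h2()
            return float(np.mean(list(trans.values())))

        target = net.trans_h2_target
        hi = 1.0
        while avg_trans_h2(hi) < target and hi < 64:
            hi *= 2.0
        if avg_trans_h2(hi) < target:
            raise ValueError("trans heritability target infeasible for this topology")
        kappa = optimize.brentq(lambda k: avg_trans_h2(k) - target, 0.0, hi, xtol=1e-12)
        net.edges = {c: {p: w * kappa for p, w in ps.items()} for c, ps in base_edges.items()}

        noise_sd = {}
        for gene in net.topological_genes():
            sys_var = _systematic_variances(net, noise_sd)[gene]
            if sys_var >= 1.0 - 1e-9:
                raise ValueError(f"gene {gene!r} infeasible: systematic variance {sys_var:.3f} >= 1")
            noise_sd[gene] = float(np.sqrt(1.0 - sys_var))

    return replace(net, noise_sd=noise_sd, calibrated=True)


def simulate_genotypes(
    n: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.10, 0.40),
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Independent biallelic dosages: per-SNP MAF uniform on the range, Binomial(2, maf)."""
    low, high = maf_range
    if not 0.0 < low <= high <= 0.5:
        raise ValueError(f"invalid MAF range ({low}, {high})")
    rng = as_rng(seed)
    mafs = rng.uniform(low, high, size=n_snps)
    dosages = rng.binomial(2, mafs, size=(n, n_snps)).astype(float)
    return dosages, mafs


def simulate_expression(
    net: CausalNetworkSpec,
    dosages: np.ndarray,
    mafs: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Generate expression for all genes of a calibrated network.

    Genes are evaluated in topological order as weight-summed parents plus
    cis effects on standardized dosages ``(x - 2m) / sqrt(2m(1 - m))`` plus
    Gaussian noise.  Returns an n x genes frame (columns in cis-then-
    downstream order).
    """
    if not net.calibrated or net.noise_sd is None:
        raise ValueError("network must be calibrated before simulating expression")
    dosages = np.asarray(dosages, dtype=float)
    if dosages.shape[1] != net.n_snps:
        raise ValueError(f"dosage matrix has {dosages.shape[1]} SNPs, network expects {net.n_snps}")
    rng = as_rng(seed)
    mafs = np.asarray(mafs, dtype=float)
    x = (dosages - 2.0 * mafs) / np.sqrt(2.0 * mafs * (1.0 - mafs))
    n = dosages.shape[0]
    values: dict[str, np.ndarray] = {}
    for gene in net.topological_genes():
        y = np.zeros(n)
        if gene in net.cis_effects:
            y += x[:, net.cis_blocks[gene]] @ net.cis_effects[gene]
        for parent, w in net.edges.get(gene, {}).items():
            y += w * values[parent]
        sd = net.noise_sd[gene]
        if sd > 0:
            y = y + sd * rng.standard_normal(n)
        values[gene] = y
    return pd.DataFrame({gene: values[gene] for gene in net.genes})


@dataclass
class SimulatedCohort:
    """One simulated cohort: dosages, MAFs, and full expression."""

    dosages: np.ndarray
    mafs: np.ndarray
    expression: pd.DataFrame
    net: CausalNetworkSpec
    n: int

    @property
    def downstream_expression(self) -> np.ndarray:
        return self.expression[self.net.downstream_genes].to_numpy()


def simulate_cohort(
    net: CausalNetworkSpec,
    n: int,
    seed: int = 0,
    maf_range: tuple[float, float] = (0.10, 0.40),
) -> SimulatedCohort:
    rng = np.random.default_rng(seed)
    dosages, mafs = simulate_genotypes(n, net.n_snps, maf_range, seed=rng)
    expr = simulate_expression(net, dosages, mafs, seed=rng)
    return SimulatedCohort(dosages=dosages, mafs=mafs, expression=expr, net=net, n=n)


def _pairwise_z(dosages: np.ndarray, expression: np.ndarray, use_t: bool = False):
    """Z (and p) of simple regression of each expression column on each dosage column."""
    n = dosages.shape[0]
    if n < 3:
        raise ValueError("need at least 3 individuals for per-pair regression")
    xs = dosages.std(axis=0)
    ys = expression.std(axis=0)
    if np.any(xs == 0):
        raise ValueError(f"constant dosage column at index {int(np.argmax(xs == 0))}")
    if np.any(ys == 0):
        raise ValueError(f"constant expression column at index {int(np.argmax(ys == 0))}")
    xc = (dosages - dosages.mean(axis=0)) / xs
    yc = (expression - expression.mean(axis=0)) / ys
    r = xc.T @ yc / n
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    z = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    if use_t:
        p = 2.0 * stats.t.sf(np.abs(z), df=n - 2)
    else:
        p = 2.0 * stats.norm.sf(np.abs(z))
    return z, p


def map_trans_eqtl(
    dosages: np.ndarray,
    expression: np.ndarray | pd.DataFrame,
    gene_subset: list | None = None,
    mafs: np.ndarray | None = None,
    variant_ids: list[str] | None = None,
    use_t: bool = False,
) -> SummaryMatrix:
    """Standard per-pair trans-eQTL mapping on a simulated cohort.

    Each (variant, gene) pair is a simple linear regression of expression on
    dosage; ``Z = slope / SE`` with two-sided normal p-values (Student-t via
    ``use_t``).  The result carries synthetic annotation: variants on "chr1",
    genes on "chr2", so every pair is trans by construction.
    """
    if isinstance(expression, pd.DataFrame):
        if gene_subset is not None:
            expression = expression[list(gene_subset)]
        gene_ids = [str(c) for c in expression.columns]
        expr = expression.to_numpy(float)
    else:
        expr = np.asarray(expression, dtype=float)
        if gene_subset is not None:
            expr = expr[:, list(gene_subset)]
            gene_ids = [f"gene{j}" for j in gene_subset]
        else:
            gene_ids = [f"gene{j}" for j in range(expr.shape[1])]
    dosages = np.asarray(dosages, dtype=float)
    n, p = dosages.shape
    z, pv = _pairwise_z(dosages, expr, use_t=use_t)
    if variant_ids is None:
        variant_ids = [f"snp{i}" for i in range(p)]
    if mafs is None:
        mafs = np.clip(dosages.mean(axis=0) / 2.0, 1e-6, 0.5)
    mafs = np.minimum(np.asarray(mafs, dtype=float), 0.5)
    variants = pd.DataFrame(
        {
            "variant_id": variant_ids,
            "chromosome": "chr1",
            "position": (np.arange(p) + 1) * 1_000_000,
            "maf": mafs,
            "trait_label": "simulated",
        }
    )
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chromosome": "chr2",
            "tss": (np.arange(len(gene_ids)) + 1) * 1_000_000,
        }
    )
    return SummaryMatrix(Z=z, P=pv, variants=variants, genes=genes, n_study=n)


@dataclass
class MetricsReport:
    """Container for harness results; rates are proportions in [0, 1]."""

    reps: int
    alpha: float | dict | None = None
    type1: dict | None = None
    power_by_gene_set: pd.DataFrame | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    detections: dict = field(default_factory=dict)
    gene_sets: dict = field(default_factory=dict)


def _identity_corr(ids: list[str]) -> CorrelationMatrix:
    return CorrelationMatrix(np.eye(len(ids)), list(ids))


def _observed_w(cohort: SimulatedCohort, n_ref: int, coexpr_shrinkage: float, rng: np.random.Generator):
    """The whitened matrix of one simulated analysis.

    The LD matrix of independent simulated SNPs is diagonal, i.e. identity on
    the correlation scale; the co-expression matrix is re-estimated from a
    fresh reference sample of ``n_ref`` individuals.
    """
    net = cohort.net
    summary = map_trans_eqtl(
        cohort.dosages,
        cohort.expression,
        gene_subset=net.downstream_genes,
        mafs=cohort.mafs,
    )
    ref = simulate_cohort(net, n_ref, seed=int(rng.integers(2**31 - 1)))
    coexpr = estimate_coexpression(
        ref.downstream_expression, coexpr_shrinkage, ids=net.downstream_genes
    )
    ld = _identity_corr(summary.variant_ids)
    return build_w(summary, ld, coexpr), summary


def _shared_null_q2(
    g: int, p: int, M: int, K: int, cfg: SparsityConfig | None, seed: int
) -> np.ndarray:
    """Global-null cc-value ensemble after whitening.

    A null matrix drawn with vec-covariance ``Sigma_EE (x) Sigma_GG`` and then
    whitened by the same two matrices is exactly an iid standard normal
    matrix, whatever the estimates were; the ensemble therefore does not
    depend on the replicate's estimated co-expression and can be shared
    across replicates.
    """
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((M, g, p))
    return batched_component_q2(draws, K, cfg)


def estimate_type1(
    reps: int,
    alpha_grid,
    method: str = "pairwise",
    M: int = 1000,
    seed: int = 0,
    n: int = 1000,
    n_snps: int = 40,
    n_ref: int = 700,
    coexpr_shrinkage: float = 0.1,
    cfg: SparsityConfig | None = None,
) -> MetricsReport:
    """Familywise type-I error under the global-null network.

    ``pairwise``: proportion of replicates where any of the p x 9 per-pair
    p-values falls below each alpha.  ``archie``: proportion of replicates
    where at least one sparse component is significant against an M-draw
    global-null ensemble; under the sequential selection rule that event is
    "the leading component is significant", so only rank 1 is tested.
    """
    alpha_grid = np.atleast_1d(np.asarray(alpha_grid, dtype=float))
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if method not in ("pairwise", "archie"):
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    n_genes = 9
    hits = np.zeros(alpha_grid.size)

    if method == "archie":
        check_resamples(M, float(alpha_grid.min()))
        if cfg is None:
            cfg = SparsityConfig()
        null_q2 = _shared_null_q2(n_genes, n_snps, M, 1, cfg, seed=int(rng.integers(2**31 - 1)))[:, 0]

    for _ in range(reps):
        net = calibrate_effects(build_network("global_null", seed=int(rng.integers(2**31 - 1)), n_snps=n_snps))
        cohort = simulate_cohort(net, n, seed=int(rng.integers(2**31 - 1)))
        if method == "pairwise":
            summary = map_trans_eqtl(
                cohort.dosages, cohort.expression, gene_subset=net.downstream_genes, mafs=cohort.mafs
            )
            min_p = summary.P.min()
            hits += min_p < alpha_grid
        else:
            W, _ = _observed_w(cohort, n_ref, coexpr_shrinkage, rng)
            q2 = fit_component(W, cfg).q2
            p1 = float(np.mean(null_q2 >= q2))
            hits += p1 < alpha_grid
    rates = {float(a): float(h / reps) for a, h in zip(alpha_grid, hits)}
    return MetricsReport(reps=reps, alpha=rates if len(rates) > 1 else float(alpha_grid[0]), type1=rates)


def gene_layers(net: CausalNetworkSpec) -> dict[int, list[str]]:
    """Downstream genes grouped by depth: the longest mediation path from any cis gene."""
    dag = net.graph()
    depth: dict[str, int] = {}
    for gene in net.topological_genes():
        if gene in net.cis_genes:
            depth[gene] = 0
        else:
            parents = net.edges.get(gene, {})
            depth[gene] = 1 + max((depth[p] for p in parents), default=0)
    layers: dict[int, list[str]] = {}
    for gene in net.downstream_genes:
        layers.setdefault(depth[gene], []).append(gene)
    return layers


def estimate_power(
    preset: str,
    reps: int,
    n: int,
    alpha_archie: float = 9e-4,
    alpha_pairwise: float = 1e-6,
    seed: int = 0,
    n_snps: int = 40,
    n_ref: int = 700,
    K: int | None = None,
    M: int | None = None,
    coexpr_shrinkage: float = 0.1,
    cfg: SparsityConfig | None = None,
) -> MetricsReport:
    """Per-gene detection power by network layer, pairwise mapping vs sparse CCA.

    A gene is detected by pairwise mapping when any of its per-variant
    p-values falls below ``alpha_pairwise``, and by the aggregative test when
    it carries a non-zero loading in a significant gene component (components
    judged at ``alpha_archie`` against the shared global-null ensemble, cut by
    the sequential rule).
    """
    if preset not in ("sparse", "dense", "master_regulator"):
        raise ValueError(f"unknown power preset {preset!r}")
    if M is None:
        M = int(np.ceil(10.0 / alpha_archie))
    check_resamples(M, alpha_archie)
    rng = np.random.default_rng(seed)
    n_genes = 9
    if K is None:
        K = min(n_genes, n_snps)
    if cfg is None:
        cfg = SparsityConfig()
    null_q2 = _shared_null_q2(n_genes, n_snps, M, K, cfg, seed=int(rng.integers(2**31 - 1)))

    det_arch = np.zeros((reps, n_genes), dtype=bool)
    det_pair = np.zeros((reps, n_genes), dtype=bool)
    net0 = None
    for rep in range(reps):
        net = calibrate_effects(build_network(preset, seed=int(rng.integers(2**31 - 1)), n_snps=n_snps))
        net0 = net0 or net
        cohort = simulate_cohort(net, n, seed=int(rng.integers(2**31 - 1)))
        W, summary = _observed_w(cohort, n_ref, coexpr_shrinkage, rng)
        det_pair[rep] = (summary.P < alpha_pairwise).any(axis=0)

        comps = fit_components(W, K, cfg)
        obs_q2 = comps.q2
        p_vals = (null_q2[:, : obs_q2.size] >= obs_q2[None, :]).mean(axis=0)
        # any component below the level is significant and its genes are noted
        selected = set()
        for comp, p_k in zip(comps.components, p_vals):
            if p_k < alpha_archie:
                selected.update(comp.selected_genes.tolist())
        det_arch[rep, sorted(selected)] = True

    layers = gene_layers(net0)
    gene_index = {gene: j for j, gene in enumerate(net0.downstream_genes)}
    rows = []
    for depth, genes in sorted(layers.items()):
        cols = [gene_index[gene] for gene in genes]
        rows.append(
            {
                "gene_set": f"layer{depth}",
                "genes": ",".join(genes),
                "power_archie": float(det_arch[:, cols].mean()),
                "power_pairwise": float(det_pair[:, cols].mean()),
            }
        )
    table = pd.DataFrame(rows)
    return MetricsReport(
        reps=reps,
        alpha={"archie": alpha_archie, "pairwise": alpha_pairwise},
        power_by_gene_set=table,
        detections={"archie": det_arch, "pairwise": det_pair},
        gene_sets={f"layer{d}": genes for d, genes in sorted(layers.items())},
    )


def selection_metrics(selected_genes, truth, universe) -> tuple[float, float]:
    """(sensitivity, specificity) of a selected gene set against the truth."""
    selected, truth, universe = set(selected_genes), set(truth), set(universe)
    if not truth:
        raise ValueError("truth set must be non-empty")
    if not truth <= universe:
        raise ValueError("truth must be a subset of the universe")
    sens = len(selected & truth) / len(truth)
    negatives = universe - truth
    spec = len(negatives - selected) / len(negatives) if negatives else 1.0
    return sens, spec
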