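"""Resampling significance for sparse canonical components.

Trait-associated variants are enriched for trans-eQTLs in general, so the
relevant reference distribution for a trait-specific analysis is *competitive*:
matrices of trans-association statistics assembled from GWAS variants of other
traits (at most one variant per trait where possible) and random gene sets.
A *global* null with correlation structure but no variant-gene association is
also provided: a genes x variants Gaussian matrix whose row-stacked
vectorization has covariance ``Sigma_EE (x) Sigma_GG`` (Kronecker product).

Observed cc-values are converted to p-values by their exceedance proportion in
the null ensemble,

    p_k = (1/M) * #{ i : q2_k;null(i) >= q2_k },

and the number of significant leading components is the sequential cut
``L = min{k : p_k > alpha} - 1`` (L = K when no p-value exceeds alpha).  The
exceedance direction here is the reverse of one printed presentation of this
estimator (which counts nulls the observation exceeds and therefore is not a
p-value); the printed variant is available via ``printed_direction=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._utils import as_rng, spawn_seeds
from .reference_correlation import (
    CorrelationMatrix,
    estimate_coexpression,
    estimate_ld,
    inverse_sqrt,
    matrix_sqrt,
    z_to_correlation,
)
from .scca_core import SparsityConfig, batched_component_q2
from .summary_io import SummaryMatrix

__all__ = [
    "NullEnsemble",
    "SignificanceResult",
    "TraitMixture",
    "build_competitive_null",
    "competitive_null_ensemble",
    "sample_global_null",
    "global_null_ensemble",
    "component_pvalues",
    "select_significant",
    "trait_specificity_experiment",
    "check_resamples",
]


@dataclass
class NullEnsemble:
    """M resampled cc-values per component rank (columns ordered by rank)."""

    null_q2: np.ndarray  # (M, K)
    kind: str  # "competitive" | "global"
    seed: int = 0

    def __post_init__(self) -> None:
        self.null_q2 = np.atleast_2d(np.asarray(self.null_q2, dtype=float))
        if self.null_q2.shape[0] < 1:
            raise ValueError("need at least one resample")
        if ((self.null_q2 < 0) | (self.null_q2 > 1)).any():
            raise ValueError("null cc-values must lie in [0, 1]")
        if self.kind not in ("competitive", "global"):
            raise ValueError(f"unknown ensemble kind {self.kind!r}")

    @property
    def M(self) -> int:
        return self.null_q2.shape[0]

    @property
    def K(self) -> int:
        return self.null_q2.shape[1]


@dataclass
class SignificanceResult:
    p_values: np.ndarray
    alpha: float | None = None
    L: int | None = None
    M: int = 0

    def __post_init__(self) -> None:
        self.p_values = np.asarray(self.p_values, dtype=float)
        if ((self.p_values < 0) | (self.p_values > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")

    def describe(self) -> list[str]:
        """Human-readable p-values; exact zeros are reported as '< 1/M'."""
        out = []
        for p in self.p_values:
            out.append(f"< {1.0 / self.M:.3g}" if (p == 0 and self.M) else f"{p:.4g}")
        return out


@dataclass
class TraitMixture:
    """Composition of a resampled summary matrix: a fraction ``delta`` of the
    variants is trait-specific, the rest come from other traits."""

    delta: float
    n_variants: int
    n_genes: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if self.n_variants < 1 or self.n_genes < 1:
            raise ValueError("mixture dimensions must be positive")


def check_resamples(M: int, alpha: float) -> None:
    """Enforce the resolution rule M + 1 >= 10 / alpha for a decision at level alpha.

    The +1 counts the observed statistic alongside the M resamples, the usual
    permutation-test convention (e.g. M = 999 supports alpha = 0.01).
    """
    if M + 1 < 10.0 / alpha:
        raise ValueError(
            f"M={M} gives insufficient resolution for alpha={alpha}; need M >= {10.0 / alpha - 1:.0f}"
        )


def _sample_background_variants(
    pool: SummaryMatrix,
    p: int,
    exclude_traits,
    rng: np.random.Generator,
) -> np.ndarray:
    """Row indices of p pool variants, one per distinct non-excluded trait while possible."""
    labels = pool.variants["trait_label"].to_numpy()
    eligible = np.flatnonzero(~np.isin(labels, list(exclude_traits)))
    if eligible.size < p:
        raise ValueError(
            f"pool has only {eligible.size} variants outside excluded traits; need {p}"
        )
    by_trait: dict[object, list[int]] = {}
    for i in eligible:
        by_trait.setdefault(labels[i], []).append(int(i))
    traits = np.array(sorted(by_trait, key=str), dtype=object)
    if traits.size >= p:
        chosen_traits = rng.choice(traits, size=p, replace=False)
        rows = np.array([by_trait[t][rng.integers(len(by_trait[t]))] for t in chosen_traits])
    else:
        rows = np.array([by_trait[t][rng.integers(len(by_trait[t]))] for t in traits])
        rest = np.setdiff1d(eligible, rows)
        rows = np.concatenate([rows, rng.choice(rest, size=p - rows.size, replace=False)])
    return np.sort(rows)


def build_competitive_null(
    pool: SummaryMatrix,
    p: int,
    g: int,
    exclude_traits: set | frozenset = frozenset(),
    seed: int | np.random.Generator = 0,
) -> SummaryMatrix:
    """One competitive-null draw: p background variants x g random genes.

    Variants are sampled without replacement from the pool after removing the
    excluded traits, one per distinct trait while distinct traits remain
    (mirroring a draw of one variant from each of p randomly chosen other
    traits); genes are sampled uniformly without replacement.
    """
    rng = as_rng(seed)
    if pool.shape[1] < g:
        raise ValueError(f"pool has only {pool.shape[1]} genes; need {g}")
    rows = _sample_background_variants(pool, p, exclude_traits, rng)
    cols = rng.choice(pool.shape[1], size=g, replace=False)
    return pool.take_variants(rows).take_genes(np.sort(cols))


def sample_global_null(
    coexpr: CorrelationMatrix,
    ld: CorrelationMatrix,
    seed: int | np.random.Generator = 0,
    size: int | None = None,
) -> np.ndarray:
    """Draw g x p matrices with vec-covariance ``Sigma_EE (x) Sigma_GG``.

    Implemented as ``A @ Ztilde @ B.T`` with A, B the symmetric square roots of
    the co-expression and LD matrices and Ztilde iid standard normal.  Returns
    ``(g, p)`` for ``size=None``, else ``(size, g, p)``.
    """
    rng = as_rng(seed)
    A = matrix_sqrt(coexpr)
    B = matrix_sqrt(ld)
    g, p = coexpr.dim, ld.dim
    ztilde = rng.standard_normal((1 if size is None else size, g, p))
    draws = np.einsum("gh,bhq,qp->bgp", A, ztilde, B, optimize=True)
    return draws[0] if size is None else draws


def global_null_ensemble(
    coexpr: CorrelationMatrix,
    ld: CorrelationMatrix,
    M: int,
    K: int = 1,
    cfg: SparsityConfig | None = None,
    seed: int = 0,
) -> NullEnsemble:
    """cc-values of M global-null draws pushed through the whitening + sCCA path."""
    draws = sample_global_null(coexpr, ld, seed=seed, size=M)
    W = np.einsum("gh,bhq,qp->bgp", inverse_sqrt(coexpr), draws, inverse_sqrt(ld), optimize=True)
    q2 = batched_component_q2(W, K, cfg)
    return NullEnsemble(null_q2=q2, kind="global", seed=seed)


def competitive_null_ensemble(
    pool: SummaryMatrix,
    p: int,
    g: int,
    M: int,
    K: int = 1,
    cfg: SparsityConfig | None = None,
    exclude_traits: set | frozenset = frozenset(),
    expression_ref: np.ndarray | None = None,
    dosage_ref: np.ndarray | None = None,
    coexpr_shrinkage: float = 0.1,
    ld_shrinkage: float = 0.0,
    z_map: str = "t_to_r",
    seed: int = 0,
) -> NullEnsemble:
    """Competitive null ensemble: M draws, each re-analyzed like the original.

    ``expression_ref`` (samples x pool genes) and ``dosage_ref`` (samples x
    pool variants) supply per-draw reference submatrices for the co-expression
    and LD estimates; when omitted, identity correlation is used, which is the
    analysis of the raw Z submatrix.
    """
    gene_pos = {gid: j for j, gid in enumerate(pool.gene_ids)}
    var_pos = {vid: i for i, vid in enumerate(pool.variant_ids)}
    seeds = spawn_seeds(seed, M)
    stack = np.empty((M, g, p))
    coexpr_cache: dict[tuple, np.ndarray] = {}  # repeated gene sets (e.g. g = whole pool) share one eigh
    for m in range(M):
        draw = build_competitive_null(pool, p, g, exclude_traits, seed=seeds[m])
        sigma_ge = z_to_correlation(draw.Z, draw.n_study, method=z_map).T
        if expression_ref is not None:
            key = tuple(draw.gene_ids) if g == pool.shape[1] else None
            if key is None or key not in coexpr_cache:
                cols = [gene_pos[gid] for gid in draw.gene_ids]
                co = estimate_coexpression(expression_ref[:, cols], coexpr_shrinkage, ids=draw.gene_ids)
                einv = inverse_sqrt(co)
                if key is not None:
                    coexpr_cache[key] = einv
            else:
                einv = coexpr_cache[key]
            sigma_ge = einv @ sigma_ge
        if dosage_ref is not None:
            rows = [var_pos[vid] for vid in draw.variant_ids]
            ld = estimate_ld(dosage_ref[:, rows], ld_shrinkage, ids=draw.variant_ids)
            sigma_ge = sigma_ge @ inverse_sqrt(ld)
        stack[m] = sigma_ge
    q2 = batched_component_q2(stack, K, cfg)
    return NullEnsemble(null_q2=q2, kind="competitive", seed=seed)


def component_pvalues(
    observed_q2: np.ndarray,
    nulls: NullEnsemble,
    printed_direction: bool = False,
    add_one: bool = False,
) -> SignificanceResult:
    """Exceedance p-values of observed cc-values against a null ensemble.

    Default: ``p_k`` is the fraction of null draws at or above the observation.
    ``printed_direction`` instead counts the fraction of nulls the observation
    strictly exceeds. ``add_one`` applies the (1 + count) / (1 + M) correction.
    """
    obs = np.atleast_1d(np.asarray(observed_q2, dtype=float))
    K = obs.size
    if nulls.K < K:
        raise ValueError(f"ensemble has {nulls.K} ranks but {K} observed components")
    nq = nulls.null_q2[:, :K]
    if printed_direction:
        count = (obs[None, :] > nq).sum(axis=0)
    else:
        count = (nq >= obs[None, :]).sum(axis=0)
    if add_one:
        p = (1.0 + count) / (1.0 + nulls.M)
    else:
        p = count / nulls.M
    return SignificanceResult(p_values=p, M=nulls.M)


def select_significant(result: SignificanceResult, alpha: float) -> int:
    """Sequential selection ``L = min{k : p_k > alpha} - 1``; L = K if none exceed."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    above = np.flatnonzero(result.p_values > alpha)
    L = int(above[0]) if above.size else len(result.p_values)
    result.alpha = alpha
    result.L = L
    return L


def trait_specificity_experiment(
    trait_pool: SummaryMatrix,
    other_pool: SummaryMatrix,
    mix: TraitMixture,
    reps: int,
    M: int,
    alpha: float,
    seed: int = 0,
    cfg: SparsityConfig | None = None,
) -> float:
    """Fraction of replicates with >= 1 significant component at mixing level delta.

    Each replicate assembles a matrix of ``ceil(delta * p)`` trait variants
    plus background variants (one per other trait where possible) over a fresh
    random gene set, runs the sparse CCA and the competitive-null test on the
    raw Z scale, and checks whether the leading component is significant.
    Under the sequential selection rule, "at least one significant component"
    is exactly "the first component is significant".
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    check_resamples(M, alpha)
    p, g = mix.n_variants, mix.n_genes
    n_trait = int(np.ceil(mix.delta * p))
    if trait_pool.shape[0] < n_trait:
        raise ValueError("trait pool too small for requested delta")
    gene_pos = {gid: j for j, gid in enumerate(other_pool.gene_ids)}
    shared = [gid for gid in trait_pool.gene_ids if gid in gene_pos]
    if len(shared) < g:
        raise ValueError("pools share too few genes for the requested g")
    rng = as_rng(seed)
    hits = 0
    for rep in range(reps):
        rep_seed = int(rng.integers(2**31 - 1))
        rep_rng = np.random.default_rng(rep_seed)
        gene_subset = rep_rng.choice(len(shared), size=g, replace=False)
        gene_ids = [shared[j] for j in np.sort(gene_subset)]
        t_cols = [trait_pool.gene_ids.index(gid) for gid in gene_ids]
        o_cols = [gene_pos[gid] for gid in gene_ids]

        blocks = []
        if n_trait:
            t_rows = rep_rng.choice(trait_pool.shape[0], size=n_trait, replace=False)
            blocks.append(trait_pool.Z[np.ix_(np.sort(t_rows), t_cols)])
        if p - n_trait:
            bg_rows = _sample_background_variants(other_pool, p - n_trait, frozenset(), rep_rng)
            blocks.append(other_pool.Z[np.ix_(bg_rows, o_cols)])
        Z = np.vstack(blocks)

        obs_q2 = batched_component_q2(Z.T[None, :, :], 1, cfg)[0]
        nulls = competitive_null_ensemble(
            other_pool, p, g, M, K=1, cfg=cfg, z_map="identity", seed=rep_seed
        )
        res = component_pvalues(obs_q2, nulls)
        if select_significant(res, alpha) >= 1:
            hits += 1
    return hits / reps
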