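"""Trans-imputed expression scores (TIES) and heritability enrichment.

For an independent cohort with dosages ``x_ik`` at the p trait-related
variants, the trans-imputed expression score of target gene j for individual
k weights MAF-standardized dosages by the trans-eQTL Z scores::

    TIES_jk = sum_i Z_ij * x_ik / sqrt(2 * m_i * (1 - m_i))

The scores for G target genes enter a multiple regression on the phenotype
(identity link for quantitative traits, logistic for binary), and the model's
pseudo-r2 estimates the trait variance mediated by those genes' trans
associations.  Significance is assessed by resampling: either the G target
genes are replaced by random gene sets from a pool (competitive over genes)
or the phenotype is replaced by random traits, giving a null distribution of
pseudo-r2 values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from ._utils import as_rng

__all__ = [
    "TIESMatrix",
    "PhenotypeVector",
    "EnrichmentResult",
    "compute_ties",
    "fit_ties_regression",
    "enrichment_test",
]


@dataclass
class TIESMatrix:
    """n individuals x G target genes score matrix (linear in the dosages)."""

    scores: np.ndarray
    gene_ids: list[str]
    variant_ids: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape[1] != len(self.gene_ids):
            raise ValueError("scores width does not match gene_ids")
        if not np.isfinite(self.scores).all():
            raise ValueError("TIES scores contain non-finite values")


@dataclass
class PhenotypeVector:
    y: np.ndarray
    family: str = "gaussian"  # "gaussian" (identity link) | "binomial" (logistic)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "binomial" and not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("binomial phenotype must be coded 0/1")


@dataclass
class EnrichmentResult:
    observed_r2: float
    coefficients: np.ndarray
    null_r2: np.ndarray
    p_value: float
    mode: str
    seed: int

    def describe_p(self) -> str:
        B = self.null_r2.size
        return f"< {1.0 / B:.3g}" if self.p_value == 0 else f"{self.p_value:.4g}"


def compute_ties(
    Z: np.ndarray,
    dosages: np.ndarray,
    mafs: np.ndarray,
    gene_ids: list[str] | None = None,
    variant_ids: list[str] | None = None,
) -> TIESMatrix:
    """Evaluate the score sum exactly; missing dosages are mean-imputed to 2m."""
    Z = np.asarray(Z, dtype=float)
    dosages = np.asarray(dosages, dtype=float)
    mafs = np.asarray(mafs, dtype=float)
    p, G = Z.shape
    if dosages.shape[1] != p or mafs.shape != (p,):
        raise ValueError("Z, dosages and mafs dimensions disagree")
    if np.any((mafs <= 0) | (mafs >= 1)):
        raise ValueError("allele frequencies must lie strictly in (0, 1)")
    filled = np.where(np.isnan(dosages), 2.0 * mafs, dosages)
    scores = (filled / np.sqrt(2.0 * mafs * (1.0 - mafs))) @ Z
    return TIESMatrix(
        scores=scores,
        gene_ids=gene_ids or [f"gene{j}" for j in range(G)],
        variant_ids=variant_ids or [f"snp{i}" for i in range(p)],
    )


def _gaussian_r2(scores: np.ndarray, y: np.ndarray) -> float:
    """Fast OLS coefficient of determination (least-squares residual path)."""
    X = np.column_stack([np.ones(len(y)), scores])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        return 0.0
    return max(0.0, 1.0 - float(resid @ resid) / sst)


def fit_ties_regression(
    ties: TIESMatrix,
    phenotype: PhenotypeVector,
    pseudo_r2: str = "mcfadden",
) -> tuple[float, np.ndarray]:
    """Multi-score phenotype regression -> (pseudo_r2, coefficients).

    Gaussian family: ordinary least squares, r2 = coefficient of
    determination.  Binomial family: logistic maximum likelihood; pseudo-r2 is
    McFadden's ``1 - logL_full / logL_null`` by default or Nagelkerke via
    ``pseudo_r2="nagelkerke"``.
    """
    scores = ties.scores
    y = phenotype.y
    n, G = scores.shape
    if len(y) != n:
        raise ValueError("phenotype length does not match TIES rows")
    if n <= G + 1:
        raise ValueError(f"need n > G + 1 observations (n={n}, G={G})")
    if np.any(scores.std(axis=0) == 0):
        bad = ties.gene_ids[int(np.argmax(scores.std(axis=0) == 0))]
        raise ValueError(f"constant TIES column for gene {bad!r}")
    X = sm.add_constant(scores)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient TIES design (collinear score columns)")
    if phenotype.family == "gaussian":
        fit = sm.OLS(y, X).fit()
        return float(fit.rsquared), np.asarray(fit.params)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises several flavors on separation
        raise ValueError(f"logistic fit failed (possible separation): {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise ValueError("logistic fit did not converge")
    mcfadden = 1.0 - fit.llf / fit.llnull
    if pseudo_r2 == "mcfadden":
        r2 = mcfadden
    elif pseudo_r2 == "nagelkerke":
        cox = 1.0 - np.exp(2.0 * (fit.llnull - fit.llf) / n)
        r2 = cox / (1.0 - np.exp(2.0 * fit.llnull / n))
    else:
        raise ValueError(f"unknown pseudo_r2 rule {pseudo_r2!r}")
    return float(r2), np.asarray(fit.params)


def _null_r2(
    scores: np.ndarray, phenotype: PhenotypeVector, gene_ids: list[str], variant_ids: list[str]
) -> float:
    if phenotype.family == "gaussian":
        return _gaussian_r2(scores, phenotype.y)
    r2, _ = fit_ties_regression(TIESMatrix(scores, gene_ids, variant_ids), phenotype)
    return r2


def enrichment_test(
    target_Z: np.ndarray,
    pool_Z: np.ndarray,
    dosages: np.ndarray,
    mafs: np.ndarray,
    phenotype: PhenotypeVector,
    B: int = 1000,
    mode: str = "random_genes",
    seed: int = 0,
    phenotype_collection: np.ndarray | None = None,
    add_one: bool = False,
    pseudo_r2: str = "mcfadden",
) -> EnrichmentResult:
    """Resampling enrichment test of the target genes' mediated heritability.

    ``pool_Z`` is the p x G_pool matrix of candidate null genes (the caller
    excludes the targets).  ``random_genes`` draws G-gene subsets of the pool
    per replicate; ``random_trait`` keeps the target genes and redraws the
    phenotype column from ``phenotype_collection`` (n x n_traits).  The
    p-value is the plain exceedance proportion, with the add-one variant
    available.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if mode not in ("random_genes", "random_trait"):
        raise ValueError(f"unknown mode {mode!r}")
    target_Z = np.asarray(target_Z, dtype=float)
    pool_Z = np.asarray(pool_Z, dtype=float)
    G = target_Z.shape[1]
    if mode == "random_genes" and pool_Z.shape[1] < G:
        raise ValueError(f"pool has {pool_Z.shape[1]} genes; need at least {G}")
    if mode == "random_trait":
        if phenotype_collection is None or np.size(phenotype_collection) == 0:
            raise ValueError("random_trait mode needs a non-empty phenotype_collection")
        phenotype_collection = np.atleast_2d(np.asarray(phenotype_collection, dtype=float))
        if phenotype_collection.shape[0] != len(phenotype.y):
            phenotype_collection = phenotype_collection.T

    rng = as_rng(seed)
    obs_ties = compute_ties(target_Z, dosages, mafs)
    observed_r2, coefficients = fit_ties_regression(obs_ties, phenotype, pseudo_r2=pseudo_r2)

    null_r2 = np.empty(B)
    for b in range(B):
        if mode == "random_genes":
            cols = rng.choice(pool_Z.shape[1], size=G, replace=False)
            scores = compute_ties(pool_Z[:, cols], dosages, mafs).scores
            null_r2[b] = _null_r2(scores, phenotype, [f"pool{c}" for c in cols], obs_ties.variant_ids)
        else:
            col = rng.integers(phenotype_collection.shape[1])
            pheno_b = PhenotypeVector(phenotype_collection[:, col], family=phenotype.family)
            null_r2[b] = _null_r2(obs_ties.scores, pheno_b, obs_ties.gene_ids, obs_ties.variant_ids)

    count = int((null_r2 >= observed_r2).sum())
    p_value = (1.0 + count) / (1.0 + B) if add_one else count / B
    return EnrichmentResult(
        observed_r2=observed_r2,
        coefficients=coefficients,
        null_r2=null_r2,
        p_value=p_value,
        mode=mode,
        seed=seed if isinstance(seed, int) else -1,
    )
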