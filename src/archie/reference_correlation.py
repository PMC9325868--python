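"""Reference LD / co-expression estimation and the adjusted cross-matrix W.

Summary Z scores carry correlation induced by linkage disequilibrium among the
variants (Sigma_GG) and by co-expression among the genes (Sigma_EE).  Before
sparse CCA those dependencies are removed by two-sided whitening of the
variant-gene cross-correlation matrix Sigma_GE::

    W = Sigma_EE^(-1/2) @ Sigma_GE @ Sigma_GG^(-1/2)

with W oriented genes x variants so that the bilinear form ``v.T @ W @ u`` is
well defined for a gene-loading vector v and a variant-loading vector u.
Both correlation matrices are estimated from reference panels (individual
level genotype dosages, expression), optionally shrunk linearly toward the
identity for invertibility, and inverted through an eigenvalue-floored
inverse square root.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .summary_io import SummaryMatrix

__all__ = [
    "CorrelationMatrix",
    "AdjustedMatrix",
    "estimate_ld",
    "estimate_coexpression",
    "inverse_sqrt",
    "matrix_sqrt",
    "z_to_correlation",
    "build_w",
    "read_dosage_tsv",
    "read_vcf_dosages",
    "read_expression_tsv",
]

DEFAULT_EIGEN_FLOOR = 1e-6


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal correlation estimate with its conditioning knobs.

    ``values`` is the (possibly shrunk) correlation matrix, ``ids`` the
    row/column labels, ``shrinkage`` the weight lambda of the linear shrinkage
    ``(1 - lambda) * S + lambda * I`` already applied, and ``eigen_floor`` the
    relative floor epsilon used when the matrix is inverted.
    """

    values: np.ndarray
    ids: list[str]
    shrinkage: float = 0.0
    eigen_floor: float = DEFAULT_EIGEN_FLOOR

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix must be square")
        if len(self.ids) != n:
            raise ValueError("ids length does not match matrix dimension")
        if np.abs(self.values - self.values.T).max(initial=0.0) > 1e-10:
            raise ValueError("correlation matrix is not symmetric")
        if n and np.abs(np.diag(self.values) - 1.0).max() > 1e-10:
            raise ValueError("correlation matrix diagonal is not 1")
        if not 0.0 <= self.shrinkage <= 1.0:
            raise ValueError("shrinkage must be in [0, 1]")

    @property
    def dim(self) -> int:
        return self.values.shape[0]


@dataclass
class AdjustedMatrix:
    """The whitened genes x variants cross-matrix W with its provenance."""

    values: np.ndarray
    gene_ids: list[str]
    variant_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.variant_ids)):
            raise ValueError("W shape does not match gene/variant id lists")
        if not np.isfinite(self.values).all():
            raise ValueError("W contains non-finite entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _pearson_columns(data: np.ndarray, ids: list[str], what: str) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError(f"need a 2-D matrix with at least 2 reference samples for {what}")
    sd = data.std(axis=0)
    if np.any(sd == 0):
        bad = ids[int(np.argmax(sd == 0))]
        raise ValueError(f"constant {what} column: {bad!r}")
    centered = (data - data.mean(axis=0)) / sd
    corr = centered.T @ centered / data.shape[0]
    np.fill_diagonal(corr, 1.0)
    return (corr + corr.T) / 2.0


def _ledoit_wolf_lambda(data: np.ndarray) -> float:
    from sklearn.covariance import LedoitWolf

    std = (data - data.mean(axis=0)) / data.std(axis=0)
    return float(LedoitWolf(assume_centered=True).fit(std).shrinkage_)


def _shrink(corr: np.ndarray, lam: float) -> np.ndarray:
    out = (1.0 - lam) * corr + lam * np.eye(corr.shape[0])
    np.fill_diagonal(out, 1.0)
    return out


def estimate_ld(
    dosages: np.ndarray,
    shrinkage: float = 0.0,
    ids: list[str] | None = None,
    eigen_floor: float = DEFAULT_EIGEN_FLOOR,
) -> CorrelationMatrix:
    """Empirical LD: Pearson correlation of dosage columns, shrunk toward I.

    ``dosages`` is samples x variants. ``shrinkage`` is the linear weight
    lambda of ``(1 - lambda) * S + lambda * I``.
    """
    dosages = np.asarray(dosages, dtype=float)
    if ids is None:
        ids = [f"variant{i}" for i in range(dosages.shape[1])]
    corr = _pearson_columns(dosages, ids, "dosage")
    return CorrelationMatrix(_shrink(corr, shrinkage), list(ids), shrinkage, eigen_floor)


def estimate_coexpression(
    expression: np.ndarray,
    shrinkage: float | str = 0.1,
    ids: list[str] | None = None,
    quantile_normalize: bool = False,
    eigen_floor: float = DEFAULT_EIGEN_FLOOR,
) -> CorrelationMatrix:
    """Penalized co-expression: column Pearson correlation shrunk toward I.

    ``expression`` is samples x genes.  ``shrinkage`` is either a fixed lambda
    in [0, 1] or ``"ledoit-wolf"`` for the data-driven plug-in.  When
    ``quantile_normalize`` is set, each gene is first mapped to normal scores
    by a rank-based inverse-normal transform (ties broken by average rank).
    """
    expression = np.asarray(expression, dtype=float)
    if ids is None:
        ids = [f"gene{j}" for j in range(expression.shape[1])]
    if quantile_normalize:
        n = expression.shape[0]
        ranks = np.apply_along_axis(stats.rankdata, 0, expression)
        expression = stats.norm.ppf((ranks - 0.5) / n)
    if isinstance(shrinkage, str):
        if shrinkage != "ledoit-wolf":
            raise ValueError(f"unknown shrinkage rule {shrinkage!r}")
        lam = _ledoit_wolf_lambda(expression)
    else:
        lam = float(shrinkage)
    corr = _pearson_columns(expression, ids, "gene")
    return CorrelationMatrix(_shrink(corr, lam), list(ids), lam, eigen_floor)


def _floored_eigh(C: CorrelationMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values = C.values if isinstance(C, CorrelationMatrix) else np.asarray(C, dtype=float)
    floor = C.eigen_floor if isinstance(C, CorrelationMatrix) else DEFAULT_EIGEN_FLOOR
    if np.abs(values - values.T).max(initial=0.0) > 1e-8:
        raise ValueError("matrix is not symmetric")
    vals, vecs = np.linalg.eigh(values)
    top = vals[-1]
    if top <= 0:
        raise ValueError("matrix has no positive eigenvalue")
    return np.maximum(vals, floor * top), vecs


def inverse_sqrt(C: CorrelationMatrix | np.ndarray) -> np.ndarray:
    """Symmetric inverse square root with eigenvalues floored at eps * lambda_max."""
    vals, vecs = _floored_eigh(C)
    return (vecs / np.sqrt(vals)) @ vecs.T


def matrix_sqrt(C: CorrelationMatrix | np.ndarray) -> np.ndarray:
    """Symmetric square root with the same eigenvalue floor as inverse_sqrt."""
    vals, vecs = _floored_eigh(C)
    return (vecs * np.sqrt(vals)) @ vecs.T


def z_to_correlation(Z: np.ndarray, n_study: int, method: str = "t_to_r") -> np.ndarray:
    """Map summary Z scores to variant-gene correlation estimates.

    ``t_to_r`` inverts the t-to-r transform of simple regression,
    ``r = Z / sqrt(n - 2 + Z**2)``; ``linear`` uses ``Z / sqrt(n)``.
    """
    Z = np.asarray(Z, dtype=float)
    if method == "t_to_r":
        if n_study <= 2:
            raise ValueError("t_to_r mapping needs n_study > 2")
        return Z / np.sqrt(n_study - 2 + Z**2)
    if method == "linear":
        if n_study <= 0:
            raise ValueError("linear mapping needs n_study > 0")
        return Z / np.sqrt(n_study)
    if method == "identity":
        return Z.copy()
    raise ValueError(f"unknown Z-to-correlation method {method!r}")


def _check_ids(expected: list[str], got: list[str], what: str) -> None:
    if list(expected) != list(got):
        for i, (a, b) in enumerate(zip(expected, got)):
            if a != b:
                raise ValueError(f"{what} id mismatch at position {i}: summary has {a!r}, reference has {b!r}")
        raise ValueError(f"{what} id lists have different lengths ({len(expected)} vs {len(got)})")


def build_w(
    summary: SummaryMatrix,
    ld: CorrelationMatrix,
    coexpr: CorrelationMatrix,
    z_map: str = "t_to_r",
) -> AdjustedMatrix:
    """Assemble ``W = Sigma_EE^(-1/2) @ Sigma_GE @ Sigma_GG^(-1/2)``.

    ``Sigma_GE`` (genes x variants) is the Z-derived cross-correlation; for
    ``z_map="identity"`` the raw Z matrix is whitened directly, which leaves
    the downstream sparse CCA unchanged because the cc-value is scale
    invariant.
    """
    _check_ids(summary.variant_ids, ld.ids, "variant")
    _check_ids(summary.gene_ids, coexpr.ids, "gene")
    sigma_ge = z_to_correlation(summary.Z, summary.n_study, method=z_map).T
    W = inverse_sqrt(coexpr) @ sigma_ge @ inverse_sqrt(ld)
    return AdjustedMatrix(
        values=W,
        gene_ids=summary.gene_ids,
        variant_ids=summary.variant_ids,
        provenance={
            "z_map": z_map,
            "n_study": summary.n_study,
            "ld_shrinkage": ld.shrinkage,
            "coexpr_shrinkage": coexpr.shrinkage,
            "eigen_floor": (ld.eigen_floor, coexpr.eigen_floor),
        },
    )


# ---------------------------------------------------------------------------
# reference-panel readers

def read_dosage_tsv(path) -> tuple[np.ndarray, list[str]]:
    """Samples x variants dosage TSV (header row = variant ids, first column = sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(float), [str(c) for c in df.columns]


def read_vcf_dosages(path) -> tuple[np.ndarray, list[str]]:
    """Dosages from a VCF: DS field when present, else alternate-allele count from GT."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids, rows = [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            rows.append(np.asarray(ds, dtype=float).ravel())
        else:
            gt = np.asarray(var.genotype.array())[:, :2]
            rows.append(np.where(gt < 0, np.nan, gt).sum(axis=1).astype(float))
    return np.array(rows).T, ids


def read_expression_tsv(path) -> tuple[np.ndarray, list[str]]:
    """Genes-in-rows expression TSV (first column gene id) -> samples x genes matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(float).T, [str(i) for i in df.index]
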