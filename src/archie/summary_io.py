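"""Load, validate and filter trans-eQTL summary statistics.

The raw evidence for an aggregative trans-association analysis is a table of
per-(variant, gene) Z scores (and optionally p-values) from standard
trans-eQTL mapping, together with variant annotation (position, minor allele
frequency, associated trait) and gene annotation (transcription start site).
This module turns such tables into a dense, fully observed variants x genes
:class:`SummaryMatrix` and implements the distal ("trans") gene filter: a gene
is trans to a variant iff the two are on different chromosomes or the variant
lies at least ``window_bp`` (default 5 Mb) from the gene's TSS.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import normalize_chrom

__all__ = [
    "SummaryError",
    "EmptyMatrixError",
    "SummaryMatrix",
    "load_summary",
    "write_summary",
    "filter_trans",
    "intersect_expressed",
]

#: required columns of the summary TSV dialect (header names)
SUMMARY_COLUMNS = ["SNP", "SNPChr", "SNPPos", "Gene", "GeneChr", "GenePos", "Zscore"]

VARIANT_COLUMNS = ["variant_id", "chromosome", "position", "maf", "trait_label"]
GENE_COLUMNS = ["gene_id", "chromosome", "tss"]


class SummaryError(ValueError):
    """Malformed or inconsistent summary-statistics input."""


class EmptyMatrixError(SummaryError):
    """A filter removed every variant or every gene."""


def _validate_variants(variants: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise SummaryError(f"variant table missing columns: {missing}")
    if variants["variant_id"].duplicated().any():
        dup = variants.loc[variants["variant_id"].duplicated(), "variant_id"].iloc[0]
        raise SummaryError(f"duplicated variant_id: {dup!r}")
    maf = variants["maf"].to_numpy(float)
    if np.any((maf <= 0) | (maf > 0.5)):
        bad = variants.loc[(maf <= 0) | (maf > 0.5), "variant_id"].iloc[0]
        raise SummaryError(f"variant {bad!r} has MAF outside (0, 0.5]")
    if (variants["position"].to_numpy(int) < 1).any():
        raise SummaryError("variant positions must be >= 1 (1-based bp)")
    return variants.reset_index(drop=True)


def _validate_genes(genes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise SummaryError(f"gene table missing columns: {missing}")
    if genes["gene_id"].duplicated().any():
        dup = genes.loc[genes["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise SummaryError(f"duplicated gene_id: {dup!r}")
    if (genes["tss"].to_numpy(int) < 1).any():
        raise SummaryError("gene TSS must be >= 1 (1-based bp)")
    return genes.reset_index(drop=True)


@dataclass
class SummaryMatrix:
    """Dense p variants x g genes matrix of trans-eQTL summary statistics.

    Attributes
    ----------
    Z
        ``(p, g)`` array of association Z scores, ``Z[i, j]`` for variant ``i``
        and gene ``j``.
    P
        Optional ``(p, g)`` array of two-sided p-values.
    variants
        Annotation frame with columns ``variant_id, chromosome, position, maf,
        trait_label`` aligned with the rows of ``Z``.
    genes
        Annotation frame with columns ``gene_id, chromosome, tss`` aligned with
        the columns of ``Z``.
    n_study
        Effective sample size of the eQTL study the Z scores came from.
    """

    Z: np.ndarray
    variants: pd.DataFrame
    genes: pd.DataFrame
    P: np.ndarray | None = None
    n_study: int = 0

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2:
            raise SummaryError("Z must be a 2-D array")
        self.variants = _validate_variants(pd.DataFrame(self.variants))
        self.genes = _validate_genes(pd.DataFrame(self.genes))
        p, g = self.Z.shape
        if len(self.variants) != p or len(self.genes) != g:
            raise SummaryError(
                f"Z is {p}x{g} but annotation has {len(self.variants)} variants "
                f"and {len(self.genes)} genes"
            )
        if not np.isfinite(self.Z).all():
            raise SummaryError("Z contains missing or non-finite entries")
        if self.P is not None:
            self.P = np.asarray(self.P, dtype=float)
            if self.P.shape != self.Z.shape:
                raise SummaryError("P and Z shapes differ")

    @property
    def shape(self) -> tuple[int, int]:
        return self.Z.shape

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["variant_id"].tolist()

    @property
    def gene_ids(self) -> list[str]:
        return self.genes["gene_id"].tolist()

    def take_variants(self, rows: np.ndarray) -> "SummaryMatrix":
        rows = np.asarray(rows)
        if rows.size == 0:
            raise EmptyMatrixError("selection leaves no variants")
        return replace(
            self,
            Z=self.Z[rows],
            P=None if self.P is None else self.P[rows],
            variants=self.variants.iloc[rows].reset_index(drop=True),
        )

    def take_genes(self, cols: np.ndarray) -> "SummaryMatrix":
        cols = np.asarray(cols)
        if cols.size == 0:
            raise EmptyMatrixError("selection leaves no genes")
        return replace(
            self,
            Z=self.Z[:, cols],
            P=None if self.P is None else self.P[:, cols],
            genes=self.genes.iloc[cols].reset_index(drop=True),
        )


def _read_table(path, required: list[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SummaryError(f"{what} file {path!r} missing columns: {missing}")
    return df


def _to_float(df: pd.DataFrame, col: str, what: str) -> np.ndarray:
    raw = df[col]
    vals = pd.to_numeric(raw, errors="coerce")
    bad = vals.isna() & raw.notna()
    if bad.any():
        # +2: header line plus 1-based numbering
        line = int(bad.idxmax()) + 2
        raise SummaryError(f"unparseable {col} value {raw[bad.idxmax()]!r} on line {line} of {what}")
    if vals.isna().any():
        line = int(vals.isna().idxmax()) + 2
        raise SummaryError(f"missing {col} value on line {line} of {what}")
    return vals.to_numpy(float)


def check_zp_consistency(Z: np.ndarray, P: np.ndarray, tol: float = 0.01, strict: bool = False) -> None:
    """Check |P - 2*Phi(-|Z|)| <= tol; warn (default) or raise (``strict``)."""
    expected = 2.0 * stats.norm.sf(np.abs(Z))
    dev = np.nanmax(np.abs(P - expected)) if P.size else 0.0
    if dev > tol:
        msg = f"p-values deviate from 2*Phi(-|Z|) by up to {dev:.3g} (tolerance {tol})"
        if strict:
            raise SummaryError(msg)
        warnings.warn(msg, stacklevel=3)


def load_summary(
    path,
    variant_meta,
    gene_meta,
    missing_policy: str = "drop_gene",
    n_study: int = 0,
    zp_tol: float = 0.01,
    strict_zp: bool = False,
) -> SummaryMatrix:
    """Read a summary TSV plus annotation tables into a complete matrix.

    Parameters
    ----------
    path
        Summary TSV with columns ``SNP, SNPChr, SNPPos, Gene, GeneChr,
        GenePos, Zscore`` and optionally ``Pvalue``; one row per observed
        (variant, gene) pair.
    variant_meta, gene_meta
        Annotation TSVs with the :data:`VARIANT_COLUMNS` / :data:`GENE_COLUMNS`
        fields.
    missing_policy
        How to handle (variant, gene) pairs absent from the file:
        ``drop_gene`` removes genes with any missing variant, ``drop_variant``
        removes variants with any missing gene, ``error`` raises.

    Rows and columns are ordered by sorted id, so the result is independent of
    file row order.
    """
    if missing_policy not in ("drop_gene", "drop_variant", "error"):
        raise SummaryError(f"unknown missing_policy {missing_policy!r}")
    df = _read_table(path, SUMMARY_COLUMNS, "summary")
    z = _to_float(df, "Zscore", "summary file")
    pvals = _to_float(df, "Pvalue", "summary file") if "Pvalue" in df.columns else None

    dup = df.duplicated(subset=["SNP", "Gene"])
    if dup.any():
        i = int(dup.idxmax())
        raise SummaryError(
            f"duplicated (variant, gene) pair ({df['SNP'][i]!r}, {df['Gene'][i]!r}) on line {i + 2}"
        )

    vmeta = _validate_variants(
        _read_table(variant_meta, VARIANT_COLUMNS, "variant annotation").assign(
            position=lambda d: pd.to_numeric(d["position"]).astype(int),
            maf=lambda d: pd.to_numeric(d["maf"]).astype(float),
        )
    )
    gmeta = _validate_genes(
        _read_table(gene_meta, GENE_COLUMNS, "gene annotation").assign(
            tss=lambda d: pd.to_numeric(d["tss"]).astype(int)
        )
    )

    variant_ids = sorted(df["SNP"].unique())
    gene_ids = sorted(df["Gene"].unique())
    unknown_v = set(variant_ids) - set(vmeta["variant_id"])
    if unknown_v:
        raise SummaryError(f"variants absent from annotation: {sorted(unknown_v)[:5]}")
    unknown_g = set(gene_ids) - set(gmeta["gene_id"])
    if unknown_g:
        raise SummaryError(f"genes absent from annotation: {sorted(unknown_g)[:5]}")

    ridx = {v: i for i, v in enumerate(variant_ids)}
    cidx = {g: j for j, g in enumerate(gene_ids)}
    p, g = len(variant_ids), len(gene_ids)
    Z = np.full((p, g), np.nan)
    rows = df["SNP"].map(ridx).to_numpy()
    cols = df["Gene"].map(cidx).to_numpy()
    Z[rows, cols] = z
    P = None
    if pvals is not None:
        P = np.full((p, g), np.nan)
        P[rows, cols] = pvals

    observed = ~np.isnan(Z)
    if not observed.all():
        if missing_policy == "error":
            n_missing = int((~observed).sum())
            raise SummaryError(f"{n_missing} (variant, gene) pairs absent and missing_policy='error'")
        if missing_policy == "drop_gene":
            keep = observed.all(axis=0)
            if not keep.any():
                raise EmptyMatrixError("every gene has at least one missing variant")
            Z = Z[:, keep]
            P = None if P is None else P[:, keep]
            gene_ids = [gid for gid, k in zip(gene_ids, keep) if k]
        else:  # drop_variant
            keep = observed.all(axis=1)
            if not keep.any():
                raise EmptyMatrixError("every variant has at least one missing gene")
            Z = Z[keep]
            P = None if P is None else P[keep]
            variant_ids = [vid for vid, k in zip(variant_ids, keep) if k]

    variants = vmeta.set_index("variant_id").loc[variant_ids].reset_index()
    genes = gmeta.set_index("gene_id").loc[gene_ids].reset_index()
    if P is not None:
        check_zp_consistency(Z, P, tol=zp_tol, strict=strict_zp)
    return SummaryMatrix(Z=Z, P=P, variants=variants, genes=genes, n_study=n_study)


def write_summary(summary: SummaryMatrix, path) -> None:
    """Write a SummaryMatrix back to the long TSV dialect read by load_summary."""
    p, g = summary.shape
    v = summary.variants
    ge = summary.genes
    rows = np.repeat(np.arange(p), g)
    cols = np.tile(np.arange(g), p)
    out = pd.DataFrame(
        {
            "SNP": v["variant_id"].to_numpy()[rows],
            "SNPChr": v["chromosome"].to_numpy()[rows],
            "SNPPos": v["position"].to_numpy()[rows],
            "Gene": ge["gene_id"].to_numpy()[cols],
            "GeneChr": ge["chromosome"].to_numpy()[cols],
            "GenePos": ge["tss"].to_numpy()[cols],
            "Zscore": summary.Z[rows, cols],
        }
    )
    if summary.P is not None:
        out["Pvalue"] = summary.P[rows, cols]
    buf = io.StringIO()
    out.to_csv(buf, sep="\t", index=False, float_format="%.17g")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def trans_mask(summary: SummaryMatrix, window_bp: int = 5_000_000) -> np.ndarray:
    """Boolean ``(p, g)`` mask: entry True iff the gene is trans to the variant."""
    vchrom = np.array([normalize_chrom(c) for c in summary.variants["chromosome"]])
    gchrom = np.array([normalize_chrom(c) for c in summary.genes["chromosome"]])
    vpos = summary.variants["position"].to_numpy(int)[:, None]
    gtss = summary.genes["tss"].to_numpy(int)[None, :]
    diff_chrom = vchrom[:, None] != gchrom[None, :]
    far = np.abs(vpos - gtss) >= window_bp
    return diff_chrom | far


def filter_trans(summary: SummaryMatrix, window_bp: int = 5_000_000) -> SummaryMatrix:
    """Keep exactly the genes that are trans to *every* variant in the matrix.

    A gene is trans to a variant iff they sit on different (normalized)
    chromosomes or the variant is at least ``window_bp`` base pairs from the
    gene's transcription start site.
    """
    keep = np.flatnonzero(trans_mask(summary, window_bp).all(axis=0))
    if keep.size == 0:
        raise EmptyMatrixError("no gene is trans to all variants")
    return summary.take_genes(keep)


def intersect_expressed(summary: SummaryMatrix, expressed_gene_ids) -> SummaryMatrix:
    """Restrict the gene columns to those in ``expressed_gene_ids`` (order kept)."""
    expressed = set(expressed_gene_ids)
    keep = np.flatnonzero(summary.genes["gene_id"].isin(expressed).to_numpy())
    if keep.size == 0:
        raise EmptyMatrixError("no summary gene is in the expressed set")
    return summary.take_genes(keep)
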