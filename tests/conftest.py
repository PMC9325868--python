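import numpy as np
import pandas as pd
import pytest

from archie.summary_io import SummaryMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_summary(Z, vchrom=None, vpos=None, gchrom=None, gtss=None, traits=None, n_study=1000, P=None):
    """Small helper building a SummaryMatrix with synthetic annotation."""
    Z = np.asarray(Z, dtype=float)
    p, g = Z.shape
    variants = pd.DataFrame(
        {
            "variant_id": [f"s{i}" for i in range(p)],
            "chromosome": vchrom if vchrom is not None else ["1"] * p,
            "position": vpos if vpos is not None else (np.arange(p) + 1) * 1_000_000,
            "maf": np.full(p, 0.3),
            "trait_label": traits if traits is not None else ["t"] * p,
        }
    )
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{j}" for j in range(g)],
            "chromosome": gchrom if gchrom is not None else ["2"] * g,
            "tss": gtss if gtss is not None else (np.arange(g) + 1) * 1_000_000,
        }
    )
    return SummaryMatrix(Z=Z, P=P, variants=variants, genes=genes, n_study=n_study)


@pytest.fixture
def summary_files(tmp_path):
    """A tiny complete 2 variants x 2 genes summary bundle on disk."""
    (tmp_path / "summary.tsv").write_text(
        "SNP\tSNPChr\tSNPPos\tGene\tGeneChr\tGenePos\tZscore\tPvalue\n"
        "rs2\t1\t2000000\tgB\t2\t9000000\t-1.0\t0.3173105\n"
        "rs1\t1\t1000000\tgA\t2\t8000000\t2.0\t0.0455003\n"
        "rs1\t1\t1000000\tgB\t2\t9000000\t0.0\t1.0\n"
        "rs2\t1\t2000000\tgA\t2\t8000000\t1.0\t0.3173105\n"
    )
    (tmp_path / "variants.tsv").write_text(
        "variant_id\tchromosome\tposition\tmaf\ttrait_label\n"
        "rs1\t1\t1000000\t0.2\ttraitA\n"
        "rs2\t1\t2000000\t0.4\ttraitB\n"
    )
    (tmp_path / "genes.tsv").write_text(
        "gene_id\tchromosome\ttss\ngA\t2\t8000000\ngB\t2\t9000000\n"
    )
    return {
        "summary": tmp_path / "summary.tsv",
        "variant_meta": tmp_path / "variants.tsv",
        "gene_meta": tmp_path / "genes.tsv",
    }


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    from archie.fixtures import make_fixtures

    out = tmp_path_factory.mktemp("bundle")
    return make_fixtures(seed=0, out=out)
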