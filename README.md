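# archie-scca

Aggregative trans-association analysis for genetic studies of gene
regulation.  Trait-associated variants influence the expression of distal
("trans") genes through many individually weak effects that per-pair
trans-eQTL mapping cannot detect after multiple-testing correction.  This
package detects them in aggregate: it whitens the variants x genes matrix of
trans-eQTL summary Z scores with reference LD and co-expression estimates,

    W = Σ_EE^(-1/2) Σ_GE Σ_GG^(-1/2),

and applies sparse canonical correlation analysis to extract paired sparse
*variant components* (u) and *gene components* (v) maximizing `vᵀWu` under
L1 budgets.  The non-zero loadings name the trait-relevant variants and
target genes; each component's strength is the cc-value
`q² = (vᵀWu)² / √((uᵀWᵀWu)(vᵀWWᵀv)) ∈ [0, 1]`.  Component significance is
assessed against a resampled *competitive null* built from GWAS variants of
other traits, and the number of significant leading components is the
sequential cut `L = min{k : p_k > α} − 1`.

The package also provides the supporting machinery end to end:

* a calibrated linear-SEM simulation engine (SNP blocks → cis genes →
  downstream gene network, cis h² 20–22%, trans h² 10–14%) with type-I and
  power harnesses;
* global-null sampling (`vec(Σ_GE;null) ~ N(0, Σ_EE ⊗ Σ_GG)`);
* trans-imputed expression scores (TIES) and a resampling enrichment test
  for trait heritability mediated by the selected genes;
* plain-text I/O for summary TSVs, dosage matrices (TSV or VCF), and
  expression panels, plus a synthetic fixture generator so everything runs
  with no external data.

Intended users: statistical geneticists and computational biologists working
with trans-eQTL summary statistics (eQTLGen-style exports) and reference
panels.  See `docs/methods.md` for the model, assumptions, and limitations.

## Worked example

```python
import numpy as np
from archie import (
    make_fixtures, load_summary, filter_trans, estimate_ld,
    estimate_coexpression, build_w, fit_components,
    competitive_null_ensemble, component_pvalues, select_significant,
)
from archie.reference_correlation import read_dosage_tsv, read_expression_tsv

fx = make_fixtures(seed=0, out="scratch/fixtures")
summary = load_summary(fx["summary"], fx["variant_meta"], fx["gene_meta"], n_study=5000)
summary = filter_trans(summary)                      # >= 5 Mb or other chromosome

trait_rows = np.flatnonzero(summary.variants["trait_label"] == "trait_signal")
observed = summary.take_variants(trait_rows)

dosages, dosage_ids = read_dosage_tsv(fx["genotype_reference"])
expr, expr_ids = read_expression_tsv(fx["expression_reference"])
ld = estimate_ld(dosages[:, [dosage_ids.index(v) for v in observed.variant_ids]],
                 ids=observed.variant_ids)
coexpr = estimate_coexpression(expr, shrinkage=0.1, ids=expr_ids)
W = build_w(observed, ld, coexpr)

comps = fit_components(W, K=2)
nulls = competitive_null_ensemble(summary, *observed.shape, M=199, K=2,
                                  exclude_traits={"trait_signal"},
                                  expression_ref=expr, seed=1)
result = component_pvalues(comps.q2, nulls)
L = select_significant(result, alpha=0.05)
print("q2:", [round(q, 3) for q in comps.q2])
print("p: ", result.describe(), " L =", L)
```

On the bundled fixture (20 trait variants, 8 of which drive a planted
rank-one module over 30 of 500 genes) this prints

```
q2: [0.786, 0.863]
p:  ['< 0.00503', '< 0.00503']  L = 2
```

— both components beat every one of the 199 competitive-null draws
(p < 1/M), so L = 2 component pairs are declared trait-specific; the
non-zero gene loadings of those components recover the planted target-gene
module.  Running the same analysis for the signal-free trait in the bundle
(`trait_null`) yields p-values of about 0.94 and 0.52 and L = 0.

The same pipeline is scriptable from the shell (`archie run --config
config.yaml`), with subcommands `filter`, `build-w`, `fit`, `type1`,
`power`, `simulate`, `ties`, and `fixtures`.

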