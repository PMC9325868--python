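"""Competitive / global resampling nulls and the sequential significance rule."""

import numpy as np
import pytest

from archie.reference_correlation import CorrelationMatrix
from archie.scca_core import SparsityConfig
from archie.significance import (
    NullEnsemble,
    TraitMixture,
    build_competitive_null,
    check_resamples,
    component_pvalues,
    global_null_ensemble,
    sample_global_null,
    select_significant,
    trait_specificity_experiment,
)

from conftest import make_summary


def pool_summary(rng, p=60, g=30, n_traits=30):
    traits = [f"trait{i % n_traits:02d}" for i in range(p)]
    return make_summary(rng.standard_normal((p, g)), traits=traits)


class TestCompetitiveNull:
    def test_excluded_trait_never_sampled(self, rng):
        pool = pool_summary(rng)
        for seed in range(200):
            draw = build_competitive_null(pool, p=10, g=5, exclude_traits={"trait00"}, seed=seed)
            assert "trait00" not in set(draw.variants["trait_label"])
            assert draw.shape == (10, 5)

    def test_one_variant_per_trait_when_traits_suffice(self, rng):
        pool = pool_summary(rng, p=60, g=10, n_traits=30)
        draw = build_competitive_null(pool, p=20, g=5, seed=1)
        assert draw.variants["trait_label"].nunique() == 20

    def test_seed_reproducibility(self, rng):
        pool = pool_summary(rng)
        a = build_competitive_null(pool, 10, 5, seed=7)
        b = build_competitive_null(pool, 10, 5, seed=7)
        c = build_competitive_null(pool, 10, 5, seed=8)
        assert a.variant_ids == b.variant_ids and a.gene_ids == b.gene_ids
        assert a.variant_ids != c.variant_ids or a.gene_ids != c.gene_ids

    def test_insufficient_pool_reports_shortfall(self, rng):
        pool = pool_summary(rng, p=8, g=5, n_traits=2)
        with pytest.raises(ValueError, match="only"):
            build_competitive_null(pool, p=20, g=3)


class TestGlobalNull:
    def test_shape_and_identity_moments(self):
        co = CorrelationMatrix(np.eye(3), ["a", "b", "c"])
        ld = CorrelationMatrix(np.eye(4), list("wxyz"))
        one = sample_global_null(co, ld, seed=0)
        assert one.shape == (3, 4)
        draws = sample_global_null(co, ld, seed=1, size=10_000)
        assert draws.std() == pytest.approx(1.0, abs=0.03)

    def test_kronecker_covariance_on_two_by_two(self):
        co = CorrelationMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]), ["a", "b"])
        ld = CorrelationMatrix(np.eye(2), ["x", "y"])
        draws = sample_global_null(co, ld, seed=2, size=10_000)
        within_column = np.corrcoef(draws[:, 0, 0], draws[:, 1, 0])[0, 1]
        across = np.corrcoef(draws[:, 0, 0], draws[:, 1, 1])[0, 1]
        assert within_column == pytest.approx(0.5, abs=0.03)
        assert across == pytest.approx(0.0, abs=0.03)

    def test_ensemble_values_bounded(self):
        co = CorrelationMatrix(np.eye(4), list("abcd"))
        ld = CorrelationMatrix(np.eye(5), list("vwxyz"))
        ens = global_null_ensemble(co, ld, M=50, K=2, seed=0)
        assert ens.null_q2.shape == (50, 2)
        assert ((ens.null_q2 >= 0) & (ens.null_q2 <= 1)).all()


class TestPValuesAndSelection:
    def test_counting_cases(self):
        nulls = NullEnsemble(null_q2=np.linspace(0.1, 1.0, 10)[:, None], kind="global")
        assert component_pvalues([2.0], nulls).p_values[0] == 0.0
        assert component_pvalues([0.05], nulls).p_values[0] == 1.0
        assert component_pvalues([0.75], nulls).p_values[0] == pytest.approx(0.3)
        res = component_pvalues([2.0], nulls)
        assert res.describe()[0].startswith("<")
        assert component_pvalues([2.0], nulls, add_one=True).p_values[0] == pytest.approx(1 / 11)

    def test_printed_direction_is_the_reverse_count(self):
        nulls = NullEnsemble(null_q2=np.linspace(0.1, 1.0, 10)[:, None], kind="global")
        assert component_pvalues([0.75], nulls, printed_direction=True).p_values[0] == pytest.approx(0.7)

    def test_monotone_in_observed(self, rng):
        nulls = NullEnsemble(null_q2=rng.random((100, 1)), kind="global")
        grid = np.linspace(0, 1, 21)
        ps = [component_pvalues([q], nulls).p_values[0] for q in grid]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_rank_mismatch(self, rng):
        nulls = NullEnsemble(null_q2=rng.random((10, 2)), kind="global")
        with pytest.raises(ValueError, match="ranks"):
            component_pvalues([0.5, 0.5, 0.5], nulls)

    @pytest.mark.parametrize(
        "pvals,alpha,expected_L",
        [([0.001, 0.2, 0.3], 0.05, 1), ([0.2, 0.01], 0.05, 0), ([0.001, 0.002], 0.05, 2)],
    )
    def test_sequential_selection(self, pvals, alpha, expected_L):
        from archie.significance import SignificanceResult

        res = SignificanceResult(p_values=np.array(pvals), M=1000)
        assert select_significant(res, alpha) == expected_L

    def test_selection_ignores_pvalues_after_first_exceedance(self):
        from archie.significance import SignificanceResult

        a = SignificanceResult(p_values=np.array([0.01, 0.5, 0.9]), M=100)
        b = SignificanceResult(p_values=np.array([0.01, 0.5, 0.001]), M=100)
        assert select_significant(a, 0.05) == select_significant(b, 0.05) == 1

    def test_resolution_rule(self):
        check_resamples(999, 0.01)
        with pytest.raises(ValueError, match="resolution"):
            check_resamples(50, 0.01)


class TestTraitSpecificity:
    def build_pools(self, rng, signal):
        g = 40
        trait_Z = rng.standard_normal((30, g))
        if signal:
            # trait variants share a module confined to 8 genes; per-variant
            # strength is lognormal so a few variants dominate the pattern
            # (the scale-invariant cc-value responds to shape, not amplitude)
            u = np.exp(rng.normal(0.0, 1.2, 30))
            w = np.zeros(g)
            w[rng.choice(g, 8, replace=False)] = np.abs(rng.normal(1.0, 0.3, 8))
            trait_Z += 6.0 * np.outer(u, w) / max(np.abs(u).mean(), 1e-9)
        other = pool_summary(rng, p=80, g=g, n_traits=40)
        return make_summary(trait_Z, traits=["target"] * 30), other

    def test_planted_signal_increases_detection(self, rng):
        trait_pool, other_pool = self.build_pools(rng, signal=True)
        mix1 = TraitMixture(delta=1.0, n_variants=20, n_genes=30)
        mix0 = TraitMixture(delta=0.0, n_variants=20, n_genes=30)
        cfg = SparsityConfig()
        kw = dict(reps=12, M=199, alpha=0.05, seed=0, cfg=cfg)
        frac1 = trait_specificity_experiment(trait_pool, other_pool, mix1, **kw)
        frac0 = trait_specificity_experiment(trait_pool, other_pool, mix0, **kw)
        assert 0.0 <= frac0 <= frac1 <= 1.0
        assert frac1 >= 0.5 and frac0 <= 0.2

    def test_null_delta_calibrated(self, rng):
        trait_pool, other_pool = self.build_pools(rng, signal=False)
        mix0 = TraitMixture(delta=0.0, n_variants=10, n_genes=12)
        reps, alpha = 40, 0.1
        frac = trait_specificity_experiment(
            trait_pool, other_pool, mix0, reps=reps, M=99, alpha=alpha, seed=1
        )
        assert frac <= alpha + 2 * np.sqrt(alpha / reps)

    def test_validation_errors(self, rng):
        trait_pool, other_pool = self.build_pools(rng, signal=False)
        mix = TraitMixture(delta=0.5, n_variants=10, n_genes=12)
        with pytest.raises(ValueError, match="reps"):
            trait_specificity_experiment(trait_pool, other_pool, mix, reps=0, M=99, alpha=0.1)
        with pytest.raises(ValueError):
            TraitMixture(delta=1.5, n_variants=5, n_genes=5)
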