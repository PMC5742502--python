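"""Hypergeometric and contrast tests, q-values, module classification."""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from modulecontrast import (
    PlantedModule,
    bh_adjust,
    classify_modules,
    contrast_test,
    compute_folds,
    enrich_catalog,
    filter_low_counts,
    generate_counts,
    hypergeom_test,
    normalize,
    storey_q,
)


def enumerate_hypergeom_tail(n_universe, n_module, n_sample, n_overlap) -> Fraction:
    """Oracle: P(X >= n_overlap) by enumerating all C(N, n) draws."""
    hits = total = 0
    for draw in combinations(range(n_universe), n_sample):
        total += 1
        if sum(1 for i in draw if i < n_module) >= n_overlap:
            hits += 1
    return Fraction(hits, total)


class TestHypergeomTest:
    def test_hand_enumerated_example(self):
        """Universe 10, module 4, sample 5, overlap 4 -> p = 6/252."""
        universe = {f"g{i}" for i in range(10)}
        module = {"g0", "g1", "g2", "g3"}
        sample = {"g0", "g1", "g2", "g3", "g4"}
        n_overlap, expected, p = hypergeom_test(module, sample, universe)
        assert n_overlap == 4
        assert expected == pytest.approx(2.0)
        assert p == pytest.approx(6 / 252, abs=1e-12)

    def test_sample_equals_universe(self):
        universe = {f"g{i}" for i in range(8)}
        module = {"g0", "g1", "g2"}
        n_overlap, _, p = hypergeom_test(module, universe, universe)
        assert n_overlap == len(module) and p == pytest.approx(1.0)

    def test_zero_overlap_tail_is_one(self):
        universe = {f"g{i}" for i in range(6)}
        _, _, p = hypergeom_test({"g0"}, {"g5"}, universe)
        assert p == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_test(set(), set(), set())

    def test_non_subset_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_test({"zzz"}, set(), {"g0"})

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        universe = {f"g{i}" for i in range(n)}
        module = {f"g{i}" for i in range(int(rng.integers(1, n)))}
        sample = set(rng.choice(sorted(universe), int(rng.integers(1, n)), replace=False))
        n_overlap, _, p = hypergeom_test(module, sample, universe)
        oracle = enumerate_hypergeom_tail(n, len(module), len(sample), n_overlap)
        assert p == pytest.approx(float(oracle), abs=1e-12)


class TestContrastTest:
    def test_module_equal_to_universe_gives_zero_contrast_unit_p(self):
        folds = pd.Series([1.0, -2.0, 3.0], index=["a", "b", "c"])
        contrast, p = contrast_test({"a", "b", "c"}, folds, seed=0)
        assert contrast == pytest.approx(0.0) and p == 1.0

    def test_exhaustive_size_one_enumeration(self):
        """Folds {+2, 0, 0, -2}, module = the +2 gene: 2 of 4 singleton draws
        reach |contrast| >= 2, so p = 0.5 exactly."""
        folds = pd.Series([2.0, 0.0, 0.0, -2.0], index=["a", "b", "c", "d"])
        contrast, p = contrast_test({"a"}, folds, seed=0)
        assert contrast == pytest.approx(2.0) and p == pytest.approx(0.5)

    def test_monte_carlo_consistent_with_exhaustive(self):
        """Forced Monte-Carlo p at 20,000 draws agrees with the exact
        enumerated p within 3 binomial standard errors."""
        rng = np.random.default_rng(1)
        folds = pd.Series(rng.normal(size=16), index=[f"g{i}" for i in range(16)])
        module = {"g0", "g1", "g2"}  # C(16,3) = 560 subsets
        _, p_exact = contrast_test(module, folds, seed=0)
        _, p_mc = contrast_test(
            module, folds, n_samplings=20_000, seed=5, force_monte_carlo=True
        )
        se = math.sqrt(p_exact * (1 - p_exact) / 20_000)
        assert abs(p_mc - p_exact) <= 3 * se + 1 / 20_000

    def test_monte_carlo_p_is_never_zero(self):
        rng = np.random.default_rng(2)
        folds = pd.Series(
            np.concatenate([rng.normal(size=200), [50.0] * 30]),
            index=[f"g{i}" for i in range(230)],
        )
        module = {f"g{i}" for i in range(200, 230)}  # extreme planted module
        _, p = contrast_test(module, folds, n_samplings=1000, seed=0)
        assert p >= 1 / 1001

    def test_determinism(self):
        rng = np.random.default_rng(3)
        folds = pd.Series(rng.normal(size=500), index=[f"g{i}" for i in range(500)])
        module = set(folds.index[:40])
        r1 = contrast_test(module, folds, n_samplings=2000, seed=7)
        r2 = contrast_test(module, folds, n_samplings=2000, seed=7)
        assert r1 == r2

    def test_module_outside_universe_rejected(self):
        folds = pd.Series([1.0], index=["a"])
        with pytest.raises(ValueError):
            contrast_test({"zzz"}, folds, seed=0)
        with pytest.raises(ValueError):
            contrast_test(set(), folds, seed=0)


class TestCorrections:
    def test_storey_with_forced_pi0_hand_example(self):
        np.testing.assert_allclose(
            storey_q([0.01, 0.02, 0.9], pi0=1.0), [0.03, 0.03, 0.9]
        )

    def test_bh_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.01, 0.03, 0.04]), [0.02, 0.02, 0.04, 0.04]
        )

    def test_all_unit_pvalues_stay_unit(self):
        np.testing.assert_allclose(storey_q([1.0] * 20), 1.0)
        np.testing.assert_allclose(bh_adjust([1.0] * 5), 1.0)

    def test_single_pvalue_unchanged_by_bh(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_adjusted_values_dominate_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=100)
        assert np.all(bh_adjust(p) >= p - 1e-15)

    def test_storey_pi0_one_equals_bh(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        np.testing.assert_allclose(storey_q(p, pi0=1.0), bh_adjust(p))

    def test_small_input_falls_back_to_pi0_one(self, caplog):
        p = [0.01, 0.5, 0.9]
        np.testing.assert_allclose(storey_q(p), bh_adjust(p))

    def test_pi0_deflates_q_under_strong_signal(self):
        rng = np.random.default_rng(2)
        p = np.concatenate([rng.uniform(0, 1e-4, 300), rng.uniform(size=100)])
        q = storey_q(p)
        assert np.all(q <= bh_adjust(p) + 1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_permutation_equivariance(self, pvals):
        p = np.array(pvals)
        perm = np.random.RandomState(0).permutation(len(p))
        np.testing.assert_allclose(storey_q(p, pi0=1.0)[perm], storey_q(p[perm], pi0=1.0))
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_out_of_range_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            storey_q([-0.1, 0.5])


class TestClassifyModules:
    def frame(self, rows):
        return pd.DataFrame(
            rows, columns=["module_id", "contrast", "contrast_q"]
        ).set_index("module_id")

    def test_direction_follows_contrast_sign_at_significance(self):
        res = self.frame([("m1", 0.8, 0.01), ("m2", -0.8, 0.5), ("m3", -0.4, 0.02)])
        induced, inhibited = classify_modules(res, q_threshold=0.10)
        assert induced == ["m1"] and inhibited == ["m3"]

    def test_missing_q_column_rejected(self):
        with pytest.raises(ValueError):
            classify_modules(pd.DataFrame({"contrast": [1.0]}))

    def test_planted_induced_inhibited_ratio_recovered(self):
        """20 up- and 4 down-planted modules at |effect| 2.0: the detected
        induced:inhibited ratio comes out near 5:1."""
        planted = [PlantedModule(f"UP{i}", 30, 2.0) for i in range(20)]
        planted += [PlantedModule(f"DN{i}", 30, -2.0) for i in range(4)]
        cm, truth = generate_counts(4000, 3, planted, seed=17)
        f = filter_low_counts(cm)
        folds = compute_folds(normalize(f, "quantile"), f)
        universe = set(folds.index)
        modules = {
            mid: frozenset(set(genes) & universe)
            for mid, genes in truth.module_genes.items()
        }
        results = enrich_catalog(
            modules, folds["log2fold"], de_sample=set(), n_samplings=2000, seed=17
        )
        induced, inhibited = classify_modules(results, q_threshold=0.10)
        assert 4 <= len(induced) / len(inhibited) <= 6


def test_enrich_catalog_output_shape_and_qvalues():
    rng = np.random.default_rng(4)
    folds = pd.Series(rng.normal(size=400), index=[f"g{i}" for i in range(400)])
    modules = {
        f"M{i}": frozenset(
            np.random.RandomState(i).choice(folds.index, 20, replace=False)
        )
        for i in range(12)
    }
    res = enrich_catalog(modules, folds, de_sample=set(folds.index[:50]),
                         n_samplings=500, seed=0)
    assert len(res) == 12
    assert {"hyper_q", "contrast_q", "direction"} <= set(res.columns)
    assert ((res["contrast_p"] > 0) & (res["contrast_p"] <= 1)).all()
    # q-values are a monotone transform of the p-value ranking
    srt = res.sort_values("contrast_p")
    assert np.all(np.diff(srt["contrast_q"]) >= -1e-12)
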