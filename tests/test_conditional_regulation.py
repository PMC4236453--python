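"""The conditional-regulon statistic: filters, median test, permutation null,
BH correction, dispersion coupling, gene selection, and orchestration."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ffrpnet import conditional_regulation as cr
from ffrpnet.expression_compendium import ExpressionCompendium
from ffrpnet._stats import bh_adjust
from conftest import small_compendium


def compendium_from_matrix(X, genes, sets):
    """sets: list of (name, n_arrays); X columns grouped in that order."""
    arrays, manifest = [], {}
    for cs, m in sets:
        for _ in range(m):
            aid = f"A{len(arrays)+1:03d}"
            arrays.append(aid)
            manifest[aid] = cs
    return ExpressionCompendium(
        pd.DataFrame(X, index=genes, columns=arrays), pd.Series(manifest))


class TestFilterConditionSets:
    def test_range_against_log2_threshold(self):
        # TF values {0.1, 0.5, 1.0}: range 0.9 >= log2(1.75) ~ 0.8074
        X = np.zeros((2, 6))
        X[0, :3] = [0.1, 0.5, 1.0]
        X[0, 3:] = [0.0, 0.15, 0.3]
        comp = compendium_from_matrix(X, ["tf", "g1"],
                                      [("cs1", 3), ("cs2", 3)])
        assert cr.filter_condition_sets(comp, "tf") == ["cs1"]

    def test_small_range_fails(self):
        X = np.zeros((2, 4))
        X[0, :2] = [0.0, 0.3]
        X[0, 2:] = [0.0, 2.0]
        comp = compendium_from_matrix(X, ["tf", "g1"],
                                      [("cs1", 2), ("cs2", 2)])
        assert cr.filter_condition_sets(comp, "tf") == ["cs2"]

    def test_min_fold_one_passes_everything(self):
        comp = small_compendium(n_genes=4)
        passing = cr.filter_condition_sets(comp, "g001", min_fold=1.0)
        assert passing == sorted(comp.condition_sets)

    def test_all_missing_tf_excluded(self):
        X = np.zeros((2, 5))
        X[0, :3] = np.nan
        X[0, 3:] = [0, 5]
        comp = compendium_from_matrix(X, ["tf", "g1"],
                                      [("cs1", 3), ("cs2", 2)])
        assert cr.filter_condition_sets(comp, "tf") == ["cs2"]


class TestPerGeneCorrelations:
    def test_targets_equal_to_tf_give_r_one(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=8)
        X = np.vstack([z, z, z, z, rng.normal(size=8)])
        comp = compendium_from_matrix(X, ["tf", "t1", "t2", "t3", "other"],
                                      [("cs1", 8)])
        r = cr.per_gene_correlations(comp, "tf", ["t1", "t2", "t3"], "cs1")
        assert np.allclose(r.values, 1.0)

    def test_negated_targets_give_r_minus_one(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=8)
        X = np.vstack([z, -z, -(z**3)])
        comp = compendium_from_matrix(X, ["tf", "t1", "t2"], [("cs1", 8)])
        r = cr.per_gene_correlations(comp, "tf", ["t1", "t2"], "cs1")
        assert np.allclose(r.values, -1.0)

    def test_too_few_arrays_raises(self):
        comp = small_compendium(n_genes=4, sets=(("cs1", 4), ("cs2", 6)))
        with pytest.raises(ValueError):
            cr.per_gene_correlations(comp, "g001", ["g002"], "cs1",
                                     min_arrays=6)

    def test_absent_target_skipped(self):
        comp = small_compendium(n_genes=4, sets=(("cs1", 8), ("cs2", 8)))
        r = cr.per_gene_correlations(comp, "g001", ["g002", "ghost"], "cs1")
        assert list(r.index) == ["g002"]


class TestMedianStatistic:
    @pytest.mark.parametrize("values,expected", [
        ((0.9, 0.8, 0.5, 0.2, -0.1), 0.5),
        ((-0.7, -0.6, 0.1), -0.6),
        ((-0.4, -0.2, 0.2, 0.4), 0.0),
    ])
    def test_order_statistic(self, values, expected):
        assert cr.median_statistic(values) == pytest.approx(expected)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            cr.median_statistic([])
        with pytest.raises(ValueError):
            cr.median_statistic([np.nan])


class TestPermutationPvalue:
    def exhaustive_p(self, gene_r, size, observed, tail):
        hits = total = 0
        for combo in itertools.combinations(gene_r, size):
            med = float(np.median(combo))
            total += 1
            if tail == "upper" and med >= observed - 1e-12:
                hits += 1
            if tail == "lower" and med <= observed + 1e-12:
                hits += 1
        return hits / total

    @pytest.mark.parametrize("config_seed", range(6))
    def test_matches_exhaustive_enumeration(self, config_seed):
        rng = np.random.default_rng(config_seed)
        m = 10
        z = rng.normal(size=m)
        X = np.vstack([z] + [0.5 * z + rng.normal(size=m) for _ in range(10)])
        genes = ["tf"] + [f"g{i}" for i in range(10)]
        comp = compendium_from_matrix(X, genes, [("cs1", m)])
        size = int(rng.integers(2, 6))
        tail = "upper" if config_seed % 2 == 0 else "lower"
        obs = float(rng.uniform(-0.6, 0.6))
        n_perm = 10000
        spec = cr.PermutationSpec(n_perm=n_perm, seed=100 + config_seed)
        p_hat = cr.permutation_pvalue(comp, "tf", size, "cs1", obs, tail, spec)
        gene_r = cr._universe_correlations(comp, "tf", "cs1", "spearman").values
        exact = self.exhaustive_p(gene_r, size, obs, tail)
        se = math.sqrt(max(exact * (1 - exact), 1e-12) / n_perm)
        assert abs(p_hat - exact) <= 3 * se + 2 / (n_perm + 1)

    def test_floor_of_estimator(self):
        rng = np.random.default_rng(9)
        m = 8
        z = rng.normal(size=m)
        X = np.vstack([z] + [rng.normal(size=m) for _ in range(12)])
        genes = ["tf"] + [f"g{i}" for i in range(12)]
        comp = compendium_from_matrix(X, genes, [("cs1", m)])
        spec = cr.PermutationSpec(n_perm=2000, seed=1)
        # an observed median larger than any possible draw
        p = cr.permutation_pvalue(comp, "tf", 3, "cs1", 1.1, "upper", spec)
        assert p == pytest.approx(1 / 2001)

    def test_null_observed_gives_half(self):
        rng = np.random.default_rng(10)
        m = 10
        X = rng.normal(size=(40, m))
        genes = ["tf"] + [f"g{i}" for i in range(39)]
        comp = compendium_from_matrix(X, genes, [("cs1", m)])
        gene_r = cr._universe_correlations(comp, "tf", "cs1", "spearman").values
        centre = float(np.median(gene_r))
        spec = cr.PermutationSpec(n_perm=4000, seed=2)
        p = cr.permutation_pvalue(comp, "tf", 5, "cs1", centre, "upper", spec)
        assert 0.35 < p < 0.65

    def test_zero_set_size_raises(self):
        comp = small_compendium(n_genes=5, sets=(("cs1", 6), ("cs2", 6)))
        spec = cr.PermutationSpec(n_perm=10, seed=0)
        with pytest.raises(ValueError):
            cr.permutation_pvalue(comp, "g001", 0, "cs1", 0.0, "upper", spec)


class TestBHAdjust:
    def test_single_p(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1,
                    max_size=40))
    def test_q_at_least_p_and_matches_statsmodels(self, ps):
        from statsmodels.stats.multitest import multipletests
        q = bh_adjust(ps)
        assert (q >= np.asarray(ps) - 1e-15).all()
        _, q_ref, _, _ = multipletests(ps, method="fdr_bh")
        np.testing.assert_allclose(q, q_ref, atol=1e-12)

    def test_out_of_domain_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDispersionFilter:
    def test_constructed_coupling_gives_small_p(self):
        rng = np.random.default_rng(3)
        m = 14
        z = np.linspace(0, 2, m) + rng.normal(0, 0.05, m)
        # targets spread proportionally to the TF level
        offsets = rng.normal(0, 1, size=20)
        X = [z]
        for off in offsets:
            X.append(off * z + rng.normal(0, 0.05, m))
        for _ in range(30):  # background genes
            X.append(rng.normal(0, 0.3, size=m))
        genes = ["tf"] + [f"t{i}" for i in range(20)] + \
            [f"b{i}" for i in range(30)]
        comp = compendium_from_matrix(np.vstack(X), genes, [("cs1", m)])
        spec = cr.PermutationSpec(n_perm=500, seed=4)
        stat, p = cr.dispersion_coupling_filter(
            comp, "tf", [f"t{i}" for i in range(20)], "cs1", spec)
        assert stat > 0.8
        assert p < 0.01

    def test_independent_targets_null_p_uniform(self):
        ps = []
        for seed in range(25):
            rng = np.random.default_rng(200 + seed)
            m = 12
            X = rng.normal(size=(30, m))
            genes = ["tf"] + [f"g{i}" for i in range(29)]
            comp = compendium_from_matrix(X, genes, [("cs1", m)])
            spec = cr.PermutationSpec(n_perm=200, seed=seed)
            _, p = cr.dispersion_coupling_filter(
                comp, "tf", [f"g{i}" for i in range(10)], "cs1", spec)
            ps.append(p)
        # under the null p should not pile up near zero
        assert np.mean(np.asarray(ps) < 0.1) < 0.4
        assert np.mean(ps) > 0.25

    def test_constant_targets_fail_closed(self):
        m = 10
        rng = np.random.default_rng(5)
        X = np.vstack([rng.normal(size=m), np.ones(m), np.ones(m),
                       rng.normal(size=m)])
        comp = compendium_from_matrix(X, ["tf", "t1", "t2", "g1"],
                                      [("cs1", m)])
        spec = cr.PermutationSpec(n_perm=100, seed=6)
        stat, p = cr.dispersion_coupling_filter(comp, "tf", ["t1", "t2"],
                                                "cs1", spec)
        assert np.isnan(stat) and np.isnan(p)

    def test_permutation_null_agrees_in_direction(self):
        rng = np.random.default_rng(7)
        m = 12
        z = np.linspace(0, 2, m)
        X = [z]
        for off in rng.normal(0, 1, size=15):
            X.append(off * z + rng.normal(0, 0.05, m))
        for _ in range(60):
            X.append(rng.normal(0, 0.3, size=m))
        genes = ["tf"] + [f"t{i}" for i in range(15)] + \
            [f"b{i}" for i in range(60)]
        comp = compendium_from_matrix(np.vstack(X), genes, [("cs1", m)])
        spec = cr.PermutationSpec(n_perm=400, seed=8)
        _, p_perm = cr.dispersion_coupling_filter(
            comp, "tf", [f"t{i}" for i in range(15)], "cs1", spec,
            null="permutation")
        assert p_perm < 0.05


class TestSelectConditionalGenes:
    def test_strictly_above_median_for_activator(self):
        r = pd.Series([0.9, 0.8, 0.5, 0.2, -0.1],
                      index=["a", "b", "c", "d", "e"])
        assert cr.select_conditional_genes(r, "activator") == {"a", "b"}

    def test_strictly_below_median_for_repressor(self):
        r = pd.Series([-0.9, -0.7, -0.5, 0.1], index=list("abcd"))
        assert cr.select_conditional_genes(r, "repressor") == {"a", "b"}

    def test_all_equal_selects_nothing(self):
        r = pd.Series([0.5, 0.5, 0.5], index=list("abc"))
        assert cr.select_conditional_genes(r, "activator") == frozenset()

    @pytest.mark.parametrize("n", [3, 4, 7, 10])
    def test_distinct_values_select_floor_half(self, n):
        rng = np.random.default_rng(n)
        r = pd.Series(rng.permutation(np.linspace(-1, 1, n)),
                      index=[f"g{i}" for i in range(n)])
        sel = cr.select_conditional_genes(r, "activator")
        assert len(sel) == n // 2 if n % 2 == 1 else len(sel) == n // 2


@pytest.fixture(scope="module")
def planted_run():
    from ffrpnet import synthetic_data as sd
    base = sd.SimulationConfig(n_genes=400, n_operons=100, n_tfs=2,
                               n_condition_sets=6, arrays_per_set=(10, 14),
                               targets_per_tf=(60, 80), seed=7)
    ann = sd.generate_annotation(base)
    tfs = sd.plant_ground_truth(base, ann).tf_ids
    cfg = sd.SimulationConfig(
        n_genes=400, n_operons=100, n_tfs=2, n_condition_sets=6,
        arrays_per_set=(10, 14), targets_per_tf=(60, 80), seed=7,
        planted_regulons=[
            sd.PlantedRegulon(tfs[0], "cs02", "activator"),
            sd.PlantedRegulon(tfs[1], "cs04", "repressor"),
        ])
    gt = sd.plant_ground_truth(cfg, ann)
    comp = sd.generate_compendium(cfg, gt)
    spec = cr.PermutationSpec(n_perm=3000, seed=11)
    results = cr.call_regulons(comp, gt.targets, spec)
    return gt, comp, spec, results


class TestCallRegulons:
    def test_planted_activator_and_repressor_called(self, planted_run):
        gt, _, _, results = planted_run
        by_key = {(r.tf, r.condition_set): r for r in results}
        for (tf, cs), role in gt.roles.items():
            r = by_key[(tf, cs)]
            assert r.called, f"({tf},{cs}) not called"
            assert r.role == role
            if role == "activator":
                assert r.median_r > 0.4
            else:
                assert r.median_r < -0.4

    def test_selected_genes_overlap_planted_coupled(self, planted_run):
        gt, _, _, results = planted_run
        by_key = {(r.tf, r.condition_set): r for r in results}
        for key, coupled in gt.coupled.items():
            sel = set(by_key[key].selected_genes)
            jac = len(sel & coupled) / len(sel | coupled)
            assert jac >= 0.5
            assert sel <= gt.targets[key[0]]

    def test_reproducible_with_same_seed(self, planted_run):
        gt, comp, spec, results = planted_run
        again = cr.call_regulons(comp, gt.targets, spec)
        for r1, r2 in zip(results, again):
            assert (r1.tf, r1.condition_set) == (r2.tf, r2.condition_set)
            assert r1.permuted_p == r2.permuted_p
            assert r1.bh_q == r2.bh_q
            assert r1.selected_genes == r2.selected_genes

    def test_invariant_to_row_and_column_order(self, planted_run):
        gt, comp, spec, results = planted_run
        rng = np.random.default_rng(0)
        shuffled = comp.matrix.iloc[rng.permutation(len(comp.matrix)),
                                    rng.permutation(comp.matrix.shape[1])]
        comp2 = ExpressionCompendium(shuffled, comp.manifest)
        again = cr.call_regulons(comp2, gt.targets, spec)
        for r1, r2 in zip(results, again):
            assert r1.permuted_p == r2.permuted_p
            assert r1.selected_genes == r2.selected_genes

    def test_permuted_p_within_estimator_bounds(self, planted_run):
        _, _, spec, results = planted_run
        for r in results:
            assert 1 / (spec.n_perm + 1) <= r.permuted_p <= 1.0
            assert 1 / (spec.n_perm + 1) <= r.p_upper <= 1.0
            assert 1 / (spec.n_perm + 1) <= r.p_lower <= 1.0

    def test_results_frame_schema(self, planted_run):
        _, _, _, results = planted_run
        frame = cr.results_to_frame(results)
        assert list(frame.columns) == [
            "tf", "condition_set", "role", "fold_change", "median_r",
            "permuted_p", "bh_q", "dispersion_p", "called", "n_selected"]
        assert len(frame) == len(results)
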