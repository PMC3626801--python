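import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexnet import (
    ModuleAssignment,
    cluster_and_cut,
    module_eigengenes,
    module_group_test,
    module_membership,
    module_preservation,
    module_trait_correlation,
    scaled_intramodular_connectivity,
    signed_adjacency,
    topological_overlap,
)
from coexnet.network import AdjacencyMatrix


def _assignment(labels: dict) -> ModuleAssignment:
    return ModuleAssignment(labels=pd.Series(labels))


def _expr(data, genes=None, samples=None):
    data = np.asarray(data, dtype=float)
    genes = genes or [f"g{i}" for i in range(data.shape[0])]
    samples = samples or [f"s{j}" for j in range(data.shape[1])]
    return pd.DataFrame(data, index=genes, columns=samples)


class TestModuleEigengenes:
    def test_identical_profiles_rank_one(self, rng):
        profile = rng.standard_normal(15)
        expr = _expr(np.vstack([2 * profile + 1, profile - 3, 0.5 * profile]))
        assignment = _assignment({"g0": "blue", "g1": "blue", "g2": "blue"})
        mes = module_eigengenes(expr, assignment)
        r = np.corrcoef(mes.eigengenes["blue"], profile)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-12)
        assert mes.variance_explained["blue"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_eigenvector_oracle(self, rng):
        expr = _expr(rng.standard_normal((10, 25)))
        assignment = _assignment({f"g{i}": "blue" for i in range(10)})
        mes = module_eigengenes(expr, assignment)
        # oracle: leading eigenvector of the gene-gene correlation matrix,
        # projected back to sample space
        x = expr.to_numpy()
        xz = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
        corr = np.corrcoef(x)
        w, v = np.linalg.eigh(corr)
        lead = v[:, np.argmax(w)]
        me_oracle = lead @ xz
        me_oracle = (me_oracle - me_oracle.mean()) / me_oracle.std(ddof=1)
        r = np.corrcoef(mes.eigengenes["blue"], me_oracle)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-8)
        # variance explained agrees with the eigenvalue share
        assert mes.variance_explained["blue"] == pytest.approx(
            w.max() / w.sum(), abs=1e-6
        )

    def test_orientation_mean_kme_nonnegative(self, rng):
        expr = _expr(rng.standard_normal((8, 20)))
        assignment = _assignment({f"g{i}": "blue" for i in range(8)})
        mes = module_eigengenes(expr, assignment)
        kme = module_membership(expr, mes)
        assert kme["blue"].mean() >= 0

    def test_gene_scaling_invariance(self, rng):
        expr = _expr(rng.standard_normal((6, 15)))
        assignment = _assignment({f"g{i}": "blue" for i in range(6)})
        scaled = expr.copy()
        scaled.iloc[0] *= 17.0
        a = module_eigengenes(expr, assignment)
        b = module_eigengenes(scaled, assignment)
        np.testing.assert_allclose(
            a.eigengenes.to_numpy(), b.eigengenes.to_numpy(), atol=1e-10
        )

    def test_constant_module_raises(self):
        expr = _expr(np.ones((2, 10)))
        assignment = _assignment({"g0": "blue", "g1": "blue"})
        with pytest.raises(ValueError, match="blue"):
            module_eigengenes(expr, assignment)

    def test_unit_variance(self, rng):
        expr = _expr(rng.standard_normal((5, 12)))
        mes = module_eigengenes(expr, _assignment({f"g{i}": "m" for i in range(5)}))
        assert mes.eigengenes["m"].std(ddof=1) == pytest.approx(1.0)


class TestModuleMembership:
    def test_gene_identical_to_me(self, rng):
        expr = _expr(rng.standard_normal((5, 20)))
        assignment = _assignment({f"g{i}": "blue" for i in range(5)})
        mes = module_eigengenes(expr, assignment)
        expr2 = pd.concat(
            [expr, mes.eigengenes["blue"].rename("gX").to_frame().T]
        )
        kme = module_membership(expr2, mes)
        assert kme.loc["gX", "blue"] == pytest.approx(1.0)

    def test_equals_direct_pearson(self, rng):
        expr = _expr(rng.standard_normal((6, 18)))
        assignment = _assignment({f"g{i}": "blue" for i in range(6)})
        mes = module_eigengenes(expr, assignment)
        kme = module_membership(expr, mes)
        for g in expr.index:
            expected, _ = stats.pearsonr(expr.loc[g], mes.eigengenes["blue"])
            assert kme.loc[g, "blue"] == pytest.approx(expected, abs=1e-12)

    def test_constant_gene_nan(self, rng):
        expr = _expr(rng.standard_normal((4, 10)))
        expr.iloc[0] = 5.0
        assignment = _assignment({f"g{i}": "blue" for i in range(1, 4)})
        mes = module_eigengenes(expr, assignment)
        with pytest.warns(UserWarning, match="constant"):
            kme = module_membership(expr, mes)
        assert np.isnan(kme.loc["g0", "blue"])


class TestScaledConnectivity:
    def test_hand_summed_three_genes(self):
        a = np.array(
            [[1.0, 0.5, 0.3], [0.5, 1.0, 0.2], [0.3, 0.2, 1.0]]
        )
        adj = AdjacencyMatrix(values=pd.DataFrame(
            a, index=["g0", "g1", "g2"], columns=["g0", "g1", "g2"]))
        table = scaled_intramodular_connectivity(
            adj, _assignment({"g0": "m", "g1": "m", "g2": "m"})
        )
        np.testing.assert_allclose(table["kIN"], [0.8, 0.7, 0.5])
        np.testing.assert_allclose(table["scaled_kIN"], [1.0, 0.875, 0.625])

    def test_hub_scaled_to_one(self, three_module_study):
        study, _ = three_module_study
        adj = signed_adjacency(study.expression)
        tom = topological_overlap(adj)
        assignment = cluster_and_cut(tom, min_module_size=30)
        table = scaled_intramodular_connectivity(adj, assignment)
        for label in assignment.module_sizes().index:
            sub = table[table["module"] == label]
            assert (sub["scaled_kIN"] == 1.0).sum() == 1
            assert sub["scaled_kIN"].between(0, 1).all()

    def test_two_gene_module_both_one(self):
        a = np.array([[1.0, 0.4], [0.4, 1.0]])
        adj = AdjacencyMatrix(values=pd.DataFrame(
            a, index=["g0", "g1"], columns=["g0", "g1"]))
        table = scaled_intramodular_connectivity(
            adj, _assignment({"g0": "m", "g1": "m"})
        )
        np.testing.assert_allclose(table["scaled_kIN"], [1.0, 1.0])

    def test_singleton_module_missing(self):
        a = np.eye(2)
        adj = AdjacencyMatrix(values=pd.DataFrame(
            a, index=["g0", "g1"], columns=["g0", "g1"]))
        table = scaled_intramodular_connectivity(
            adj, _assignment({"g0": "m", "g1": "grey"})
        )
        assert np.isnan(table.loc["g0", "scaled_kIN"])

    def test_kme_tracks_connectivity(self, three_module_study):
        study, _ = three_module_study
        adj = signed_adjacency(study.expression)
        assignment = cluster_and_cut(topological_overlap(adj), min_module_size=30)
        table = scaled_intramodular_connectivity(
            adj, assignment, expression=study.expression
        )
        label = assignment.module_sizes().index[0]
        sub = table[table["module"] == label].dropna()
        rho = stats.spearmanr(sub["kME"], sub["scaled_kIN"]).statistic
        assert rho > 0.5


class TestModuleTraitCorrelation:
    def test_trait_equal_to_me(self, small_trait_study):
        study, _ = small_trait_study
        assignment = _assignment(
            {g: ("M1" if g.startswith("M1") else "grey") for g in study.genes}
        )
        mes = module_eigengenes(study.expression, assignment)
        pheno = study.phenotypes.copy()
        pheno["fake"] = mes.eigengenes["M1"]
        result = module_trait_correlation(mes, pheno, "fake")
        assert result["R"].iloc[0] == pytest.approx(1.0)

    def test_planted_effect_recovered_and_permutation_p(self):
        from coexnet import ModuleSpec, SyntheticDesign, generate_study_truth

        design = SyntheticDesign(
            modules=[ModuleSpec("M1", 30, factor_loading=0.95, trait_effect=0.6)],
            samples_per_group={"B": 200},
            noise_sd=0.3,
            seed=17,
        )
        study, truth = generate_study_truth(design)
        assignment = _assignment({g: "M1" for g in study.genes})
        mes = module_eigengenes(study.expression, assignment)
        result = module_trait_correlation(mes, study.phenotypes, "GCR")
        r_obs = result["R"].iloc[0]
        assert r_obs == pytest.approx(0.6, abs=0.1)
        # permutation oracle for the p-value
        rng = np.random.default_rng(1)
        me = mes.eigengenes["M1"].to_numpy()
        trait = study.phenotypes["GCR"].to_numpy()
        perm = np.array(
            [abs(np.corrcoef(me, rng.permutation(trait))[0, 1]) for _ in range(10000)]
        )
        p_perm = (1 + (perm >= abs(r_obs)).sum()) / 10001
        p_t = result["p"].iloc[0]
        # both are essentially 0 at n=200, r=0.6
        assert p_t < 1e-6 and p_perm < 1e-3

    def test_permutation_p_agrees_at_moderate_signal(self, rng):
        me = rng.standard_normal(30)
        trait = 0.35 * me + rng.standard_normal(30)
        r, p_t = stats.pearsonr(me, trait)
        perm = np.array(
            [abs(np.corrcoef(me, rng.permutation(trait))[0, 1]) for _ in range(10000)]
        )
        p_perm = (1 + (perm >= abs(r)).sum()) / 10001
        assert p_perm == pytest.approx(p_t, abs=3 * np.sqrt(p_t * (1 - p_t) / 10000) + 1e-3)

    def test_sample_filter(self, small_trait_study):
        study, _ = small_trait_study
        assignment = _assignment(
            {g: ("M1" if g.startswith("M1") else "grey") for g in study.genes}
        )
        mes = module_eigengenes(study.expression, assignment)
        mask = study.phenotypes["group"] != "A"
        result = module_trait_correlation(
            mes, study.phenotypes, "GCR", sample_filter=mask
        )
        assert result["n"].iloc[0] == int(mask.sum())

    def test_all_missing_trait_raises(self, small_trait_study):
        study, _ = small_trait_study
        assignment = _assignment(
            {g: ("M1" if g.startswith("M1") else "grey") for g in study.genes}
        )
        mes = module_eigengenes(study.expression, assignment)
        pheno = study.phenotypes.copy()
        pheno["empty"] = np.nan
        with pytest.raises(ValueError):
            module_trait_correlation(mes, pheno, "empty")

    def test_constant_trait_raises(self, small_trait_study):
        study, _ = small_trait_study
        assignment = _assignment(
            {g: ("M1" if g.startswith("M1") else "grey") for g in study.genes}
        )
        mes = module_eigengenes(study.expression, assignment)
        pheno = study.phenotypes.copy()
        pheno["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            module_trait_correlation(mes, pheno, "flat")


class TestModuleGroupTest:
    @staticmethod
    def _mes_from_values(values, samples):
        eg = pd.DataFrame({"m": values}, index=samples)
        from coexnet.module_stats import ModuleEigengenes

        return ModuleEigengenes(
            eigengenes=eg,
            variance_explained=pd.Series({"m": 1.0}),
            orientation=pd.Series({"m": 1.0}),
        )

    def test_identical_values_h_zero_p_one(self):
        samples = [f"s{i}" for i in range(12)]
        pheno = pd.DataFrame(
            {"group": ["A"] * 4 + ["B"] * 4 + ["C"] * 4}, index=samples
        )
        mes = self._mes_from_values(np.ones(12), samples)
        out = module_group_test(mes, pheno)
        assert out["kruskal_H"].iloc[0] == 0.0
        assert out["kruskal_p"].iloc[0] == 1.0

    def test_shifted_group_detected_and_f_oracle(self, rng):
        samples = [f"s{i}" for i in range(30)]
        groups = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        values = rng.standard_normal(30)
        values[20:] += 3.0
        pheno = pd.DataFrame({"group": groups}, index=samples)
        mes = self._mes_from_values(values, samples)
        out = module_group_test(mes, pheno)
        assert out["anova_p"].iloc[0] < 0.05
        assert out["kruskal_p"].iloc[0] < 0.05
        # textbook between/within variance ratio
        arrays = [values[:10], values[10:20], values[20:]]
        grand = values.mean()
        ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
        ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
        f_oracle = (ss_between / 2) / (ss_within / 27)
        assert out["anova_F"].iloc[0] == pytest.approx(f_oracle, rel=1e-10)

    def test_two_groups_f_equals_t_squared(self, rng):
        samples = [f"s{i}" for i in range(20)]
        values = rng.standard_normal(20)
        pheno = pd.DataFrame({"group": ["A"] * 10 + ["B"] * 10}, index=samples)
        mes = self._mes_from_values(values, samples)
        out = module_group_test(mes, pheno)
        t, _ = stats.ttest_ind(values[:10], values[10:])
        assert out["anova_F"].iloc[0] == pytest.approx(t**2, rel=1e-10)

    def test_small_group_raises(self, rng):
        samples = [f"s{i}" for i in range(5)]
        pheno = pd.DataFrame({"group": ["A"] * 4 + ["B"]}, index=samples)
        mes = self._mes_from_values(rng.standard_normal(5), samples)
        with pytest.raises(ValueError, match="B"):
            module_group_test(mes, pheno)

    def test_anova_kw_agreement_on_shifted_modules(self, rng):
        agree = 0
        total = 40
        for i in range(total):
            values = rng.standard_normal(24)
            values[16:] += 2.5  # strong shift
            samples = [f"s{j}" for j in range(24)]
            pheno = pd.DataFrame(
                {"group": ["A"] * 8 + ["B"] * 8 + ["C"] * 8}, index=samples
            )
            out = module_group_test(self._mes_from_values(values, samples), pheno)
            if (out["anova_p"].iloc[0] < 0.05) == (out["kruskal_p"].iloc[0] < 0.05):
                agree += 1
        assert agree / total >= 0.9


class TestModulePreservation:
    def test_self_preservation_strong(self, three_module_study):
        study, _ = three_module_study
        tom = topological_overlap(signed_adjacency(study.expression))
        assignment = cluster_and_cut(tom, min_module_size=30)
        result = module_preservation(
            study.expression, assignment, study.expression,
            n_permutations=50, seed=1,
        )
        assert (result.table["Z_summary"] > 10).all()

    def test_random_module_null(self, three_module_study):
        from coexnet import ModuleSpec, SyntheticDesign, generate_study

        study, truth = three_module_study
        rng = np.random.default_rng(2)
        background = [g for g in study.genes if g.startswith("BG")]
        chosen = set(rng.choice(background, 50, replace=False))
        labels = pd.Series(
            ["rand" if g in chosen else "grey" for g in study.genes],
            index=study.genes,
        )
        # test data without any planted structure: all genes exchangeable,
        # so a random gene set must look unpreserved
        other = generate_study(
            SyntheticDesign(
                modules=[ModuleSpec("M1", 100, factor_loading=0.0),
                         ModuleSpec("M2", 80, factor_loading=0.0),
                         ModuleSpec("M3", 60, factor_loading=0.0)],
                n_background_genes=100, samples_per_group={"A": 40},
                noise_sd=0.5, seed=777,
            )
        )
        result = module_preservation(
            study.expression, ModuleAssignment(labels=labels), other.expression,
            n_permutations=50, seed=3,
        )
        assert abs(result.table["Z_summary"].iloc[0]) < 2

    def test_deterministic(self, three_module_study):
        study, _ = three_module_study
        labels = pd.Series(
            ["m" if g.startswith("M1") else "grey" for g in study.genes],
            index=study.genes,
        )
        kwargs = dict(n_permutations=20, seed=9)
        a = module_preservation(
            study.expression, ModuleAssignment(labels=labels),
            study.expression, **kwargs,
        )
        b = module_preservation(
            study.expression, ModuleAssignment(labels=labels),
            study.expression, **kwargs,
        )
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_too_few_permutations_raises(self, three_module_study):
        study, _ = three_module_study
        labels = pd.Series("m", index=study.genes)
        with pytest.raises(ValueError, match="n_permutations"):
            module_preservation(
                study.expression, ModuleAssignment(labels=labels),
                study.expression, n_permutations=10,
            )

    def test_absent_module_missing_result(self, three_module_study):
        study, _ = three_module_study
        labels = pd.Series(
            ["m" if g.startswith("M1") else "grey" for g in study.genes],
            index=study.genes,
        )
        test_expr = study.expression.loc[
            [g for g in study.genes if not g.startswith("M1")]
        ]
        result = module_preservation(
            study.expression, ModuleAssignment(labels=labels), test_expr,
            n_permutations=20,
        )
        assert np.isnan(result.table["Z_summary"].iloc[0])
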