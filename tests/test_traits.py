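"""Eigengenes, module-trait statistics, hub screening, stage ANOVA."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.decomposition import PCA

from lncwgcna.network import ModuleAssignment, adjacency, average_linkage, detect_modules, tom_similarity
from lncwgcna.simulate import STAGE_ORDER, SimulationConfig, simulate_expression
from lncwgcna.traits import (
    P_FLOOR,
    cor_with_p,
    identify_hubs,
    module_eigengene,
    module_eigengenes,
    module_significance,
    screening_stats,
    select_significant_module,
    stage_anova,
    trait_scores,
)


def _assignment_from_truth(truth):
    return ModuleAssignment(labels=truth.module_labels.copy(), cut_height=np.nan)


class TestCorWithP:
    def test_self_and_anti_correlation(self, rng):
        x = rng.standard_normal(15)
        assert cor_with_p(x, x) == (1.0, P_FLOOR)
        assert cor_with_p(x, -x) == (-1.0, P_FLOOR)

    def test_p_matches_t_distribution_oracle(self):
        # r = 0.5, n = 22: p = 2 * P(T_20 > 0.5 * sqrt(20) / sqrt(0.75))
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.standard_normal(22)
            y = rng.standard_normal(22)
            r, p = cor_with_p(x, y)
            t = r * np.sqrt(20) / np.sqrt(1 - r**2)
            assert p == pytest.approx(2 * sps.t.sf(abs(t), 20), rel=1e-12)
            # independent oracle: scipy's exact pearson p
            assert p == pytest.approx(sps.pearsonr(x, y).pvalue, rel=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            cor_with_p(np.ones(10), np.arange(10.0))


class TestTraitScores:
    def test_monotone_and_standardized(self):
        stages = pd.Series(["normal"] * 7 + ["IPMA"] * 6 + ["IPMC"] * 6 + ["invasive"] * 3)
        z = trait_scores(stages, STAGE_ORDER)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=0) == pytest.approx(1.0)
        assert z[stages == "invasive"].iloc[0] > z[stages == "normal"].iloc[0]

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="mystery"):
            trait_scores(pd.Series(["normal", "mystery"]), STAGE_ORDER)


class TestModuleEigengene:
    def test_rank_one_module_recovers_common_profile(self, rng):
        profile = rng.standard_normal(12)
        m = pd.DataFrame(
            np.vstack([2 * profile + 1, 0.5 * profile - 3, profile]),
            index=list("abc"), columns=[f"s{j}" for j in range(12)],
        )
        me, ve = module_eigengene(m, list("abc"))
        z = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(me.to_numpy(), z, atol=1e-8)
        assert ve == pytest.approx(1.0)

    def test_recovers_planted_factor(self):
        rng = np.random.default_rng(0)
        n = 22
        f = rng.standard_normal(n)
        genes = np.sqrt(0.9) * f + np.sqrt(0.1) * rng.standard_normal((30, n))
        m = pd.DataFrame(genes, index=[f"g{i}" for i in range(30)])
        me, _ = module_eigengene(m, m.index)
        assert abs(np.corrcoef(me, f)[0, 1]) >= 0.95

    def test_matches_pca_oracle(self, rng):
        for _ in range(10):
            m = pd.DataFrame(rng.standard_normal((15, 10)))
            me, ve = module_eigengene(m, m.index)
            z = ((m.T - m.mean(axis=1)) / m.std(axis=1, ddof=1)).T.to_numpy()
            pca = PCA(n_components=1).fit(z.T)
            oracle = pca.transform(z.T)[:, 0]
            assert abs(np.corrcoef(me, oracle)[0, 1]) >= 0.999
            assert ve == pytest.approx(pca.explained_variance_ratio_[0], rel=1e-6)

    def test_unit_variance_and_sign_alignment(self, default_dataset):
        ds, truth = default_dataset
        genes = truth.module_labels.index[truth.module_labels == 1]
        me, _ = module_eigengene(ds.matrix, genes)
        assert me.std(ddof=1) == pytest.approx(1.0)
        mean_profile = ds.matrix.loc[genes].mean(axis=0)
        assert np.corrcoef(me, mean_profile)[0, 1] >= 0


class TestModuleSignificance:
    def test_genes_equal_to_trait_give_ms_one(self):
        stages = pd.Series(
            ["normal"] * 3 + ["IPMA"] * 3 + ["IPMC"] * 3 + ["invasive"] * 3,
            index=[f"s{j}" for j in range(12)],
        )
        trait = trait_scores(stages, STAGE_ORDER)
        m = pd.DataFrame(
            np.vstack([trait, -trait, trait]), index=list("abc"), columns=stages.index
        )
        # tiny jitter so genes are not exactly collinear for the SVD
        rng = np.random.default_rng(0)
        m += 1e-9 * rng.standard_normal(m.shape)
        asg = ModuleAssignment(labels=pd.Series([1, 1, 1], index=list("abc")), cut_height=np.nan)
        stats = module_significance(m, trait, asg)
        assert stats.loc[1, "MS"] == pytest.approx(1.0, abs=1e-6)

    def test_null_module_ms_near_theoretical_mean(self):
        # E|r| under the null is ~ sqrt(2 / (pi (n-1))) = 0.174 at n = 22
        cfg = dict(
            module_sizes=(30,), within_module_cor=(0.0,), trait_effect=(0.0,),
            n_background_genes=0, n_hub_genes=0,
        )
        ms = []
        for seed in range(200):
            ds, truth = simulate_expression(SimulationConfig(seed=seed, **cfg))
            trait = trait_scores(ds.stages, STAGE_ORDER)
            stats = module_significance(ds.matrix, trait, _assignment_from_truth(truth))
            ms.append(stats.loc[1, "MS"])
        expected = np.sqrt(2 / (np.pi * 21))
        assert abs(np.mean(ms) - expected) < 0.5 * expected

    def test_trait_module_beats_null_module(self):
        cfg = dict(
            module_sizes=(40, 40), within_module_cor=(0.7, 0.7),
            trait_effect=(-0.8, 0.0), n_background_genes=0, n_hub_genes=0,
        )
        wins = 0
        for seed in range(100):
            ds, truth = simulate_expression(SimulationConfig(seed=seed, **cfg))
            trait = trait_scores(ds.stages, STAGE_ORDER)
            stats = module_significance(ds.matrix, trait, _assignment_from_truth(truth))
            wins += stats.loc[1, "MS"] > stats.loc[2, "MS"]
        assert wins >= 95


class TestSelectSignificantModule:
    def test_single_module_selected(self):
        stats = pd.DataFrame({"MS": [0.4], "me_trait_r": [0.5]}, index=[1])
        assert select_significant_module(stats) == 1

    def test_tie_breaks_to_lower_label_with_warning(self):
        stats = pd.DataFrame(
            {"MS": [0.4, 0.4], "me_trait_r": [0.5, 0.3]}, index=[1, 2]
        )
        with pytest.warns(UserWarning, match="tie"):
            assert select_significant_module(stats) == 1

    def test_disagreement_warns_and_returns_ms_winner(self):
        stats = pd.DataFrame(
            {"MS": [0.6, 0.4], "me_trait_r": [0.2, -0.9]}, index=[1, 2]
        )
        with pytest.warns(UserWarning, match="disagree"):
            assert select_significant_module(stats) == 1


class TestScreeningStats:
    def _stats(self, seed=0, mix_weight=0.5):
        ds, truth = simulate_expression(SimulationConfig(seed=seed))
        trait = trait_scores(ds.stages, STAGE_ORDER)
        asg = _assignment_from_truth(truth)
        eigengenes, _ = module_eigengenes(ds.matrix, asg)
        return (
            screening_stats(ds.matrix, trait, asg, eigengenes, mix_weight),
            ds, truth, trait, eigengenes,
        )

    def test_mix_weight_zero_reproduces_standard(self):
        stats, *_ = self._stats(mix_weight=0.0)
        np.testing.assert_allclose(stats["cor.Weighted"], stats["cor.Standard"])

    def test_grey_genes_never_blended(self):
        stats, _, truth, *_ = self._stats()
        grey = truth.module_labels.index[truth.module_labels == 0]
        sub = stats.loc[grey]
        np.testing.assert_allclose(sub["cor.Weighted"], sub["cor.Standard"])

    def test_gene_equal_to_eigengene_blends_to_itself(self):
        stats, ds, truth, trait, eigengenes = self._stats()
        m2 = ds.matrix.copy()
        m2.loc["echo"] = eigengenes[1].loc[m2.columns].to_numpy()
        labels = pd.concat([truth.module_labels, pd.Series({"echo": 1})])
        asg = ModuleAssignment(labels=labels, cut_height=np.nan)
        st2 = screening_stats(m2, trait, asg, eigengenes)
        r_me, _ = cor_with_p(eigengenes[1].loc[m2.columns].to_numpy(), trait.loc[m2.columns].to_numpy())
        assert st2.loc["echo", "cor.Weighted"] == pytest.approx(r_me, abs=1e-9)
        assert st2.loc["echo", "cor.Standard"] == pytest.approx(r_me, abs=1e-9)

    def test_kme_of_module_members_is_high(self):
        stats, _, truth, *_ = self._stats()
        members = truth.module_labels.index[truth.module_labels == 1]
        assert stats.loc[members, "kME_1"].abs().median() > 0.7

    def test_blend_denoises_ordinary_module_members(self):
        # for a rho=0.7 member of a beta=-0.75 module, the blended trait
        # correlation beats the plain one in the vast majority of draws
        wins = total = 0
        cfg = dict(
            module_sizes=(60,), within_module_cor=(0.7,), trait_effect=(-0.75,),
            n_background_genes=0, n_hub_genes=0,
        )
        for seed in range(30):
            ds, truth = simulate_expression(SimulationConfig(seed=seed, **cfg))
            trait = trait_scores(ds.stages, STAGE_ORDER)
            asg = _assignment_from_truth(truth)
            eigengenes, _ = module_eigengenes(ds.matrix, asg)
            st = screening_stats(ds.matrix, trait, asg, eigengenes)
            wins += (st["cor.Weighted"].abs() >= st["cor.Standard"].abs()).sum()
            total += len(st)
        assert wins / total >= 0.8


class TestIdentifyHubs:
    def _frame(self, rows):
        df = pd.DataFrame(
            rows, columns=["cor.Weighted", "cor.Standard"],
            index=[f"g{i}" for i in range(len(rows))],
        )
        df["module"] = 1
        return df

    def test_published_style_rows_all_pass(self):
        stats = self._frame([(-0.948, -0.806), (-0.931, -0.802), (0.944, 0.881)])
        assert len(identify_hubs(stats, 1)) == 3

    def test_one_failing_criterion_rejects(self):
        stats = self._frame([(0.948, 0.79)])
        assert identify_hubs(stats, 1).empty

    def test_boundary_is_strict(self):
        stats = self._frame([(0.80, 0.80)])
        assert identify_hubs(stats, 1).empty

    def test_sorted_by_weighted_magnitude(self):
        stats = self._frame([(0.85, 0.9), (-0.95, -0.85), (0.9, 0.82)])
        assert list(identify_hubs(stats, 1).index) == ["g1", "g2", "g0"]

    def test_other_modules_excluded(self):
        stats = self._frame([(0.95, 0.95)])
        stats["module"] = 2
        assert identify_hubs(stats, 1).empty


class TestStageAnova:
    @staticmethod
    def _frame(groups):
        values = np.concatenate(groups)
        cols = [f"s{j}" for j in range(len(values))]
        stages = pd.Series(
            np.repeat(list(STAGE_ORDER)[: len(groups)], [len(g) for g in groups]),
            index=cols,
        )
        return pd.DataFrame([values], index=["g"], columns=cols), stages

    def test_identical_group_means_give_zero_f(self):
        m, stages = self._frame([[1, 2, 3], [1, 2, 3]])
        out = stage_anova(m, stages)
        assert out.loc["g", "F"] == 0.0 and out.loc["g", "p"] == 1.0

    def test_zero_within_variance_gives_floored_p(self):
        m, stages = self._frame([[1, 1, 1], [2, 2, 2]])
        out = stage_anova(m, stages)
        assert np.isinf(out.loc["g", "F"]) and out.loc["g", "p"] == P_FLOOR

    def test_hand_computed_example(self):
        # groups (1,2), (2,3), (4,5): F = (9.3333/2)/(1.5/3) = 9.3333 on (2,3) df
        m, stages = self._frame([[1, 2], [2, 3], [4, 5]])
        out = stage_anova(m, stages)
        assert out.loc["g", "F"] == pytest.approx(9.333333333, rel=1e-9)
        assert out.loc["g", "p"] == pytest.approx(0.05152212052, rel=1e-9)

    def test_small_group_named_in_error(self):
        m, stages = self._frame([[1, 2, 3], [4]])
        with pytest.raises(ValueError, match="IPMA"):
            stage_anova(m, stages)


class TestSignCoherence:
    def test_flipping_stage_coding_flips_correlations_only(self, default_dataset):
        ds, truth = default_dataset
        asg = _assignment_from_truth(truth)
        eigengenes, _ = module_eigengenes(ds.matrix, asg)
        fwd = trait_scores(ds.stages, STAGE_ORDER)
        rev = trait_scores(ds.stages, tuple(reversed(STAGE_ORDER)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            st_f = screening_stats(ds.matrix, fwd, asg, eigengenes)
            st_r = screening_stats(ds.matrix, rev, asg, eigengenes)
            ms_f = module_significance(ds.matrix, fwd, asg, eigengenes)
            ms_r = module_significance(ds.matrix, rev, asg, eigengenes)
        np.testing.assert_allclose(st_f["cor.Standard"], -st_r["cor.Standard"], atol=1e-12)
        np.testing.assert_allclose(st_f["cor.Weighted"], -st_r["cor.Weighted"], atol=1e-12)
        np.testing.assert_allclose(ms_f["MS"], ms_r["MS"], atol=1e-12)
        hubs_f = identify_hubs(st_f, 1)
        hubs_r = identify_hubs(st_r, 1)
        assert set(hubs_f.index) == set(hubs_r.index)
        anova_f = stage_anova(ds.matrix, ds.stages)
        np.testing.assert_allclose(anova_f["F"], stage_anova(ds.matrix, ds.stages)["F"])

    def test_ms_equals_mean_abs_cor_standard(self, default_dataset):
        ds, truth = default_dataset
        asg = _assignment_from_truth(truth)
        trait = trait_scores(ds.stages, STAGE_ORDER)
        eigengenes, _ = module_eigengenes(ds.matrix, asg)
        ms = module_significance(ds.matrix, trait, asg, eigengenes)
        st = screening_stats(ds.matrix, trait, asg, eigengenes)
        for m in ms.index:
            members = truth.module_labels.index[truth.module_labels == m]
            assert ms.loc[m, "MS"] == pytest.approx(
                st.loc[members, "cor.Standard"].abs().mean(), abs=1e-12
            )
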