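import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cochleashape import ou


@pytest.fixture(scope="module")
def scenario_trees():
    return {sid: ou.scenario_tree(sid) for sid in ou.SCENARIO_NEWICK}


class TestTrees:
    def test_newick_round_trip(self, tmp_path, scenario_trees):
        tree = scenario_trees["continuity_2.8Ma"]
        path = tmp_path / "tree.nwk"
        ou.write_newick(tree, path)
        back = ou.read_newick(path)
        assert set(back.tip_labels) == set(tree.tip_labels)
        la, Ta, tsa, _ = tree.path_times()
        lb, Tb, tsb, _ = back.path_times()
        order = [lb.index(x) for x in la]
        assert np.allclose(Tb[order], Ta, atol=1e-9)
        assert np.allclose(tsb[np.ix_(order, order)], tsa, atol=1e-9)

    def test_builtin_scenarios_match_calibration_ages(self, scenario_trees):
        # MRCA age of P. robustus and Homo: 2.8 Ma under continuity,
        # 3.5 Ma under the sister scenario (present = root depth 9 Ma)
        for sid, mrca_age in [("continuity_2.8Ma", 2.8), ("sister_3.5Ma", 3.5)]:
            tree = scenario_trees[sid]
            labels, T, t_sh, _ = tree.path_times()
            i = labels.index("Homo_sapiens")
            j = labels.index("Paranthropus_robustus")
            # Homo is an extant tip: its depth is the root age
            assert T[i] - t_sh[i, j] == pytest.approx(mrca_age)

    def test_missing_length_rejected(self):
        tree = dendropy.Tree.get(data="(a:1,b);", schema="newick")
        with pytest.raises(ValueError, match="length"):
            ou.ScenarioTree(tree=tree)

    def test_expand_tips_shares_tip_set(self, scenario_trees):
        n_spec = {t: 3 for t in scenario_trees["continuity_2.8Ma"].tip_labels}
        e1 = ou.expand_tips(scenario_trees["continuity_2.8Ma"], n_spec)
        e2 = ou.expand_tips(scenario_trees["sister_3.5Ma"], n_spec)
        assert set(e1.tip_labels) == set(e2.tip_labels)
        assert len(e1.tip_labels) == 18


class TestBMRelationship:
    def test_proportional_distances_give_max_correlation(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        rho, p = ou.bm_relationship_test(2.0 * t, t, n_perm=999, seed=0)
        assert rho == pytest.approx(1.0)
        assert p < 0.01

    def test_null_rejection_rate(self, rng):
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            d = rng.normal(size=8)
            t = rng.uniform(1, 10, size=8)
            _, p = ou.bm_relationship_test(
                d, t, n_perm=199, seed=int(rng.integers(2**31 - 1)))
            rejections += p <= 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.04)

    def test_seeded_reproducibility(self, rng):
        d, t = rng.normal(size=10), rng.uniform(1, 5, size=10)
        assert ou.bm_relationship_test(d, t, n_perm=500, seed=3) == \
            ou.bm_relationship_test(d, t, n_perm=500, seed=3)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            ou.bm_relationship_test([1, 2, 3], [1, 2, 3])


class TestCovariance:
    def test_bm_limit(self, scenario_trees):
        # alpha -> 0: cov -> sigma2 * shared path length on every tree
        for tree in scenario_trees.values():
            _, _, t_sh, _ = tree.path_times()
            _, C = ou.ou_tip_covariance(
                tree, ou.OUParams(alpha=1e-8, sigma2=1.0))
            assert np.abs(C - t_sh).max() < 1e-6

    def test_stationary_variance(self):
        tree = ou.ScenarioTree(dendropy.Tree.get(data="(a:50.0,b:50.0);",
                                                 schema="newick"))
        p = ou.OUParams(alpha=2.0, sigma2=3.0)
        _, C = ou.ou_tip_covariance(tree, p)
        assert np.allclose(np.diag(C), 3.0 / 4.0, atol=1e-8)

    def test_psd_over_random_parameters(self, rng, scenario_trees):
        for _ in range(100):
            p = ou.OUParams(alpha=float(rng.uniform(0.01, 5)),
                            sigma2=float(rng.uniform(0.1, 10)))
            tree = scenario_trees[
                list(scenario_trees)[int(rng.integers(2))]]
            _, C = ou.ou_tip_covariance(tree, p)
            assert np.linalg.eigvalsh(C).min() > -1e-10


class TestSimulation:
    def test_zero_diffusion_decays_to_theta(self, scenario_trees):
        tree = scenario_trees["continuity_2.8Ma"]
        p = ou.OUParams(alpha=1.0, sigma2=0.0, theta=2.0, x0=-1.0)
        sims = ou.ou_simulate(tree, p, n_reps=3, seed=0)
        labels, mean = ou.ou_tip_mean(tree, p)
        for rep in range(3):
            assert np.allclose(sims[labels].iloc[rep], mean, atol=1e-12)

    def test_empirical_covariance_matches_analytic(self, scenario_trees):
        tree = scenario_trees["continuity_2.8Ma"]
        p = ou.OUParams(alpha=0.4, sigma2=1.0, theta=1.0)
        sims = ou.ou_simulate(tree, p, n_reps=20_000, seed=1)
        labels, C = ou.ou_tip_covariance(tree, p)
        emp = np.cov(sims[labels].to_numpy().T)
        # each entry within 3 standard errors (~ sqrt(2/n) * var scale)
        se = 3 * np.sqrt(2.0 / 20_000) * np.outer(
            np.sqrt(np.diag(C)), np.sqrt(np.diag(C)))
        assert (np.abs(emp - C) < np.maximum(se, 1e-3)).all()

    def test_seeded_reproducibility(self, scenario_trees):
        tree = scenario_trees["sister_3.5Ma"]
        p = ou.OUParams(alpha=0.5, sigma2=1.0)
        s1 = ou.ou_simulate(tree, p, n_reps=5, seed=9)
        s2 = ou.ou_simulate(tree, p, n_reps=5, seed=9)
        assert s1.equals(s2)


class TestLikelihood:
    def test_two_tip_closed_form(self):
        tree = ou.ScenarioTree(dendropy.Tree.get(data="(a:1.0,b:1.0);",
                                                 schema="newick"))
        p = ou.OUParams(alpha=0.5, sigma2=2.0, theta=0.3, x0=-0.2)
        labels, C = ou.ou_tip_covariance(tree, p)
        _, m = ou.ou_tip_mean(tree, p)
        vals = {"a": 0.7, "b": -0.1}
        x = [vals[lab] for lab in labels]
        ref = stats.multivariate_normal(m, C).logpdf(x)
        assert ou.ou_loglik(vals, tree, p) == pytest.approx(ref)

    def test_dataframe_rows_are_independent_replicates(self):
        tree = ou.ScenarioTree(dendropy.Tree.get(data="(a:1.0,b:1.0);",
                                                 schema="newick"))
        p = ou.OUParams(alpha=0.5, sigma2=2.0)
        df = pd.DataFrame({"a": [0.7, 0.2], "b": [-0.1, 0.5]})
        separate = sum(ou.ou_loglik(df.iloc[i].to_dict(), tree, p)
                       for i in range(2))
        assert ou.ou_loglik(df, tree, p) == pytest.approx(separate)

    def test_profile_maximum_near_truth(self, rng):
        tree = ou.random_tree(40, seed=5, depth=10.0)
        truth = ou.OUParams(alpha=0.5, sigma2=1.0)
        sims = ou.ou_simulate(tree, truth, n_reps=20, seed=2)
        alphas = np.linspace(0.1, 2.0, 20)
        lls = [ou.ou_loglik(sims, tree,
                            ou.OUParams(alpha=a, sigma2=1.0))
               for a in alphas]
        best = alphas[int(np.argmax(lls))]
        assert abs(best - 0.5) < 0.3

    def test_displacement_decreases_likelihood(self):
        tree = ou.ScenarioTree(dendropy.Tree.get(data="(a:1.0,b:1.0);",
                                                 schema="newick"))
        p = ou.OUParams(alpha=0.5, sigma2=1.0, theta=0.0, x0=0.0)
        _, m = ou.ou_tip_mean(tree, p)
        lls = [ou.ou_loglik({"a": m[0] + d, "b": m[1] + d}, tree, p)
               for d in (0.0, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(lls[:-1], lls[1:]))


class TestMCMC:
    def test_seeded_chains_identical(self, scenario_trees):
        tree = scenario_trees["continuity_2.8Ma"]
        vals = ou.ou_simulate(tree, ou.OUParams(0.4, 1.0), 1,
                              seed=3).iloc[0].to_dict()
        f1 = ou.ou_fit_mcmc(vals, tree, n_iter=2000, seed=11)
        f2 = ou.ou_fit_mcmc(vals, tree, n_iter=2000, seed=11)
        assert f1["chain"].equals(f2["chain"])
        assert f1["acceptance_rate"] == f2["acceptance_rate"]

    def test_reports_all_parameters_and_rhat(self, scenario_trees):
        tree = scenario_trees["sister_3.5Ma"]
        vals = ou.ou_simulate(tree, ou.OUParams(0.4, 1.0), 1,
                              seed=4).iloc[0].to_dict()
        fit = ou.ou_fit_mcmc(vals, tree, n_iter=2000, seed=1)
        assert list(fit["summary"].index) == ["alpha", "sigma2", "theta", "x0"]
        assert np.isfinite(fit["summary"]["rhat"]).all()
        assert (fit["summary"]["ci5"] <= fit["summary"]["ci95"]).all()

    def test_minimum_iterations_enforced(self, scenario_trees):
        tree = scenario_trees["continuity_2.8Ma"]
        with pytest.raises(ValueError):
            ou.ou_fit_mcmc({t: 0.0 for t in tree.tip_labels}, tree,
                           n_iter=500)

    def test_posterior_concentrates_with_more_tips(self, rng):
        widths = []
        for n_tips in (10, 100):
            tree = ou.random_tree(n_tips, seed=17, depth=10.0)
            vals = ou.ou_simulate(tree, ou.OUParams(0.5, 1.0), 1,
                                  seed=23).iloc[0].to_dict()
            fit = ou.ou_fit_mcmc(vals, tree, n_iter=6000, seed=29)
            s = fit["summary"].loc["sigma2"]
            widths.append(np.log(s["ci95"]) - np.log(s["ci5"]))
        assert widths[1] < widths[0]


class TestScenarioComparison:
    def test_identical_trees_agree_up_to_mc_error(self, scenario_trees):
        tree = scenario_trees["continuity_2.8Ma"]
        vals = ou.ou_simulate(tree, ou.OUParams(0.3, 1.0), 1,
                              seed=6).iloc[0].to_dict()
        rep = ou.compare_scenarios(
            vals, {"one": tree, "two": tree}, n_iter=2000,
            n_rungs=8, n_iter_per_rung=1000, seed=2)
        d = abs(rep.loc["one", "logml_stepping_stone"]
                - rep.loc["two", "logml_stepping_stone"])
        assert d < 1.5

    def test_report_carries_calibration_ages(self, scenario_trees):
        vals = ou.ou_simulate(scenario_trees["continuity_2.8Ma"],
                              ou.OUParams(0.3, 1.0), 1,
                              seed=7).iloc[0].to_dict()
        rep = ou.compare_scenarios(
            vals, scenario_trees, n_iter=1500, n_rungs=6,
            n_iter_per_rung=800, seed=3)
        assert {"continuity_2.8Ma", "sister_3.5Ma"} == set(rep.index)
        assert rep.attrs["preferred"] in rep.index

    def test_tip_mismatch_rejected(self, scenario_trees):
        tree = scenario_trees["continuity_2.8Ma"]
        other = ou.random_tree(6, seed=1)
        vals = {t: 0.0 for t in tree.tip_labels}
        with pytest.raises(ValueError, match="tip"):
            ou.compare_scenarios(vals, {"a": tree, "b": other})


def test_ou_params_validation():
    with pytest.raises(ValueError):
        ou.OUParams(alpha=-0.1, sigma2=1.0)
    with pytest.raises(ValueError):
        ou.OUParams(alpha=0.1, sigma2=-1.0)
    assert ou.OUParams(alpha=0.0, sigma2=0.0).alpha == 0.0
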