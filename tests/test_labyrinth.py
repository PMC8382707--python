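import numpy as np
import pandas as pd
import pytest

from cochleashape import labyrinth as lab


def _measurements(rows):
    df = pd.DataFrame(rows, columns=["specimen_id"] + lab.MEASUREMENT_COLUMNS)
    return lab.LabyrinthMeasurements(table=df.set_index("specimen_id"))


class TestIndices:
    def test_ratio_arithmetic(self):
        m = _measurements([["a", 0.5, 40.0, 50.0, 16.0, 20.0, 19.0, 38.0]])
        idx = lab.compute_indices(m)
        assert idx.loc["a", "ECL/POL"] == pytest.approx(1.9)
        assert idx.loc["a", "HZL/POL"] == pytest.approx(0.8)
        assert idx.loc["a", "TLI"] == 0.5

    def test_equal_canals_give_unit_ratios(self):
        m = _measurements([["a", 0.5, 40.0, 50.0, 18.0, 18.0, 18.0, 36.0]])
        idx = lab.compute_indices(m)
        for col in ("HZL/ANL", "HZL/POL", "POL/ANL"):
            assert idx.loc["a", col] == pytest.approx(1.0)

    def test_missing_anl_masks_dependent_ratios(self):
        # damaged anterior canal: every ANL-based index is masked, the rest
        # stay usable (the incomplete-labyrinth variant analysis)
        m = _measurements([["kb", 0.5, 40.0, 50.0, 16.0, 20.0, np.nan, 38.0]])
        idx = lab.compute_indices(m)
        for col in ("HZL/ANL", "POL/ANL", "ECL/ANL"):
            assert np.isnan(idx.loc["kb", col])
        for col in ("HZL/POL", "ECL/HZL", "ECL/POL", "TLI"):
            assert np.isfinite(idx.loc["kb", col])

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError, match="arc length"):
            _measurements([["a", 0.5, 40.0, 50.0, -1.0, 20.0, 19.0, 38.0]])

    def test_angle_range_enforced(self):
        with pytest.raises(ValueError, match="angle"):
            _measurements([["a", 0.5, 190.0, 50.0, 16.0, 20.0, 19.0, 38.0]])


class TestIndexPCA:
    def test_groups_separate_on_pc1_with_tli_loading(self, rng):
        # TLI separates the groups almost perfectly; the angles carry a
        # weaker group signal, so PC1 is the group axis with TLI on top
        rows = []
        for i in range(12):
            rows.append([f"g1_{i}", 0.45 + rng.normal(0, 0.01),
                         40 + rng.normal(0, 1), 50 + rng.normal(0, 1),
                         16, 20, 19, 38])
        for i in range(12):
            rows.append([f"g2_{i}", 0.70 + rng.normal(0, 0.01),
                         40.8 + rng.normal(0, 1), 50.6 + rng.normal(0, 1),
                         16, 20, 19, 38])
        idx = lab.compute_indices(_measurements(rows))
        with pytest.warns(UserWarning):   # constant ratio columns dropped
            scores, loadings, fractions = lab.index_pca(idx)
        g1 = scores.iloc[:12]["PC1"]
        g2 = scores.iloc[12:]["PC1"]
        pooled_sd = np.sqrt(0.5 * (g1.var() + g2.var()))
        assert abs(g1.mean() - g2.mean()) > 2 * pooled_sd
        ranked = loadings["PC1"].abs().sort_values(ascending=False)
        assert "TLI" in ranked.index[:2]

    def test_fraction_sum_and_centering(self, rng):
        rows = [[f"s{i}", 0.5 + rng.normal(0, 0.05),
                 40 + rng.normal(0, 2), 50 + rng.normal(0, 2),
                 16 + rng.normal(0, 0.5), 20 + rng.normal(0, 0.5),
                 19 + rng.normal(0, 0.5), 38 + rng.normal(0, 1)]
                for i in range(10)]
        idx = lab.compute_indices(_measurements(rows))
        scores, loadings, fractions = lab.index_pca(idx)
        assert np.isclose(fractions.sum(), 1.0)
        assert np.allclose(scores.mean(axis=0), 0.0, atol=1e-9)

    def test_requires_three_complete_rows(self):
        rows = [["a", 0.5, 40, 50, 16, 20, np.nan, 38],
                ["b", 0.5, 40, 50, 16, 20, np.nan, 38],
                ["c", 0.5, 40, 50, 16, 20, 19, 38]]
        idx = lab.compute_indices(_measurements(rows))
        with pytest.raises(ValueError):
            lab.index_pca(idx)
        # restricting to ANL-free columns recovers all three specimens
        cols = ["TLI", "APA_LSCm", "COs_LSCm", "HZL/POL", "ECL/HZL", "ECL/POL"]
        scores, _, _ = lab.index_pca(idx, columns=cols)
        assert len(scores) == 3


class TestICC:
    def test_identical_sessions(self, rng):
        s1 = pd.DataFrame({"v": rng.normal(size=20)})
        out = lab.icc(s1, s1.copy())
        assert out["v"] == pytest.approx(1.0)

    def test_pure_noise_near_zero(self, rng):
        # no specimen effect: ICC scattered around 0
        vals = []
        for _ in range(50):
            s1 = pd.DataFrame({"v": rng.normal(size=30)})
            s2 = pd.DataFrame({"v": rng.normal(size=30)})
            vals.append(lab.icc(s1, s2)["v"])
        assert abs(np.mean(vals)) < 0.15

    def test_variance_components_oracle(self, rng):
        # specimen variance 9x error variance -> ICC ~ 0.9
        vals = []
        for _ in range(200):
            truth = rng.normal(scale=3.0, size=30)
            s1 = pd.DataFrame({"v": truth + rng.normal(size=30)})
            s2 = pd.DataFrame({"v": truth + rng.normal(size=30)})
            vals.append(lab.icc(s1, s2)["v"])
        assert np.mean(vals) == pytest.approx(0.9, abs=0.05)

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        truth = rng.normal(scale=2.0, size=15)
        s1 = pd.Series(truth + rng.normal(size=15) + 0.3)  # session offset
        s2 = pd.Series(truth + rng.normal(size=15))
        ours = lab.icc(pd.DataFrame({"v": s1}), pd.DataFrame({"v": s2}))["v"]
        long = pd.DataFrame({
            "targets": list(range(15)) * 2,
            "raters": ["s1"] * 15 + ["s2"] * 15,
            "score": np.concatenate([s1, s2]),
        })
        ref = pingouin.intraclass_corr(long, targets="targets",
                                       raters="raters", ratings="score")
        mask = ref["Type"].str.contains(r"ICC2$|A,1")
        icc2 = ref.loc[mask, "ICC"].iloc[0]
        assert ours == pytest.approx(icc2, abs=1e-10)


class TestPermutationTest:
    def _distance_matrix(self, rng, n_spec=8, sep=1.0, within=0.01):
        centers = rng.normal(scale=sep, size=(n_spec, 3))
        pts = np.repeat(centers, 2, axis=0) + rng.normal(
            scale=within, size=(2 * n_spec, 3))
        ids = np.repeat([f"s{i}" for i in range(n_spec)], 2)
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        return D, ids

    def test_minimal_p_for_exact_repeats(self, rng):
        D, ids = self._distance_matrix(rng, within=0.0)
        stat, p = lab.procrustes_permutation_test(D, ids, n_perm=1000, seed=0)
        assert p == pytest.approx(1 / 1001)
        assert stat > 0

    def test_seeded_reproducibility(self, rng):
        D, ids = self._distance_matrix(rng)
        r1 = lab.procrustes_permutation_test(D, ids, n_perm=200, seed=42)
        r2 = lab.procrustes_permutation_test(D, ids, n_perm=200, seed=42)
        assert r1 == r2

    def test_null_p_uniform(self, rng):
        # repeats indistinguishable from specimens: p ~ U(0,1)
        from scipy import stats

        ps = []
        for _ in range(400):
            pts = rng.normal(size=(16, 3))
            ids = np.repeat([f"s{i}" for i in range(8)], 2)
            D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            _, p = lab.procrustes_permutation_test(
                D, ids, n_perm=99, seed=int(rng.integers(2**31 - 1)))
            ps.append(p)
        rej = np.mean(np.asarray(ps) <= 0.05)
        assert abs(rej - 0.05) < 0.03
        assert stats.kstest(ps, "uniform").pvalue > 0.001

    def test_too_few_specimens(self, rng):
        D = np.zeros((6, 6))
        ids = np.repeat(["a", "b", "c"], 2)
        with pytest.raises(ValueError):
            lab.procrustes_permutation_test(D, ids)


class TestGPA:
    def _config(self, rng, n_lm=12):
        return rng.normal(size=(n_lm, 3))

    def test_similarity_copies_have_zero_shape_variance(self, rng):
        base = self._config(rng)
        configs = []
        for _ in range(5):
            from .conftest import random_rotation

            R = random_rotation(rng)
            configs.append(base * rng.uniform(0.5, 2.0) @ R.T
                           + rng.normal(size=3))
        scores, fractions, consensus = lab.gpa_pca(np.array(configs))
        assert np.abs(scores).max() < 1e-6

    def test_consensus_equidistant_for_pair_plus_mean(self, rng):
        base = self._config(rng)
        other = base + rng.normal(scale=0.1, size=base.shape)
        aligned, consensus = lab.gpa(
            np.array([base, other, 0.5 * (base + other)]))
        d = [np.linalg.norm(a - consensus) for a in aligned[:2]]
        assert abs(d[0] - d[1]) < 0.05 * max(d)

    def test_order_invariance(self, rng):
        configs = np.array([self._config(rng) for _ in range(4)])
        _, c1 = lab.gpa(configs)
        _, c2 = lab.gpa(configs[::-1])
        # consensus may differ by a rotation; compare Procrustes-aligned
        A = c1.T @ c2
        U, _, Vt = np.linalg.svd(A)
        d = np.sign(np.linalg.det(U @ Vt))
        R = U @ np.diag([1, 1, d]) @ Vt
        assert np.abs(c2 @ R.T - c1).max() < 1e-6

    def test_needs_three_configs(self, rng):
        with pytest.raises(ValueError):
            lab.gpa(np.array([self._config(rng), self._config(rng)]))
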