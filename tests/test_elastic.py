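import numpy as np
import pytest

from cochleashape import _dp, elastic
from cochleashape.curves import (
    Curve3D, SRVFCurve, l2_inner, l2_norm, shape_srvf,
)
from cochleashape.simulate import CochleaTemplate, generate_cochlea

from .conftest import helix_curve, random_rotation, random_smooth_curve


def _rz(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a), 0],
                     [np.sin(a), np.cos(a), 0],
                     [0, 0, 1.0]])


class TestRotation:
    def test_recovers_known_rotation(self, rng):
        q1 = shape_srvf(random_smooth_curve(rng), 100)
        R = _rz(30)
        q2 = SRVFCurve(q=q1.q @ R.T, norm_flag=True)
        Rhat = elastic.optimal_rotation(q1, q2)
        assert np.abs(Rhat - R.T).max() < 1e-6
        assert l2_norm(q1.q - q2.q @ Rhat.T) < 1e-9

    def test_identity_for_identical(self, rng):
        q = shape_srvf(random_smooth_curve(rng), 100)
        assert np.abs(elastic.optimal_rotation(q, q) - np.eye(3)).max() < 1e-9

    def test_beats_random_search(self, rng):
        q1 = shape_srvf(random_smooth_curve(rng), 80)
        q2 = shape_srvf(random_smooth_curve(rng), 80)
        R = elastic.optimal_rotation(q1, q2)
        best = l2_norm(q1.q - q2.q @ R.T)
        assert best <= l2_norm(q1.q - q2.q) + 1e-12
        for _ in range(1000):
            Rr = random_rotation(rng)
            assert best <= l2_norm(q1.q - q2.q @ Rr.T) + 1e-9

    def test_never_reflects(self, rng):
        for _ in range(10):
            q1 = shape_srvf(random_smooth_curve(rng), 60)
            q2 = shape_srvf(random_smooth_curve(rng), 60)
            R = elastic.optimal_rotation(q1, q2)
            assert np.isclose(np.linalg.det(R), 1.0, atol=1e-9)


class TestReparameterization:
    def test_identity_for_identical(self, rng):
        q = shape_srvf(random_smooth_curve(rng), 60)
        gamma = elastic.optimal_reparameterization(q, q)
        grid = np.linspace(0, 1, 60)
        assert np.abs(gamma - grid).max() <= 1.0 / 59 + 1e-12

    def test_recovers_constructed_warp(self, rng):
        # warp a curve by a known smooth gamma0 and ask DP to undo it
        n = 120
        t = np.linspace(0, 1, 2000)
        base = random_smooth_curve(rng, n=2000)
        gamma0 = t + 0.08 * np.sin(2 * np.pi * t)
        warped_pts = np.column_stack([
            np.interp(gamma0, t, base.points[:, k]) for k in range(3)])
        q1 = shape_srvf(base, n)
        q2 = shape_srvf(Curve3D(warped_pts), n)
        d_unwarped = np.arccos(np.clip(l2_inner(q1.q, q2.q), -1, 1))
        al = elastic.align_srvf(q1, q2)
        assert al.aligned_distance < 0.05 * max(d_unwarped, 1e-6) + 1e-3

    @pytest.mark.parametrize("n", [9, 11])
    def test_dp_equals_exhaustive_on_tiny_grids(self, rng, n):
        for _ in range(3):
            q1 = shape_srvf(random_smooth_curve(rng), n)
            q2 = shape_srvf(random_smooth_curve(rng), n)
            g_dp, e_dp = _dp.dp_optimal_warp(q1.q, q2.q)
            g_ex, e_ex = _dp.exhaustive_optimal_warp(q1.q, q2.q)
            assert np.isclose(e_dp, e_ex, rtol=1e-10)
            assert np.abs(g_dp - g_ex).max() < 1e-12

    def test_warp_is_monotone_boundary_fixed(self, rng):
        q1 = shape_srvf(random_smooth_curve(rng), 80)
        q2 = shape_srvf(random_smooth_curve(rng), 80)
        gamma = elastic.optimal_reparameterization(q1, q2)
        assert gamma[0] == 0.0 and gamma[-1] == 1.0
        assert np.all(np.diff(gamma) >= -1e-12)


class TestDistance:
    def test_similarity_invariance(self, rng):
        c = random_smooth_curve(rng)
        R = random_rotation(rng)
        moved = Curve3D(c.points * 3.1 @ R.T + np.array([5.0, -2.0, 1.0]))
        assert elastic.elastic_distance(c, moved, n_points=100) < 1e-3

    def test_reparameterized_copy_is_close(self, rng):
        t = np.linspace(0, 1, 1500)
        base = random_smooth_curve(rng, n=1500)
        gamma0 = t + 0.06 * np.sin(2 * np.pi * t)
        warped = Curve3D(np.column_stack([
            np.interp(gamma0, t, base.points[:, k]) for k in range(3)]))
        other = random_smooth_curve(rng, n=1500)
        d_same = elastic.elastic_distance(base, warped, n_points=100)
        d_other = elastic.elastic_distance(base, other, n_points=100)
        assert d_same < 0.05 * d_other

    def test_metric_axioms_on_sample(self, rng):
        curves = [random_smooth_curve(rng) for _ in range(6)]
        D = elastic.pairwise_distance_matrix(curves, n_points=60)
        assert np.allclose(D, D.T, atol=1e-6)
        assert np.allclose(np.diag(D), 0.0)
        assert (D >= 0).all()
        n = len(curves)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-6

    def test_symmetry_pairwise(self, rng):
        for _ in range(5):
            c1, c2 = random_smooth_curve(rng), random_smooth_curve(rng)
            d12 = elastic.elastic_distance(c1, c2, n_points=80)
            d21 = elastic.elastic_distance(c2, c1, n_points=80)
            assert abs(d12 - d21) < 1e-3 * max(d12, 1.0)


def _similar_pair():
    """Two cochlear variants: the domain's typical 'close shapes' regime."""
    a = generate_cochlea(CochleaTemplate(pitch=0.45, b=0.11), n_points=300)
    b = generate_cochlea(CochleaTemplate(pitch=0.58, b=0.13,
                                         turns=2.3 * 2 * np.pi), n_points=300)
    return a, b


class TestGeodesicAndMaps:
    def test_two_steps_returns_endpoints(self):
        c1, c2 = _similar_pair()
        path = elastic.geodesic_path(c1, c2, 2, n_points=100)
        assert len(path) == 2
        assert elastic.elastic_distance(path[0], c1, n_points=100) < 5e-3

    def test_midpoint_equidistant_on_sphere(self):
        # by construction the slerp midpoint is exactly equidistant from the
        # registered endpoint SRVFs
        c1, c2 = _similar_pair()
        q1 = shape_srvf(c1, 100)
        q2 = shape_srvf(c2, 100)
        al = elastic.align_srvf(q1, q2)
        theta = al.aligned_distance
        mid = (np.sin(theta / 2) * q1.q
               + np.sin(theta / 2) * al.aligned_q2) / np.sin(theta)
        d1 = np.arccos(np.clip(l2_inner(mid, q1.q), -1, 1))
        d2 = np.arccos(np.clip(l2_inner(mid, al.aligned_q2), -1, 1))
        assert abs(d1 - d2) < 1e-9
        assert abs(d1 - theta / 2) < 1e-9

    def test_midpoint_equidistant_as_curves(self):
        # re-extracted midpoint curve, independently re-registered to both
        # ends: equidistance holds up to warp-discretization error
        c1, c2 = _similar_pair()
        mid = elastic.geodesic_path(c1, c2, 3, n_points=100)[1]
        d1 = elastic.elastic_distance(mid, c1, n_points=100)
        d2 = elastic.elastic_distance(mid, c2, n_points=100)
        assert abs(d1 - d2) < 1e-3 + 0.05 * max(d1, d2)

    def test_path_length_matches_distance(self, rng):
        for _ in range(3):
            c1, c2 = random_smooth_curve(rng), random_smooth_curve(rng)
            q1 = shape_srvf(c1, 80)
            q2 = shape_srvf(c2, 80)
            al = elastic.align_srvf(q1, q2)
            path_q = []
            theta = al.aligned_distance
            for s in np.linspace(0, 1, 12):
                q = (np.sin((1 - s) * theta) * q1.q
                     + np.sin(s * theta) * al.aligned_q2) / np.sin(theta)
                path_q.append(q)
            length = sum(
                np.arccos(np.clip(l2_inner(a, b), -1, 1))
                for a, b in zip(path_q[:-1], path_q[1:]))
            assert abs(length - theta) < 0.01 * theta

    def test_log_exp_round_trip(self, rng):
        mean_q = shape_srvf(random_smooth_curve(rng), 80)
        for _ in range(20):
            q = shape_srvf(random_smooth_curve(rng), 80)
            al = elastic.align_srvf(mean_q, q)
            qa = SRVFCurve(q=al.aligned_q2, norm_flag=True)
            v = elastic.log_map(mean_q, qa)
            back = elastic.exp_map(mean_q, v)
            assert l2_norm(back.q - qa.q) < 1e-6
            # shooting-vector norm equals the sphere arc distance
            assert abs(v.norm - al.aligned_distance) < 1e-9
            # tangency at the base point
            assert abs(l2_inner(v.v, mean_q.q)) < 1e-6

    def test_log_map_of_base_is_zero(self, rng):
        q = shape_srvf(random_smooth_curve(rng), 60)
        assert elastic.log_map(q, q).norm == 0.0


class TestFrechetMean:
    def test_identical_copies(self):
        c = helix_curve()
        mean, info = elastic.frechet_mean([c, c, c], n_points=100,
                                          return_info=True)
        assert info["n_iter"] <= 2
        assert elastic.elastic_distance(mean, c, n_points=100) < 1e-3

    def test_mean_of_two_equidistant(self):
        # the defining property: geodesic distances from the mean to the two
        # curves agree (measured by registration to the mean)
        c1, c2 = _similar_pair()
        _, info = elastic.frechet_mean([c1, c2], n_points=200, tol=1e-8,
                                       max_iter=80, return_info=True)
        d1, d2 = info["distances"]
        assert abs(d1 - d2) / max(d1, d2) < 1e-3

    def test_recovery_from_symmetric_sample(self, rng):
        base = CochleaTemplate()
        truth = generate_cochlea(base, n_points=100)
        curves = [
            generate_cochlea(base, seed=int(rng.integers(2**31 - 1)),
                             n_points=100, landmark_noise_sd=0.002)
            for _ in range(10)
        ]
        mean = elastic.frechet_mean(curves, n_points=100)
        d_truth = elastic.elastic_distance(mean, truth, n_points=100)
        d_noise = np.mean([
            elastic.elastic_distance(c, truth, n_points=100) for c in curves])
        assert d_truth < d_noise

    def test_single_curve(self):
        c = helix_curve()
        mean = elastic.frechet_mean([c], n_points=80)
        assert elastic.elastic_distance(mean, c, n_points=80) < 1e-3


class TestTangentPCA:
    def test_geodesic_family_concentrates_on_pc1(self):
        # curves along a single geodesic: PC1 carries > 99% of the variance
        # a short 1-parameter template family traces a near-geodesic arc
        curves = [
            generate_cochlea(CochleaTemplate(pitch=p, b=0.11), n_points=300)
            for p in np.linspace(0.40, 0.55, 8)
        ]
        tp = elastic.tangent_pca(curves, n_points=150)
        assert tp.variance_fractions[0] > 0.99

    def test_fractions_and_reconstruction(self, rng):
        curves = [
            generate_cochlea(
                CochleaTemplate(pitch=0.45 + dp, b=0.11 + db,
                                turns=(2.5 + dt) * 2 * np.pi),
                n_points=200)
            for dp, db, dt in rng.normal(scale=[0.04, 0.01, 0.08],
                                         size=(6, 3))
        ]
        tp = elastic.tangent_pca(curves, n_points=60)
        assert np.isclose(tp.variance_fractions.sum(), 1.0, atol=1e-9)
        assert np.all(np.diff(tp.variance_fractions) <= 1e-12)
        # orthonormal components in L2
        k = tp.n_components
        for i in range(k):
            for j in range(k):
                ip = l2_inner(tp.components[i], tp.components[j])
                assert abs(ip - (1.0 if i == j else 0.0)) < 1e-6

    def test_mean_scores_zero(self, rng):
        curves = [
            generate_cochlea(CochleaTemplate(pitch=0.45 + dp, b=0.11 + db),
                             n_points=100)
            for dp, db in rng.normal(scale=[0.03, 0.008], size=(5, 2))
        ]
        mean = elastic.frechet_mean(curves, n_points=100)
        tp = elastic.tangent_pca(curves + [mean], mean=mean, n_points=100)
        assert np.abs(tp.scores[-1]).max() < 1e-6

    def test_too_few_curves(self, rng):
        with pytest.raises(ValueError):
            elastic.tangent_pca([random_smooth_curve(rng)] * 2, n_points=60)


def test_pairwise_matrix_matches_elementwise(rng):
    curves = [random_smooth_curve(rng) for _ in range(3)]
    D = elastic.pairwise_distance_matrix(curves, n_points=60)
    d01 = elastic.elastic_distance(curves[0], curves[1], n_points=60)
    assert abs(D[0, 1] - d01) < 1e-9
    one = elastic.pairwise_distance_matrix([curves[0], curves[0]], n_points=60)
    assert np.allclose(one, 0.0, atol=1e-6)
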