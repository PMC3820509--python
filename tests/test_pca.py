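"""Covariance PCA: oracles, projections, clustering, RMSF, overlap."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import ensdyn
from ensdyn.pca_conformers import reconstruct


def brute_force_covariance(frames):
    """Double-loop evaluation of the covariance definition: no matrix
    algebra, the independent oracle for the covariance operation."""
    F, N = frames.shape[0], frames.shape[1]
    X = frames.reshape(F, 3 * N)
    mean = [sum(X[f][i] for f in range(F)) / F for i in range(3 * N)]
    C = np.empty((3 * N, 3 * N))
    for i in range(3 * N):
        for j in range(3 * N):
            C[i, j] = sum((X[f][i] - mean[i]) * (X[f][j] - mean[j])
                          for f in range(F)) / F
    return C


class TestCovariance:
    def test_two_frames_single_coordinate_quarter_d_squared(self):
        d = 2.6
        frames = np.zeros((2, 3, 3))
        frames[1, 1, 2] = d  # one coordinate differs by d
        cov = ensdyn.covariance(frames)
        expected = np.zeros((9, 9))
        expected[5, 5] = d ** 2 / 4  # population convention
        np.testing.assert_allclose(cov.matrix, expected, atol=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        frames = rng.normal(size=(3, 2, 3)) * 2
        cov = ensdyn.covariance(frames)
        np.testing.assert_allclose(cov.matrix,
                                   brute_force_covariance(frames),
                                   atol=1e-10)

    def test_single_frame_fatal(self):
        with pytest.raises(ValueError):
            ensdyn.covariance(np.zeros((1, 4, 3)))

    def test_recovers_generator_covariance_entrywise(self):
        """Sampled covariance of a known multivariate normal is within
        3 standard errors of the generator covariance, entrywise."""
        rng = np.random.default_rng(12)
        mean = rng.normal(size=(3, 3)) * 4
        modes = rng.normal(size=(2, 9))
        variances = np.array([4.0, 1.0])
        noise = 0.5
        spec = ensdyn.GeneratorSpec(seed=12, mean=mean, modes=modes,
                                    variances=variances, noise=noise)
        ens = ensdyn.gaussian_ensemble(spec, 5000)
        cov = ensdyn.covariance(ens).matrix
        from ensdyn.synthetic_data import _orthonormalize
        M = _orthonormalize(modes)
        truth = (M.T * variances) @ M + noise ** 2 * np.eye(9)
        F = 5000
        se = np.sqrt((np.outer(np.diag(truth), np.diag(truth))
                      + truth ** 2) / F)
        assert (np.abs(cov - truth) <= 3 * se).all()


class TestPCA:
    def test_two_conformers_single_mode(self, two_state):
        up, down = two_state
        frames = np.concatenate([up.frames, down.frames])
        model = ensdyn.pca(ensdyn.covariance(frames))
        assert model.fractions[0] == pytest.approx(1.0)
        assert model.cumulative[0] == pytest.approx(1.0)
        diff = (down.frames[0] - up.frames[0]).reshape(-1)
        diff /= np.linalg.norm(diff)
        overlap = abs(diff @ model.eigenvectors[:, 0])
        assert overlap == pytest.approx(1.0, abs=1e-8)

    def test_rank3_fraction_recovery(self):
        rng = np.random.default_rng(2)
        spec = ensdyn.GeneratorSpec(
            seed=2, mean=rng.normal(size=(20, 3)) * 8,
            modes=rng.normal(size=(3, 60)),
            variances=np.array([9.0, 3.0, 1.0]))
        ens = ensdyn.gaussian_ensemble(spec, 2000)
        model = ensdyn.pca(ensdyn.covariance(ens))
        target = np.array([9, 3, 1]) / 13
        tol = 3 * target * np.sqrt(2 / 2000)
        assert (np.abs(model.fractions[:3] - target) <= tol).all()

    def test_eigenvalue_sum_equals_trace(self, switching):
        ens, _ = switching
        cov = ensdyn.covariance(ens)
        model = ensdyn.pca(cov)
        assert model.eigenvalues.sum() == pytest.approx(cov.trace,
                                                        rel=1e-8)

    def test_pca_of_reconstruction_reproduces_eigenvalues(self, switching):
        ens, _ = switching
        model = ensdyn.pca(ensdyn.covariance(ens))
        scores = ensdyn.project(ens, model).scores
        rebuilt = reconstruct(scores, model)
        model2 = ensdyn.pca(ensdyn.covariance(rebuilt))
        np.testing.assert_allclose(model2.eigenvalues, model.eigenvalues,
                                   atol=1e-8 * model.eigenvalues[0])


class TestProjection:
    def test_mean_projects_to_zero(self, switching):
        ens, _ = switching
        model = ensdyn.pca(ensdyn.covariance(ens))
        mean_frame = model.mean.reshape(1, -1, 3)
        scores = ensdyn.project(mean_frame, model, 5).scores
        np.testing.assert_allclose(scores, 0.0, atol=1e-8)

    def test_full_reconstruction_roundtrip(self, switching):
        ens, _ = switching
        model = ensdyn.pca(ensdyn.covariance(ens))
        scores = ensdyn.project(ens, model).scores
        rebuilt = reconstruct(scores, model)
        assert np.abs(rebuilt - ens.frames).max() < 1e-6

    def test_score_variance_equals_eigenvalue(self, switching):
        ens, _ = switching
        model = ensdyn.pca(ensdyn.covariance(ens))
        scores = ensdyn.project(ens, model, 3).scores
        for k in range(3):
            var = np.mean((scores[:, k] - scores[:, k].mean()) ** 2)
            assert var == pytest.approx(model.eigenvalues[k], rel=1e-6)

    def test_dimension_mismatch_fatal(self, switching):
        ens, _ = switching
        model = ensdyn.pca(ensdyn.covariance(ens))
        with pytest.raises(ValueError, match="mismatch"):
            ensdyn.project(np.zeros((2, 5, 3)), model)


class TestContributions:
    def test_single_moving_position(self):
        frames = np.zeros((2, 6, 3))
        frames[:, :, 0] = np.arange(6) * 4  # spread positions
        frames[1, 5] += np.array([0.0, 2.0, 0.0])
        model = ensdyn.pca(ensdyn.covariance(frames))
        contrib = ensdyn.residue_contributions(model, 0)
        assert contrib[5] == pytest.approx(1.0)
        np.testing.assert_allclose(contrib[:5], 0.0, atol=1e-12)
        assert contrib.sum() == pytest.approx(1.0)


class TestPorcupine:
    def test_interpolation_sweeps_pc(self, tmp_path, switching):
        from ensdyn.pca_conformers import porcupine_pdb
        ens, _ = switching
        model = ensdyn.pca(ensdyn.covariance(ens))
        p = tmp_path / "pc1.pdb"
        porcupine_pdb(model, 0, p, n_steps=5, amplitude=1.0)
        back = ensdyn.read_trajectory(None, p)
        assert back.n_frames == 5
        # middle frame is the mean conformation
        mid = back.frames[2].reshape(-1)
        assert np.abs(mid - model.mean).max() <= 0.0011


class TestClustering:
    def test_identical_frames_single_effective_cluster(self):
        scores = np.zeros((6, 5))
        proj = ensdyn.ProjectionSet(scores=scores, labels=list(range(6)))
        out = ensdyn.cluster_conformers(proj, K=3)
        # zero-height tree: all labels identical frames share a label
        assert len(set(out.labels)) >= 1
        assert (out.linkage_tree[:, 2] == 0).all()

    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(9)
        blob1 = rng.normal(0.0, 1.0, size=(20, 5))
        blob2 = rng.normal(0.0, 1.0, size=(20, 5)) + 10.0
        scores = np.vstack([blob1, blob2])
        proj = ensdyn.ProjectionSet(scores=scores, labels=list(range(40)))
        out = ensdyn.cluster_conformers(proj, K=2)
        assert len(set(out.labels[:20])) == 1
        assert len(set(out.labels[20:])) == 1
        assert out.labels[0] != out.labels[-1]

    def test_labels_invariant_under_frame_reordering(self):
        rng = np.random.default_rng(10)
        scores = np.vstack([rng.normal(size=(10, 5)),
                            rng.normal(size=(10, 5)) + 8.0])
        perm = rng.permutation(20)
        proj = ensdyn.ProjectionSet(scores=scores, labels=list(range(20)))
        proj_p = ensdyn.ProjectionSet(scores=scores[perm],
                                      labels=perm.tolist())
        a = ensdyn.cluster_conformers(proj, K=2).labels
        b = ensdyn.cluster_conformers(proj_p, K=2).labels
        # same partition: co-membership is preserved under permutation
        for i in range(20):
            for j in range(20):
                same_a = a[perm[i]] == a[perm[j]]
                same_b = b[i] == b[j]
                assert same_a == same_b

    def test_k_exceeding_frames_fatal(self):
        proj = ensdyn.ProjectionSet(scores=np.zeros((3, 5)),
                                    labels=[0, 1, 2])
        with pytest.raises(ValueError):
            ensdyn.cluster_conformers(proj, K=4)


class TestRMSF:
    def test_static_ensemble_zero(self, toy):
        frames = np.repeat(toy.frames, 4, axis=0)
        np.testing.assert_allclose(ensdyn.rmsf(frames), 0.0, atol=1e-12)

    def test_isotropic_jitter_sigma_sqrt3(self):
        rng = np.random.default_rng(11)
        sigma = 0.8
        frames = rng.normal(0.0, sigma, size=(4000, 10, 3))
        prof = ensdyn.rmsf(frames)
        assert np.allclose(prof, sigma * np.sqrt(3), rtol=0.05)

    def test_bfactor_quadratic_relation_r2_one(self, switching):
        ens, _ = switching
        prof = ensdyn.rmsf(ens)
        b = (8 * np.pi ** 2 / 3) * prof ** 2
        assert ensdyn.bfactor_correlation(prof, b) == pytest.approx(1.0)

    def test_constant_profile_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            out = ensdyn.bfactor_correlation(np.ones(5), np.ones(5))
        assert np.isnan(out)


class TestSubspaceOverlap:
    def test_self_overlap_is_one(self, switching):
        ens, _ = switching
        model = ensdyn.pca(ensdyn.covariance(ens))
        assert ensdyn.subspace_overlap(model, model, 2) == pytest.approx(1.0)

    def test_orthogonal_leading_pcs_zero(self):
        frames_a = np.zeros((3, 3, 3))
        frames_a[:, 0, 0] = [0.0, 1.0, 2.0]   # motion along x of pos 0
        frames_b = np.zeros((3, 3, 3))
        frames_b[:, 2, 1] = [0.0, 1.0, 2.0]   # motion along y of pos 2
        ma = ensdyn.pca(ensdyn.covariance(frames_a))
        mb = ensdyn.pca(ensdyn.covariance(frames_b))
        assert ensdyn.subspace_overlap(ma, mb, 1, n_ref=1) == \
            pytest.approx(0.0, abs=1e-10)

    def test_rotated_rank5_overlap_one(self):
        """A random orthogonal change of basis spans the same subspace:
        overlap at K=5 of a rank-5 generator equals 1."""
        rng = np.random.default_rng(13)
        modes = rng.normal(size=(5, 30))
        variances = np.array([16.0, 8.0, 4.0, 2.0, 1.0])
        spec_a = ensdyn.GeneratorSpec(seed=20, mean=np.zeros((10, 3)),
                                      modes=modes, variances=variances)
        ens = ensdyn.gaussian_ensemble(spec_a, 500)
        ma = ensdyn.pca(ensdyn.covariance(ens))
        # second model: same frames in a rotated score basis -> same span
        R = Rotation.random(rng=rng).as_matrix()
        mb_vecs = ma.eigenvectors.copy()
        from scipy.stats import ortho_group
        Q = ortho_group.rvs(5, random_state=np.random.RandomState(4))
        mb_vecs[:, :5] = mb_vecs[:, :5] @ Q
        mb = ensdyn.PCAModel(
            eigenvectors=mb_vecs, eigenvalues=ma.eigenvalues,
            fractions=ma.fractions, cumulative=ma.cumulative,
            mean=ma.mean, n_positions=ma.n_positions)
        assert ensdyn.subspace_overlap(ma, mb, 5) == pytest.approx(
            1.0, abs=1e-6)
        # monotone non-decreasing in K
        vals = [ensdyn.subspace_overlap(ma, mb, k) for k in range(1, 6)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
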