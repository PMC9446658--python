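"""CSP spatial filters, sliding log-variance, and quantized-MI ranking."""

import numpy as np
import pytest
from scipy import linalg as sla

from mibci import features as feat


def _toy_trials(rng, cov, n_trials=40, n_samp=300):
    chol = np.linalg.cholesky(cov)
    return np.einsum("cd,tds->tcs", chol, rng.standard_normal((n_trials, cov.shape[0], n_samp)))


class TestCSP:
    def test_matches_dense_generalized_eigendecomposition(self):
        """CSP filters equal the generalized eigenvectors of (Ca, Ca+Cb)
        computed directly, up to sign/scale (angle < 1e-6 rad)."""
        rng = np.random.default_rng(0)
        for n_ch in (3, 4, 5):
            A = rng.normal(size=(n_ch, n_ch))
            B = rng.normal(size=(n_ch, n_ch))
            cov_a = A @ A.T + n_ch * np.eye(n_ch)
            cov_b = B @ B.T + n_ch * np.eye(n_ch)
            ta = _toy_trials(rng, cov_a, n_trials=60, n_samp=4000)
            tb = _toy_trials(rng, cov_b, n_trials=60, n_samp=4000)
            m = 1
            filters, vals = feat.fit_csp(ta, tb, n_pairs=m)
            # oracle: dense eigendecomposition on the same estimated covariances
            ca = feat._normalized_covariance(ta)
            cb = feat._normalized_covariance(tb)
            w_oracle, v_oracle = sla.eigh(ca, ca + cb)
            order = np.argsort(w_oracle)[::-1]
            v_oracle = v_oracle[:, order][:, [0, n_ch - 1]].T
            for w, v in zip(filters, v_oracle):
                cosang = abs(w @ v) / (np.linalg.norm(w) * np.linalg.norm(v))
                assert np.arccos(min(cosang, 1.0)) < 1e-6

    def test_identical_covariances_give_half_eigenvalues(self):
        rng = np.random.default_rng(1)
        t = _toy_trials(rng, np.eye(3), n_trials=2, n_samp=500)
        _, vals = feat.fit_csp(t, t.copy(), n_pairs=1)
        np.testing.assert_allclose(vals, 0.5, atol=1e-12)

    def test_projected_variance_ratio_equals_eigenvalue(self):
        """On training data, filter i's class-a variance fraction is its
        generalized eigenvalue, with top/bottom pairs straddling 0.5."""
        rng = np.random.default_rng(2)
        cov_a = np.diag([4.0, 1.0, 1.0])
        cov_b = np.diag([1.0, 1.0, 4.0])
        ta = _toy_trials(rng, cov_a, n_samp=2000)
        tb = _toy_trials(rng, cov_b, n_samp=2000)
        filters, vals = feat.fit_csp(ta, tb, n_pairs=1)
        ca, cb = feat._normalized_covariance(ta), feat._normalized_covariance(tb)
        for w, lam in zip(filters, vals):
            ratio = (w @ ca @ w) / (w @ (ca + cb) @ w)
            assert ratio == pytest.approx(lam, rel=1e-9)
        assert vals[0] >= 0.5 >= vals[-1]

    def test_invariant_to_joint_channel_scaling(self):
        """With raw covariance averaging, joint channel rescaling leaves
        the eigenvalues unchanged and rescales the filters inversely, so
        projected variances are identical.  The default per-trial trace
        normalization keeps the eigenvalues stable only approximately
        (it reweights trials by their scaled broadband power)."""
        rng = np.random.default_rng(3)
        ta = _toy_trials(rng, np.diag([3.0, 1.0, 0.5]))
        tb = _toy_trials(rng, np.diag([0.5, 1.0, 3.0]))
        scale = np.array([2.0, 0.5, 7.0])[None, :, None]
        f1, v1 = feat.fit_csp(ta, tb, n_pairs=1, normalize=None)
        f2, v2 = feat.fit_csp(ta * scale, tb * scale, n_pairs=1, normalize=None)
        np.testing.assert_allclose(v1, v2, atol=1e-10)
        proj1 = np.einsum("fc,tcs->tfs", f1, ta).var()
        proj2 = np.einsum("fc,tcs->tfs", f2, ta * scale).var()
        assert proj1 == pytest.approx(proj2, rel=1e-6)
        # default estimate: eigenvalues move only slightly under mild scaling
        mild = np.array([1.2, 0.9, 1.1])[None, :, None]
        _, v3 = feat.fit_csp(ta, tb, n_pairs=1)
        _, v4 = feat.fit_csp(ta * mild, tb * mild, n_pairs=1)
        np.testing.assert_allclose(v3, v4, atol=0.05)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            feat.fit_csp(np.zeros((1, 3, 10)), np.zeros((5, 3, 10)))

    def test_bank_yields_24_features(self, small_strong_dataset):
        ds = small_strong_dataset
        X, y, _ = ds.pair_arrays("LR")
        csp = feat.fit_csp_bank(
            X[y == 1], X[y == 0], n_pairs=3, task_slice=feat.task_slice_for(ds.times)
        )
        assert csp.filters.shape == (4, 6, 21)
        assert csp.n_features == 24


class TestLogVar:
    def _identity_csp(self, n_ch=2, n_bands=1):
        filters = np.stack([np.eye(n_ch)] * n_bands)
        return feat.CSPModel(filters=filters, eigvals=np.full((n_bands, n_ch), 0.5), n_pairs=n_ch // 2)

    def test_frame_count_and_times(self):
        assert len(feat.frame_times()) == 226
        assert feat.frame_times()[0] == -1.0
        assert feat.frame_times()[-1] == pytest.approx(8.0)

    def test_unit_variance_noise_gives_logvar_near_zero(self):
        rng = np.random.default_rng(0)
        trials = rng.standard_normal((6, 2, 1, 1250))
        feats, t = feat.extract_logvar(trials, self._identity_csp())
        assert feats.shape == (6, 2, 226)
        assert abs(feats.mean()) < 0.05

    def test_constant_signal_clamped_to_floor(self):
        trials = np.ones((1, 2, 1, 1250))
        with pytest.warns(UserWarning, match="clamped"):
            feats, _ = feat.extract_logvar(trials, self._identity_csp())
        np.testing.assert_allclose(feats, np.log(1e-12))

    def test_short_epoch_rejected(self):
        with pytest.raises(ValueError, match="span"):
            feat.extract_logvar(np.zeros((1, 2, 1, 100)), self._identity_csp())


class TestQuantizedMI:
    def test_label_independent_feature_has_near_zero_mi(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        y = rng.integers(0, 2, size=2000)
        assert feat.quantized_mi(x, y) < 0.02

    def test_perfectly_separating_binary_feature_is_one_bit(self):
        x = np.array([0.0] * 50 + [1.0] * 50)
        y = np.array([0] * 50 + [1] * 50)
        assert feat.quantized_mi(x, y) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_histogram_on_toy(self):
        """Vectorized estimator equals the textbook sum over the joint
        quantized histogram, feature by feature."""
        rng = np.random.default_rng(5)
        n, n_bins = 400, 8
        F = rng.normal(size=(n, 5, 1))
        y = rng.integers(0, 2, size=n)
        F[:, 2, 0] += 1.5 * y  # one informative feature
        mi_vec = feat._mi_frames(F, y, n_bins)[:, 0]
        for f in range(5):
            edges = np.quantile(F[:, f, 0], np.linspace(0, 1, n_bins + 1)[1:-1])
            b = (F[:, f, 0][None] > edges[:, None]).sum(axis=0)
            joint = np.zeros((n_bins, 2))
            for bi, yi in zip(b, y):
                joint[bi, yi] += 1
            joint /= n
            mi = 0.0
            for i in range(n_bins):
                for j in range(2):
                    if joint[i, j] > 0:
                        mi += joint[i, j] * np.log2(
                            joint[i, j] / (joint[i].sum() * joint[:, j].sum())
                        )
            assert mi_vec[f] == pytest.approx(mi, abs=1e-12)
        ranking = feat.mi_rank(F[:, :, 0], y, n_bins=n_bins)
        assert ranking.ranking[0] == 2

    def test_converges_to_analytic_mi_on_discretized_gaussian(self):
        """Median-split Gaussian location model: MI(bin; label) has a
        closed form from the 2x2 table; the estimator with 2 bins matches
        within 0.05 bits at n = 2000."""
        rng = np.random.default_rng(7)
        n, delta = 2000, 1.2
        y = np.repeat([0, 1], n // 2)
        x = rng.standard_normal(n) + delta * y
        est = feat.quantized_mi(x, y, n_bins=2)
        # oracle: exact MI of the (sign vs label) table for the median split
        thresh = np.median(x)
        p = np.array(
            [
                [(x[y == 0] <= thresh).mean(), (x[y == 0] > thresh).mean()],
                [(x[y == 1] <= thresh).mean(), (x[y == 1] > thresh).mean()],
            ]
        ) / 2.0
        mi_true = sum(
            p[i, j] * np.log2(p[i, j] / (p[i].sum() * p[:, j].sum()))
            for i in range(2)
            for j in range(2)
            if p[i, j] > 0
        )
        assert est == pytest.approx(mi_true, abs=0.05)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            feat.mi_rank(np.random.default_rng(0).normal(size=(10, 3)), np.zeros(10))


class TestSelectFeatures:
    def test_top_k_by_rank(self):
        ranking = feat.MIRanking(
            mi_per_frame=np.zeros((4, 1)),
            mi=np.array([0.2, 0.9, 0.5, 0.9]),
            ranking=np.lexsort((np.arange(4), -np.array([0.2, 0.9, 0.5, 0.9]))),
            n_bins=8,
            summary="max",
        )
        np.testing.assert_array_equal(feat.select_features(ranking, 2), [1, 3])
        np.testing.assert_array_equal(feat.select_features(ranking, 4), [1, 3, 2, 0])

    def test_equal_mi_breaks_toward_lower_index(self):
        mi = np.array([0.5, 0.5, 0.5])
        ranking = feat.mi_rank(
            np.tile(np.array([[0.0], [1.0]]), (5, 3))[:, :, None][:, :, 0][:, :, None].squeeze(-1),
            np.array([0, 1] * 5),
        )
        np.testing.assert_array_equal(ranking.ranking, [0, 1, 2])

    def test_k_beyond_feature_count_rejected(self):
        ranking = feat.MIRanking(np.zeros((3, 1)), np.zeros(3), np.arange(3), 8, "max")
        with pytest.raises(ValueError):
            feat.select_features(ranking, 5)
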