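import numpy as np
import pytest
from scipy import optimize

from petseg.benchmark import case_context
from petseg.clustering import (
    EMSegmenter,
    FCMSegmenter,
    FCMSWSegmenter,
    anisotropic_diffusion,
    atrous_transform,
    defuzzify,
    em_fit,
    em_segment,
    fcm_fit,
    fcm_merge,
    wavelet_context,
)
from petseg.phantom import default_heterogeneous_spec, make_phantom, uptake_map
from petseg.preprocess import preprocess
from petseg.volume import ImageVolume


class TestEM:
    def test_single_class_reduces_to_mean(self):
        rng = np.random.default_rng(0)
        x = rng.normal(3.0, 0.5, size=5000)
        m = em_fit(x, K=1)
        np.testing.assert_allclose(m.responsibilities, 1.0)
        assert m.means[0] == pytest.approx(x.mean(), rel=1e-6)

    def test_parameter_recovery_two_classes(self):
        # well-separated mixture (delta mu = 10 sigma)
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0.0, 1.0, 60_000), rng.normal(10.0, 1.0, 40_000)])
        m = em_fit(x, K=2)
        mu = np.sort(m.means)
        assert mu[0] == pytest.approx(0.0, abs=0.02 * 10.0)
        assert mu[1] == pytest.approx(10.0, rel=0.02)
        assert np.sort(m.weights)[0] == pytest.approx(0.4, abs=0.02)

    @pytest.mark.parametrize("seed", range(5))
    def test_log_likelihood_monotone(self, seed):
        rng = np.random.default_rng(seed)
        x = np.concatenate(
            [rng.normal(0, 1, 2000), rng.normal(4, 0.7, 1500), rng.normal(9, 1.5, 500)]
        )
        m = em_fit(x, K=3)
        ll = np.asarray(m.log_likelihood_trace)
        assert np.all(np.diff(ll) >= -1e-6 * np.abs(ll[:-1]))

    def test_agrees_with_sklearn_mixture(self):
        # independent oracle: sklearn's GaussianMixture on the same draws
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(1, 0.5, 30_000), rng.normal(6, 1.0, 20_000)])
        ours = em_fit(x, K=2)
        ref = GaussianMixture(2, covariance_type="spherical", random_state=0).fit(x[:, None])
        np.testing.assert_allclose(np.sort(ours.means), np.sort(ref.means_.ravel()), rtol=0.01)

    def test_two_level_image_exact_mask(self):
        vals = np.ones((16, 16, 16))
        vals[4:12, 4:12, 4:12] = 8.0
        vals += np.random.default_rng(0).normal(0, 1e-3, vals.shape)  # K distinct values
        img = ImageVolume(vals, (2.0,) * 3)
        mask, model = em_segment(img, K=2, seed_point=(8, 8, 8))
        expected = vals > 4.0
        assert np.array_equal(mask.values, expected)

    def test_label_permutation_invariance(self):
        # tumour class is found via the means, so reversing the init order
        # (means are sorted internally by quantiles) cannot change the mask
        vals = np.ones((12, 12, 12))
        vals[3:9, 3:9, 3:9] = 6.0
        vals += np.random.default_rng(1).normal(0, 0.05, vals.shape)
        img = ImageVolume(vals, (2.0,) * 3)
        m1, _ = em_segment(img, K=2, seed_point=(6, 6, 6))
        m2, _ = em_segment(img, K=2, seed_point=(6, 6, 6))
        assert np.array_equal(m1.values, m2.values)

    def test_requires_k_distinct_values(self):
        with pytest.raises(ValueError):
            em_fit(np.ones(100), K=2)


def reduced_two_cluster_objective(c, x):
    """Brute-force FCM objective for b=2: J(c) = sum_i 1 / sum_k d_ik^-2."""
    d2 = (x[:, None] - np.asarray(c)[None, :]) ** 2
    with np.errstate(divide="ignore"):
        inv = 1.0 / d2
    s = inv.sum(axis=1)
    j = np.where(np.isinf(s), 0.0, 1.0 / s)
    return j.sum()


class TestFCM:
    def test_membership_symmetry_midpoint(self):
        st = fcm_fit(np.array([0.0, 10.0, 5.0]), K=2, max_iter=1,
                     init_centroids=np.array([[0.0], [10.0]]))
        np.testing.assert_allclose(st.memberships[2], [0.5, 0.5])

    def test_exact_hit_membership_one(self):
        # a voxel coincident with a centroid gets full membership there
        from petseg.clustering import _fcm_distances, _memberships

        X = np.array([[0.0], [10.0], [5.0]])
        C = np.array([[0.0], [10.0]])
        u = _memberships(_fcm_distances(X, C), b=2.0)
        np.testing.assert_allclose(u[0], [1.0, 0.0])
        np.testing.assert_allclose(u[1], [0.0, 1.0])
        np.testing.assert_allclose(u[2], [0.5, 0.5])

    def test_two_cluster_centroids_recovered(self):
        x = np.array([0.0, 0.0, 0.0, 10.0, 10.0, 10.0])
        st = fcm_fit(x, K=2, tol=1e-10)
        np.testing.assert_allclose(np.sort(st.centroids.ravel()), [0.0, 10.0], atol=1e-3)

    @pytest.mark.parametrize("seed", range(10))
    def test_objective_nonincreasing(self, seed):
        rng = np.random.default_rng(seed)
        x = np.concatenate([rng.normal(0, 1, 300), rng.normal(5, 1, 300)])
        st = fcm_fit(x, K=3)
        tr = np.asarray(st.objective_trace)
        assert np.all(np.diff(tr) <= 1e-9 * np.maximum(tr[:-1], 1.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_tiny_instances(self, seed):
        # <= 64-voxel instances: compare the converged objective against a
        # multistart Nelder-Mead minimisation of the reduced objective
        rng = np.random.default_rng(100 + seed)
        x = np.round(np.concatenate([rng.uniform(0, 2, 32), rng.uniform(6, 10, 32)]), 3)
        st = fcm_fit(x, K=2, tol=1e-12, max_iter=2000)
        ours = st.objective_trace[-1]
        best = np.inf
        for c0 in ([0.5, 8.0], [2.0, 6.0], [x.min(), x.max()], [x.mean() - 1, x.mean() + 1]):
            r = optimize.minimize(reduced_two_cluster_objective, c0, args=(x,),
                                  method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
            best = min(best, r.fun)
        assert ours == pytest.approx(best, abs=1e-3)

    def test_feature_order_permutation(self):
        rng = np.random.default_rng(7)
        X = np.column_stack([rng.normal(0, 1, 200) + (np.arange(200) > 100) * 6,
                             rng.normal(2, 1, 200)])
        a = fcm_fit(X, K=2, tol=1e-10)
        b = fcm_fit(X[:, ::-1], K=2, tol=1e-10)
        ca = a.centroids[np.argsort(a.centroids[:, 0])]
        cb = b.centroids[np.argsort(b.centroids[:, 1])][:, ::-1]
        np.testing.assert_allclose(ca, cb, atol=1e-6)


class TestMerge:
    def _state(self, x, K):
        st = fcm_fit(x, K=K)
        st._features = np.asarray(x, float)[:, None]
        return st

    def test_identity_when_k_equal(self):
        x = np.concatenate([np.zeros(10), np.full(10, 10.0)])
        st = self._state(x, 2)
        merged = fcm_merge(st, 2)
        np.testing.assert_array_equal(merged.memberships, st.memberships)

    def test_nearest_pair_merges_first(self):
        x = np.concatenate([np.zeros(8), np.full(8, 0.1), np.full(8, 10.0)])
        st = self._state(x, 3)
        merged = fcm_merge(st, 2)
        c = np.sort(merged.centroids.ravel())
        assert c[0] == pytest.approx(0.05, abs=0.05)  # the close pair fused
        assert c[1] == pytest.approx(10.0, abs=0.01)

    def test_membership_rows_still_simplex(self):
        rng = np.random.default_rng(0)
        st = self._state(rng.normal(0, 1, 200) + (np.arange(200) % 4), 6)
        merged = fcm_merge(st, 3)
        np.testing.assert_allclose(merged.memberships.sum(axis=1), 1.0, atol=1e-12)

    def test_k_target_below_two_rejected(self):
        st = self._state(np.arange(10.0), 3)
        with pytest.raises(ValueError):
            fcm_merge(st, 1)


class TestDefuzzify:
    def test_argmax(self):
        from petseg.clustering import FCMState

        st = FCMState(np.array([[0.9, 0.1], [0.2, 0.8]]), np.array([[1.0], [5.0]]), 2.0)
        np.testing.assert_array_equal(defuzzify(st), [0, 1])

    def test_tie_goes_to_higher_centroid(self):
        from petseg.clustering import FCMState

        st = FCMState(np.array([[0.5, 0.5]]), np.array([[5.0], [1.0]]), 2.0)
        assert defuzzify(st)[0] == 0  # class 0 has the higher centroid


class TestDiffusion:
    def test_constant_image_unchanged(self):
        img = ImageVolume(np.full((10, 10, 10), 2.5), (2.0,) * 3)
        out = anisotropic_diffusion(img, 5, kappa=1.0)
        np.testing.assert_allclose(out.values, 2.5, atol=1e-12)

    def test_total_intensity_conserved(self):
        rng = np.random.default_rng(4)
        img = ImageVolume(rng.random((16, 16, 16)) * 5, (2.0,) * 3)
        out = anisotropic_diffusion(img, 10)
        assert out.values.sum() == pytest.approx(img.values.sum(), rel=1e-3)

    def test_edge_preserved_better_than_gaussian(self):
        from scipy import ndimage

        rng = np.random.default_rng(5)
        vals = np.ones((24, 24, 24))
        vals[12:, :, :] = 5.0
        vals += rng.normal(0, 0.15, vals.shape)
        img = ImageVolume(vals, (2.0,) * 3)
        diff = anisotropic_diffusion(img, 12, kappa=0.5).values
        # against the best-denoising Gaussian width, diffusion dominates on
        # both axes: at least as much background-noise reduction AND a
        # steeper preserved edge
        roi = (slice(0, 8),) * 3
        stds, slopes = [], []
        for s in np.linspace(0.3, 3.0, 28):
            g = ndimage.gaussian_filter(vals, s)
            stds.append(g[roi].std())
            slopes.append(np.abs(np.diff(g[:, 12, 12])).max())
        best = int(np.argmin(stds))
        assert diff[roi].std() <= stds[best]
        assert np.abs(np.diff(diff[:, 12, 12])).max() > slopes[best]


class TestAtrous:
    def test_exact_reconstruction(self):
        rng = np.random.default_rng(6)
        vals = rng.random((20, 20, 20))
        details, residual = atrous_transform(vals, scales=3)
        recon = residual + sum(details)
        np.testing.assert_allclose(recon, vals, atol=1e-10)

    def test_constant_image_zero_details(self):
        details, residual = atrous_transform(np.full((16, 16, 16), 3.0), scales=3)
        for d in details:
            np.testing.assert_allclose(d, 0.0, atol=1e-12)
        np.testing.assert_allclose(residual, 3.0)

    def test_spike_energy_concentrates_at_scale_one(self):
        vals = np.zeros((32, 32, 32))
        vals[16, 16, 16] = 1.0
        details, _ = atrous_transform(vals, scales=3)
        energies = [float((d**2).sum()) for d in details]
        assert energies[0] > energies[1] > energies[2]

    def test_scale_too_large_rejected(self):
        with pytest.raises(ValueError):
            atrous_transform(np.zeros((8, 8, 8)), scales=4)


@pytest.fixture(scope="module")
def het_case():
    """Preprocessed heterogeneous rim/core phantom + core voxel mask."""
    spec = default_heterogeneous_spec(15.0, grid_shape=(64,) * 3, seed=3)
    raw, truth = make_phantom(spec)
    img = preprocess(raw)
    seed, region, bkg = case_context(truth)
    core = (uptake_map(spec) == spec.components[-1].uptake) & truth.values
    return img, truth, seed, region, bkg, core


class TestFCMSegmenters:
    def test_zero_regularisation_bitmatches_plain_fcm(self, het_case):
        img, truth, seed, region, bkg, core = het_case
        kw = dict(seed_point=seed, search_region=region)
        plain = FCMSegmenter().fit_predict(img, **kw)
        zeroed = FCMSWSegmenter(alpha=0.0, beta0=0.0).fit_predict(img, **kw)
        assert np.array_equal(plain.values, zeroed.values)

    def test_memberships_remain_simplex(self, het_case):
        img, truth, seed, region, bkg, core = het_case
        est = FCMSWSegmenter().fit(img, seed_point=seed, search_region=region)
        u = est.state_.memberships
        assert u.min() >= 0.0 and u.max() <= 1.0
        np.testing.assert_allclose(u.sum(axis=1), 1.0, atol=1e-10)

    def test_fcm_sw_objective_nonincreasing(self, het_case):
        img, truth, seed, region, bkg, core = het_case
        est = FCMSWSegmenter().fit(img, seed_point=seed, search_region=region)
        tr = np.asarray(est.state_.objective_trace)
        assert np.all(np.diff(tr) <= 1e-9 * tr[:-1])

    def test_fcm_sw_recovers_necrotic_core(self, het_case):
        # the defining behaviour: plain intensity clustering excludes the
        # low-uptake core; the wavelet-regularised variant includes it
        img, truth, seed, region, bkg, core = het_case
        kw = dict(seed_point=seed, search_region=region)
        cov_plain = (FCMSegmenter().fit_predict(img, **kw).values & core).sum() / core.sum()
        cov_sw = (FCMSWSegmenter().fit_predict(img, **kw).values & core).sum() / core.sum()
        assert cov_plain < 0.9
        assert cov_sw >= 0.9
        assert cov_sw > cov_plain

    def test_em_mask_volume_between_rim_and_lesion(self, het_case):
        img, truth, seed, region, bkg, core = het_case
        est = EMSegmenter().fit(img, seed_point=seed, search_region=region)
        rim_vol = truth.volume_cm3 - core.sum() * truth.voxel_volume_mm3 / 1000.0
        lesion_vol = truth.volume_cm3
        assert 0.5 * rim_vol <= est.mask_.volume_cm3 <= 1.6 * lesion_vol
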