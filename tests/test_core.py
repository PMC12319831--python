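import numpy as np
import pytest

from trifle.core import (align_sign, demean_over_time,
                         denoised_reconstruction, mode_covariance_scaling,
                         moving_average, project_loci, select_task_tfm,
                         task_regressor, time_resolved_mixing)
from trifle.hrf import canonical_hrf
from trifle.io import EventTable
from trifle.spatial import SpatialDecomposition
from trifle.tfm import TfmDecomposition


def _zscore(x):
    return (x - x.mean(axis=-1, keepdims=True)) / x.std(axis=-1, keepdims=True)


def _tfm(mixing, modes):
    return TfmDecomposition(mixing=mixing, modes=modes, k=modes.shape[0],
                            seed=0, n_iter=1, converged=True,
                            order_index=np.arange(modes.shape[0]),
                            negentropy=0.0)


def _spatial(maps, ts=None):
    return SpatialDecomposition(maps_subject=maps,
                                timeseries=ts if ts is not None else
                                np.zeros((maps.shape[1], 2)),
                                pinv_maps=np.linalg.pinv(maps),
                                template_tag="t", condition_number=1.0,
                                labels=[str(i) for i in range(maps.shape[1])])


class TestModeCovarianceScaling:
    def test_orthonormal_rows_give_identity(self):
        q, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(100, 3)))
        B = q.T  # rows orthonormal
        np.testing.assert_allclose(mode_covariance_scaling(B), np.eye(3),
                                   atol=1e-10)

    def test_uncorrelated_unit_rows_approach_inverse_n(self):
        rng = np.random.default_rng(3)
        n = 5000
        B = _zscore(rng.normal(size=(3, n)))
        Z = mode_covariance_scaling(B)
        np.testing.assert_allclose(np.diag(Z), 1.0 / n, rtol=0.05)

    def test_duplicated_row_is_singular(self, rng):
        B = rng.normal(size=(2, 50))
        B[1] = B[0]
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            mode_covariance_scaling(B)


class TestDenoisedReconstruction:
    def test_identity_mixing_returns_s_times_t(self, rng):
        S = rng.normal(size=(20, 3))
        T = rng.normal(size=(3, 40))
        out = denoised_reconstruction(_spatial(S), _tfm(np.eye(3), T))
        np.testing.assert_allclose(out, S @ T, atol=1e-12)

    def test_zero_modes_give_zero(self, rng):
        S = rng.normal(size=(20, 3))
        out = denoised_reconstruction(_spatial(S),
                                      _tfm(rng.normal(size=(3, 2)),
                                           np.zeros((2, 40))))
        assert np.all(out == 0)

    def test_matches_stepwise_product(self, rng):
        S = rng.normal(size=(11, 4))
        M = rng.normal(size=(4, 2))
        B = rng.normal(size=(2, 17))
        out = denoised_reconstruction(_spatial(S), _tfm(M, B))
        np.testing.assert_allclose(out, (S @ M) @ B, atol=1e-10)


class TestTimeResolvedMixing:
    def test_scalar_case(self):
        rng = np.random.default_rng(1)
        n = 500
        B = _zscore(rng.normal(size=(1, n)))
        trm = time_resolved_mixing(np.array([[1.0]]), B, B)
        np.testing.assert_allclose(trm.scaling, [[1.0 / n]], atol=1e-12)
        np.testing.assert_allclose(trm.f[0, 0], B[0] ** 2, atol=1e-10)
        assert trm.f.mean(axis=2)[0, 0] == pytest.approx(1.0, abs=1e-10)

    def test_temporal_average_recovers_mixing(self):
        rng = np.random.default_rng(2)
        S = rng.normal(size=(20, 3))
        M = rng.normal(size=(3, 2))
        B = _zscore(rng.normal(size=(2, 600)))
        A = np.linalg.pinv(S)
        trm = time_resolved_mixing(A, S @ M @ B, B)
        np.testing.assert_allclose(trm.f.mean(axis=2), M, atol=1e-8)

    def test_matches_frame_by_frame_outer_products(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(2, 6))
        X = rng.normal(size=(6, 5))
        B = rng.normal(size=(2, 5))
        Z = mode_covariance_scaling(B)
        trm = time_resolved_mixing(A, X, B, scaling=Z)
        for t in range(5):
            mt = np.outer(A @ X[:, t], B[:, t]) @ Z
            np.testing.assert_allclose(trm.f[:, :, t], 5 * mt, atol=1e-10)

    def test_dimension_and_finiteness_errors(self, rng):
        A = rng.normal(size=(2, 6))
        B = rng.normal(size=(2, 5))
        with pytest.raises(ValueError, match="voxel count"):
            time_resolved_mixing(A, rng.normal(size=(5, 5)), B)
        bad = rng.normal(size=(6, 5))
        bad[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            time_resolved_mixing(A, bad, B)


class TestDemean:
    def _trm(self, rng):
        A = rng.normal(size=(2, 6))
        X = rng.normal(size=(6, 50))
        B = _zscore(rng.normal(size=(2, 50)))
        return time_resolved_mixing(A, X, B)

    def test_constant_series_becomes_zero(self):
        rng = np.random.default_rng(0)
        trm = self._trm(rng)
        trm.f[0, 0, :] = 3.3
        out = demean_over_time(trm)
        np.testing.assert_allclose(out.f[0, 0], 0.0, atol=1e-12)

    def test_zero_mean_and_reconstruction(self):
        rng = np.random.default_rng(1)
        trm = self._trm(rng)
        out = demean_over_time(trm)
        assert np.abs(out.f.mean(axis=2)).max() < 1e-10
        np.testing.assert_allclose(
            out.f + out.static_mixing[:, :, None], trm.f, atol=1e-10)

    def test_double_demean_rejected(self):
        rng = np.random.default_rng(2)
        out = demean_over_time(self._trm(rng))
        with pytest.raises(ValueError, match="already demeaned"):
            demean_over_time(out)


class TestTaskRegressor:
    def _events(self, onsets):
        n = len(onsets)
        return EventTable(np.asarray(onsets, float), np.full(n, 0.2),
                          np.full(n, 0.5), np.array(["hit"] * n, dtype=object))

    def test_no_events_returns_zero(self):
        ev = self._events([])
        reg = task_regressor(ev, canonical_hrf(1.0), tr=1.0, n_frames=50)
        assert np.all(reg == 0)

    def test_single_onset_places_hrf_at_head(self):
        hrf = canonical_hrf(1.0)
        reg = task_regressor(self._events([0.0]), hrf, tr=1.0, n_frames=40,
                             zscore=False)
        np.testing.assert_allclose(reg[:32], hrf[:32], atol=1e-12)

    def test_superposition(self):
        hrf = canonical_hrf(1.0)
        both = task_regressor(self._events([2.0, 10.0]), hrf, 1.0, 60,
                              zscore=False)
        a = task_regressor(self._events([2.0]), hrf, 1.0, 60, zscore=False)
        b = task_regressor(self._events([10.0]), hrf, 1.0, 60, zscore=False)
        np.testing.assert_allclose(both, a + b, atol=1e-12)

    def test_onset_beyond_run_errors(self):
        with pytest.raises(ValueError, match="outside the run"):
            task_regressor(self._events([100.0]), canonical_hrf(1.0), 1.0, 50)


class TestSelectAndAlign:
    def test_mode_equal_to_regressor(self, rng):
        reg = _zscore(rng.normal(size=80))
        modes = np.vstack([_zscore(rng.normal(size=80)), reg])
        dec = _tfm(rng.normal(size=(3, 2)), modes)
        idx, corr, sign = select_task_tfm(dec, reg)
        assert (idx, sign) == (1, 1.0)
        assert corr == pytest.approx(1.0)

    def test_negated_mode(self, rng):
        reg = _zscore(rng.normal(size=80))
        modes = np.vstack([-reg, _zscore(rng.normal(size=80))])
        dec = _tfm(rng.normal(size=(3, 2)), modes)
        idx, corr, sign = select_task_tfm(dec, reg)
        assert (idx, sign) == (0, -1.0)

    def test_planted_partial_correlation_found(self):
        rng = np.random.default_rng(8)
        reg = _zscore(rng.normal(size=2000))
        noise = [_zscore(rng.normal(size=2000)) for _ in range(5)]
        planted = _zscore(0.6 * reg + 0.8 * rng.normal(size=2000))
        modes = np.vstack(noise[:3] + [planted] + noise[3:])
        dec = _tfm(rng.normal(size=(6, 6)), modes)
        idx, corr, _ = select_task_tfm(dec, reg)
        assert idx == 3
        assert 0.4 < abs(corr) < 0.8

    def test_constant_regressor_rejected(self, rng):
        dec = _tfm(rng.normal(size=(2, 2)), rng.normal(size=(2, 50)))
        with pytest.raises(ValueError, match="constant"):
            select_task_tfm(dec, np.ones(50))

    def _trm(self, rng):
        A = rng.normal(size=(3, 8))
        X = rng.normal(size=(8, 60))
        B = _zscore(rng.normal(size=(2, 60)))
        return time_resolved_mixing(A, X, B)

    def test_plus_one_is_identity(self):
        rng = np.random.default_rng(0)
        trm = self._trm(rng)
        out = align_sign(trm, 0, +1)
        np.testing.assert_array_equal(out.f, trm.f)

    def test_flip_is_involution(self):
        rng = np.random.default_rng(1)
        trm = self._trm(rng)
        out = align_sign(align_sign(trm, 1, -1), 1, -1)
        np.testing.assert_allclose(out.f, trm.f, atol=1e-14)
        np.testing.assert_array_equal(out.sign_flips, trm.sign_flips)

    def test_flip_makes_task_correlation_nonnegative(self):
        rng = np.random.default_rng(2)
        trm = self._trm(rng)
        reg = _zscore(rng.normal(size=60))
        avg = trm.f[:, 0, :].mean(axis=0)
        sign = -1.0 if np.corrcoef(avg, reg)[0, 1] < 0 else 1.0
        out = align_sign(trm, 0, sign)
        assert np.corrcoef(out.f[:, 0, :].mean(axis=0), reg)[0, 1] >= 0


class TestProjectLoci:
    def _setup(self, rng):
        S = rng.normal(size=(15, 3))
        A = np.linalg.pinv(S)
        B = _zscore(rng.normal(size=(2, 30)))
        trm = time_resolved_mixing(A, rng.normal(size=(15, 30)), B)
        return S, trm

    def test_zero_weights_give_zero_map(self):
        rng = np.random.default_rng(0)
        S, trm = self._setup(rng)
        trm.f[:, 0, 5] = 0.0
        np.testing.assert_allclose(project_loci(S, trm, 0, 5), 0.0, atol=1e-14)

    def test_unit_weight_selects_map_column(self):
        rng = np.random.default_rng(1)
        S, trm = self._setup(rng)
        trm.f[:, 1, 3] = np.array([0.0, 1.0, 0.0])
        np.testing.assert_allclose(project_loci(S, trm, 1, 3), S[:, 1],
                                   atol=1e-12)

    def test_matches_longhand_dot_product(self):
        rng = np.random.default_rng(2)
        S, trm = self._setup(rng)
        out = project_loci(S, trm, 0, 7)
        longhand = np.array([sum(S[v, j] * trm.f[j, 0, 7] for j in range(3))
                             for v in range(15)])
        np.testing.assert_allclose(out, longhand, atol=1e-10)

    def test_index_errors(self):
        rng = np.random.default_rng(3)
        S, trm = self._setup(rng)
        with pytest.raises(IndexError):
            project_loci(S, trm, 5, 0)
        with pytest.raises(IndexError):
            project_loci(S, trm, 0, 999)

    def test_batched_projection_shape(self):
        rng = np.random.default_rng(4)
        S, trm = self._setup(rng)
        assert project_loci(S, trm, 0).shape == (15, 30)


def test_instantaneous_product_equals_pearson(rng):
    x = rng.normal(size=500)
    y = 0.4 * x + rng.normal(size=500)
    zx, zy = _zscore(x), _zscore(y)
    assert abs((zx * zy).mean() - np.corrcoef(x, y)[0, 1]) < 1e-12


def test_moving_average_preserves_slow_signal(rng):
    t = np.arange(2000)
    slow = np.sin(2 * np.pi * t / 1000)
    noisy = slow + rng.normal(size=2000)
    sm = moving_average(noisy, 101)
    assert np.corrcoef(sm, slow)[0, 1] > 0.95
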