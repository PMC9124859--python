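import numpy as np
import pytest

from hemidiff.headmodel import Leadfield, SensorArray, SourceSpace, three_sphere_leadfield
from hemidiff.inverse import (InverseOperator, NoiseCovariance,
                              SourceWeighting, WMNEInverse, apply_inverse,
                              build_wmne_operator, depth_weights,
                              estimate_noise_covariance)
from hemidiff.preprocess import EpochSet
from hemidiff.scouts import extract_scout_series
from hemidiff.simulate import SimConfig, project_to_scalp
from hemidiff.simulate import GroundTruth

from oracles import ridge_source_estimate


def random_problem(rng, n_sensors=6, n_sources=15):
    L = rng.normal(size=(n_sensors, n_sources))
    A = rng.normal(size=(n_sensors, n_sensors))
    C = NoiseCovariance(matrix=A @ A.T + n_sensors * np.eye(n_sensors),
                        loading=0.0)
    W = SourceWeighting(weights=rng.uniform(0.5, 2.0, n_sources), gamma=1.0)
    y = rng.normal(size=n_sensors)
    return L, C, W, y


class TestNoiseCovariance:
    def test_long_white_baseline_is_identity(self, rng):
        data = rng.standard_normal((6, 100_000))
        cov = estimate_noise_covariance([data], loading=0.0)
        off = cov.matrix - np.diag(np.diag(cov.matrix))
        assert np.max(np.abs(off)) < 0.05
        np.testing.assert_allclose(np.diag(cov.matrix), 1.0, atol=0.05)

    def test_full_loading_is_spherical(self, rng):
        data = rng.standard_normal((4, 500)) * np.array([[1], [2], [3], [4]])
        cov = estimate_noise_covariance([data], loading=1.0)
        target = np.mean(np.var(data, axis=1, ddof=1))
        np.testing.assert_allclose(cov.matrix, target * np.eye(4), rtol=0.05)
        assert np.allclose(cov.matrix - np.diag(np.diag(cov.matrix)), 0.0)

    def test_duplicated_channel_off_diagonal(self, rng):
        base = rng.standard_normal(20_000)
        data = np.stack([base, base, rng.standard_normal(20_000)])
        cov = estimate_noise_covariance([data], loading=0.0)
        shared = np.var(base, ddof=1)
        assert cov.matrix[0, 1] == pytest.approx(shared, rel=1e-6)

    def test_segments_concatenated(self, rng):
        segs = [rng.standard_normal((3, 400)) for _ in range(5)]
        cov = estimate_noise_covariance(segs, loading=0.0)
        assert cov.n_samples == 2000

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no baseline segments"):
            estimate_noise_covariance([])

    def test_short_baseline_warns_and_loads(self, rng):
        with pytest.warns(RuntimeWarning, match="baseline samples"):
            cov = estimate_noise_covariance([rng.standard_normal((10, 5))],
                                            loading=0.1)
        assert cov.loading == 0.5


class TestDepthWeights:
    def test_gamma_zero_is_unweighted(self, rng):
        L = rng.normal(size=(5, 8))
        w = depth_weights(L, gamma=0.0)
        np.testing.assert_array_equal(w.weights, 1.0)

    def test_weights_scale_with_leadfield(self, rng):
        L = rng.normal(size=(5, 8))
        w1 = depth_weights(L, gamma=1.0)
        w2 = depth_weights(2.0 * L, gamma=1.0)
        np.testing.assert_allclose(w2.weights, 2.0 * w1.weights, rtol=1e-12)

    def test_deeper_sources_get_smaller_weights(self, montage):
        z = np.linspace(0.07, 0.01, 8)  # shallow -> deep
        line = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        src = SourceSpace(line, np.tile([0.0, 0.0, 1.0], (len(z), 1)))
        lf = three_sphere_leadfield(montage, src, n_terms=250,
                                    average_reference=False)
        w = depth_weights(lf, gamma=0.5)
        assert np.all(np.diff(w.weights) < 0)

    def test_zero_column_rejected(self):
        L = np.ones((4, 3))
        L[:, 1] = 0.0
        with pytest.raises(ValueError, match="column 1"):
            depth_weights(L)


class TestWMNEOperator:
    def test_identity_leadfield_identity_kernel(self):
        C = NoiseCovariance(matrix=np.eye(2), loading=0.0)
        W = SourceWeighting(weights=np.ones(2), gamma=0.0)
        op = build_wmne_operator(np.eye(2), C, W, lam=0.0)
        np.testing.assert_allclose(op.kernel, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(op.kernel @ [1.0, 0.0], [1.0, 0.0],
                                   atol=1e-12)

    def test_matches_normal_equation_oracle(self, rng):
        for _ in range(20):
            L, C, W, y = random_problem(rng)
            op = build_wmne_operator(L, C, W, lam=0.1)
            expected = ridge_source_estimate(L, C.matrix, W.weights, 0.1, y)
            assert np.max(np.abs(op.kernel @ y - expected)) < 1e-8

    def test_infinite_regularization_shrinks_kernel(self, rng):
        L = rng.normal(size=(8, 20))
        C = NoiseCovariance(matrix=np.eye(8), loading=0.0)
        W = depth_weights(L)
        small = build_wmne_operator(L, C, W, lam=1.0)
        large = build_wmne_operator(L, C, W, lam=1e6)
        assert np.linalg.norm(large.kernel) < 1e-4 * np.linalg.norm(small.kernel)

    def test_monotone_shrinkage_of_weighted_norm(self, rng):
        L, C, W, y = random_problem(rng)
        norms = []
        for lam in (0.01, 0.1, 1.0, 10.0):
            op = build_wmne_operator(L, C, W, lam=lam)
            norms.append(np.linalg.norm(W.weights * (op.kernel @ y)))
        assert np.all(np.diff(norms) < 0)

    def test_auto_lambda_positive(self, rng):
        L, C, W, _ = random_problem(rng)
        op = build_wmne_operator(L, C, W, lam="auto")
        assert op.lam > 0


class TestApplyInverse:
    @pytest.fixture()
    def operator(self, rng):
        L, C, W, _ = random_problem(rng, n_sensors=4, n_sources=10)
        return build_wmne_operator(L, C, W, lam=0.5)

    def test_zero_in_zero_out(self, operator):
        epochs = EpochSet(epochs=np.zeros((3, 4, 100)),
                          labels=np.array(["T1", "T2", "T3"]), fs=160.0)
        out = apply_inverse(operator, epochs)
        assert out.epochs.shape == (3, 10, 100)
        np.testing.assert_array_equal(out.epochs, 0.0)

    def test_linearity_and_label_conservation(self, operator, rng):
        e1 = rng.normal(size=(2, 4, 50))
        e2 = rng.normal(size=(2, 4, 50))
        labels = np.array(["T1", "T4"])
        mk = lambda e: EpochSet(epochs=e, labels=labels, fs=160.0)
        lhs = apply_inverse(operator, mk(2 * e1 - e2))
        rhs = (2 * apply_inverse(operator, mk(e1)).epochs
               - apply_inverse(operator, mk(e2)).epochs)
        np.testing.assert_allclose(lhs.epochs, rhs, rtol=1e-9, atol=1e-12)
        np.testing.assert_array_equal(lhs.labels, labels)

    def test_channel_mismatch_reported(self, operator):
        epochs = EpochSet(epochs=np.zeros((1, 7, 10)),
                          labels=np.array(["T1"]), fs=160.0)
        with pytest.raises(ValueError, match="does not match"):
            apply_inverse(operator, epochs)


class TestLocalization:
    def test_active_scout_recovered(self, forward_model):
        """A single strongly active scout dominates reconstructed band power."""
        montage, _, leadfield, scouts, _ = forward_model
        cfg = SimConfig(sensor_snr_db=30.0)
        t = np.arange(cfg.n_samples) / cfg.fs
        series = np.zeros((18, cfg.n_samples))
        target = 4  # the C3 scout
        series[target] = np.sin(2 * np.pi * 11.0 * t)
        truth = GroundTruth(series=series, label="T2",
                            active_rois=(target,), erd_bands=("mu",))
        scalp = project_to_scalp(truth, leadfield, scouts, cfg,
                                 np.random.default_rng(3))
        epochs = EpochSet(epochs=scalp[None], labels=np.array(["T2"]),
                          fs=cfg.fs, montage=montage.names)
        imager = WMNEInverse(leadfield=leadfield, lam="auto")
        imager.fit(np.random.default_rng(4).standard_normal((64, 5000))
                   * np.sqrt(np.mean(scalp ** 2)) / 10)
        source_epochs = imager.transform(epochs)
        scout_series = extract_scout_series(source_epochs, scouts)
        power = (scout_series[0] ** 2).mean(axis=1)
        assert int(np.argmax(power)) == target
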