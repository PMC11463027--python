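import numpy as np
import pytest

from cspselect import EpochSet, ValidationError, apply_csp, class_covariances, fit_csp
from cspselect.csp import ClassCovariances


def epochs_from_data(data, labels, sfreq=128.0):
    return EpochSet(
        data=data,
        labels=np.asarray(labels),
        ch_names=tuple(f"CH{i}" for i in range(data.shape[1])),
        sfreq=sfreq,
    )


def random_spd_pair(rng, n):
    def spd():
        a = rng.standard_normal((n, n))
        m = a @ a.T + 0.1 * np.eye(n)
        return m / np.trace(m)

    return ClassCovariances(
        sigma1=spd(), sigma2=spd(), class_order=("left", "right"),
        ch_names=tuple(f"CH{i}" for i in range(n)),
    )


class TestClassCovariances:
    def test_white_noise_approaches_scaled_identity(self):
        """Law of large numbers: i.i.d. unit-variance channels give
        covariance identity/n_channels after trace normalization."""
        rng = np.random.default_rng(0)
        n_ch = 4
        data = rng.standard_normal((4, n_ch, 100_000))
        covs = class_covariances(
            epochs_from_data(data, ["left", "left", "right", "right"])
        )
        target = np.eye(n_ch) / n_ch
        assert np.max(np.abs(covs.sigma1 - target)) < 0.02
        assert np.max(np.abs(covs.sigma2 - target)) < 0.02

    def test_full_shrinkage_forces_identity_target(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((4, 3, 50))
        covs = class_covariances(
            epochs_from_data(data, ["left", "left", "right", "right"]),
            shrinkage=1.0,
        )
        assert np.allclose(covs.sigma1, np.eye(3) / 3, atol=1e-12)
        assert np.allclose(covs.sigma2, np.eye(3) / 3, atol=1e-12)

    def test_perfectly_correlated_channels_give_rank_one(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(64)
        data = np.stack([np.stack([x, x])] * 4)  # every trial: ch2 == ch1
        covs = class_covariances(
            epochs_from_data(data, ["left", "left", "right", "right"])
        )
        assert abs(covs.sigma1[0, 1] - covs.sigma1[0, 0]) < 1e-12
        assert np.linalg.matrix_rank(covs.sigma1, tol=1e-10) == 1

    def test_trace_normalized_and_symmetric(self, strong_session):
        covs = class_covariances(strong_session)
        for s in (covs.sigma1, covs.sigma2):
            assert abs(np.trace(s) - 1) < 1e-9
            assert np.max(np.abs(s - s.T)) < 1e-12
            assert np.linalg.eigvalsh(s).min() >= -1e-10

    def test_single_trial_class_rejected(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((3, 2, 16))
        with pytest.raises(ValidationError, match="at least 2"):
            class_covariances(epochs_from_data(data, ["left", "left", "right"]))


class TestFitCSP:
    def test_diagonal_closed_form(self):
        covs = ClassCovariances(
            sigma1=np.diag([0.9, 0.1]), sigma2=np.diag([0.1, 0.9]),
            class_order=("left", "right"), ch_names=("A", "B"),
        )
        model = fit_csp(covs, 2)
        assert np.allclose(model.eigvals, [0.9, 0.1], atol=1e-10)
        # filters are the coordinate axes up to sign/scale
        for w in model.filters:
            assert np.min(np.abs(w)) < 1e-10 * np.max(np.abs(w))

    def test_equal_covariances_are_nondiscriminative(self):
        sigma = np.eye(3) / 3
        covs = ClassCovariances(sigma, sigma, ("left", "right"), ("A", "B", "C"))
        assert np.allclose(fit_csp(covs, 3).eigvals, 0.5, atol=1e-12)

    def test_leading_filter_beats_random_rayleigh_quotients(self, rng):
        """Brute-force oracle: no random unit vector achieves a higher
        variance-ratio Rayleigh quotient than the first CSP filter."""
        covs = random_spd_pair(rng, 6)
        model = fit_csp(covs, 6)
        lam = model.eigvals[0]
        w1 = model.filters[0] if lam >= 0.5 else model.filters[
            int(np.argmin(model.eigvals))
        ]
        num_sigma = covs.sigma1 if lam >= 0.5 else covs.sigma2
        comp = covs.sigma1 + covs.sigma2

        def ratio(w):
            return (w @ num_sigma @ w) / (w @ comp @ w)

        best = ratio(w1)
        vs = rng.standard_normal((1000, 6))
        rand = np.einsum("ij,jk,ik->i", vs, num_sigma, vs) / np.einsum(
            "ij,jk,ik->i", vs, comp, vs
        )
        assert best >= rand.max() - 1e-12

    def test_simultaneous_diagonalization(self, rng):
        covs = random_spd_pair(rng, 5)
        model = fit_csp(covs, 5)
        w = model.filters.T
        d1 = w.T @ covs.sigma1 @ w
        d2 = w.T @ covs.sigma2 @ w
        assert np.max(np.abs(d1 - np.diag(np.diag(d1)))) < 1e-8
        assert np.max(np.abs(d2 - np.diag(np.diag(d2)))) < 1e-8
        assert np.allclose(np.diag(d1) + np.diag(d2), 1.0, atol=1e-8)
        assert np.allclose(w.T @ (covs.sigma1 + covs.sigma2) @ w, np.eye(5),
                           atol=1e-8)

    def test_class_swap_maps_eigenvalues(self, rng):
        covs = random_spd_pair(rng, 4)
        m1 = fit_csp(covs, 4)
        m2 = fit_csp(covs.swapped(), 4)
        assert np.allclose(
            np.sort(m1.eigvals), np.sort(1 - m2.eigvals), atol=1e-10
        )
        # same filters up to sign and order
        f1 = {tuple(np.round(np.abs(w) / np.max(np.abs(w)), 6)) for w in m1.filters}
        f2 = {tuple(np.round(np.abs(w) / np.max(np.abs(w)), 6)) for w in m2.filters}
        assert f1 == f2

    def test_scale_invariance(self, strong_session):
        covs = class_covariances(strong_session)
        scaled = class_covariances(
            strong_session.with_data(strong_session.data * 17.0)
        )
        assert np.allclose(
            fit_csp(covs, 8).eigvals, fit_csp(scaled, 8).eigvals, atol=1e-10
        )

    def test_patterns_invert_filters(self, strong_session):
        model = fit_csp(class_covariances(strong_session), 16)
        assert np.allclose(model.patterns @ model.filters.T, np.eye(16), atol=1e-8)

    def test_deterministic_sign_convention(self, strong_session):
        covs = class_covariances(strong_session)
        m1, m2 = fit_csp(covs, 8), fit_csp(covs, 8)
        assert np.array_equal(m1.filters, m2.filters)
        for w in m1.filters:
            assert w[int(np.argmax(np.abs(w)))] > 0


class TestApplyCSP:
    def test_log_variance_of_projected_direction(self):
        """Projection oracle: features equal the log variance of the
        spatially filtered time course, computed directly."""
        rng = np.random.default_rng(7)
        data = rng.standard_normal((6, 3, 256))
        epochs = epochs_from_data(data, ["left", "right"] * 3)
        model = fit_csp(class_covariances(epochs), 3)
        feats = apply_csp(model, epochs)
        direct = np.log(
            np.einsum("kc,tcs->tks", model.filters, data).var(axis=-1, ddof=1)
        )
        assert np.allclose(feats, direct, atol=1e-12)

    def test_identical_trials_identical_features(self):
        rng = np.random.default_rng(8)
        one = rng.standard_normal((1, 3, 64))
        data = np.concatenate([one, one, one, one])
        epochs = epochs_from_data(data, ["left", "left", "right", "right"])
        model = fit_csp(class_covariances(epochs, shrinkage=0.5), 2)
        feats = apply_csp(model, epochs)
        assert np.allclose(feats[0], feats[1], atol=1e-12)

    def test_scaling_adds_twice_log_scale(self):
        rng = np.random.default_rng(9)
        data = rng.standard_normal((4, 3, 64))
        epochs = epochs_from_data(data, ["left", "left", "right", "right"])
        model = fit_csp(class_covariances(epochs), 3)
        c = 3.0
        shift = apply_csp(model, epochs.with_data(data * c)) - apply_csp(model, epochs)
        assert np.allclose(shift, 2 * np.log(c), atol=1e-10)

    def test_channel_mismatch_rejected(self, strong_session):
        model = fit_csp(class_covariances(strong_session), 4)
        from cspselect import ChannelSubset, subset_channels

        reduced = subset_channels(strong_session, ChannelSubset(("C3", "C4")))
        with pytest.raises(ValidationError, match="mismatch"):
            apply_csp(model, reduced)


def test_matches_mne_csp_on_shared_covariances(strong_session):
    """Independent oracle: MNE's CSP, driven by the same per-trial
    trace-normalized covariance convention, finds filters with the same
    leading discriminability."""
    mne = pytest.importorskip("mne")
    from cspselect import ChannelSubset, subset_channels

    small = subset_channels(strong_session, ChannelSubset(("C3", "Cz", "C4")))
    csp = mne.decoding.CSP(
        n_components=3, cov_est="epoch", norm_trace=True, transform_into="csp_space"
    )
    y = (small.labels == "right").astype(int)
    csp.fit(small.data.copy(), y)
    ours = fit_csp(class_covariances(small), 3)
    covs = class_covariances(small)
    comp = covs.sigma1 + covs.sigma2

    def disc(w):
        lam = (w @ covs.sigma1 @ w) / (w @ comp @ w)
        return max(lam, 1 - lam)

    best_mne = max(disc(w) for w in csp.filters_)
    assert abs(disc(ours.filters[0]) - best_mne) < 0.05
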