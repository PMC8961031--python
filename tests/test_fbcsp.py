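"""CSP fitting, log-variance features, MI estimation and mode selection."""

import numpy as np
import pandas as pd
import pytest

from neuromode.fbcsp import (
    BandDefinition,
    CSPModel,
    apply_csp,
    extract_features,
    filter_bank,
    fit_csp,
    mutual_information,
    pattern_topography,
    rank_modes,
    select_top_modes,
)

from .conftest import make_epochs


def _epochs_with_cov(rng, cov_chol, n_trials=30, n_samp=400):
    n_ch = cov_chol.shape[0]
    data = np.einsum(
        "ij,tjs->tis", cov_chol, rng.standard_normal((n_trials, n_ch, n_samp))
    )
    return make_epochs(data, fs=100.0, tmin=0.0)


def csp_oracle_angle(c0, c1, step_deg=1.0):
    """Exhaustive unit-vector search maximising var0/(var0+var1) (2-D)."""
    best, best_angle = -1.0, None
    for deg in np.arange(0.0, 180.0, step_deg):
        w = np.array([np.cos(np.radians(deg)), np.sin(np.radians(deg))])
        v0, v1 = w @ c0 @ w, w @ c1 @ w
        ratio = v0 / (v0 + v1)
        if ratio > best:
            best, best_angle = ratio, deg
    return best_angle, best


class TestFitCsp:
    def test_identical_covariances_give_half_ratios(self, rng):
        ep = _epochs_with_cov(rng, np.eye(3))
        model = fit_csp(ep, ep, m=1, window=None)
        np.testing.assert_allclose(model.eigenvalues, 0.5, atol=1e-9)

    def test_joint_diagonalisation_invariants(self, rng):
        ep0 = _epochs_with_cov(rng, np.diag([2.0, 1.0, 0.5]))
        ep1 = _epochs_with_cov(rng, np.diag([0.5, 1.0, 2.0]))
        model = fit_csp(ep0, ep1, m=1, window=None)
        from neuromode.fbcsp import _class_covariance

        c0 = _class_covariance(ep0.data)
        c1 = _class_covariance(ep1.data)
        w = model.filters
        d0, d1 = w @ c0 @ w.T, w @ c1 @ w.T
        assert np.abs(d0 - np.diag(np.diag(d0))).max() < 1e-8
        assert np.abs(d1 - np.diag(np.diag(d1))).max() < 1e-8
        np.testing.assert_allclose(np.diag(d0) + np.diag(d1), 1.0, atol=1e-9)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        assert np.all((model.eigenvalues >= 0) & (model.eigenvalues <= 1))

    def test_two_channel_toy_matches_grid_oracle(self, rng):
        ep0 = _epochs_with_cov(rng, np.diag([2.0, 1.0]), n_trials=100)
        ep1 = _epochs_with_cov(rng, np.diag([1.0, 2.0]), n_trials=100)
        model = fit_csp(ep0, ep1, m=1, window=None)
        lead = model.filters[0] / np.linalg.norm(model.filters[0])
        angle = np.degrees(np.arctan2(abs(lead[1]), abs(lead[0])))
        assert angle < 2.0  # leading filter hugs the channel-0 axis

    def test_m_default_keeps_four_components(self, rng):
        ep0 = _epochs_with_cov(rng, np.eye(5))
        ep1 = _epochs_with_cov(rng, np.diag([2, 1, 1, 1, 0.5]).astype(float))
        model = fit_csp(ep0, ep1, window=None)
        assert model.m == 2 and model.kept_components.size == 4

    def test_rank_deficient_covariance_suggests_ridge(self, rng):
        data = rng.standard_normal((10, 3, 200))
        data[:, 2, :] = data[:, 0, :]  # linearly dependent channel
        ep = make_epochs(data, fs=100.0, tmin=0.0)
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            fit_csp(ep, ep, m=1, window=None)


class TestApplyAndFeatures:
    def test_identity_filters_return_input(self, rng):
        data = rng.standard_normal((4, 2, 100))
        ep = make_epochs(data, fs=100.0, tmin=0.0)
        model = CSPModel(
            band=BandDefinition("b", 1, 2), filters=np.eye(2), patterns=np.eye(2),
            eigenvalues=np.array([0.6, 0.4]), m=1, channel_names=ep.channel_names,
        )
        z = apply_csp(model, ep)
        np.testing.assert_allclose(z, data)

    def test_linearity(self, rng):
        data = rng.standard_normal((3, 2, 50))
        ep = make_epochs(data, fs=100.0, tmin=0.0)
        ep3 = make_epochs(3 * data, fs=100.0, tmin=0.0)
        model = CSPModel(
            band=BandDefinition("b", 1, 2),
            filters=rng.standard_normal((2, 2)), patterns=np.eye(2),
            eigenvalues=np.array([0.6, 0.4]), m=1, channel_names=ep.channel_names,
        )
        np.testing.assert_allclose(apply_csp(model, ep3), 3 * apply_csp(model, ep))

    def test_hand_computed_projection(self):
        w = np.array([[1.0, 2.0], [3.0, 4.0]])
        trial = np.array([[1.0, 0.0, 2.0, 1.0], [0.0, 1.0, 1.0, 2.0]])
        ep = make_epochs(trial[None], fs=100.0, tmin=0.0)
        model = CSPModel(
            band=BandDefinition("b", 1, 2), filters=w, patterns=np.linalg.inv(w),
            eigenvalues=np.array([0.7, 0.3]), m=1, channel_names=ep.channel_names,
        )
        np.testing.assert_allclose(apply_csp(model, ep)[0], w @ trial)

    def test_equal_variances_feature(self):
        z = np.tile(np.array([1.0, -1.0]), 50)[None, None, :].repeat(4, axis=1)
        feats = extract_features(z)
        np.testing.assert_allclose(feats, np.log(0.25), atol=1e-12)

    def test_unequal_variances_feature(self):
        base = np.tile(np.array([1.0, -1.0]), 50)
        z = np.stack([base, base, base, np.sqrt(5) * base])[None]
        feats = extract_features(z)
        np.testing.assert_allclose(
            feats[0], np.log([1 / 8, 1 / 8, 1 / 8, 5 / 8]), atol=1e-12
        )

    def test_feature_normalisation_and_sign(self, rng):
        z = rng.standard_normal((6, 4, 128))
        feats = extract_features(z)
        np.testing.assert_allclose(np.exp(feats).sum(axis=1), 1.0, atol=1e-9)
        assert np.all(feats <= 0)

    def test_scale_invariance(self, rng):
        z = rng.standard_normal((3, 4, 64))
        np.testing.assert_allclose(
            extract_features(z), extract_features(7.3 * z), atol=1e-9
        )


class TestMutualInformation:
    def test_constant_feature_zero_bits(self):
        x = np.full(40, 2.5)
        labels = np.arange(40) % 2
        assert mutual_information(x, labels) == 0.0

    def test_perfect_separation_one_bit(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        labels = np.r_[np.zeros(20), np.ones(20)]
        assert mutual_information(x, labels) == pytest.approx(1.0, abs=1e-12)

    def test_discrete_joint_matches_direct_summation(self):
        # joint p(x, l) = [[0.4, 0.1], [0.1, 0.4]] realised exactly in counts
        x = np.r_[np.zeros(8), np.zeros(2), np.ones(2), np.ones(8)]
        labels = np.r_[np.zeros(8), np.ones(2), np.zeros(2), np.ones(8)]
        joint = np.array([[0.4, 0.1], [0.1, 0.4]])
        px, pl = joint.sum(1), joint.sum(0)
        oracle = sum(
            joint[i, j] * np.log2(joint[i, j] / (px[i] * pl[j]))
            for i in range(2)
            for j in range(2)
        )
        assert mutual_information(x, labels) == pytest.approx(oracle, abs=1e-12)
        assert oracle == pytest.approx(0.278, abs=5e-4)

    def test_bounds_for_balanced_binary_labels(self, rng):
        labels = np.arange(100) % 2
        for _ in range(50):
            x = rng.standard_normal(100)
            mi = mutual_information(x, labels)
            assert 0.0 <= mi <= 1.0

    def test_label_noise_does_not_inflate_mi(self, rng):
        # label-independent noise added to an informative feature should not
        # raise the estimate beyond its small-sample bias (monotone trend)
        wins = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            labels = np.arange(200) % 2
            x = labels + 0.5 * r.standard_normal(200)
            mis = [
                mutual_information(x + s * r.standard_normal(200), labels)
                for s in (0.0, 1.0, 3.0)
            ]
            wins += mis[0] >= mis[1] >= mis[2] - 0.05
        assert wins >= 9

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            mutual_information(np.arange(10.0), np.zeros(10))

    def test_quantile_strategy_agrees_on_discrete_data(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        labels = np.r_[np.zeros(10), np.ones(10)]
        a = mutual_information(x, labels, strategy="width")
        b = mutual_information(x, labels, strategy="quantile")
        assert a == pytest.approx(b, abs=1e-12)


class TestRankingAndTopography:
    def test_rank_and_tie_break_prefers_lower_band(self):
        x_sep = np.r_[np.zeros(10), np.ones(10)][:, None]
        labels = np.r_[np.zeros(10), np.ones(10)]
        feats = {"beta": x_sep, "theta": x_sep}  # identical MI, tie
        ranking = rank_modes(feats, labels, band_order={"theta": 4.0, "beta": 13.0})
        assert ranking.iloc[0]["band"] == "theta"

    def test_select_top_modes_k_equals_rows(self):
        ranking = pd.DataFrame(
            {"band": ["theta"], "component": [0], "mi_bits": [0.5], "rank": [1]}
        )
        out = select_top_modes(ranking, k=1)
        assert len(out) == 1

    def test_select_more_than_available_warns_and_returns_all(self, caplog):
        ranking = pd.DataFrame(
            {"band": ["theta"], "component": [0], "mi_bits": [0.5], "rank": [1]}
        )
        with caplog.at_level("WARNING"):
            out = select_top_modes(ranking, k=5)
        assert len(out) == 1

    def test_orthonormal_filters_pattern_equals_filter_row(self):
        theta = np.radians(30)
        w = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        model = CSPModel(
            band=BandDefinition("b", 1, 2), filters=w, patterns=np.linalg.inv(w),
            eigenvalues=np.array([0.7, 0.3]), m=1, channel_names=["a", "b"],
        )
        topo = pattern_topography(model, 0)
        expected = w[0] / np.abs(w[0]).max()
        np.testing.assert_allclose(topo["weight"], expected, atol=1e-12)

    def test_topography_max_weight_is_one(self, rng):
        w = rng.standard_normal((3, 3))
        model = CSPModel(
            band=BandDefinition("b", 1, 2), filters=w, patterns=np.linalg.inv(w),
            eigenvalues=np.array([0.8, 0.5, 0.2]), m=1, channel_names=["a", "b", "c"],
        )
        topo = pattern_topography(model, 1)  # kept set is {0, 2} -> index 1 = last
        assert np.abs(topo["weight"]).max() == pytest.approx(1.0)

    def test_bad_component_rejected(self):
        model = CSPModel(
            band=BandDefinition("b", 1, 2), filters=np.eye(2), patterns=np.eye(2),
            eigenvalues=np.array([0.6, 0.4]), m=1, channel_names=["a", "b"],
        )
        with pytest.raises(ValueError):
            pattern_topography(model, 5)


class TestFilterBank:
    def test_theta_tone_survives_theta_branch_only(self):
        fs = 250.0
        t = np.arange(int(3 * fs)) / fs
        sig = np.sin(2 * np.pi * 6 * t)
        ep = make_epochs(np.tile(sig, (3, 2, 1)), fs=fs, tmin=0.0)
        bands = (BandDefinition("theta", 4, 8), BandDefinition("beta", 13, 30))
        out = filter_bank(ep, bands)
        mid = slice(int(fs), int(2 * fs))
        theta_amp = np.abs(out["theta"].data[0, 0, mid]).max()
        beta_amp = np.abs(out["beta"].data[0, 0, mid]).max()
        assert theta_amp > 0.9
        assert beta_amp < theta_amp * 10 ** (-20 / 20)

    def test_trial_channel_counts_preserved(self, rng):
        ep = make_epochs(rng.standard_normal((5, 3, 750)), fs=250.0, tmin=0.0)
        out = filter_bank(ep, (BandDefinition("theta", 4, 8),))
        assert out["theta"].data.shape == ep.data.shape

    def test_band_above_nyquist_rejected(self, rng):
        ep = make_epochs(rng.standard_normal((2, 2, 750)), fs=100.0, tmin=0.0)
        with pytest.raises(ValueError):
            filter_bank(ep, (BandDefinition("high", 30, 60),))
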