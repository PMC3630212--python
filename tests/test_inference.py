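"""Optimal posteriors, KL divergence, and information-loss metrics."""

import numpy as np
import pytest

from oracles import GridPosterior, GridPosterior1D
from multisense.inference import (
    GaussianPosterior,
    InferenceError,
    center_of_mass,
    coordtrans_posterior,
    decoupled_optimal_covariance,
    flat_prior_proxy,
    gaussian_kl,
    info_loss_fraction,
    integration_moments,
    integration_posterior,
)
from multisense.kinematics import ArmModel, forward_kinematics
from multisense.popcode import (
    GainPrior,
    StimulusPrior,
    build_population,
    mean_rates,
)

ARM = ArmModel()
ARM1D = ArmModel(mode="cosine-1d", joint_limits=(np.pi / 6, 5 * np.pi / 6))


@pytest.fixture(scope="module")
def pops():
    from multisense.experiments import workspace_bounds

    return {
        "prop": build_population("prop", ARM.joint_limits, 12),
        "vis": build_population("vis", workspace_bounds(ARM), 12),
    }


class TestCenterOfMass:
    def test_single_spike_returns_preferred(self, pops):
        k = np.zeros(pops["prop"].n_units)
        k[37] = 1
        assert np.allclose(center_of_mass(k, pops["prop"]), pops["prop"].preferred[37])

    def test_two_equal_counts_midpoint(self, pops):
        k = np.zeros(pops["prop"].n_units)
        k[[10, 50]] = 3
        mid = pops["prop"].preferred[[10, 50]].mean(axis=0)
        assert np.allclose(center_of_mass(k, pops["prop"]), mid)

    def test_zero_counts_flagged_nan(self, pops):
        assert np.all(np.isnan(center_of_mass(np.zeros(pops["prop"].n_units), pops["prop"])))

    def test_matches_grid_likelihood_argmax(self, pops):
        # the center of mass is the MLE for one population (interior stimulus)
        rng = np.random.default_rng(5)
        pop = pops["prop"]
        theta = np.asarray(ARM.joint_center) + 0.05
        k = rng.poisson(mean_rates(theta, 15.0, pop))
        lims = np.asarray(ARM.joint_limits)
        g = np.stack(
            np.meshgrid(
                np.linspace(*lims[0], 300), np.linspace(*lims[1], 300), indexing="ij"
            ),
            axis=-1,
        ).reshape(-1, 2)
        phi = mean_rates(g, 1.0, pop)
        ll = np.log(np.maximum(phi, 1e-300)) @ k - 15.0 * phi.sum(axis=1)
        best = g[np.argmax(ll)]
        com = center_of_mass(k, pop)
        spacing = np.array([np.ptp(lims[0]) / 299, np.ptp(lims[1]) / 299])
        assert np.all(np.abs(com - best) < 3 * spacing + 0.01)


class TestIntegrationPosterior:
    def test_prop_only_when_vis_silent(self, pops):
        rng = np.random.default_rng(0)
        k = rng.poisson(mean_rates(ARM.joint_center, 15.0, pops["prop"]))
        post = integration_posterior(
            k, np.zeros(pops["vis"].n_units), None, ARM, pops["prop"], pops["vis"]
        )
        expected = pops["prop"].sigma_tc**2 / k.sum() * np.eye(2)
        assert np.allclose(post.covariance, expected, rtol=1e-9)

    def test_all_silent_flat_prior_raises(self, pops):
        with pytest.raises(InferenceError):
            integration_posterior(
                np.zeros(pops["prop"].n_units),
                np.zeros(pops["vis"].n_units),
                None, ARM, pops["prop"], pops["vis"],
            )

    def test_matches_grid_oracle(self):
        """Closed form vs brute-force grid integration on random interior trials.

        Uses 20x20 populations: the Gaussian-posterior approximation relies
        on total counts large enough for the errors to stay in the linear
        regime of the kinematics, which very sparse codes do not provide.
        """
        from multisense.experiments import workspace_bounds

        big = {
            "prop": build_population("prop", ARM.joint_limits, 20),
            "vis": build_population("vis", workspace_bounds(ARM), 20),
        }
        oracle = GridPosterior(ARM, big["prop"], big["vis"], n_grid=121, half_width_sd=6)
        rng = np.random.default_rng(11)
        lims = np.asarray(ARM.joint_limits)
        span = lims[:, 1] - lims[:, 0]
        n_trials = 30
        th = rng.uniform(lims[:, 0] + 0.25 * span, lims[:, 1] - 0.25 * span, (n_trials, 2))
        gp = rng.uniform(12, 18, n_trials)
        gv = rng.uniform(12, 18, n_trials)
        kp = rng.poisson(mean_rates(th, gp, big["prop"]))
        kv = rng.poisson(mean_rates(forward_kinematics(th, ARM), gv, big["vis"]))
        means, covs, ok = integration_moments(
            kp, kv, None, ARM, big["prop"], big["vis"]
        )
        assert np.all(ok)
        spacing = max(big["prop"].spacing)
        for i in range(n_trials):
            m_ref, c_ref = oracle.moments(kp[i], kv[i], gp[i], gv[i])
            assert np.linalg.norm(means[i] - m_ref) < 0.1 * spacing
            rel = np.linalg.norm(covs[i] - c_ref) / np.linalg.norm(c_ref)
            assert rel < 0.02

    def test_precision_additive_in_cues(self, pops):
        rng = np.random.default_rng(3)
        th = np.asarray(ARM.joint_center)
        kp = rng.poisson(mean_rates(th, 15.0, pops["prop"]))
        kv = rng.poisson(mean_rates(forward_kinematics(th, ARM), 15.0, pops["vis"]))
        _, cov_both, _ = integration_moments(kp, kv, None, ARM, pops["prop"], pops["vis"])
        _, cov_prop, _ = integration_moments(
            kp, np.zeros_like(kv), None, ARM, pops["prop"], pops["vis"]
        )
        gap = np.linalg.inv(cov_both[0]) - np.linalg.inv(cov_prop[0])
        assert np.all(np.linalg.eigvalsh(gap) >= -1e-9)

    def test_high_gain_mean_tracks_reliable_cue(self, pops):
        rng = np.random.default_rng(4)
        th = np.asarray(ARM.joint_center) + 0.1
        kp = rng.poisson(mean_rates(th, 5.0, pops["prop"]))
        kv = rng.poisson(mean_rates(forward_kinematics(th, ARM), 300.0, pops["vis"]))
        mean, _, _ = integration_moments(kp, kv, None, ARM, pops["prop"], pops["vis"])
        oracle = GridPosterior(ARM, pops["prop"], pops["vis"], n_grid=150)
        m_ref, _ = oracle.moments(kp, kv, 5.0, 300.0)
        assert np.linalg.norm(mean[0] - m_ref) < 0.02


class TestCoordtransPosterior:
    @pytest.fixture(scope="class")
    def pops1d(self):
        return {
            "prop": build_population("prop", [tuple(ARM1D.joint_limits)], 24),
            "vis": build_population("vis", [(-13.5, 13.5)], 24),
            "eye": build_population("eye", [(-13.5, 13.5)], 24),
        }

    def draw(self, pops1d, xb, eye, gains, seed=0):
        rng = np.random.default_rng(seed)
        th = np.arccos(xb / ARM1D.link_1d)
        return {
            "prop": rng.poisson(mean_rates(np.atleast_1d(th), gains["prop"], pops1d["prop"])),
            "vis": rng.poisson(mean_rates(np.atleast_1d(xb - eye), gains["vis"], pops1d["vis"])),
            "eye": rng.poisson(mean_rates(np.atleast_1d(eye), gains["eye"], pops1d["eye"])),
        }

    def test_vis_eye_chain_without_prop(self, pops1d):
        gains = {"prop": 45.0, "vis": 15.0, "eye": 15.0}
        k = self.draw(pops1d, 5.0, -3.0, gains, seed=1)
        kz = np.zeros(pops1d["prop"].n_units)
        post = coordtrans_posterior(kz, k["vis"], k["eye"], pops1d, ARM1D)
        com_v = center_of_mass(k["vis"], pops1d["vis"])[0]
        com_e = center_of_mass(k["eye"], pops1d["eye"])[0]
        var = (
            pops1d["vis"].sigma_tc**2 / k["vis"].sum()
            + pops1d["eye"].sigma_tc**2 / k["eye"].sum()
        )
        assert post.mean[0] == pytest.approx(com_v + com_e)
        assert post.covariance[0, 0] == pytest.approx(var)

    def test_three_cue_matches_grid_oracle(self, pops1d):
        oracle = GridPosterior1D(ARM1D, pops1d, (-27, 27), (-13.5, 13.5), n_grid=200)
        gains = {"prop": 45.0, "vis": 15.0, "eye": 15.0}
        for seed, xb, eye in [(2, 4.0, 6.0), (3, -8.0, -2.0), (4, 0.5, 10.0)]:
            k = self.draw(pops1d, xb, eye, gains, seed=seed)
            post = coordtrans_posterior(
                k["prop"], k["vis"], k["eye"], pops1d, ARM1D
            )
            counts = k
            m_ref, v_ref = oracle.xb_moments(counts, gains)
            grid_res = 54.0 / 199
            assert abs(post.mean[0] - m_ref) < 2 * grid_res
            assert post.covariance[0, 0] == pytest.approx(v_ref, rel=0.15)

    def test_removing_eye_cue_inflates_variance(self, pops1d):
        gains = {"prop": 45.0, "vis": 15.0, "eye": 15.0}
        k = self.draw(pops1d, 5.0, -3.0, gains, seed=5)
        full = coordtrans_posterior(k["prop"], k["vis"], k["eye"], pops1d, ARM1D)
        no_eye = coordtrans_posterior(
            k["prop"], k["vis"], np.zeros(pops1d["eye"].n_units), pops1d, ARM1D
        )
        assert no_eye.covariance[0, 0] > full.covariance[0, 0]


class TestMixtureCovariance:
    def test_endpoints(self):
        a, b = np.diag([1.0, 2.0]), np.diag([3.0, 5.0])
        assert np.allclose(decoupled_optimal_covariance(a, b, 1.0), a)
        assert np.allclose(decoupled_optimal_covariance(a, b, 0.0), b)

    def test_matches_condition_aware_estimator_simulation(self):
        # 1D toy: two noisy cues of s; coupled trials integrate, others use cue 1
        rng = np.random.default_rng(8)
        n = 10_000
        p = 0.6
        s = rng.normal(0, 1, n)
        v1, v2 = 0.04, 0.09
        c1 = s + rng.normal(0, np.sqrt(v1), n)
        c2 = s + rng.normal(0, np.sqrt(v2), n)
        coupled = rng.random(n) < p
        w = (1 / v1) / (1 / v1 + 1 / v2)
        est = np.where(coupled, w * c1 + (1 - w) * c2, c1)
        err_var = np.var(est - s)
        pred = decoupled_optimal_covariance(
            np.array([[1 / (1 / v1 + 1 / v2)]]), np.array([[v1]]), p
        )[0, 0]
        assert err_var == pytest.approx(pred, rel=0.05)


class TestKL:
    def test_identical_distributions(self):
        p = GaussianPosterior("prop", [0.1, 0.2], np.diag([1.0, 2.0]))
        assert gaussian_kl(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_1d_closed_form_cov_only(self):
        p = GaussianPosterior("prop", [0.0], [[1.0]])
        q = GaussianPosterior("prop", [0.0], [[2.0]])
        assert gaussian_kl(p, q, cov_only=True) == pytest.approx(
            0.5 * (0.5 - 1 + np.log(2)), abs=1e-12
        )
        assert gaussian_kl(p, q, cov_only=True) == pytest.approx(0.0966, abs=1e-4)

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            a = rng.normal(size=(2, 2))
            b = rng.normal(size=(2, 2))
            p = GaussianPosterior("prop", rng.normal(size=2), a @ a.T + 0.1 * np.eye(2))
            q = GaussianPosterior("prop", rng.normal(size=2), b @ b.T + 0.1 * np.eye(2))
            assert gaussian_kl(p, q) >= 0

    def test_space_mismatch_rejected(self):
        p = GaussianPosterior("prop", [0.0], [[1.0]])
        q = GaussianPosterior("vis", [0.0], [[1.0]])
        with pytest.raises(InferenceError):
            gaussian_kl(p, q)

    def test_non_spd_rejected(self):
        with pytest.raises(InferenceError):
            GaussianPosterior("prop", [0.0, 0.0], [[1.0, 2.0], [2.0, 1.0]])


class TestInfoLoss:
    def setup_method(self):
        self.opt = GaussianPosterior("prop", [0.5, 1.5], np.diag([1e-4, 2e-4]))
        self.prior = flat_prior_proxy(ARM.joint_limits)

    def test_best_case_zero(self):
        assert info_loss_fraction(self.opt, self.opt, self.prior) == pytest.approx(0.0)

    def test_worst_case_one(self):
        assert info_loss_fraction(self.opt, self.prior, self.prior) == pytest.approx(1.0)

    def test_monotone_in_model_divergence(self):
        m1 = GaussianPosterior("prop", [0.5, 1.5], np.diag([1.5e-4, 2.5e-4]))
        m2 = GaussianPosterior("prop", [0.5, 1.5], np.diag([4e-4, 8e-4]))
        f1 = info_loss_fraction(self.opt, m1, self.prior)
        f2 = info_loss_fraction(self.opt, m2, self.prior)
        assert 0 < f1 < f2

    def test_flat_prior_proxy_moments(self):
        g = flat_prior_proxy([(0.0, 1.0), (0.0, 2.0)])
        assert np.allclose(g.mean, [0.5, 1.0])
        assert np.allclose(np.diag(g.covariance), [1 / 12, 4 / 12])
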