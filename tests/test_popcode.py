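"""Population encoding and the synthetic trial generators."""

import numpy as np
import pytest

from multisense._rng import seed_stream
from multisense.inference import center_of_mass
from multisense.kinematics import ArmModel, forward_kinematics, inverse_1d, inverse_kinematics
from multisense.popcode import (
    ConfigError,
    GainPrior,
    StimulusPrior,
    build_population,
    encode,
    input_covariance_scale,
    mean_rates,
    sample_coordtrans_batch,
    sample_decoupled_batch,
    sample_discrepant_batch,
    sample_integration_batch,
)

ARM = ArmModel()
FWHM = 2 * np.sqrt(2 * np.log(2))


def small_pops(n=12):
    from multisense.experiments import workspace_bounds

    return {
        "prop": build_population("prop", ARM.joint_limits, n),
        "vis": build_population("vis", workspace_bounds(ARM), n),
    }


class TestBuildPopulation:
    def test_standard_grid_size(self):
        pop = build_population("prop", ARM.joint_limits, 30)
        assert pop.n_units == 900

    def test_zero_margin_spans_response_area(self):
        pop = build_population("prop", [(0.0, 1.0), (0.0, 2.0)], 5, margin_sd=0.0)
        pref = pop.preferred
        assert pref[:, 0].min() == pytest.approx(0.0)
        assert pref[:, 0].max() == pytest.approx(1.0)
        assert pref[:, 1].max() == pytest.approx(2.0)

    def test_fwhm_sigma_identity(self):
        pop = build_population("vis", [(0.0, 60.0)], 30)
        assert pop.sigma_tc == pytest.approx(60.0 / (6 * FWHM), rel=1e-12)
        assert pop.sigma_tc == pytest.approx(4.2466, abs=1e-3)

    def test_margin_width(self):
        pop = build_population("prop", [(0.0, 1.0)], 9, margin_sd=4.0)
        assert pop.preferred[0, 0] == pytest.approx(-4 * pop.sigma_tc)
        assert pop.preferred[-1, 0] == pytest.approx(1.0 + 4 * pop.sigma_tc)

    def test_regular_spacing(self):
        pop = build_population("prop", ARM.joint_limits, 7)
        xs = np.unique(pop.preferred[:, 0])
        assert np.allclose(np.diff(xs), pop.spacing[0])

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ConfigError):
            build_population("prop", [(1.0, 1.0)], 5)


class TestRatesAndEncoding:
    def test_rate_at_preferred_equals_gain(self):
        pop = build_population("prop", ARM.joint_limits, 8)
        rates = mean_rates(pop.preferred[30], 15.0, pop)
        assert rates[30] == pytest.approx(15.0)
        assert rates.max() == pytest.approx(15.0)

    def test_zero_gain_silences(self):
        pop = build_population("prop", ARM.joint_limits, 8)
        assert np.all(mean_rates([0.5, 1.5], 0.0, pop) == 0)
        assert np.all(encode([0.5, 1.5], 0.0, pop, np.random.default_rng(0)) == 0)

    def test_total_count_matches_grid_sum_formula(self):
        # sum over the grid of an interior Gaussian bump ~ g * 2 pi sigma^2 / (d1 d2)
        pop = build_population("prop", ARM.joint_limits, 20)
        center = np.asarray(ARM.joint_center)
        total = mean_rates(center, 15.0, pop).sum()
        expected = 15.0 * 2 * np.pi * pop.sigma_tc**2 / np.prod(pop.spacing)
        assert total == pytest.approx(expected, rel=1e-3)

    def test_poisson_moments(self):
        pop = build_population("prop", ARM.joint_limits, 8)
        rng = np.random.default_rng(1)
        rates = mean_rates(ARM.joint_center, 15.0, pop)
        draws = rng.poisson(np.broadcast_to(rates, (10_000, rates.size)))
        se = np.sqrt(rates / 10_000)
        assert np.all(np.abs(draws.mean(0) - rates) < 3 * se + 1e-9)
        big = rates > 1.0
        assert np.allclose(draws.var(0)[big], draws.mean(0)[big], rtol=0.2)

    def test_translation_covariance_in_interior(self):
        pop = build_population("prop", ARM.joint_limits, 15)
        s0 = np.asarray(ARM.joint_center)
        r0 = mean_rates(s0, 15.0, pop).reshape(15, 15)
        r1 = mean_rates(s0 + [pop.spacing[0], 0.0], 15.0, pop).reshape(15, 15)
        assert np.allclose(r1[1:, :], r0[:-1, :], atol=1e-9)

    def test_margin_suppresses_edge_spillover(self):
        # a stimulus at the response-area edge barely excites the grid border
        pop = build_population("prop", ARM.joint_limits, 15)
        lims = np.asarray(ARM.joint_limits)
        edge = np.array([lims[0, 0], lims[1, 0]])
        rates = mean_rates(edge, 15.0, pop).reshape(15, 15)
        assert rates[0, 0] < 1e-4 * 15.0


class TestIntegrationBatch:
    def test_empty_batch(self):
        pops = small_pops()
        b = sample_integration_batch(
            0, StimulusPrior(), {"prop": GainPrior(), "vis": GainPrior()},
            ARM, pops, np.random.default_rng(0),
        )
        assert b.n_trials == 0 and b.counts.shape[1] == 2 * pops["prop"].n_units

    def test_visual_stimulus_consistent(self):
        pops = small_pops()
        b = sample_integration_batch(
            50, StimulusPrior(), {"prop": GainPrior(), "vis": GainPrior()},
            ARM, pops, np.random.default_rng(0),
        )
        assert np.allclose(b.x, forward_kinematics(b.theta, ARM))

    def test_mean_total_count_at_fixed_gain(self):
        pops = small_pops()
        gp = {"prop": GainPrior(15, 15), "vis": GainPrior(15, 15)}
        b = sample_integration_batch(
            1000, StimulusPrior(), gp, ARM, pops, np.random.default_rng(0)
        )
        got = b.counts_for("prop").sum(axis=1).mean()
        pred = np.mean(
            [mean_rates(t, 15.0, pops["prop"]).sum() for t in b.theta[:200]]
        )
        assert got == pytest.approx(pred, rel=0.05)

    def test_reproducible_from_seed(self):
        pops = small_pops()
        args = (20, StimulusPrior(), {"prop": GainPrior(), "vis": GainPrior()}, ARM, pops)
        b1 = sample_integration_batch(*args, seed_stream(7, "train-data"))
        b2 = sample_integration_batch(*args, seed_stream(7, "train-data"))
        assert np.array_equal(b1.counts, b2.counts)
        assert np.allclose(b1.theta, b2.theta)


class TestDiscrepantBatch:
    def test_zero_discrepancy_matches_integration(self):
        pops = small_pops()
        gp = {"prop": GainPrior(), "vis": GainPrior()}
        b = sample_discrepant_batch(
            100, 0.0, [1, 0], StimulusPrior(), gp, ARM, pops,
            np.random.default_rng(0),
        )
        assert np.allclose(b.meta["discrepancy"], 0.0)
        assert b.meta["n_resampled"] == 0

    def test_decoded_shift_matches_delta(self):
        pops = small_pops()
        gp = {"prop": GainPrior(), "vis": GainPrior()}
        b = sample_discrepant_batch(
            3000, 5.0, [1, 0], StimulusPrior(), gp, ARM, pops,
            np.random.default_rng(1),
        )
        delta = np.asarray(b.meta["discrepancy"])
        com_p = center_of_mass(b.counts_for("prop"), pops["prop"])
        com_v = center_of_mass(b.counts_for("vis"), pops["vis"])
        ok = np.isfinite(com_p).all(1) & np.isfinite(com_v).all(1)
        th_v = inverse_kinematics(com_v[ok], ARM, clamp=True)
        gap = (com_p[ok] - th_v).mean(axis=0)
        assert np.allclose(gap, delta, atol=4 * np.abs(delta).max() / 10 + 0.01)

    def test_scale_unit_positive(self):
        pops = small_pops()
        s = input_covariance_scale(ARM, pops, {"prop": GainPrior(), "vis": GainPrior()}, [1, 0])
        assert 0 < s < 0.2  # a few hundredths of a radian for these codes


class TestDecoupledBatch:
    def test_fully_coupled_has_silent_toggle(self):
        pops = small_pops()
        gp = {"prop": GainPrior(), "vis": GainPrior()}
        b = sample_decoupled_batch(
            200, 1.0, StimulusPrior(), gp, ARM, pops, np.random.default_rng(0)
        )
        assert np.all(b.counts_for("toggle") == 0)
        assert np.allclose(b.x, forward_kinematics(b.theta, ARM))

    def test_coupling_fraction_and_independence(self):
        pops = small_pops(8)
        gp = {"prop": GainPrior(), "vis": GainPrior()}
        b = sample_decoupled_batch(
            10_000, 0.5, StimulusPrior(), gp, ARM, pops, np.random.default_rng(2)
        )
        frac = np.mean(b.meta["coupled"])
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(10_000)
        dec = ~np.asarray(b.meta["coupled"])
        th_r = b.theta[dec]
        th_l = inverse_kinematics(b.x[dec], ARM)
        corr = np.corrcoef(th_r[:, 0], th_l[:, 0])[0, 1]
        assert abs(corr) < 0.05

    def test_toggle_fires_on_decoupled_trials(self):
        pops = small_pops(8)
        gp = {"prop": GainPrior(), "vis": GainPrior()}
        b = sample_decoupled_batch(
            2000, 0.3, StimulusPrior(), gp, ARM, pops, np.random.default_rng(3)
        )
        tog = b.counts_for("toggle")[:, 0]
        dec = ~np.asarray(b.meta["coupled"])
        assert np.all(tog[~dec] == 0)
        assert tog[dec].mean() == pytest.approx(b.gains["vis"][dec].mean(), rel=0.1)


class TestCoordtransBatch:
    arm = ArmModel(mode="cosine-1d", joint_limits=(np.pi / 6, 5 * np.pi / 6), link_1d=32.0)

    def make(self, n, units=60, seed=0):
        ranges = {"retinal": (-13.5, 13.5), "eye": (-13.5, 13.5)}
        pops = {
            "prop": build_population("prop", [tuple(self.arm.joint_limits)], units),
            "vis": build_population("vis", [(-13.5, 13.5)], units),
            "eye": build_population("eye", [(-13.5, 13.5)], units),
        }
        gp = {k: GainPrior() for k in pops}
        return sample_coordtrans_batch(
            n, ranges, gp, self.arm, pops, np.random.default_rng(seed)
        ), pops

    def test_standard_unit_allocation(self):
        b, _ = self.make(5)
        assert b.counts.shape[1] == 180

    def test_retinal_geometry(self):
        b, _ = self.make(300, units=10)
        xb = b.x[:, 0]
        assert np.allclose(b.meta["retinal"], xb - b.meta["eye"])
        assert np.allclose(inverse_1d(xb, self.arm), b.theta[:, 0])

    def test_range_outside_joint_limits_rejected(self):
        # X_b = X_r + E would reach +/-40 cm, beyond the joint range's image
        ranges = {"retinal": (-20.0, 20.0), "eye": (-20.0, 20.0)}
        pops = {
            "prop": build_population("prop", [tuple(self.arm.joint_limits)], 10),
            "vis": build_population("vis", [(-20.0, 20.0)], 10),
            "eye": build_population("eye", [(-20.0, 20.0)], 10),
        }
        gp = {k: GainPrior() for k in pops}
        with pytest.raises(ConfigError):
            sample_coordtrans_batch(
                5, ranges, gp, self.arm, pops, np.random.default_rng(0)
            )


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        pops = small_pops(8)
        b = sample_integration_batch(
            30, StimulusPrior(), {"prop": GainPrior(), "vis": GainPrior()},
            ARM, pops, np.random.default_rng(0),
        )
        path = tmp_path / "batch.npz"
        b.save(str(path))
        from multisense.popcode import TrialBatch

        b2 = TrialBatch.load(str(path))
        assert np.array_equal(b.counts, b2.counts)
        assert b2.layout == b.layout
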