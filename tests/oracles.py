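"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's closed-form inference paths: the
posterior oracle integrates the exact Poisson likelihoods on a dense grid,
and the CD-1 oracle enumerates the model's conditional distributions.
"""

from __future__ import annotations

import numpy as np

from multisense.kinematics import forward_kinematics
from multisense.popcode import mean_rates


class GridPosterior:
    """Brute-force posterior over theta for the two-population model.

    For each trial the exact unnormalized posterior

        log p(theta | k) = const + sum_i k_i log f_i(theta) - sum_i f_i(theta)
                           + log prior(theta)

    is integrated on a dense *local* grid centered on the prop center of
    mass: the posterior is orders of magnitude narrower than the joint box,
    so a global grid fine enough for covariance estimates would be
    prohibitive, while essentially all posterior mass lies within a few
    standard deviations of the center of mass.
    """

    def __init__(self, arm, pop_prop, pop_vis, n_grid=161, half_width_sd=7.0,
                 prior=None):
        self.arm = arm
        self.pop_prop = pop_prop
        self.pop_vis = pop_vis
        self.n_grid = n_grid
        self.half_width_sd = half_width_sd
        self.prior = prior

    def moments(self, counts_prop, counts_vis, gain_prop, gain_vis):
        """Posterior mean and covariance for one trial by local grid integration."""
        kp = np.asarray(counts_prop, dtype=float)
        kv = np.asarray(counts_vis, dtype=float)
        center = (kp @ self.pop_prop.preferred) / kp.sum()
        # conservative width scale: single-population posterior sd
        sd = self.pop_prop.sigma_tc / np.sqrt(max(kp.sum(), 1.0))
        half = self.half_width_sd * sd
        g1 = np.linspace(center[0] - half, center[0] + half, self.n_grid)
        g2 = np.linspace(center[1] - half, center[1] + half, self.n_grid)
        lims = np.asarray(self.arm.joint_limits, dtype=float)
        g1 = np.clip(g1, lims[0, 0], lims[0, 1])
        g2 = np.clip(g2, lims[1, 0], lims[1, 1])
        grid = np.stack(np.meshgrid(g1, g2, indexing="ij"), axis=-1).reshape(-1, 2)
        x = forward_kinematics(grid, self.arm)
        phi_p = mean_rates(grid, 1.0, self.pop_prop)
        phi_v = mean_rates(x, 1.0, self.pop_vis)
        with np.errstate(divide="ignore"):
            ll = (
                np.log(np.maximum(phi_p, 1e-300)) @ kp
                + np.log(np.maximum(phi_v, 1e-300)) @ kv
                - gain_prop * phi_p.sum(axis=1)
                - gain_vis * phi_v.sum(axis=1)
            )
        if self.prior is not None and self.prior.kind == "gaussian-joint":
            d = grid - np.asarray(self.prior.mean)
            pinv = np.linalg.inv(np.asarray(self.prior.covariance))
            ll = ll - 0.5 * np.einsum("gi,ij,gj->g", d, pinv, d)
        ll -= ll.max()
        w = np.exp(ll)
        w /= w.sum()
        mean = w @ grid
        d = grid - mean
        cov = (w[:, None] * d).T @ d
        return mean, cov


class GridPosterior1D:
    """Dense-grid posterior over (X_b, E) for the coordinate-transform model."""

    def __init__(self, arm_1d, pops, body_range, eye_range, n_grid=220):
        L = arm_1d.link_1d
        xb = np.linspace(*body_range, n_grid)
        ey = np.linspace(*eye_range, n_grid)
        XB, E = np.meshgrid(xb, ey, indexing="ij")
        self.xb_axis = xb
        self.XB = XB
        theta = np.arccos(np.clip(XB / L, -1, 1)).ravel()
        xr = (XB - E).ravel()
        self.phi = {
            "prop": mean_rates(theta[:, None], 1.0, pops["prop"]),
            "vis": mean_rates(xr[:, None], 1.0, pops["vis"]),
            "eye": mean_rates(E.ravel()[:, None], 1.0, pops["eye"]),
        }
        self.log_phi = {
            k: np.log(np.maximum(v, 1e-300)) for k, v in self.phi.items()
        }
        self.sum_phi = {k: v.sum(axis=1) for k, v in self.phi.items()}

    def xb_moments(self, counts, gains):
        ll = 0.0
        for name in ("prop", "vis", "eye"):
            k = np.asarray(counts[name], dtype=float)
            g = gains[name]
            ll = ll + self.log_phi[name] @ k - g * self.sum_phi[name]
        ll -= ll.max()
        w = np.exp(ll)
        w /= w.sum()
        xb = self.XB.ravel()
        mean = w @ xb
        var = w @ (xb - mean) ** 2
        return mean, var


def enumerate_cd1_expectation(model, p_data, r_states, pos_hidden="mean"):
    """Exact expected CD-1 weight update for a tiny Poisson-Bernoulli model.

    ``r_states`` enumerates the visible count vectors with their data
    probabilities ``p_data``; hidden states and one full Gibbs reconstruction
    step (visible counts truncated to the enumerated state set's range) are
    summed exactly.
    """
    from itertools import product

    from scipy.special import expit
    from scipy.stats import poisson

    W, bv, bh = model.W, model.b_vis, model.b_hid
    nv, nh = W.shape
    h_states = np.array(list(product([0.0, 1.0], repeat=nh)))
    kmax = int(r_states.max() + 20)
    r_grid = np.array(
        list(product(range(kmax + 1), repeat=nv)), dtype=float
    )

    pos = np.zeros_like(W)
    neg = np.zeros_like(W)
    for r, pr in zip(r_states, p_data):
        ph = expit(bh + r @ W)  # p(v_i = 1 | r)
        v_stat = ph  # mean statistics; "sample" has the same expectation
        pos += pr * np.outer(r, v_stat)
        # enumerate hidden samples v, then reconstructions r_hat
        pv = np.prod(h_states * ph + (1 - h_states) * (1 - ph), axis=1)
        for v, pvi in zip(h_states, pv):
            mu = np.minimum(np.exp(bv + W @ v), model.rate_cap)
            # p(r_hat | v): independent Poissons, truncated at kmax
            pr_hat = np.ones(len(r_grid))
            for j in range(nv):
                pr_hat *= poisson.pmf(r_grid[:, j], mu[j])
            pr_hat /= pr_hat.sum()
            vhat = expit(bh + r_grid @ W)  # (R, nh)
            neg += pr * pvi * (r_grid * pr_hat[:, None]).T @ vhat
    return pos - neg
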