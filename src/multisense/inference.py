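"""Closed-form optimal posteriors over the stimulus, and divergence metrics.

For a single Gaussian-tuned Poisson population the likelihood of the stimulus
given spike counts ``k`` is (up to edge effects) Gaussian with mean the
spike-count-weighted center of mass of the preferred stimuli and covariance
``sigma_tc^2 / n`` per dimension, where ``n`` is the total spike count.  The
posterior given several populations (and a flat or Gaussian prior) therefore
has additive precision:

    P = Sigma_prior^-1  +  (n_p / sigma_p^2) I  +  n_v J^T J / sigma_v^2

with ``J`` the forward-kinematics Jacobian (evaluated at the prop center of
mass) warping the Cartesian visual cue into joint space, and posterior mean
the precision-weighted combination of the prior mean, the prop center of
mass, and the back-transformed visual center of mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinematics import ArmModel, inverse_kinematics, jacobian
from .popcode import PopulationCode, StimulusPrior

__all__ = [
    "GaussianPosterior",
    "center_of_mass",
    "integration_posterior",
    "integration_moments",
    "coordtrans_posterior",
    "decoupled_optimal_covariance",
    "gaussian_kl",
    "info_loss_fraction",
    "flat_prior_proxy",
]


class InferenceError(ValueError):
    pass


@dataclass(frozen=True)
class GaussianPosterior:
    """Gaussian belief over the stimulus in a named coordinate space."""

    space_id: str
    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        cov = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)
        if not np.all(np.isfinite(mean)):
            raise InferenceError("posterior mean must be finite")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise InferenceError("covariance must be symmetric")
        if np.any(np.linalg.eigvalsh(cov) <= 0):
            raise InferenceError("covariance must be positive definite")

    @property
    def ndim(self) -> int:
        return self.mean.shape[0]

    @property
    def precision(self) -> np.ndarray:
        return np.linalg.inv(self.covariance)


def center_of_mass(counts, pop: PopulationCode) -> np.ndarray:
    """Spike-count-weighted mean of preferred stimuli (single-population MLE).

    Batched over leading axes.  Rows with zero total count are undecodable
    and yield NaN; callers drop and log them.
    """
    k = np.asarray(counts, dtype=float)
    tot = k.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        com = (k @ pop.preferred) / tot
    return np.where(tot > 0, com, np.nan)


def _prior_terms(stim_prior: StimulusPrior | None, ndim: int):
    if stim_prior is None or stim_prior.kind.startswith("uniform"):
        return np.zeros((ndim, ndim)), np.zeros(ndim)
    p0 = np.linalg.inv(np.asarray(stim_prior.covariance, dtype=float))
    return p0, p0 @ np.asarray(stim_prior.mean, dtype=float)


def integration_moments(
    counts_prop,
    counts_vis,
    stim_prior: StimulusPrior | None,
    arm: ArmModel,
    pop_prop: PopulationCode,
    pop_vis: PopulationCode,
    extra_joint_cues=(),
):
    """Batched posterior (means, covariances) over theta for cue-integration trials.

    ``counts_prop``/``counts_vis`` have shape (n, units); real-valued "counts"
    (e.g. expected counts decoded from a hidden layer) are accepted.
    ``extra_joint_cues`` is a sequence of (counts, pop) pairs for further
    populations that encode theta directly (hierarchical integration).
    Returns (means (n,2), covs (n,2,2), valid (n,)) — trials where every cue
    is empty and the prior is flat are invalid.
    """
    kp = np.atleast_2d(np.asarray(counts_prop, dtype=float))
    kv = np.atleast_2d(np.asarray(counts_vis, dtype=float))
    n = kp.shape[0]
    p0, p0mu0 = _prior_terms(stim_prior, 2)

    n_p = kp.sum(axis=-1)
    n_v = kv.sum(axis=-1)
    com_p = center_of_mass(kp, pop_prop)
    com_v = center_of_mass(kv, pop_vis)

    # Jacobian evaluation point: prop center of mass; if prop is silent fall
    # back to the vis estimate mapped through the inverse kinematics.
    eval_pt = com_p.copy()
    need = ~np.isfinite(eval_pt).all(axis=-1)
    if np.any(need):
        safe = np.isfinite(com_v).all(axis=-1) & need
        if np.any(safe):
            eval_pt[safe] = inverse_kinematics(com_v[safe], arm, clamp=True)
    valid = np.isfinite(eval_pt).all(axis=-1)
    eval_clipped = np.where(
        valid[:, None], np.clip(eval_pt, *np.transpose(arm.joint_limits)), arm.joint_center
    )

    J = jacobian(eval_clipped, arm)  # (n, 2, 2)
    wv = (n_v / pop_vis.sigma_tc**2)[:, None, None] * np.einsum(
        "nji,njk->nik", J, J
    )
    wp = (n_p / pop_prop.sigma_tc**2)[:, None, None] * np.eye(2)
    prec = p0[None] + wp + wv
    rhs = np.broadcast_to(p0mu0, (n, 2)).copy()
    rhs += np.where(n_p[:, None] > 0, np.einsum(
        "nij,nj->ni", wp, np.nan_to_num(com_p)
    ), 0.0)
    theta_v = np.full((n, 2), np.nan)
    has_v = np.isfinite(com_v).all(axis=-1)
    if np.any(has_v):
        theta_v[has_v] = inverse_kinematics(com_v[has_v], arm, clamp=True)
    rhs += np.where(
        has_v[:, None], np.einsum("nij,nj->ni", wv, np.nan_to_num(theta_v)), 0.0
    )
    for k_extra, pop_extra in extra_joint_cues:
        ke = np.atleast_2d(np.asarray(k_extra, dtype=float))
        n_e = ke.sum(axis=-1)
        com_e = center_of_mass(ke, pop_extra)
        we = (n_e / pop_extra.sigma_tc**2)[:, None, None] * np.eye(2)
        prec = prec + we
        rhs += np.where(
            n_e[:, None] > 0, np.einsum("nij,nj->ni", we, np.nan_to_num(com_e)), 0.0
        )

    det = np.linalg.det(prec)
    valid = valid & (det > 1e-300)
    prec_safe = np.where(valid[:, None, None], prec, np.eye(2))
    covs = np.linalg.inv(prec_safe)
    means = np.einsum("nij,nj->ni", covs, rhs)
    return means, covs, valid


def integration_posterior(
    counts_prop,
    counts_vis,
    stim_prior: StimulusPrior | None,
    arm: ArmModel,
    pop_prop: PopulationCode,
    pop_vis: PopulationCode,
) -> GaussianPosterior:
    """Single-trial optimal posterior over theta (joint space)."""
    means, covs, valid = integration_moments(
        counts_prop, counts_vis, stim_prior, arm, pop_prop, pop_vis
    )
    if not valid[0]:
        raise InferenceError(
            "posterior undefined: all counts zero and prior is flat"
        )
    return GaussianPosterior("prop", means[0], covs[0])


def coordtrans_posterior(
    counts_theta,
    counts_vis,
    counts_eye,
    pops: dict[str, PopulationCode],
    arm_1d: ArmModel,
    return_eye: bool = False,
):
    """Gaussian posterior over body-centered hand position X_b (1D model).

    The prop cue is mapped through the local derivative of the cosine link
    (X_b = L cos theta); the vis and eye cues chain as X_b = X_r + E.  With
    flat priors the exact Gaussian marginal over X_b is the precision-weighted
    combination of the prop cue and the summed vis+eye cue.  Batched.
    """
    kt = np.atleast_2d(np.asarray(counts_theta, dtype=float))
    kv = np.atleast_2d(np.asarray(counts_vis, dtype=float))
    ke = np.atleast_2d(np.asarray(counts_eye, dtype=float))
    L = arm_1d.link_1d

    n_t, n_v, n_e = (k.sum(axis=-1) for k in (kt, kv, ke))
    com_t = center_of_mass(kt, pops["prop"])[..., 0]
    com_v = center_of_mass(kv, pops["vis"])[..., 0]
    com_e = center_of_mass(ke, pops["eye"])[..., 0]

    with np.errstate(invalid="ignore", divide="ignore"):
        var_t = pops["prop"].sigma_tc**2 / n_t
        var_v = pops["vis"].sigma_tc**2 / n_v
        var_e = pops["eye"].sigma_tc**2 / n_e
        slope = -L * np.sin(com_t)
        mu_p = L * np.cos(com_t)
        var_p = slope**2 * var_t  # prop cue, in X_b units
        mu_ve = com_v + com_e
        var_ve = var_v + var_e
        w_p = np.where(n_t > 0, 1.0 / var_p, 0.0)
        w_ve = np.where((n_v > 0) & (n_e > 0), 1.0 / var_ve, 0.0)
        w = w_p + w_ve
        mean = (np.nan_to_num(w_p * mu_p) + np.nan_to_num(w_ve * mu_ve)) / w
        var = 1.0 / w
    valid = w > 0
    if kt.shape[0] == 1 and np.ndim(counts_theta) == 1:
        if not valid[0]:
            raise InferenceError("coordinate-transform posterior undefined")
        post = GaussianPosterior("body", mean[:1], var[:1, None])
        if not return_eye:
            return post
        # eye posterior: direct cue plus (prop - vis) chain
        w_dir = np.where(n_e > 0, 1.0 / var_e, 0.0)
        w_ch = np.where((n_t > 0) & (n_v > 0), 1.0 / (var_p + var_v), 0.0)
        mu_e = (
            np.nan_to_num(w_dir * com_e) + np.nan_to_num(w_ch * (mu_p - com_v))
        ) / (w_dir + w_ch)
        return post, GaussianPosterior(
            "eye", mu_e[:1], (1.0 / (w_dir + w_ch))[:1, None]
        )
    return mean, var, valid


def decoupled_optimal_covariance(cov_coupled, cov_uncoupled, p_couple: float):
    """Error covariance of the condition-aware optimal estimator.

    The optimal estimator integrates on coupled trials and falls back to the
    prop-only estimate otherwise, so its marginal error covariance is the
    mixture p * cov_coupled + (1 - p) * cov_uncoupled.
    """
    if not (0.0 <= p_couple <= 1.0):
        raise InferenceError("p_couple must lie in [0, 1]")
    a = np.asarray(cov_coupled, dtype=float)
    b = np.asarray(cov_uncoupled, dtype=float)
    for m in (a, b):
        if np.any(np.linalg.eigvalsh(np.atleast_2d(m)) <= 0):
            raise InferenceError("covariances must be SPD")
    return p_couple * a + (1.0 - p_couple) * b


def gaussian_kl(p: GaussianPosterior, q: GaussianPosterior, cov_only: bool = False) -> float:
    """KL(p || q) in nats between two Gaussian posteriors on the same space.

    With ``cov_only`` the mean-difference term is dropped, isolating the
    divergence contributed by mismatched covariances.
    """
    if p.space_id != q.space_id or p.ndim != q.ndim:
        raise InferenceError("posteriors live in different spaces")
    return float(
        _kl_terms(
            p.mean[None], p.covariance[None], q.mean[None], q.covariance[None], cov_only
        )[0]
    )


def _kl_terms(mu_p, cov_p, mu_q, cov_q, cov_only=False):
    """Vectorized Gaussian KL over leading batch axis."""
    d = mu_p.shape[-1]
    qinv = np.linalg.inv(cov_q)
    tr = np.einsum("nij,nji->n", qinv, cov_p)
    _, ld_q = np.linalg.slogdet(cov_q)
    _, ld_p = np.linalg.slogdet(cov_p)
    kl = 0.5 * (tr - d + ld_q - ld_p)
    if not cov_only:
        dm = mu_q - mu_p
        kl = kl + 0.5 * np.einsum("ni,nij,nj->n", dm, qinv, dm)
    return kl


def flat_prior_proxy(bounds, space_id: str = "prop") -> GaussianPosterior:
    """Moment-matched Gaussian standing in for a flat prior over a box.

    A truly flat prior has no finite KL from a Gaussian posterior in general;
    the normalized information-loss ratio therefore uses the Gaussian with
    the same first two moments as the uniform distribution on the response
    area (mean the box center, variance extent^2/12 per dimension).
    """
    b = np.atleast_2d(np.asarray(bounds, dtype=float))
    mean = b.mean(axis=1)
    var = (b[:, 1] - b[:, 0]) ** 2 / 12.0
    return GaussianPosterior(space_id, mean, np.diag(var))


def info_loss_fraction(
    opt: GaussianPosterior, model: GaussianPosterior, prior: GaussianPosterior
) -> float:
    """Fractional information lost from input to hidden layer.

    Normalized KL divergence KL(opt || model) / KL(opt || prior): 0 when the
    decoded posterior equals the optimal one, 1 when it has degraded to the
    prior.
    """
    denom = gaussian_kl(opt, prior)
    if denom <= 0:
        raise InferenceError("prior equals the optimal posterior; ratio undefined")
    return gaussian_kl(opt, model) / denom


def info_loss_fractions(
    means_opt, covs_opt, means_model, covs_model, prior: GaussianPosterior
) -> np.ndarray:
    """Per-trial information-loss fractions for batches of posteriors."""
    num = _kl_terms(means_opt, covs_opt, means_model, covs_model)
    n = means_opt.shape[0]
    den = _kl_terms(
        means_opt,
        covs_opt,
        np.broadcast_to(prior.mean, (n, prior.ndim)),
        np.broadcast_to(prior.covariance, (n, prior.ndim, prior.ndim)),
    )
    return num / den
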