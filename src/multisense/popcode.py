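"""Gaussian-tuned Poisson population codes and the synthetic trial generators.

A stimulus ``s`` is encoded by a grid of neurons with isotropic Gaussian
tuning curves and independent Poisson spike counts (a probabilistic
population code):

    rate_i = g * exp(-||s - s_i||^2 / (2 sigma_tc^2)),     k_i ~ Poisson(rate_i)

where ``g`` is a per-trial, per-population gain (the maximum mean spike
count, hence the reliability of that modality on that trial) and ``s_i``
the i-th preferred stimulus.  Preferred stimuli tile a "response area"
plus a surrounding margin of 4 tuning-curve standard deviations, so that
stimuli at the edge of the response area still produce an (almost)
untruncated activity profile.  Tuning widths are set so the curves' full
width at half maximum spans one-sixth of the response area.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .kinematics import (
    ArmModel,
    forward_kinematics,
    inverse_1d,
    jacobian,
)

__all__ = [
    "PopulationCode",
    "GainPrior",
    "StimulusPrior",
    "TrialBatch",
    "build_population",
    "mean_rates",
    "encode",
    "sample_integration_batch",
    "sample_discrepant_batch",
    "sample_decoupled_batch",
    "sample_coordtrans_batch",
]

# FWHM of a Gaussian = 2 sqrt(2 ln 2) sigma
_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PopulationCode:
    """A regular grid of Gaussian-tuned Poisson neurons over one stimulus space."""

    space_id: str
    grid_shape: tuple[int, ...]
    response_area: tuple[tuple[float, float], ...]  # per-dimension (lo, hi)
    sigma_tc: float
    margin_sd: float
    preferred: np.ndarray = field(repr=False)  # (n_units, ndim)
    spacing: tuple[float, ...] = ()

    @property
    def n_units(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def ndim(self) -> int:
        return len(self.grid_shape)


def build_population(
    space_id: str,
    bounds,
    units_per_dim,
    margin_sd: float = 4.0,
    fwhm_fraction: float = 1.0 / 6.0,
) -> PopulationCode:
    """Construct a population whose preferred stimuli tile ``bounds`` plus margin.

    ``bounds`` is the response area: a sequence of per-dimension (lo, hi).
    The tuning width is isotropic, with FWHM = ``fwhm_fraction`` times the
    geometric-mean extent of the response area.
    """
    bounds = tuple((float(lo), float(hi)) for lo, hi in np.atleast_2d(bounds))
    shape = tuple(np.atleast_1d(units_per_dim).astype(int))
    if len(shape) == 1 and len(bounds) > 1:
        shape = shape * len(bounds)
    if len(shape) != len(bounds):
        raise ConfigError("units_per_dim and bounds dimensionality disagree")
    if any(n < 2 for n in shape):
        raise ConfigError("need at least 2 units per dimension")
    extents = np.array([hi - lo for lo, hi in bounds])
    if np.any(extents <= 0):
        raise ConfigError(f"degenerate response area bounds for {space_id!r}")
    gm_extent = float(np.exp(np.mean(np.log(extents))))
    sigma = fwhm_fraction * gm_extent / _FWHM_FACTOR
    axes = [
        np.linspace(lo - margin_sd * sigma, hi + margin_sd * sigma, n)
        for (lo, hi), n in zip(bounds, shape)
    ]
    spacing = tuple(float(ax[1] - ax[0]) for ax in axes)
    mesh = np.meshgrid(*axes, indexing="ij")
    preferred = np.stack([m.ravel() for m in mesh], axis=-1)
    return PopulationCode(
        space_id=space_id,
        grid_shape=shape,
        response_area=bounds,
        sigma_tc=float(sigma),
        margin_sd=float(margin_sd),
        preferred=preferred,
        spacing=spacing,
    )


def mean_rates(stimulus, gain, pop: PopulationCode) -> np.ndarray:
    """Mean spike counts for each unit; batched over leading axes of ``stimulus``."""
    s = np.atleast_1d(np.asarray(stimulus, dtype=float))
    if pop.ndim == 1 and s.ndim >= 1 and s.shape[-1] != 1:
        s = s[..., None]  # 1-D spaces: a 1-D input array is a batch of stimuli
    d2 = np.sum((s[..., None, :] - pop.preferred) ** 2, axis=-1)
    g = np.asarray(gain, dtype=float)
    return g[..., None] * np.exp(-d2 / (2.0 * pop.sigma_tc**2)) if g.ndim else g * np.exp(
        -d2 / (2.0 * pop.sigma_tc**2)
    )


def encode(stimulus, gain, pop: PopulationCode, rng: np.random.Generator) -> np.ndarray:
    """Draw independent Poisson spike counts with means :func:`mean_rates`."""
    return rng.poisson(mean_rates(stimulus, gain, pop))


@dataclass(frozen=True)
class GainPrior:
    """Uniform prior on a population's maximum mean spike count."""

    lo: float = 12.0
    hi: float = 18.0

    def __post_init__(self):
        if not (0 <= self.lo <= self.hi):
            raise ConfigError(f"invalid gain interval [{self.lo}, {self.hi}]")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lo, self.hi, size=n)

    @property
    def median(self) -> float:
        return 0.5 * (self.lo + self.hi)


@dataclass(frozen=True)
class StimulusPrior:
    """Prior over the stimulus: uniform or Gaussian in joint space, or uniform 1D."""

    kind: str = "uniform-joint"
    mean: np.ndarray | None = None
    covariance: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("uniform-joint", "gaussian-joint", "uniform-1d"):
            raise ConfigError(f"unknown stimulus prior kind {self.kind!r}")
        if self.kind == "gaussian-joint":
            cov = np.asarray(self.covariance, dtype=float)
            if not np.allclose(cov, cov.T) or np.any(np.linalg.eigvalsh(cov) <= 0):
                raise ConfigError("gaussian prior covariance must be SPD")

    def sample(self, rng: np.random.Generator, n: int, arm: ArmModel) -> np.ndarray:
        lims = np.atleast_2d(np.asarray(arm.joint_limits, dtype=float))
        if self.kind == "uniform-joint":
            return rng.uniform(lims[:, 0], lims[:, 1], size=(n, lims.shape[0]))
        if self.kind == "uniform-1d":
            return rng.uniform(lims[0, 0], lims[0, 1], size=(n, 1))
        out = np.empty((n, lims.shape[0]))
        todo = np.arange(n)
        # tight priors make out-of-limits draws rare; resample to stay a
        # genuine (truncated) Gaussian over the joint box
        while todo.size:
            draw = rng.multivariate_normal(
                np.asarray(self.mean, dtype=float), self.covariance, size=todo.size
            )
            out[todo] = draw
            ok = np.all((draw >= lims[:, 0]) & (draw <= lims[:, 1]), axis=-1)
            todo = todo[~ok]
        return out


@dataclass
class TrialBatch:
    """Per-trial stimuli, gains and concatenated spike-count vectors.

    ``layout`` records the fixed concatenation order of the count vector as
    ``{population name: (start, stop)}`` column slices.
    """

    theta: np.ndarray  # (n, d) true joint-space stimulus (the "right hand")
    x: np.ndarray  # (n, d) Cartesian stimulus actually encoded by vis
    gains: dict[str, np.ndarray]
    counts: np.ndarray  # (n, n_visible) nonnegative integers
    layout: dict[str, tuple[int, int]]
    meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    def counts_for(self, name: str) -> np.ndarray:
        start, stop = self.layout[name]
        return self.counts[:, start:stop]

    def save(self, path: str) -> None:
        base = str(path).removesuffix(".npz")
        np.savez_compressed(
            base + ".npz",
            theta=self.theta,
            x=self.x,
            counts=self.counts,
            **{f"gain_{k}": v for k, v in self.gains.items()},
        )
        manifest = {
            "layout": {k: list(v) for k, v in self.layout.items()},
            "gains": sorted(self.gains),
            "meta": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.meta.items()
            },
            "n_trials": int(self.n_trials),
        }
        with open(base + ".json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "TrialBatch":
        base = str(path).removesuffix(".npz")
        arrs = np.load(base + ".npz")
        with open(base + ".json") as fh:
            manifest = json.load(fh)
        gains = {k: arrs[f"gain_{k}"] for k in manifest["gains"]}
        return cls(
            theta=arrs["theta"],
            x=arrs["x"],
            gains=gains,
            counts=arrs["counts"],
            layout={k: tuple(v) for k, v in manifest["layout"].items()},
            meta=manifest["meta"],
        )


def _concat_layout(parts: dict[str, np.ndarray]):
    layout = {}
    start = 0
    arrays = []
    for name, arr in parts.items():
        stop = start + arr.shape[1]
        layout[name] = (start, stop)
        arrays.append(arr.astype(np.int16, copy=False))  # counts are small
        start = stop
    return np.concatenate(arrays, axis=1), layout


def sample_integration_batch(
    n: int,
    stim_prior: StimulusPrior,
    gain_priors: dict[str, GainPrior],
    arm: ArmModel,
    pops: dict[str, PopulationCode],
    rng: np.random.Generator,
) -> TrialBatch:
    """World model for cue integration: one hand, two noisy reports of it.

    Per trial, draw theta from the stimulus prior and per-population gains,
    set x = f(theta), and emit Poisson counts [prop(theta), vis(x)].
    """
    theta = stim_prior.sample(rng, n, arm)
    x = forward_kinematics(theta, arm) if n else np.empty((0, 2))
    gains = {name: gain_priors[name].sample(rng, n) for name in pops}
    stimuli = {"prop": theta, "vis": x}
    parts = {
        name: rng.poisson(mean_rates(stimuli[name], gains[name], pops[name]))
        if n
        else np.empty((0, pops[name].n_units), dtype=int)
        for name in pops
    }
    counts, layout = _concat_layout(parts)
    return TrialBatch(theta=theta, x=x, gains=gains, counts=counts, layout=layout)


def input_covariance_scale(
    arm: ArmModel,
    pops: dict[str, PopulationCode],
    gain_priors: dict[str, GainPrior],
    direction,
) -> float:
    """Std of the summed single-population posterior covariances along ``direction``.

    Evaluated in joint space at the center of the joint box with median gains;
    this is the natural unit for an imposed inter-modality discrepancy.
    """
    theta0 = np.asarray(arm.joint_center, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    covs = []
    for name, pop in pops.items():
        g = gain_priors[name].median
        stim = theta0 if name == "prop" else forward_kinematics(theta0, arm)
        ntot = mean_rates(stim, g, pop).sum()
        cov = pop.sigma_tc**2 / ntot * np.eye(pop.ndim)
        if name == "vis":
            jinv = np.linalg.inv(jacobian(theta0, arm))
            cov = jinv @ cov @ jinv.T
        covs.append(cov)
    total = np.sum(covs, axis=0)
    return float(np.sqrt(d @ total @ d))


def sample_discrepant_batch(
    n: int,
    k_sd: float,
    direction,
    stim_prior: StimulusPrior,
    gain_priors: dict[str, GainPrior],
    arm: ArmModel,
    pops: dict[str, PopulationCode],
    rng: np.random.Generator,
) -> TrialBatch:
    """Integration trials with the prop report displaced by a fixed discrepancy.

    The displacement is ``k_sd`` standard deviations of the summed input
    covariance along ``direction``, applied to theta before prop encoding
    only.  Trials whose shifted angles leave the joint box are resampled
    (count recorded in ``meta``) so the prior over theta is unchanged.
    """
    if k_sd < 0:
        raise ConfigError("k_sd must be nonnegative")
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    delta = k_sd * input_covariance_scale(arm, pops, gain_priors, d) * d

    theta = np.empty((n, 2))
    resampled = 0
    todo = np.arange(n)
    while todo.size:
        draw = stim_prior.sample(rng, todo.size, arm)
        theta[todo] = draw
        ok = arm.contains(draw + delta)
        resampled += int(np.sum(~ok))
        todo = todo[~ok]
    theta_prop = theta + delta
    x = forward_kinematics(theta, arm) if n else np.empty((0, 2))
    gains = {name: gain_priors[name].sample(rng, n) for name in pops}
    stimuli = {"prop": theta_prop, "vis": x}
    parts = {
        name: rng.poisson(mean_rates(stimuli[name], gains[name], pops[name]))
        if n
        else np.empty((0, pops[name].n_units), dtype=int)
        for name in pops
    }
    counts, layout = _concat_layout(parts)
    return TrialBatch(
        theta=theta,
        x=x,
        gains=gains,
        counts=counts,
        layout=layout,
        meta={"discrepancy": delta, "k_sd": float(k_sd), "n_resampled": resampled},
    )


def sample_decoupled_batch(
    n: int,
    p_couple: float,
    stim_prior: StimulusPrior,
    gain_priors: dict[str, GainPrior],
    arm: ArmModel,
    pops: dict[str, PopulationCode],
    rng: np.random.Generator,
) -> TrialBatch:
    """Trials on which vision sometimes reports a different ("left") hand.

    With probability ``p_couple`` the visual population encodes the same hand
    as prop; otherwise it encodes an independently drawn stimulus and a
    dedicated toggle unit (appended as the last visible column) fires at the
    trial's visual gain (Poisson); on coupled trials the toggle is silent.
    """
    if not (0.0 <= p_couple <= 1.0):
        raise ConfigError("p_couple must lie in [0, 1]")
    theta = stim_prior.sample(rng, n, arm)
    coupled = rng.random(n) < p_couple
    theta_left = stim_prior.sample(rng, n, arm)
    theta_vis = np.where(coupled[:, None], theta, theta_left)
    x = forward_kinematics(theta_vis, arm) if n else np.empty((0, 2))
    gains = {name: gain_priors[name].sample(rng, n) for name in pops}
    parts = {}
    for name in pops:
        stim = theta if name == "prop" else x
        parts[name] = (
            rng.poisson(mean_rates(stim, gains[name], pops[name]))
            if n
            else np.empty((0, pops[name].n_units), dtype=int)
        )
    toggle_mean = np.where(coupled, 0.0, gains["vis"])
    parts["toggle"] = rng.poisson(toggle_mean)[:, None] if n else np.empty((0, 1), int)
    counts, layout = _concat_layout(parts)
    return TrialBatch(
        theta=theta,
        x=x,
        gains=gains,
        counts=counts,
        layout=layout,
        meta={"coupled": coupled, "p_couple": float(p_couple)},
    )


def sample_coordtrans_batch(
    n: int,
    ranges: dict[str, tuple[float, float]],
    gain_priors: dict[str, GainPrior],
    arm_1d: ArmModel,
    pops: dict[str, PopulationCode],
    rng: np.random.Generator,
) -> TrialBatch:
    """Coordinate-transformation trials: prop(theta), vis(X_r), eye(E).

    The retinal hand position X_r and the gaze angle E are independent and
    uniform on their configured ranges; the body-centered position is their
    sum, X_b = X_r + E (so the sampled (X_b, E) region is a parallelogram),
    and theta is the inverse cosine map of X_b.  Because X_b spans the sum
    of both ranges, the proprioceptive population is responsible for a
    larger space than either of the other two.
    """
    xr_lo, xr_hi = ranges["retinal"]
    e_lo, e_hi = ranges["eye"]
    L = arm_1d.link_1d
    lo, hi = np.asarray(arm_1d.joint_limits, dtype=float).reshape(2)
    # attainable X_b given the joint range is [L cos hi, L cos lo]
    if not (L * np.cos(hi) <= xr_lo + e_lo and xr_hi + e_hi <= L * np.cos(lo)):
        raise ConfigError(
            "retinal + eye ranges sum outside the 1D joint limits"
        )
    xr = rng.uniform(xr_lo, xr_hi, size=n)
    eye = rng.uniform(e_lo, e_hi, size=n)
    xb = xr + eye
    theta = inverse_1d(xb, arm_1d) if n else np.empty(0)
    gains = {name: gain_priors[name].sample(rng, n) for name in pops}
    stimuli = {"prop": theta, "vis": xr, "eye": eye}
    parts = {
        name: rng.poisson(mean_rates(stimuli[name][:, None], gains[name], pops[name]))
        if n
        else np.empty((0, pops[name].n_units), dtype=int)
        for name in pops
    }
    counts, layout = _concat_layout(parts)
    return TrialBatch(
        theta=theta[:, None] if n else np.empty((0, 1)),
        x=xb[:, None] if n else np.empty((0, 1)),
        gains=gains,
        counts=counts,
        layout=layout,
        meta={"eye": eye, "retinal": xr, "ranges": ranges},
    )
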