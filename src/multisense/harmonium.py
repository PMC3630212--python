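"""Exponential-family harmonium: Poisson visible units, Bernoulli hidden units.

A two-layer undirected model with full interlayer and no intralayer
connections.  Conditionals use the inverse canonical links of each family:

    p(v_i = 1 | r) = logistic(b_hid_i + (W^T r)_i)          (hidden, Bernoulli)
    E[r_j | v]     = min(exp(b_vis_j + (W v)_j), rate_cap)   (visible, Poisson)

Alternating draws from these conditionals are Gibbs sampling from the joint.
Training uses one-step contrastive divergence (CD-1): propagate data up,
reconstruct down, propagate back up, and move each weight by the difference
of the data-phase and reconstruction-phase pairwise correlations — a Hebbian
and an anti-Hebbian term.

The rate cap is a numerical guard on the exponential link (which can explode
early in training); with sensible learning rates it stops binding after the
first stage, and binding events are counted in the training trace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "Harmonium",
    "TrainingSchedule",
    "init_harmonium",
    "up_mean",
    "down_mean",
    "gibbs_sample",
    "cd1_step",
    "train",
    "hidden_code",
]


class TrainingDivergence(RuntimeError):
    """Raised when a parameter update becomes non-finite (learning rate too high)."""


@dataclass
class Harmonium:
    W: np.ndarray  # (n_visible, n_hidden)
    b_vis: np.ndarray  # (n_visible,)
    b_hid: np.ndarray  # (n_hidden,)
    rate_cap: float | np.ndarray = 54.0  # scalar or per-visible-unit vector

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    def save(self, path: str, **meta) -> None:
        np.savez_compressed(path, W=self.W, b_vis=self.b_vis, b_hid=self.b_hid)
        cap = self.rate_cap
        info = {
            "n_visible": self.n_visible,
            "n_hidden": self.n_hidden,
            "rate_cap": cap.tolist() if isinstance(cap, np.ndarray) else cap,
            "visible_family": "poisson",
            "hidden_family": "bernoulli",
        }
        info.update(meta)
        with open(str(path) + ".json", "w") as fh:
            json.dump(info, fh, indent=1, sort_keys=True, default=str)

    @classmethod
    def load(cls, path: str) -> "Harmonium":
        base = str(path).removesuffix(".npz")
        arrs = np.load(base + ".npz")
        with open(base + ".json") as fh:
            info = json.load(fh)
        cap = info["rate_cap"]
        return cls(
            W=arrs["W"],
            b_vis=arrs["b_vis"],
            b_hid=arrs["b_hid"],
            rate_cap=np.asarray(cap, dtype=float) if isinstance(cap, list) else float(cap),
        )


@dataclass(frozen=True)
class TrainingSchedule:
    """CD-1 schedule: stages of fixed epochs with annealed learning rates."""

    n_vectors: int = 40_000
    minibatch: int = 40
    epochs_per_stage: int = 15
    n_stages: int = 6
    lr_w: float = 5e-3
    lr_b: float = 5e-3
    anneal_factor: float = 0.8
    neg_hidden: str = "mean"  # "mean" (variance-reduced) or "sample"
    pos_hidden: str = "mean"  # statistics for the data phase

    def __post_init__(self):
        for name in ("n_vectors", "minibatch", "epochs_per_stage", "n_stages"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.anneal_factor <= 1):
            raise ValueError("anneal_factor must lie in (0, 1]")
        if self.neg_hidden not in ("mean", "sample"):
            raise ValueError("neg_hidden must be 'mean' or 'sample'")
        if self.pos_hidden not in ("mean", "sample"):
            raise ValueError("pos_hidden must be 'mean' or 'sample'")

    @property
    def total_epochs(self) -> int:
        return self.epochs_per_stage * self.n_stages


def init_harmonium(
    n_visible: int,
    n_hidden: int,
    rng: np.random.Generator,
    mean_rates: np.ndarray | None = None,
    weight_sd: float = 0.01,
    rate_cap: float = 54.0,
    dtype=np.float64,
) -> Harmonium:
    """Gaussian weight init; visible biases start at the data's log mean rates."""
    W = rng.normal(0.0, weight_sd, size=(n_visible, n_hidden)).astype(dtype)
    if mean_rates is not None:
        b_vis = np.log(np.asarray(mean_rates, dtype=dtype) + 1e-3)
    else:
        b_vis = np.zeros(n_visible, dtype=dtype)
    return Harmonium(W=W, b_vis=b_vis, b_hid=np.zeros(n_hidden, dtype=dtype),
                     rate_cap=rate_cap)


def up_mean(model: Harmonium, r: np.ndarray) -> np.ndarray:
    """Hidden Bernoulli means given visible counts; batched over leading axis."""
    r = np.asarray(r)
    if r.dtype != model.W.dtype:
        r = r.astype(model.W.dtype)
    a = model.b_hid + r @ model.W
    return expit(a)  # numerically safe logistic


def down_mean(model: Harmonium, v: np.ndarray) -> np.ndarray:
    """Visible Poisson means given hidden activities (capped exponential link)."""
    v = np.asarray(v)
    if v.dtype != model.W.dtype:
        v = v.astype(model.W.dtype)
    a = model.b_vis + v @ model.W.T
    return np.minimum(np.exp(np.minimum(a, np.log(model.rate_cap))), model.rate_cap)


def gibbs_sample(means: np.ndarray, family: str, rng: np.random.Generator) -> np.ndarray:
    """Realize units from their conditional means."""
    if family == "bernoulli":
        means = np.asarray(means)
        return (rng.random(means.shape, dtype=np.float32 if means.dtype == np.float32 else np.float64) < means).astype(means.dtype)
    if family == "poisson":
        return rng.poisson(means).astype(np.asarray(means).dtype)
    raise ValueError(f"unknown family {family!r}")


def cd1_step(
    model: Harmonium,
    r_batch: np.ndarray,
    lr_w: float,
    lr_b: float,
    rng: np.random.Generator,
    neg_hidden: str = "mean",
    pos_hidden: str = "mean",
) -> float:
    """One CD-1 update on a minibatch; returns the cap-bind fraction.

    Up (sample), down (sample), and back up; weights move along the
    difference of data-phase and reconstruction-phase correlations, biases
    along the corresponding activity differences.  The Gibbs chain always
    descends from *sampled* hidden states; the correlation statistics use
    conditional means by default (same expectation, lower variance), with
    "sample" variants available for both phases.
    """
    r = np.asarray(r_batch)
    if r.dtype != model.W.dtype:
        r = r.astype(model.W.dtype)
    B = r.shape[0]
    ph = up_mean(model, r)
    v = gibbs_sample(ph, "bernoulli", rng)
    r_hat_mean = down_mean(model, v)
    if not np.isfinite(r_hat_mean).all():
        raise TrainingDivergence(
            "non-finite reconstruction means: lower the learning rate "
            f"(lr_w={lr_w}, lr_b={lr_b})"
        )
    r_hat = gibbs_sample(r_hat_mean, "poisson", rng)
    v_hat = up_mean(model, r_hat)
    if neg_hidden == "sample":
        v_hat = gibbs_sample(v_hat, "bernoulli", rng)
    v_pos = v if pos_hidden == "sample" else ph

    dW = (r.T @ v_pos - r_hat.T @ v_hat) / B
    db_vis = (r - r_hat).mean(axis=0)
    db_hid = (v_pos - v_hat).mean(axis=0)
    if not (np.isfinite(dW).all() and np.isfinite(db_vis).all() and np.isfinite(db_hid).all()):
        raise TrainingDivergence(
            "non-finite CD-1 update: lower the learning rate "
            f"(lr_w={lr_w}, lr_b={lr_b})"
        )
    model.W += lr_w * dW
    model.b_vis += lr_b * db_vis
    model.b_hid += lr_b * db_hid
    return float(np.mean(r_hat_mean >= model.rate_cap))


def poisson_deviance(r: np.ndarray, mu: np.ndarray) -> float:
    """Mean per-unit Poisson deviance, the reconstruction monitoring loss."""
    r = np.asarray(r, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(r > 0, r * np.log(r / mu), 0.0)
    return float(2.0 * np.mean(term - (r - mu)))


def train(
    model: Harmonium,
    data: np.ndarray,
    schedule: TrainingSchedule,
    rng: np.random.Generator,
    monitor_size: int = 1000,
) -> dict:
    """Train in place with CD-1 over shuffled minibatches; returns the trace.

    The trace records per-epoch reconstruction deviance on a fixed monitoring
    subset, the learning rate in force, and the fraction of reconstruction
    means clipped by the rate cap.
    """
    data = np.asarray(data)  # kept in its stored dtype; minibatches are cast
    n = min(schedule.n_vectors, data.shape[0])
    data = data[:n]
    monitor = data[: min(monitor_size, n)]
    lr_w, lr_b = schedule.lr_w, schedule.lr_b
    trace = {"deviance": [], "lr_w": [], "cap_fraction": []}
    for epoch in range(schedule.total_epochs):
        if epoch > 0 and epoch % schedule.epochs_per_stage == 0:
            lr_w *= schedule.anneal_factor
            lr_b *= schedule.anneal_factor
        order = rng.permutation(n)
        cap = 0.0
        n_batches = 0
        for start in range(0, n - schedule.minibatch + 1, schedule.minibatch):
            idx = order[start : start + schedule.minibatch]
            cap += cd1_step(
                model, data[idx], lr_w, lr_b, rng,
                neg_hidden=schedule.neg_hidden, pos_hidden=schedule.pos_hidden,
            )
            n_batches += 1
        mon = monitor.astype(float)
        recon = down_mean(model, up_mean(model, mon))
        trace["deviance"].append(poisson_deviance(mon, recon))
        trace["lr_w"].append(lr_w)
        trace["cap_fraction"].append(cap / max(n_batches, 1))
    return trace


def hidden_code(
    model: Harmonium,
    r: np.ndarray,
    n_samples: int | None = 15,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Average of ``n_samples`` Bernoulli draws from the hidden conditional.

    ``n_samples=None`` returns the hidden means themselves (infinite
    samples).  The average of n i.i.d. Bernoulli draws is Binomial(n, p)/n,
    which is how it is generated.
    """
    ph = up_mean(model, r)
    if n_samples is None:
        return ph
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1 (or None for means)")
    if rng is None:
        raise ValueError("sampled hidden codes require an rng")
    return rng.binomial(n_samples, ph) / float(n_samples)
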