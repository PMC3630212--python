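"""Decoding stimulus posteriors from hidden-layer activity.

Because the harmonium is a generative model, its hidden-to-visible weights
turn a hidden vector back into expected input spike counts, which are then
decoded exactly like real input activity: centers of mass give the posterior
mean, per-population total counts set the cue weights of the posterior
precision.  Decoding never touches true stimuli or gains; the only learned
component is an optional regressor that calibrates reconstructed total
counts against true totals, fit on trials disjoint from those evaluated
(and never used on the covariance path).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neural_network import MLPRegressor

from .harmonium import Harmonium, down_mean
from .inference import center_of_mass, integration_moments
from .kinematics import ArmModel
from .popcode import PopulationCode, StimulusPrior

__all__ = [
    "decode_expected_inputs",
    "decode_posterior_mean",
    "recover_totals",
    "CountCalibrator",
    "fit_count_calibrator",
    "decode_posterior",
]


class DecodeError(ValueError):
    pass


def decode_expected_inputs(
    model: Harmonium, vbar: np.ndarray, layout: dict[str, tuple[int, int]]
) -> dict[str, np.ndarray]:
    """Expected visible counts from hidden activity, split per population."""
    vbar = np.asarray(vbar, dtype=float)
    if np.any(vbar < -1e-9) or np.any(vbar > 1 + 1e-9):
        raise DecodeError("hidden activities must lie in [0, 1]")
    expected = down_mean(model, vbar)
    stop_max = max(stop for _, stop in layout.values())
    if stop_max != model.n_visible:
        raise DecodeError(
            f"layout covers {stop_max} columns but model has {model.n_visible}"
        )
    return {name: expected[..., a:b] for name, (a, b) in layout.items()}


def decode_posterior_mean(
    model: Harmonium,
    vbar: np.ndarray,
    pops: dict[str, PopulationCode],
    layout: dict[str, tuple[int, int]],
    target_space: str = "prop",
) -> np.ndarray:
    """Stimulus estimate: center of mass of one decoded population.

    ``target_space`` "prop" reports in joint space, "vis" in Cartesian space
    (decoding the correspondingly tuned population directly, which in
    practice matches the full weighted combination).
    """
    if target_space not in pops:
        raise DecodeError(f"no population decodes space {target_space!r}")
    parts = decode_expected_inputs(model, vbar, layout)
    return center_of_mass(parts[target_space], pops[target_space])


def recover_totals(
    model: Harmonium,
    vbar: np.ndarray,
    layout: dict[str, tuple[int, int]],
    populations: tuple[str, ...] = ("prop", "vis"),
    calibrator: "CountCalibrator | None" = None,
) -> np.ndarray:
    """Per-population total spike counts reconstructed from the hidden layer.

    Returns an array (..., n_populations) of summed expected counts, passed
    through the calibrator when one is supplied.
    """
    parts = decode_expected_inputs(model, vbar, layout)
    raw = np.stack([parts[name].sum(axis=-1) for name in populations], axis=-1)
    if calibrator is None:
        return raw
    return calibrator.predict(raw)


@dataclass
class CountCalibrator:
    """Small regressor mapping reconstructed totals to true totals.

    Inputs and targets are standardized around the training moments so the
    logistic hidden layer operates away from saturation.
    """

    net: MLPRegressor
    x_loc: np.ndarray | None = None
    x_scale: np.ndarray | None = None
    y_loc: np.ndarray | None = None
    y_scale: np.ndarray | None = None
    train_ids: np.ndarray | None = None

    def predict(self, raw_totals: np.ndarray) -> np.ndarray:
        raw = np.atleast_2d(np.asarray(raw_totals, dtype=float))
        z = (raw - self.x_loc) / self.x_scale
        out = self.net.predict(z) * self.y_scale + self.y_loc
        return np.maximum(out, 0.0)


def fit_count_calibrator(
    raw_totals: np.ndarray,
    true_totals: np.ndarray,
    seed: int = 0,
    trial_ids: np.ndarray | None = None,
    hidden_units: int = 32,
) -> CountCalibrator:
    """Fit the total-count calibration network on training trials.

    One hidden layer of logistic units, squared-error loss, early stopping
    on a validation split.  ``raw_totals`` may be the reconstructed sums
    alone or any feature set derived from the hidden vector (e.g. sums
    concatenated with the hidden activities themselves).  ``trial_ids``,
    when given, are stored so that :func:`check_disjoint` can verify
    train/test separation.
    """
    x = np.asarray(raw_totals, dtype=float)
    y = np.asarray(true_totals, dtype=float)
    x_loc, x_scale = x.mean(axis=0), np.maximum(x.std(axis=0), 1e-9)
    y_loc, y_scale = y.mean(axis=0), np.maximum(y.std(axis=0), 1e-9)
    net = MLPRegressor(
        hidden_layer_sizes=(hidden_units,),
        activation="logistic",
        solver="adam",
        early_stopping=True,
        validation_fraction=0.15,
        max_iter=800,
        random_state=int(seed) % (2**32),
    )
    net.fit((x - x_loc) / x_scale, (y - y_loc) / y_scale)
    ids = None if trial_ids is None else np.asarray(trial_ids).copy()
    return CountCalibrator(
        net=net, x_loc=x_loc, x_scale=x_scale, y_loc=y_loc, y_scale=y_scale,
        train_ids=ids,
    )


def check_disjoint(calibrator: CountCalibrator, test_ids: np.ndarray) -> None:
    """Raise if the calibrator was trained on any of the given trials."""
    if calibrator.train_ids is None:
        return
    if np.intersect1d(calibrator.train_ids, np.asarray(test_ids)).size:
        raise DecodeError("calibrator training and evaluation trials overlap")


def decode_posterior(
    model: Harmonium,
    vbar: np.ndarray,
    pops: dict[str, PopulationCode],
    layout: dict[str, tuple[int, int]],
    arm: ArmModel,
    stim_prior: StimulusPrior | None = None,
    extra_joint: tuple[str, ...] = (),
):
    """The harmonium-based posterior over theta, from hidden activity alone.

    The decoded expected counts play the role of observed counts in the
    optimal-posterior formula: centers of mass give the cue means, summed
    expected counts the cue weights, with the Jacobian evaluated at the
    decoded prop center of mass.  Batched: returns (means, covs, valid).
    """
    parts = decode_expected_inputs(model, vbar, layout)
    extra = [(parts[name], pops[name]) for name in extra_joint]
    return integration_moments(
        parts["prop"],
        parts["vis"],
        stim_prior,
        arm,
        pops["prop"],
        pops["vis"],
        extra_joint_cues=extra,
    )
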