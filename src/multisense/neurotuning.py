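"""Hidden-unit characterization: tuning curves, sharpening, reference frames.

All analyses here consume only the trained model's parameters and stimulus
grids — never the training internals.  Responses are computed noiselessly
(means in both layers) unless a sampled activity count is explicitly asked
for, matching how electrophysiological tuning curves are averaged.
"""

from __future__ import annotations

import numpy as np

from .harmonium import Harmonium, up_mean
from .kinematics import ArmModel, forward_kinematics, inverse_1d
from .popcode import PopulationCode, mean_rates

__all__ = [
    "tuning_curves",
    "tuned_mask",
    "active_fraction",
    "arc_tuning",
    "coordtrans_response_maps",
    "reference_frame_analysis",
]


def _visible_means_integration(
    theta_grid: np.ndarray,
    gain: float,
    pops: dict[str, PopulationCode],
    layout: dict[str, tuple[int, int]],
    arm: ArmModel,
) -> np.ndarray:
    """Noiseless visible activity for each grid stimulus, in layout order."""
    n_vis = max(stop for _, stop in layout.values())
    out = np.zeros((theta_grid.shape[0], n_vis))
    x = forward_kinematics(theta_grid, arm)
    stimuli = {"prop": theta_grid, "vis": x}
    for name, (a, b) in layout.items():
        if name in stimuli:
            out[:, a:b] = mean_rates(stimuli[name], gain, pops[name])
    return out


def tuning_curves(
    model: Harmonium,
    theta_grid: np.ndarray,
    pops: dict[str, PopulationCode],
    layout: dict[str, tuple[int, int]],
    arm: ArmModel,
    gain: float = 15.0,
) -> np.ndarray:
    """Hidden firing probability over a joint-space grid, per unit.

    Returns (n_grid, n_hidden); deterministic (no sampling anywhere).
    """
    r = _visible_means_integration(np.atleast_2d(theta_grid), gain, pops, layout, arm)
    return up_mean(model, r)


def tuned_mask(curves: np.ndarray, threshold: float = 0.1) -> np.ndarray:
    """Units whose firing probability varies by more than ``threshold``.

    The mask is computed over whatever stimulus domain ``curves`` was
    collected on (full plane or an arc); the domain is part of the contract.
    """
    rng = curves.max(axis=0) - curves.min(axis=0)
    return rng > threshold


def active_fraction(
    model: Harmonium,
    counts: np.ndarray,
    rng: np.random.Generator,
    n_samples: int = 15,
) -> tuple[float, float]:
    """Fractions of (hidden, input) units active on the given trials.

    A hidden unit is active if it spikes at least once in ``n_samples``
    Bernoulli draws; an input unit if its count is nonzero.  Sharper hidden
    tuning at higher gain shows up as a *decreasing* hidden fraction even as
    the input fraction increases.
    """
    r = np.asarray(counts, dtype=float)
    ph = up_mean(model, r)
    spikes = rng.binomial(n_samples, ph)
    hidden_frac = float(np.mean(spikes > 0))
    input_frac = float(np.mean(r > 0))
    return hidden_frac, input_frac


def arc_tuning(
    model: Harmonium,
    arc_thetas: np.ndarray,
    pops: dict[str, PopulationCode],
    layout: dict[str, tuple[int, int]],
    arm: ArmModel,
    gain_list=(9.0, 15.0, 21.0),
) -> np.ndarray:
    """Tuning along a 1D arc of joint-space stimuli, at several gains.

    Returns (n_gains, n_arc_points, n_hidden).
    """
    return np.stack(
        [tuning_curves(model, arc_thetas, pops, layout, arm, g) for g in gain_list]
    )


def coordtrans_response_maps(
    model: Harmonium,
    hb_grid: np.ndarray,
    e_grid: np.ndarray,
    pops: dict[str, PopulationCode],
    layout: dict[str, tuple[int, int]],
    arm_1d: ArmModel,
    gains: dict[str, float] | None = None,
) -> np.ndarray:
    """Noiseless hidden responses over the (H_b, E) rectangle.

    Returns (n_hidden, len(hb_grid), len(e_grid)).
    """
    if gains is None:
        gains = {"prop": 45.0, "vis": 15.0, "eye": 15.0}
    HB, E = np.meshgrid(hb_grid, e_grid, indexing="ij")
    theta = inverse_1d(HB.ravel(), arm_1d)
    xr = (HB - E).ravel()
    n_vis = max(stop for _, stop in layout.values())
    r = np.zeros((HB.size, n_vis))
    stimuli = {"prop": theta, "vis": xr, "eye": E.ravel()}
    for name, (a, b) in layout.items():
        r[:, a:b] = mean_rates(stimuli[name][:, None], gains[name], pops[name])
    ph = up_mean(model, r)
    return np.moveaxis(ph.reshape(len(hb_grid), len(e_grid), -1), -1, 0)


def reference_frame_analysis(
    maps: np.ndarray,
    hb_grid: np.ndarray,
    e_grid: np.ndarray,
    tuned_threshold: float = 0.1,
    separability_threshold: float = 0.95,
    align_tolerance_deg: float = 15.0,
    hist_bin_deg: float = 15.0,
) -> dict:
    """Gradient-direction and separability analysis of (H_b, E) tuning maps.

    For each tuned unit the analysis computes (1) a separability index —
    the fraction of variance captured by the first singular value of the
    mean-centered response matrix, 1 for any product-form map g(H_b)h(E)
    (a pure gain field) — and (2) the reference frame: the axial circular
    mean of the response-gradient direction in the (H_b, E) plane.  A unit
    tuned purely to H_b has gradient along 0 deg; to E, 90 deg; to the
    retinal position H_r = H_b - E, along the -45 deg diagonal; to H_b + E,
    along +45 deg.  Angles are axial (mod 180, reported in [-90, 90)).
    """
    maps = np.asarray(maps, dtype=float)
    if maps.ndim == 2:
        maps = maps[None]
    n_units = maps.shape[0]
    tuned = np.array(
        [m.max() - m.min() > tuned_threshold for m in maps]
    )
    sep = np.full(n_units, np.nan)
    angle = np.full(n_units, np.nan)
    dhb = float(np.mean(np.diff(hb_grid)))
    de = float(np.mean(np.diff(e_grid)))
    for u in range(n_units):
        if not tuned[u]:
            continue
        # separability on the raw (uncentered) matrix: any product-form map
        # g(H_b) h(E) is exactly rank one and scores 1
        s = np.linalg.svd(maps[u], compute_uv=False)
        sep[u] = float(s[0] ** 2 / np.sum(s**2))
        g_hb, g_e = np.gradient(maps[u], dhb, de)
        w = np.hypot(g_hb, g_e).ravel()
        # axial statistics: double the angle so that opposite gradients agree
        th = np.arctan2(g_e, g_hb).ravel()
        c = np.sum(w * np.cos(2 * th))
        s2 = np.sum(w * np.sin(2 * th))
        ang = 0.5 * np.degrees(np.arctan2(s2, c))
        angle[u] = ((ang + 90.0) % 180.0) - 90.0

    def classify(a, s):
        if not np.isfinite(a):
            return "untuned"
        if np.isfinite(s) and s >= separability_threshold:
            return "separable"
        tol = align_tolerance_deg
        axes = {"Hb": 0.0, "Hb+E": 45.0, "E": 90.0, "Hr": -45.0}
        for name, ax in axes.items():
            d = abs(((a - ax) + 90.0) % 180.0 - 90.0)
            if d <= tol:
                return name
        return "intermediate"

    labels = [classify(angle[u], sep[u]) for u in range(n_units)]
    edges = np.arange(-90.0, 90.0 + hist_bin_deg, hist_bin_deg)
    hist, _ = np.histogram(angle[np.isfinite(angle)], bins=edges)
    return {
        "tuned": tuned,
        "separability": sep,
        "gradient_angle_deg": angle,
        "labels": labels,
        "histogram": {"edges_deg": edges.tolist(), "counts": hist.tolist()},
    }
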