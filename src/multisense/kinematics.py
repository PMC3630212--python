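"""Arm geometry: joint space, Cartesian hand space, and 1D eye-centered space.

The planar two-link arm maps shoulder/elbow joint angles ``theta = (th1, th2)``
to a fingertip position

    x = (L1 cos th1 + L2 cos(th1 + th2),  L1 sin th1 + L2 sin(th1 + th2)),

with the shoulder at the origin, ``th2`` measured as elbow flexion relative to
the upper-arm axis, radians and centimetres throughout.  Restricting the elbow
to one side of full extension makes the map injective on the configured joint
box, so joint and Cartesian coordinates are two interchangeable descriptions
of the same stimulus.

The one-degree-of-freedom variant used for coordinate transformation maps a
single joint angle to a body-centered position ``H_b = L cos(theta)`` and a
retinal position ``H_r = H_b - E`` for gaze angle ``E``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ArmModel",
    "forward_kinematics",
    "jacobian",
    "inverse_kinematics",
    "forward_1d",
    "inverse_1d",
    "DEFAULT_ARM",
    "DEFAULT_ARM_1D",
]


class KinematicsError(ValueError):
    """Raised for out-of-domain joint angles or unreachable targets."""


@dataclass(frozen=True)
class ArmModel:
    """Geometry of the simulated arm.

    Parameters
    ----------
    link_lengths : (L1, L2) in cm (upper arm, forearm); planar-2link mode.
    joint_limits : ((lo, hi), (lo, hi)) closed intervals in rad for
        (shoulder, elbow) — or a single interval in cosine-1d mode.
    mode : "planar-2link" or "cosine-1d".
    link_1d : link length in cm for the cosine-1d map.
    """

    link_lengths: tuple[float, float] = (12.0, 20.0)
    joint_limits: tuple = ((0.0, np.pi / 2), (np.pi / 3, 5 * np.pi / 6))
    mode: str = "planar-2link"
    link_1d: float = 32.0

    def __post_init__(self):
        if self.mode not in ("planar-2link", "cosine-1d"):
            raise ValueError(f"unknown arm mode {self.mode!r}")
        if self.mode == "planar-2link":
            l1, l2 = self.link_lengths
            if not (l1 > 0 and l2 > 0):
                raise ValueError("link lengths must be strictly positive")
            lims = np.asarray(self.joint_limits, dtype=float)
            if lims.shape != (2, 2):
                raise ValueError("joint_limits must be two (lo, hi) intervals")
            if not np.all(np.isfinite(lims)):
                raise ValueError("joint limits must be finite")
            if np.any(lims[:, 1] <= lims[:, 0]):
                raise ValueError("joint_limits must be non-degenerate intervals")
            self._verify_injective()
        else:
            if self.link_1d <= 0:
                raise ValueError("link_1d must be strictly positive")
            lo, hi = np.asarray(self.joint_limits, dtype=float).reshape(2)
            if not (0.0 <= lo < hi <= np.pi):
                # cos is injective only on [0, pi]
                raise ValueError("1D joint range must lie within [0, pi]")

    def _verify_injective(self, n: int = 21) -> None:
        # Injectivity of the 2-link map holds iff the elbow never crosses a
        # singular configuration (sin th2 = 0) in the interior; verify on a
        # grid and by round-tripping through the closed-form inverse.
        (s_lo, s_hi), (e_lo, e_hi) = self.joint_limits
        th2 = np.linspace(e_lo, e_hi, n)[1:-1]
        if np.any(np.sin(th2) == 0.0):
            raise ValueError("elbow range crosses a kinematic singularity")
        g1 = np.linspace(s_lo, s_hi, n)
        g2 = np.linspace(e_lo, e_hi, n)
        th = np.stack(np.meshgrid(g1, g2, indexing="ij"), axis=-1).reshape(-1, 2)
        x = forward_kinematics(th, self)
        back = inverse_kinematics(x, self)
        # tolerance allows arccos round-off at the straight-arm boundary
        if not np.allclose(back, th, atol=1e-6):
            raise ValueError("forward map is not injective on the joint box")

    # convenience
    @property
    def joint_center(self) -> np.ndarray:
        lims = np.asarray(self.joint_limits, dtype=float)
        if self.mode == "cosine-1d":
            return lims.reshape(2).mean(keepdims=True)
        return lims.mean(axis=1)

    def contains(self, theta: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        lims = np.atleast_2d(np.asarray(self.joint_limits, dtype=float))
        th = np.atleast_2d(np.asarray(theta, dtype=float))
        ok = np.all((th >= lims[:, 0] - atol) & (th <= lims[:, 1] + atol), axis=-1)
        return ok if np.asarray(theta).ndim > 1 else bool(ok[0])


def _check_limits(theta: np.ndarray, arm: ArmModel) -> np.ndarray:
    th = np.asarray(theta, dtype=float)
    lims = np.atleast_2d(np.asarray(arm.joint_limits, dtype=float))
    flat = np.atleast_2d(th)
    for j in range(lims.shape[0]):
        col = flat[..., j]
        if np.any(col < lims[j, 0] - 1e-9) or np.any(col > lims[j, 1] + 1e-9):
            name = ("shoulder", "elbow")[j] if lims.shape[0] == 2 else "joint"
            raise KinematicsError(
                f"{name} angle outside joint limits "
                f"[{lims[j, 0]:.4f}, {lims[j, 1]:.4f}] rad"
            )
    return th


def forward_kinematics(theta, arm: ArmModel) -> np.ndarray:
    """Fingertip position (cm) of the planar 2-link arm; batched over leading axes."""
    th = _check_limits(theta, arm)
    l1, l2 = arm.link_lengths
    th1 = th[..., 0]
    th12 = th[..., 0] + th[..., 1]
    return np.stack(
        [l1 * np.cos(th1) + l2 * np.cos(th12), l1 * np.sin(th1) + l2 * np.sin(th12)],
        axis=-1,
    )


def jacobian(theta, arm: ArmModel) -> np.ndarray:
    """Analytic Jacobian d(x)/d(theta), shape (..., 2, 2), det = L1 L2 sin(th2)."""
    th = _check_limits(theta, arm)
    l1, l2 = arm.link_lengths
    th1 = th[..., 0]
    th12 = th[..., 0] + th[..., 1]
    s1, c1 = np.sin(th1), np.cos(th1)
    s12, c12 = np.sin(th12), np.cos(th12)
    row1 = np.stack([-l1 * s1 - l2 * s12, -l2 * s12], axis=-1)
    row2 = np.stack([l1 * c1 + l2 * c12, l2 * c12], axis=-1)
    return np.stack([row1, row2], axis=-2)


def inverse_kinematics(x, arm: ArmModel, clamp: bool = False) -> np.ndarray:
    """Closed-form inverse of the 2-link map, selecting the in-limits elbow branch.

    With ``clamp`` (used when decoding noisy estimates that may stray just
    outside the workspace sector), the branch with the smallest joint-limit
    violation is chosen and clipped into the joint box instead of raising.
    """
    xx = np.asarray(x, dtype=float)
    l1, l2 = arm.link_lengths
    r2 = np.sum(xx**2, axis=-1)
    c2 = (r2 - l1**2 - l2**2) / (2 * l1 * l2)
    if not clamp and (np.any(c2 > 1 + 1e-12) or np.any(c2 < -1 - 1e-12)):
        raise KinematicsError("target outside the reachable annulus")
    c2 = np.clip(c2, -1.0, 1.0)
    th2 = np.arccos(c2)  # elbow >= 0 branch
    lims = np.asarray(arm.joint_limits, dtype=float)
    base = np.arctan2(xx[..., 1], xx[..., 0])
    mid = lims[0].mean()
    cands, viols = [], []
    for sign in (+1.0, -1.0):
        t2 = sign * th2
        t1 = base - np.arctan2(l2 * np.sin(t2), l1 + l2 * np.cos(t2))
        # wrap th1 into the 2pi window centered on the shoulder range
        t1 = np.mod(t1 - (mid - np.pi), 2 * np.pi) + (mid - np.pi)
        cand = np.stack([t1, t2], axis=-1)
        viol = np.sum(
            np.maximum(lims[:, 0] - cand, 0) + np.maximum(cand - lims[:, 1], 0),
            axis=-1,
        )
        cands.append(cand)
        viols.append(viol)
    pick = viols[1] < viols[0]
    sol = np.where(pick[..., None], cands[1], cands[0])
    best = np.where(pick, viols[1], viols[0])
    if clamp:
        return np.clip(sol, lims[:, 0], lims[:, 1])
    if np.any(best > 1e-9):
        raise KinematicsError("no elbow branch lies inside the joint limits")
    return sol


def forward_1d(theta, eye, arm: ArmModel):
    """Cosine map of the 1D arm: returns (body-centered, retinal) positions in cm.

    body_centered = L cos(theta); retinal = body_centered - eye  (H_r = H_b - E).
    """
    th = np.asarray(theta, dtype=float)
    lo, hi = np.asarray(arm.joint_limits, dtype=float).reshape(2)
    if np.any(th < lo - 1e-9) or np.any(th > hi + 1e-9):
        raise KinematicsError(f"joint angle outside limits [{lo:.4f}, {hi:.4f}] rad")
    body = arm.link_1d * np.cos(th)
    return body, body - np.asarray(eye, dtype=float)


def inverse_1d(body_centered, arm: ArmModel) -> np.ndarray:
    """Joint angle of the 1D arm from body-centered position (inverse cosine map)."""
    xb = np.asarray(body_centered, dtype=float)
    c = xb / arm.link_1d
    if np.any(np.abs(c) > 1 + 1e-12):
        raise KinematicsError("body-centered position outside the arm's reach")
    th = np.arccos(np.clip(c, -1.0, 1.0))
    lo, hi = np.asarray(arm.joint_limits, dtype=float).reshape(2)
    if np.any(th < lo - 1e-9) or np.any(th > hi + 1e-9):
        raise KinematicsError("position maps outside the 1D joint range")
    return th


DEFAULT_ARM = ArmModel()
DEFAULT_ARM_1D = ArmModel(
    mode="cosine-1d", joint_limits=(np.pi / 6, 5 * np.pi / 6), link_1d=32.0
)
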