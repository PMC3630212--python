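"""Small plotting helpers for evaluation reports (error ellipses)."""

from __future__ import annotations

import numpy as np

# 95% confidence for a 2D Gaussian: chi-square 2-dof quantile
CHI2_95_2DOF = 5.991


def error_ellipse(mean, cov, ax=None, confidence_scale: float = CHI2_95_2DOF, **kw):
    """Draw the 95% confidence ellipse of a 2D Gaussian on ``ax``."""
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    vals, vecs = np.linalg.eigh(cov)
    angle = np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1]))
    width, height = 2.0 * np.sqrt(confidence_scale * vals[::-1])
    if ax is None:
        ax = plt.gca()
    patch = Ellipse(mean, width, height, angle=angle, fill=False, **kw)
    ax.add_patch(patch)
    return patch
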