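"""Independent oracles used by the tests.

These deliberately avoid the package's own code paths: IOU by enumerating
unit pixels on a boolean grid, and AP by adaptive numerical quadrature of
the interpolated precision envelope.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad


def pixel_iou(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> float:
    """IOU of two integer-coordinate boxes by counting unit cells on a grid."""
    hi = max(a[2], b[2], a[3], b[3]) + 1
    grid_a = np.zeros((hi, hi), dtype=bool)
    grid_b = np.zeros((hi, hi), dtype=bool)
    grid_a[a[1] : a[3], a[0] : a[2]] = True
    grid_b[b[1] : b[3], b[0] : b[2]] = True
    union = int((grid_a | grid_b).sum())
    if union == 0:
        raise ValueError("degenerate boxes")
    return int((grid_a & grid_b).sum()) / union


def quad_average_precision(points: list[tuple[float, float]]) -> float:
    """AP by numerical quadrature of the all-points precision envelope.

    The envelope at recall r is the max precision over points with
    recall >= r (0 beyond max recall); quad subdivides at the recall
    breakpoints, on which Gauss-Kronrod is exact for the piecewise-constant
    integrand.
    """

    def envelope(r: float) -> float:
        vals = [p for rec, p in points if rec >= r]
        return max(vals) if vals else 0.0

    breakpoints = sorted({r for r, _p in points if 0.0 < r < 1.0})
    val, _err = quad(envelope, 0.0, 1.0, points=breakpoints, limit=200)
    return val
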