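"""Shared fixtures and independent brute-force oracles.

The oracles recompute the chi-square objective from its definition and
minimize it by exhaustive (zooming) grid search, independent of the
package's fitting path.
"""

from __future__ import annotations

import numpy as np
import pytest


def chi2_effective_variance(x, y, sx, sy, a, b):
    """Chi-square with effective-variance weights, written from scratch."""
    return np.sum((y - a - b * x) ** 2 / (sy**2 + b**2 * sx**2))


def grid_minimize_chi2(x, y, sx, sy, a_window, b_window, resolution=1e-4,
                       n_grid=101):
    """Zooming 2-D grid search for the (a, b) minimizing the chi-square.

    Refines the grid around the current argmin until the step is below
    ``resolution`` in both parameters.
    """
    a_lo, a_hi = a_window
    b_lo, b_hi = b_window
    while True:
        A = np.linspace(a_lo, a_hi, n_grid)
        B = np.linspace(b_lo, b_hi, n_grid)
        AA, BB = np.meshgrid(A, B, indexing="ij")
        C = np.empty_like(AA)
        for j, b in enumerate(B):
            w = 1.0 / (sy**2 + b**2 * sx**2)
            resid = y[None, :] - A[:, None] - b * x[None, :]
            C[:, j] = np.sum(w * resid**2, axis=1)
        i, j = np.unravel_index(np.argmin(C), C.shape)
        da = A[1] - A[0]
        db = B[1] - B[0]
        if da < resolution and db < resolution:
            return A[i], B[j]
        a_lo, a_hi = A[i] - 2 * da, A[i] + 2 * da
        b_lo, b_hi = B[j] - 2 * db, B[j] + 2 * db


def profile_scan_se_b(x, y, sx, sy, b_center, halfspan, resolution=1e-4):
    """Brute-force scan of min_a chi2(a, b) vs b; Delta-chi2 = 1 interval.

    Returns the symmetrized (max) half-width of the interval where the
    profiled chi-square stays within 1 of its minimum.
    """
    bs = np.arange(b_center - halfspan, b_center + halfspan, resolution)
    prof = np.empty_like(bs)
    for i, b in enumerate(bs):
        w = 1.0 / (sy**2 + b**2 * sx**2)
        a = np.sum(w * (y - b * x)) / np.sum(w)
        prof[i] = chi2_effective_variance(x, y, sx, sy, a, b)
    cmin = prof.min()
    inside = bs[prof <= cmin + 1.0]
    b_best = bs[np.argmin(prof)]
    return max(b_best - inside.min(), inside.max() - b_best)


@pytest.fixture
def six_point_dataset():
    """A fixed seeded 6-point dataset with errors in both coordinates."""
    rng = np.random.default_rng(42)
    x0 = np.linspace(0.2, 1.8, 6)
    sx = 0.05 * x0
    sy = np.full(6, 0.12)
    a_true, b_true = -1.5, 0.9
    x = x0 + rng.normal(0, sx)
    y = a_true + b_true * x0 + rng.normal(0, sy)
    return x, y, sx, sy
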