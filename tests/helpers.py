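"""Independent oracles used by the test suite.

These deliberately avoid the library's own code paths: the grid search is
exhaustive enumeration where the profiler anneals, and the flux oracle is a
literal per-frame state machine where the detector works on collapsed
region sequences.
"""

from __future__ import annotations

import numpy as np


def grid_search_radius(atoms, z: float, extent: float = 12.0, coarse: float = 0.1,
                       fine: float = 0.005) -> float:
    """Exhaustive two-stage in-plane grid search for the largest probe sphere.

    Evaluates min_i(|c − x_i| − vdw_i) on a coarse grid over
    [-extent, extent]², then refines around the best coarse point.
    """
    coords = atoms.coords
    radii = atoms.vdw_radius

    def objective(cx, cy):
        d = np.sqrt((coords[:, 0] - cx) ** 2 + (coords[:, 1] - cy) ** 2 + (coords[:, 2] - z) ** 2)
        return np.min(d - radii)

    best = (-np.inf, 0.0, 0.0)
    for cx in np.arange(-extent, extent + coarse / 2, coarse):
        for cy in np.arange(-extent, extent + coarse / 2, coarse):
            f = objective(cx, cy)
            if f > best[0]:
                best = (f, cx, cy)
    _, bx, by = best
    for cx in np.arange(bx - coarse, bx + coarse, fine):
        for cy in np.arange(by - coarse, by + coarse, fine):
            f = objective(cx, cy)
            if f > best[0]:
                best = (f, cx, cy)
    return best[0]


def flux_oracle(z: np.ndarray, z_lo: float, z_hi: float):
    """Per-frame state-machine replay of traversal counting.

    States: 'below', 'above', 'inside_from_below', 'inside_from_above',
    or None before the particle first leaves the gate region.
    """
    n_frames, n_particles = z.shape
    up = 0
    down = 0
    for p in range(n_particles):
        state = None
        for f in range(n_frames):
            v = z[f, p]
            if v < z_lo:
                if state in ("inside_from_above", "above"):
                    down += 1
                state = "below"
            elif v > z_hi:
                if state in ("inside_from_below", "below"):
                    up += 1
                state = "above"
            else:
                if state == "below":
                    state = "inside_from_below"
                elif state == "above":
                    state = "inside_from_above"
    return up, down
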