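import logging

import numpy as np
import pytest

import popgrid as pg

# boundary-policy warnings are expected in many constructions; keep the
# test output readable
logging.getLogger("popgrid").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def cond_model():
    return pg.archive_model("cond2d")


@pytest.fixture(scope="session")
def cond_grid():
    """Moderate-resolution conductance-model grid for shared use."""
    return pg.build_grid((-72.0, -54.0, -0.2, 1.0), (60, 60))


@pytest.fixture(scope="session")
def cond_det_matrix(cond_model, cond_grid):
    return pg.generate_deterministic_matrix(cond_model, cond_grid)


@pytest.fixture(scope="session")
def zero_field_model():
    def zero(y, t):
        return (0.0 * y[0], 0.0 * y[1])

    return pg.NeuronModel(name="zero", vector_field=zero, timestep=1e-3)


def sample_quad_points(quad, n, rng):
    """Uniform random points inside a (possibly non-convex) quadrilateral.

    Splits the quad along the 0-2 diagonal into two triangles (the same fan
    the implementation uses) and samples each in proportion to its area —
    an independent Monte Carlo area oracle.
    """
    quad = np.asarray(quad, dtype=float)
    tris = [quad[[0, 1, 2]], quad[[0, 2, 3]]]
    areas = []
    for t in tris:
        (ax, ay), (bx, by), (cx, cy) = t
        areas.append(abs((bx - ax) * (cy - ay) - (cx - ax) * (by - ay)) / 2)
    areas = np.asarray(areas)
    n1 = rng.binomial(n, areas[0] / areas.sum())
    pts = []
    for t, m in zip(tris, (n1, n - n1)):
        u = rng.random(m)
        v = rng.random(m)
        flip = u + v > 1
        u[flip] = 1 - u[flip]
        v[flip] = 1 - v[flip]
        pts.append(t[0] + np.outer(u, t[1] - t[0]) + np.outer(v, t[2] - t[0]))
    return np.vstack(pts)


def mc_overlap_fractions(quad, grid, n, rng):
    """Monte-Carlo estimate of per-cell overlap fractions of a quad."""
    pts = sample_quad_points(quad, n, rng)
    counts = {}
    for v, h in pts:
        c = grid.cell_of_point(float(v), float(h))
        counts[c] = counts.get(c, 0) + 1
    return {c: k / n for c, k in counts.items()}
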