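"""Independent oracles and shared fixtures for the test suite.

Everything here is deliberately implemented without using the package's own
algorithms (brute-force enumeration, dense-grid scans, a zero-temperature
string method), so that tests compare two independent routes to the same
quantity.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import tapspath as tp

# ---------------------------------------------------------------------------
# Mueller-Brown reference geometry
# ---------------------------------------------------------------------------

MB_MINIMA_GUESSES = [(-0.55, 1.45), (-0.05, 0.47), (0.6, 0.0)]
MB_SADDLES = [np.array([-0.822, 0.624]), np.array([0.212, 0.293])]


def mb_minimum(guess, scale: float = 1.0) -> np.ndarray:
    mb = tp.get_potential("mueller_brown", {"scale": scale})
    res = minimize(
        lambda x: mb.energy_at(x), np.asarray(guess, dtype=float),
        jac=lambda x: mb.gradient_at(x), method="BFGS",
        options={"gtol": 1e-10 * max(scale, 1e-3)},
    )
    return res.x


def string_method_path(system, a, c, n: int = 41, eta: float = 2e-6, iters: int = 60000):
    """Zero-temperature string: steepest descent + equal-arclength
    redistribution on a dense node set. Independent of the TAPS machinery."""
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    t = np.linspace(0.0, 1.0, n)[:, None]
    x = a + t * (c - a)
    for _ in range(iters):
        g = system.gradient(x)
        x[1:-1] -= eta * g[1:-1]
        d = np.r_[0.0, np.cumsum(np.linalg.norm(np.diff(x, axis=0), axis=1))]
        d /= d[-1]
        xi = np.linspace(0.0, 1.0, n)
        x = np.column_stack([np.interp(xi, d, x[:, 0]), np.interp(xi, d, x[:, 1])])
    return x


def dist_to_polyline(p, poly) -> float:
    """Minimum distance from point p to the polyline through poly."""
    p = np.asarray(p, dtype=float)
    poly = np.asarray(poly, dtype=float)
    a, b = poly[:-1], poly[1:]
    ab = b - a
    t = np.clip(np.einsum("id,id->i", p - a, ab) / np.einsum("id,id->i", ab, ab), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return float(np.linalg.norm(p - proj, axis=1).min())


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def grid_rotation_rmsd(mobile, reference, axis, step_deg: float = 1.0) -> float:
    """Best RMSD over a dense grid of rotations about a known axis (after
    centroid alignment). Oracle for the Kabsch superposition."""
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    mc = mob - mob.mean(axis=0)
    rc = ref - ref.mean(axis=0)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    best = np.inf
    for deg in np.arange(0.0, 360.0, step_deg):
        r = Rotation.from_rotvec(np.deg2rad(deg) * axis).as_matrix()
        rmsd = np.sqrt(np.mean(np.sum((mc @ r.T - rc) ** 2, axis=1)))
        best = min(best, rmsd)
    return float(best)


def exhaustive_medoid(points, metric=None) -> int:
    """Index minimizing the summed distance to all other members."""
    metric = metric or tp.MetricSpec()
    pts = np.asarray(points, dtype=float)
    sums = [
        sum(tp.conf_distance(pts[i], pts[j], metric) for j in range(len(pts)))
        for i in range(len(pts))
    ]
    return int(np.argmin(sums))


def exhaustive_open_tour(dist, fixed_endpoints=True):
    """Best open-tour permutation by full enumeration (tiny N only)."""
    n = dist.shape[0]
    def length(p):
        return sum(dist[p[i], p[i + 1]] for i in range(len(p) - 1))
    best_perm, best_len = None, np.inf
    if fixed_endpoints:
        for mid in permutations(range(1, n - 1)):
            p = (0,) + mid + (n - 1,)
            ln = length(p)
            if ln < best_len:
                best_len, best_perm = ln, p
    else:
        for p in permutations(range(n)):
            ln = length(p)
            if ln < best_len:
                best_len, best_perm = ln, p
    return np.array(best_perm), float(best_len)


def brute_force_min_distance(frame, group_a, group_b) -> float:
    frame = np.asarray(frame, dtype=float)
    return min(
        float(np.linalg.norm(frame[i] - frame[j])) for i in group_a for j in group_b
    )


# ---------------------------------------------------------------------------
# the multi-step staircase study conditions
# ---------------------------------------------------------------------------
# Basin/barrier ladder (kcal/mol) of a six-step loading process: forward
# barriers 6.15, 6.37, 5.47, 5.24, 9.90, 7.16; backward barriers 4.28, 4.24,
# 4.06, 4.06, 13.99, 6.10; endpoint difference 3.56; total forward 40.29.
STAIR_MINIMA = (0.0, 1.87, 4.00, 5.41, 6.59, 2.50, 3.56)
STAIR_MAXIMA = (6.15, 8.24, 9.47, 10.65, 16.49, 9.66)
STAIR_POSITIONS = tuple(2.0 * i for i in range(7))
STAIR_WIDTH = 0.8


def wildtype_staircase():
    """The staircase system used across the end-to-end tests."""
    spec = tp.StaircaseSpec(STAIR_MINIMA, STAIR_MAXIMA, STAIR_POSITIONS, STAIR_WIDTH)
    return tp.build_staircase(spec, k_edge=250.0), spec
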