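"""Analytic benchmark landscapes and bead-model conformation generators.

These systems stand in for an all-atom force field so that every stage of the
path-search pipeline (biased sampling, path optimization, umbrella sampling,
WHAM, profile analytics) can be exercised and verified on a desk machine:

* a registry of classic low-dimensional potentials (harmonic well, 1D/2D
  double wells, the Mueller-Brown surface),
* a configurable 1D "staircase" landscape with a prescribed ladder of minima
  and maxima, emulating a multi-step loading process with several
  intermediate and transition states between two endpoint basins,
* random bead "molecules" with a known superposition RMSD, for testing the
  align-set/RMS-set conformational metric.

Energies are in kJ/mol internally; :class:`StaircaseSpec` extrema are given
in kcal/mol because that is the unit in which barrier ladders are usually
quoted, and are converted on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import KJ_PER_KCAL
from .errors import RegistryError, ValidationError

__all__ = [
    "PotentialSystem",
    "StaircaseSpec",
    "BeadModel",
    "get_potential",
    "build_staircase",
    "bead_model_pair",
    "registered_potentials",
]


@dataclass(frozen=True)
class PotentialSystem:
    """An analytic potential-energy system.

    ``energy`` maps an array of shape ``(..., dimension)`` to energies of
    shape ``(...,)`` in kJ/mol; ``gradient`` returns the same leading shape
    with a trailing ``dimension`` axis, in kJ/mol per unit length.
    """

    dimension: int
    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    label: str

    def energy_at(self, x) -> float:
        return float(self.energy(np.asarray(x, dtype=float)))

    def gradient_at(self, x) -> np.ndarray:
        return np.asarray(self.gradient(np.asarray(x, dtype=float)), dtype=float)


def _points(x, dimension: int) -> np.ndarray:
    """Coerce input to shape (..., dimension)."""
    x = np.asarray(x, dtype=float)
    if dimension == 1 and (x.ndim == 0 or x.shape[-1] != 1):
        x = x[..., np.newaxis]
    if x.shape[-1] != dimension:
        raise ValidationError(
            f"expected coordinates with last axis {dimension}, got shape {x.shape}"
        )
    return x


# ---------------------------------------------------------------------------
# registry potentials
# ---------------------------------------------------------------------------


def _harmonic(k: float = 1.0, center=0.0, dimension: int = 1) -> PotentialSystem:
    if k <= 0:
        raise ValidationError("harmonic: field 'k' must be positive")
    if dimension < 1:
        raise ValidationError("harmonic: field 'dimension' must be >= 1")
    c = np.broadcast_to(np.asarray(center, dtype=float), (dimension,)).copy()

    def energy(x):
        x = _points(x, dimension)
        return 0.5 * k * np.sum((x - c) ** 2, axis=-1)

    def gradient(x):
        x = _points(x, dimension)
        return k * (x - c)

    return PotentialSystem(dimension, energy, gradient, f"harmonic(k={k})")


def _double_well_1d(a: float = 1.0, b: float = 2.0) -> PotentialSystem:
    """U(x) = a x^4 - b x^2, symmetric about 0.

    Minima at +-sqrt(b/2a), barrier height b^2/(4a) at x = 0.
    """
    if a <= 0:
        raise ValidationError("double_well_1d: field 'a' must be positive")
    if b <= 0:
        raise ValidationError("double_well_1d: field 'b' must be positive")

    def energy(x):
        x = _points(x, 1)[..., 0]
        return a * x**4 - b * x**2

    def gradient(x):
        x1 = _points(x, 1)[..., 0]
        return (4.0 * a * x1**3 - 2.0 * b * x1)[..., np.newaxis]

    return PotentialSystem(1, energy, gradient, f"double_well_1d(a={a},b={b})")


def _double_well_2d(a: float = 1.0, b: float = 2.0, k_perp: float = 4.0) -> PotentialSystem:
    """Double well along x with a harmonic valley in y; saddle at the origin."""
    if a <= 0 or b <= 0 or k_perp <= 0:
        raise ValidationError("double_well_2d: fields 'a', 'b', 'k_perp' must be positive")

    def energy(x):
        x = _points(x, 2)
        return a * x[..., 0] ** 4 - b * x[..., 0] ** 2 + 0.5 * k_perp * x[..., 1] ** 2

    def gradient(x):
        x = _points(x, 2)
        g = np.empty_like(x)
        g[..., 0] = 4.0 * a * x[..., 0] ** 3 - 2.0 * b * x[..., 0]
        g[..., 1] = k_perp * x[..., 1]
        return g

    return PotentialSystem(2, energy, gradient, "double_well_2d")


# Standard four-Gaussian Mueller-Brown parameterization.
_MB_A = np.array([-200.0, -100.0, -170.0, 15.0])
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])

#: Conventional locations of the three Mueller-Brown minima (dimensionless).
MUELLER_BROWN_MINIMA_GUESSES = ((-0.55, 1.45), (-0.05, 0.47), (0.6, 0.0))
#: Conventional locations of the two saddle points.
MUELLER_BROWN_SADDLE_GUESSES = ((-0.82, 0.62), (0.2, 0.3))


def _mueller_brown(scale: float = 1.0) -> PotentialSystem:
    """The Mueller-Brown surface: three minima, two saddles.

    Coordinates are dimensionless; energies are mapped to kJ/mol by
    ``scale`` (default 1).
    """
    if scale <= 0:
        raise ValidationError("mueller_brown: field 'scale' must be positive")

    def energy(x):
        x = _points(x, 2)
        dx = x[..., 0, np.newaxis] - _MB_x0
        dy = x[..., 1, np.newaxis] - _MB_y0
        terms = _MB_A * np.exp(_MB_a * dx**2 + _MB_b * dx * dy + _MB_c * dy**2)
        return scale * np.sum(terms, axis=-1)

    def gradient(x):
        x = _points(x, 2)
        dx = x[..., 0, np.newaxis] - _MB_x0
        dy = x[..., 1, np.newaxis] - _MB_y0
        terms = _MB_A * np.exp(_MB_a * dx**2 + _MB_b * dx * dy + _MB_c * dy**2)
        g = np.empty_like(x)
        g[..., 0] = scale * np.sum(terms * (2.0 * _MB_a * dx + _MB_b * dy), axis=-1)
        g[..., 1] = scale * np.sum(terms * (_MB_b * dx + 2.0 * _MB_c * dy), axis=-1)
        return g

    return PotentialSystem(2, energy, gradient, f"mueller_brown(scale={scale})")


# ---------------------------------------------------------------------------
# staircase landscape
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StaircaseSpec:
    """Prescription for a 1D multi-step landscape.

    ``minima_values`` (kcal/mol) lists every basin including the two
    endpoints, first conventionally 0; ``maxima_values`` lists the barrier
    tops separating adjacent basins (one fewer than minima).
    ``minima_positions`` places the basins on the coordinate axis;
    barrier tops sit midway between adjacent basins.
    """

    minima_values: tuple
    maxima_values: tuple
    minima_positions: tuple
    smoothing_width: float = 0.5

    def __post_init__(self):
        mins = np.asarray(self.minima_values, dtype=float)
        maxs = np.asarray(self.maxima_values, dtype=float)
        pos = np.asarray(self.minima_positions, dtype=float)
        if mins.size < 2:
            raise ValidationError("StaircaseSpec: need at least 2 minima (the endpoints)")
        if maxs.size != mins.size - 1:
            raise ValidationError(
                "StaircaseSpec: need exactly len(minima_values) - 1 maxima, got "
                f"{maxs.size} for {mins.size} minima"
            )
        if pos.size != mins.size:
            raise ValidationError("StaircaseSpec: minima_positions must match minima_values")
        if not np.all(np.diff(pos) > 0):
            raise ValidationError("StaircaseSpec: minima_positions must be strictly increasing")
        if self.smoothing_width <= 0:
            raise ValidationError("StaircaseSpec: smoothing_width must be positive")
        for i in range(maxs.size):
            if not (maxs[i] > mins[i] and maxs[i] > mins[i + 1]):
                raise ValidationError(
                    f"StaircaseSpec: maximum {i} ({maxs[i]}) must exceed its flanking "
                    f"minima ({mins[i]}, {mins[i + 1]}) — extrema must alternate"
                )

    @property
    def extrema_positions(self) -> np.ndarray:
        """Interleaved positions: min0, max0, min1, max1, ..., min_last."""
        pos = np.asarray(self.minima_positions, dtype=float)
        mids = 0.5 * (pos[:-1] + pos[1:])
        out = np.empty(pos.size + mids.size)
        out[0::2] = pos
        out[1::2] = mids
        return out

    @property
    def extrema_values_kcal(self) -> np.ndarray:
        mins = np.asarray(self.minima_values, dtype=float)
        maxs = np.asarray(self.maxima_values, dtype=float)
        out = np.empty(mins.size + maxs.size)
        out[0::2] = mins
        out[1::2] = maxs
        return out


def _gaussian_design(centers: np.ndarray, width: float, x: np.ndarray):
    """Value and derivative design matrices for a Gaussian basis."""
    d = x[:, np.newaxis] - centers[np.newaxis, :]
    phi = np.exp(-0.5 * (d / width) ** 2)
    dphi = phi * (-d / width**2)
    return phi, dphi


def build_staircase(spec: StaircaseSpec, k_edge: float | None = None) -> PotentialSystem:
    """Construct a smooth 1D potential hitting the prescribed extrema.

    The landscape is a sum of Gaussians of width ``smoothing_width`` placed at
    the extrema and midway between them, with coefficients solved by least
    squares against value and zero-slope conditions at every extremum, then
    refined by re-locating the realized extrema and correcting the targets.
    One-sided quadratic walls outside the endpoint basins confine sampling.
    Achieved extrema match the specification to well within 1%.
    """
    anchors0 = spec.extrema_positions
    targets = spec.extrema_values_kcal * KJ_PER_KCAL  # internal kJ/mol
    width = float(spec.smoothing_width)
    lo, hi = anchors0[0], anchors0[-1]

    # Basis: Gaussians at every anchor plus three interior points per anchor
    # gap — overcomplete relative to the 2K value/slope conditions, so least
    # squares can interpolate even for the smallest ladders.
    fracs = np.array([0.25, 0.5, 0.75])
    fill = (anchors0[:-1, None] + fracs * np.diff(anchors0)[:, None]).ravel()
    centers = np.sort(np.concatenate([anchors0, fill]))

    anchors = anchors0.copy()
    correction = np.zeros_like(targets)
    coef = None
    scale = max(1.0, np.max(np.abs(targets)))
    grid = np.linspace(lo, hi, 4001)

    for _ in range(12):
        phi_v, _ = _gaussian_design(centers, width, anchors)
        _, dphi = _gaussian_design(centers, width, anchors)
        # Derivative rows scaled by width to balance units against value rows.
        A = np.vstack([phi_v, width * dphi])
        b = np.concatenate([targets + correction, np.zeros_like(anchors)])
        coef, *_ = np.linalg.lstsq(A, b, rcond=None)

        gphi, _ = _gaussian_design(centers, width, grid)
        f = gphi @ coef
        # locate realized extrema: alternating min/max between anchors
        found_pos = np.empty_like(anchors)
        found_val = np.empty_like(anchors)
        ok = True
        for j in range(anchors.size):
            left = lo if j == 0 else 0.5 * (anchors[j - 1] + anchors[j])
            right = hi if j == anchors.size - 1 else 0.5 * (anchors[j] + anchors[j + 1])
            m = (grid >= left) & (grid <= right)
            seg, segx = f[m], grid[m]
            idx = np.argmax(seg) if j % 2 == 1 else np.argmin(seg)
            found_pos[j] = segx[idx]
            found_val[j] = seg[idx]
            if idx == 0 or idx == seg.size - 1:
                ok = False  # extremum escaped its bracket; keep iterating
        err = np.max(np.abs(found_val - targets))
        correction += targets - found_val
        anchors = found_pos
        if ok and err < 1e-9 * scale:
            break

    coef_final = coef
    centers_final = centers

    if k_edge is None:
        k_edge = 20.0 * scale / width**2

    def _core(x1):
        d = x1[..., np.newaxis] - centers_final
        return np.exp(-0.5 * (d / width) ** 2) @ coef_final

    def _core_grad(x1):
        d = x1[..., np.newaxis] - centers_final
        phi = np.exp(-0.5 * (d / width) ** 2)
        return (phi * (-d / width**2)) @ coef_final

    def energy(x):
        x1 = _points(x, 1)[..., 0]
        e = _core(x1)
        e = e + k_edge * np.where(x1 < lo, (x1 - lo) ** 2, 0.0)
        e = e + k_edge * np.where(x1 > hi, (x1 - hi) ** 2, 0.0)
        return e

    def gradient(x):
        x1 = _points(x, 1)[..., 0]
        g = _core_grad(x1)
        g = g + 2.0 * k_edge * np.where(x1 < lo, x1 - lo, 0.0)
        g = g + 2.0 * k_edge * np.where(x1 > hi, x1 - hi, 0.0)
        return g[..., np.newaxis]

    system = PotentialSystem(1, energy, gradient, "staircase")

    # construction guarantee: realized extrema within 1% (of the value scale)
    achieved = _scan_extrema(system, lo, hi, n=8001)
    if achieved.shape[0] != targets.size:
        raise ValidationError(
            f"staircase construction produced {achieved.shape[0]} extrema, "
            f"expected {targets.size}; adjust smoothing_width"
        )
    if np.max(np.abs(achieved[:, 1] - targets)) > 0.01 * scale:
        raise ValidationError("staircase construction missed the extrema by more than 1%")
    return system


def _scan_extrema(system: PotentialSystem, lo: float, hi: float, n: int = 8001) -> np.ndarray:
    """Dense grid scan for interior+endpoint extrema of a 1D system.

    Returns an array of (position, energy) rows, ordered by position,
    treating the domain endpoints as extrema of their basins.
    """
    x = np.linspace(lo, hi, n)
    f = system.energy(x[:, np.newaxis])
    sign = np.sign(np.diff(f))
    # interior sign changes
    idx = [0]
    for i in range(1, n - 1):
        if sign[i - 1] != 0 and sign[i] != 0 and sign[i] != sign[i - 1]:
            idx.append(i)
    idx.append(n - 1)
    # merge boundary points with an interior extremum hugging the boundary
    # (the endpoint basin's minimum may sit a grid step inside the domain)
    if len(idx) > 2 and idx[1] - idx[0] <= 3:
        del idx[0]
    if len(idx) > 2 and idx[-1] - idx[-2] <= 3:
        del idx[-1]
    return np.array([(x[i], f[i]) for i in idx])


# ---------------------------------------------------------------------------
# bead models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BeadModel:
    """A toy 'molecule': n_beads points in 3-space with align/RMS index sets."""

    n_beads: int
    coordinates: np.ndarray
    align_set: tuple = field(default=())
    rms_set: tuple = field(default=())
    seed: int = 0

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.shape != (self.n_beads, 3):
            raise ValidationError(
                f"BeadModel: coordinates shape {coords.shape} != ({self.n_beads}, 3)"
            )
        object.__setattr__(self, "coordinates", coords)
        align = tuple(self.align_set) if self.align_set else tuple(range(self.n_beads))
        rms = tuple(self.rms_set) if self.rms_set else tuple(range(self.n_beads))
        for name, s in (("align_set", align), ("rms_set", rms)):
            if len(s) == 0:
                raise ValidationError(f"BeadModel: {name} must be non-empty")
            if min(s) < 0 or max(s) >= self.n_beads:
                raise ValidationError(f"BeadModel: {name} indices out of range")
        object.__setattr__(self, "align_set", align)
        object.__setattr__(self, "rms_set", rms)


def _skew(w: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, -w[2], w[1]], [w[2], 0.0, -w[0]], [-w[1], w[0], 0.0]]
    )


def _antisym_vec(m: np.ndarray) -> np.ndarray:
    return np.array([m[2, 1] - m[1, 2], m[0, 2] - m[2, 0], m[1, 0] - m[0, 1]])


def bead_model_pair(
    n_beads: int, rotation_angle: float, noise_sigma: float, seed: int
) -> tuple[BeadModel, BeadModel, float]:
    """Generate a bead model and a rotated+translated+perturbed copy.

    The noise field is post-processed (zero mean, symmetric cross-covariance
    with the reference) so that the optimal superposition of the copy onto the
    original is exactly the applied rigid motion, making ``true_rmsd`` — the
    root-mean-square of the stored displacement field — the exact minimum
    attainable RMSD. Deterministic in ``seed``.
    """
    if n_beads < 3:
        raise ValidationError("bead_model_pair: n_beads must be >= 3 (superposition underdetermined)")
    if noise_sigma < 0:
        raise ValidationError("bead_model_pair: noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    a = rng.normal(scale=3.0, size=(n_beads, 3))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    rot = Rotation.from_rotvec(rotation_angle * axis).as_matrix()
    trans = rng.normal(scale=5.0, size=3)

    if noise_sigma > 0:
        delta = rng.normal(scale=noise_sigma, size=(n_beads, 3))
        delta -= delta.mean(axis=0)
        ac = a - a.mean(axis=0)
        s_mat = ac.T @ ac
        a_mat = ac.T @ delta
        # Remove the infinitesimal-rotation component: find omega with
        # antisym(A - S W(omega)) = 0; linear 3x3 solve.
        cols = np.column_stack(
            [_antisym_vec(s_mat @ _skew(e)) for e in np.eye(3)]
        )
        omega = np.linalg.solve(cols, _antisym_vec(a_mat))
        delta = delta + ac @ _skew(omega).T
        delta -= delta.mean(axis=0)
        cross = ac.T @ (ac + delta)
        if np.min(np.linalg.eigvalsh(0.5 * (cross + cross.T))) <= 0:
            raise ValidationError(
                "bead_model_pair: noise too large relative to the bead cloud"
            )
        true_rmsd = float(np.sqrt(np.mean(np.sum(delta**2, axis=-1))))
    else:
        delta = np.zeros_like(a)
        true_rmsd = 0.0

    b = (a + delta) @ rot.T + trans
    model_a = BeadModel(n_beads, a, seed=seed)
    model_b = BeadModel(n_beads, b, seed=seed)
    return model_a, model_b, true_rmsd


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

_REGISTRY: Mapping[str, Callable[..., PotentialSystem]] = {
    "harmonic": _harmonic,
    "double_well_1d": _double_well_1d,
    "double_well_2d": _double_well_2d,
    "mueller_brown": _mueller_brown,
    "staircase": lambda **params: build_staircase(StaircaseSpec(**params)),
}


def registered_potentials() -> Sequence[str]:
    return sorted(_REGISTRY)


def get_potential(name: str, params: Mapping | None = None) -> PotentialSystem:
    """Look up a named analytic potential.

    Raises :class:`RegistryError` for unknown names (listing valid ones) and
    :class:`ValidationError` for malformed parameters.
    """
    if name not in _REGISTRY:
        raise RegistryError(
            f"unknown potential '{name}'; valid names: {', '.join(registered_potentials())}"
        )
    params = dict(params or {})
    try:
        return _REGISTRY[name](**params)
    except TypeError as exc:
        raise ValidationError(f"{name}: invalid parameters: {exc}") from exc
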