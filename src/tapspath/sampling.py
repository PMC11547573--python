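"""Overdamped Langevin dynamics under composable biases.

The sampler integrates the Euler-Maruyama discretization of Brownian dynamics

    x <- x - (dt/friction) * grad(U + V_bias) + sqrt(2 kB T dt / friction) * xi

on an analytic :class:`~tapspath.toy_systems.PotentialSystem`. Biases act
through the path collective variables (s, z) of a reference path and compose
freely in a :class:`BiasStack`:

* well-tempered metadynamics hills on s (heights decay exponentially with the
  accumulated bias, controlled by the bias factor gamma),
* a one-sided harmonic wall on z confining sampling to a tube around the path,
* a harmonic umbrella restraint on s,
* and, separately, targeted MD: a harmonic restraint on the metric distance
  to a target conformation with a time-dependent spring constant.

Everything is bit-reproducible under a fixed seed. An overdamped integrator
is used rather than velocity Verlet plus a thermostat because only the
equilibrium distribution matters for free-energy reconstruction; inertial
dynamics would add thermostat choices without changing any observable
computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB
from .errors import DivergenceError, ValidationError
from .geometry import MetricSpec
from .path_cv import PathDefinition, PCVValue
from .toy_systems import PotentialSystem

__all__ = [
    "LangevinParams",
    "HillRecord",
    "MetadParams",
    "WallParams",
    "TMDSchedule",
    "Trajectory",
    "BiasStack",
    "bias_energy",
    "metad_deposit",
    "run_langevin",
    "targeted_md",
]

_NOISE_BLOCK = 4096


@dataclass(frozen=True)
class LangevinParams:
    """Integrator settings. Times in ps, temperature in K, friction in 1/ps."""

    temperature: float = DEFAULT_TEMPERATURE
    friction: float = 1.0
    timestep: float = 0.01
    n_steps: int = 1000
    seed: int = 0
    record_every: int = 10

    def __post_init__(self):
        if self.temperature < 0:
            raise ValidationError("LangevinParams: temperature must be >= 0")
        if self.friction <= 0 or self.timestep <= 0:
            raise ValidationError("LangevinParams: friction and timestep must be positive")
        if self.n_steps < 1 or self.record_every < 1:
            raise ValidationError("LangevinParams: n_steps and record_every must be >= 1")


@dataclass(frozen=True)
class HillRecord:
    """One deposited metadynamics Gaussian on the s axis."""

    center_s: float
    height: float  # kJ/mol
    width: float  # sigma, s units
    deposit_step: int = 0

    def __post_init__(self):
        if self.height <= 0 or self.width <= 0:
            raise ValidationError("HillRecord: height and width must be positive")


@dataclass(frozen=True)
class MetadParams:
    """Well-tempered metadynamics settings (defaults follow the standard
    2 kJ/mol x 1.0 hills every 5 ps with bias factor 10)."""

    initial_height: float = 2.0  # kJ/mol
    width: float = 1.0  # s units
    bias_factor: float = 10.0
    pace: float = 5.0  # ps

    def __post_init__(self):
        if self.initial_height <= 0 or self.width <= 0:
            raise ValidationError("MetadParams: height and width must be positive")
        if self.bias_factor <= 1:
            raise ValidationError("MetadParams: bias_factor must be > 1")
        if self.pace <= 0:
            raise ValidationError("MetadParams: pace must be positive")


@dataclass(frozen=True)
class WallParams:
    """One-sided harmonic wall on z: k_wall*(z - z_wall)^2 for z > z_wall.

    Defaults follow the reference parameter table: wall position 0.0064
    squared distance units, force constant 2e7 kJ/mol per squared-unit^2
    (an alternative 2e6 appears in some write-ups; both are accepted).
    """

    z_wall: float = 0.0064
    k_wall: float = 2.0e7

    def __post_init__(self):
        if self.z_wall < 0 or self.k_wall < 0:
            raise ValidationError("WallParams: z_wall and k_wall must be >= 0")


@dataclass(frozen=True)
class TMDSchedule:
    """Targeted-MD spring schedule: piecewise-constant k(t), right-continuous.

    ``breakpoints`` are (time_ps, k) pairs with strictly increasing times and
    non-negative, non-decreasing k; k = 0 before the first breakpoint and each
    value holds from its time onward.
    """

    breakpoints: tuple
    target: np.ndarray
    metric: MetricSpec = field(default_factory=MetricSpec)

    def __post_init__(self):
        bps = tuple((float(t), float(k)) for t, k in self.breakpoints)
        if not bps:
            raise ValidationError("TMDSchedule: need at least one breakpoint")
        times = [t for t, _ in bps]
        ks = [k for _, k in bps]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError("TMDSchedule: breakpoint times must be strictly increasing")
        if any(k < 0 for k in ks):
            raise ValidationError("TMDSchedule: spring constants must be >= 0")
        if any(k2 < k1 for k1, k2 in zip(ks, ks[1:])):
            raise ValidationError("TMDSchedule: spring constants must be non-decreasing")
        object.__setattr__(self, "breakpoints", bps)
        object.__setattr__(self, "target", np.asarray(self.target, dtype=float))

    def k_at(self, t: float) -> float:
        k = 0.0
        for bt, bk in self.breakpoints:
            if t >= bt:
                k = bk
            else:
                break
        return k


@dataclass
class Trajectory:
    """Recorded frames, times (ps) and per-frame scalar channels."""

    frames: np.ndarray
    times: np.ndarray
    scalars: dict = field(default_factory=dict)
    info: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def final_frame(self) -> np.ndarray:
        return self.frames[-1]


class BiasStack:
    """Accumulated biases evaluable (with gradients) in the (s, z) plane.

    Holds deposited metadynamics hills, an optional z-wall, an optional
    umbrella restraint on s, and optionally a :class:`MetadParams` enabling
    on-the-fly hill deposition during :func:`run_langevin`. The ``path``
    defines the collective variables; a stack without a path contributes no
    force (useful for plain dynamics).
    """

    def __init__(
        self,
        path: PathDefinition | None = None,
        wall: WallParams | None = None,
        umbrella: tuple[float, float] | None = None,
        metad: MetadParams | None = None,
        hills: list[HillRecord] | None = None,
    ):
        self.path = path
        self.wall = wall
        self.umbrella = umbrella  # (center_s, k_s)
        self.metad = metad
        self.hills: list[HillRecord] = []
        # growable parallel arrays for fast evaluation
        self._cap = 256
        self._c = np.empty(self._cap)
        self._h = np.empty(self._cap)
        self._s2 = np.empty(self._cap)  # 2*sigma^2
        self._n = 0
        for hill in hills or []:
            self.add_hill(hill)

    def add_hill(self, hill: HillRecord) -> None:
        if self._n == self._cap:
            self._cap *= 2
            for name in ("_c", "_h", "_s2"):
                buf = np.empty(self._cap)
                buf[: self._n] = getattr(self, name)[: self._n]
                setattr(self, name, buf)
        self._c[self._n] = hill.center_s
        self._h[self._n] = hill.height
        self._s2[self._n] = 2.0 * hill.width**2
        self._n += 1
        self.hills.append(hill)

    def hills_energy(self, s: float) -> float:
        if self._n == 0:
            return 0.0
        d = s - self._c[: self._n]
        return float(np.sum(self._h[: self._n] * np.exp(-(d**2) / self._s2[: self._n])))

    def energy_sz(self, s: float, z: float) -> tuple[float, float, float]:
        """Bias energy and its partial derivatives w.r.t. s and z."""
        e = 0.0
        de_ds = 0.0
        de_dz = 0.0
        if self._n:
            d = s - self._c[: self._n]
            g = self._h[: self._n] * np.exp(-(d**2) / self._s2[: self._n])
            e += float(np.sum(g))
            de_ds += float(np.sum(g * (-2.0 * d / self._s2[: self._n])))
        if self.wall is not None and z > self.wall.z_wall:
            dz = z - self.wall.z_wall
            e += self.wall.k_wall * dz * dz
            de_dz += 2.0 * self.wall.k_wall * dz
        if self.umbrella is not None:
            s0, k_s = self.umbrella
            e += 0.5 * k_s * (s - s0) ** 2
            de_ds += k_s * (s - s0)
        return e, de_ds, de_dz


def bias_energy(stack: BiasStack, value: PCVValue) -> tuple[float, float, float]:
    """Total bias energy (kJ/mol) and d/ds, d/dz at a PCV value."""
    return stack.energy_sz(value.s, value.z)


def metad_deposit(
    hills, s_now: float, params: MetadParams, temperature: float, deposit_step: int = 0
) -> HillRecord:
    """Well-tempered deposition rule: the new hill's height is damped by the
    bias already accumulated at the current s,

        w = w0 * exp(-V_hills(s_now) / ((gamma - 1) kB T)).
    """
    if params.bias_factor <= 1:
        raise ValidationError("metad_deposit: bias_factor must be > 1")
    if isinstance(hills, BiasStack):
        v_now = hills.hills_energy(s_now)
    else:
        v_now = float(
            sum(h.height * np.exp(-((s_now - h.center_s) ** 2) / (2.0 * h.width**2)) for h in hills)
        )
    height = params.initial_height * np.exp(
        -v_now / ((params.bias_factor - 1.0) * KB * temperature)
    )
    return HillRecord(center_s=float(s_now), height=float(height), width=params.width,
                      deposit_step=deposit_step)


def _check_finite(x: np.ndarray, step: int) -> None:
    if not np.all(np.isfinite(x)):
        raise DivergenceError(
            f"non-finite coordinates at step {step}; reduce the timestep", step=step
        )


def run_langevin(
    system: PotentialSystem,
    biases: BiasStack | None,
    start,
    params: LangevinParams,
) -> Trajectory:
    """Integrate overdamped Langevin dynamics; bit-reproducible under seed.

    Records a frame at step 0 and every ``record_every`` steps (so
    ``floor(n_steps / record_every) + 1`` frames), with per-frame potential
    energy and, when a path is attached, the (s, z) collective variables.
    If ``biases.metad`` is set, hills are deposited on the fly every
    ``pace`` ps and accumulate in the stack.
    """
    x = np.asarray(start, dtype=float).reshape(-1).copy()
    if x.size != system.dimension:
        raise ValidationError(
            f"start has dimension {x.size}, system expects {system.dimension}"
        )
    stack = biases if biases is not None else BiasStack()
    rng = np.random.default_rng(params.seed)
    dt = params.timestep
    mob = dt / params.friction
    noise_scale = np.sqrt(2.0 * KB * params.temperature * dt / params.friction)

    n_rec = params.n_steps // params.record_every + 1
    frames = np.empty((n_rec, x.size))
    times = np.empty(n_rec)
    energies = np.empty(n_rec)
    has_path = stack.path is not None
    s_rec = np.empty(n_rec) if has_path else None
    z_rec = np.empty(n_rec) if has_path else None

    pace_steps = 0
    if stack.metad is not None:
        if not has_path:
            raise ValidationError("metadynamics requires a path on the bias stack")
        pace_steps = max(1, round(stack.metad.pace / dt))

    if has_path:
        if stack.path.metric.kind != "euclidean":
            raise NotImplementedError("biased dynamics require the euclidean metric")
        nodes = stack.path.nodes.reshape(stack.path.n_nodes, -1)
        node_idx = np.arange(1.0, stack.path.n_nodes + 1.0)
        lam = stack.path.lam

    energy_fn = system.energy
    gradient_fn = system.gradient
    noise = None
    rec = 0
    for step in range(params.n_steps + 1):
        if has_path:
            # inline PCV s/z + gradients (hot loop; see path_cv for the math)
            diff = x - nodes
            m = np.einsum("ij,ij->i", diff, diff)
            m_min = m.min()
            w = np.exp(lam * (m_min - m))
            wsum = w.sum()
            s_val = float(node_idx @ w / wsum)
            z_val = float(m_min - np.log(wsum) / lam)
            if pace_steps and step > 0 and step % pace_steps == 0:
                hill = metad_deposit(stack, s_val, stack.metad, params.temperature, step)
                stack.add_hill(hill)
            _, de_ds, de_dz = stack.energy_sz(s_val, z_val)
        if step % params.record_every == 0:
            _check_finite(x, step)
            frames[rec] = x
            times[rec] = step * dt
            energies[rec] = float(energy_fn(x))
            if has_path:
                s_rec[rec] = s_val
                z_rec[rec] = z_val
            rec += 1
        if step == params.n_steps:
            break
        grad = np.asarray(gradient_fn(x), dtype=float)
        if has_path and (de_ds != 0.0 or de_dz != 0.0):
            wn = w / wsum
            dm = 2.0 * diff
            ds_dx = (-lam * ((node_idx - s_val) * wn)) @ dm
            dz_dx = wn @ dm
            grad = grad + de_ds * ds_dx + de_dz * dz_dx
        i = step % _NOISE_BLOCK
        if i == 0:
            noise = rng.standard_normal((_NOISE_BLOCK, x.size))
        x = x - mob * grad + noise_scale * noise[i]
        if not np.all(np.isfinite(x)):
            raise DivergenceError(
                f"non-finite coordinates at step {step + 1}; reduce the timestep",
                step=step + 1,
            )

    scalars = {"energy": energies}
    if has_path:
        scalars["s"] = s_rec
        scalars["z"] = z_rec
    return Trajectory(frames=frames, times=times, scalars=scalars,
                      info={"seed": params.seed, "n_steps": params.n_steps})


def targeted_md(
    start,
    schedule: TMDSchedule,
    system: PotentialSystem,
    params: LangevinParams,
    tolerance: float | None = None,
) -> Trajectory:
    """Langevin dynamics with a time-dependent harmonic pull to a target.

    The restraint V(t) = k(t) * d(x, target)^2 / 2 uses the schedule's metric
    (Euclidean for analytic systems). The per-frame distance to the target is
    recorded; if ``tolerance`` is given and the final distance exceeds it, a
    warning is issued and ``info['tmd_converged']`` is False.
    """
    if schedule.metric.kind != "euclidean":
        raise NotImplementedError("targeted_md forces require the euclidean metric")
    x = np.asarray(start, dtype=float).reshape(-1).copy()
    target = schedule.target.reshape(-1)
    if x.size != system.dimension or target.size != system.dimension:
        raise ValidationError("targeted_md: start/target dimension mismatch with system")
    rng = np.random.default_rng(params.seed)
    dt = params.timestep
    mob = dt / params.friction
    noise_scale = np.sqrt(2.0 * KB * params.temperature * dt / params.friction)

    n_rec = params.n_steps // params.record_every + 1
    frames = np.empty((n_rec, x.size))
    times = np.empty(n_rec)
    energies = np.empty(n_rec)
    dist = np.empty(n_rec)

    noise = None
    rec = 0
    for step in range(params.n_steps + 1):
        if step % params.record_every == 0:
            _check_finite(x, step)
            frames[rec] = x
            times[rec] = step * dt
            energies[rec] = system.energy_at(x)
            dist[rec] = np.linalg.norm(x - target)
            rec += 1
        if step == params.n_steps:
            break
        k = schedule.k_at(step * dt)
        grad = system.gradient_at(x) + k * (x - target)
        i = step % _NOISE_BLOCK
        if i == 0:
            noise = rng.standard_normal((_NOISE_BLOCK, x.size))
        x = x - mob * grad + noise_scale * noise[i]
        if not np.all(np.isfinite(x)):
            raise DivergenceError(
                f"non-finite coordinates at step {step + 1}; the spring jump may be too "
                "stiff for this timestep",
                step=step + 1,
            )

    converged = True
    if tolerance is not None and dist[-1] > tolerance:
        converged = False
        warnings.warn(
            f"targeted MD ended {dist[-1]:.4g} from the target (tolerance {tolerance:g})",
            UserWarning,
            stacklevel=2,
        )
    return Trajectory(
        frames=frames,
        times=times,
        scalars={"energy": energies, "restraint_distance": dist},
        info={"seed": params.seed, "tmd_converged": converged},
    )
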