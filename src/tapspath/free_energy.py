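"""Umbrella sampling along PCV-s, WHAM reconstruction, and profile analytics.

Windows tile the s axis at a fixed insert gap (centers at multiples of the
gap over (0, N], i.e. round(N / gap) windows for an N-node path), each with a
harmonic restraint on s and the shared one-sided z-wall that keeps sampling
inside the path tube. The weighted histogram analysis method (WHAM) recombines
the window histograms into an unbiased free-energy profile F(s), reported in
kcal/mol with F = 0 at the initial state. Profile analytics then identify the
intermediate states (interior minima, IS) and transition states (interior
maxima, TS) and tabulate per-step forward/backward barriers, the endpoint
free-energy difference Delta = F(Fin) - F(Ini), and the total forward barrier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB, kj_to_kcal
from .errors import CoverageWarning, SupportError, ValidationError
from .path_cv import PathDefinition
from .sampling import BiasStack, LangevinParams, WallParams, run_langevin
from .seeding import derive_seed
from .toy_systems import PotentialSystem

__all__ = [
    "UmbrellaWindow",
    "WindowSamples",
    "FEProfile",
    "StationaryPoint",
    "StationaryPointReport",
    "BarrierStats",
    "make_windows",
    "adaptive_windows",
    "merge_window_samples",
    "run_umbrella",
    "wham",
    "locate_states",
    "barrier_table",
]


@dataclass(frozen=True)
class UmbrellaWindow:
    """One restrained window: harmonic k_s/2 (s - center_s)^2 plus the z-wall."""

    center_s: float
    k_s: float = 200.0  # kJ/mol per s-unit^2
    wall: WallParams | None = field(default_factory=WallParams)
    sampling_time: float = 4000.0  # ps
    seed: int = 0

    def __post_init__(self):
        if self.k_s <= 0:
            raise ValidationError("UmbrellaWindow: k_s must be positive")
        if self.sampling_time <= 0:
            raise ValidationError("UmbrellaWindow: sampling_time must be positive")


@dataclass
class WindowSamples:
    """Per-window s (and z, for QC) samples plus window metadata."""

    windows: list
    s_samples: list
    z_samples: list
    wall_violations: list = field(default_factory=list)

    def __post_init__(self):
        if not (len(self.windows) == len(self.s_samples) == len(self.z_samples)):
            raise ValidationError("WindowSamples: lengths must match")
        for i, s in enumerate(self.s_samples):
            if len(s) < 1:
                raise ValidationError(f"WindowSamples: window {i} has no retained samples")


@dataclass
class FEProfile:
    """Free energy versus PCV-s on a grid, kcal/mol, zero at the reference."""

    s_grid: np.ndarray
    f: np.ndarray  # kcal/mol
    bin_width: float
    temperature: float
    reference: str = "ini"

    @property
    def s_norm_grid(self) -> np.ndarray:
        lo, hi = self.s_grid[0], self.s_grid[-1]
        return (self.s_grid - lo) / (hi - lo)


@dataclass(frozen=True)
class StationaryPoint:
    label: str
    s: float
    f: float  # kcal/mol


@dataclass
class StationaryPointReport:
    """Classified minima (Ini, IS1.., Fin) and maxima (TS1..) along s."""

    minima: list
    maxima: list
    smoothing: dict = field(default_factory=dict)

    @property
    def n_is(self) -> int:
        return len(self.minima) - 2

    @property
    def n_ts(self) -> int:
        return len(self.maxima)


@dataclass
class BarrierStats:
    """Delta = F(Fin) - F(Ini); per-step forward/backward barriers; total forward."""

    delta: float
    forward_barriers: np.ndarray
    backward_barriers: np.ndarray
    total_forward: float


# ---------------------------------------------------------------------------
# window construction and sampling
# ---------------------------------------------------------------------------


_DEFAULT_WALL = object()


def make_windows(
    n_nodes: int,
    gap: float,
    k_s: float = 200.0,
    wall=_DEFAULT_WALL,
    sampling_time: float = 4000.0,
    master_seed: int = 0,
) -> list[UmbrellaWindow]:
    """Tile (0, n_nodes] with windows at centers gap, 2*gap, ..., giving
    round(n_nodes / gap) windows; per-window seeds derive deterministically
    from ``master_seed``. ``wall=None`` disables the z-wall (sensible for 1D
    systems, where there is no transverse direction to confine)."""
    if n_nodes < 2:
        raise ValidationError("make_windows: n_nodes must be >= 2")
    if gap <= 0:
        raise ValidationError("make_windows: gap must be positive")
    wall = WallParams() if wall is _DEFAULT_WALL else wall
    count = round(n_nodes / gap)
    if count < 1:
        count = 1
    if gap > n_nodes:
        warnings.warn(
            f"gap {gap} exceeds the s range {n_nodes}; degenerate single window",
            UserWarning,
            stacklevel=2,
        )
    return [
        UmbrellaWindow(
            center_s=gap * i,
            k_s=k_s,
            wall=wall,
            sampling_time=sampling_time,
            seed=derive_seed(master_seed, "umbrella", i),
        )
        for i in range(1, count + 1)
    ]


def _start_at_s(path: PathDefinition, s0: float) -> np.ndarray:
    """Linear interpolation between the flanking nodes (euclidean paths)."""
    n = path.n_nodes
    s0 = min(max(s0, 1.0), float(n))
    i = int(np.floor(s0))
    if i >= n:
        return np.array(path.nodes[-1], dtype=float)
    frac = s0 - i
    if path.metric.kind == "euclidean":
        return (1.0 - frac) * path.nodes[i - 1] + frac * path.nodes[i]
    return np.array(path.nodes[i - 1] if frac < 0.5 else path.nodes[i], dtype=float)


def _overlap_fraction(a: np.ndarray, b: np.ndarray, n_bins: int = 40) -> float:
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi <= lo:
        return 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    ha, _ = np.histogram(a, bins=edges, density=False)
    hb, _ = np.histogram(b, bins=edges, density=False)
    return float(np.minimum(ha / len(a), hb / len(b)).sum())


def _run_windows_batched(
    windows: list[UmbrellaWindow],
    path: PathDefinition,
    system: PotentialSystem,
    params: LangevinParams,
) -> tuple[list, list]:
    """Integrate all equal-length windows as one vectorized batch.

    Each window keeps its own noise stream seeded by its own seed.
    """
    from .constants import KB as _KB
    from .errors import DivergenceError

    n_steps = max(1, round(windows[0].sampling_time / params.timestep))
    n_win = len(windows)
    dim = system.dimension
    nodes = path.nodes.reshape(path.n_nodes, -1)
    node_idx = np.arange(1.0, path.n_nodes + 1.0)
    lam = path.lam
    centers = np.array([w.center_s for w in windows])
    k_s = np.array([w.k_s for w in windows])
    z_wall = np.array([w.wall.z_wall if w.wall else np.inf for w in windows])
    k_wall = np.array([w.wall.k_wall if w.wall else 0.0 for w in windows])

    x = np.stack([_start_at_s(path, c).reshape(-1) for c in centers])
    rngs = [np.random.default_rng(w.seed) for w in windows]
    dt = params.timestep
    mob = dt / params.friction
    noise_scale = np.sqrt(2.0 * _KB * params.temperature * dt / params.friction)
    block = 2048
    noise = None

    n_rec = n_steps // params.record_every + 1
    s_rec = np.empty((n_win, n_rec))
    z_rec = np.empty((n_win, n_rec))
    rec = 0
    for step in range(n_steps + 1):
        diff = x[:, np.newaxis, :] - nodes[np.newaxis, :, :]  # (W, N, d)
        m = np.einsum("wnd,wnd->wn", diff, diff)
        m_min = m.min(axis=1)
        w_arr = np.exp(lam * (m_min[:, None] - m))
        wsum = w_arr.sum(axis=1)
        s_val = (w_arr @ node_idx) / wsum
        z_val = m_min - np.log(wsum) / lam
        if step % params.record_every == 0:
            if not np.all(np.isfinite(x)):
                raise DivergenceError(
                    f"non-finite window coordinates at step {step}", step=step
                )
            s_rec[:, rec] = s_val
            z_rec[:, rec] = z_val
            rec += 1
        if step == n_steps:
            break
        de_ds = k_s * (s_val - centers)
        over = z_val - z_wall
        de_dz = np.where(over > 0.0, 2.0 * k_wall * over, 0.0)
        wn = w_arr / wsum[:, None]
        dm = 2.0 * diff
        ds_dx = np.einsum("wn,wnd->wd", -lam * (node_idx[None, :] - s_val[:, None]) * wn, dm)
        dz_dx = np.einsum("wn,wnd->wd", wn, dm)
        grad = system.gradient(x) + de_ds[:, None] * ds_dx + de_dz[:, None] * dz_dx
        i = step % block
        if i == 0:
            noise = np.stack([r.standard_normal((block, dim)) for r in rngs], axis=0)
        x = x - mob * grad + noise_scale * noise[:, i, :]
    return list(s_rec), list(z_rec)


def adaptive_windows(
    samples: WindowSamples, min_overlap: float = 0.1, master_seed: int = 0
) -> list[UmbrellaWindow]:
    """Extra windows bridging poorly overlapping neighbours.

    For every adjacent pair whose s-histogram overlap falls below
    ``min_overlap``, a new window is proposed midway between the two
    centers, inheriting the stiffer k_s and the wall of the left member.
    Sample these with :func:`run_umbrella` and merge before WHAM.
    """
    extras = []
    for i in range(len(samples.windows) - 1):
        a, b = samples.windows[i], samples.windows[i + 1]
        if _overlap_fraction(samples.s_samples[i], samples.s_samples[i + 1]) < min_overlap:
            extras.append(
                UmbrellaWindow(
                    center_s=0.5 * (a.center_s + b.center_s),
                    k_s=max(a.k_s, b.k_s),
                    wall=a.wall,
                    sampling_time=a.sampling_time,
                    seed=derive_seed(master_seed, "umbrella_adaptive", i),
                )
            )
    return extras


def merge_window_samples(*sample_sets: WindowSamples) -> WindowSamples:
    """Concatenate window sample sets (ordered by window center) for WHAM."""
    windows, s_s, z_s, viol = [], [], [], []
    for ws in sample_sets:
        windows.extend(ws.windows)
        s_s.extend(ws.s_samples)
        z_s.extend(ws.z_samples)
        viol.extend(ws.wall_violations)
    order = np.argsort([w.center_s for w in windows])
    return WindowSamples(
        windows=[windows[i] for i in order],
        s_samples=[s_s[i] for i in order],
        z_samples=[z_s[i] for i in order],
        wall_violations=[viol[i] for i in order],
    )


def run_umbrella(
    windows: list[UmbrellaWindow],
    path: PathDefinition,
    system: PotentialSystem,
    params: LangevinParams,
    burn_in: float = 0.1,
    min_overlap: float = 0.05,
) -> WindowSamples:
    """Sample every window; deterministic under the window seeds.

    ``params`` supplies the integrator settings (temperature, friction,
    timestep, record_every); each window's duration and seed come from the
    window itself. The first ``burn_in`` fraction of frames is discarded.
    Equal-length windows on a Euclidean-metric path are integrated as one
    vectorized batch; every window owns its own seeded noise stream, so
    results are reproducible and statistically identical to sequential
    runs. Poor adjacent-window histogram overlap triggers
    a :class:`CoverageWarning` naming the gap; window starvation is flagged,
    not fatal.
    """
    s_samples, z_samples, violations = [], [], []
    can_batch = (
        path.metric.kind == "euclidean"
        and len({w.sampling_time for w in windows}) == 1
        and len(windows) > 1
    )
    if can_batch:
        s_all, z_all = _run_windows_batched(windows, path, system, params)
        n_frames = len(s_all[0])
        skip = int(burn_in * n_frames)
        s_kept = [s[skip:] for s in s_all]
        z_kept = [z[skip:] for z in z_all]
    else:
        s_kept, z_kept = [], []
        for w in windows:
            wp = LangevinParams(
                temperature=params.temperature,
                friction=params.friction,
                timestep=params.timestep,
                n_steps=max(1, round(w.sampling_time / params.timestep)),
                seed=w.seed,
                record_every=params.record_every,
            )
            stack = BiasStack(path=path, wall=w.wall, umbrella=(w.center_s, w.k_s))
            traj = run_langevin(system, stack, _start_at_s(path, w.center_s), wp)
            skip = int(burn_in * traj.n_frames)
            s_kept.append(traj.scalars["s"][skip:])
            z_kept.append(traj.scalars["z"][skip:])
    for w, s, z in zip(windows, s_kept, z_kept):
        s_samples.append(s)
        z_samples.append(z)
        if w.wall is not None and w.wall.k_wall > 0:
            margin = w.wall.z_wall + 3.0 * np.sqrt(KB * params.temperature / w.wall.k_wall)
            violations.append(float(np.mean(z > margin)))
        else:
            violations.append(0.0)
    for i in range(len(windows) - 1):
        ov = _overlap_fraction(s_samples[i], s_samples[i + 1])
        if ov < min_overlap:
            warnings.warn(
                f"windows {i} (s0={windows[i].center_s:g}) and {i + 1} "
                f"(s0={windows[i + 1].center_s:g}) overlap poorly ({ov:.3f})",
                CoverageWarning,
                stacklevel=2,
            )
    return WindowSamples(
        windows=list(windows), s_samples=s_samples, z_samples=z_samples,
        wall_violations=violations,
    )


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------


def wham(
    samples: WindowSamples,
    temperature: float = DEFAULT_TEMPERATURE,
    n_bins: int = 200,
    tol: float = 1e-8,
    max_iter: int = 100000,
    reference: str = "ini",
    reference_s: float | None = None,
) -> FEProfile:
    """Self-consistent WHAM reconstruction of F(s) from umbrella windows.

    Iterates the standard coupled equations for the unnormalized bin density
    and per-window free-energy offsets until the largest offset change is
    below ``tol`` (in kT). ``reference='ini'`` zeroes F at the bin nearest
    ``reference_s`` (default: the smallest sampled s); ``'min'`` zeroes the
    global minimum. Output in kcal/mol.
    """
    if n_bins < len(samples.windows):
        raise ValidationError("wham: n_bins must be >= the number of windows")
    if reference not in ("ini", "min"):
        raise ValidationError("wham: reference must be 'ini' or 'min'")
    kt_kj = KB * temperature
    all_s = np.concatenate(samples.s_samples)
    lo, hi = float(all_s.min()), float(all_s.max())
    if hi <= lo:
        raise ValidationError("wham: degenerate s range")
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = edges[1] - edges[0]

    n_win = len(samples.windows)
    counts = np.empty((n_win, n_bins))
    totals = np.empty(n_win)
    for j, s in enumerate(samples.s_samples):
        counts[j], _ = np.histogram(s, bins=edges)
        totals[j] = len(s)

    # Support check: a gap of several empty bins is fatal only when it
    # separates two regions that each hold real weight — empty bins in
    # sparsely sampled tails are harmless (they just stay unresolved).
    total_counts = counts.sum(axis=0)
    nz = np.flatnonzero(total_counts > 0)
    min_gap = max(2, n_bins // 50)
    gaps = np.flatnonzero(np.diff(nz) > min_gap)
    grand_total = total_counts.sum()
    for g in gaps:
        left = total_counts[: nz[g] + 1].sum()
        right = total_counts[nz[g + 1]:].sum()
        if min(left, right) > 0.05 * grand_total:
            raise SupportError(
                "wham: histogram support is disconnected over "
                f"s in ({centers[nz[g]]:.4g}, {centers[nz[g + 1]]:.4g}); "
                "add windows bridging this interval"
            )

    bias = np.empty((n_win, n_bins))
    for j, w in enumerate(samples.windows):
        bias[j] = 0.5 * w.k_s * (centers - w.center_s) ** 2
    c = np.exp(-bias / kt_kj)  # (n_win, n_bins)

    f_off = np.zeros(n_win)  # -ln Z_j, in kT units
    rho = np.zeros(n_bins)
    for _ in range(max_iter):
        denom = (totals[:, None] * np.exp(f_off)[:, None] * c).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = np.where(denom > 0, total_counts / denom, 0.0)
        z_j = (c * rho[None, :]).sum(axis=1)
        new_f = -np.log(z_j)
        new_f -= new_f[0]
        change = np.max(np.abs(new_f - f_off))
        f_off = new_f
        if change < tol:
            break

    mask = rho > 0
    f_kt = np.full(n_bins, np.nan)
    f_kt[mask] = -np.log(rho[mask])
    f_kcal = kj_to_kcal(f_kt * kt_kj)

    if reference == "min":
        f_kcal -= np.nanmin(f_kcal)
    else:
        ref_s = reference_s if reference_s is not None else lo
        covered = np.flatnonzero(mask)
        ref_bin = covered[np.argmin(np.abs(centers[covered] - ref_s))]
        f_kcal -= f_kcal[ref_bin]

    return FEProfile(
        s_grid=centers, f=f_kcal, bin_width=float(width), temperature=temperature,
        reference=reference,
    )


# ---------------------------------------------------------------------------
# profile analytics
# ---------------------------------------------------------------------------


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.copy()
    k = int(window) | 1  # odd
    pad = k // 2
    ext = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
    kernel = np.ones(k) / k
    return np.convolve(ext, kernel, mode="valid")


def locate_states(
    profile: FEProfile, smoothing_window: int = 5, min_depth: float = 0.5
) -> StationaryPointReport:
    """Identify intermediate (IS) and transition (TS) states on a profile.

    The profile is smoothed by a moving average, interior extrema are found
    by discrete derivative sign changes, and features shallower than
    ``min_depth`` (kcal/mol) are merged into their neighbours. The two
    endpoints are always reported as the Ini and Fin minima; minima and
    maxima alternate.
    """
    s = profile.s_grid
    y_raw = profile.f
    good = np.isfinite(y_raw)
    s = s[good]
    y = _moving_average(y_raw[good], smoothing_window)
    n = y.size
    if n < 3:
        raise ValidationError("locate_states: profile too short")

    # interior extrema via sign changes of the discrete derivative
    d = np.diff(y)
    sign = np.sign(d)
    # carry the last nonzero sign through flats
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    kinds = []  # (index, +1 max / -1 min)
    for i in range(1, sign.size):
        if sign[i - 1] > 0 and sign[i] < 0:
            kinds.append((i, +1))
        elif sign[i - 1] < 0 and sign[i] > 0:
            kinds.append((i, -1))

    # assemble alternating chain: endpoint, interior extrema, endpoint.
    # endpoints act as the Ini/Fin minima; if the first interior extremum is
    # a minimum the intervening maximum collapsed in smoothing — drop the
    # weaker of the clashing pair to restore alternation.
    chain = [(0, -1)] + kinds + [(n - 1, -1)]
    chain = _enforce_alternation(chain, y)
    chain = _merge_shallow(chain, y, min_depth)

    minima = [c for c in chain if c[1] == -1]
    maxima = [c for c in chain if c[1] == +1]
    n_is = len(minima) - 2
    min_labels = ["Ini"] + [f"IS{i}" for i in range(1, n_is + 1)] + ["Fin"]
    max_labels = [f"TS{i}" for i in range(1, len(maxima) + 1)]
    return StationaryPointReport(
        minima=[
            StationaryPoint(lbl, float(s[i]), float(y[i]))
            for lbl, (i, _) in zip(min_labels, minima)
        ],
        maxima=[
            StationaryPoint(lbl, float(s[i]), float(y[i]))
            for lbl, (i, _) in zip(max_labels, maxima)
        ],
        smoothing={"smoothing_window": smoothing_window, "min_depth": min_depth},
    )


def _enforce_alternation(chain, y):
    """Remove clashing same-kind neighbours, keeping the more extreme one.

    Endpoints (first/last entries) are never removed.
    """
    out = list(chain)
    changed = True
    while changed and len(out) > 2:
        changed = False
        for i in range(len(out) - 1):
            (ia, ka), (ib, kb) = out[i], out[i + 1]
            if ka == kb:
                if ka == -1:  # two minima: keep the lower
                    drop = i if y[ia] > y[ib] else i + 1
                else:  # two maxima: keep the higher
                    drop = i if y[ia] < y[ib] else i + 1
                if drop == 0:
                    drop = 1
                if drop == len(out) - 1:
                    drop = len(out) - 2
                del out[drop]
                changed = True
                break
    return out


def _merge_shallow(chain, y, min_depth):
    """Iteratively delete the shallowest adjacent (min, max) pair below
    ``min_depth``, merging its basin into a neighbour; endpoints survive."""
    out = list(chain)
    while len(out) > 2:
        best = None
        best_amp = min_depth
        for i in range(len(out) - 1):
            if i == 0 and len(out) >= 2 and out[0][1] == out[1][1]:
                continue
            a, b = out[i], out[i + 1]
            if a[1] == b[1]:
                continue
            # never delete a pair containing an endpoint
            if i == 0 or i + 1 == len(out) - 1:
                continue
            amp = abs(y[a[0]] - y[b[0]])
            if amp < best_amp:
                best_amp = amp
                best = i
        if best is None:
            break
        del out[best : best + 2]
        out = _enforce_alternation(out, y)
    return out


def barrier_table(report: StationaryPointReport) -> BarrierStats:
    """Per-step barriers and totals from a classified profile.

    forward_i = F(TS_i) - F(min_{i-1}); backward_i = F(TS_i) - F(min_i);
    delta = F(Fin) - F(Ini); total_forward = sum(forward). The telescoping
    identity delta = sum(forward) - sum(backward) holds exactly.
    """
    mins = report.minima
    maxs = report.maxima
    if len(maxs) != len(mins) - 1:
        raise ValidationError(
            "barrier_table: report must alternate (need len(maxima) == len(minima) - 1)"
        )
    fwd = np.array([maxs[i].f - mins[i].f for i in range(len(maxs))])
    bwd = np.array([maxs[i].f - mins[i + 1].f for i in range(len(maxs))])
    return BarrierStats(
        delta=float(mins[-1].f - mins[0].f),
        forward_barriers=fwd,
        backward_barriers=bwd,
        total_forward=float(fwd.sum()),
    )
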