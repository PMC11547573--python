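"""The TAPS iteration: traveling-salesman-based automated path searching.

Each iteration refines the current path toward the minimum free energy path:

1. *sample*: one well-tempered-metadynamics walker per node, biased along the
   path progress variable s and confined near the path by a one-sided wall on
   z; frames from all walkers are pooled into per-node bins by rounded s;
2. *update*: each interior node is replaced by the medoid of the frames whose
   z lies in a central quantile band around the median z — the band's most
   central member, never a coordinate average, so nodes remain realizable
   configurations;
3. *order*: node order is re-optimized as an open traveling-salesman tour
   with fixed endpoints (exact Held-Karp dynamic programming for small N,
   nearest-neighbor plus 2-opt otherwise);
4. *reparameterize*: extra nodes are inserted wherever adjacent nodes are
   farther apart than a tolerance, by linear interpolation or by a short
   targeted-MD run, and the PCV smoothing parameter lambda is refreshed.

Iterations stop when the mean node displacement stays below a convergence
tolerance for two consecutive iterations. Endpoints are never modified.
Convergence can additionally be inspected with classical multidimensional
scaling (:func:`mds_embed`) and the per-iteration z statistics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .constants import DEFAULT_TEMPERATURE
from .errors import LowSupportWarning, StarvationWarning, ValidationError
from .geometry import MetricSpec, conf_distance
from .path_cv import PathDefinition, PCVValue, suggest_lambda
from .sampling import (
    BiasStack,
    LangevinParams,
    MetadParams,
    TMDSchedule,
    WallParams,
    run_langevin,
    targeted_md,
)
from .seeding import derive_seed
from .toy_systems import PotentialSystem

__all__ = [
    "TapsConfig",
    "NodeSample",
    "TapsResult",
    "OrderResult",
    "MDSResult",
    "sample_node",
    "update_node",
    "order_nodes",
    "reparameterize",
    "run_taps",
    "mds_embed",
    "path_from_trajectory",
]


@dataclass(frozen=True)
class TapsConfig:
    """Settings for one TAPS optimization run.

    ``sampling_time`` is per node (ps); ``gap_tolerance`` is the maximum
    allowed adjacent-node distance after reparameterization (metric units);
    ``median_band`` the central z-quantile fraction used for node updates;
    ``convergence_tol`` defaults to ``gap_tolerance / 4``.
    """

    sampling_time: float = 4000.0
    gap_tolerance: float = 2.0
    median_band: float = 0.2
    max_iterations: int = 20
    convergence_tol: float | None = None
    metad: MetadParams | None = field(default_factory=MetadParams)
    wall: WallParams = field(default_factory=WallParams)
    seed: int = 0
    temperature: float = DEFAULT_TEMPERATURE
    friction: float = 1.0
    timestep: float = 0.01
    record_interval: float | None = None  # ps; defaults to the metadynamics pace
    inserter: str = "linear"
    tmd_time: float = 10.0
    tmd_k: float = 150000.0

    def __post_init__(self):
        if not (0.0 < self.median_band <= 1.0):
            raise ValidationError("TapsConfig: median_band must be in (0, 1]")
        if self.gap_tolerance <= 0:
            raise ValidationError("TapsConfig: gap_tolerance must be positive")
        if self.sampling_time <= 0 or self.timestep <= 0:
            raise ValidationError("TapsConfig: sampling_time and timestep must be positive")
        if self.inserter not in ("linear", "tmd"):
            raise ValidationError("TapsConfig: inserter must be 'linear' or 'tmd'")

    @property
    def effective_convergence_tol(self) -> float:
        return self.convergence_tol if self.convergence_tol is not None else self.gap_tolerance / 4.0

    def langevin(self, seed: int) -> LangevinParams:
        record = self.record_interval if self.record_interval is not None else self.metad.pace
        return LangevinParams(
            temperature=self.temperature,
            friction=self.friction,
            timestep=self.timestep,
            n_steps=max(1, round(self.sampling_time / self.timestep)),
            seed=seed,
            record_every=max(1, round(record / self.timestep)),
        )


@dataclass
class NodeSample:
    """Frames assigned to one node bin, with their PCV values."""

    conformations: np.ndarray  # (M, ...) coordinates
    s: np.ndarray
    z: np.ndarray
    source_node_index: int

    def __post_init__(self):
        if not (len(self.conformations) == len(self.s) == len(self.z)):
            raise ValidationError("NodeSample: conformations and PCV arrays must match")
        if len(self.z) and not np.all(np.isfinite(self.z)):
            raise ValidationError("NodeSample: non-finite z values")

    @property
    def n_frames(self) -> int:
        return int(len(self.conformations))

    @property
    def pcv_values(self) -> list[PCVValue]:
        # s_norm needs the node count, which the bare sample does not carry
        return [
            PCVValue(s=float(si), s_norm=float("nan"), z=float(zi))
            for si, zi in zip(self.s, self.z)
        ]


@dataclass
class TapsResult:
    final_path: PathDefinition
    per_iteration: list
    converged: bool


@dataclass(frozen=True)
class OrderResult:
    permutation: np.ndarray
    tour_length: float
    exact: bool


@dataclass(frozen=True)
class MDSResult:
    coords: np.ndarray
    eigenvalues: np.ndarray
    n_informative: int


# ---------------------------------------------------------------------------
# sampling and node update
# ---------------------------------------------------------------------------


def _walker(path, node_index, system, config, seed):
    """All recorded frames of one metadynamics walker started at a node."""
    stack = BiasStack(path=path, wall=config.wall, metad=config.metad)
    traj = run_langevin(system, stack, path.nodes[node_index - 1], config.langevin(seed))
    frames = traj.frames.reshape((traj.n_frames,) + path.nodes.shape[1:])
    return frames, traj.scalars["s"], traj.scalars["z"]


def _walkers_batched(path, system, config, seeds):
    """One well-tempered metadynamics walker per node, integrated as a
    vectorized batch (Euclidean metric only).

    Each walker carries its own hill history and noise stream; the pooled
    recorded frames with their (s, z) values are returned as arrays of shape
    (n_walkers, n_frames, ...).
    """
    from .constants import KB as _KB
    from .errors import DivergenceError

    lp = config.langevin(0)
    n_steps = lp.n_steps
    n_win = path.n_nodes
    nodes = path.nodes.reshape(n_win, -1)
    dim = nodes.shape[1]
    node_idx = np.arange(1.0, n_win + 1.0)
    lam = path.lam
    metad = config.metad
    wall = config.wall
    if metad is not None:
        pace_steps = max(1, round(metad.pace / lp.timestep))
        n_hills_max = n_steps // pace_steps + 1
        sigma2 = 2.0 * metad.width**2
        damp = (metad.bias_factor - 1.0) * _KB * lp.temperature
    else:
        pace_steps = 0
        n_hills_max = 1
        sigma2 = 1.0
        damp = 1.0

    x = nodes.copy()
    rngs = [np.random.default_rng(s) for s in seeds]
    dt = lp.timestep
    mob = dt / lp.friction
    noise_scale = np.sqrt(2.0 * _KB * lp.temperature * dt / lp.friction)
    block = 2048
    noise = None

    hill_c = np.empty((n_win, n_hills_max))
    hill_h = np.empty((n_win, n_hills_max))
    n_h = 0

    n_rec = n_steps // lp.record_every + 1
    frames = np.empty((n_win, n_rec, dim))
    s_rec = np.empty((n_win, n_rec))
    z_rec = np.empty((n_win, n_rec))
    rec = 0
    for step in range(n_steps + 1):
        diff = x[:, np.newaxis, :] - nodes[np.newaxis, :, :]
        m = np.einsum("wnd,wnd->wn", diff, diff)
        m_min = m.min(axis=1)
        w_arr = np.exp(lam * (m_min[:, None] - m))
        wsum = w_arr.sum(axis=1)
        s_val = (w_arr @ node_idx) / wsum
        z_val = m_min - np.log(wsum) / lam
        if pace_steps and step > 0 and step % pace_steps == 0:
            if n_h:
                d = s_val[:, None] - hill_c[:, :n_h]
                v_now = (hill_h[:, :n_h] * np.exp(-(d**2) / sigma2)).sum(axis=1)
            else:
                v_now = np.zeros(n_win)
            hill_c[:, n_h] = s_val
            hill_h[:, n_h] = metad.initial_height * np.exp(-v_now / damp)
            n_h += 1
        if step % lp.record_every == 0:
            if not np.all(np.isfinite(x)):
                raise DivergenceError(f"non-finite walker coordinates at step {step}", step=step)
            frames[:, rec] = x
            s_rec[:, rec] = s_val
            z_rec[:, rec] = z_val
            rec += 1
        if step == n_steps:
            break
        if n_h:
            d = s_val[:, None] - hill_c[:, :n_h]
            g = hill_h[:, :n_h] * np.exp(-(d**2) / sigma2)
            de_ds = (g * (-2.0 * d / sigma2)).sum(axis=1)
        else:
            de_ds = np.zeros(n_win)
        if wall is not None and wall.k_wall > 0:
            over = z_val - wall.z_wall
            de_dz = np.where(over > 0.0, 2.0 * wall.k_wall * over, 0.0)
        else:
            de_dz = np.zeros(n_win)
        wn = w_arr / wsum[:, None]
        dm = 2.0 * diff
        ds_dx = np.einsum("wn,wnd->wd", -lam * (node_idx[None, :] - s_val[:, None]) * wn, dm)
        dz_dx = np.einsum("wn,wnd->wd", wn, dm)
        grad = system.gradient(x) + de_ds[:, None] * ds_dx + de_dz[:, None] * dz_dx
        i = step % block
        if i == 0:
            noise = np.stack([r.standard_normal((block, dim)) for r in rngs], axis=0)
        x = x - mob * grad + noise_scale * noise[:, i, :]
    return frames, s_rec, z_rec


def sample_node(
    path: PathDefinition,
    node_index: int,
    system: PotentialSystem,
    config: TapsConfig,
    seed: int | None = None,
) -> NodeSample:
    """Metadynamics walker started at node ``node_index`` (1-based).

    Returns the recorded frames whose rounded s equals ``node_index``. If no
    frame lands in the bin a :class:`StarvationWarning` carrying the s
    histogram is issued and the sample is empty.
    """
    n = path.n_nodes
    if not (1 <= node_index <= n):
        raise ValidationError(f"node_index {node_index} outside 1..{n}")
    if seed is None:
        seed = derive_seed(config.seed, "sample_node", node_index)
    frames, s, z = _walker(path, node_index, system, config, seed)
    keep = np.rint(s).astype(int) == node_index
    if not np.any(keep):
        hist, edges = np.histogram(s, bins=np.arange(0.5, n + 1.5))
        warnings.warn(
            f"node {node_index}: no frames with rounded s == {node_index}; "
            f"s histogram over bins 1..{n}: {hist.tolist()}",
            StarvationWarning,
            stacklevel=2,
        )
    return NodeSample(
        conformations=frames[keep], s=s[keep], z=z[keep], source_node_index=node_index
    )


def _pairwise_distances(confs: np.ndarray, metric: MetricSpec) -> np.ndarray:
    if metric.kind == "euclidean":
        flat = confs.reshape(len(confs), -1)
        return squareform(pdist(flat))
    m = len(confs)
    d = np.zeros((m, m))
    for i, j in combinations(range(m), 2):
        d[i, j] = d[j, i] = conf_distance(confs[i], confs[j], metric)
    return d


def update_node(sample: NodeSample, metric: MetricSpec, band: float = 0.2) -> np.ndarray:
    """New node: medoid of the frames whose z lies in the central ``band``
    quantile interval around the median z."""
    if sample.n_frames == 0:
        raise ValidationError("update_node: empty sample")
    if sample.n_frames == 1:
        warnings.warn(
            f"node {sample.source_node_index}: single conformation in bin; returned as-is",
            LowSupportWarning,
            stacklevel=2,
        )
        return np.array(sample.conformations[0])
    z = sample.z
    lo = np.quantile(z, 0.5 - band / 2.0)
    hi = np.quantile(z, 0.5 + band / 2.0)
    sel = np.flatnonzero((z >= lo) & (z <= hi))
    if sel.size == 0:  # numerical corner: fall back to the single median frame
        sel = np.array([int(np.argsort(z)[len(z) // 2])])
    confs = sample.conformations[sel]
    d = _pairwise_distances(confs, metric)
    medoid = int(np.argmin(d.sum(axis=0)))
    return np.array(confs[medoid])


# ---------------------------------------------------------------------------
# node ordering (open-tour TSP)
# ---------------------------------------------------------------------------


def _tour_length(d: np.ndarray, perm) -> float:
    perm = np.asarray(perm)
    return float(d[perm[:-1], perm[1:]].sum())


def _held_karp_fixed(d: np.ndarray) -> np.ndarray:
    """Exact open tour from node 0 to node n-1 visiting all interior nodes."""
    n = d.shape[0]
    interior = list(range(1, n - 1))
    m = len(interior)
    if m == 0:
        return np.array([0, n - 1])
    inf = math.inf
    size = 1 << m
    dp = [[inf] * m for _ in range(size)]
    parent = [[-1] * m for _ in range(size)]
    for j in range(m):
        dp[1 << j][j] = d[0, interior[j]]
    for mask in range(size):
        row = dp[mask]
        for j in range(m):
            cj = row[j]
            if cj == inf or not (mask >> j) & 1:
                continue
            for k in range(m):
                if (mask >> k) & 1:
                    continue
                nm = mask | (1 << k)
                cand = cj + d[interior[j], interior[k]]
                if cand < dp[nm][k]:
                    dp[nm][k] = cand
                    parent[nm][k] = j
    full = size - 1
    best_j = min(range(m), key=lambda j: dp[full][j] + d[interior[j], n - 1])
    order = []
    mask, j = full, best_j
    while j != -1:
        order.append(interior[j])
        pj = parent[mask][j]
        mask ^= 1 << j
        j = pj
    order.reverse()
    return np.array([0] + order + [n - 1])


def _held_karp_free(d: np.ndarray) -> np.ndarray:
    """Exact open tour over all nodes, endpoints free."""
    n = d.shape[0]
    inf = math.inf
    size = 1 << n
    dp = [[inf] * n for _ in range(size)]
    parent = [[-1] * n for _ in range(size)]
    for j in range(n):
        dp[1 << j][j] = 0.0
    for mask in range(size):
        row = dp[mask]
        for j in range(n):
            cj = row[j]
            if cj == inf or not (mask >> j) & 1:
                continue
            for k in range(n):
                if (mask >> k) & 1:
                    continue
                nm = mask | (1 << k)
                cand = cj + d[j, k]
                if cand < dp[nm][k]:
                    dp[nm][k] = cand
                    parent[nm][k] = j
    full = size - 1
    best_j = min(range(n), key=lambda j: dp[full][j])
    order = []
    mask, j = full, best_j
    while j != -1:
        order.append(j)
        pj = parent[mask][j]
        mask ^= 1 << j
        j = pj
    order.reverse()
    return np.array(order)


def _two_opt(d: np.ndarray, perm: np.ndarray, fixed_endpoints: bool) -> np.ndarray:
    perm = perm.copy()
    n = len(perm)
    lo = 1 if fixed_endpoints else 0
    improved = True
    while improved:
        improved = False
        for i in range(lo, n - 1):
            for j in range(i + 1, n if not fixed_endpoints else n - 1):
                # reverse segment [i, j]
                before = 0.0
                after = 0.0
                if i > 0:
                    before += d[perm[i - 1], perm[i]]
                    after += d[perm[i - 1], perm[j]]
                if j < n - 1:
                    before += d[perm[j], perm[j + 1]]
                    after += d[perm[i], perm[j + 1]]
                if after < before - 1e-12:
                    perm[i : j + 1] = perm[i : j + 1][::-1]
                    improved = True
    return perm


def _nearest_neighbor(d: np.ndarray, fixed_endpoints: bool) -> np.ndarray:
    n = d.shape[0]
    start = 0
    visited = [start]
    remaining = set(range(n)) - {start}
    last = n - 1
    if fixed_endpoints:
        remaining.discard(last)
    cur = start
    while remaining:
        nxt = min(remaining, key=lambda k: d[cur, k])
        visited.append(nxt)
        remaining.discard(nxt)
        cur = nxt
    if fixed_endpoints:
        visited.append(last)
    return np.array(visited)


def order_nodes(nodes, metric: MetricSpec | None = None, fixed_endpoints: bool = True) -> OrderResult:
    """Permutation minimizing the open-tour adjacent-distance sum.

    Exact dynamic programming (Held-Karp) for N <= 13; nearest-neighbor
    seeding plus 2-opt otherwise (``exact=False``). The returned tour is never
    longer than the input order.
    """
    metric = metric or MetricSpec()
    nodes = np.asarray(nodes, dtype=float)
    n = nodes.shape[0]
    if n < 2:
        raise ValidationError("order_nodes: need at least 2 nodes")
    d = _pairwise_distances(nodes, metric)
    identity = np.arange(n)
    if n <= 13:
        perm = _held_karp_fixed(d) if fixed_endpoints else _held_karp_free(d)
        exact = True
    else:
        cand = [
            _two_opt(d, _nearest_neighbor(d, fixed_endpoints), fixed_endpoints),
            _two_opt(d, identity.copy(), fixed_endpoints),
        ]
        perm = min(cand, key=lambda p: _tour_length(d, p))
        exact = False
    if _tour_length(d, perm) > _tour_length(d, identity):
        perm = identity  # never worse than the input order
    return OrderResult(permutation=perm, tour_length=_tour_length(d, perm), exact=exact)


# ---------------------------------------------------------------------------
# reparameterization
# ---------------------------------------------------------------------------


def _tmd_insert(
    a: np.ndarray,
    b: np.ndarray,
    n_insert: int,
    system: PotentialSystem,
    config: TapsConfig,
    seed: int,
) -> list[np.ndarray] | None:
    """Frames of a short targeted-MD run a->b nearest the evenly spaced
    distances-to-target; None when the run fails to approach the target."""
    gap = float(np.linalg.norm(np.ravel(b) - np.ravel(a)))
    schedule = TMDSchedule(breakpoints=((0.0, config.tmd_k),), target=np.ravel(b))
    params = LangevinParams(
        temperature=config.temperature,
        friction=config.friction,
        timestep=config.timestep,
        n_steps=max(10, round(config.tmd_time / config.timestep)),
        seed=seed,
        record_every=1,
    )
    traj = targeted_md(np.ravel(a), schedule, system, params)
    dist = traj.scalars["restraint_distance"]
    targets = gap * (1.0 - np.arange(1, n_insert + 1) / (n_insert + 1.0))
    if dist.min() > targets.min():
        return None
    out = []
    for t in targets:
        idx = int(np.argmin(np.abs(dist - t)))
        out.append(traj.frames[idx].reshape(np.shape(a)))
    # the run must actually yield distinct intermediate frames; a too-stiff
    # spring can overshoot so that the nearest frame to a target is an
    # endpoint duplicate — treat that as failure and let the caller fall back
    chain = [np.ravel(a)] + [np.ravel(o) for o in out] + [np.ravel(b)]
    for u, v in zip(chain[:-1], chain[1:]):
        if np.linalg.norm(u - v) <= 1e-9 * max(gap, 1.0):
            return None
    return out


def reparameterize(
    path: PathDefinition,
    tolerance: float,
    inserter: str = "linear",
    system: PotentialSystem | None = None,
    config: TapsConfig | None = None,
    seed: int = 0,
) -> PathDefinition:
    """Insert nodes so every adjacent gap is <= ``tolerance``.

    For a gap d, ceil(d / tolerance) - 1 evenly spaced nodes are inserted.
    The ``tmd`` inserter draws them from a short targeted-MD run between the
    two nodes and falls back to linear interpolation (with a warning) when
    the run does not approach the target; node count never decreases. The
    smoothing parameter lambda is refreshed for the new spacing.
    """
    if tolerance <= 0:
        raise ValidationError("reparameterize: tolerance must be positive")
    if inserter not in ("linear", "tmd"):
        raise ValidationError("reparameterize: inserter must be 'linear' or 'tmd'")
    if inserter == "tmd" and (system is None or config is None):
        raise ValidationError("reparameterize: the tmd inserter needs a system and config")
    nodes = path.nodes
    out = [nodes[0]]
    for i in range(path.n_nodes - 1):
        a, b = nodes[i], nodes[i + 1]
        d = conf_distance(a, b, path.metric)
        n_insert = max(0, math.ceil(d / tolerance) - 1)
        if n_insert:
            inserted = None
            if inserter == "tmd":
                inserted = _tmd_insert(
                    a, b, n_insert, system, config, derive_seed(seed, "tmd_insert", i)
                )
                if inserted is None:
                    warnings.warn(
                        f"tmd inserter failed to approach node {i + 1}; using linear "
                        "interpolation",
                        UserWarning,
                        stacklevel=2,
                    )
            if inserted is None:
                fracs = np.arange(1, n_insert + 1) / (n_insert + 1.0)
                inserted = [a + f * (b - a) for f in fracs]
            out.extend(inserted)
        out.append(b)
    new_nodes = np.asarray(out)
    lam = suggest_lambda(new_nodes, path.metric)
    return PathDefinition(nodes=new_nodes, metric=path.metric, lam=lam)


# ---------------------------------------------------------------------------
# the full iteration
# ---------------------------------------------------------------------------


def run_taps(
    initial_path: PathDefinition, system: PotentialSystem, config: TapsConfig
) -> TapsResult:
    """Iterate sample -> update -> order -> reparameterize to convergence.

    Convergence: mean node displacement (between the pre-update and
    post-update node sets) below ``convergence_tol`` for two consecutive
    iterations. Endpoints are preserved bitwise. Non-convergence within
    ``max_iterations`` returns ``converged=False`` with full diagnostics
    rather than raising.
    """
    path = initial_path
    first = np.array(initial_path.nodes[0])
    last = np.array(initial_path.nodes[-1])
    diagnostics = []
    converged = False
    streak = 0
    tol = config.effective_convergence_tol

    for iteration in range(config.max_iterations):
        n = path.n_nodes
        # one walker per node; pool frames across walkers by rounded s
        seeds = [
            derive_seed(config.seed, "sample", iteration * 100000 + j)
            for j in range(1, n + 1)
        ]
        if path.metric.kind == "euclidean":
            bf, bs, bz = _walkers_batched(path, system, config, seeds)
            shape = (-1,) + path.nodes.shape[1:]
            pool_frames = bf.reshape(shape)
            pool_s = bs.reshape(-1)
            pool_z = bz.reshape(-1)
        else:
            all_frames, all_s, all_z = [], [], []
            for j in range(1, n + 1):
                frames, s, z = _walker(path, j, system, config, seeds[j - 1])
                all_frames.append(frames)
                all_s.append(s)
                all_z.append(z)
            pool_frames = np.concatenate(all_frames)
            pool_s = np.concatenate(all_s)
            pool_z = np.concatenate(all_z)
        bins = np.rint(pool_s).astype(int)

        new_nodes = [first]
        starved = 0
        for j in range(2, n):
            sel = np.flatnonzero(bins == j)
            if sel.size == 0:
                starved += 1
                new_nodes.append(np.array(path.nodes[j - 1]))
                continue
            sample = NodeSample(
                conformations=pool_frames[sel], s=pool_s[sel], z=pool_z[sel],
                source_node_index=j,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", LowSupportWarning)
                new_nodes.append(update_node(sample, path.metric, config.median_band))
        new_nodes.append(last)
        new_nodes = np.asarray(new_nodes)

        disp = np.array(
            [conf_distance(path.nodes[i], new_nodes[i], path.metric) for i in range(n)]
        )
        length_before = sum(
            conf_distance(new_nodes[i], new_nodes[i + 1], path.metric)
            for i in range(len(new_nodes) - 1)
        )
        order = order_nodes(new_nodes, path.metric, fixed_endpoints=True)
        ordered = new_nodes[order.permutation]
        # adjacent bins may elect the same or nearly the same medoid frame;
        # merge nodes closer than half the gap tolerance so the node count
        # stays bounded by the path resolution (reparameterization refills
        # any over-pruned stretch)
        keep = [0]
        for i in range(1, len(ordered) - 1):
            if conf_distance(ordered[keep[-1]], ordered[i], path.metric) > 0.5 * config.gap_tolerance:
                keep.append(i)
        last_i = len(ordered) - 1
        if len(keep) > 1 and conf_distance(ordered[keep[-1]], ordered[last_i], path.metric) < 1e-12:
            keep.pop()
        keep.append(last_i)
        ordered = ordered[keep]
        interim = PathDefinition(ordered, path.metric, path.lam)
        path = reparameterize(
            interim,
            config.gap_tolerance,
            inserter=config.inserter,
            system=system,
            config=config,
            seed=derive_seed(config.seed, "reparam", iteration),
        )
        diagnostics.append(
            {
                "iteration": iteration,
                "mean_displacement": float(disp.mean()),
                "max_displacement": float(disp.max()),
                "max_z": float(pool_z.max()) if pool_z.size else float("nan"),
                "path_length": path.length(),
                "tsp_improvement": float(length_before - order.tour_length),
                "n_nodes": path.n_nodes,
                "starved_bins": starved,
            }
        )
        if disp.mean() < tol:
            streak += 1
            if streak >= 2:
                converged = True
                break
        else:
            streak = 0

    return TapsResult(final_path=path, per_iteration=diagnostics, converged=converged)


# ---------------------------------------------------------------------------
# diagnostics and path construction
# ---------------------------------------------------------------------------


def mds_embed(node_sets, metric: MetricSpec | None = None) -> MDSResult:
    """Classical (Torgerson) multidimensional scaling to 2D.

    Double-centers the squared-distance matrix and takes the top-2
    eigenvectors; exact for sets embeddable in the plane. Rank-deficient
    inputs yield fewer informative axes, reported in ``n_informative``.
    """
    metric = metric or MetricSpec()
    confs = np.asarray(node_sets, dtype=float)
    m = confs.shape[0]
    if m < 3:
        raise ValidationError("mds_embed: need at least 3 conformations")
    d2 = _pairwise_distances(confs, metric) ** 2
    j = np.eye(m) - np.full((m, m), 1.0 / m)
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-12, 1e-9 * max(vals[0], 0.0))
    n_informative = int(np.sum(vals[:2] > tol))
    coords = np.zeros((m, 2))
    for k in range(n_informative):
        coords[:, k] = vecs[:, k] * np.sqrt(vals[k])
    return MDSResult(coords=coords, eigenvalues=vals, n_informative=n_informative)


def path_from_trajectory(
    frames, interval: float = 1.0, metric: MetricSpec | None = None
) -> PathDefinition:
    """Build an initial path by picking trajectory frames at fixed metric
    intervals (default 1.0 distance units), always keeping the first and
    last frames."""
    metric = metric or MetricSpec()
    frames = np.asarray(frames, dtype=float)
    if frames.shape[0] < 2:
        raise ValidationError("path_from_trajectory: need at least 2 frames")
    if interval <= 0:
        raise ValidationError("path_from_trajectory: interval must be positive")
    kept = [0]
    for i in range(1, frames.shape[0]):
        if conf_distance(frames[kept[-1]], frames[i], metric) >= interval:
            kept.append(i)
    if kept[-1] != frames.shape[0] - 1:
        if conf_distance(frames[kept[-1]], frames[-1], metric) > 0:
            kept.append(frames.shape[0] - 1)
    nodes = frames[kept]
    return PathDefinition(nodes=nodes, metric=metric, lam=suggest_lambda(nodes, metric))
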