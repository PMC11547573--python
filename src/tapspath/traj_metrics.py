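"""Trajectory observables: group distances and contacts, RMSF, radius of
gyration, hydrogen-bond counts, and bend angles.

All functions accept frames as an array of shape (n_frames, n_particles, 3)
(a single frame may be (n_particles, 3)); selections are index sequences.
Boundary conventions are inclusive throughout (a pair exactly at the contact
cutoff counts as a contact; a hydrogen-bond geometry exactly at both
thresholds counts as a bond) so results are reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import SelectionError, ShapeError, ValidationError
from .geometry import superpose

__all__ = [
    "SelectionPair",
    "HBondCriteria",
    "min_distance_series",
    "rmsf",
    "radius_of_gyration",
    "hbond_count",
    "bend_angle",
]


@dataclass(frozen=True)
class SelectionPair:
    """Two particle groups whose cross-distance is monitored."""

    group_a: tuple
    group_b: tuple
    label: str = ""

    def __post_init__(self):
        if len(self.group_a) == 0 or len(self.group_b) == 0:
            raise SelectionError("SelectionPair: groups must be non-empty")
        object.__setattr__(self, "group_a", tuple(self.group_a))
        object.__setattr__(self, "group_b", tuple(self.group_b))


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond definition: donor-acceptor distance cutoff
    (Angstrom) and minimum donor-hydrogen-acceptor angle (degrees)."""

    max_donor_acceptor: float = 3.5
    min_angle: float = 150.0

    def __post_init__(self):
        if self.max_donor_acceptor <= 0:
            raise ValidationError("HBondCriteria: distance cutoff must be positive")
        if not (0.0 < self.min_angle <= 180.0):
            raise ValidationError("HBondCriteria: angle must be in (0, 180]")


def _frames_3d(frames) -> np.ndarray:
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[np.newaxis]
    if frames.ndim != 3 or frames.shape[-1] != 3:
        raise ShapeError(f"expected frames of shape (T, n, 3), got {frames.shape}")
    return frames


def min_distance_series(frames, pair: SelectionPair, cutoff: float = 5.0):
    """Per-frame minimum cross-pair distance and the fraction of frames in
    contact (minimum distance <= cutoff, boundary inclusive)."""
    frames = _frames_3d(frames)
    n = frames.shape[1]
    for g in (pair.group_a, pair.group_b):
        if min(g) < 0 or max(g) >= n:
            raise SelectionError("min_distance_series: selection index out of range")
    a = np.asarray(pair.group_a, dtype=int)
    b = np.asarray(pair.group_b, dtype=int)
    out = np.empty(frames.shape[0])
    for t in range(frames.shape[0]):
        out[t] = cdist(frames[t, a], frames[t, b]).min()
    return out, float(np.mean(out <= cutoff))


def rmsf(frames, selection=None, align_set=None) -> np.ndarray:
    """Per-particle root-mean-square fluctuation after superposition.

    Frames are aligned to their mean structure (one refinement pass: align to
    the first frame, average, re-align to the average) so rigid-body motion
    does not inflate the fluctuations; RMSF_i = sqrt(<|x_i - <x_i>|^2>).
    """
    frames = _frames_3d(frames)
    if frames.shape[0] < 2:
        raise ValidationError("rmsf: need at least 2 frames")
    aligned = np.empty_like(frames)
    for t in range(frames.shape[0]):
        aligned[t] = superpose(frames[t], frames[0], align_set).apply(frames[t])
    mean = aligned.mean(axis=0)
    for t in range(frames.shape[0]):
        aligned[t] = superpose(frames[t], mean, align_set).apply(frames[t])
    mean = aligned.mean(axis=0)
    sq = np.mean(np.sum((aligned - mean) ** 2, axis=-1), axis=0)
    out = np.sqrt(sq)
    if selection is not None:
        out = out[np.asarray(selection, dtype=int)]
    return out


def radius_of_gyration(frames, selection=None) -> np.ndarray:
    """Per-frame unweighted radius of gyration of the selection."""
    frames = _frames_3d(frames)
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
        if sel.size == 0:
            raise SelectionError("radius_of_gyration: empty selection")
        frames = frames[:, sel]
    center = frames.mean(axis=1, keepdims=True)
    return np.sqrt(np.mean(np.sum((frames - center) ** 2, axis=-1), axis=-1))


def hbond_count(frame, donors, hydrogens, acceptors, criteria: HBondCriteria | None = None) -> int:
    """Count (donor, hydrogen, acceptor) triples satisfying the geometric
    criterion: d(D, A) <= cutoff and angle(D-H...A) >= min_angle, both
    boundaries inclusive. ``donors`` and ``hydrogens`` are matched lists
    (donor i is bonded to hydrogen i); an acceptor identical to the donor of
    a triple is skipped."""
    criteria = criteria or HBondCriteria()
    coords = np.asarray(frame, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ShapeError(f"hbond_count expects a single frame (n, 3), got {coords.shape}")
    donors = list(donors)
    hydrogens = list(hydrogens)
    if len(donors) != len(hydrogens):
        raise ValidationError("hbond_count: donors and hydrogens must be matched lists")
    count = 0
    cos_min = np.cos(np.deg2rad(criteria.min_angle))
    for d_idx, h_idx in zip(donors, hydrogens):
        d = coords[d_idx]
        h = coords[h_idx]
        for a_idx in acceptors:
            if a_idx == d_idx:
                continue
            a = coords[a_idx]
            # distance <= cutoff, inclusive at the boundary
            if np.linalg.norm(d - a) > criteria.max_donor_acceptor + 1e-12:
                continue
            v1 = d - h
            v2 = a - h
            n1 = np.linalg.norm(v1)
            n2 = np.linalg.norm(v2)
            if n1 == 0.0 or n2 == 0.0:
                continue
            # angle >= min_angle <=> cos(angle) <= cos(min_angle)
            if np.dot(v1, v2) / (n1 * n2) <= cos_min + 1e-12:
                count += 1
    return count


def bend_angle(frames, p1, p2, p3) -> np.ndarray:
    """Per-frame angle (degrees, in [0, 180]) at the centroid of ``p2``
    between the centroids of ``p1`` and ``p3``."""
    frames = _frames_3d(frames)
    sels = [np.asarray(p, dtype=int) for p in (p1, p2, p3)]
    for s in sels:
        if s.size == 0:
            raise SelectionError("bend_angle: empty selection")
    c1 = frames[:, sels[0]].mean(axis=1)
    c2 = frames[:, sels[1]].mean(axis=1)
    c3 = frames[:, sels[2]].mean(axis=1)
    v1 = c1 - c2
    v2 = c3 - c2
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    if np.any(n1 == 0.0) or np.any(n2 == 0.0):
        raise ValidationError("bend_angle: coincident centroids give an undefined angle")
    cosang = np.clip(np.sum(v1 * v2, axis=-1) / (n1 * n2), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))
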