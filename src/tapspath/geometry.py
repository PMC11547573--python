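"""Conformational distance: rigid-body superposition and RMSD.

The molecular metric follows the split atom-set convention used for large
nucleoprotein complexes: an *align set* (typically protein C-alpha and
nucleic-acid phosphorus atoms) defines the optimal rigid superposition, and a
possibly different *RMS set* (e.g. all heavy atoms, or a per-residue key-atom
selection) defines the atoms over which the RMSD is evaluated after
superposition. Analytic benchmark systems use the plain Euclidean metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegeneracyError, ShapeError, ValidationError

__all__ = [
    "MetricSpec",
    "RigidTransform",
    "superpose",
    "conf_distance",
    "conf_sqdist",
    "load_atom_sets",
]


@dataclass(frozen=True)
class MetricSpec:
    """How to measure the distance between two conformations.

    ``euclidean``: flat Euclidean norm of the coordinate difference.
    ``superposed_rmsd``: Kabsch superposition on ``align_set`` followed by
    RMSD over ``rms_set`` (defaults: all particles for both).
    """

    kind: str = "euclidean"
    align_set: tuple | None = None
    rms_set: tuple | None = None
    mass_weighting: bool = False

    def __post_init__(self):
        if self.kind not in ("euclidean", "superposed_rmsd"):
            raise ValidationError(f"MetricSpec: unknown kind '{self.kind}'")
        if self.align_set is not None:
            object.__setattr__(self, "align_set", tuple(self.align_set))
            if self.kind == "superposed_rmsd" and len(self.align_set) < 3:
                raise ValidationError("MetricSpec: align_set must have >= 3 indices")
        if self.rms_set is not None:
            object.__setattr__(self, "rms_set", tuple(self.rms_set))
        if self.mass_weighting:
            raise ValidationError("MetricSpec: mass weighting is not implemented")


@dataclass(frozen=True)
class RigidTransform:
    """y = x @ rotation.T + translation (proper rotation, det = +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(rot_inv, -rot_inv @ self.translation)


def _as_coords(x) -> np.ndarray:
    """Coerce a conformation to (n, 3); flat vectors of length 3n accepted."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        if x.size % 3 != 0:
            raise ShapeError(f"cannot view flat vector of size {x.size} as (n, 3)")
        x = x.reshape(-1, 3)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ShapeError(f"expected (n, 3) coordinates, got shape {x.shape}")
    return x


def superpose(mobile, reference, align_set=None) -> RigidTransform:
    """Kabsch superposition of ``mobile`` onto ``reference`` over ``align_set``.

    Returns the :class:`RigidTransform` minimizing the RMSD of the align-set
    atoms; the rotation is always proper (reflections corrected by flipping
    the smallest singular axis).
    """
    mob = _as_coords(mobile)
    ref = _as_coords(reference)
    if mob.shape != ref.shape:
        raise ShapeError(f"mobile {mob.shape} and reference {ref.shape} differ")
    idx = np.arange(mob.shape[0]) if align_set is None else np.asarray(align_set, dtype=int)
    if idx.size < 3:
        raise ValidationError("superpose: align_set must contain >= 3 points")
    p = mob[idx]
    q = ref[idx]
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    # rank check: collinear (or coincident) align sets are degenerate
    if np.linalg.matrix_rank(pc, tol=1e-10 * max(1.0, np.abs(pc).max())) < 2:
        raise DegeneracyError("superpose: align set is collinear or degenerate")
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = q.mean(axis=0) - rot @ p.mean(axis=0)
    return RigidTransform(rot, trans)


def conf_sqdist(a, b, spec: MetricSpec) -> float:
    """Squared conformational distance (mean-square deviation for RMSD kinds).

    This squared variant is the quantity the path collective variables are
    built on; the z-wall of the free-energy stage is quoted in squared units.
    """
    if spec.kind == "euclidean":
        av = np.asarray(a, dtype=float).ravel()
        bv = np.asarray(b, dtype=float).ravel()
        if av.shape != bv.shape:
            raise ShapeError(f"shape mismatch: {av.shape} vs {bv.shape}")
        return float(np.sum((av - bv) ** 2))
    ac = _as_coords(a)
    bc = _as_coords(b)
    if ac.shape != bc.shape:
        raise ShapeError(f"shape mismatch: {ac.shape} vs {bc.shape}")
    transform = superpose(ac, bc, spec.align_set)
    moved = transform.apply(ac)
    rms_idx = (
        np.arange(ac.shape[0]) if spec.rms_set is None else np.asarray(spec.rms_set, dtype=int)
    )
    diff = moved[rms_idx] - bc[rms_idx]
    return float(np.mean(np.sum(diff**2, axis=-1)))


def conf_distance(a, b, spec: MetricSpec) -> float:
    """Conformational distance under ``spec`` (Euclidean norm or superposed RMSD)."""
    return float(np.sqrt(conf_sqdist(a, b, spec)))


def load_atom_sets(path) -> dict:
    """Read a per-residue align/RMS atom table.

    Whitespace- or tab-separated lines: ``residue  align_atom  rms_atoms``
    where ``rms_atoms`` is comma-separated and ``/`` means none. Lines
    starting with ``#`` are ignored. Returns
    ``{residue: (align_atom, (rms_atom, ...))}``.
    """
    table = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValidationError(f"atom-set table line {lineno}: expected >= 2 columns")
        residue, align_atom = parts[0], parts[1]
        rms_field = parts[2] if len(parts) > 2 else "/"
        rms_atoms = () if rms_field == "/" else tuple(
            a.strip() for a in rms_field.split(",") if a.strip()
        )
        table[residue] = (align_atom, rms_atoms)
    return table
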