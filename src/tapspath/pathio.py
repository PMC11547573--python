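"""Reading and writing paths, trajectories, hills, and profiles.

Analytic paths and trajectories are plain TSV (one row per node/frame);
molecular paths, trajectories, and bead models are multi-model PDB (one MODEL
per node, node order = MODEL order), handled through biotite.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .errors import ValidationError
from .geometry import MetricSpec
from .path_cv import PathDefinition, suggest_lambda
from .sampling import HillRecord, Trajectory
from .free_energy import FEProfile

__all__ = [
    "write_path",
    "read_path",
    "write_hills",
    "read_hills",
    "write_trajectory",
    "read_trajectory",
    "write_profile",
    "read_profile",
    "write_bead_pdb",
]


def _is_pdb(path) -> bool:
    return str(path).lower().endswith(".pdb")


def _coords_to_stack(coords: np.ndarray) -> struc.AtomArrayStack:
    """(M, n, 3) coordinates as a stack of pseudo-atom models."""
    m, n, _ = coords.shape
    stack = struc.AtomArrayStack(m, n)
    stack.coord = np.asarray(coords, dtype=np.float32)
    stack.atom_name = np.array(["CA"] * n)
    stack.res_name = np.array(["GLY"] * n)
    stack.res_id = np.arange(1, n + 1)
    stack.chain_id = np.array(["A"] * n)
    stack.element = np.array(["C"] * n)
    return stack


def write_path(path: PathDefinition, file) -> None:
    """Write a path as TSV (analytic) or multi-model PDB (molecular)."""
    if _is_pdb(file):
        nodes = path.nodes
        if nodes.ndim == 2 and nodes.shape[1] % 3 == 0:
            nodes = nodes.reshape(nodes.shape[0], -1, 3)
        if nodes.ndim != 3 or nodes.shape[-1] != 3:
            raise ValidationError("write_path: PDB output needs (N, n_atoms, 3) nodes")
        pdb = PDBFile()
        pdb.set_structure(_coords_to_stack(nodes))
        pdb.write(str(file))
        return
    flat = path.nodes.reshape(path.n_nodes, -1)
    with open(file, "w") as fh:
        fh.write("# tapspath path\n")
        fh.write(f"# lambda={path.lam!r}\n")
        fh.write(f"# metric={path.metric.kind}\n")
        fh.write("\t".join(f"x{i}" for i in range(flat.shape[1])) + "\n")
        for row in flat:
            fh.write("\t".join(f"{v:.12g}" for v in row) + "\n")


def read_path(file, metric: MetricSpec | None = None) -> PathDefinition:
    """Read a path written by :func:`write_path`.

    TSV files carry lambda and metric kind in header comments; PDB files get
    a superposed-RMSD metric by default and a suggested lambda. MODEL ids out
    of order are accepted (file order wins) with a warning.
    """
    if _is_pdb(file):
        text = Path(file).read_text()
        model_ids = [
            int(line.split()[1]) for line in text.splitlines() if line.startswith("MODEL")
        ]
        if model_ids and model_ids != sorted(model_ids):
            warnings.warn(
                "MODEL ids out of order; nodes ordered by file appearance",
                UserWarning,
                stacklevel=2,
            )
        pdb = PDBFile.read(str(file))
        stack = pdb.get_structure()
        nodes = np.asarray(stack.coord, dtype=float)
        metric = metric or MetricSpec(kind="superposed_rmsd")
        return PathDefinition(nodes=nodes, metric=metric, lam=suggest_lambda(nodes, metric))
    lam = None
    kind = "euclidean"
    rows = []
    header_seen = False
    for lineno, raw in enumerate(Path(file).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("lambda="):
                lam = float(body.split("=", 1)[1])
            elif body.startswith("metric="):
                kind = body.split("=", 1)[1].strip()
            continue
        if not header_seen:
            header_seen = True  # column header row
            continue
        try:
            rows.append([float(v) for v in line.split("\t")])
        except ValueError as exc:
            raise ValidationError(f"read_path: malformed record at line {lineno}") from exc
    if len(rows) < 2:
        raise ValidationError("read_path: fewer than 2 nodes in file")
    nodes = np.asarray(rows, dtype=float)
    metric = metric or MetricSpec(kind=kind)
    if lam is None:
        lam = suggest_lambda(nodes, metric)
    return PathDefinition(nodes=nodes, metric=metric, lam=lam)


def write_hills(hills, file) -> None:
    df = pd.DataFrame(
        {
            "step": [h.deposit_step for h in hills],
            "center_s": [h.center_s for h in hills],
            "height_kJmol": [h.height for h in hills],
            "width": [h.width for h in hills],
        }
    )
    df.to_csv(file, sep="\t", index=False)


def read_hills(file) -> list[HillRecord]:
    df = pd.read_csv(file, sep="\t")
    return [
        HillRecord(
            center_s=float(r.center_s),
            height=float(r.height_kJmol),
            width=float(r.width),
            deposit_step=int(r.step),
        )
        for r in df.itertuples()
    ]


def write_trajectory(traj: Trajectory, file) -> None:
    """Trajectory as TSV: time, coordinates, then any scalar channels."""
    if _is_pdb(file):
        coords = traj.frames
        if coords.ndim == 2 and coords.shape[1] % 3 == 0:
            coords = coords.reshape(coords.shape[0], -1, 3)
        pdb = PDBFile()
        pdb.set_structure(_coords_to_stack(coords))
        pdb.write(str(file))
        return
    flat = traj.frames.reshape(traj.n_frames, -1)
    data = {"time_ps": traj.times}
    for i in range(flat.shape[1]):
        data[f"x{i}"] = flat[:, i]
    for name, series in traj.scalars.items():
        data[name] = series
    pd.DataFrame(data).to_csv(file, sep="\t", index=False)


def read_trajectory(file) -> Trajectory:
    if _is_pdb(file):
        pdb = PDBFile.read(str(file))
        stack = pdb.get_structure()
        coords = np.asarray(stack.coord, dtype=float)
        return Trajectory(frames=coords, times=np.arange(len(coords), dtype=float))
    df = pd.read_csv(file, sep="\t")
    coord_cols = [c for c in df.columns if c.startswith("x") and c[1:].isdigit()]
    coord_cols.sort(key=lambda c: int(c[1:]))
    frames = df[coord_cols].to_numpy(dtype=float)
    scalars = {
        c: df[c].to_numpy(dtype=float)
        for c in df.columns
        if c not in coord_cols and c != "time_ps"
    }
    return Trajectory(frames=frames, times=df["time_ps"].to_numpy(dtype=float), scalars=scalars)


def write_profile(profile: FEProfile, file) -> None:
    pd.DataFrame(
        {
            "s": profile.s_grid,
            "s_norm": profile.s_norm_grid,
            "F_kcal_per_mol": profile.f,
        }
    ).to_csv(file, sep="\t", index=False)


def read_profile(file, temperature: float = 310.0) -> FEProfile:
    df = pd.read_csv(file, sep="\t")
    s = df["s"].to_numpy(dtype=float)
    width = float(s[1] - s[0]) if len(s) > 1 else 1.0
    return FEProfile(
        s_grid=s,
        f=df["F_kcal_per_mol"].to_numpy(dtype=float),
        bin_width=width,
        temperature=temperature,
    )


def write_bead_pdb(model, file) -> None:
    """A bead model as a single-model PDB, bead order = serial order."""
    pdb = PDBFile()
    stack = _coords_to_stack(model.coordinates[np.newaxis])
    pdb.set_structure(stack[0])
    pdb.write(str(file))
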