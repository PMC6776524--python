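"""Trajectory containers, file I/O, re-imaging, superposition and RMSD.

Coordinates are in Å throughout; times in ns.  Only orthorhombic boxes are
supported — the simulation systems this package targets use rectangular
cells (e.g. 190.1 × 190.1 × 177.5 Å³) and triclinic input raises an
explicit error.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pdbio
from .selections import select as _select

# default trajectory output interval in ns used when a file stores no times
DEFAULT_DT_NS = 1.2

_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "K": 39.098, "Cl": 35.45, "Na": 22.990, "Mg": 24.305,
    "Ca": 40.078, "F": 18.998, "X": 12.0,
}


class TrajectoryError(ValueError):
    pass


@dataclass
class Topology:
    """Static description of the system: atoms, molecules, named selections.

    Atom indices are 0-based and contiguous.  ``molecule_ids`` groups atoms
    into molecules (every atom belongs to exactly one); ``named_selections``
    maps labels (e.g. per-ligand labels ``L1``–``L20``) to atom-index arrays.
    """

    names: np.ndarray
    elements: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chains: np.ndarray
    molecule_ids: np.ndarray
    named_selections: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.names = np.asarray(self.names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.chains = np.asarray(self.chains, dtype=object)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        n = len(self.names)
        for arr in (self.elements, self.resids, self.resnames, self.chains,
                    self.molecule_ids):
            if len(arr) != n:
                raise TrajectoryError("topology arrays have inconsistent lengths")
        for label, idx in self.named_selections.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise TrajectoryError(
                    f"named selection {label!r} references non-existent atoms")
            self.named_selections[label] = idx

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def masses(self) -> np.ndarray:
        return np.array([_ELEMENT_MASSES.get(e, 12.0) for e in self.elements])

    def select(self, expr: str) -> np.ndarray:
        """Atom indices matching a selection expression (see selections.py)."""
        return _select(self, expr)

    def molecules(self) -> list[np.ndarray]:
        """Atom-index arrays, one per molecule, in molecule-id order."""
        order = np.argsort(self.molecule_ids, kind="stable")
        ids = self.molecule_ids[order]
        bounds = np.flatnonzero(np.diff(ids)) + 1
        return np.split(order, bounds)

    def residue_groups(self, atom_indices=None) -> dict[tuple, np.ndarray]:
        """Map (chain, resid, resname) → atom indices, optionally restricted."""
        idx = np.arange(self.n_atoms) if atom_indices is None else np.asarray(atom_indices)
        groups: dict[tuple, list] = {}
        for i in idx:
            key = (self.chains[i], int(self.resids[i]), self.resnames[i])
            groups.setdefault(key, []).append(i)
        return {k: np.asarray(v) for k, v in groups.items()}


@dataclass
class Trajectory:
    """Ordered coordinate frames with per-frame box lengths and times.

    ``coords`` has shape (n_frames, n_atoms, 3) in Å, ``box`` (n_frames, 3)
    in Å, ``times`` (n_frames,) in ns and strictly increasing.
    """

    topology: Topology
    coords: np.ndarray
    box: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise TrajectoryError(
                f"frame atom count {self.coords.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}")
        if self.box.shape != (self.n_frames, 3):
            raise TrajectoryError("box must have shape (n_frames, 3)")
        if np.any(self.box <= 0):
            raise TrajectoryError("box lengths must be positive")
        if self.times.shape != (self.n_frames,):
            raise TrajectoryError("times must have shape (n_frames,)")
        if self.n_frames > 1 and np.any(np.diff(self.times) <= 0):
            raise TrajectoryError("time stamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def copy(self) -> "Trajectory":
        return Trajectory(self.topology, self.coords.copy(), self.box.copy(),
                          self.times.copy())


@dataclass
class RmsdSeries:
    time_ns: np.ndarray
    rmsd_A: np.ndarray
    selection: str
    reference_frame: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ns": self.time_ns, "rmsd_A": self.rmsd_A,
            "selection": self.selection, "reference_frame": self.reference_frame,
        })

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# loading

def load_topology(path: str) -> Topology:
    """Read a PDB file into a Topology.

    Molecules are inferred from TER records and chain changes; duplicate
    serial numbers are re-indexed 0..N−1 with a warning (emitted by the
    reader).  Residue ranges, atom names and element classes are available
    through :meth:`Topology.select`.
    """
    raw = pdbio.read_pdb(path)
    n = len(raw.names)
    mol_ids = np.zeros(n, dtype=int)
    ter = set(raw.ter_after)
    current = 0
    for i in range(n):
        if i > 0 and raw.chains[i] != raw.chains[i - 1]:
            current += 1
        mol_ids[i] = current
        if i in ter:
            current += 1
    return Topology(
        names=raw.names, elements=raw.elements, resids=raw.resids,
        resnames=raw.resnames, chains=raw.chains, molecule_ids=mol_ids,
    )


def load_trajectory(path: str, topology: Topology,
                    box=None, dt_ns: float = DEFAULT_DT_NS) -> Trajectory:
    """Read coordinate frames from a multi-model PDB, DCD or XTC file.

    The box is taken from the file when present, else from ``box``
    (a length-3 sequence in Å).  Times default to ``frame_index × dt_ns``
    (binary formats store engine-dependent time units, so the configured
    output interval is authoritative).
    """
    ext = os.path.splitext(path)[1].lower()
    if ext in (".pdb", ".ent"):
        raw = pdbio.read_pdb(path)
        n_file = len(raw.names)
        frames = np.stack(raw.models)
        file_box = raw.box
    elif ext in (".dcd", ".xtc", ".trr"):
        frames, file_box = _read_binary(path)
        n_file = frames.shape[1]
    else:
        raise TrajectoryError(f"unsupported trajectory format {ext!r}")

    if n_file != topology.n_atoms:
        raise TrajectoryError(
            f"atom count mismatch: file {path!r} has {n_file} atoms, "
            f"topology has {topology.n_atoms}")
    n_frames = frames.shape[0]
    if file_box is not None:
        box_arr = np.broadcast_to(np.asarray(file_box, dtype=float),
                                  (n_frames, 3)).copy()
    elif box is not None:
        box_arr = np.broadcast_to(np.asarray(box, dtype=float), (n_frames, 3)).copy()
    else:
        raise TrajectoryError(f"{path}: no box in file and none supplied")
    times = np.arange(n_frames) * dt_ns
    return Trajectory(topology, frames, box_arr, times)


def _read_binary(path: str):
    """Read DCD/XTC/TRR frames via MDAnalysis coordinate readers."""
    import MDAnalysis.coordinates as mdc

    ext = os.path.splitext(path)[1].lower()
    reader_cls = {".dcd": mdc.DCD.DCDReader, ".xtc": mdc.XTC.XTCReader,
                  ".trr": mdc.TRR.TRRReader}[ext]
    frames, box = [], None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reader = reader_cls(path)
        try:
            for i, ts in enumerate(reader):
                try:
                    frames.append(np.array(ts.positions, dtype=float))
                except Exception as exc:  # pragma: no cover - corrupt frame
                    raise TrajectoryError(f"{path}: unreadable frame {i}") from exc
                if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                    if not np.allclose(ts.dimensions[3:6], 90.0, atol=1e-3):
                        raise TrajectoryError(
                            f"{path}: triclinic boxes are unsupported "
                            f"(angles {ts.dimensions[3:6]})")
                    box = tuple(float(v) for v in ts.dimensions[:3])
        finally:
            reader.close()
    return np.stack(frames), box


# ---------------------------------------------------------------------------
# writing

def write_trajectory(traj: Trajectory, path: str) -> None:
    """Write a trajectory as multi-model PDB (.pdb) or via MDAnalysis
    (.dcd/.xtc)."""
    ext = os.path.splitext(path)[1].lower()
    top = traj.topology
    if ext in (".pdb", ".ent"):
        pdbio.write_pdb(path, traj.coords, top.names, top.resnames, top.chains,
                        top.resids, top.elements, top.molecule_ids,
                        box=tuple(traj.box[0]))
        return
    if ext in (".dcd", ".xtc"):
        import MDAnalysis as mda

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe.empty(traj.n_atoms, trajectory=True)
            with mda.Writer(path, n_atoms=traj.n_atoms) as w:
                for f in range(traj.n_frames):
                    u.atoms.positions = traj.coords[f]
                    u.dimensions = [*traj.box[f], 90.0, 90.0, 90.0]
                    u.trajectory.ts.frame = f
                    w.write(u.atoms)
        return
    raise TrajectoryError(f"unsupported output format {ext!r}")


# ---------------------------------------------------------------------------
# re-imaging

def reimage_to_anchor(traj: Trajectory, anchor: str | np.ndarray) -> Trajectory:
    """Translate each molecule by integer box multiples so its centroid lies
    within half a box length of the anchor selection's centroid in x, y, z.

    Intra-molecule geometry is unchanged (whole-molecule shifts only), so
    all intra-molecule pairwise distances are preserved exactly.
    """
    anchor_idx = traj.topology.select(anchor) if isinstance(anchor, str) else np.asarray(anchor)
    if anchor_idx.size == 0:
        raise TrajectoryError("anchor selection is empty")
    out = traj.copy()
    mols = traj.topology.molecules()
    for f in range(traj.n_frames):
        L = traj.box[f]
        anchor_com = out.coords[f, anchor_idx].mean(axis=0)
        for mol in mols:
            com = out.coords[f, mol].mean(axis=0)
            shift = -np.round((com - anchor_com) / L) * L
            if np.any(shift):
                out.coords[f, mol] += shift
    return out


# ---------------------------------------------------------------------------
# superposition and RMSD

def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray):
    """Least-squares rotation (no reflection) and translation mapping
    ``mobile`` onto ``reference`` after centering.  Returns (R, t) with
    x' = x @ R.T + t."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    H = (mobile - mc).T @ (reference - rc)
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    return R, t


def _check_noncollinear(points: np.ndarray) -> None:
    if len(points) < 3:
        raise TrajectoryError("superposition selection needs ≥ 3 atoms")
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise TrajectoryError("superposition selection is collinear/degenerate")


def superpose_frames(traj: Trajectory, reference_frame: int = 0,
                     selection: str | np.ndarray = "all") -> Trajectory:
    """Rigid-body fit every frame onto ``reference_frame`` minimizing the
    least-squares deviation over ``selection``; reflections forbidden."""
    sel = traj.topology.select(selection) if isinstance(selection, str) else np.asarray(selection)
    ref = traj.coords[reference_frame, sel]
    _check_noncollinear(ref)
    out = traj.copy()
    for f in range(traj.n_frames):
        R, t = kabsch_rotation(traj.coords[f, sel], ref)
        out.coords[f] = traj.coords[f] @ R.T + t
    return out


def rmsd_series(traj: Trajectory, reference_frame: int = 0,
                selection: str | np.ndarray = "backbone") -> RmsdSeries:
    """Per-frame best-fit RMSD (Å) over ``selection`` after superposition on
    the same selection."""
    sel = traj.topology.select(selection) if isinstance(selection, str) else np.asarray(selection)
    if sel.size == 0:
        raise TrajectoryError("RMSD selection is empty")
    label = selection if isinstance(selection, str) else f"<{sel.size} atoms>"
    ref = traj.coords[reference_frame, sel]
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        R, t = kabsch_rotation(traj.coords[f, sel], ref)
        moved = traj.coords[f, sel] @ R.T + t
        values[f] = np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))
    return RmsdSeries(traj.times.copy(), values, label, reference_frame)
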