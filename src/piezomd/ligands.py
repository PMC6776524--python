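"""Ligand mobility ranking, binding-site contacts, and membrane-entry
classification.

Stable binders are found by windowed RMSF: for a ligand whose pose is
fixed, the root-mean-square fluctuation of its heavy atoms about their
window-mean positions stays near zero, while a ligand diffusing in the
membrane or solvent shows large values.  Ranking the time-averaged RMSF
over a tail interval orders ligands from most to least stably bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Trajectory

#: default window length in frames (24 ns at a 1.2 ns output interval)
DEFAULT_WINDOW = 20


@dataclass
class LigandRmsfSeries:
    label: str
    window_start_ns: np.ndarray
    rmsf_A: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"window_start_ns": self.window_start_ns,
                             "rmsf_A": self.rmsf_A, "ligand": self.label})


@dataclass
class BindingSiteReport:
    ligand: str
    contact_fractions: dict  # (chain, resid, resname) -> fraction in [0, 1]
    residues_above_threshold: list
    entry_leaflet: str = "none"
    entry_time_ns: float | None = None


@dataclass
class StabilityRanking:
    """Ligand labels ordered by ascending time-averaged RMSF."""

    order: list
    mean_rmsf: dict
    ties: list = field(default_factory=list)


def _heavy(traj: Trajectory, idx: np.ndarray) -> np.ndarray:
    return idx[traj.topology.elements[idx] != "H"]


def ligand_rmsf_timecourse(traj: Trajectory, ligand_selections: dict,
                           window: int = DEFAULT_WINDOW) -> dict:
    """Windowed heavy-atom RMSF per ligand.

    The trajectory must already be superposed on the protein so ligand
    motion is measured in the protein frame.  Windows are non-overlapping
    blocks of ``window`` frames (a trailing partial window is dropped);
    RMSF per window is the square root of the mean — over window frames and
    ligand heavy atoms — of the squared deviation from the window-mean
    atomic positions.
    """
    if window < 2:
        raise ValueError("window must span at least 2 frames")
    n_win = traj.n_frames // window
    if n_win == 0:
        raise ValueError(f"trajectory shorter than one {window}-frame window")
    out = {}
    for label, sel in ligand_selections.items():
        sel = traj.topology.select(sel) if isinstance(sel, str) else np.asarray(sel)
        if sel.size == 0:
            raise ValueError(f"ligand selection {label!r} is empty")
        atoms = _heavy(traj, sel)
        starts = np.empty(n_win)
        rmsf = np.empty(n_win)
        for w in range(n_win):
            block = traj.coords[w * window:(w + 1) * window, atoms]
            dev = block - block.mean(axis=0, keepdims=True)
            rmsf[w] = np.sqrt(np.mean(np.sum(dev**2, axis=2)))
            starts[w] = traj.times[w * window]
        out[label] = LigandRmsfSeries(label, starts, rmsf)
    return out


def rank_ligand_stability(series: dict, tail_fraction: float = 0.5) -> StabilityRanking:
    """Order ligands by ascending mean RMSF over the last ``tail_fraction``
    of windows; exact ties are broken by label order and reported."""
    if not series:
        raise ValueError("no RMSF series supplied")
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must be in (0, 1]")
    means = {}
    for label, s in series.items():
        n = len(s.rmsf_A)
        start = n - max(1, int(round(tail_fraction * n)))
        means[label] = float(np.mean(s.rmsf_A[start:]))
    labels = list(series.keys())
    order = sorted(labels, key=lambda lb: (means[lb], labels.index(lb)))
    ties = [(a, b) for a, b in zip(order, order[1:]) if means[a] == means[b]]
    return StabilityRanking(order, means, ties)


def binding_contacts(traj: Trajectory, ligand, interval: tuple,
                     cutoff: float = 4.0, fraction_threshold: float = 0.5,
                     scope: str = "all") -> BindingSiteReport:
    """Per-residue contact fractions of a ligand over a frame interval.

    A residue is 'in contact' in a frame when any ligand heavy atom lies
    within ``cutoff`` Å of any of its heavy atoms; the fraction is the share
    of interval frames in contact.  Residues at or above
    ``fraction_threshold`` form the reported binding site.
    """
    top = traj.topology
    lig = top.select(ligand) if isinstance(ligand, str) else np.asarray(ligand)
    lig = _heavy(traj, lig)
    if lig.size == 0:
        raise ValueError("ligand selection is empty")
    start, stop = interval
    frames = range(*slice(start, stop).indices(traj.n_frames))
    n_frames = len(frames)
    if n_frames == 0:
        raise ValueError(f"empty analysis interval {interval}")

    scope_idx = top.select(scope) if isinstance(scope, str) else np.asarray(scope)
    scope_idx = _heavy(traj, np.setdiff1d(scope_idx, lig))
    groups = top.residue_groups(scope_idx)
    keys = list(groups)
    counts = dict.fromkeys(keys, 0)
    if cutoff > 0 and scope_idx.size:
        atom_res = {}
        for key, atoms in groups.items():
            for a in atoms:
                atom_res[a] = key
        for f in frames:
            tree = cKDTree(traj.coords[f, lig])
            hit = tree.query_ball_point(traj.coords[f, scope_idx], r=cutoff)
            touched = {atom_res[scope_idx[i]] for i, lst in enumerate(hit) if lst}
            for key in touched:
                counts[key] += 1
    fractions = {k: counts[k] / n_frames for k in keys}
    above = sorted([k for k, v in fractions.items() if v >= fraction_threshold],
                   key=lambda k: (k[0], k[1]))
    label = ligand if isinstance(ligand, str) else f"<{lig.size} atoms>"
    return BindingSiteReport(label, fractions, above)


@dataclass
class EntryClassification:
    leaflet: str  # 'upper' | 'lower' | 'none'
    entry_frame: int | None
    entry_time_ns: float | None


def classify_entry_leaflet(traj: Trajectory, ligand,
                           upper_z: np.ndarray, lower_z: np.ndarray) -> EntryClassification:
    """Side from which a ligand first enters the membrane slab.

    The slab at frame f is [``lower_z[f]``, ``upper_z[f]``] — per-frame mean
    phosphate z of each leaflet.  The first frame at which the ligand COM z
    crosses from bulk solvent into the slab fixes the entry side ('upper' if
    it came from above, 'lower' from below); 'none' if it never enters.  A
    ligand already inside the slab at frame 0 is classified by its nearest
    boundary.
    """
    top = traj.topology
    lig = top.select(ligand) if isinstance(ligand, str) else np.asarray(ligand)
    if lig.size == 0:
        raise ValueError("ligand selection is empty")
    w = top.masses[lig]
    z = (traj.coords[:, lig, 2] * w).sum(axis=1) / w.sum()
    upper_z = np.broadcast_to(np.asarray(upper_z, dtype=float), (traj.n_frames,))
    lower_z = np.broadcast_to(np.asarray(lower_z, dtype=float), (traj.n_frames,))
    inside = (z >= lower_z) & (z <= upper_z)
    if not inside.any():
        return EntryClassification("none", None, None)
    f = int(np.argmax(inside))
    if f == 0:
        side = "upper" if upper_z[0] - z[0] <= z[0] - lower_z[0] else "lower"
    else:
        side = "upper" if z[f - 1] > upper_z[f - 1] else "lower"
    return EntryClassification(side, f, float(traj.times[f]))
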