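"""Principal-component analysis of Cα motion and arm tilt/twist angles.

The leading eigenmodes of the 3N × 3N coordinate covariance capture the
dominant collective motions of the channel arms under membrane stretch —
an outward tilt of the distal arm region and a twist of the distal end.
Tilt and twist are reported as spherical-angle changes of the
proximal→distal arm axis relative to the membrane normal (z), zeroed at a
reference frame; this is a convention of the package (the simplest one
consistent with an outward tilt plus a distal twist), configurable through
the arm definitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Trajectory, kabsch_rotation


@dataclass
class PCAResult:
    mean: np.ndarray          # (n_atoms, 3) mean structure, Å
    eigenvectors: np.ndarray  # (n_modes, 3 n_atoms), orthonormal rows
    eigenvalues: np.ndarray   # (n_modes,), Å², descending
    atom_indices: np.ndarray

    @property
    def variance_fractions(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues


@dataclass
class ModeProjection:
    time_ns: np.ndarray
    projections: np.ndarray  # (n_frames, n_modes), Å of total Cα displacement
    modes: tuple

    def to_frame(self) -> pd.DataFrame:
        data = {"time_ns": self.time_ns}
        for k, m in enumerate(self.modes):
            data[f"pc{m}_A"] = self.projections[:, k]
        return pd.DataFrame(data)


@dataclass
class TiltTwistSeries:
    arm: str
    time_ns: np.ndarray
    tilt_deg: np.ndarray
    twist_deg: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.time_ns, "arm": self.arm,
                             "tilt_deg": self.tilt_deg,
                             "twist_deg": self.twist_deg})


def fit_pca(traj: Trajectory, selection="name CA", interval=None,
            superpose: bool = True) -> PCAResult:
    """Eigendecomposition of the Cα coordinate covariance over an interval.

    Frames are first least-squares superposed on the interval's first frame
    over the same selection.  Eigenvalues are the variances (Å²) along each
    mode; mode k's variance fraction is λ_k/Σλ.  Each eigenvector is
    oriented so that its projection increases over the interval.
    """
    sel = traj.topology.select(selection) if isinstance(selection, str) else np.asarray(selection)
    start, stop = (0, traj.n_frames) if interval is None else interval
    frames = range(*slice(start, stop).indices(traj.n_frames))
    if len(frames) < 3:
        raise ValueError("need at least 3 frames for PCA")

    X = np.empty((len(frames), sel.size * 3))
    ref = traj.coords[frames[0], sel]
    for row, f in enumerate(frames):
        pos = traj.coords[f, sel]
        if superpose:
            R, t = kabsch_rotation(pos, ref)
            pos = pos @ R.T + t
        X[row] = pos.ravel()
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of the centered data matrix: eigenvalues of the covariance are s²/F
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / len(frames)
    keep = eigenvalues > max(eigenvalues[0], 1.0) * 1e-12 if eigenvalues.size else slice(0)
    eigenvalues = eigenvalues[keep]
    vectors = Vt[keep]
    # orient each mode so its projection trends upward over the interval
    proj = Xc @ vectors.T
    flip = proj[-1] - proj[0] < 0
    vectors[flip] *= -1.0
    return PCAResult(mean.reshape(-1, 3), vectors, eigenvalues, sel)


def project_onto_modes(traj: Trajectory, pca: PCAResult,
                       modes=(1, 2), superpose: bool = True) -> ModeProjection:
    """Dot product of (frame − mean) with each eigenvector; 1-based mode
    indices.  Zero projection marks the average structure."""
    modes = tuple(modes)
    for m in modes:
        if not 1 <= m <= len(pca.eigenvalues):
            raise ValueError(f"mode index {m} out of range 1..{len(pca.eigenvalues)}")
    sel = pca.atom_indices
    mean_flat = pca.mean.ravel()
    V = pca.eigenvectors[[m - 1 for m in modes]]
    out = np.empty((traj.n_frames, len(modes)))
    ref = pca.mean
    for f in range(traj.n_frames):
        pos = traj.coords[f, sel]
        if superpose:
            R, t = kabsch_rotation(pos, ref)
            pos = pos @ R.T + t
        out[f] = V @ (pos.ravel() - mean_flat)
    return ModeProjection(traj.times.copy(), out, modes)


def tilt_twist_angles(traj: Trajectory, arms: dict,
                      reference_frame: int = 0) -> dict:
    """Per-arm tilt/twist angle series relative to a reference frame.

    ``arms`` maps an arm label to (proximal selection, distal selection).
    The arm axis is the vector from the proximal to the distal Cα centroid;
    tilt is the change of its polar angle from the membrane normal (z),
    twist the change of its azimuth about z (unwrapped), both in degrees
    and signed; both are zero at the reference frame.
    """
    out = {}
    top = traj.topology
    for label, (prox, dist) in arms.items():
        pi = top.select(prox) if isinstance(prox, str) else np.asarray(prox)
        di = top.select(dist) if isinstance(dist, str) else np.asarray(dist)
        if pi.size == 0 or di.size == 0:
            raise ValueError(f"arm {label!r} has an empty selection")
        axis = traj.coords[:, di].mean(axis=1) - traj.coords[:, pi].mean(axis=1)
        norm = np.linalg.norm(axis, axis=1)
        if np.any(norm < 1e-9):
            raise ValueError(f"arm {label!r} has a zero-length axis")
        theta = np.degrees(np.arccos(np.clip(axis[:, 2] / norm, -1.0, 1.0)))
        phi = np.degrees(np.unwrap(np.arctan2(axis[:, 1], axis[:, 0])))
        tilt = theta - theta[reference_frame]
        twist = phi - phi[reference_frame]
        out[label] = TiltTwistSeries(label, traj.times.copy(), tilt, twist)
    return out
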