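"""Synthetic trajectory and assay generators with known ground truth.

Every analysis stage in this package has a generator here that emulates the
corresponding feature of a mechanosensitive-channel simulation system —
curved bilayer, bound/free ligand ensembles, correlated-motion
communities, tilting arms, charge-biased ions, and functional-assay
readouts — together with the analytic ground truth the analysis should
recover.  All generators are seed-deterministic: the same spec and seed
reproduce the output bit-for-bit on one platform.

Lipids are two-atom (head, tail) pseudo-molecules: enough for leaflet
assignment and headgroup-COM gridding, which is all the curvature math
consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .assays import FluorescenceTrace
from .core import DEFAULT_DT_NS, Topology, Trajectory
from .curvature import LipidConfig, curvature_radius

AVOGADRO = 6.02214076e23

#: the reference simulation box, Å (orthorhombic)
REFERENCE_BOX = (190.1, 190.1, 177.5)


def _topology_from_rows(rows, selections=None) -> Topology:
    names, elements, resids, resnames, chains, mols = zip(*rows)
    return Topology(np.array(names, dtype=object), np.array(elements, dtype=object),
                    np.array(resids), np.array(resnames, dtype=object),
                    np.array(chains, dtype=object), np.array(mols),
                    named_selections=selections or {})


def _times(n: int) -> np.ndarray:
    return np.arange(n) * DEFAULT_DT_NS


# ---------------------------------------------------------------------------
# curved bilayer

@dataclass
class DomeSpec:
    """Curved POPC-like bilayer on a radial Gaussian dome.

    Defaults put the analytic curvature radius at ≈ 8.2 nm, inside the
    8–10 nm regime of the channel dome; ``flatten_to`` ramps the dome depth
    linearly toward that value to emulate flattening under tension.
    """

    seed: int = 0
    box: tuple = (280.0, 280.0, 180.0)
    z0: float = 0.0          # mid-plane plateau height, Å
    zh: float = -30.0        # dome depth (signed), Å
    sigma: float = 70.0      # dome width, Å
    center: tuple = (0.0, 0.0)
    thickness: float = 38.0  # head-to-head bilayer thickness, Å
    tail_offset: float = 8.0 # head-to-tail distance within a lipid, Å
    lipid_spacing: float = 8.0  # lattice spacing → 1 lipid per (8 Å)²
    xy_jitter: float = 0.5   # uniform lateral jitter, Å
    noise_sd: float = 1.0    # Gaussian noise on head z, Å
    n_frames: int = 1
    flatten_to: float | None = None


@dataclass
class DomeGroundTruth:
    zh: np.ndarray        # per-frame dome depth
    sigma: float
    R: np.ndarray         # per-frame analytic curvature radius, Å
    labels: np.ndarray    # per-lipid leaflet label
    config: LipidConfig


def make_dome_membrane(spec: DomeSpec) -> tuple[Trajectory, DomeGroundTruth]:
    """Two leaflets of head/tail pseudo-lipids on a Gaussian dome surface."""
    if spec.lipid_spacing > 10.0:
        raise ValueError("lipid density below 1 per (10 Å)²")
    if spec.thickness / 2.0 - spec.tail_offset <= 3.0 * spec.noise_sd:
        raise ValueError("leaflets would self-intersect: thickness too small "
                         "for the tail offset and noise level")
    rng = np.random.default_rng(spec.seed)
    Lx, Ly = spec.box[0], spec.box[1]
    nx = int(Lx / spec.lipid_spacing)
    ny = int(Ly / spec.lipid_spacing)
    gx = -Lx / 2 + spec.lipid_spacing * (np.arange(nx) + 0.5)
    gy = -Ly / 2 + spec.lipid_spacing * (np.arange(ny) + 0.5)
    XX, YY = np.meshgrid(gx, gy)
    base_xy = np.column_stack([XX.ravel(), YY.ravel()])
    n_per_leaflet = len(base_xy)

    zh_t = (np.linspace(spec.zh, spec.flatten_to, spec.n_frames)
            if spec.flatten_to is not None
            else np.full(spec.n_frames, spec.zh))

    rows, labels = [], []
    mol = 0
    for leaflet in ("upper", "lower"):
        for i in range(n_per_leaflet):
            resid = mol + 1
            rows.append(("PO4", "P", resid, "POP", "M", mol))
            rows.append(("C4A", "C", resid, "POP", "M", mol))
            labels.append(leaflet)
            mol += 1
    top = _topology_from_rows(rows)

    xy = np.concatenate([
        base_xy + rng.uniform(-spec.xy_jitter, spec.xy_jitter, base_xy.shape),
        base_xy + rng.uniform(-spec.xy_jitter, spec.xy_jitter, base_xy.shape),
    ])
    sign = np.repeat([1.0, -1.0], n_per_leaflet)  # upper, lower
    r2 = ((xy[:, 0] - spec.center[0]) ** 2 + (xy[:, 1] - spec.center[1]) ** 2)

    coords = np.empty((spec.n_frames, top.n_atoms, 3))
    for f in range(spec.n_frames):
        surface = spec.z0 + zh_t[f] * np.exp(-r2 / spec.sigma**2)
        head_z = (surface + sign * spec.thickness / 2.0
                  + rng.normal(0.0, spec.noise_sd, len(xy)))
        tail_z = head_z - sign * spec.tail_offset
        coords[f, 0::2, 0] = xy[:, 0]
        coords[f, 0::2, 1] = xy[:, 1]
        coords[f, 0::2, 2] = head_z
        coords[f, 1::2, 0] = xy[:, 0]
        coords[f, 1::2, 1] = xy[:, 1]
        coords[f, 1::2, 2] = tail_z

    traj = Trajectory(top, coords,
                      np.tile(np.asarray(spec.box), (spec.n_frames, 1)),
                      _times(spec.n_frames))
    R = np.array([curvature_radius(z, spec.sigma) for z in zh_t])
    truth = DomeGroundTruth(zh_t, spec.sigma, R,
                            np.array(labels, dtype=object), LipidConfig())
    return traj, truth


# ---------------------------------------------------------------------------
# ligand ensembles

@dataclass
class LigandSpec:
    """Ensemble of mean-reverting (bound) and diffusing (free) ligands.

    Bound ligands follow a discrete first-order mean-reverting process
    around a pocket site with stationary standard deviation ``tether_sd``;
    free ligands random-walk laterally within the membrane slab with step
    standard deviation ``step_sd``.  Optionally one free ligand performs a
    scripted membrane-entry event from ``entry_side`` at ``entry_frame``.
    """

    seed: int = 0
    n_bound: int = 2
    n_free: int = 18
    tether_sd: float = 0.5   # Å, stationary sd of the bound process
    step_sd: float = 3.0     # Å, per-frame step of the free walk
    rho: float = 0.9         # mean-reversion memory per frame
    n_frames: int = 400
    box: tuple = REFERENCE_BOX
    slab_half: float = 19.0  # membrane half-thickness, Å
    atoms_per_ligand: int = 5
    entry_side: str | None = None   # 'upper' | 'lower' | None
    entry_frame: int = 17
    shuffle_labels: bool = True


@dataclass
class LigandGroundTruth:
    bound_labels: list
    free_labels: list
    entry_label: str | None
    entry_side: str | None
    entry_frame: int | None
    pocket_residues: dict    # bound label -> list of (chain, resid, resname)
    upper_z: np.ndarray      # per-frame slab boundaries
    lower_z: np.ndarray


#: residue numbers used for the synthetic binding pockets and decoys
_POCKET_RESIDS = [(1718, 2091, 2094), (1326, 1533, 1972), (1961, 2063, 2100)]


def make_ligand_ensemble(spec: LigandSpec) -> tuple[Trajectory, LigandGroundTruth]:
    if spec.tether_sd >= spec.step_sd:
        raise ValueError("bound tether sd must be below the free step sd")
    rng = np.random.default_rng(spec.seed)
    n_lig = spec.n_bound + spec.n_free
    labels = [f"L{i + 1}" for i in range(n_lig)]
    roles = ["bound"] * spec.n_bound + ["free"] * spec.n_free
    if spec.shuffle_labels:
        rng.shuffle(roles)
    bound_labels = [lb for lb, r in zip(labels, roles) if r == "bound"]
    free_labels = [lb for lb, r in zip(labels, roles) if r == "free"]
    entry_label = free_labels[-1] if (spec.entry_side and free_labels) else None

    Lx, Ly, Lz = spec.box
    # pocket sites inside the slab, well separated laterally
    n_sites = max(spec.n_bound, 1)
    angles = 2 * np.pi * np.arange(n_sites) / n_sites
    sites = np.column_stack([0.3 * Lx * np.cos(angles) / 2,
                             0.3 * Ly * np.sin(angles) / 2,
                             np.full(n_sites, 5.0)])

    rows = []
    selections: dict[str, np.ndarray] = {}
    mol = 0
    pocket_residues: dict[str, list] = {}
    # pocket residues: 3 per bound site at ~3 Å, plus far decoys
    atom_cursor = 0
    for s, lb in enumerate(bound_labels):
        resids = _POCKET_RESIDS[s % len(_POCKET_RESIDS)]
        pocket_residues[lb] = []
        for k, resid in enumerate(resids):
            rows.append(("CB", "C", resid, "ALA", "P", mol))
            pocket_residues[lb].append(("P", resid, "ALA"))
            atom_cursor += 1
        mol += 1
    n_decoys = 6
    for k in range(n_decoys):
        rows.append(("CB", "C", 100 + k, "ALA", "P", mol))
        atom_cursor += 1
    mol += 1

    lig_atom_start = {}
    offsets = {}
    for lb in labels:
        lig_atom_start[lb] = atom_cursor
        for a in range(spec.atoms_per_ligand):
            rows.append((f"C{a + 1}", "C", 0, "YOD", "L", mol))
            atom_cursor += 1
        selections[lb] = np.arange(lig_atom_start[lb],
                                   lig_atom_start[lb] + spec.atoms_per_ligand)
        mol += 1
        offsets[lb] = rng.normal(0.0, 1.0, (spec.atoms_per_ligand, 3))
        offsets[lb] -= offsets[lb].mean(axis=0)
    # fix ligand resids to their label number for readability
    rows = [(n, e, (int(lab[1:]) if rn == "YOD" else rid), rn, ch, m)
            for (n, e, rid, rn, ch, m), lab in zip(
                rows, _expand_labels(rows, labels, spec.atoms_per_ligand))]
    top = _topology_from_rows(rows, selections)

    # static protein scaffold: residue positions around their site
    protein_pos = []
    for s in range(len(bound_labels)):
        for k in range(3):
            ang = 2 * np.pi * k / 3
            protein_pos.append(sites[s] + 3.0 * np.array([np.cos(ang), np.sin(ang), 0.3]))
    for k in range(n_decoys):
        protein_pos.append(np.array([0.45 * Lx, 0.45 * Ly, 40.0 + 3.0 * k]))
    protein_pos = np.array(protein_pos) if protein_pos else np.empty((0, 3))

    coords = np.empty((spec.n_frames, top.n_atoms, 3))
    coords[:, :len(protein_pos)] = protein_pos[None]

    site_iter = iter(sites)
    sd_innov = spec.tether_sd * math.sqrt(1.0 - spec.rho**2)
    for lb in labels:
        sel = selections[lb]
        if lb in bound_labels:
            mu = next(site_iter)
            com = np.empty((spec.n_frames, 3))
            com[0] = mu + rng.normal(0.0, spec.tether_sd, 3)
            for t in range(1, spec.n_frames):
                com[t] = mu + spec.rho * (com[t - 1] - mu) + rng.normal(0.0, sd_innov, 3)
        elif lb == entry_label:
            com = _scripted_entry(spec, rng)
        else:
            com = _free_walk(spec, rng)
        coords[:, sel] = com[:, None, :] + offsets[lb][None]

    traj = Trajectory(top, coords,
                      np.tile(np.asarray(spec.box), (spec.n_frames, 1)),
                      _times(spec.n_frames))
    truth = LigandGroundTruth(
        bound_labels, free_labels, entry_label, spec.entry_side,
        spec.entry_frame if entry_label else None, pocket_residues,
        np.full(spec.n_frames, spec.slab_half),
        np.full(spec.n_frames, -spec.slab_half))
    return traj, truth


def _expand_labels(rows, labels, atoms_per_ligand):
    """Per-row ligand label (or None) aligned with ``rows``."""
    out = []
    lig_rows = iter([lb for lb in labels for _ in range(atoms_per_ligand)])
    for row in rows:
        out.append(next(lig_rows) if row[3] == "YOD" else "L0")
    return out


def _free_walk(spec: LigandSpec, rng) -> np.ndarray:
    Lx, Ly, _ = spec.box
    zmax = 0.9 * spec.slab_half
    com = np.empty((spec.n_frames, 3))
    com[0] = [rng.uniform(-Lx / 2, Lx / 2), rng.uniform(-Ly / 2, Ly / 2),
              rng.uniform(-zmax, zmax)]
    steps = rng.normal(0.0, spec.step_sd, (spec.n_frames - 1, 3))
    for t in range(1, spec.n_frames):
        com[t] = com[t - 1] + steps[t - 1]
        com[t, 0] = (com[t, 0] + Lx / 2) % Lx - Lx / 2
        com[t, 1] = (com[t, 1] + Ly / 2) % Ly - Ly / 2
        # reflect z inside the slab
        z = com[t, 2]
        while not -zmax <= z <= zmax:
            z = np.clip(2 * (zmax if z > zmax else -zmax) - z, -3 * zmax, 3 * zmax)
        com[t, 2] = z
    return com


def _scripted_entry(spec: LigandSpec, rng) -> np.ndarray:
    """Approach from outside the slab, crossing the boundary exactly at
    ``entry_frame``, then a free walk inside."""
    sgn = 1.0 if spec.entry_side == "upper" else -1.0
    boundary = sgn * spec.slab_half
    start_z = boundary + sgn * 15.0
    com = np.empty((spec.n_frames, 3))
    x0 = rng.uniform(-spec.box[0] / 4, spec.box[0] / 4)
    y0 = rng.uniform(-spec.box[1] / 4, spec.box[1] / 4)
    ef = min(spec.entry_frame, spec.n_frames - 1)
    for t in range(ef + 1):
        frac = t / ef if ef else 1.0
        com[t] = [x0, y0, start_z + frac * (boundary - sgn * 0.5 - start_z)]
    inner = _free_walk(spec, rng)
    if ef + 1 < spec.n_frames:
        delta = com[ef] - inner[ef]
        com[ef + 1:] = inner[ef + 1:] + delta
        com[ef + 1:, 2] = np.clip(inner[ef + 1:, 2], -0.9 * spec.slab_half,
                                  0.9 * spec.slab_half)
    return com


# ---------------------------------------------------------------------------
# correlated-motion communities

@dataclass
class CommunitySpec:
    """Cα chains with planted correlated-motion communities.

    Residues of one community share a latent 3-D displacement of amplitude
    ``intra_amp``; an optional global component of amplitude
    ``inter_coupling`` correlates everything; independent noise of sd
    ``noise`` is added on top.  The emitted contact mask connects chain
    neighbors within each community plus the configured bridges.
    """

    seed: int = 0
    sizes: tuple = (10, 10, 10)
    intra_amp: float = 3.0
    inter_coupling: float = 0.0
    noise: float = 0.5
    n_frames: int = 300
    bridges: tuple = ((0, 1), (1, 2))
    cluster_sep: float = 30.0
    #: chain separation up to which residues of one community are in
    #: contact; None → all pairs (a compact helical bundle)
    neighbor_range: int | None = None


@dataclass
class CommunityGroundTruth:
    partition: list          # list of node-index sets
    mask: np.ndarray
    nodes: list


def make_community_trajectory(spec: CommunitySpec) -> tuple[Trajectory, np.ndarray, CommunityGroundTruth]:
    if spec.intra_amp <= spec.noise:
        raise ValueError("intra-community amplitude must exceed the noise level")
    rng = np.random.default_rng(spec.seed)
    n = sum(spec.sizes)
    comm_of = np.concatenate([np.full(s, k) for k, s in enumerate(spec.sizes)])
    bounds = np.cumsum((0,) + tuple(spec.sizes))

    rows = []
    base = np.empty((n, 3))
    chains = "ABCDEFGH"
    node = 0
    for k, size in enumerate(spec.sizes):
        center = np.array([spec.cluster_sep * k, 0.0, 0.0])
        for j in range(size):
            rows.append(("CA", "C", node + 1, "ALA", chains[k % len(chains)], k))
            base[node] = center + np.array([4.0 * j - 2.0 * size, 0.0, 0.0])
            node += 1
    top = _topology_from_rows(rows)

    mask = np.zeros((n, n), dtype=bool)
    for k, size in enumerate(spec.sizes):
        reach = size if spec.neighbor_range is None else spec.neighbor_range
        for i in range(bounds[k], bounds[k + 1]):
            for j in range(i + 1, min(i + reach + 1, bounds[k + 1])):
                mask[i, j] = mask[j, i] = True
    for a, b in spec.bridges:
        i, j = bounds[a + 1] - 1, bounds[b]
        mask[i, j] = mask[j, i] = True

    latents = rng.normal(0.0, 1.0, (spec.n_frames, len(spec.sizes), 3))
    shared = rng.normal(0.0, 1.0, (spec.n_frames, 3))
    noise = rng.normal(0.0, spec.noise, (spec.n_frames, n, 3))
    coords = (base[None] + spec.intra_amp * latents[:, comm_of]
              + spec.inter_coupling * shared[:, None] + noise)

    box = (spec.cluster_sep * (len(spec.sizes) + 2),) * 3
    traj = Trajectory(top, coords, np.tile(box, (spec.n_frames, 1)),
                      _times(spec.n_frames))
    partition = [set(range(bounds[k], bounds[k + 1]))
                 for k in range(len(spec.sizes))]
    truth = CommunityGroundTruth(partition, mask, list(range(n)))
    return traj, mask, truth


# ---------------------------------------------------------------------------
# rigid tilting arms

@dataclass
class ArmSchedule:
    label: str
    tilt_deg: object = 30.0    # scalar max (linear ramp) or per-frame array
    twist_deg: object = 0.0


@dataclass
class ArmSpec:
    """Rigid rod arms rotating about a hinge per a tilt/twist schedule."""

    seed: int = 0
    arms: tuple = (ArmSchedule("A", 80.0), ArmSchedule("B", 65.0),
                   ArmSchedule("C", 68.0))
    n_frames: int = 100
    n_atoms: int = 8
    length: float = 40.0
    theta0: float = 30.0     # initial polar angle from z, degrees
    hinge_radius: float = 10.0
    noise: float = 0.0
    box: tuple = (200.0, 200.0, 200.0)


@dataclass
class ArmGroundTruth:
    tilt_deg: dict   # label -> per-frame array
    twist_deg: dict
    arms: dict       # label -> (proximal selection name, distal selection name)


def _schedule(value, n_frames) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.linspace(0.0, float(arr), n_frames)
    if arr.shape != (n_frames,):
        raise ValueError("schedule array length must equal n_frames")
    return arr


def make_arm_tilt_trajectory(spec: ArmSpec) -> tuple[Trajectory, ArmGroundTruth]:
    if spec.n_atoms < 5:
        raise ValueError("arms need at least 5 pseudo-atoms")
    rng = np.random.default_rng(spec.seed)
    rows, selections = [], {}
    n_arms = len(spec.arms)
    atom = 0
    for k, arm in enumerate(spec.arms):
        for j in range(spec.n_atoms):
            rows.append(("CA", "C", j + 1, "ALA", arm.label[:1], k))
        selections[f"{arm.label}_proximal"] = np.arange(atom, atom + 2)
        selections[f"{arm.label}_distal"] = np.arange(atom + spec.n_atoms - 2,
                                                      atom + spec.n_atoms)
        atom += spec.n_atoms
    top = _topology_from_rows(rows, selections)

    tilt_truth, twist_truth, arm_sel = {}, {}, {}
    coords = np.empty((spec.n_frames, top.n_atoms, 3))
    s = 5.0 + spec.length * np.arange(spec.n_atoms) / (spec.n_atoms - 1)
    for k, arm in enumerate(spec.arms):
        phi0 = 2 * np.pi * k / n_arms
        hinge = spec.hinge_radius * np.array([np.cos(phi0), np.sin(phi0), 0.0])
        tilt = _schedule(arm.tilt_deg, spec.n_frames)
        twist = _schedule(arm.twist_deg, spec.n_frames)
        theta = np.radians(spec.theta0 + tilt)
        phi = phi0 + np.radians(twist)
        u = np.column_stack([np.sin(theta) * np.cos(phi),
                             np.sin(theta) * np.sin(phi),
                             np.cos(theta)])
        block = hinge[None, None] + s[None, :, None] * u[:, None, :]
        if spec.noise > 0:
            block = block + rng.normal(0.0, spec.noise, block.shape)
        coords[:, k * spec.n_atoms:(k + 1) * spec.n_atoms] = block
        tilt_truth[arm.label] = tilt
        twist_truth[arm.label] = twist
        arm_sel[arm.label] = (f"{arm.label}_proximal", f"{arm.label}_distal")

    traj = Trajectory(top, coords, np.tile(spec.box, (spec.n_frames, 1)),
                      _times(spec.n_frames))
    return traj, ArmGroundTruth(tilt_truth, twist_truth, arm_sel)


# ---------------------------------------------------------------------------
# charge-biased ion box

@dataclass
class IonSpec:
    """Ions biased toward fixed negative charge sites.

    Cation positions are drawn with density enhanced by a factor exp(beta)
    within ``site_radius`` of any charge site (rejection sampling); anions
    carry the reciprocal suppression exp(−beta); uniform elsewhere."""

    seed: int = 0
    box: tuple = (60.0, 60.0, 60.0)
    sites: tuple = ((30.0, 30.0, 30.0), (30.0, 34.0, 30.0), (34.0, 30.0, 30.0))
    beta: float = 2.0
    n_cations: int = 40
    n_anions: int = 40
    n_frames: int = 50
    site_radius: float = 5.0


def make_ion_box(spec: IonSpec) -> Trajectory:
    if spec.n_cations < 0 or spec.n_anions < 0:
        raise ValueError("ion counts must be nonnegative")
    rng = np.random.default_rng(spec.seed)
    sites = np.asarray(spec.sites, dtype=float)
    box = np.asarray(spec.box, dtype=float)

    rows = []
    mol = 0
    for k in range(len(sites)):
        rows.append(("OE1", "O", 2487 + k, "GLU", "P", mol))
        mol += 1
    for k in range(spec.n_cations):
        rows.append(("K", "K", k + 1, "K", "I", mol))
        mol += 1
    for k in range(spec.n_anions):
        rows.append(("CL", "Cl", k + 1, "CL", "J", mol))
        mol += 1
    top = _topology_from_rows(rows)

    def draw(n, accept_near, accept_far):
        out = np.empty((n, 3))
        filled = 0
        while filled < n:
            cand = rng.uniform(0.0, 1.0, (4 * n, 3)) * box
            d = np.min(np.linalg.norm(cand[:, None] - sites[None], axis=2), axis=1)
            near = d < spec.site_radius
            pacc = np.where(near, accept_near, accept_far)
            keep = cand[rng.uniform(size=len(cand)) < pacc]
            take = min(n - filled, len(keep))
            out[filled:filled + take] = keep[:take]
            filled += take
        return out

    coords = np.empty((spec.n_frames, top.n_atoms, 3))
    coords[:, :len(sites)] = sites[None]
    e = math.exp(-spec.beta)
    for f in range(spec.n_frames):
        coords[f, len(sites):len(sites) + spec.n_cations] = draw(
            spec.n_cations, 1.0, e)
        coords[f, len(sites) + spec.n_cations:] = draw(spec.n_anions, e, 1.0)
    return Trajectory(top, coords, np.tile(box, (spec.n_frames, 1)),
                      _times(spec.n_frames))


# ---------------------------------------------------------------------------
# functional assays

@dataclass
class AssaySpec:
    """Fluorescence trace, pressure–response table, and two-group samples.

    The trace rises from the baseline after the stimulus time (agonist
    added at t = 10 s) toward a known ΔF/F₀ plateau; currents follow a
    Boltzmann with known (P50, k); the two samples are normal with a
    prescribed location shift."""

    seed: int = 0
    f0: float = 100.0
    dff_plateau: float = 1.5
    stimulus_time: float = 10.0
    rise_tau: float = 2.0
    duration: float = 60.0
    dt: float = 1.0
    f_noise: float = 0.0        # absolute fluorescence noise sd
    p50: float = -45.0          # mmHg (suction)
    k: float = -8.0             # mmHg
    imax: float = 1.0
    pressures: tuple = tuple(range(-5, -85, -5))
    i_noise: float = 0.0
    group_n: int = 10
    group_shift: float = 0.0
    group_sd: float = 1.0


@dataclass
class AssayData:
    trace: FluorescenceTrace
    pressures: np.ndarray
    currents: np.ndarray
    group_a: np.ndarray
    group_b: np.ndarray
    truth: dict = field(default_factory=dict)


def make_assay_data(spec: AssaySpec) -> AssayData:
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.duration + spec.dt / 2, spec.dt)
    rise = np.where(t < spec.stimulus_time, 0.0,
                    1.0 - np.exp(-(t - spec.stimulus_time) / spec.rise_tau))
    F = spec.f0 * (1.0 + spec.dff_plateau * rise)
    if spec.f_noise > 0:
        F = np.maximum(F + rng.normal(0.0, spec.f_noise, F.shape), 1e-6)
    trace = FluorescenceTrace(t, F, roi="synthetic")

    p = np.asarray(spec.pressures, dtype=float)
    i = spec.imax / (1.0 + np.exp((spec.p50 - p) / spec.k))
    if spec.i_noise > 0:
        i = i + rng.normal(0.0, spec.i_noise, i.shape)

    a = rng.normal(0.0, spec.group_sd, spec.group_n)
    b = rng.normal(spec.group_shift, spec.group_sd, spec.group_n)
    truth = {"dff": spec.dff_plateau, "p50": spec.p50, "k": spec.k,
             "imax": spec.imax, "shift": spec.group_shift}
    return AssayData(trace, p, i, a, b, truth)


# ---------------------------------------------------------------------------

def ligand_concentration(box_lengths, n_molecules: int) -> float:
    """Concentration in mM of ``n_molecules`` in an orthorhombic box (Å).

    20 molecules in the reference 190.1 × 190.1 × 177.5 Å³ box come out at
    ≈ 5.2 mM (about 5 mM)."""
    L = np.asarray(box_lengths, dtype=float)
    if np.any(L <= 0):
        raise ValueError("box lengths must be positive")
    if n_molecules < 0:
        raise ValueError("molecule count must be nonnegative")
    volume_liters = float(np.prod(L)) * 1e-27  # Å³ → L
    return n_molecules / (AVOGADRO * volume_liters) * 1e3
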