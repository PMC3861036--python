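"""Synthetic trajectories with exact ground truth.

This module is the package's source of test data: it emits topologies and
trajectories whose analysis results are known by construction, so every
analysis stage can be validated without an MD engine.  The unfolding is
scripted (kinematic), solvent molecules are rigid pseudo-molecules, and urea
stickiness is a jump process — none of it is thermodynamically realistic and
it must never be mistaken for simulation.

Ground truth covers: per-contact telegraph schedules (open/close rates),
per-species diffusion constants, the exact residence-event log of sticky
urea, the first-shell urea enrichment factor, and the secondary-structure
labels of the built protein.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree

from .system import Atom, MolecularSystem, Residue, Trajectory, classify_system

__all__ = [
    "SyntheticSpec",
    "SolventSpec",
    "TelegraphSpec",
    "StickySpec",
    "SyntheticGroundTruth",
    "SyntheticResult",
    "build_toy_protein",
    "build_extended_protein",
    "unfolding_interpolation",
    "brownian_positions",
    "synthesize_trajectory",
    "stiffness_pair",
    "build_hbond_fixture",
]

# ideal backbone internal coordinates (Angstrom, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N, _A_CA_C_O = 121.7, 111.2, 116.2, 120.8
HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)
EXTENDED_PHI_PSI = (180.0, 180.0)

# rigid pseudo-molecules.  Water carries one heavy atom at the diffusion
# center; pseudo-urea carries its four heavy atoms nearly coincident, so both
# species have a point-like heavy-atom footprint and molecule-level shell
# boundaries stay sharp (see docs/methods.md); atom counts still differ.
_WATER_OFFSETS = {"O": (0.0, 0.0, 0.0), "H1": (0.7586, 0.586, 0.0),
                  "H2": (-0.7586, 0.586, 0.0)}
_UREA_OFFSETS = {"C": (0.0, 0.0, 0.0), "O": (0.0, 0.05, 0.0),
                 "N1": (0.043, -0.025, 0.0), "N2": (-0.043, -0.025, 0.0)}


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF placement of atom d from a-b-c internal coordinates."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(angle),
                  bond * np.sin(angle) * np.cos(torsion),
                  bond * np.sin(angle) * np.sin(torsion)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_backbone(n_residues: int, phi: float, psi: float,
                    with_cb: bool = True):
    """Ideal-geometry backbone (N, CA, C, O [, CB]) with constant phi/psi."""
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = np.radians(180.0 - _A_N_CA_C)
    C = [CA[0] + _B_CA_C * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])]
    for i in range(1, n_residues):
        N.append(_place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi))
        CA.append(_place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, 180.0))
        C.append(_place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi))
    O, CB = [], []
    for i in range(n_residues):
        if i + 1 < n_residues:
            O.append(_place_atom(N[i + 1], CA[i], C[i], _B_C_O, _A_CA_C_O, 180.0))
        else:
            O.append(_place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi + 180.0))
        if with_cb:
            CB.append(_place_atom(N[i], C[i], CA[i], _B_CA_CB, 110.6, 122.6))
    return N, CA, C, O, CB


def _assemble_protein(per_residue_atoms, resnames, chain="A") -> tuple[MolecularSystem, np.ndarray]:
    atoms, residues, coords = [], [], []
    serial = 1
    for ridx, (atom_list, rname) in enumerate(zip(per_residue_atoms, resnames)):
        res = Residue(index=ridx, name=rname, chain=chain)
        for name, elem, xyz in atom_list:
            atoms.append(Atom(serial=serial, name=name, element=elem,
                              is_heavy=elem.upper() not in ("H", "D"),
                              residue_index=ridx, residue_name=rname,
                              chain=chain))
            res.atom_indices.append(len(coords))
            coords.append(np.asarray(xyz, dtype=float))
            serial += 1
        residues.append(res)
    system = classify_system(MolecularSystem(atoms, residues))
    return system, np.stack(coords)


def _backbone_residue_atoms(N, CA, C, O, CB, i, with_cb=True):
    out = [("N", "N", N[i]), ("CA", "C", CA[i]), ("C", "C", C[i]),
           ("O", "O", O[i])]
    if with_cb and CB:
        out.append(("CB", "C", CB[i]))
    return out


def build_toy_protein(kind: str, n_residues: int, sequence=None):
    """Toy protein with ideal geometry: helix, antiparallel hairpin or beads.

    Returns ``(system, native_frame)``.  Helices use phi=-57, psi=-47;
    hairpins two ideal strands joined by a 4-residue turn, the second strand
    rigidly placed so the inter-strand Kabsch-Sander hydrogen bonds form;
    beads are CA-only chains (3.8 Angstrom spacing).
    """
    if n_residues < 6:
        raise ValueError("need at least 6 residues")
    if sequence is None:
        sequence = ["ALA"] * n_residues
    if kind == "helix":
        N, CA, C, O, CB = _build_backbone(n_residues, *HELIX_PHI_PSI)
        per_res = [_backbone_residue_atoms(N, CA, C, O, CB, i)
                   for i in range(n_residues)]
        return _assemble_protein(per_res, sequence)
    if kind == "beads":
        per_res = [[("CA", "C", np.array([3.8 * i, 0.0, 0.0]))]
                   for i in range(n_residues)]
        return _assemble_protein(per_res, sequence)
    if kind == "hairpin":
        return _build_hairpin(n_residues, sequence)
    raise ValueError(f"unsupported kind {kind!r}")


def build_extended_protein(n_residues: int, sequence=None):
    """Fully extended chain (phi = psi = 180) with the helix topology."""
    if sequence is None:
        sequence = ["ALA"] * n_residues
    N, CA, C, O, CB = _build_backbone(n_residues, *EXTENDED_PHI_PSI)
    per_res = [_backbone_residue_atoms(N, CA, C, O, CB, i)
               for i in range(n_residues)]
    return _assemble_protein(per_res, sequence)


def _build_hairpin(n_residues: int, sequence):
    """Two antiparallel ideal strands + 4-residue turn.

    Strand 2 is a rigid copy of strand 1 rotated/translated; the placement is
    refined numerically so the mutual N-H...O=C pairs sit at 2.9 Angstrom.
    """
    from scipy.optimize import least_squares
    from scipy.spatial.transform import Rotation

    m = (n_residues - 4) // 2
    if m < 3:
        raise ValueError("hairpin needs at least 10 residues")
    n_turn = n_residues - 2 * m
    N, CA, C, O, CB = _build_backbone(m, *STRAND_PHI_PSI)
    s1 = {k: np.stack(v) for k, v in
          zip("N CA C O CB".split(), (N, CA, C, O, CB))}

    # strand axis and mean carbonyl direction give the sheet frame used to
    # seed the rigid placement of strand 2
    u = s1["CA"][-1] - s1["CA"][0]
    u = u / np.linalg.norm(u)
    co = np.mean([(s1["O"][i] - s1["C"][i]) * (1 if i % 2 == 0 else -1)
                  for i in range(m)], axis=0)
    co = co - co.dot(u) * u
    co = co / np.linalg.norm(co)
    nrm = np.cross(u, co)

    def transform(params, pts):
        R = Rotation.from_rotvec(params[:3]).as_matrix()
        return {k: v @ R.T + params[3:] for k, v in pts.items()}

    def amide_h(pts, j):
        if j == 0:
            return None
        v1 = pts["N"][j] - pts["C"][j - 1]
        v2 = pts["N"][j] - pts["CA"][j]
        w = v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2)
        return pts["N"][j] + 1.01 * w / np.linalg.norm(w)

    # pairing: strand-1 residue i faces strand-2 residue m-1-i; mutual
    # N...O targets of 2.9 (H...O of 1.9) on alternating residues
    def residuals(params):
        s2 = transform(params, s1)
        res = []
        for i in range(m):
            j = m - 1 - i
            res.append(np.linalg.norm(s1["CA"][i] - s2["CA"][j]) - 4.9)
            if i % 2 == 0:
                res.append(np.linalg.norm(s2["N"][j] - s1["O"][i]) - 2.9)
                res.append(np.linalg.norm(s1["N"][i] - s2["O"][j]) - 2.9)
                h2 = amide_h(s2, j)
                if h2 is not None:
                    res.append(np.linalg.norm(h2 - s1["O"][i]) - 1.9)
                h1 = amide_h(s1, i)
                if h1 is not None:
                    res.append(np.linalg.norm(h1 - s2["O"][j]) - 1.9)
        return np.array(res)

    cen = s1["CA"].mean(axis=0)
    best = None
    for w in (co, -co, nrm, -nrm):
        for axis in (co, nrm):
            R0 = Rotation.from_rotvec(np.pi * axis)
            t0 = cen + 4.9 * w - R0.as_matrix() @ cen
            p0 = np.concatenate([R0.as_rotvec(), t0])
            fit = least_squares(residuals, p0, method="lm", max_nfev=20000)
            if best is None or fit.cost < best.cost:
                best = fit
    s2 = transform(best.x, s1)

    per_res = []
    for i in range(m):
        per_res.append([("N", "N", s1["N"][i]), ("CA", "C", s1["CA"][i]),
                        ("C", "C", s1["C"][i]), ("O", "O", s1["O"][i]),
                        ("CB", "C", s1["CB"][i])])
    # turn: interpolate between strand-1 C-terminus and strand-2 N-terminus,
    # pushed outward so turn atoms do not clash with the strands
    start = s1["CA"][m - 1]
    end = s2["CA"][0]
    mid = 0.5 * (start + end)
    axis = np.cross(end - start, np.array([0.0, 0.0, 1.0]))
    axis = axis / (np.linalg.norm(axis) + 1e-9)
    for t in range(n_turn):
        frac = (t + 1) / (n_turn + 1)
        bulge = np.sin(np.pi * frac) * 4.0
        ca = start + frac * (end - start) + bulge * axis
        per_res.append([("N", "N", ca + np.array([-0.8, 0.5, 0.3])),
                        ("CA", "C", ca),
                        ("C", "C", ca + np.array([0.9, 0.5, -0.3])),
                        ("O", "O", ca + np.array([1.0, 1.6, -0.3]))])
    for j in range(m):  # natural N->C order; residue j pairs with s1[m-1-j]
        per_res.append([("N", "N", s2["N"][j]), ("CA", "C", s2["CA"][j]),
                        ("C", "C", s2["C"][j]), ("O", "O", s2["O"][j]),
                        ("CB", "C", s2["CB"][j])])
    names = list(sequence[:len(per_res)])
    while len(names) < len(per_res):
        names.append("ALA")
    return _assemble_protein(per_res, names)


def unfolding_interpolation(n_residues: int = 16, n_frames: int = 60,
                            dt_ns: float = 0.1):
    """Scripted native-helix -> fully-extended interpolation trajectory."""
    system, native = build_toy_protein("helix", n_residues)
    _, extended = build_extended_protein(n_residues)
    fracs = np.linspace(0.0, 1.0, n_frames)
    coords = native[None, :, :] * (1 - fracs)[:, None, None] \
        + extended[None, :, :] * fracs[:, None, None]
    traj = Trajectory(coords, np.arange(n_frames) * dt_ns)
    return system, traj


# ---------------------------------------------------------------------------
# Brownian solvent

def brownian_positions(n_molecules: int, D: float, dt_ns: float,
                       n_frames: int, box, seed=None) -> np.ndarray:
    """Unwrapped Brownian centers: per-axis steps ~ N(0, sqrt(2 D dt))."""
    if D < 0 or dt_ns <= 0:
        raise ValueError("D must be >= 0 and dt > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    box = np.asarray(box, dtype=float)
    start = rng.uniform(0.0, box, size=(n_molecules, 3))
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt_ns),
                       size=(n_frames - 1, n_molecules, 3))
    return np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])


# ---------------------------------------------------------------------------
# full synthetic systems

@dataclass
class TelegraphSpec:
    """Two-state Markov (telegraph) contact schedules.

    ``k_open`` is the closed->open rate, ``k_close`` the open->closed rate
    (1/ns); mean opening duration is 1/k_close.  Scalar rates apply to every
    contact; arrays give per-contact rates.
    """
    n_contacts: int = 10
    k_open: float | list = 1.0
    k_close: float | list = 1.0
    closed_distance: float = 3.0
    open_distance: float = 9.0


@dataclass
class SolventSpec:
    n_water: int = 0
    n_urea: int = 0
    d_water: float = 4.0  # Angstrom^2/ns
    d_urea: float = 1.0
    mode: str = "brownian"  # brownian | resample (independent frames)
    boundary: str = "reflective"  # reflective walls | unwrapped free walks
    min_spacing: float = 1.5  # minimum solvent-solvent placement distance
    fss_enrichment: float = 1.0  # urea density multiplier in the FSS
    fss_cutoff: float = 5.0
    exclusion: float = 2.5  # no solvent closer than this to the protein


@dataclass
class StickySpec:
    k_off: float = 1.0  # ns^-1 escape rate
    capture_prob: float = 1.0  # on entering the capture zone
    capture_radius: float = 5.0  # first-shell entry triggers capture
    target_residues: list | None = None  # default: all protein residues
    tether_distance: float = 2.8
    release_distance: float = 7.0
    jitter: float = 0.1


@dataclass
class SyntheticSpec:
    seed: int = 0
    dt_ns: float = 0.05
    n_frames: int = 200
    box: tuple = (40.0, 40.0, 40.0)
    protein: str = "helix"  # helix | hairpin | beads | telegraph
    n_residues: int = 16
    telegraph: TelegraphSpec | None = None
    solvent: SolventSpec | None = None
    sticky: StickySpec | None = None
    long_binder: tuple | None = None  # (molecule, start_frame, end_frame)


@dataclass
class SyntheticGroundTruth:
    seed: int
    dt_ns: float
    n_frames: int
    contact_pairs: list = field(default_factory=list)
    schedules: np.ndarray | None = None  # bool closed, (n_contacts, n_frames)
    k_open: list = field(default_factory=list)
    k_close: list = field(default_factory=list)
    d_water: float | None = None
    d_urea: float | None = None
    residence_events: list = field(default_factory=list)  # (mol_res, f0, f1)
    fss_enrichment: float = 1.0
    expected_fss_ratio: float | None = None
    expected_bulk_ratio: float | None = None
    ss_labels: list = field(default_factory=list)

    def to_json(self, path) -> None:
        d = asdict(self)
        if self.schedules is not None:
            d["schedules"] = self.schedules.astype(int).tolist()
        with open(path, "w") as fh:
            json.dump(d, fh)


@dataclass
class SyntheticResult:
    system: MolecularSystem
    trajectory: Trajectory
    ground_truth: SyntheticGroundTruth
    spec: SyntheticSpec

    def write(self, out_dir, formats=("pdb",)) -> dict:
        """Write trajectory (multi-model PDB, optional DCD), ground truth and
        a YAML echo of the generating parameters; returns the path map."""
        import os
        import yaml
        from .system import write_trajectory

        os.makedirs(out_dir, exist_ok=True)
        paths = {}
        for fmt in formats:
            p = os.path.join(out_dir, f"trajectory.{fmt}")
            write_trajectory(p, self.system, self.trajectory)
            paths[fmt] = p
        gt = os.path.join(out_dir, "ground_truth.json")
        self.ground_truth.to_json(gt)
        paths["ground_truth"] = gt
        spec_path = os.path.join(out_dir, "spec.yaml")
        with open(spec_path, "w") as fh:
            yaml.safe_dump(_spec_to_dict(self.spec), fh)
        paths["spec"] = spec_path
        return paths


def _spec_to_dict(spec: SyntheticSpec) -> dict:
    d = asdict(spec)
    d["box"] = list(spec.box)
    return d


def _telegraph_protein(n_contacts: int):
    """Disjoint 'breathing' bead pairs: block k holds residues 4k..4k+3 and
    the scripted contact (4k, 4k+3); fillers sit far from everything."""
    per_res = []
    pairs = []
    for k in range(n_contacts):
        y = 20.0 * k
        per_res.append([("CA", "C", np.array([0.0, y, 0.0]))])
        per_res.append([("CA", "C", np.array([15.0, y, 6.0]))])
        per_res.append([("CA", "C", np.array([15.0, y, 12.0]))])
        per_res.append([("CA", "C", np.array([3.0, y, 0.0]))])
        pairs.append((4 * k, 4 * k + 3))
    system, coords = _assemble_protein(per_res, ["ALA"] * len(per_res))
    return system, coords, pairs


def _simulate_telegraph(rng, n_contacts, k_open, k_close, dt, n_frames):
    k_o = np.broadcast_to(np.asarray(k_open, dtype=float), (n_contacts,))
    k_c = np.broadcast_to(np.asarray(k_close, dtype=float), (n_contacts,))
    p_open = 1.0 - np.exp(-k_o * dt)
    p_close = 1.0 - np.exp(-k_c * dt)
    closed = np.empty((n_contacts, n_frames), dtype=bool)
    state = rng.random(n_contacts) < k_c / (k_o + k_c)  # stationary start
    for f in range(n_frames):
        closed[:, f] = state
        u = rng.random(n_contacts)
        flip = np.where(state, u < p_open, u < p_close)
        state = np.where(flip, ~state, state)
    return closed, k_o, k_c


def _solvent_system(protein_system: MolecularSystem, n_water: int, n_urea: int):
    atoms = list(protein_system.atoms)
    residues = [Residue(index=r.index, name=r.name, chain=r.chain,
                        atom_indices=list(r.atom_indices))
                for r in protein_system.residues]
    serial = len(atoms) + 1
    offsets = []
    ridx = len(residues)
    for count, rname, template, chain in (
            (n_urea, "URE", _UREA_OFFSETS, "U"),
            (n_water, "HOH", _WATER_OFFSETS, "W")):
        for _ in range(count):
            res = Residue(index=ridx, name=rname, chain=chain)
            for aname, off in template.items():
                elem = aname[0]
                atoms.append(Atom(serial=serial, name=aname, element=elem,
                                  is_heavy=elem.upper() != "H",
                                  residue_index=ridx, residue_name=rname,
                                  chain=chain))
                res.atom_indices.append(len(atoms) - 1)
                offsets.append(np.asarray(off, dtype=float))
                serial += 1
            residues.append(res)
            ridx += 1
    system = classify_system(MolecularSystem(atoms, residues))
    return system, np.stack(offsets) if offsets else np.zeros((0, 3))


def _sample_positions(rng, n, box, protein_tree, min_dist, region="free",
                      shell_cutoff=5.0, max_tries=200, spacing=0.0,
                      existing=None):
    """Uniform points in the box with protein-distance constraints.

    region='free': distance > min_dist; region='shell': min_dist < d <=
    shell_cutoff.  ``spacing`` enforces a minimum solvent-solvent distance
    (overlap check); an overfull box raises.
    """
    n_prior = 0 if existing is None else len(existing)
    buf = np.empty((n_prior + n, 3))
    if n_prior:
        buf[:n_prior] = existing
    got = 0
    tries = 0
    sp2 = spacing ** 2
    while got < n:
        tries += 1
        if tries > max_tries:
            raise ValueError("box too small for the requested solvent count")
        cand = rng.uniform(0.0, np.asarray(box), size=(max(8 * (n - got), 256), 3))
        d, _ = protein_tree.query(cand)
        if region == "free":
            ok = d > min_dist
        else:
            ok = (d > min_dist) & (d <= shell_cutoff)
        for p in cand[ok]:
            k = n_prior + got
            if spacing > 0.0 and k:
                if np.min(np.sum((buf[:k] - p) ** 2, axis=1)) < sp2:
                    continue
            buf[k] = p
            got += 1
            if got == n:
                break
    return buf[n_prior:]


def synthesize_trajectory(spec: SyntheticSpec) -> SyntheticResult:
    """Generate a full synthetic system per the spec; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    dt, n_frames = spec.dt_ns, spec.n_frames
    box = np.asarray(spec.box, dtype=float)
    gt = SyntheticGroundTruth(seed=spec.seed, dt_ns=dt, n_frames=n_frames)

    # --- protein ---------------------------------------------------------
    pairs = []
    if spec.protein == "telegraph":
        tspec = spec.telegraph or TelegraphSpec()
        prot_system, prot_coords, pairs = _telegraph_protein(tspec.n_contacts)
        closed, k_o, k_c = _simulate_telegraph(
            rng, tspec.n_contacts, tspec.k_open, tspec.k_close, dt, n_frames)
        gt.contact_pairs = pairs
        gt.schedules = closed
        gt.k_open = k_o.tolist()
        gt.k_close = k_c.tolist()
    else:
        prot_system, prot_coords = build_toy_protein(spec.protein, spec.n_residues)

    center = box / 2.0 - prot_coords.mean(axis=0)
    prot_coords = prot_coords + center
    n_prot_atoms = prot_coords.shape[0]

    # --- solvent ---------------------------------------------------------
    sspec = spec.solvent or SolventSpec()
    n_water, n_urea_base = sspec.n_water, sspec.n_urea
    tree = cKDTree(prot_coords)

    n_extra = 0
    if sspec.fss_enrichment != 1.0 and sspec.mode != "resample":
        raise ValueError("fss_enrichment requires mode='resample' "
                         "(independent snapshot frames)")
    if sspec.fss_enrichment != 1.0 and n_urea_base > 0:
        # Monte Carlo estimate of the first-shell fraction of the free volume
        probe = rng.uniform(0.0, box, size=(30000, 3))
        d, _ = tree.query(probe)
        free_frac = float(np.mean(d > sspec.exclusion))
        shell_frac = float(np.mean((d > sspec.exclusion) & (d <= sspec.fss_cutoff)))
        # extra urea placed uniformly inside the shell so the shell urea
        # density is fss_enrichment times the background density
        n_extra = int(round((sspec.fss_enrichment - 1.0) * n_urea_base
                            * shell_frac / free_frac))
    n_urea = n_urea_base + n_extra

    gt.fss_enrichment = sspec.fss_enrichment
    if n_urea_base > 0 and n_water > 0:
        gt.expected_bulk_ratio = n_water / n_urea_base
        gt.expected_fss_ratio = n_water / (n_urea_base * sspec.fss_enrichment)

    mol_centers = None
    sticky_events: list[tuple[int, int, int]] = []

    if n_water + n_urea > 0:
        if sspec.mode == "resample":
            sp = sspec.min_spacing
            mol_centers = np.empty((n_frames, n_urea + n_water, 3))
            for f in range(n_frames):
                u = _sample_positions(rng, n_urea_base, box, tree,
                                      sspec.exclusion, spacing=sp)
                if n_extra:
                    ue = _sample_positions(rng, n_extra, box, tree,
                                           sspec.exclusion, region="shell",
                                           shell_cutoff=sspec.fss_cutoff,
                                           spacing=sp, existing=u)
                    u = np.concatenate([u, ue])
                w = _sample_positions(rng, n_water, box, tree,
                                      sspec.exclusion, spacing=sp, existing=u)
                mol_centers[f] = np.concatenate([u, w])
        else:
            reflect = sspec.boundary == "reflective"
            starts_u = _sample_positions(rng, n_urea_base, box, tree,
                                         sspec.exclusion,
                                         spacing=sspec.min_spacing)
            starts_w = _sample_positions(rng, n_water, box, tree,
                                         sspec.exclusion,
                                         spacing=sspec.min_spacing,
                                         existing=starts_u)
            cen_u = _brownian_from(rng, starts_u, sspec.d_urea, dt, n_frames)
            cen_w = _brownian_from(rng, starts_w, sspec.d_water, dt, n_frames)
            if reflect:
                cen_u, cen_w = _fold(cen_u, box), _fold(cen_w, box)
            if spec.sticky is not None and n_urea_base > 0:
                cen_u, sticky_events = _apply_sticky(
                    rng, cen_u, prot_system, prot_coords, spec.sticky, dt,
                    box if reflect else None, long_binder=spec.long_binder)
            mol_centers = np.concatenate([cen_u, cen_w], axis=1)
        gt.d_water, gt.d_urea = sspec.d_water, sspec.d_urea

    system, offsets = _solvent_system(prot_system, n_water, n_urea)
    n_solvent_atoms = offsets.shape[0]
    all_coords = np.empty((n_frames, n_prot_atoms + n_solvent_atoms, 3))

    for f in range(n_frames):
        pc = prot_coords.copy()
        if spec.protein == "telegraph":
            tspec = spec.telegraph or TelegraphSpec()
            for k, (i, j) in enumerate(pairs):
                dist = (tspec.closed_distance if gt.schedules[k, f]
                        else tspec.open_distance)
                base = pc[system.atoms_of_residue(i)[0]]
                pc[system.atoms_of_residue(j)[0]] = base + np.array([dist, 0, 0])
        all_coords[f, :n_prot_atoms] = pc
        if n_solvent_atoms:
            # solvent residues are ordered urea first, then water
            n_atoms_u = len(_UREA_OFFSETS)
            n_atoms_w = len(_WATER_OFFSETS)
            centers = mol_centers[f]
            rep = np.concatenate([
                np.repeat(centers[:n_urea], n_atoms_u, axis=0),
                np.repeat(centers[n_urea:], n_atoms_w, axis=0)])
            all_coords[f, n_prot_atoms:] = rep + offsets

    times = np.arange(n_frames) * dt
    traj = Trajectory(all_coords, times, box=np.tile(box, (n_frames, 1)))

    # ground truth bookkeeping
    first_solvent_res = prot_system.n_residues
    gt.residence_events = [(first_solvent_res + m, int(f0), int(f1))
                           for (m, f0, f1) in sticky_events]
    if spec.protein in ("helix", "hairpin"):
        from .metrics import assign_ss
        gt.ss_labels = assign_ss(prot_coords, prot_system).tolist()
    return SyntheticResult(system, traj, gt, spec)


def _brownian_from(rng, starts, D, dt, n_frames):
    n = starts.shape[0]
    if n == 0:
        return np.zeros((n_frames, 0, 3))
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n_frames - 1, n, 3))
    return np.concatenate([starts[None], starts[None] + np.cumsum(steps, axis=0)])


def _fold(x, box):
    """Reflect coordinates into [0, box] (reflective walls)."""
    box = np.asarray(box, dtype=float)
    y = np.mod(x, 2.0 * box)
    return np.where(y > box, 2.0 * box - y, y)


def _apply_sticky(rng, centers, prot_system, prot_coords, sticky: StickySpec,
                  dt, box=None, long_binder=None):
    """Jump-process urea stickiness: on first contact, tether; exponential
    escape.  Returns modified centers and the exact event log (mol, f0, f1)."""
    n_frames, n_mol, _ = centers.shape
    target_res = (sticky.target_residues
                  or [r.index for r in prot_system.residues
                      if r.species == "protein"])
    tgt_atoms = np.concatenate([prot_system.atoms_of_residue(r)
                                for r in target_res])
    tgt_pos = prot_coords[tgt_atoms]
    tree = cKDTree(tgt_pos)
    prot_tree = cKDTree(prot_coords[prot_system.heavy_mask])
    p_escape = 1.0 - np.exp(-sticky.k_off * dt)
    # molecule heavy-atom reach of the pseudo-urea (max offset norm)
    reach = max(np.linalg.norm(np.asarray(v)) for v in _UREA_OFFSETS.values())
    contact_range = 3.5 - reach  # com distance guaranteeing a 3.5 A contact

    def release_point(site):
        """A point with clearance from every protein heavy atom, so the
        escape frame is contact-free and recapture needs real diffusion."""
        _, k = tree.query(site)
        for _ in range(200):
            p = tgt_pos[k] + _random_unit(rng) * sticky.release_distance
            if box is not None:
                p = _fold(p, box)
            d, _ = prot_tree.query(p)
            if d > 4.2:
                return p
        raise ValueError("could not find a clear release point; box too tight")

    events = []
    out = centers.copy()
    forced = {}
    if long_binder is not None:
        mol, f0, f1 = long_binder
        forced[mol] = (f0, f1)
    for m in range(n_mol):
        tethered = False
        site = None
        start = 0
        fb = forced.get(m)
        offset = out[0, m].copy()
        for f in range(n_frames):
            if fb is not None and fb[0] <= f < fb[1]:
                if not tethered or site is None:
                    k = int(rng.integers(tgt_pos.shape[0]))
                    site = tgt_pos[k] + _random_unit(rng) * sticky.tether_distance
                    tethered, start = True, f
                out[f, m] = site + np.clip(
                    rng.normal(0, sticky.jitter, 3), -0.2, 0.2)
                continue
            if fb is not None and f == fb[1] and tethered:
                # forced window end (exclusive): release like an escape so the
                # event and its successor stay separated by a contact-free frame
                events.append((m, start, f - 1))
                tethered = False
                offset = release_point(site)
                out[f, m] = offset
                continue
            if not tethered:
                # free Brownian motion relative to the current anchor,
                # reflected at the walls when a box is given
                if f > 0:
                    offset = offset + (centers[f, m] - centers[f - 1, m])
                    if box is not None:
                        offset = _fold(offset, box)
                out[f, m] = offset
                d, k = tree.query(out[f, m])
                if d <= sticky.capture_radius and rng.random() < sticky.capture_prob:
                    u = out[f, m] - tgt_pos[k]
                    u = u / (np.linalg.norm(u) + 1e-9)
                    site = tgt_pos[k] + u * sticky.tether_distance
                    out[f, m] = site
                    tethered, start = True, f
            else:
                if rng.random() < p_escape:
                    events.append((m, start, f - 1))
                    tethered = False
                    offset = release_point(site)
                    out[f, m] = offset
                else:
                    out[f, m] = site + np.clip(
                        rng.normal(0, sticky.jitter, 3), -0.2, 0.2)
        if tethered:
            events.append((m, start, n_frames - 1))
    return out, events


def _random_unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# side-chain stiffness pair

def stiffness_pair(n_residues: int = 15, n_frames: int = 400,
                   sigma: float = 0.30, scale_a=None, seed: int = 0,
                   dt_ns: float = 0.05):
    """Two trajectories of a toy helix whose CB atoms jitter with prescribed
    per-residue amplitude ratios (condition a vs b).

    ``scale_a`` is the per-residue amplitude multiplier of condition a
    relative to b (default 0.8 everywhere: a uniformly stiffer in a, the
    viscosity-slowdown picture).  Returns (system, traj_a, traj_b, scale_a).
    """
    rng = np.random.default_rng(seed)
    system, native = build_toy_protein("helix", n_residues)
    cb = [i for i, a in enumerate(system.atoms) if a.name == "CB"]
    res_of_cb = [system.atoms[i].residue_index for i in cb]
    if scale_a is None:
        scale_a = np.full(n_residues, 0.8)
    scale_a = np.asarray(scale_a, dtype=float)

    def make(scales):
        coords = np.tile(native, (n_frames, 1, 1))
        for i, r in zip(cb, res_of_cb):
            s = scales[r] if scales is not None else 1.0
            coords[:, i, :] += rng.normal(0.0, sigma * s, size=(n_frames, 3))
        return Trajectory(coords, np.arange(n_frames) * dt_ns)

    traj_a = make(scale_a)
    traj_b = make(np.ones(n_residues))
    return system, traj_a, traj_b, scale_a


# ---------------------------------------------------------------------------
# hydrogen-bond geometry fixtures

def _h_between(donor, acceptor, angle_deg, bond=1.0):
    """H at ``bond`` from the donor with the prescribed D-H-A angle."""
    d = np.asarray(donor, dtype=float)
    a = np.asarray(acceptor, dtype=float)
    u = a - d
    dist = np.linalg.norm(u)
    u = u / dist

    # rotate H away from the D->A axis until angle(D-H-A) == angle_deg
    perp = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(u, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)

    def angle_at(alpha):
        h = d + bond * (np.cos(alpha) * u + np.sin(alpha) * perp)
        v1 = d - h
        v2 = a - h
        c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return np.degrees(np.arccos(np.clip(c, -1, 1)))

    lo, hi = 0.0, np.pi * 0.95
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if angle_at(mid) > angle_deg:
            lo = mid
        else:
            hi = mid
    # lo keeps angle_at(lo) strictly above the target, so a fixture built at
    # the detection boundary falls on the accepted side
    return d + bond * (np.cos(lo) * u + np.sin(lo) * perp)


def build_hbond_fixture():
    """Small system of solvent-protein hydrogen-bond geometries straddling
    the 3.50 Angstrom / 120 degree cutoffs.

    Returns (system, frame, expected): ``expected`` is a list of
    (description, donor_species, should_detect) in cluster order; clusters
    are spaced 30 Angstrom apart so they cannot interact.
    """
    cases = [
        ("water donor, 3.0 A, 180 deg", "water", 3.0, 180.0, True),
        ("water donor, 3.6 A, 180 deg", "water", 3.6, 180.0, False),
        ("water donor, 3.0 A, 110 deg", "water", 3.0, 110.0, False),
        ("urea donor, 3.4 A, 150 deg", "urea", 3.4, 150.0, True),
        ("water donor, 3.5 A, 120 deg (boundary)", "water", 3.5, 120.0, True),
    ]
    atoms, residues, coords = [], [], []
    serial = 1

    def add_residue(name, chain, atom_specs):
        nonlocal serial
        ridx = len(residues)
        res = Residue(index=ridx, name=name, chain=chain)
        for aname, elem, xyz in atom_specs:
            atoms.append(Atom(serial=serial, name=aname, element=elem,
                              is_heavy=elem.upper() != "H",
                              residue_index=ridx, residue_name=name,
                              chain=chain))
            res.atom_indices.append(len(coords))
            coords.append(np.asarray(xyz, dtype=float))
            serial += 1
        residues.append(res)

    expected = []
    for k, (desc, species, dist, angle, detect) in enumerate(cases):
        base = np.array([30.0 * k, 0.0, 0.0])
        # minimal protein residue: backbone O acceptor; companion atoms kept
        # > 4.5 Angstrom from the donor so only the intended bond can form
        acceptor = base + np.array([0.0, 0.0, 0.0])
        add_residue("ALA", "A", [
            ("N", "N", base + [-2.4, -2.3, 0.0]),
            ("CA", "C", base + [-1.0, -2.3, 0.0]),
            ("C", "C", base + [0.0, -1.3, 0.0]),
            ("O", "O", acceptor),
        ])
        donor = acceptor + np.array([0.0, dist, 0.0])
        h = _h_between(donor, acceptor, angle)
        if species == "water":
            add_residue("HOH", "W", [
                ("O", "O", donor),
                ("H1", "H", h),
                ("H2", "H", donor + [0.76, 0.0, 0.59]),
            ])
        else:
            add_residue("URE", "U", [
                ("C", "C", donor + [0.0, 1.33, 0.0]),
                ("O", "O", donor + [1.1, 2.0, 0.0]),
                ("N1", "N", donor),
                ("N2", "N", donor + [-1.2, 2.0, 0.0]),
                ("H11", "H", h),
                ("H12", "H", donor + [-0.85, -0.5, 0.0]),
            ])
        expected.append((desc, species, detect))
    system = classify_system(MolecularSystem(atoms, residues))
    return system, np.stack(coords), expected
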