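"""Solvation-shell composition, urea preference and residence statistics.

A solvent molecule belongs to the first solvation shell (FSS) when any of its
heavy atoms is within 5 Angstrom of a protein heavy atom, and to the bulk
when all of them are beyond 6 Angstrom; the 5-6 Angstrom band is the
intermediate region excluded from both.  CC_UW is the ratio of protein
heavy-atom contacts with urea to those with water.  Residence events are
maximal runs of frames in which one solvent molecule keeps at least one
heavy-atom contact with the protein.  A direct-sum nonbonded energy
decomposition (Coulomb + Lennard-Jones, Lorentz-Berthelot mixing) supports
per-urea-molecule energy traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .system import MolecularSystem, Trajectory

__all__ = [
    "ShellAssignment",
    "ResidenceEvent",
    "NonbondedParams",
    "ShellRatios",
    "shell_assign",
    "shell_assign_series",
    "shell_ratio_series",
    "cc_uw",
    "residence_events",
    "long_residence_report",
    "nonbonded_energy",
    "COULOMB_CONSTANT",
]

COULOMB_CONSTANT = 332.0636  # kcal mol^-1 Angstrom e^-2

FSS, INTERMEDIATE, BULK = 0, 1, 2
SHELL_LABELS = {FSS: "FSS", INTERMEDIATE: "intermediate", BULK: "bulk"}


@dataclass
class ShellAssignment:
    """Shell label per solvent molecule (rows = frames)."""

    labels: np.ndarray  # int8, (n_frames, n_molecules)
    molecule_residues: np.ndarray  # residue index per molecule
    species: np.ndarray  # 'water'/'urea' per molecule


@dataclass
class ResidenceEvent:
    molecule_residue: int
    species: str
    start_ns: float
    end_ns: float
    duration_ns: float
    start_frame: int
    n_frames: int
    contacted_residues: frozenset = field(default_factory=frozenset)


@dataclass
class NonbondedParams:
    charge: np.ndarray  # e
    sigma: np.ndarray  # Angstrom
    epsilon: np.ndarray  # kcal/mol

    def __post_init__(self):
        self.charge = np.asarray(self.charge, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if np.any(self.epsilon < 0) or np.any(self.sigma <= 0):
            raise ValueError("epsilon must be >= 0 and sigma > 0")


@dataclass
class ShellRatios:
    times: np.ndarray
    fss_ratio: np.ndarray  # per-frame water/urea ratio (NaN when no urea)
    bulk_ratio: np.ndarray
    fss_mean: float  # mean of per-frame ratios
    fss_sd: float
    bulk_mean: float
    bulk_sd: float
    n_excluded_fss: int
    n_excluded_bulk: int
    fss_pooled: float = float("nan")  # ratio of summed counts (no small-count bias)
    bulk_pooled: float = float("nan")


def _solvent_layout(system: MolecularSystem, include_ions: bool = False):
    """(molecule residue indices, species array, per-molecule heavy atoms)."""
    mols = system.solvent_molecules(include_ions=include_ions)
    res_idx = np.array([m.index for m in mols], dtype=np.intp)
    species = np.array([m.species for m in mols])
    atoms = [system.atoms_of_residue(m.index, heavy_only=True) for m in mols]
    return res_idx, species, atoms


def _min_dist_per_molecule(frame, protein_tree, mol_atoms, box=None):
    """Minimum heavy-atom distance to the protein, per solvent molecule."""
    flat = np.concatenate(mol_atoms)
    counts = np.array([len(a) for a in mol_atoms])
    pts = frame[flat]
    if box is not None:
        pts = np.mod(pts, box)
    d, _ = protein_tree.query(pts)
    mins = np.full(len(mol_atoms), np.inf)
    np.minimum.at(mins, np.repeat(np.arange(len(mol_atoms)), counts), d)
    return mins


def _protein_tree(system, frame, box=None):
    pts = frame[system.protein_heavy_indices()]
    if box is not None:
        return cKDTree(np.mod(pts, box), boxsize=box)
    return cKDTree(pts)


def shell_assign(frame: np.ndarray, system: MolecularSystem,
                 fss_cutoff: float = 5.0, bulk_cutoff: float = 6.0,
                 box: np.ndarray | None = None,
                 include_ions: bool = False) -> ShellAssignment:
    """Assign every solvent molecule of one frame to FSS/intermediate/bulk."""
    if fss_cutoff > bulk_cutoff:
        raise ValueError("fss_cutoff must be <= bulk_cutoff")
    res_idx, species, mol_atoms = _solvent_layout(system, include_ions)
    frame = np.asarray(frame, dtype=float)
    tree = _protein_tree(system, frame, box)
    mins = _min_dist_per_molecule(frame, tree, mol_atoms, box)
    labels = np.full(len(mol_atoms), INTERMEDIATE, dtype=np.int8)
    labels[mins <= fss_cutoff] = FSS
    labels[mins > bulk_cutoff] = BULK
    return ShellAssignment(labels[None, :], res_idx, species)


def shell_assign_series(traj: Trajectory, system: MolecularSystem,
                        **kwargs) -> ShellAssignment:
    frames = [shell_assign(traj.coordinates[f], system,
                           box=traj.frame_box(f), **kwargs)
              for f in range(traj.n_frames)]
    return ShellAssignment(np.concatenate([a.labels for a in frames]),
                           frames[0].molecule_residues, frames[0].species)


def shell_ratio_series(assignment: ShellAssignment,
                       times: np.ndarray | None = None) -> ShellRatios:
    """Per-frame and average water/urea molecule-count ratio in FSS and bulk.

    Frames with zero urea in a shell give an undefined (NaN) ratio and are
    excluded from the average; the exclusion counts are reported.
    """
    is_water = assignment.species == "water"
    is_urea = assignment.species == "urea"
    if not is_water.any() or not is_urea.any():
        raise ValueError("both water and urea must be present")
    n_frames = assignment.labels.shape[0]
    if times is None:
        times = np.arange(n_frames, dtype=float)
    ratios = {FSS: np.full(n_frames, np.nan), BULK: np.full(n_frames, np.nan)}
    pooled = {}
    for shell in (FSS, BULK):
        in_shell = assignment.labels == shell
        n_w = (in_shell & is_water[None, :]).sum(axis=1)
        n_u = (in_shell & is_urea[None, :]).sum(axis=1)
        ok = n_u > 0
        ratios[shell][ok] = n_w[ok] / n_u[ok]
        pooled[shell] = (float(n_w.sum() / n_u.sum()) if n_u.sum() > 0
                         else float("nan"))

    def _avg(r):
        ok = ~np.isnan(r)
        if not ok.any():
            return float("nan"), float("nan"), int((~ok).sum())
        return float(np.mean(r[ok])), float(np.std(r[ok])), int((~ok).sum())

    fss_mean, fss_sd, nex_f = _avg(ratios[FSS])
    bulk_mean, bulk_sd, nex_b = _avg(ratios[BULK])
    return ShellRatios(np.asarray(times, dtype=float), ratios[FSS], ratios[BULK],
                       fss_mean, fss_sd, bulk_mean, bulk_sd, nex_f, nex_b,
                       fss_pooled=pooled[FSS], bulk_pooled=pooled[BULK])


# ---------------------------------------------------------------------------
# urea-preference coefficient

def cc_uw(traj: Trajectory, system: MolecularSystem, cutoff: float = 3.5,
          group_by: str = "polarity_class", normalize_bulk: bool = False):
    """Urea/water contact-count ratio per residue group.

    For each group, the time-averaged number of protein-heavy-atom / urea-
    heavy-atom pairs closer than the cutoff is divided by the equivalent
    count against water.  Groups: ``residue`` (per residue), ``polarity_class``
    (hydrophobic/polar/charged), ``role`` (sidechain/backbone), ``core``
    (core/non-core; requires ``Residue.is_core``).  Groups with zero water
    contacts are returned as NaN and listed in the flagged set.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    prot_heavy = system.protein_heavy_indices()
    counts = {}
    for species in ("urea", "water"):
        mols = system.solvent_molecules(species=species)
        if not mols:
            raise ValueError(f"no {species} present")
        sol = np.concatenate([system.atoms_of_residue(m.index) for m in mols])
        per_atom = np.zeros(prot_heavy.size)
        for f in range(traj.n_frames):
            frame = traj.coordinates[f]
            box = traj.frame_box(f)
            pts_s = frame[sol]
            pts_p = frame[prot_heavy]
            if box is not None:
                tree = cKDTree(np.mod(pts_s, box), boxsize=box)
                nb = tree.query_ball_point(np.mod(pts_p, box), r=cutoff,
                                           return_length=True)
            else:
                tree = cKDTree(pts_s)
                nb = tree.query_ball_point(pts_p, r=cutoff, return_length=True)
            per_atom += nb
        counts[species] = per_atom / traj.n_frames

    def group_key(atom_pos: int):
        ai = prot_heavy[atom_pos]
        atom = system.atoms[ai]
        res = system.residues[atom.residue_index]
        if group_by == "residue":
            return res.index
        if group_by == "polarity_class":
            return res.polarity_class
        if group_by == "role":
            return atom.role
        if group_by == "core":
            if res.is_core is None:
                raise ValueError("core flags not computed; set Residue.is_core")
            return "core" if res.is_core else "non_core"
        raise ValueError(f"unknown group_by {group_by!r}")

    urea_g: dict = {}
    water_g: dict = {}
    for k in range(prot_heavy.size):
        g = group_key(k)
        urea_g[g] = urea_g.get(g, 0.0) + counts["urea"][k]
        water_g[g] = water_g.get(g, 0.0) + counts["water"][k]
    scale = 1.0
    if normalize_bulk:
        n_u = sum(len(system.atoms_of_residue(m.index))
                  for m in system.solvent_molecules(species="urea"))
        n_w = sum(len(system.atoms_of_residue(m.index))
                  for m in system.solvent_molecules(species="water"))
        scale = n_w / n_u
    result, flagged = {}, set()
    for g in urea_g:
        if water_g[g] == 0:
            result[g] = float("nan")
            flagged.add(g)
        else:
            result[g] = scale * urea_g[g] / water_g[g]
    return result, flagged


# ---------------------------------------------------------------------------
# residence events

def _contact_matrix(traj, system, mol_atoms, target_atoms, cutoff):
    """bool (n_frames, n_molecules): any heavy-atom contact with the target."""
    flat = np.concatenate(mol_atoms)
    counts = np.array([len(a) for a in mol_atoms])
    owner = np.repeat(np.arange(len(mol_atoms)), counts)
    out = np.zeros((traj.n_frames, len(mol_atoms)), dtype=bool)
    for f in range(traj.n_frames):
        frame = traj.coordinates[f]
        box = traj.frame_box(f)
        tgt = frame[target_atoms]
        pts = frame[flat]
        if box is not None:
            tree = cKDTree(np.mod(tgt, box), boxsize=box)
            n = tree.query_ball_point(np.mod(pts, box), r=cutoff,
                                      return_length=True)
        else:
            tree = cKDTree(tgt)
            n = tree.query_ball_point(pts, r=cutoff, return_length=True)
        hit = n > 0
        np.logical_or.at(out[f], owner, hit)
    return out


def residence_events(traj: Trajectory, system: MolecularSystem,
                     species: str = "urea", target=None, cutoff: float = 3.5,
                     gap_tolerance_frames: int = 0) -> list[ResidenceEvent]:
    """Maximal contact runs of each solvent molecule with the target.

    ``target`` is an atom-index set (default: all protein heavy atoms).
    Runs separated by gaps of at most ``gap_tolerance_frames`` are merged.
    """
    mols = system.solvent_molecules(species=species)
    if not mols:
        return []
    mol_atoms = [system.atoms_of_residue(m.index) for m in mols]
    target_atoms = (system.protein_heavy_indices() if target is None
                    else np.asarray(list(target), dtype=np.intp))
    dt = traj.dt_ns
    contact = _contact_matrix(traj, system, mol_atoms, target_atoms, cutoff)
    events = []
    for m, mol in enumerate(mols):
        col = contact[:, m]
        frames = np.flatnonzero(col)
        if frames.size == 0:
            continue
        # merge runs across tolerated gaps
        breaks = np.flatnonzero(np.diff(frames) > gap_tolerance_frames + 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [frames.size - 1]])
        for s, e in zip(starts, ends):
            f0, f1 = int(frames[s]), int(frames[e])
            n = f1 - f0 + 1
            events.append(ResidenceEvent(
                molecule_residue=mol.index, species=species,
                start_ns=float(traj.times[f0]),
                end_ns=float(traj.times[f0]) + n * dt,
                duration_ns=n * dt, start_frame=f0, n_frames=n))
    return events


def long_residence_report(traj: Trajectory, system: MolecularSystem,
                          events: list[ResidenceEvent], min_duration_ns: float,
                          cutoff: float = 3.5):
    """Urea molecules with any residence event >= min_duration, ranked by
    their longest event, each with a (residue, frame) contact dot-map."""
    best: dict[int, float] = {}
    for ev in events:
        if ev.duration_ns >= min_duration_ns:
            best[ev.molecule_residue] = max(best.get(ev.molecule_residue, 0.0),
                                            ev.duration_ns)
    ranked = sorted(best, key=lambda m: -best[m])
    prot_heavy = system.protein_heavy_indices()
    res_of_heavy = system.atom_residue_index[prot_heavy]
    report = []
    for mol in ranked:
        mol_atoms = system.atoms_of_residue(mol)
        dots = []
        for f in range(traj.n_frames):
            frame = traj.coordinates[f]
            box = traj.frame_box(f)
            tgt = frame[prot_heavy]
            pts = frame[mol_atoms]
            if box is not None:
                tree = cKDTree(np.mod(tgt, box), boxsize=box)
                hits = tree.query_ball_point(np.mod(pts, box), r=cutoff)
            else:
                tree = cKDTree(tgt)
                hits = tree.query_ball_point(pts, r=cutoff)
            res = {int(res_of_heavy[j]) for h in hits for j in h}
            dots.extend((r, f) for r in sorted(res))
        report.append({"molecule_residue": mol, "longest_ns": best[mol],
                       "dots": dots})
    return report


# ---------------------------------------------------------------------------
# nonbonded energy decomposition

def nonbonded_energy(frame: np.ndarray, params: NonbondedParams,
                     group_a, group_b, cutoff: float = 9.0,
                     box: np.ndarray | None = None):
    """Direct-sum Coulomb and Lennard-Jones energy between two atom groups.

    elec = sum 332.0636 q_i q_j / r_ij; vdw = sum 4 eps_ij [(sig_ij/r)^12 -
    (sig_ij/r)^6] with Lorentz-Berthelot mixing, over pairs with r <= cutoff.
    Approximate relative energies (no Ewald, no long-range correction).
    """
    ia = np.asarray(list(group_a), dtype=np.intp)
    ib = np.asarray(list(group_b), dtype=np.intp)
    if np.intersect1d(ia, ib).size:
        raise ValueError("groups must be disjoint")
    frame = np.asarray(frame, dtype=float)
    pa, pb = frame[ia], frame[ib]
    if box is not None:
        box = np.asarray(box, dtype=float)
        tree = cKDTree(np.mod(pb, box), boxsize=box)
        nbrs = tree.query_ball_point(np.mod(pa, box), r=cutoff)
    else:
        tree = cKDTree(pb)
        nbrs = tree.query_ball_point(pa, r=cutoff)
    elec = vdw = 0.0
    for k, nb in enumerate(nbrs):
        if not nb:
            continue
        j = ib[np.asarray(nb, dtype=np.intp)]
        d = pb[np.asarray(nb, dtype=np.intp)] - pa[k]
        if box is not None:
            d -= box * np.round(d / box)
        r = np.sqrt(np.sum(d * d, axis=1))
        if np.any(r < 0.1):
            raise ValueError("atomic clash: pair distance below 0.1 Angstrom")
        i = ia[k]
        elec += COULOMB_CONSTANT * params.charge[i] * np.sum(params.charge[j] / r)
        sig = 0.5 * (params.sigma[i] + params.sigma[j])
        eps = np.sqrt(params.epsilon[i] * params.epsilon[j])
        sr6 = (sig / r) ** 6
        vdw += float(np.sum(4.0 * eps * (sr6 ** 2 - sr6)))
    return float(elec), float(vdw)
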