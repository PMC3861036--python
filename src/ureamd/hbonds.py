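"""Geometric hydrogen-bond detection between solvent and protein.

A bond is detected when the donor-acceptor heavy-atom distance is at most
3.50 Angstrom and the donor-H-acceptor angle is at least 120 degrees (bonds
more linear than 120 degrees accepted; tools differ on this convention, so
it is a switch).  Occupancy filtering keeps bonds whose total detected time
exceeds 0.5 ns, and the partition reports urea vs water, donor vs acceptor
and backbone vs side-chain fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.spatial import cKDTree

from .contacts import run_lengths
from .system import MolecularSystem, Trajectory

__all__ = [
    "HBondKey",
    "HBondRecord",
    "donors_and_acceptors",
    "detect_hbonds",
    "hbond_occupancy",
    "hbond_partition",
]


class HBondKey(NamedTuple):
    donor: int  # atom index of the donor heavy atom (N or O)
    acceptor: int  # atom index of the acceptor heavy atom
    donor_side: str  # protein | urea | water
    acceptor_side: str  # protein | urea | water
    protein_part: str  # backbone | sidechain | n/a


@dataclass
class HBondRecord:
    key: HBondKey
    total_ns: float
    longest_ns: float
    retained: bool

    @property
    def solvent_species(self) -> str | None:
        if self.key.donor_side in ("urea", "water"):
            return self.key.donor_side
        if self.key.acceptor_side in ("urea", "water"):
            return self.key.acceptor_side
        return None

    @property
    def solvent_is_donor(self) -> bool:
        return self.key.donor_side in ("urea", "water")


def _attach_hydrogens(system: MolecularSystem, frame: np.ndarray,
                      max_bond: float = 1.25) -> dict[int, list[int]]:
    """Map each N/O heavy atom to its covalently attached hydrogens.

    Attachment is geometric (nearest N/O host within the same residue, bond
    length below ``max_bond`` Angstrom) from the given frame; rigid solvent
    molecules keep the mapping valid for a whole trajectory.
    """
    attached: dict[int, list[int]] = {}
    for res in system.residues:
        idx = res.atom_indices
        hyd = [i for i in idx if not system.atoms[i].is_heavy]
        hosts = [i for i in idx if system.atoms[i].element.upper() in ("N", "O")]
        if not hyd or not hosts:
            continue
        hostpos = frame[np.asarray(hosts, dtype=np.intp)]
        for h in hyd:
            d = np.linalg.norm(hostpos - frame[h], axis=1)
            k = int(np.argmin(d))
            if d[k] < max_bond:
                attached.setdefault(hosts[k], []).append(h)
    return attached


def _reconstruct_backbone_h(system: MolecularSystem, frame: np.ndarray,
                            n_atom: int) -> np.ndarray | None:
    """Amide H on the bisector opposite C(prev)-N-CA, 1.01 Angstrom from N."""
    res = system.residues[system.atoms[n_atom].residue_index]
    if res.index == 0:
        return None
    prev = system.residues[res.index - 1]
    if prev.species != "protein" or prev.chain != res.chain:
        return None
    c_prev = ca = None
    for ai in prev.atom_indices:
        if system.atoms[ai].name.upper() == "C":
            c_prev = frame[ai]
    for ai in res.atom_indices:
        if system.atoms[ai].name.upper() == "CA":
            ca = frame[ai]
    if c_prev is None or ca is None:
        return None
    npos = frame[n_atom]
    u = (npos - c_prev) / np.linalg.norm(npos - c_prev) \
        + (npos - ca) / np.linalg.norm(npos - ca)
    norm = np.linalg.norm(u)
    if norm < 1e-8:
        return None
    return npos + 1.01 * u / norm


def donors_and_acceptors(system: MolecularSystem, frame: np.ndarray,
                         reconstruct_backbone_h: bool = True):
    """(donors, acceptors): donor atom -> H positions; acceptor atom list.

    Donors are N/O atoms with at least one attached hydrogen (protein
    backbone N gets a geometrically reconstructed amide H when the file has
    none); acceptors are all N/O heavy atoms.  Sulfur is excluded.
    """
    frame = np.asarray(frame, dtype=float)
    attached = _attach_hydrogens(system, frame)
    donors: dict[int, list[np.ndarray]] = {}
    acceptors: list[int] = []
    for i, atom in enumerate(system.atoms):
        if not atom.is_heavy or atom.element.upper() not in ("N", "O"):
            continue
        acceptors.append(i)
        hs = attached.get(i, [])
        if hs:
            donors[i] = [frame[h] for h in hs]
        elif (reconstruct_backbone_h and atom.role == "backbone"
              and atom.name.upper() == "N"):
            hpos = _reconstruct_backbone_h(system, frame, i)
            if hpos is not None:
                donors[i] = [hpos]
    return donors, acceptors


def _key_for(system: MolecularSystem, donor: int, acceptor: int) -> HBondKey:
    d_sp = str(system.atom_species[donor])
    a_sp = str(system.atom_species[acceptor])
    part = "n/a"
    if d_sp == "protein":
        part = system.atoms[donor].role
    elif a_sp == "protein":
        part = system.atoms[acceptor].role
    return HBondKey(donor, acceptor, d_sp, a_sp, part)


def detect_hbonds(frame: np.ndarray, system: MolecularSystem,
                  dist_cutoff: float = 3.50, angle_cutoff_deg: float = 120.0,
                  between: str = "solvent-protein",
                  angle_convention: str = "DHA",
                  reconstruct_backbone_h: bool = True) -> list[HBondKey]:
    """Geometric hydrogen bonds in one frame.

    ``between='solvent-protein'`` (default) keeps bonds with one side on the
    protein and the other on water/urea; ``'all'`` considers every
    inter-residue donor/acceptor pair.  ``angle_convention``: 'DHA' accepts
    donor-H-acceptor angles >= cutoff (more linear); 'HDA' accepts
    H-donor-acceptor angles <= 180 - cutoff (the equivalent bent-angle form).
    """
    frame = np.asarray(frame, dtype=float)
    donors, acceptors = donors_and_acceptors(
        system, frame, reconstruct_backbone_h=reconstruct_backbone_h)
    if not donors:
        raise ValueError("no donor with a hydrogen or a reconstruction rule")
    acc = np.asarray(acceptors, dtype=np.intp)
    tree = cKDTree(frame[acc])
    out = []
    species = system.atom_species
    for d_atom, h_list in donors.items():
        d_res_idx = system.atom_residue_index[d_atom]
        d_sp = species[d_atom]
        for k in tree.query_ball_point(frame[d_atom], r=dist_cutoff):
            a_atom = int(acc[k])
            if system.atom_residue_index[a_atom] == d_res_idx:
                continue
            if between == "solvent-protein":
                pair = {d_sp, species[a_atom]}
                if "protein" not in pair or not pair & {"water", "urea"}:
                    continue
            for hpos in h_list:
                if angle_convention == "DHA":
                    u = frame[d_atom] - hpos
                    w = frame[a_atom] - hpos
                else:  # HDA
                    u = hpos - frame[d_atom]
                    w = frame[a_atom] - frame[d_atom]
                nu, nw = np.linalg.norm(u), np.linalg.norm(w)
                if nu < 1e-8 or nw < 1e-8:
                    continue
                ang = np.degrees(np.arccos(np.clip(np.dot(u, w) / (nu * nw),
                                                   -1.0, 1.0)))
                ok = (ang >= angle_cutoff_deg if angle_convention == "DHA"
                      else ang <= 180.0 - angle_cutoff_deg)
                if ok:
                    out.append(_key_for(system, d_atom, a_atom))
                    break
    return out


def hbond_occupancy(traj: Trajectory, system: MolecularSystem,
                    min_occupancy_ns: float = 0.5,
                    **detect_kwargs) -> list[HBondRecord]:
    """Total time and longest continuous lifetime per hydrogen bond.

    A bond is retained when its total time strictly exceeds the occupancy
    threshold (default 0.5 ns).
    """
    dt = traj.dt_ns
    presence: dict[HBondKey, list[int]] = {}
    for f in range(traj.n_frames):
        for key in set(detect_hbonds(traj.coordinates[f], system,
                                     **detect_kwargs)):
            presence.setdefault(key, []).append(f)
    records = []
    for key, frames in sorted(presence.items()):
        mask = np.zeros(traj.n_frames, dtype=bool)
        mask[frames] = True
        runs = run_lengths(mask)
        total = len(frames) * dt
        records.append(HBondRecord(key, total, max(runs) * dt,
                                   retained=total > min_occupancy_ns))
    return records


def hbond_partition(records: list[HBondRecord], retained_only: bool = True):
    """Partition of the solvent-protein hydrogen-bond population.

    Returns counts plus: urea/water percentage of all solvent-protein bonds;
    per species, the percentage in which the solvent acts as hydrogen donor
    vs acceptor; and the backbone vs side-chain split of the protein partner.
    All partitions sum to 100% within rounding.
    """
    bonds = [r for r in records
             if (r.retained or not retained_only) and r.solvent_species]
    if not bonds:
        raise ValueError("empty solvent-protein hydrogen-bond set")
    count = {"urea": 0, "water": 0}
    detail = {s: {"donor": 0, "acceptor": 0, "backbone": 0, "sidechain": 0}
              for s in ("urea", "water")}
    for r in bonds:
        sp = r.solvent_species
        count[sp] += 1
        detail[sp]["donor" if r.solvent_is_donor else "acceptor"] += 1
        if r.key.protein_part in ("backbone", "sidechain"):
            detail[sp][r.key.protein_part] += 1
    total = count["urea"] + count["water"]
    result = {
        "n_bonds": total,
        "counts": dict(count),
        "urea_pct": 100.0 * count["urea"] / total,
        "water_pct": 100.0 * count["water"] / total,
        "by_species": {},
    }
    for sp in ("urea", "water"):
        n = count[sp]
        d = detail[sp]
        result["by_species"][sp] = {
            "n": n,
            "donor_pct": 100.0 * d["donor"] / n if n else float("nan"),
            "acceptor_pct": 100.0 * d["acceptor"] / n if n else float("nan"),
            "backbone_pct": 100.0 * d["backbone"] / n if n else float("nan"),
            "sidechain_pct": 100.0 * d["sidechain"] / n if n else float("nan"),
        }
    return result
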