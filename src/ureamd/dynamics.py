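"""Flexibility and transport metrics.

RMSF about the mean structure (with optional superposition), the pseudo
B-factor scaling B = (8 pi^2 / 3) RMSF^2, side-chain stiffness comparison
between two conditions, time-lag RMSD, solvent mean square displacement and
the Einstein-relation diffusion coefficient D = slope/6 of the MSD line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .metrics import kabsch_superpose
from .system import MolecularSystem, Trajectory, minimum_image_displacement

__all__ = [
    "rmsf",
    "bfactor_scale",
    "bfactor_to_rmsf",
    "sidechain_stiffness_compare",
    "timelag_rmsd",
    "msd_curve",
    "diffusion_coefficient",
    "MSDCurve",
    "DiffusionFit",
]

_B_SCALE = 8.0 * np.pi ** 2 / 3.0


@dataclass
class MSDCurve:
    lags_ns: np.ndarray
    msd: np.ndarray  # Angstrom^2
    n_samples: np.ndarray


@dataclass
class DiffusionFit:
    D: float  # Angstrom^2 / ns
    slope: float
    intercept: float
    r_squared: float
    fit_lags_ns: np.ndarray
    flagged: bool  # True when the fitted slope is negative


def _superposed_coords(traj: Trajectory, sel: np.ndarray,
                       fit_sel: np.ndarray | None = None) -> np.ndarray:
    """Frames superposed (on fit_sel, default sel) onto the mean structure."""
    fit = sel if fit_sel is None else fit_sel
    ref = traj.coordinates[0]
    aligned = np.empty((traj.n_frames, traj.n_atoms, 3))
    for f in range(traj.n_frames):
        R, t, _ = kabsch_superpose(ref[fit], traj.coordinates[f][fit])
        aligned[f] = traj.coordinates[f] @ R.T + t
    mean = aligned.mean(axis=0)
    for f in range(traj.n_frames):
        R, t, _ = kabsch_superpose(mean[fit], aligned[f][fit])
        aligned[f] = aligned[f] @ R.T + t
    return aligned


def rmsf(traj: Trajectory, system: MolecularSystem, selection=None,
         superpose: bool = True, per_residue: bool = True):
    """Root-mean-square fluctuation about the mean position.

    Per residue, the value is the mass-unweighted mean of the atomic RMSF
    over the residue's heavy atoms.  Returns a dict residue->RMSF when
    ``per_residue`` else an array over the selection.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    sel = (system.protein_heavy_indices() if selection is None
           else np.asarray(list(selection), dtype=np.intp))
    coords = (_superposed_coords(traj, sel) if superpose
              else traj.coordinates)
    x = coords[:, sel, :]
    mean = x.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=2), axis=0))
    if not per_residue:
        return per_atom
    res_of = system.atom_residue_index[sel]
    out: dict[int, float] = {}
    for r in np.unique(res_of):
        out[int(r)] = float(per_atom[res_of == r].mean())
    return out


def bfactor_scale(rmsf_values):
    """Pseudo B-factor B = (8 pi^2 / 3) RMSF^2 (Angstrom^2)."""
    v = np.asarray(rmsf_values, dtype=float)
    if np.any(v < 0):
        raise ValueError("RMSF must be non-negative")
    return _B_SCALE * v ** 2


def bfactor_to_rmsf(b_values):
    """Inverse transform of :func:`bfactor_scale`."""
    v = np.asarray(b_values, dtype=float)
    if np.any(v < 0):
        raise ValueError("B-factors must be non-negative")
    return np.sqrt(v / _B_SCALE)


def sidechain_stiffness_compare(traj_a: Trajectory, traj_b: Trajectory,
                                system: MolecularSystem):
    """Fraction of residues whose side chain fluctuates less in condition a.

    Both trajectories are superposed on the protein backbone; per residue the
    side-chain heavy-atom RMSF is compared, 'stiffer in a' meaning strictly
    smaller RMSF.  Returns (fraction, per-residue table of (rmsf_a, rmsf_b)).
    """
    bb = np.flatnonzero(system.backbone_mask & system.heavy_mask)
    sc = np.flatnonzero(~system.backbone_mask & system.heavy_mask
                        & system.protein_atom_mask)
    if sc.size == 0:
        raise ValueError("no side-chain heavy atoms (glycine-only selection?)")

    def _sc_rmsf(traj):
        coords = _superposed_coords(traj, sc, fit_sel=bb)
        x = coords[:, sc, :]
        mean = x.mean(axis=0)
        per_atom = np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=2), axis=0))
        res_of = system.atom_residue_index[sc]
        return {int(r): float(per_atom[res_of == r].mean())
                for r in np.unique(res_of)}

    ra, rb = _sc_rmsf(traj_a), _sc_rmsf(traj_b)
    table = {r: (ra[r], rb[r]) for r in ra}
    stiffer = sum(1 for r in table if table[r][0] < table[r][1])
    return stiffer / len(table), table


def timelag_rmsd(traj: Trajectory, lags_ns, selection=None,
                 superpose: bool = True):
    """Mean RMSD between frames separated by each lag.

    The reference structure is always the first frame of the window; the
    average runs over all window starts.  Returns (lags_ns, mean_rmsd).
    """
    lags_ns = np.asarray(lags_ns, dtype=float)
    dt = traj.dt_ns
    if np.any(lags_ns >= traj.duration_ns + dt / 2):
        raise ValueError("lag must be smaller than the trajectory duration")
    sel = (np.arange(traj.n_atoms) if selection is None
           else np.asarray(list(selection), dtype=np.intp))
    out = np.empty(len(lags_ns))
    for li, lag in enumerate(lags_ns):
        k = int(round(lag / dt))
        if k < 1:
            out[li] = 0.0
            continue
        vals = []
        for t in range(traj.n_frames - k):
            a = traj.coordinates[t][sel]
            b = traj.coordinates[t + k][sel]
            if superpose:
                _, _, r = kabsch_superpose(a, b)
            else:
                r = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
            vals.append(r)
        out[li] = float(np.mean(vals))
    return lags_ns, out


def _molecule_com_series(traj: Trajectory, system: MolecularSystem,
                         species: str, use_com: bool = True,
                         unwrap: bool = False) -> np.ndarray:
    mols = system.solvent_molecules(species=species)
    if not mols:
        raise ValueError(f"no {species} molecules in the system")
    if use_com:
        pos = np.stack([traj.coordinates[:, system.atoms_of_residue(m.index), :]
                        .mean(axis=1) for m in mols], axis=1)
    else:
        first = [system.atoms_of_residue(m.index)[0] for m in mols]
        pos = traj.coordinates[:, np.asarray(first, dtype=np.intp), :]
    if unwrap:
        if traj.box is None:
            raise ValueError("cannot unwrap without a box")
        steps = np.diff(pos, axis=0)
        for f in range(steps.shape[0]):
            steps[f] = minimum_image_displacement(steps[f], traj.box[f])
            if np.any(np.abs(steps[f]) > traj.box[f] / 2 - 1e-9):
                raise ValueError("molecule moved more than box/2 per frame; "
                                 "cannot unwrap reliably")
        pos = np.concatenate([pos[:1], pos[:1] + np.cumsum(steps, axis=0)])
    return pos  # (n_frames, n_molecules, 3)


def msd_curve(traj: Trajectory, system: MolecularSystem, species: str,
              lags_ns, use_com: bool = True, unwrap: bool = False) -> MSDCurve:
    """Mean square displacement over molecules and all overlapping origins.

    Coordinates are assumed unwrapped (the synthetic generator emits
    unwrapped solvent); pass ``unwrap=True`` for wrapped input with a box.
    """
    pos = _molecule_com_series(traj, system, species, use_com, unwrap)
    dt = traj.dt_ns
    lags_ns = np.asarray(lags_ns, dtype=float)
    msd = np.empty(len(lags_ns))
    n_samples = np.empty(len(lags_ns), dtype=int)
    for li, lag in enumerate(lags_ns):
        k = int(round(lag / dt))
        if k == 0:
            msd[li], n_samples[li] = 0.0, pos.shape[0] * pos.shape[1]
            continue
        if k >= pos.shape[0]:
            raise ValueError(f"lag {lag} ns exceeds trajectory duration")
        disp = pos[k:] - pos[:-k]
        msd[li] = float(np.mean(np.sum(disp ** 2, axis=2)))
        n_samples[li] = disp.shape[0] * disp.shape[1]
    return MSDCurve(lags_ns, msd, n_samples)


def diffusion_coefficient(msd: MSDCurve,
                          fit_range: tuple[float, float] = (0.1, 0.5)) -> DiffusionFit:
    """Einstein-relation diffusion coefficient D = slope/6 (Angstrom^2/ns).

    The least-squares line is fitted over the stated fraction interval of the
    maximum lag (default 10-50%, avoiding the ballistic start and the poorly
    sampled tail); slope, intercept and R^2 are reported as diagnostics.
    """
    lags = msd.lags_ns
    lo, hi = fit_range
    max_lag = lags.max()
    mask = (lags >= lo * max_lag) & (lags <= hi * max_lag)
    if mask.sum() < 3:
        raise ValueError("need at least 3 lag points in the fit range")
    fit = stats.linregress(lags[mask], msd.msd[mask])
    D = fit.slope / 6.0
    return DiffusionFit(D=float(D), slope=float(fit.slope),
                        intercept=float(fit.intercept),
                        r_squared=float(fit.rvalue ** 2),
                        fit_lags_ns=lags[mask], flagged=bool(fit.slope < 0))
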