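"""Per-frame global structure descriptors.

RMSD (Kabsch superposition), radius of gyration, Shrake-Rupley SASA with a
water-reference normalisation and a polar/apolar split, TM-score, a
simplified three-state secondary-structure assignment (Kabsch-Sander
hydrogen-bond energy), the native secondary-structure index S2, and the
global structure index combining S2 with the native-contact index S3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .system import MolecularSystem, Trajectory

__all__ = [
    "MetricSeries",
    "kabsch_superpose",
    "rmsd_series",
    "radius_of_gyration",
    "rg_series",
    "sasa",
    "sasa_series",
    "sasa_partition",
    "sasa_normalize",
    "tm_score",
    "assign_ss",
    "assign_ss_series",
    "s2_index",
    "structure_index",
    "BONDI_RADII",
]

#: Bondi van der Waals radii (Angstrom), the standard Shrake-Rupley table.
BONDI_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
               "P": 1.80, "X": 1.70, "Na": 2.27, "Cl": 1.75, "K": 2.75}


@dataclass
class MetricSeries:
    name: str
    values: np.ndarray
    times: np.ndarray
    units: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.values) != len(self.times):
            raise ValueError("values and times must have equal length")
        if not self.units:
            raise ValueError("units must be non-empty")


# ---------------------------------------------------------------------------
# superposition

def kabsch_superpose(reference: np.ndarray, mobile: np.ndarray,
                     weights: np.ndarray | None = None):
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (det = +1); ``rotation @ x + translation`` maps mobile points onto the
    reference frame.  Two points are the accepted minimum (the rotation is
    then degenerate but the RMSD is still the rigid-body optimum).
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape:
        raise ValueError("point-count mismatch between reference and mobile")
    if ref.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if weights is None:
        w = np.ones(ref.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape[0] != ref.shape[0] or np.any(w < 0) or w.sum() == 0:
            raise ValueError("invalid weights")
    wsum = w.sum()
    ref_c = (w[:, None] * ref).sum(0) / wsum
    mob_c = (w[:, None] * mob).sum(0) / wsum
    P = (mob - mob_c) * w[:, None]
    Q = ref - ref_c
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_c - R @ mob_c
    moved = (R @ mob.T).T + t
    rmsd = float(np.sqrt(np.sum(w * np.sum((moved - ref) ** 2, axis=1)) / wsum))
    return R, t, rmsd


def rmsd_series(traj: Trajectory, reference: np.ndarray,
                selection: np.ndarray) -> MetricSeries:
    """Kabsch RMSD of each frame against a reference frame, on ``selection``."""
    sel = np.asarray(list(selection), dtype=np.intp)
    if sel.size == 0:
        raise ValueError("empty selection")
    ref = np.asarray(reference, dtype=float)[sel]
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, values[f] = kabsch_superpose(ref, traj.coordinates[f][sel])
    return MetricSeries("RMSD", values, traj.times, "Angstrom")


# ---------------------------------------------------------------------------
# radius of gyration

def radius_of_gyration(frame: np.ndarray, selection=None,
                       weights: np.ndarray | None = None) -> float:
    frame = np.asarray(frame, dtype=float)
    if selection is not None:
        sel = np.asarray(list(selection), dtype=np.intp)
        if sel.size == 0:
            raise ValueError("empty selection")
        frame = frame[sel]
        if weights is not None:
            weights = np.asarray(weights, dtype=float)
            if len(weights) != sel.size:
                weights = weights[sel]
    if frame.shape[0] == 0:
        raise ValueError("empty selection")
    w = np.ones(frame.shape[0]) if weights is None else np.asarray(weights, float)
    com = (w[:, None] * frame).sum(0) / w.sum()
    return float(np.sqrt(np.sum(w * np.sum((frame - com) ** 2, axis=1)) / w.sum()))


def rg_series(traj: Trajectory, system: MolecularSystem,
              selection=None, mass_weighted: bool = False) -> MetricSeries:
    sel = (system.protein_heavy_indices() if selection is None
           else np.asarray(list(selection), dtype=np.intp))
    w = system.masses[sel] if mass_weighted else None
    values = np.array([radius_of_gyration(traj.coordinates[f], sel, w)
                       for f in range(traj.n_frames)])
    return MetricSeries("RadGyr", values, traj.times, "Angstrom")


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley)

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def sasa(frame: np.ndarray, system: MolecularSystem, probe: float = 1.4,
         n_points: int = 960, radii: dict | None = None,
         selection=None) -> np.ndarray:
    """Shrake-Rupley solvent-accessible surface area, per atom (Angstrom^2).

    Computed on heavy atoms only (hydrogens are absorbed into heavy-atom
    radii); the returned array has one entry per atom of the system, zero for
    hydrogens and non-selected atoms.
    """
    radii = BONDI_RADII if radii is None else radii
    frame = np.asarray(frame, dtype=float)
    if selection is None:
        sel = np.flatnonzero(system.heavy_mask & system.protein_atom_mask)
        if sel.size == 0:  # non-protein toy systems: all heavy atoms
            sel = system.heavy_indices()
    else:
        sel = np.asarray(list(selection), dtype=np.intp)
        sel = sel[system.heavy_mask[sel]]
    missing = sorted({system.atoms[i].element for i in sel
                      if system.atoms[i].element not in radii})
    if missing:
        raise KeyError(f"missing van der Waals radius for element(s): {missing}")
    r = np.array([radii[system.atoms[i].element] for i in sel]) + probe
    pos = frame[sel]
    unit = _sphere_points(n_points)
    tree = cKDTree(pos)
    out = np.zeros(system.n_atoms)
    max_r = r.max()
    for k in range(sel.size):
        nbrs = [j for j in tree.query_ball_point(pos[k], r[k] + max_r)
                if j != k]
        pts = pos[k] + r[k] * unit
        if nbrs:
            nb = np.asarray(nbrs, dtype=np.intp)
            d2 = np.sum((pts[:, None, :] - pos[nb][None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < (r[nb] ** 2)[None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[sel[k]] = frac * 4.0 * np.pi * r[k] ** 2
    return out


def sasa_series(traj: Trajectory, system: MolecularSystem, **kwargs) -> MetricSeries:
    values = np.array([sasa(traj.coordinates[f], system, **kwargs).sum()
                       for f in range(traj.n_frames)])
    return MetricSeries("SASA", values, traj.times, "Angstrom^2")


def sasa_partition(per_atom: np.ndarray, system: MolecularSystem):
    """(total, polar, apolar, per-residue) protein SASA.

    Polar collects residues classed polar or charged; apolar the hydrophobic
    ones — the split is by residue class, not per-atom chemistry.
    """
    per_atom = np.asarray(per_atom, dtype=float)
    per_residue = {}
    total = polar = apolar = 0.0
    for res in system.residues:
        if res.species != "protein":
            continue
        area = float(per_atom[np.asarray(res.atom_indices, dtype=np.intp)].sum())
        per_residue[res.index] = area
        total += area
        if res.polarity_class == "hydrophobic":
            apolar += area
        else:
            polar += area
    return total, polar, apolar, per_residue


def sasa_normalize(series: MetricSeries, water_reference: MetricSeries) -> MetricSeries:
    """Divide a SASA series by the mean of the water-condition reference."""
    if len(water_reference.values) == 0:
        raise ValueError("empty water reference")
    mean = float(np.mean(water_reference.values))
    if mean == 0:
        raise ValueError("zero reference mean")
    return MetricSeries(series.name + "_norm", series.values / mean,
                        series.times, "dimensionless")


# ---------------------------------------------------------------------------
# TM-score

def _tm_d0(L: int) -> float:
    return 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8


def tm_score(reference_ca: np.ndarray, model_ca: np.ndarray,
             refine: bool = True, superpose: bool = True) -> float:
    """Length-normalised structural similarity in (0, 1].

    TM = (1/L) sum 1/(1+(d_i/d0)^2), d0 = 1.24 (L-15)^(1/3) - 1.8.  The
    superposition is Kabsch on all CA; with ``refine`` the superposition is
    iteratively recomputed on the residues closer than d0 and the best score
    found is returned (a lower bound of the exhaustive optimum).
    """
    ref = np.asarray(reference_ca, dtype=float)
    mod = np.asarray(model_ca, dtype=float)
    if ref.shape != mod.shape:
        raise ValueError("CA trace length mismatch")
    L = ref.shape[0]
    if L < 16:
        raise ValueError("TM-score requires at least 16 residues (d0 > 0)")
    d0 = _tm_d0(L)

    def score_at(R, t):
        moved = (R @ mod.T).T + t
        d = np.linalg.norm(moved - ref, axis=1)
        return float(np.mean(1.0 / (1.0 + (d / d0) ** 2))), d

    if not superpose:
        d = np.linalg.norm(mod - ref, axis=1)
        return float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))

    R, t, _ = kabsch_superpose(ref, mod)
    best, d = score_at(R, t)
    if refine:
        thresh = max(d0, 3.0)
        prev_sel: frozenset = frozenset()
        for _ in range(20):
            sel = np.flatnonzero(d < thresh)
            if sel.size < 3 or frozenset(sel.tolist()) == prev_sel:
                break
            prev_sel = frozenset(sel.tolist())
            R, t, _ = kabsch_superpose(ref[sel], mod[sel])
            s, d = score_at(R, t)
            if s > best:
                best = s
            else:
                break
    return min(best, 1.0)


# ---------------------------------------------------------------------------
# secondary structure (simplified Kabsch-Sander DSSP, 3 states)

_KS_Q = 0.084 * 332.0  # kcal/mol * Angstrom
_HB_ENERGY_CUT = -0.5


def _backbone_arrays(system: MolecularSystem, frame: np.ndarray):
    """Per protein residue: N, CA, C, O coordinates (NaN when missing)."""
    prot = [r for r in system.residues if r.species == "protein"]
    n = len(prot)
    out = {name: np.full((n, 3), np.nan) for name in ("N", "CA", "C", "O")}
    chains = np.empty(n, dtype=object)
    for k, res in enumerate(prot):
        chains[k] = res.chain
        for ai in res.atom_indices:
            a = system.atoms[ai]
            if a.name.upper() in out:
                out[a.name.upper()][k] = frame[ai]
    return prot, out, chains


def _ks_hbond_matrix(Ncrd, CAcrd, Ccrd, Ocrd, chains):
    """hb[a, d] True when C=O of residue a accepts the N-H of residue d."""
    n = Ncrd.shape[0]
    hb = np.zeros((n, n), dtype=bool)
    # amide H reconstructed on the N-H bisector opposite C(prev) and CA
    H = np.full((n, 3), np.nan)
    for i in range(1, n):
        if chains[i] != chains[i - 1]:
            continue
        v1 = Ncrd[i] - Ccrd[i - 1]
        v2 = Ncrd[i] - CAcrd[i]
        if np.any(np.isnan(v1)) or np.any(np.isnan(v2)):
            continue
        u = v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2)
        nu = np.linalg.norm(u)
        if nu > 1e-8:
            H[i] = Ncrd[i] + u / nu * 1.01
    valid_ca = ~np.isnan(CAcrd[:, 0])
    tree = cKDTree(np.where(valid_ca[:, None], CAcrd, 1e6))
    pairs = tree.query_pairs(9.0, output_type="ndarray")
    for i, j in pairs:
        for a, d in ((i, j), (j, i)):
            if abs(a - d) < 2 or np.any(np.isnan(H[d])) or np.any(np.isnan(Ocrd[a])):
                continue
            r_on = np.linalg.norm(Ocrd[a] - Ncrd[d])
            r_ch = np.linalg.norm(Ccrd[a] - H[d])
            r_oh = np.linalg.norm(Ocrd[a] - H[d])
            r_cn = np.linalg.norm(Ccrd[a] - Ncrd[d])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue
            E = _KS_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if E < _HB_ENERGY_CUT:
                hb[a, d] = True
    return hb


def assign_ss(frame: np.ndarray, system: MolecularSystem) -> np.ndarray:
    """Three-state secondary structure {H, E, C} per protein residue.

    Hydrogen bonds use the Kabsch-Sander electrostatic energy with a
    -0.5 kcal/mol threshold and a reconstructed amide hydrogen; helices from
    consecutive i -> i+4 turns, strands from bridge ladders of length >= 2.
    Residues with missing backbone atoms are labelled C with a warning.
    """
    prot, bb, chains = _backbone_arrays(system, np.asarray(frame, dtype=float))
    n = len(prot)
    labels = np.full(n, "C", dtype="<U1")
    if n == 0:
        return labels
    missing = np.zeros(n, dtype=bool)
    for name in ("N", "CA", "C", "O"):
        missing |= np.isnan(bb[name][:, 0])
    if np.any(missing):
        warnings.warn(f"{int(missing.sum())} protein residue(s) lack full "
                      "backbone; labelled C", stacklevel=2)
    if n < 5:
        return labels
    hb = _ks_hbond_matrix(bb["N"], bb["CA"], bb["C"], bb["O"], chains)

    # helices: two consecutive 4-turns (CO of i accepts NH of i+4)
    turn4 = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        if chains[i] == chains[i + 4]:
            turn4[i] = hb[i, i + 4]
    helix = np.zeros(n, dtype=bool)
    for i in range(1, n - 4):
        if turn4[i - 1] and turn4[i]:
            helix[i:i + 4] = True

    # beta bridges (Kabsch-Sander parallel/antiparallel rules)
    bridges = set()
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            anti = (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1])
            para = (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1])
            if anti or para:
                bridges.add((i, j))
    strand = np.zeros(n, dtype=bool)
    for (i, j) in bridges:
        ladder = any(b in bridges for b in
                     ((i + 1, j - 1), (i - 1, j + 1), (i + 1, j + 1), (i - 1, j - 1)))
        if ladder:
            strand[i] = strand[j] = True
    labels[strand] = "E"
    labels[helix] = "H"  # helix takes precedence
    labels[missing] = "C"
    return labels


def assign_ss_series(traj: Trajectory, system: MolecularSystem) -> np.ndarray:
    """(n_frames, n_protein_residues) array of {H, E, C} labels."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.stack([assign_ss(traj.coordinates[f], system)
                         for f in range(traj.n_frames)])


def s2_index(current: np.ndarray, native: np.ndarray) -> float:
    """Fraction of natively H/E residues keeping their native label."""
    current = np.asarray(current)
    native = np.asarray(native)
    if current.shape != native.shape:
        raise ValueError("residue-set mismatch")
    mask = (native == "H") | (native == "E")
    if not np.any(mask):
        warnings.warn("no native H/E residues; S2 degenerate, returning 1",
                      stacklevel=2)
        return 1.0
    return float(np.mean(current[mask] == native[mask]))


def structure_index(s2: float, s3: float, mode: str = "mean") -> float:
    """Global unfolding index, 1 = fully native, toward 0 as structure is lost."""
    for v in (s2, s3):
        if not 0.0 <= v <= 1.0:
            raise ValueError("s2 and s3 must lie in [0, 1]")
    if mode == "mean":
        return 0.5 * (s2 + s3)
    if mode == "s3_only":
        return s3
    raise ValueError(f"unknown mode {mode!r}")
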