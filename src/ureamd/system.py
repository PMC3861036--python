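"""Topology/trajectory ingestion, atom and residue classification, distance machinery.

The in-memory model is deliberately small: a :class:`MolecularSystem` holds
atoms and residues with the classification flags every downstream analysis
needs (protein / urea / water / ion; backbone / side chain; hydrophobic /
polar / charged; core / non-core), and a :class:`Trajectory` is a plain
``(n_frames, n_atoms, 3)`` coordinate array in Angstrom with times in ns and
an optional orthorhombic box.  File I/O is delegated to MDAnalysis readers
and writers; classification and distance searches live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Residue",
    "MolecularSystem",
    "Trajectory",
    "ClassificationTables",
    "load_topology",
    "load_trajectory",
    "write_trajectory",
    "classify_system",
    "pair_distances",
]

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Kyte-Doolittle style grouping; HIS treated as polar at neutral pH.
DEFAULT_HYDROPHOBIC = frozenset("ALA VAL LEU ILE MET PHE TRP PRO GLY CYS".split())
DEFAULT_POLAR = frozenset("SER THR ASN GLN TYR HIS".split())
DEFAULT_CHARGED = frozenset("ASP GLU LYS ARG".split())

DEFAULT_WATER_NAMES = frozenset("HOH WAT TIP3 SPC SOL".split())
DEFAULT_UREA_NAMES = frozenset("URE UREA".split())
DEFAULT_ION_NAMES = frozenset("NA NA+ CL CL- SOD CLA K K+ MG CA2".split())

#: Atomic masses (amu) for the elements this package meets in practice.
ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "NA": 22.990, "CL": 35.45, "K": 39.098,
    "MG": 24.305, "CA": 40.078, "FE": 55.845, "ZN": 65.38, "X": 1.0,
}

_TWO_LETTER_ELEMENTS = frozenset({"NA", "CL", "MG", "FE", "ZN", "BR", "MN", "CU"})


@dataclass(slots=True)
class Atom:
    """One atom, in file order, with the flags the analyses key on."""

    serial: int
    name: str
    element: str
    is_heavy: bool
    residue_index: int
    residue_name: str
    chain: str
    role: str = "sidechain"  # backbone | sidechain | solvent | ion


@dataclass(slots=True)
class Residue:
    index: int
    name: str
    species: str = "protein"  # protein | water | urea | ion
    polarity_class: str = "n/a"  # hydrophobic | polar | charged | n/a
    is_core: bool | None = None
    atom_indices: list[int] = field(default_factory=list)
    chain: str = "A"


@dataclass
class ClassificationTables:
    """Residue-name lookup tables; every set is user-overridable."""

    hydrophobic: frozenset = DEFAULT_HYDROPHOBIC
    polar: frozenset = DEFAULT_POLAR
    charged: frozenset = DEFAULT_CHARGED
    water: frozenset = DEFAULT_WATER_NAMES
    urea: frozenset = DEFAULT_UREA_NAMES
    ions: frozenset = DEFAULT_ION_NAMES

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ClassificationTables":
        kwargs = {}
        for key in ("hydrophobic", "polar", "charged", "water", "urea", "ions"):
            if key in mapping:
                kwargs[key] = frozenset(str(x).upper() for x in mapping[key])
        return cls(**kwargs)


class MolecularSystem:
    """Atoms + residues + named selections; provides cached index arrays."""

    def __init__(self, atoms: list[Atom], residues: list[Residue],
                 selections: dict[str, np.ndarray] | None = None):
        self.atoms = atoms
        self.residues = residues
        self.selections = selections or {}
        self._rebuild_caches()

    def _rebuild_caches(self) -> None:
        n = len(self.atoms)
        self.atom_residue_index = np.array(
            [a.residue_index for a in self.atoms], dtype=np.intp)
        self.heavy_mask = np.array([a.is_heavy for a in self.atoms], dtype=bool)
        self.elements = np.array([a.element for a in self.atoms])
        self.masses = np.array(
            [ATOMIC_MASSES.get(a.element.upper(), 1.0) for a in self.atoms])
        roles = np.array([a.role for a in self.atoms])
        self.backbone_mask = roles == "backbone"
        species = np.array([self.residues[a.residue_index].species
                            for a in self.atoms])
        self.protein_atom_mask = species == "protein"
        self.atom_species = species
        assert self.atom_residue_index.shape == (n,)

    # -- convenience selections -------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.species == "protein"]

    def protein_heavy_indices(self) -> np.ndarray:
        return np.flatnonzero(self.protein_atom_mask & self.heavy_mask)

    def heavy_indices(self) -> np.ndarray:
        return np.flatnonzero(self.heavy_mask)

    def solvent_molecules(self, species: str | None = None,
                          include_ions: bool = False) -> list[Residue]:
        """Solvent residues (one residue == one molecule).

        Ions are excluded from shell/solvent statistics by default.
        """
        wanted = {"water", "urea"} if species is None else {species}
        if include_ions:
            wanted = wanted | {"ion"}
        return [r for r in self.residues if r.species in wanted]

    def atoms_of_residue(self, residue_index: int, heavy_only: bool = True) -> np.ndarray:
        idx = np.asarray(self.residues[residue_index].atom_indices, dtype=np.intp)
        if heavy_only:
            idx = idx[self.heavy_mask[idx]]
        return idx


@dataclass
class Trajectory:
    """Ordered frames of coordinates (Angstrom) with times (ns)."""

    coordinates: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray  # (n_frames,), ns, strictly increasing
    box: np.ndarray | None = None  # (n_frames, 3) orthorhombic lengths or None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != self.coordinates.shape[0]:
            raise ValueError("times length must equal n_frames")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.ndim == 1:
                self.box = np.tile(self.box, (self.n_frames, 1))
            if np.any(self.box <= 0):
                raise ValueError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def dt_ns(self) -> float:
        if self.n_frames < 2:
            raise ValueError("dt undefined for a single-frame trajectory")
        steps = np.diff(self.times)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValueError("non-uniform frame spacing; dt undefined")
        return float(steps[0])

    @property
    def duration_ns(self) -> float:
        return float(self.times[-1] - self.times[0])

    def frame_box(self, f: int) -> np.ndarray | None:
        return None if self.box is None else self.box[f]


# ---------------------------------------------------------------------------
# element inference

def infer_element(atom_name: str, residue_name: str = "") -> str:
    """PDB atom-name -> element heuristic for files lacking the element column.

    Leading digits are part of hydrogen naming (e.g. ``1HB``); names starting
    with H/D after digit-stripping are hydrogens/deuteriums.  Two-letter
    elements are recognised for ion residues (NA, CL, ...).
    """
    name = atom_name.strip().upper()
    res = residue_name.strip().upper()
    stripped = name.lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element for atom name {atom_name!r}")
    if res in DEFAULT_ION_NAMES and stripped[:2] in _TWO_LETTER_ELEMENTS:
        return stripped[:2].capitalize()
    first = stripped[0]
    if first in ("H", "D") and (name != stripped or res or True):
        # 1HB, HB1, HD21 ... are hydrogens; lone "HG" in a protein residue is
        # a gamma hydrogen, not mercury.
        return first
    return first


# ---------------------------------------------------------------------------
# loading

def _system_from_mda(universe) -> MolecularSystem:
    atoms: list[Atom] = []
    residues: list[Residue] = []
    has_elements = hasattr(universe.atoms, "elements")
    res_key_to_index: dict = {}
    seen_triples: dict = {}
    for i, a in enumerate(universe.atoms):
        chain = ""
        for attr in ("chainID", "segid"):
            chain = getattr(a, attr, "") or chain
            if chain:
                break
        chain = (chain or "A").strip() or "A"
        rkey = (chain, a.resid, a.resname, a.residue.ix)
        if rkey not in res_key_to_index:
            res_key_to_index[rkey] = len(residues)
            residues.append(Residue(index=len(residues), name=a.resname.strip(),
                                    chain=chain))
        ridx = res_key_to_index[rkey]
        triple = (chain, a.resid, a.name.strip())
        if triple in seen_triples:
            raise ValueError(
                f"duplicate atom (chain={chain!r}, resid={a.resid}, "
                f"name={a.name!r}) at serial {int(getattr(a, 'id', i + 1))}; "
                f"first seen at serial {seen_triples[triple]}")
        seen_triples[triple] = int(getattr(a, "id", i + 1))
        elem = ""
        if has_elements:
            elem = str(a.element).strip()
        if not elem:
            elem = infer_element(a.name, a.resname)
        elem = elem.capitalize()
        is_heavy = elem.upper() not in ("H", "D")
        atom = Atom(serial=int(getattr(a, "id", i + 1)), name=a.name.strip(),
                    element=elem, is_heavy=is_heavy, residue_index=ridx,
                    residue_name=a.resname.strip(), chain=chain)
        residues[ridx].atom_indices.append(i)
        atoms.append(atom)
    if not atoms:
        raise ValueError("topology contains zero atoms")
    return MolecularSystem(atoms, residues)


def load_topology(path) -> MolecularSystem:
    """Read a PDB file into a :class:`MolecularSystem` (atoms in file order).

    Elements come from the PDB element column when present, otherwise from
    the atom-name heuristic.  Duplicate (chain, resid, atom-name) triples are
    an error naming the offending serial.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except (OSError, ValueError, EOFError) as exc:
            raise ValueError(f"unreadable topology file {path}: {exc}") from exc
    return _system_from_mda(u)


def _times_from_reader(reader, n_frames: int, dt_ns: float | None,
                       fmt_has_time: bool, file_times_ps: np.ndarray) -> np.ndarray:
    if dt_ns is not None:
        return np.arange(n_frames) * float(dt_ns)
    if fmt_has_time and len(file_times_ps) == n_frames and np.all(np.diff(file_times_ps) > 0):
        return file_times_ps / 1000.0  # ps -> ns
    warnings.warn("no usable time metadata; assuming dt = 1 ns", stacklevel=3)
    return np.arange(n_frames, dtype=float)


def load_trajectory(path, system: MolecularSystem,
                    dt_ns: float | None = None) -> Trajectory:
    """Read a multi-model PDB, DCD or XTC trajectory.

    Frame times come from ``dt_ns`` when given, else from file metadata
    (DCD/XTC, ps converted to ns), else 0, 1, 2, ... ns with a warning.
    """
    import MDAnalysis as mda
    from MDAnalysis.coordinates.core import get_reader_for

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reader_cls = get_reader_for(str(path))
        reader = reader_cls(str(path))
        coords = []
        boxes = []
        file_times = []
        for ts in reader:
            if ts.n_atoms != system.n_atoms:
                raise ValueError(
                    f"atom-count mismatch: trajectory has {ts.n_atoms}, "
                    f"system has {system.n_atoms}")
            coords.append(np.array(ts.positions, dtype=float))
            file_times.append(float(ts.time) if ts.time is not None else 0.0)
            dims = ts.dimensions
            if dims is not None and np.all(np.asarray(dims)[:3] > 0):
                if not np.allclose(dims[3:], 90.0, atol=1e-3):
                    raise ValueError("only orthorhombic boxes are supported")
                boxes.append(np.asarray(dims[:3], dtype=float))
            else:
                boxes.append(None)
        reader.close()
    if not coords:
        raise ValueError(f"trajectory {path} contains zero frames")
    fmt = str(path).rsplit(".", 1)[-1].lower()
    times = _times_from_reader(reader, len(coords), dt_ns,
                               fmt in ("dcd", "xtc", "trr"),
                               np.asarray(file_times))
    box = None
    if all(b is not None for b in boxes):
        box = np.stack(boxes)
    return Trajectory(np.stack(coords), times, box)


def write_trajectory(path, system: MolecularSystem, traj: Trajectory) -> None:
    """Write a multi-model PDB (or DCD, by extension) via MDAnalysis."""
    import MDAnalysis as mda

    n = system.n_atoms
    u = mda.Universe.empty(n, n_residues=system.n_residues,
                           atom_resindex=system.atom_residue_index,
                           residue_segindex=np.zeros(system.n_residues, dtype=int),
                           trajectory=True)
    u.add_TopologyAttr("names", [a.name for a in system.atoms])
    u.add_TopologyAttr("elements", [a.element for a in system.atoms])
    u.add_TopologyAttr("resnames", [r.name for r in system.residues])
    u.add_TopologyAttr("resids", np.arange(1, system.n_residues + 1))
    u.add_TopologyAttr("chainIDs", [a.chain[:1] for a in system.atoms])
    u.add_TopologyAttr("segids", ["SYS"])
    dims = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=n, multiframe=True) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.coordinates[f]
                if traj.box is not None:
                    dims = np.concatenate([traj.box[f], [90.0, 90.0, 90.0]])
                    u.dimensions = dims
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# classification

def classify_system(system: MolecularSystem,
                    tables: ClassificationTables | dict | None = None) -> MolecularSystem:
    """Assign residue species/polarity and atom roles in place (idempotent).

    Unknown residue names raise, listing every offender: silent guessing of
    species would corrupt every downstream solvent statistic.
    """
    if tables is None:
        tables = ClassificationTables()
    elif isinstance(tables, dict):
        tables = ClassificationTables.from_mapping(tables)
    protein_names = tables.hydrophobic | tables.polar | tables.charged
    unknown = sorted({r.name for r in system.residues
                      if r.name.upper() not in protein_names
                      and r.name.upper() not in tables.water
                      and r.name.upper() not in tables.urea
                      and r.name.upper() not in tables.ions})
    if unknown:
        raise ValueError(f"unknown residue name(s) with no table entry: {unknown}")
    for res in system.residues:
        name = res.name.upper()
        if name in tables.water:
            res.species, res.polarity_class = "water", "n/a"
        elif name in tables.urea:
            res.species, res.polarity_class = "urea", "n/a"
        elif name in tables.ions:
            res.species, res.polarity_class = "ion", "n/a"
        else:
            res.species = "protein"
            if name in tables.hydrophobic:
                res.polarity_class = "hydrophobic"
            elif name in tables.polar:
                res.polarity_class = "polar"
            else:
                res.polarity_class = "charged"
        for ai in res.atom_indices:
            atom = system.atoms[ai]
            if res.species == "protein":
                atom.role = "backbone" if atom.name.upper() in BACKBONE_NAMES else "sidechain"
            elif res.species == "ion":
                atom.role = "ion"
            else:
                atom.role = "solvent"
    system._rebuild_caches()
    return system


# ---------------------------------------------------------------------------
# distances

def _wrap(points: np.ndarray, box: np.ndarray) -> np.ndarray:
    return np.mod(points, box)


def pair_distances(frame: np.ndarray, set_a, set_b, cutoff: float,
                   box: np.ndarray | None = None) -> list[tuple[int, int, float]]:
    """All pairs (i in set_a, j in set_b) with distance strictly below cutoff.

    Exact: a k-d tree prunes candidates, then true (minimum-image when a box
    is given) distances are compared against the cutoff.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    frame = np.asarray(frame, dtype=float)
    ia = np.asarray(list(set_a), dtype=np.intp)
    ib = np.asarray(list(set_b), dtype=np.intp)
    if ia.size == 0 or ib.size == 0:
        return []
    pa, pb = frame[ia], frame[ib]
    if box is not None:
        box = np.asarray(box, dtype=float)
        tree = cKDTree(_wrap(pb, box), boxsize=box)
        neighbors = tree.query_ball_point(_wrap(pa, box), r=cutoff)
    else:
        tree = cKDTree(pb)
        neighbors = tree.query_ball_point(pa, r=cutoff)
    out = []
    for k, nbrs in enumerate(neighbors):
        if not nbrs:
            continue
        i = ia[k]
        js = ib[np.asarray(nbrs, dtype=np.intp)]
        d = pb[np.asarray(nbrs, dtype=np.intp)] - pa[k]
        if box is not None:
            d -= box * np.round(d / box)
        dist = np.sqrt(np.sum(d * d, axis=1))
        for j, dj in zip(js, dist):
            if int(j) != int(i) and dj < cutoff:
                out.append((int(i), int(j), float(dj)))
    return out


def minimum_image_displacement(d: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return d
    return d - box * np.round(d / box)
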