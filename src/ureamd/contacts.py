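"""Residue-residue contact timelines and native-contact kinetics.

A contact between two residues exists in a frame when at least one pair of
heavy atoms across them is closer than the cutoff (default 3.5 Angstrom).
Native contacts are those present more than 80% of the time in a reference
native-state (water) trajectory.  From the boolean timeline the module
derives the native-contact index S3, opening-interval statistics, the
water/urea opening-time shift classification, per-residue lost-contact time
and the cross-condition Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from .metrics import MetricSeries
from .system import MolecularSystem, Trajectory

__all__ = [
    "ContactTimeline",
    "NativeContacts",
    "OpeningStats",
    "contact_timeline",
    "native_contact_set",
    "s3_series",
    "opening_stats",
    "opening_shift_classify",
    "lost_time_per_residue",
    "lost_time_correlation",
    "run_lengths",
]


@dataclass
class ContactTimeline:
    pairs: list[tuple[int, int]]  # residue-index pairs, i < j
    presence: np.ndarray  # bool, (n_pairs, n_frames)
    times: np.ndarray  # ns

    def __post_init__(self):
        if len(self.pairs) != self.presence.shape[0]:
            raise ValueError("pairs/presence shape mismatch")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate contact pairs")

    @property
    def n_frames(self) -> int:
        return self.presence.shape[1]

    @property
    def dt_ns(self) -> float:
        steps = np.diff(self.times)
        if len(steps) == 0:
            raise ValueError("single-frame timeline has no dt")
        return float(steps[0])

    def occupancy(self) -> np.ndarray:
        return self.presence.mean(axis=1)


@dataclass
class NativeContacts:
    pairs: list[tuple[int, int]]
    occupancies: np.ndarray  # reference occupancy per pair

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class OpeningStats:
    pairs: list[tuple[int, int]]
    n_open: np.ndarray  # number of open (broken) intervals
    mean_open_ns: np.ndarray  # mean open duration (0 when never open)
    total_open_ns: np.ndarray


def contact_timeline(traj: Trajectory, system: MolecularSystem,
                     cutoff: float = 3.5, min_seq_sep: int = 3,
                     pairs=None) -> ContactTimeline:
    """Boolean residue-pair contact matrix over frames (heavy atoms only)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    heavy = system.protein_heavy_indices()
    res_of_heavy = system.atom_residue_index[heavy]
    protein_res = {r.index for r in system.residues if r.species == "protein"}
    if len(protein_res) < 2:
        raise ValueError("need at least 2 protein residues")
    restrict = None if pairs is None else {tuple(sorted(p)) for p in pairs}
    seen: dict[tuple[int, int], list[int]] = {}
    for f in range(traj.n_frames):
        pos = traj.coordinates[f][heavy]
        tree = cKDTree(pos)
        cand = tree.query_pairs(cutoff, output_type="ndarray")
        if cand.size:
            d = np.linalg.norm(pos[cand[:, 0]] - pos[cand[:, 1]], axis=1)
            cand = cand[d < cutoff]
        frame_pairs = set()
        for a, b in cand:
            ri, rj = int(res_of_heavy[a]), int(res_of_heavy[b])
            if ri == rj:
                continue
            if ri > rj:
                ri, rj = rj, ri
            if rj - ri < min_seq_sep:
                continue
            if restrict is not None and (ri, rj) not in restrict:
                continue
            frame_pairs.add((ri, rj))
        for p in frame_pairs:
            seen.setdefault(p, []).append(f)
    pair_list = sorted(seen)
    presence = np.zeros((len(pair_list), traj.n_frames), dtype=bool)
    for k, p in enumerate(pair_list):
        presence[k, seen[p]] = True
    return ContactTimeline(pair_list, presence, traj.times.copy())


def native_contact_set(reference_timeline: ContactTimeline,
                       occupancy_threshold: float = 0.80) -> NativeContacts:
    """Pairs whose reference occupancy is strictly above the threshold."""
    if len(reference_timeline.pairs) == 0:
        raise ValueError("empty reference timeline")
    occ = reference_timeline.occupancy()
    keep = occ > occupancy_threshold
    return NativeContacts([p for p, k in zip(reference_timeline.pairs, keep) if k],
                          occ[keep])


def _aligned_presence(timeline: ContactTimeline, native: NativeContacts) -> np.ndarray:
    """Presence rows in native-pair order; pairs never seen are all-absent."""
    index = {p: k for k, p in enumerate(timeline.pairs)}
    rows = np.zeros((len(native.pairs), timeline.n_frames), dtype=bool)
    for k, p in enumerate(native.pairs):
        if p in index:
            rows[k] = timeline.presence[index[p]]
    return rows


def s3_series(timeline: ContactTimeline, native: NativeContacts) -> MetricSeries:
    """Per-frame fraction of native contacts present (native-contact index)."""
    if len(native) == 0:
        raise ValueError("empty native contact set")
    rows = _aligned_presence(timeline, native)
    return MetricSeries("S3", rows.mean(axis=0), timeline.times, "fraction")


def run_lengths(absent: np.ndarray) -> list[int]:
    """Lengths of maximal runs of True in a boolean vector."""
    out = []
    count = 0
    for v in absent:
        if v:
            count += 1
        elif count:
            out.append(count)
            count = 0
    if count:
        out.append(count)
    return out


def opening_stats(timeline: ContactTimeline, native: NativeContacts) -> OpeningStats:
    """Open (broken) interval statistics per native contact."""
    rows = _aligned_presence(timeline, native)
    dt = timeline.dt_ns
    n_open = np.zeros(len(native.pairs), dtype=int)
    mean_open = np.zeros(len(native.pairs))
    total_open = np.zeros(len(native.pairs))
    for k in range(rows.shape[0]):
        runs = run_lengths(~rows[k])
        n_open[k] = len(runs)
        total_open[k] = sum(runs) * dt
        mean_open[k] = total_open[k] / len(runs) if runs else 0.0
    return OpeningStats(list(native.pairs), n_open, mean_open, total_open)


def opening_shift_classify(stats_a: OpeningStats, stats_b: OpeningStats,
                           threshold_ns: float = 0.1):
    """Percentages of native contacts with longer openings in a, in b, total.

    A contact counts for a condition when its mean opening time exceeds the
    other condition's by strictly more than the threshold (default |0.1| ns).
    """
    if stats_a.pairs != stats_b.pairs:
        raise ValueError("contact-set mismatch between conditions")
    n = len(stats_a.pairs)
    if n == 0:
        raise ValueError("empty contact set")
    diff = stats_a.mean_open_ns - stats_b.mean_open_ns
    pct_a = 100.0 * np.count_nonzero(diff > threshold_ns) / n
    pct_b = 100.0 * np.count_nonzero(-diff > threshold_ns) / n
    return pct_a, pct_b, pct_a + pct_b


def lost_time_per_residue(timeline: ContactTimeline, native: NativeContacts,
                          reference_occupancies: np.ndarray | None = None,
                          mode: str = "absolute") -> dict[int, float]:
    """Average % of lost time over the native contacts each residue forms.

    ``absolute``: lost% of a contact is the fraction of frames it is broken.
    ``reference_excess``: 100 * max(0, occ_ref - occ_now) / occ_ref, the
    excess loss relative to the native-state reference.  Residues with no
    native contacts are omitted from the result.
    """
    if len(native) == 0:
        raise ValueError("empty native contact set")
    rows = _aligned_presence(timeline, native)
    occ_now = rows.mean(axis=1)
    if mode == "absolute":
        lost = 100.0 * (1.0 - occ_now)
    elif mode == "reference_excess":
        occ_ref = (native.occupancies if reference_occupancies is None
                   else np.asarray(reference_occupancies, dtype=float))
        if np.any(occ_ref <= 0):
            raise ValueError("reference occupancies must be positive")
        lost = 100.0 * np.maximum(0.0, occ_ref - occ_now) / occ_ref
    else:
        raise ValueError(f"unknown mode {mode!r}")
    acc: dict[int, list[float]] = {}
    for (i, j), v in zip(native.pairs, lost):
        acc.setdefault(i, []).append(v)
        acc.setdefault(j, []).append(v)
    return {r: float(np.mean(vs)) for r, vs in sorted(acc.items())}


def lost_time_correlation(lost_a, lost_b):
    """Pearson r and two-sided p-value between paired lost-time vectors."""
    a = np.asarray(lost_a, dtype=float)
    b = np.asarray(lost_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors of equal length required")
    if a.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
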