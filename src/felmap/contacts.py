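"""Residue contact maps from replicate trajectories.

A residue pair is probed by the smallest heavy-atom distance between the two
residues in each frame.  A pair enters a state's contact map when (i) the
fraction of frames with that minimum distance strictly below the 4 Angstrom
cutoff is at least 0.5 in BOTH replicate runs, (ii) the mean minimum
distance agrees between the runs within 0.5 Angstrom, and (iii) the pair is
at least ``min_seq_sep`` apart in sequence (default 2; pass 0 to include
sequence neighbours).  The contact-map difference between two states lists
the pairs unique to each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .trajio import AtomisticTrajectory

__all__ = ["ContactRecord", "ContactMap", "min_distance_series",
           "contact_map", "contact_map_difference"]

DEFAULT_CUTOFF_A = 4.0
DEFAULT_MIN_OCCUPANCY = 0.5
DEFAULT_CROSS_RUN_TOL_A = 0.5
DEFAULT_MIN_SEQ_SEP = 2


@dataclass(frozen=True)
class ContactRecord:
    pair: tuple[int, int]
    occupancy: tuple[float, float]
    mean_distance: tuple[float, float]


@dataclass
class ContactMap:
    state: str
    records: dict[tuple[int, int], ContactRecord]
    cutoff: float = DEFAULT_CUTOFF_A
    min_occupancy: float = DEFAULT_MIN_OCCUPANCY
    cross_run_tol: float = DEFAULT_CROSS_RUN_TOL_A
    min_seq_sep: int = DEFAULT_MIN_SEQ_SEP

    @property
    def pairs(self) -> set[tuple[int, int]]:
        return set(self.records)

    def same_filters(self, other: "ContactMap") -> bool:
        return (self.cutoff, self.min_occupancy, self.cross_run_tol,
                self.min_seq_sep) == (other.cutoff, other.min_occupancy,
                                      other.cross_run_tol, other.min_seq_sep)


def min_distance_series(traj: AtomisticTrajectory, res_i: int,
                        res_j: int) -> np.ndarray:
    """Per-frame smallest heavy-atom distance (Angstrom) between two residues."""
    if res_i == res_j:
        raise ValueError("a residue cannot be in contact with itself")
    ai = traj.atom_indices(res_i, heavy_only=True)
    aj = traj.atom_indices(res_j, heavy_only=True)
    if ai.size == 0:
        raise ValueError(f"residue {res_i} has no heavy atoms")
    if aj.size == 0:
        raise ValueError(f"residue {res_j} has no heavy atoms")
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        out[f] = cdist(traj.coords[f, ai], traj.coords[f, aj]).min()
    return out


def _min_dist_matrix(traj: AtomisticTrajectory) -> tuple[np.ndarray, list[int]]:
    """frames x pairs matrix of per-frame min heavy-atom distances."""
    residues = sorted(traj.residue_numbers)
    groups = {r: traj.atom_indices(r, heavy_only=True) for r in residues}
    for r, idx in groups.items():
        if idx.size == 0:
            raise ValueError(f"residue {r} has no heavy atoms")
    pairs = [(a, b) for k, a in enumerate(residues) for b in residues[k + 1:]]
    dmat = np.empty((traj.n_frames, len(pairs)))
    for f in range(traj.n_frames):
        xyz = traj.coords[f]
        full = cdist(xyz, xyz)
        for p, (a, b) in enumerate(pairs):
            dmat[f, p] = full[np.ix_(groups[a], groups[b])].min()
    return dmat, pairs


def contact_map(run1: AtomisticTrajectory, run2: AtomisticTrajectory,
                state: str = "",
                cutoff: float = DEFAULT_CUTOFF_A,
                min_occupancy: float = DEFAULT_MIN_OCCUPANCY,
                cross_run_tol: float = DEFAULT_CROSS_RUN_TOL_A,
                min_seq_sep: int = DEFAULT_MIN_SEQ_SEP) -> ContactMap:
    """Occupancy- and consistency-filtered contact map of two replicate runs."""
    if sorted(run1.residue_numbers) != sorted(run2.residue_numbers):
        raise ValueError("replicate runs must share residue numbering")
    d1, pairs = _min_dist_matrix(run1)
    d2, _ = _min_dist_matrix(run2)

    records: dict[tuple[int, int], ContactRecord] = {}
    for p, (a, b) in enumerate(pairs):
        if abs(a - b) < min_seq_sep:
            continue
        occ1 = float(np.mean(d1[:, p] < cutoff))
        occ2 = float(np.mean(d2[:, p] < cutoff))
        if occ1 < min_occupancy or occ2 < min_occupancy:
            continue
        m1, m2 = float(d1[:, p].mean()), float(d2[:, p].mean())
        if abs(m1 - m2) > cross_run_tol:
            continue
        records[(a, b)] = ContactRecord((a, b), (occ1, occ2), (m1, m2))
    return ContactMap(state, records, cutoff, min_occupancy,
                      cross_run_tol, min_seq_sep)


def contact_map_difference(cm_a: ContactMap, cm_b: ContactMap
                           ) -> tuple[set[tuple[int, int]], set[tuple[int, int]]]:
    """Pairs unique to each map: (A-only, B-only)."""
    if not cm_a.same_filters(cm_b):
        raise ValueError("contact maps were built with different filters")
    return cm_a.pairs - cm_b.pairs, cm_b.pairs - cm_a.pairs
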