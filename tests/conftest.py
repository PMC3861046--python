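"""Shared fixtures: small programmatically built trajectories."""

from __future__ import annotations

import numpy as np
import pytest

from felmap.trajio import Atom, AtomisticTrajectory

_RES_ATOMS = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C")]


def make_protein_traj(n_residues: int = 3, n_frames: int = 4, seed: int = 0,
                      spread: float = 5.0, first_residue: int = 1,
                      atoms_per_residue=None) -> AtomisticTrajectory:
    """Random small multi-atom trajectory with standard backbone names."""
    names = atoms_per_residue or _RES_ATOMS
    atoms = [Atom(n, e, r, "ALA")
             for r in range(first_residue, first_residue + n_residues)
             for n, e in names]
    rng = np.random.default_rng(seed)
    coords = rng.normal(scale=spread, size=(n_frames, len(atoms), 3))
    return AtomisticTrajectory(atoms, coords, 2.0 * np.arange(n_frames))


def place_pair_traj(distances_run: np.ndarray, seq_sep: int = 5
                    ) -> AtomisticTrajectory:
    """Two single-heavy-atom residues at prescribed per-frame separations."""
    d = np.asarray(distances_run, float)
    atoms = [Atom("CA", "C", 1, "GLY"), Atom("CA", "C", 1 + seq_sep, "GLY")]
    coords = np.zeros((d.size, 2, 3))
    coords[:, 1, 0] = d
    return AtomisticTrajectory(atoms, coords, 2.0 * np.arange(d.size))


@pytest.fixture
def small_traj() -> AtomisticTrajectory:
    return make_protein_traj()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
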