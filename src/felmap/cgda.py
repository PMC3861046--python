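"""Coarse-grained dihedral angles (CGDAs) from consecutive Calpha atoms.

The angle gamma_i probes the local main-chain conformation at residue i: it
is the dihedral formed by the virtual bonds joining the four successive
Calpha atoms (i-1, i, i+1, i+2).  The zero is the cis arrangement of
Calpha(i-1) and Calpha(i+2), and the sign is positive for a clockwise
rotation of the Calpha(i+1)-Calpha(i+2) bond when looking from Calpha(i)
towards Calpha(i+1).  Values lie in the half-open interval (-180, +180]
degrees (a tie at +/-180 is reported as +180 so histogram binning is
unambiguous).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajio import CalphaTrajectory

__all__ = ["DihedralSeries", "UndefinedDihedralError", "compute_dihedral",
           "gamma_series", "write_gamma_tsv", "read_gamma_tsv"]

#: squared cross-product norm below which the dihedral is declared undefined
COLLINEARITY_TOL = 1e-10


class UndefinedDihedralError(ValueError):
    """Raised when three consecutive points are (numerically) collinear."""


@dataclass
class DihedralSeries:
    """Frames x angles matrix of gamma values in degrees.

    ``angle_indices[j]`` is the residue number i labelling column j, so for a
    residue range [r_min, r_max] the indices run r_min+1 ... r_max-2.
    """

    angle_indices: np.ndarray
    values: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.angle_indices = np.asarray(self.angle_indices, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be frames x angles")
        if self.values.shape[1] != self.angle_indices.shape[0]:
            raise ValueError("one column per angle index required")
        if self.values.size and (
            self.values.min() <= -180.0 or self.values.max() > 180.0
        ):
            raise ValueError("dihedral values must lie in (-180, +180]")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def column(self, angle_index: int) -> np.ndarray:
        """Per-frame values of gamma_{angle_index}."""
        j = np.flatnonzero(self.angle_indices == angle_index)
        if j.size == 0:
            raise KeyError(f"no angle with index {angle_index}")
        return self.values[:, j[0]]

    def subset(self, indices) -> "DihedralSeries":
        cols = []
        for i in indices:
            j = np.flatnonzero(self.angle_indices == i)
            if j.size == 0:
                raise KeyError(f"no angle with index {i}")
            cols.append(j[0])
        return DihedralSeries(
            np.asarray(list(indices), int), self.values[:, cols], self.frame_times
        )


def _canonical_degrees(rad: np.ndarray) -> np.ndarray:
    deg = np.degrees(rad)
    # fold into (-180, 180]; -180 maps to +180
    deg = np.where(deg <= -180.0, deg + 360.0, deg)
    return deg


def compute_dihedral(p1, p2, p3, p4) -> float:
    """Dihedral angle (degrees in (-180, +180]) of four points.

    Sign convention: 0 at cis, positive for clockwise rotation of the distal
    bond viewed from p2 towards p3.
    """
    out = compute_dihedral_batch(
        np.asarray(p1, float)[None], np.asarray(p2, float)[None],
        np.asarray(p3, float)[None], np.asarray(p4, float)[None],
    )
    return float(out[0])


def compute_dihedral_batch(p1, p2, p3, p4) -> np.ndarray:
    """Vectorized :func:`compute_dihedral` over leading axes."""
    u = p1 - p2            # proximal bond, pointing back from the axis
    w = p4 - p3            # distal bond
    axis = p3 - p2

    n1 = np.cross(u, axis)
    n2 = np.cross(axis, w)
    if np.any(np.einsum("...i,...i", n1, n1) < COLLINEARITY_TOL) or np.any(
        np.einsum("...i,...i", n2, n2) < COLLINEARITY_TOL
    ):
        raise UndefinedDihedralError("collinear points: dihedral undefined")

    norm = np.linalg.norm(axis, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        raise UndefinedDihedralError("degenerate central bond")
    a_hat = axis / norm

    # remove axial components; angle between the two half-planes
    u_perp = u - np.einsum("...i,...i", u, a_hat)[..., None] * a_hat
    w_perp = w - np.einsum("...i,...i", w, a_hat)[..., None] * a_hat
    y = np.einsum("...i,...i", np.cross(u_perp, w_perp), a_hat)
    x = np.einsum("...i,...i", u_perp, w_perp)
    return _canonical_degrees(np.arctan2(y, x))


def gamma_series(traj: CalphaTrajectory) -> DihedralSeries:
    """All CGDAs gamma_i of a Calpha trajectory.

    For n residues there are n - 3 angles; gamma_i is built on
    Calpha(i-1), Calpha(i), Calpha(i+1), Calpha(i+2).
    """
    n = traj.n_residues
    if n < 4:
        raise ValueError("at least 4 residues are required for one dihedral")
    c = traj.coords
    values = compute_dihedral_batch(c[:, :-3], c[:, 1:-2], c[:, 2:-1], c[:, 3:])
    indices = traj.residue_numbers[1:-2]
    return DihedralSeries(indices, values, traj.frame_times)


def write_gamma_tsv(series: DihedralSeries, path) -> None:
    """TSV: frame_time then one column per angle index."""
    import pandas as pd

    df = pd.DataFrame(series.values,
                      columns=[f"gamma_{i}" for i in series.angle_indices])
    df.insert(0, "frame_time", series.frame_times)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gamma_tsv(path) -> DihedralSeries:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    cols = [c for c in df.columns if c.startswith("gamma_")]
    indices = [int(c.split("_", 1)[1]) for c in cols]
    return DihedralSeries(
        np.asarray(indices, int),
        df[cols].to_numpy(float),
        df["frame_time"].to_numpy(float),
    )
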