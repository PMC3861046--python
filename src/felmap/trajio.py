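"""Trajectory containers and I/O.

Conformational ensembles are exchanged either as multi-model PDB files
(MODEL/ENDMDL blocks, one block per frame) or as a plain tab-separated
coordinate table with columns ``frame, residue, atom, x, y, z``.  All
coordinates are in Angstrom, times in picoseconds, and residues keep the
1-based author numbering of the input file -- angles and contacts downstream
are always reported against those numbers.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "AtomisticTrajectory",
    "CalphaTrajectory",
    "SubdomainMap",
    "TrajectoryParseError",
    "load_trajectory",
    "write_trajectory",
    "calpha_view",
    "load_subdomain_map",
    "dnak_subdomain_map",
]

#: default sampling interval (ps) when the input format carries no times
DEFAULT_FRAME_SPACING_PS = 2.0

_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


class TrajectoryParseError(ValueError):
    """Structured parse failure; carries the offending frame/model when known."""

    def __init__(self, message: str, frame: int | None = None):
        super().__init__(message)
        self.frame = frame


@dataclass(frozen=True)
class Atom:
    """One atom record, constant across frames."""

    name: str
    element: str
    residue_number: int
    residue_name: str

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    @property
    def is_backbone(self) -> bool:
        return self.name in _BACKBONE_NAMES


@dataclass
class AtomisticTrajectory:
    """Ordered conformations sharing one atom table.

    Attributes
    ----------
    atoms : list of :class:`Atom`
        Identical ordering in every frame.
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Cartesian coordinates in Angstrom.
    frame_times : ndarray, shape (n_frames,)
        Strictly increasing times in ps.
    """

    atoms: list[Atom]
    coords: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("coords second axis must match atom count")
        if self.coords.shape[0] != self.frame_times.shape[0]:
            raise ValueError("one frame time per frame required")
        if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residue_numbers(self) -> list[int]:
        """Distinct residue numbers in order of first appearance."""
        seen: dict[int, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_number, None)
        return list(seen)

    def atom_indices(self, residue_number: int, heavy_only: bool = True) -> np.ndarray:
        idx = [
            i
            for i, a in enumerate(self.atoms)
            if a.residue_number == residue_number and (a.is_heavy or not heavy_only)
        ]
        return np.asarray(idx, dtype=int)


@dataclass
class CalphaTrajectory:
    """Per-frame ordered Calpha coordinates.

    Exactly one coordinate per residue per frame; residue numbers strictly
    increasing (author numbering, never renumbered).
    """

    residue_numbers: np.ndarray
    coords: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_residues, 3)")
        if self.coords.shape[1] != self.residue_numbers.shape[0]:
            raise ValueError("one coordinate per residue per frame required")
        if len(self.residue_numbers) > 1 and not np.all(np.diff(self.residue_numbers) > 0):
            raise ValueError("residue_numbers must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.residue_numbers.shape[0]


@dataclass
class SubdomainMap:
    """Named sets of closed, 1-based residue intervals (e.g. ``NBD-IB: 38-111``)."""

    entries: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def label_of(self, residue: int) -> str:
        for label, intervals in self.entries.items():
            for lo, hi in intervals:
                if lo <= residue <= hi:
                    return label
        return "unassigned"

    @property
    def labels(self) -> list[str]:
        return list(self.entries)


# ---------------------------------------------------------------------------
# Readers / writers


def _parse_pdb_models(path) -> AtomisticTrajectory:
    # Bio.PDB handles the MODEL/ENDMDL dialect, altlocs and insertion codes.
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("traj", str(path))

    models = list(structure)
    if not models:
        raise TrajectoryParseError(f"no MODEL records found in {path}")

    frames: list[np.ndarray] = []
    atom_tables: list[list[Atom]] = []
    for model in models:
        atoms: list[Atom] = []
        xyz: list[np.ndarray] = []
        for chain in model:
            for res in chain:
                resnum = res.id[1]
                for atom in res:
                    elem = (atom.element or atom.get_name()[0]).strip() or "X"
                    atoms.append(Atom(atom.get_name(), elem, resnum, res.get_resname()))
                    xyz.append(atom.get_coord())
        atom_tables.append(atoms)
        frames.append(np.asarray(xyz, dtype=float))

    n0 = len(atom_tables[0])
    for k, tab in enumerate(atom_tables):
        if len(tab) != n0:
            raise TrajectoryParseError(
                f"model {models[k].serial_num} has {len(tab)} atoms, expected {n0}",
                frame=models[k].serial_num,
            )
        if tab != atom_tables[0]:
            raise TrajectoryParseError(
                f"model {models[k].serial_num} atom table differs from model 1",
                frame=models[k].serial_num,
            )
    times = DEFAULT_FRAME_SPACING_PS * np.arange(len(frames))
    return AtomisticTrajectory(atom_tables[0], np.stack(frames), times)


def _parse_table(path) -> AtomisticTrajectory:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    required = {"frame", "residue", "atom", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise TrajectoryParseError(
            f"table file missing columns {sorted(required - set(df.columns))}"
        )
    frame_ids = sorted(df["frame"].unique())
    groups = {fid: g for fid, g in df.groupby("frame", sort=True)}

    first = groups[frame_ids[0]]
    key_cols = ["residue", "atom"]
    ref_key = list(map(tuple, first[key_cols].itertuples(index=False)))
    atoms = []
    for _, row in first.iterrows():
        name = str(row["atom"])
        elem = str(row.get("element", name[0])) if "element" in df.columns else name[0]
        resname = str(row["resname"]) if "resname" in df.columns else "UNK"
        atoms.append(Atom(name, elem, int(row["residue"]), resname))

    frames = []
    for fid in frame_ids:
        g = groups[fid]
        key = list(map(tuple, g[key_cols].itertuples(index=False)))
        if key != ref_key:
            raise TrajectoryParseError(
                f"frame {fid} atom rows differ from frame {frame_ids[0]}", frame=fid
            )
        frames.append(g[["x", "y", "z"]].to_numpy(dtype=float))

    if "time_ps" in df.columns:
        times = np.asarray([groups[f]["time_ps"].iloc[0] for f in frame_ids], float)
    else:
        times = DEFAULT_FRAME_SPACING_PS * np.arange(len(frame_ids))
    return AtomisticTrajectory(atoms, np.stack(frames), times)


def load_trajectory(path, format: str = "pdb_models") -> AtomisticTrajectory:
    """Read a conformational ensemble.

    Parameters
    ----------
    path : str or Path
        Input file.
    format : {"pdb_models", "table"}
        Multi-model PDB or the TSV coordinate table.
    """
    if format == "pdb_models":
        return _parse_pdb_models(path)
    if format == "table":
        return _parse_table(path)
    raise ValueError(f"unknown trajectory format {format!r}")


def write_trajectory(traj: AtomisticTrajectory, path, format: str = "pdb_models") -> None:
    """Write a trajectory in either interchange dialect (lossless for TSV,
    1e-3 Angstrom for PDB's fixed-width fields)."""
    if format == "pdb_models":
        buf = io.StringIO()
        for f in range(traj.n_frames):
            buf.write(f"MODEL     {f + 1:4d}\n")
            for i, a in enumerate(traj.atoms):
                x, y, z = traj.coords[f, i]
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                buf.write(
                    f"ATOM  {i + 1:5d} {name:<4s} {a.residue_name:<3s} A"
                    f"{a.residue_number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"  1.00  0.00          {a.element:>2s}\n"
                )
            buf.write("ENDMDL\n")
        buf.write("END\n")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())
    elif format == "table":
        rows = []
        for f in range(traj.n_frames):
            for i, a in enumerate(traj.atoms):
                x, y, z = traj.coords[f, i]
                rows.append(
                    (f, traj.frame_times[f], a.residue_number, a.residue_name,
                     a.name, a.element, x, y, z)
                )
        df = pd.DataFrame(
            rows,
            columns=["frame", "time_ps", "residue", "resname", "atom", "element",
                     "x", "y", "z"],
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


def calpha_view(traj: AtomisticTrajectory) -> CalphaTrajectory:
    """Extract the Calpha trace (one CA per residue, coordinates copied)."""
    by_res: dict[int, int] = {}
    for i, a in enumerate(traj.atoms):
        if a.name == "CA":
            if a.residue_number in by_res:
                raise ValueError(f"residue {a.residue_number} has multiple CA atoms")
            by_res[a.residue_number] = i
    residues = traj.residue_numbers
    missing = [r for r in residues if r not in by_res]
    if missing:
        raise ValueError(f"residue {missing[0]} has no CA atom")
    order = sorted(residues)
    idx = np.asarray([by_res[r] for r in order], dtype=int)
    return CalphaTrajectory(
        residue_numbers=np.asarray(order, dtype=int),
        coords=traj.coords[:, idx, :].copy(),
        frame_times=traj.frame_times.copy(),
    )


# ---------------------------------------------------------------------------
# Subdomain maps


def _parse_interval(token: str) -> tuple[int, int]:
    lo, _, hi = token.partition("-")
    lo_i, hi_i = int(lo), int(hi or lo)
    if lo_i > hi_i:
        raise ValueError(f"malformed interval {token!r}: lo > hi")
    return lo_i, hi_i


def load_subdomain_map(source: str | dict) -> SubdomainMap:
    """Parse a subdomain config (``label: lo-hi[, lo-hi...]`` per line, or a
    literal ``{label: [(lo, hi), ...]}`` mapping).

    Overlaps between labels are kept but warned about.
    """
    entries: dict[str, list[tuple[int, int]]] = {}
    if isinstance(source, dict):
        for label, ivs in source.items():
            entries[str(label)] = [(int(lo), int(hi)) for lo, hi in ivs]
    else:
        text = source
        if "\n" not in text and ":" not in text:
            with open(text) as fh:
                text = fh.read()
        elif "\n" not in text:
            # single-line literal or a path: try the filesystem first
            try:
                with open(text) as fh:
                    text = fh.read()
            except OSError:
                pass
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            label, _, spec = line.partition(":")
            label = label.strip()
            if not _ or not label:
                raise ValueError(f"malformed subdomain line {line!r}")
            if label in entries:
                raise ValueError(f"duplicate subdomain label {label!r}")
            entries[label] = [
                _parse_interval(tok.strip()) for tok in spec.split(",") if tok.strip()
            ]
    # intervals within one label must be disjoint
    for label, ivs in entries.items():
        ordered = sorted(ivs)
        for (_lo_prev, hi_prev), (lo, _hi) in zip(ordered, ordered[1:]):
            if lo <= hi_prev:
                raise ValueError(f"overlapping intervals within label {label!r}")
    # cross-label overlap: warn, keep (first label wins on lookup)
    flat = [(lo, hi, lab) for lab, ivs in entries.items() for lo, hi in ivs]
    for i, (lo1, hi1, l1) in enumerate(flat):
        for lo2, hi2, l2 in flat[i + 1:]:
            if l1 != l2 and lo1 <= hi2 and lo2 <= hi1:
                warnings.warn(
                    f"subdomain intervals overlap across labels {l1!r} and {l2!r}"
                )
    return SubdomainMap(entries)


def dnak_subdomain_map() -> SubdomainMap:
    """The packaged DnaK subdomain map (NBD IA/IB/IIA/IIB, linker, SBD-beta/alpha)."""
    text = resources.files("felmap.data").joinpath("dnak_subdomains.txt").read_text()
    return load_subdomain_map(text)
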