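"""Replicate-convergence gating, state-pair dissimilarity and the
ligand-specific angle network.

For each ligand state two independent replicate runs are compared angle by
angle with the similarity index H; only angles with H > 0.5 (the DATA set)
are deemed converged and carry interpretable signal.  State pairs are then
compared on the intersection of their DATA sets, the dissimilarity 1 - H is
binned into weak / significant / strong influence, and a four-pattern rule
assigns each angle a specificity category: an angle is X-specific when the
two states other than X share its profile (their comparison is uninfluenced)
while both comparisons involving X are influenced; angles influenced in all
three comparisons are specific to each state.

The classified angles map onto residues (four per angle, i-1 ... i+2) and
onto structural subdomains via the central residue i.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .trajio import SubdomainMap

__all__ = [
    "SimilarityMatrix", "ConvergenceReport", "SpecificityAssignment",
    "ResidueNetwork", "gate_converged", "dissimilarity_bins",
    "classify_specificity", "residues_of_angles", "locate_network",
    "load_table3_fixture", "STATE_PAIRS", "INFLUENCE_THRESHOLD",
    "STRONG_THRESHOLD",
]

#: 1 - H at and above which a comparison counts as influenced / significant
INFLUENCE_THRESHOLD = 0.3
#: 1 - H at and above which a comparison counts as strongly influenced
STRONG_THRESHOLD = 0.7

STATE_PAIRS = (("APO", "ADP"), ("APO", "ATP"), ("ADP", "ATP"))
CATEGORIES = ("APO_specific", "ADP_specific", "ATP_specific",
              "EACH_specific", "NONE")


@dataclass
class SimilarityMatrix:
    """Per-angle H values for labelled run-pair or state-pair comparisons."""

    angle_indices: np.ndarray
    columns: dict[str, np.ndarray]
    influenced_flags: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.angle_indices = np.asarray(self.angle_indices, dtype=int)
        for label, vals in self.columns.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != self.angle_indices.shape:
                raise ValueError(f"column {label!r} length mismatch")
            if np.any((vals < 0) | (vals > 1)):
                raise ValueError(f"H values in column {label!r} outside [0, 1]")
            self.columns[label] = vals

    def column(self, label: str) -> np.ndarray:
        return self.columns[label]


@dataclass
class ConvergenceReport:
    """Angles passing the replicate gate (the DATA set) for one state."""

    state: str
    data_angles: np.ndarray
    n_total: int

    @property
    def n_pass(self) -> int:
        return int(self.data_angles.shape[0])

    @property
    def percent_converged(self) -> float:
        return 100.0 * self.n_pass / self.n_total


@dataclass
class SpecificityAssignment:
    """Category per angle; counts per category derived on demand."""

    categories: dict[int, str]
    reasons: dict[int, str] = field(default_factory=dict)

    def count(self, category: str) -> int:
        return sum(1 for c in self.categories.values() if c == category)

    def angles_in(self, category: str) -> list[int]:
        return sorted(i for i, c in self.categories.items() if c == category)

    @property
    def counts(self) -> dict[str, int]:
        return {c: self.count(c) for c in CATEGORIES}


@dataclass
class ResidueNetwork:
    """Residues touched by a set of angles (union of i-1 ... i+2)."""

    angles: np.ndarray
    residues: np.ndarray

    @property
    def n_residues(self) -> int:
        return int(self.residues.shape[0])


def gate_converged(matrix: SimilarityMatrix, column: str, state: str | None = None,
                   threshold: float = 0.5) -> ConvergenceReport:
    """Keep angles whose replicate similarity is strictly above ``threshold``."""
    h = matrix.column(column)
    keep = matrix.angle_indices[h > threshold]
    return ConvergenceReport(state or column, keep, int(matrix.angle_indices.size))


def dissimilarity_bins(h_values) -> np.ndarray:
    """Bin 1 - H into 'weak' (< 0.3), 'significant' ([0.3, 0.7)), 'strong' (>= 0.7).

    The 1 - H = 0.3 boundary is assigned upward (significant), matching the
    convention under which every printed network angle classifies consistently.
    """
    h = np.asarray(h_values, dtype=float)
    d = 1.0 - h
    out = np.where(d >= STRONG_THRESHOLD, "strong",
                   np.where(d >= INFLUENCE_THRESHOLD, "significant", "weak"))
    return out.astype(object)


def _influenced(h: float) -> bool:
    # influenced <=> 1 - H >= 0.3, evaluated on printed 2-decimal values too;
    # round-half-up guard keeps H = 0.70 exactly on the influenced side
    return (1.0 - h) >= INFLUENCE_THRESHOLD - 1e-12


def classify_specificity(matrix: SimilarityMatrix,
                         use_flags: bool = False) -> SpecificityAssignment:
    """Assign each angle one of the five specificity categories.

    ``matrix`` must carry the three state-pair columns 'APO/ADP', 'APO/ATP'
    and 'ADP/ATP'.  With ``use_flags`` the per-cell influenced flags (e.g.
    a table's printed bold marks) replace the 1 - H >= 0.3 threshold.
    """
    labels = [f"{a}/{b}" for a, b in STATE_PAIRS]
    missing = [l for l in labels if l not in matrix.columns]
    categories: dict[int, str] = {}
    reasons: dict[int, str] = {}
    if missing:
        for i in matrix.angle_indices:
            categories[int(i)] = "NONE"
            reasons[int(i)] = f"missing comparison(s): {', '.join(missing)}"
        return SpecificityAssignment(categories, reasons)

    for row, i in enumerate(matrix.angle_indices):
        if use_flags:
            if matrix.influenced_flags is None:
                raise ValueError("matrix carries no influenced flags")
            infl = {l: bool(matrix.influenced_flags[l][row]) for l in labels}
        else:
            infl = {l: _influenced(matrix.columns[l][row]) for l in labels}
        cat = "NONE"
        if all(infl.values()):
            cat = "EACH_specific"
        else:
            for x in ("APO", "ADP", "ATP"):
                others = [l for l in labels if x in l]
                excl = [l for l in labels if x not in l][0]
                if not infl[excl] and all(infl[l] for l in others):
                    cat = f"{x}_specific"
                    break
        categories[int(i)] = cat
    return SpecificityAssignment(categories, reasons)


def residues_of_angles(angles) -> ResidueNetwork:
    """Union of the four residues i-1 ... i+2 defining each angle."""
    angles = np.asarray(sorted(set(int(a) for a in angles)), dtype=int)
    residues: set[int] = set()
    for i in angles:
        residues.update(range(i - 1, i + 3))
    return ResidueNetwork(angles, np.asarray(sorted(residues), dtype=int))


def locate_network(angles, subdomains: SubdomainMap) -> dict[str, int]:
    """Per-subdomain counts of angles, each assigned by its central residue i.

    Returns a dict with one entry per map label plus 'unassigned' where
    needed, and aggregate 'NBD' / 'SBD' totals when the map uses the
    NBD-*/SBD-* naming.
    """
    counts: dict[str, int] = {}
    for i in angles:
        label = subdomains.label_of(int(i))
        counts[label] = counts.get(label, 0) + 1
    nbd = sum(v for k, v in counts.items() if k.startswith("NBD"))
    sbd = sum(v for k, v in counts.items() if k.startswith("SBD"))
    if nbd or sbd:
        counts["NBD"] = nbd
        counts["SBD"] = sbd
    return counts


def load_table3_fixture() -> SimilarityMatrix:
    """The packaged 27-angle x 3-comparison H matrix of the DnaK network,
    with the printed influenced (bold) flags and subdomain labels."""
    text = resources.files("felmap.data").joinpath("table3.tsv").read_text()
    import io

    df = pd.read_csv(io.StringIO(text), sep="\t")
    labels = {"APO/ADP": "APO_ADP", "APO/ATP": "APO_ATP", "ADP/ATP": "ADP_ATP"}
    matrix = SimilarityMatrix(
        df["angle"].to_numpy(int),
        {lab: df[f"H_{col}"].to_numpy(float) for lab, col in labels.items()},
        {lab: df[f"bold_{col}"].to_numpy(bool) for lab, col in labels.items()},
    )
    matrix.locations = dict(zip(df["angle"].astype(int), df["location"]))
    matrix.residue_strings = dict(zip(df["angle"].astype(int), df["residues"]))
    return matrix
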