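"""Circular PDFs, Boltzmann-inverted free-energy profiles and the
similarity index H.

A dihedral's sampled distribution p(gamma) is estimated as a normalized
histogram on a uniform partition of [-180, +180) (default 72 bins of 5
degrees; +180 samples are counted in the last bin, consistent with the
(-180, +180] codomain of the angles).  The free-energy profile is the
Boltzmann inversion V(gamma) = -ln p(gamma) in kBT, shifted so its finite
minimum is zero; empty bins carry +inf.

Two PDFs of the same angle are compared with the similarity index
H in [0, 1] (1 = identical, 0 = disjoint).  The default kernel is the
Bhattacharyya coefficient sum_b sqrt(p1_b * p2_b); the histogram-overlap
kernel sum_b min(p1_b, p2_b) is available as an alternative.  Two replicate
profiles are considered converged when H > 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AngularPDF", "FEProfile", "estimate_pdf", "boltzmann_fep",
           "similarity_H", "average_pdf", "CONVERGENCE_THRESHOLD"]

DEFAULT_N_BINS = 72
DEFAULT_TEMPERATURE_K = 300.0
#: replicate FEPs are "converged" iff H exceeds this (strict)
CONVERGENCE_THRESHOLD = 0.5


@dataclass
class AngularPDF:
    """Binned circular probability density over [-180, +180)."""

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.bin_edges.shape[0] != self.probabilities.shape[0] + 1:
            raise ValueError("need n_bins + 1 edges")
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0]):
            raise ValueError("bins must be uniform")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @property
    def n_bins(self) -> int:
        return self.probabilities.shape[0]

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def same_binning(self, other: "AngularPDF") -> bool:
        return self.n_bins == other.n_bins and np.allclose(
            self.bin_edges, other.bin_edges
        )


@dataclass
class FEProfile:
    """Free energy per bin in kBT; empty bins are +inf, finite minimum is 0."""

    bin_centers: np.ndarray
    values: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_centers.shape != self.values.shape:
            raise ValueError("one value per bin center required")

    def minimum_position(self) -> float:
        """Bin center of the profile minimum (the most probable gamma)."""
        return float(self.bin_centers[int(np.argmin(self.values))])


def _check_binning(p1: AngularPDF, p2: AngularPDF) -> None:
    if not p1.same_binning(p2):
        raise ValueError("PDFs have mismatched binning")


def estimate_pdf(samples, n_bins: int = DEFAULT_N_BINS) -> AngularPDF:
    """Histogram PDF of one angle's frame values (degrees in (-180, +180])."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("cannot estimate a PDF from an empty series")
    if samples.min() <= -180.0 or samples.max() > 180.0:
        raise ValueError("samples must lie in (-180, +180]")
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    # +180 belongs to the last bin: nudge exactly-+180 samples inside
    clipped = np.minimum(samples, np.nextafter(180.0, -np.inf))
    counts, _ = np.histogram(clipped, bins=edges)
    return AngularPDF(edges, counts / counts.sum())


def boltzmann_fep(pdf: AngularPDF,
                  temperature: float = DEFAULT_TEMPERATURE_K) -> FEProfile:
    """V_b = -ln p_b (kBT), shifted so the finite minimum is zero."""
    p = pdf.probabilities
    if np.all(p == 0):
        raise ValueError("all-empty PDF has no free-energy profile")
    with np.errstate(divide="ignore"):
        v = -np.log(p)
    v = v - v[np.isfinite(v)].min()
    return FEProfile(pdf.bin_centers, v, temperature)


def similarity_H(p1: AngularPDF, p2: AngularPDF,
                 kernel: str = "bhattacharyya") -> float:
    """Similarity index H in [0, 1] between two PDFs on identical bins."""
    _check_binning(p1, p2)
    a, b = p1.probabilities, p2.probabilities
    if kernel == "bhattacharyya":
        h = float(np.sqrt(a * b).sum())
    elif kernel == "overlap":
        h = float(np.minimum(a, b).sum())
    else:
        raise ValueError(f"unknown similarity kernel {kernel!r}")
    return min(h, 1.0)  # guard rounding above 1


def average_pdf(p1: AngularPDF, p2: AngularPDF) -> AngularPDF:
    """Bin-wise mean of two replicate PDFs, P = (p1 + p2) / 2."""
    _check_binning(p1, p2)
    return AngularPDF(p1.bin_edges, 0.5 * (p1.probabilities + p2.probabilities))
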