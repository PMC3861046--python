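"""Dihedral principal component analysis (dPCA).

Each dihedral gamma_i is embedded on the unit circle as the pair
u_i = (cos gamma_i, sin gamma_i), which removes the artificial periodic
boundary of the raw angle.  The 2n-dimensional covariance matrix of the
embedding (population normalizer, plain average over frames) is
diagonalized; eigenvalues lambda^k sorted descending carry the variance of
the collective modes, and the influence Delta_i^k -- the squared weight of
eigenvector e^k on angle i's (cos, sin) slots -- measures each angle's share
of mode k (sum_i Delta_i^k = 1).  The mean-square fluctuation of each
embedded angle decomposes exactly over modes, MSF_i = sum_k lambda^k
Delta_i^k.  Projections dPC^k(t) = (u(t) - <u>) . e^k are the collective
coordinates used downstream for the 2D free-energy surface.

The cosine content of a principal component (Hess's diagnostic) compares it
with a half-period cosine: values near 1 flag random-walk-like undersampling,
in which case apparent free-energy basins are sampling artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cgda import DihedralSeries

__all__ = ["SinCosEmbedding", "DPCAModel", "PCSeries", "embed", "fit_dpca",
           "msf_decompose", "project", "cosine_content"]


@dataclass
class SinCosEmbedding:
    """Frames x 2n matrix, columns ordered (cos g_i1, sin g_i1, cos g_i2, ...)."""

    angle_indices: np.ndarray
    vectors: np.ndarray
    frame_times: np.ndarray

    @property
    def n_angles(self) -> int:
        return self.angle_indices.shape[0]

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[0]


@dataclass
class DPCAModel:
    mean: np.ndarray            # (2n,)
    eigenvalues: np.ndarray     # (2n,) descending
    eigenvectors: np.ndarray    # (2n, 2n), column k = e^k
    influences: np.ndarray      # (n, 2n): Delta_i^k
    angle_indices: np.ndarray

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())

    def variance_fractions(self) -> np.ndarray:
        tot = self.total_variance
        if tot == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / tot


@dataclass
class PCSeries:
    mode: int                   # 1-based rank
    values: np.ndarray
    frame_times: np.ndarray


def embed(series: DihedralSeries, subset=None) -> SinCosEmbedding:
    """Sin/cos embedding of a (subset of a) dihedral series."""
    sub = series if subset is None else series.subset(subset)
    rad = np.radians(sub.values)
    n_frames, n = rad.shape
    vec = np.empty((n_frames, 2 * n))
    vec[:, 0::2] = np.cos(rad)
    vec[:, 1::2] = np.sin(rad)
    return SinCosEmbedding(sub.angle_indices, vec, sub.frame_times)


def fit_dpca(emb: SinCosEmbedding) -> DPCAModel:
    """Eigen-decomposition of the embedding covariance.

    Eigenvector signs are fixed so each mode's largest-magnitude component
    is positive, making projections reproducible across platforms.
    """
    x = emb.vectors
    if x.shape[0] < 2:
        raise ValueError("at least two frames are required")
    mean = x.mean(axis=0)
    centered = x - mean
    cov = centered.T @ centered / x.shape[0]   # population (1/N) normalizer
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for k in range(evecs.shape[1]):
        j = int(np.argmax(np.abs(evecs[:, k])))
        if evecs[j, k] < 0:
            evecs[:, k] *= -1
    n = emb.n_angles
    influences = evecs[0::2, :] ** 2 + evecs[1::2, :] ** 2   # (n, 2n)
    return DPCAModel(mean, evals, evecs, influences, emb.angle_indices)


def msf_decompose(model: DPCAModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-angle mean-square fluctuation and its per-mode contributions.

    Returns ``(msf, contrib)`` with ``msf[i] = sum_k contrib[i, k]`` and
    ``contrib[i, k] = lambda^k * Delta_i^k``.
    """
    contrib = model.influences * model.eigenvalues[None, :]
    return contrib.sum(axis=1), contrib


def project(emb: SinCosEmbedding, model: DPCAModel, k: int) -> PCSeries:
    """Projection dPC^k(t) of the embedding on eigenvector k (1-based)."""
    if not 1 <= k <= model.eigenvectors.shape[1]:
        raise ValueError(f"mode {k} out of range 1..{model.eigenvectors.shape[1]}")
    vals = (emb.vectors - model.mean) @ model.eigenvectors[:, k - 1]
    return PCSeries(k, vals, emb.frame_times)


def cosine_content(pc: PCSeries, k: int | None = None) -> float:
    """Cosine content of a principal component.

    CC = (2/T) (int cos(k pi t / T) p(t) dt)^2 / int p(t)^2 dt, discretized
    with the trapezoid rule on the frame time grid.  ``k`` defaults to the
    PC's rank.  A zero-energy (constant-zero) series has CC = 0 by convention.
    """
    p = np.asarray(pc.values, dtype=float)
    if p.shape[0] < 3:
        raise ValueError("at least 3 frames are required")
    t = np.asarray(pc.frame_times, dtype=float)
    dt = np.diff(t)
    if not np.allclose(dt, dt[0]):
        raise ValueError("cosine content requires uniform time spacing")
    if k is None:
        k = pc.mode
    t0 = t - t[0]
    T = t0[-1]
    cos_k = np.cos(k * np.pi * t0 / T)
    energy = np.trapezoid(p * p, t0)
    if energy == 0:
        return 0.0
    overlap = np.trapezoid(cos_k * p, t0)
    return float(2.0 / T * overlap**2 / energy)
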