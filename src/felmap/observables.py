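"""Structural observables for comparison with scattering and spectroscopy.

Covers the mass-weighted radius of gyration and its between-state
difference, the heavy-atom pair-distance distribution P(r) (the real-space
quantity probed by SAXS), side-chain center-of-mass distance series with
threshold fractions (the EPR "non-interacting" fraction is the fraction of
frames beyond 20 Angstrom), Gaussian-mixture summaries of distance
distributions, conditional dihedral free-energy profiles on frame subsets,
and a windowed-RMSD convergence criterion for trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist

from .cgda import DihedralSeries
from .fep import FEProfile, boltzmann_fep, estimate_pdf
from .trajio import AtomisticTrajectory

__all__ = ["DistanceDistribution", "GaussianSummary", "radius_of_gyration",
           "delta_rg", "pair_distance_distribution", "com_distance_series",
           "fraction_beyond", "gaussian_summary", "conditional_fep",
           "rmsd_convergence", "kabsch_rmsd"]

# standard atomic masses for the elements occurring in protein heavy atoms
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
           "P": 30.974, "SE": 78.971}


def _mass(element: str) -> float:
    return _MASSES.get(element.upper(), 12.011)


@dataclass
class DistanceDistribution:
    """Normalized density over distance bins (Angstrom)."""

    bin_edges: np.ndarray
    density: np.ndarray
    source: str = ""

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class GaussianSummary:
    """Sum-of-Gaussians fit: (weight, mean A, sd A) per component."""

    components: list[tuple[float, float, float]]
    residual_norm: float

    @property
    def means(self) -> list[float]:
        return [m for _, m, _ in self.components]


def radius_of_gyration(traj: AtomisticTrajectory,
                       heavy_only: bool = True) -> np.ndarray:
    """Per-frame mass-weighted radius of gyration in Angstrom."""
    sel = [i for i, a in enumerate(traj.atoms) if a.is_heavy or not heavy_only]
    if not sel:
        raise ValueError("empty atom selection")
    masses = np.array([_mass(traj.atoms[i].element) for i in sel])
    xyz = traj.coords[:, sel, :]
    com = (masses[None, :, None] * xyz).sum(axis=1) / masses.sum()
    d2 = ((xyz - com[:, None, :]) ** 2).sum(axis=2)
    return np.sqrt((masses[None, :] * d2).sum(axis=1) / masses.sum())


def delta_rg(ensemble_a: AtomisticTrajectory,
             ensemble_b: AtomisticTrajectory) -> float:
    """mean Rg(A) - mean Rg(B); e.g. Rg(ADP) - Rg(ATP) for the SAXS contrast."""
    return float(radius_of_gyration(ensemble_a).mean()
                 - radius_of_gyration(ensemble_b).mean())


def pair_distance_distribution(traj: AtomisticTrajectory, bin: float = 1.0,
                               heavy_only: bool = True,
                               frames=None) -> DistanceDistribution:
    """P(r) over all unordered heavy-atom pairs, averaged over frames."""
    sel = [i for i, a in enumerate(traj.atoms) if a.is_heavy or not heavy_only]
    if len(sel) < 2:
        raise ValueError("need at least two selected atoms")
    frame_ids = range(traj.n_frames) if frames is None else frames
    all_d = [pdist(traj.coords[f, sel, :]) for f in frame_ids]
    d = np.concatenate(all_d)
    n_bins = int(np.ceil(d.max() / bin)) + 1
    edges = bin * np.arange(n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    density = counts / (counts.sum() * bin)
    return DistanceDistribution(edges, density, source="frame-averaged P(r)")


def com_distance_series(traj: AtomisticTrajectory, res_a: int, res_b: int,
                        selection: str = "sidechain") -> np.ndarray:
    """Per-frame distance between the (mass-weighted) centers of mass of two
    residues' side chains (heavy atoms excluding backbone N, CA, C, O).

    Glycine (no side-chain heavy atom) falls back to its Calpha.
    """
    def com(res: int) -> np.ndarray:
        idx = [i for i in traj.atom_indices(res, heavy_only=True)
               if selection != "sidechain" or not traj.atoms[i].is_backbone]
        if not idx:  # Gly fallback
            idx = [i for i in traj.atom_indices(res, heavy_only=True)
                   if traj.atoms[i].name == "CA"]
        if not idx:
            raise ValueError(f"residue {res} has no usable atoms")
        m = np.array([_mass(traj.atoms[i].element) for i in idx])
        return (m[None, :, None] * traj.coords[:, idx, :]).sum(axis=1) / m.sum()

    return np.linalg.norm(com(res_a) - com(res_b), axis=1)


def fraction_beyond(series, threshold: float = 20.0) -> float:
    """Fraction of values strictly above ``threshold`` (e.g. f_NI at 20 A)."""
    s = np.asarray(series, dtype=float)
    if s.size == 0:
        raise ValueError("empty series")
    return float(np.mean(s > threshold))


def _gauss_mix(x, *params):
    out = np.zeros_like(x)
    for k in range(0, len(params), 3):
        w, mu, sd = params[k:k + 3]
        out = out + w * np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
    return out


def gaussian_summary(data, n_components: int = 1, bin: float = 0.5,
                     n_starts: int = 8, seed: int = 0) -> GaussianSummary:
    """Multi-start least-squares sum-of-Gaussians fit to a distance histogram.

    ``data`` is either a raw series (binned internally) or a
    :class:`DistanceDistribution`.  Deterministic for a fixed ``seed``.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if isinstance(data, DistanceDistribution):
        x, y = data.bin_centers, data.density
    else:
        s = np.asarray(data, dtype=float)
        edges = np.arange(np.floor(s.min()), np.ceil(s.max()) + bin, bin)
        counts, edges = np.histogram(s, bins=edges)
        y = counts / (counts.sum() * bin)
        x = 0.5 * (edges[:-1] + edges[1:])
    rng = np.random.default_rng(seed)
    span = x.max() - x.min()
    best, best_res = None, np.inf
    for _ in range(n_starts):
        mus = np.sort(x.min() + span * rng.random(n_components))
        p0 = []
        for mu in mus:
            p0.extend([1.0 / n_components, mu, max(span / (4 * n_components), bin)])
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # singular covariances are fine
                popt, _ = curve_fit(_gauss_mix, x, y, p0=p0, maxfev=20000)
        except RuntimeError:
            continue
        popt = np.asarray(popt)
        popt[2::3] = np.abs(popt[2::3])
        if np.any(popt[0::3] < -1e-6):
            continue
        res = float(np.linalg.norm(_gauss_mix(x, *popt) - y))
        if res < best_res:
            best, best_res = popt, res
    if best is None:
        raise RuntimeError("Gaussian fit did not converge from any start")
    comps = [(max(float(best[k]), 0.0), float(best[k + 1]), float(best[k + 2]))
             for k in range(0, len(best), 3)]
    comps.sort(key=lambda c: c[1])  # order components by mean
    return GaussianSummary(comps, best_res)


def conditional_fep(series: DihedralSeries, angle: int, frame_subset,
                    n_bins: int = 72) -> FEProfile:
    """FEP of one angle restricted to a frame subset (e.g. one distance
    subpopulation)."""
    frames = np.asarray(frame_subset, dtype=int)
    if frames.size == 0:
        raise ValueError("empty frame subset")
    return boltzmann_fep(estimate_pdf(series.column(angle)[frames], n_bins=n_bins))


def kabsch_rmsd(reference: np.ndarray, coords: np.ndarray,
                fit: bool = True) -> np.ndarray:
    """Calpha RMSD of each frame to a reference, after optimal (Kabsch)
    rigid-body superposition unless ``fit`` is False."""
    ref = reference - reference.mean(axis=0)
    out = np.empty(coords.shape[0])
    for f in range(coords.shape[0]):
        x = coords[f]
        if fit:
            xc = x - x.mean(axis=0)
            u, _s, vt = np.linalg.svd(xc.T @ ref)
            d = np.sign(np.linalg.det(u @ vt))
            rot = u @ np.diag([1.0, 1.0, d]) @ vt
            xc = xc @ rot
            out[f] = np.sqrt(((xc - ref) ** 2).sum() / ref.shape[0])
        else:
            out[f] = np.sqrt(((x - reference) ** 2).sum() / ref.shape[0])
    return out


def rmsd_convergence(ca_coords: np.ndarray, frame_times: np.ndarray,
                     reference_frame: int = 0, window: float = 10000.0,
                     sd_max: float = 0.5, sustain: float = 50000.0,
                     fit: bool = True):
    """Earliest time from which every rolling RMSD window is quiet.

    The trajectory counts as converged from time t0 when every window of
    length ``window`` ps starting in [t0, t_end - window] has an RMSD
    standard deviation below ``sd_max`` Angstrom, over a span of at least
    ``sustain`` ps.  Returns the time (float) or None with a reason string:
    ``(t0, None)`` or ``(None, reason)``.
    """
    t = np.asarray(frame_times, dtype=float)
    dt = np.diff(t)
    if dt.size and not np.allclose(dt, dt[0]):
        raise ValueError("uniform frame spacing required")
    total = t[-1] - t[0] if t.size > 1 else 0.0
    if total < sustain:
        return None, f"trajectory span {total:g} ps shorter than sustain {sustain:g} ps"
    rmsd = kabsch_rmsd(ca_coords[reference_frame], ca_coords, fit=fit)
    step = dt[0]
    w = max(int(round(window / step)), 2)
    n = rmsd.shape[0]
    if n < w:
        return None, "trajectory shorter than one window"
    sds = np.array([rmsd[i:i + w].std() for i in range(n - w + 1)])
    quiet = sds < sd_max
    need = max(int(np.ceil((sustain - window) / step)) + 1, 1)
    run = 0
    for i in range(quiet.size - 1, -1, -1):  # find last block reaching the end
        if quiet[i]:
            run += 1
        else:
            break
    if run >= need:
        start = quiet.size - run
        return float(t[start]), None
    return None, "no sustained quiet window reaching the end of the trajectory"
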