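"""2D free-energy surface on (dPC1, dPC2) and the pathway of minimum energy.

The surface is a histogram of the two leading dihedral principal components
on a uniform grid (default bin 0.1 per axis); the free energy of a bin is
-ln of its normalized count in kBT, shifted so the global minimum is zero,
with empty bins at +inf (impassable).  Each bin remembers the trajectory
frames it holds, so any point of the surface maps back to conformations and
to time.

The pathway of minimum energy (PME) between two minima A and B is built by
a greedy perpendicular-scan recursion: from the current point, advance one
bin width along the straight line towards the target, scan the segment
perpendicular to that line (clipped to the circle of diameter AB) at bin
resolution, take the finite bin of lowest free energy as the next step, and
re-aim at the target; the walk ends when the current point is within one
bin of the target.  Saddle points of a multi-leg path are the free-energy
maxima strictly between consecutive minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cgda import DihedralSeries
from .dpca import PCSeries
from .fep import FEProfile, boltzmann_fep, estimate_pdf

__all__ = ["FES2D", "Minimum", "MinimaSet", "PMEPath", "PMEError",
           "build_fes", "find_minima", "pme", "chain_pme", "step_profiles"]

DEFAULT_BIN = 0.1
DEFAULT_MINIMA_DEPTH_KBT = 3.0


class PMEError(RuntimeError):
    """Path construction failure (blocked segment or exhausted step budget)."""


@dataclass
class FES2D:
    origin: np.ndarray          # lower-left corner of bin (0, 0)
    bin: float
    counts: np.ndarray          # (nx, ny) integer counts
    free_energy: np.ndarray     # (nx, ny) kBT, +inf on empty bins
    frame_lists: dict[tuple[int, int], np.ndarray]
    frame_times: np.ndarray
    temperature: float = 300.0

    @property
    def n_frames(self) -> int:
        return int(self.counts.sum())

    def bin_of(self, x: float, y: float) -> tuple[int, int]:
        return (int(np.floor((x - self.origin[0]) / self.bin)),
                int(np.floor((y - self.origin[1]) / self.bin)))

    def center_of(self, b: tuple[int, int]) -> np.ndarray:
        return self.origin + (np.asarray(b, float) + 0.5) * self.bin

    def value(self, b: tuple[int, int]) -> float:
        i, j = b
        if 0 <= i < self.free_energy.shape[0] and 0 <= j < self.free_energy.shape[1]:
            return float(self.free_energy[i, j])
        return np.inf


@dataclass(frozen=True)
class Minimum:
    bin: tuple[int, int]
    value: float
    first_visit_time: float
    label: str = ""


@dataclass
class MinimaSet:
    minima: list[Minimum]

    def __iter__(self):
        return iter(self.minima)

    def __len__(self):
        return len(self.minima)

    def __getitem__(self, k):
        return self.minima[k]


@dataclass
class PMEPath:
    steps: list[tuple[int, int]]
    values: np.ndarray                      # V per step, kBT
    saddle_indices: list[int]               # step index of each leg's saddle
    leg_boundaries: list[int]               # step index of each minimum on path
    frame_lists: list[np.ndarray] = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def barriers(self) -> list[float]:
        """Per-leg barrier: V(saddle) - V(leg start)."""
        out = []
        for s, start in zip(self.saddle_indices, self.leg_boundaries[:-1]):
            out.append(float(self.values[s] - self.values[start]))
        return out


def build_fes(pc1: PCSeries, pc2: PCSeries, bin: float = DEFAULT_BIN,
              temperature: float = 300.0) -> FES2D:
    """Histogram the two collective coordinates and Boltzmann-invert."""
    x = np.asarray(pc1.values, float)
    y = np.asarray(pc2.values, float)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("need two equal-length, non-empty series")
    origin = np.array([np.floor(x.min() / bin) * bin,
                       np.floor(y.min() / bin) * bin])
    ix = np.floor((x - origin[0]) / bin).astype(int)
    iy = np.floor((y - origin[1]) / bin).astype(int)
    nx, ny = ix.max() + 1, iy.max() + 1
    counts = np.zeros((nx, ny), dtype=int)
    np.add.at(counts, (ix, iy), 1)
    frame_lists: dict[tuple[int, int], np.ndarray] = {}
    order = np.lexsort((iy, ix))
    flat = ix[order] * ny + iy[order]
    bounds = np.flatnonzero(np.diff(flat)) + 1
    for chunk in np.split(order, bounds):
        frame_lists[(int(ix[chunk[0]]), int(iy[chunk[0]]))] = np.sort(chunk)
    with np.errstate(divide="ignore"):
        v = -np.log(counts / counts.sum())
    v = v - v[np.isfinite(v)].min()
    return FES2D(origin, float(bin), counts, v, frame_lists,
                 np.asarray(pc1.frame_times, float), temperature)


_NEIGH = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]


def find_minima(fes: FES2D, depth: float = DEFAULT_MINIMA_DEPTH_KBT) -> MinimaSet:
    """Strict 8-neighbourhood local minima on the finite grid, retained iff
    within ``depth`` kBT of the global minimum, ordered chronologically by
    first visit.  Flat ties resolve to the lowest (row, col) bin."""
    v = fes.free_energy
    finite = np.isfinite(v)
    if not finite.any():
        raise ValueError("surface has no finite bins")
    vmin = v[finite].min()
    minima: list[Minimum] = []
    for i, j in zip(*np.nonzero(finite)):
        val = v[i, j]
        if val > vmin + depth:
            continue
        is_min = True
        for di, dj in _NEIGH:
            nb = (i + di, j + dj)
            nv = fes.value(nb)
            if nv < val or (nv == val and nb < (int(i), int(j))):
                is_min = False
                break
        if is_min:
            frames = fes.frame_lists[(int(i), int(j))]
            minima.append(Minimum((int(i), int(j)), float(val),
                                  float(fes.frame_times[frames[0]])))
    minima.sort(key=lambda m: m.first_visit_time)
    return MinimaSet([Minimum(m.bin, m.value, m.first_visit_time,
                              label=f"A{k + 1}")
                      for k, m in enumerate(minima)])


def _scan_segment(fes: FES2D, m: np.ndarray, q: np.ndarray,
                  circle_center: np.ndarray, radius: float
                  ) -> list[tuple[int, int]]:
    """Candidate bins along the perpendicular segment through ``m``,
    clipped to the leg's circle, at one-bin resolution."""
    w = m - circle_center
    wq = float(w @ q)
    disc = wq * wq - (float(w @ w) - radius * radius)
    if disc < 0:
        offsets = [0.0]
    else:
        root = np.sqrt(disc)
        s_lo, s_hi = -wq - root, -wq + root
        j_lo = int(np.ceil(s_lo / fes.bin))
        j_hi = int(np.floor(s_hi / fes.bin))
        offsets = [j * fes.bin for j in range(j_lo, j_hi + 1)]
        if s_lo <= 0.0 <= s_hi and 0.0 not in offsets:
            offsets.append(0.0)
    bins = []
    seen = set()
    for s in offsets:
        b = fes.bin_of(*(m + s * q))
        if b not in seen:
            seen.add(b)
            bins.append(b)
    return bins


def pme(fes: FES2D, start: Minimum | tuple[int, int],
        end: Minimum | tuple[int, int],
        max_steps: int | None = None) -> PMEPath:
    """Greedy perpendicular-scan pathway of minimum energy between two minima."""
    b_start = start.bin if isinstance(start, Minimum) else tuple(start)
    b_end = end.bin if isinstance(end, Minimum) else tuple(end)
    if b_start == b_end:
        raise ValueError("start and end minima must differ")
    for b in (b_start, b_end):
        if not np.isfinite(fes.value(b)):
            raise ValueError(f"bin {b} is not on the finite grid")

    a = fes.center_of(b_start)
    t = fes.center_of(b_end)
    if max_steps is None:
        max_steps = max(10, int(10 * np.linalg.norm(t - a) / fes.bin))

    # The perpendicular segment at each step is clipped to the circle whose
    # diameter is the current interpolation segment (current point ->
    # target); every candidate is then strictly closer to the target than
    # the current point, so the walk provably terminates.
    steps = [b_start]
    c = a.copy()
    for _ in range(max_steps):
        if np.linalg.norm(c - t) < fes.bin:
            break
        d = (t - c) / np.linalg.norm(t - c)
        m = c + fes.bin * d
        q = np.array([-d[1], d[0]])
        circle_center = 0.5 * (c + t)
        radius = 0.5 * float(np.linalg.norm(t - c))
        candidates = [b for b in _scan_segment(fes, m, q, circle_center, radius)
                      if np.isfinite(fes.value(b))]
        if not candidates:
            raise PMEError(
                f"no finite bin on the perpendicular segment at step {len(steps)}"
            )
        best = min(candidates, key=lambda b: (fes.value(b), b))
        if best != steps[-1]:
            steps.append(best)
        c = fes.center_of(best)
    else:
        raise PMEError(f"path did not terminate within {max_steps} steps")

    if steps[-1] != b_end:
        steps.append(b_end)
    values = np.array([fes.value(b) for b in steps])
    frames = [fes.frame_lists.get(b, np.empty(0, int)) for b in steps]
    saddles = []
    if len(steps) > 2:
        saddles = [1 + int(np.argmax(values[1:-1]))]
    return PMEPath(steps, values, saddles, [0, len(steps) - 1], frames)


def chain_pme(fes: FES2D, ordered_minima) -> PMEPath:
    """Concatenated PME through an ordered list of minima, with one saddle
    (interior free-energy maximum) per leg."""
    minima = list(ordered_minima)
    if len(minima) < 2:
        raise ValueError("at least two minima are required")
    steps: list[tuple[int, int]] = []
    boundaries: list[int] = []
    for k, (a, b) in enumerate(zip(minima, minima[1:])):
        leg = pme(fes, a, b)
        if k == 0:
            boundaries.append(0)
            steps.extend(leg.steps)
        else:
            boundaries.append(len(steps) - 1)  # joint minimum already on path
            steps.extend(leg.steps[1:])
    boundaries.append(len(steps) - 1)
    values = np.array([fes.value(s) for s in steps])
    saddles: list[int] = []
    for lo, hi in zip(boundaries, boundaries[1:]):
        if hi - lo >= 2:
            saddles.append(lo + 1 + int(np.argmax(values[lo + 1:hi])))
    frames = [fes.frame_lists.get(s, np.empty(0, int)) for s in steps]
    return PMEPath(steps, values, saddles, boundaries, frames)


@dataclass
class StepProfile:
    step: int
    n_frames: int
    first_visit_time: float | None
    feps: dict[int, FEProfile]
    most_probable: dict[int, float]
    empty: bool = False


def step_profiles(fes: FES2D, path: PMEPath, series: DihedralSeries,
                  angles, n_bins: int = 72) -> list[StepProfile]:
    """Per-step dihedral free-energy profiles along a path.

    For each path step s_j, the frames N(s_j) assigned to its bin yield a
    FEP per requested angle; gamma_i(s_j) is the bin center of that FEP's
    minimum (the most probable local conformation at that step).
    """
    out = []
    for j, frames in enumerate(path.frame_lists):
        if frames.size == 0:
            out.append(StepProfile(j, 0, None, {}, {}, empty=True))
            continue
        feps: dict[int, FEProfile] = {}
        most: dict[int, float] = {}
        for i in angles:
            vals = series.column(i)[frames]
            prof = boltzmann_fep(estimate_pdf(vals, n_bins=n_bins))
            feps[int(i)] = prof
            most[int(i)] = prof.minimum_position()
        out.append(StepProfile(j, int(frames.size),
                               float(series.frame_times[frames].min()),
                               feps, most))
    return out
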