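"""Synthetic trajectory generation and packaged in-study fixtures.

The generator produces the controlled inputs the rest of the toolkit is
validated against: per-angle time series drawn by Metropolis sampling from
prescribed circular potentials (single wells, mixture-of-wells, tabulated),
3D Calpha chains rebuilt from dihedral series by internal-coordinate
construction, replicate ensembles for three ligand states with planted
state-specific angles, and diffusive 2D walks on prescribed surfaces for
the free-energy-surface and path machinery.

Potentials are defined in kBT on the circular domain (-180, +180].  The
mixture (``double_well`` / ``multi_well``) form is

    V(g) = -ln sum_j exp(-(depth_j + stiffness_j/2 * d_j(g)^2))

with d_j the circular distance to center j in degrees, so the stationary
density exp(-V) is known in closed form and sampled profiles can be checked
against it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cgda import DihedralSeries
from .trajio import CalphaTrajectory

__all__ = ["PotentialSpec", "EnsembleSpec", "sample_dihedrals", "build_chain",
           "make_state_ensembles", "diffuse_2d", "fixtures"]

STATES = ("APO", "ADP", "ATP")


def circular_delta(a, b):
    """Signed circular difference a - b folded into (-180, 180] degrees."""
    d = (np.asarray(a, float) - np.asarray(b, float)) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


@dataclass
class PotentialSpec:
    """Circular potential in kBT.

    form 'harmonic': single center/stiffness; 'double_well'/'multi_well':
    mixture of harmonic wells with per-well depth offsets; 'tabulated':
    values on a uniform grid over [-180, 180).
    """

    form: str
    centers: list[float] = field(default_factory=lambda: [0.0])
    stiffness: list[float] = field(default_factory=lambda: [0.01])
    depths: list[float] = field(default_factory=list)
    table: np.ndarray | None = None
    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.form not in ("harmonic", "double_well", "multi_well", "tabulated"):
            raise ValueError(f"unknown potential form {self.form!r}")
        if not self.depths:
            self.depths = [0.0] * len(self.centers)
        if len(self.stiffness) == 1 and len(self.centers) > 1:
            self.stiffness = self.stiffness * len(self.centers)

    def energy(self, gamma) -> np.ndarray:
        """V(gamma) in kBT; gamma in degrees, periodic."""
        g = np.asarray(gamma, dtype=float)
        if self.form == "tabulated":
            tab = np.asarray(self.table, float)
            n = tab.shape[0]
            idx = np.floor((g + 180.0) / 360.0 * n).astype(int) % n
            return tab[idx]
        if self.form == "harmonic":
            d = circular_delta(g, self.centers[0])
            return 0.5 * self.stiffness[0] * d * d
        terms = []
        for c, k, d0 in zip(self.centers, self.stiffness, self.depths):
            d = circular_delta(g, c)
            terms.append(-(d0 + 0.5 * k * d * d))
        logs = np.stack(terms)
        m = logs.max(axis=0)
        return -(m + np.log(np.exp(logs - m).sum(axis=0)))


def _scalar_energy(spec: PotentialSpec):
    """Plain-float energy function for the tight Metropolis loop."""
    import math

    if spec.form == "tabulated":
        tab = [float(v) for v in np.asarray(spec.table, float)]
        n = len(tab)

        def e_tab(g: float) -> float:
            return tab[int((g + 180.0) / 360.0 * n) % n]

        return e_tab
    if spec.form == "harmonic":
        c0, k0 = float(spec.centers[0]), float(spec.stiffness[0])

        def e_harm(g: float) -> float:
            d = (g - c0) % 360.0
            if d > 180.0:
                d -= 360.0
            return 0.5 * k0 * d * d

        return e_harm
    wells = [(float(c), float(k), float(d0))
             for c, k, d0 in zip(spec.centers, spec.stiffness, spec.depths)]

    def e_mix(g: float) -> float:
        logs = []
        for c, k, d0 in wells:
            d = (g - c) % 360.0
            if d > 180.0:
                d -= 360.0
            logs.append(-(d0 + 0.5 * k * d * d))
        m = max(logs)
        return -(m + math.log(sum(math.exp(v - m) for v in logs)))

    return e_mix


def sample_dihedrals(spec: PotentialSpec, n_frames: int, seed: int,
                     proposal_width: float = 40.0,
                     burn_in: int = 500) -> np.ndarray:
    """Metropolis chain targeting exp(-V); reproducible per seed.

    Returns ``n_frames`` values in (-180, +180] degrees.
    """
    import math

    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    energy = _scalar_energy(spec)
    g = float(spec.centers[0]) if spec.form != "tabulated" else 0.0
    e = energy(g)
    out = np.empty(n_frames)
    proposals = rng.uniform(-proposal_width, proposal_width, burn_in + n_frames)
    accept_u = rng.random(burn_in + n_frames)
    for i in range(burn_in + n_frames):
        cand = (g + proposals[i]) % 360.0
        if cand > 180.0:
            cand -= 360.0
        if cand <= -180.0:
            cand = 180.0
        e_cand = energy(cand)
        if e_cand <= e or accept_u[i] < math.exp(e - e_cand):
            g, e = cand, e_cand
        if i >= burn_in:
            out[i - burn_in] = g
    return out


def build_chain(dihedrals, bond_length: float = 3.8, bond_angle: float = 120.0,
                frame_times=None, first_residue: int = 1) -> CalphaTrajectory:
    """Internal-coordinate chain construction from per-frame dihedral vectors.

    Fixed virtual-bond length (Angstrom) and planar bond angle (degrees);
    the resulting chain's dihedrals reproduce the inputs exactly, so this is
    the inverse of the dihedral extraction up to rigid motion.
    """
    gam = np.atleast_2d(np.asarray(dihedrals, dtype=float))
    n_frames, n_angles = gam.shape
    if not 0.0 < bond_angle < 180.0:
        raise ValueError("bond angle must lie strictly between 0 and 180 degrees")
    theta = np.radians(bond_angle)
    b = bond_length
    n_res = n_angles + 3
    coords = np.empty((n_frames, n_res, 3))
    coords[:, 0] = (0.0, 0.0, 0.0)
    coords[:, 1] = (b, 0.0, 0.0)
    coords[:, 2] = coords[:, 1] + b * np.array(
        [-np.cos(theta), np.sin(theta), 0.0]
    )
    for j in range(3, n_res):
        a_prev = coords[:, j - 3]
        b_prev = coords[:, j - 2]
        c_prev = coords[:, j - 1]
        axis = c_prev - b_prev
        a_hat = axis / np.linalg.norm(axis, axis=1, keepdims=True)
        u = a_prev - b_prev
        u_perp = u - (np.einsum("fi,fi->f", u, a_hat))[:, None] * a_hat
        e1 = u_perp / np.linalg.norm(u_perp, axis=1, keepdims=True)
        e2 = np.cross(a_hat, e1)
        g = np.radians(gam[:, j - 3])[:, None]
        coords[:, j] = (
            c_prev
            - b * np.cos(theta) * a_hat
            + b * np.sin(theta) * (np.cos(g) * e1 + np.sin(g) * e2)
        )
    if frame_times is None:
        frame_times = 2.0 * np.arange(n_frames)
    return CalphaTrajectory(
        residue_numbers=first_residue + np.arange(n_res),
        coords=coords,
        frame_times=np.asarray(frame_times, float),
    )


@dataclass
class EnsembleSpec:
    """Design of a three-state, replicated synthetic ensemble.

    ``planted`` maps an angle index to a specificity category
    ('APO_specific', 'ADP_specific', 'ATP_specific', 'EACH_specific'); all
    other angles share one generator across states and runs (differing only
    in sampling seed), so they come out converged and uninfluenced.
    """

    n_angles: int
    n_frames: int = 10_000
    n_runs: int = 2
    seed: int = 0
    first_angle_index: int = 5
    planted: dict[int, str] = field(default_factory=dict)
    base_stiffness: float = 0.008       # kBT/deg^2 -> sd ~ 11 deg
    shift_deg: float = 90.0             # planted-state well displacement

    def angle_indices(self) -> np.ndarray:
        return self.first_angle_index + np.arange(self.n_angles)


def _state_center(base: float, state: str, category: str | None,
                  shift: float) -> float:
    """Well center for one angle in one state under the planting rules."""
    if category is None:
        return base
    if category == "EACH_specific":
        offset = {"APO": 0.0, "ADP": shift, "ATP": -shift}[state]
        return float(circular_delta(base + offset, 0.0))
    x = category.split("_")[0]
    if state == x:
        return float(circular_delta(base + shift, 0.0))
    return base


def make_state_ensembles(spec: EnsembleSpec) -> dict[str, list[DihedralSeries]]:
    """Replicated dihedral ensembles for the three ligand states.

    Planted X-specific angles share identical generators in the two non-X
    states and occupy a well displaced by ``shift_deg`` in state X;
    EACH-specific angles have three distinct wells.
    """
    rng = np.random.default_rng(spec.seed)
    base_centers = rng.uniform(-150.0, 150.0, spec.n_angles)
    indices = spec.angle_indices()
    out: dict[str, list[DihedralSeries]] = {}
    times = 2.0 * np.arange(spec.n_frames)
    for s_idx, state in enumerate(STATES):
        runs = []
        for run in range(spec.n_runs):
            values = np.empty((spec.n_frames, spec.n_angles))
            for a in range(spec.n_angles):
                idx = int(indices[a])
                cat = spec.planted.get(idx)
                center = _state_center(base_centers[a], state, cat,
                                       spec.shift_deg)
                pot = PotentialSpec("harmonic", centers=[center],
                                    stiffness=[spec.base_stiffness])
                # seed depends on state only through the planted generator:
                # unplanted angles use the same chain across states per run
                gen_key = s_idx if cat is not None else 0
                sample_seed = (spec.seed + 1) * 1_000_003 + a * 101 + run * 17 + gen_key * 7919
                values[:, a] = sample_dihedrals(pot, spec.n_frames,
                                                seed=sample_seed % (2**31))
            runs.append(DihedralSeries(indices, values, times))
        out[state] = runs
    return out


def diffuse_2d(surface, n_steps: int, seed: int,
               start=(0.0, 0.0), step_sd: float = 0.15,
               bounds=((-3.0, 3.0), (-3.0, 3.0))) -> tuple[np.ndarray, np.ndarray]:
    """Overdamped Metropolis walk on a 2D potential (kBT).

    ``surface`` is a callable V(x, y); positions outside ``bounds`` are
    rejected.  The long-run histogram converges to the Boltzmann density of
    the surface.  Returns the two coordinate series.
    """
    rng = np.random.default_rng(seed)
    (x_lo, x_hi), (y_lo, y_hi) = bounds
    x, y = float(start[0]), float(start[1])
    e = float(surface(x, y))
    xs = np.empty(n_steps)
    ys = np.empty(n_steps)
    steps = rng.normal(0.0, step_sd, (n_steps, 2))
    accept_u = rng.random(n_steps)
    for i in range(n_steps):
        cx, cy = x + steps[i, 0], y + steps[i, 1]
        if x_lo <= cx <= x_hi and y_lo <= cy <= y_hi:
            e_cand = float(surface(cx, cy))
            if e_cand <= e or accept_u[i] < np.exp(e - e_cand):
                x, y, e = cx, cy, e_cand
        xs[i] = x
        ys[i] = y
    return xs, ys


def fixtures() -> dict:
    """Packaged in-study fixtures: the 27x3 similarity matrix with
    influenced flags and subdomain labels, the DnaK subdomain map, and the
    printed replicate-convergence and dissimilarity count tables."""
    from .statecompare import load_table3_fixture
    from .trajio import dnak_subdomain_map

    return {
        "table3": load_table3_fixture(),
        "subdomains": dnak_subdomain_map(),
        "data_counts": {"APO": (471, 597), "ADP": (449, 597),
                        "ATP": (447, 597)},
        "dissimilarity_counts": {
            "APO/ADP": {"strong": 6, "significant": 41, "weak": 341,
                        "total": 388,
                        "percent": {"strong": 1.6, "significant": 10.6,
                                    "weak": 87.8}},
            "APO/ATP": {"strong": 6, "significant": 26, "weak": 347,
                        "total": 379,
                        "percent": {"strong": 1.6, "significant": 6.9,
                                    "weak": 91.5}},
            "ADP/ATP": {"strong": 9, "significant": 25, "weak": 329,
                        "total": 363,
                        "percent": {"strong": 2.5, "significant": 6.9,
                                    "weak": 90.6}},
        },
    }
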