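import numpy as np
import pytest

from felmap import fes as fes_mod
from felmap import synthgen
from felmap.cgda import DihedralSeries
from felmap.dpca import PCSeries
from felmap.fes import FES2D, build_fes, chain_pme, find_minima, pme, step_profiles


def analytic_fes(v_func, x_lo=-2.0, x_hi=2.0, y_lo=-1.0, y_hi=1.0, bin=0.1,
                 v_max=30.0):
    """FES2D built directly from an analytic potential (no sampling)."""
    nx = int(round((x_hi - x_lo) / bin))
    ny = int(round((y_hi - y_lo) / bin))
    origin = np.array([x_lo, y_lo])
    v = np.empty((nx, ny))
    for i in range(nx):
        for j in range(ny):
            x = x_lo + (i + 0.5) * bin
            y = y_lo + (j + 0.5) * bin
            v[i, j] = v_func(x, y)
    v[v > v_max] = np.inf
    finite = np.isfinite(v)
    v = v - v[finite].min()
    counts = np.where(finite, 1, 0)
    return FES2D(origin, bin, counts, v, {}, np.array([0.0]))


def oracle_pme(fes, b_start, b_end):
    """Independent re-implementation of the greedy perpendicular-scan
    recursion, written against the same documented conventions."""
    a = fes.origin + (np.array(b_start, float) + 0.5) * fes.bin
    t = fes.origin + (np.array(b_end, float) + 0.5) * fes.bin
    path = [tuple(b_start)]
    c = a.copy()
    for _ in range(100000):
        if np.hypot(*(c - t)) < fes.bin:
            break
        d = (t - c) / np.hypot(*(c - t))
        m = c + fes.bin * d
        q = np.array([-d[1], d[0]])
        center, radius = (c + t) / 2.0, np.hypot(*(t - c)) / 2.0
        w = m - center
        disc = (w @ q) ** 2 - (w @ w - radius**2)
        if disc < 0:
            ss = [0.0]
        else:
            lo, hi = -(w @ q) - np.sqrt(disc), -(w @ q) + np.sqrt(disc)
            ss = sorted({j * fes.bin for j in range(int(np.ceil(lo / fes.bin)),
                                                    int(np.floor(hi / fes.bin)) + 1)}
                        | ({0.0} if lo <= 0.0 <= hi else set()))
        cand = {}
        for s in ss:
            pt = m + s * q
            b = (int(np.floor((pt[0] - fes.origin[0]) / fes.bin)),
                 int(np.floor((pt[1] - fes.origin[1]) / fes.bin)))
            val = fes.value(b)
            if np.isfinite(val):
                cand[b] = val
        assert cand, "oracle hit a blocked segment"
        best = min(cand, key=lambda b: (cand[b], b))
        if best != path[-1]:
            path.append(best)
        c = fes.origin + (np.array(best, float) + 0.5) * fes.bin
    if path[-1] != tuple(b_end):
        path.append(tuple(b_end))
    return path


class TestBuildFes:
    def test_single_point_single_bin(self):
        t = np.arange(5.0)
        surf = build_fes(PCSeries(1, np.full(5, 0.33), t),
                         PCSeries(2, np.full(5, -0.71), t))
        assert surf.counts.sum() == 5
        assert (np.isfinite(surf.free_energy)).sum() == 1
        assert surf.free_energy[np.isfinite(surf.free_energy)][0] == 0.0

    def test_two_equal_clusters_both_at_zero(self):
        x = np.array([-1.0] * 10 + [1.0] * 10)
        t = np.arange(20.0)
        surf = build_fes(PCSeries(1, x, t), PCSeries(2, np.zeros(20), t))
        finite = surf.free_energy[np.isfinite(surf.free_energy)]
        np.testing.assert_allclose(finite, 0.0)

    def test_frame_lists_partition_all_frames(self, rng):
        x, y = rng.normal(size=(2, 2000))
        t = np.arange(2000.0)
        surf = build_fes(PCSeries(1, x, t), PCSeries(2, y, t))
        all_frames = np.concatenate(list(surf.frame_lists.values()))
        assert all_frames.size == 2000
        assert np.unique(all_frames).size == 2000
        for b, frames in surf.frame_lists.items():
            assert surf.counts[b] == frames.size

    def test_isotropic_gaussian_radial_profile(self):
        rng = np.random.default_rng(6)
        sigma = 0.5
        x, y = rng.normal(0, sigma, size=(2, 100_000))
        t = np.arange(100_000.0)
        surf = build_fes(PCSeries(1, x, t), PCSeries(2, y, t))
        centers_x = surf.origin[0] + (np.arange(surf.counts.shape[0]) + 0.5) * surf.bin
        centers_y = surf.origin[1] + (np.arange(surf.counts.shape[1]) + 0.5) * surf.bin
        gx, gy = np.meshgrid(centers_x, centers_y, indexing="ij")
        r = np.sqrt(gx**2 + gy**2)
        mask = surf.counts >= 20
        # azimuthally averaged (radial) profile vs the analytic r^2 / 2 sigma^2
        annulus = np.floor(r / surf.bin).astype(int)
        radial_v, radial_ref = [], []
        for k in np.unique(annulus[mask]):
            sel = mask & (annulus == k)
            radial_v.append(surf.free_energy[sel].mean())
            radial_ref.append((r[sel] ** 2 / (2 * sigma**2)).mean())
        radial_v = np.array(radial_v)
        radial_ref = np.array(radial_ref)
        diff = radial_v - radial_ref
        assert np.abs(diff - diff.mean()).max() < 0.2


class TestFindMinima:
    def test_single_gaussian_single_minimum(self):
        # sampled densely enough that shot noise cannot fake a second basin
        rng = np.random.default_rng(7)
        x, y = rng.normal(0, 0.25, size=(2, 200_000))
        t = np.arange(200_000.0)
        surf = build_fes(PCSeries(1, x, t), PCSeries(2, y, t))
        assert len(find_minima(surf)) == 1

    def test_two_separated_clusters_two_minima(self):
        rng = np.random.default_rng(8)
        n = 20_000
        x = np.concatenate([rng.normal(-1.5, 0.2, n), rng.normal(1.5, 0.2, n)])
        y = rng.normal(0, 0.2, 2 * n)
        t = np.arange(2.0 * n)
        surf = build_fes(PCSeries(1, x, t), PCSeries(2, y, t))
        minima = find_minima(surf)
        assert len(minima) == 2
        # chronological labels: the -1.5 basin is visited first
        assert surf.center_of(minima[0].bin)[0] < 0

    def test_shallow_satellite_above_depth_excluded(self):
        def v(x, y):
            base = 8 * ((x + 1) ** 2 + y**2)
            sat = 4.0 + 8 * ((x - 1) ** 2 + y**2)
            return min(base, sat)

        surf = analytic_fes(v)
        surf.frame_lists = {b: np.array([0]) for b in
                            zip(*np.nonzero(np.isfinite(surf.free_energy)))}
        minima = find_minima(surf, depth=3.0)
        assert len(minima) == 1
        assert surf.center_of(minima[0].bin)[0] < 0


class TestPme:
    def test_straight_valley_stays_near_axis(self):
        surf = analytic_fes(lambda x, y: y * y * 10)
        path = pme(surf, surf.bin_of(-1.0, 0.0), surf.bin_of(1.0, 0.0))
        y_centers = [surf.center_of(b)[1] for b in path.steps]
        assert np.abs(y_centers).max() <= surf.bin + 1e-9

    def test_adjacent_minima_short_path(self):
        surf = analytic_fes(lambda x, y: x * x + y * y)
        b0 = surf.bin_of(0.05, 0.05)
        b1 = (b0[0] + 1, b0[1])
        path = pme(surf, b0, b1)
        assert path.steps[0] == b0 and path.steps[-1] == b1
        assert path.n_steps <= 3

    def test_blocked_surface_raises(self):
        def v(x, y):
            return np.inf if abs(x) < 0.3 else x * x + y * y

        surf = analytic_fes(v, v_max=1e9)
        with pytest.raises(fes_mod.PMEError):
            pme(surf, surf.bin_of(-1.0, 0.0), surf.bin_of(1.0, 0.0))

    def test_bin_exact_agreement_with_independent_oracle(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cx, cy = rng.uniform(0.3, 0.8), rng.uniform(-0.4, 0.4)
            amps = rng.uniform(1.0, 4.0, 3)

            def v(x, y, cx=cx, cy=cy, a=amps):
                two_basin = a[0] * (x**2 - cx**2) ** 2 / cx**4 + a[1] * (y - cy * x**2) ** 2
                ripple = 0.3 * np.sin(a[2] * x + y)
                return two_basin + ripple

            surf = analytic_fes(v, x_lo=-1.6, x_hi=1.6, y_lo=-1.2, y_hi=1.2)
            start = surf.bin_of(-cx, cy * cx**2)
            end = surf.bin_of(cx, cy * cx**2)
            path = pme(surf, start, end)
            assert path.steps == oracle_pme(surf, start, end)

    def test_monotone_approach_to_target(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            a = rng.uniform(1.0, 3.0)
            surf = analytic_fes(lambda x, y: a * (x**2 - 1) ** 2 + 3 * y**2)
            end = surf.bin_of(1.0, 0.0)
            path = pme(surf, surf.bin_of(-1.0, 0.0), end)
            t = surf.center_of(end)
            dists = [np.linalg.norm(surf.center_of(b) - t) for b in path.steps]
            assert all(d2 <= d1 + 1e-9 for d1, d2 in zip(dists, dists[1:]))


class TestChainPme:
    def test_w_shaped_surface_two_saddles(self):
        def v(x, y):
            wells = min(12 * (x + 1.2) ** 2, 2.0 + 12 * x**2,
                        12 * (x - 1.2) ** 2)
            return wells + 8 * y**2

        surf = analytic_fes(v)
        m = [surf.bin_of(-1.2, 0.0), surf.bin_of(0.0, 0.0),
             surf.bin_of(1.2, 0.0)]
        path = chain_pme(surf, m)
        assert len(path.saddle_indices) == 2
        assert len(path.leg_boundaries) == 3
        for s in path.saddle_indices:
            assert path.values[s] > min(path.values[path.leg_boundaries])

    def test_two_minima_chain_equals_single_leg(self):
        surf = analytic_fes(lambda x, y: (x**2 - 1) ** 2 + 4 * y**2)
        b0, b1 = surf.bin_of(-1.0, 0.0), surf.bin_of(1.0, 0.0)
        assert chain_pme(surf, [b0, b1]).steps == pme(surf, b0, b1).steps

    def test_planted_4kbt_barrier_recovered_from_sampled_walk(self):
        def v(x, y):
            return 4.0 * (x * x - 1.0) ** 2 + 4.0 * y * y

        xs, ys = synthgen.diffuse_2d(v, 200_000, seed=3, start=(-1.0, 0.0))
        t = 2.0 * np.arange(xs.size)
        surf = build_fes(PCSeries(1, xs, t), PCSeries(2, ys, t))
        minima = find_minima(surf, depth=3.0)
        assert len(minima) == 2
        path = chain_pme(surf, list(minima))
        barrier = path.barriers()[0]
        assert barrier == pytest.approx(4.0, abs=0.3)


class TestStepProfiles:
    @staticmethod
    def _series(values, n):
        return DihedralSeries([5, 6], np.tile(values, (n, 1)),
                              2.0 * np.arange(n))

    def test_identical_frames_reproduce_single_conformation(self):
        n = 50
        rngs = np.random.default_rng(1)
        x = rngs.normal(0, 0.3, n)
        y = rngs.normal(0, 0.3, n)
        surf = build_fes(PCSeries(1, x, 2.0 * np.arange(n)),
                         PCSeries(2, y, 2.0 * np.arange(n)))
        series = self._series(np.array([42.0, -100.0]), n)
        fake_path = fes_mod.PMEPath(
            list(surf.frame_lists), np.zeros(len(surf.frame_lists)), [], [0],
            [surf.frame_lists[b] for b in surf.frame_lists])
        profiles = step_profiles(surf, fake_path, series, [5, 6])
        for p in profiles:
            assert not p.empty
            assert abs(p.most_probable[5] - 42.0) <= 2.5    # half a 5-deg bin
            assert abs(p.most_probable[6] + 100.0) <= 2.5

    def test_conformation_switch_happens_at_basin_change(self):
        def v(x, y):
            return 4.0 * (x * x - 1.0) ** 2 + 4.0 * y * y

        xs, ys = synthgen.diffuse_2d(v, 100_000, seed=9, start=(-1.0, 0.0))
        t = 2.0 * np.arange(xs.size)
        gamma = np.where(xs < 0, -60.0, 60.0)
        series = DihedralSeries([5], gamma[:, None], t)
        surf = build_fes(PCSeries(1, xs, t), PCSeries(2, ys, t))
        minima = find_minima(surf, depth=3.0)
        assert len(minima) == 2
        path = chain_pme(surf, list(minima))
        profiles = step_profiles(surf, path, series, [5])
        values = [p.most_probable[5] for p in profiles if not p.empty]
        assert values[0] < 0 < values[-1]
        signs = np.sign(values)
        # one switch, and it happens within two steps of the saddle
        switches = np.nonzero(np.diff(signs))[0]
        assert len(switches) == 1
        assert abs(int(switches[0]) - path.saddle_indices[0]) <= 2

    def test_union_of_steps_recovers_global_profile(self, rng):
        n = 3000
        x = rng.normal(0, 0.5, n)
        y = rng.normal(0, 0.5, n)
        t = 2.0 * np.arange(n)
        surf = build_fes(PCSeries(1, x, t), PCSeries(2, y, t))
        series = DihedralSeries([5], rng.uniform(-179, 180, (n, 1)), t)
        frames = np.concatenate(list(surf.frame_lists.values()))
        from felmap.fep import estimate_pdf

        global_pdf = estimate_pdf(series.column(5))
        union_pdf = estimate_pdf(series.column(5)[np.sort(frames)])
        np.testing.assert_allclose(global_pdf.probabilities,
                                   union_pdf.probabilities)
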