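"""Straightening, ACF peak detection, region rules and per-fiber metrics."""

import numpy as np
import pytest

from myoscale.periodicity import (
    IntensityProfile,
    PeriodicityMap,
    StraightenPath,
    classify_periodic_regions,
    global_acf,
    local_acf_map,
    periodicity_metrics,
    straighten_profile,
)
from myoscale.synthetic import ProfileSegment, gen_periodic_profile


def make_map(flags, step=1.0, threshold=0.6):
    flags = np.asarray(flags, bool)
    centers = np.arange(len(flags)) * step
    prom = np.where(flags, 0.9, 0.1)
    return PeriodicityMap(
        window_centers_um=centers,
        peak_lag_um=np.full(len(flags), 2.0),
        prominence=prom,
        periodic_flags=flags,
        window_um=10.0,
        step_um=step,
        prominence_threshold=threshold,
    )


class TestStraighten:
    def test_straight_path_recovers_pattern_exactly(self):
        nx, ny, nz = 80, 21, 3
        pattern = np.sin(np.arange(nx) * 0.4) + 2
        vol = np.broadcast_to(pattern, (nz, ny, nx)).copy()
        path = StraightenPath([(0.0, 10.0), (nx - 1.0, 10.0)], half_width=3)
        prof = straighten_profile(vol, path, pixel_size_xy=0.1)
        assert np.allclose(prof.intensities, pattern[: len(prof.intensities)],
                           atol=1e-9)
        assert prof.pixel_size == 0.1

    def test_curved_path_recovers_known_pattern(self):
        # paint a pattern as a function of x only; a gently curved path
        # should recover the pattern evaluated along its own x-progress
        nx, ny = 200, 80
        xx = np.arange(nx)
        img = np.broadcast_to(np.sin(xx * 0.2) + 2.0, (ny, nx)).copy()
        t = np.linspace(0, 1, 40)
        verts = np.column_stack([10 + t * 180, 40 + 10 * np.sin(2 * np.pi * t)])
        path = StraightenPath(verts, half_width=2)
        prof = straighten_profile(img, path, pixel_size_xy=1.0)
        # ground truth: pattern at the x coordinate of each arc-length sample
        from myoscale.periodicity import _resample_polyline
        rs = _resample_polyline(verts)
        truth = np.sin(rs[:, 0] * 0.2) + 2.0
        rms = np.sqrt(np.mean((prof.intensities - truth) ** 2))
        assert rms < 0.02  # < 2% of unit amplitude

    def test_path_outside_volume_raises(self):
        vol = np.zeros((5, 20, 20))
        path = StraightenPath([(0.0, 10.0), (30.0, 10.0)])
        with pytest.raises(ValueError):
            straighten_profile(vol, path, 0.1)

    def test_xz_stage_follows_depth_drift(self):
        # signal lives on a plane that drifts in z along x
        nz, ny, nx = 9, 15, 120
        vol = np.zeros((nz, ny, nx))
        zs = np.round(np.linspace(2, 6, nx)).astype(int)
        for x in range(nx):
            vol[zs[x], :, x] = 5.0
        path = StraightenPath(
            [(1.0, 7.0), (nx - 2.0, 7.0)],
            xz_vertices=[(0.0, 2.0), (float(nx - 3), 6.0)],
            half_width=1,
        )
        prof = straighten_profile(vol, path, 0.1, 0.3)
        # profile must capture the drifting plane most of the way
        assert prof.intensities.mean() > 1.0


class TestGlobalACF:
    def test_cosine_period_recovered(self):
        dx, p = 0.083, 2.0
        pos = np.arange(0, 50, dx)
        prof = IntensityProfile(pos, 1 + np.cos(2 * np.pi * pos / p), dx)
        r = global_acf(prof)
        assert r.secondary_peak_lag_um == pytest.approx(p, abs=dx)

    def test_peak_train_period_recovered(self):
        prof, _, _ = gen_periodic_profile(
            [ProfileSegment(100.0, "periodic", 2.5, 1.0, 0.0)], seed=0)
        r = global_acf(prof)
        assert r.secondary_peak_lag_um == pytest.approx(2.5, abs=prof.pixel_size)

    def test_constant_profile_flagged(self):
        prof = IntensityProfile(np.arange(100) * 0.1, np.full(100, 3.0), 0.1)
        r = global_acf(prof)
        assert r.constant and not r.has_peak

    def test_acf_normalised_at_zero(self, rng):
        prof = IntensityProfile(np.arange(300) * 0.1,
                                rng.standard_normal(300), 0.1)
        r = global_acf(prof)
        assert r.acf[0] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.abs(r.acf) <= 1 + 1e-9)

    def test_affine_intensity_invariance(self, rng):
        x = rng.standard_normal(500)
        p1 = IntensityProfile(np.arange(500) * 0.1, x, 0.1)
        p2 = IntensityProfile(np.arange(500) * 0.1, 7.5 * x + 3.0, 0.1)
        r1, r2 = global_acf(p1), global_acf(p2)
        assert np.allclose(r1.acf, r2.acf, atol=1e-9)


class TestLocalMap:
    def test_fully_periodic_profile_flags_all_windows(self):
        prof, _, _ = gen_periodic_profile(
            [ProfileSegment(60.0, "periodic", 2.0, 1.0, 0.05)], seed=1)
        m = local_acf_map(prof)
        assert m.periodic_flags.all()

    def test_noise_profile_rarely_flags(self):
        fracs = []
        for k in range(10):
            prof, _, _ = gen_periodic_profile(
                [ProfileSegment(60.0, "noise", 2.0, 1.0, 0.1)], seed=100 + k)
            fracs.append(local_acf_map(prof).periodic_flags.mean())
        assert np.mean(fracs) < 0.05

    def test_transition_located_at_boundary(self):
        prof, mask, _ = gen_periodic_profile(
            [ProfileSegment(50.0, "periodic", 2.0, 1.0, 0.05),
             ProfileSegment(50.0, "noise", 2.0, 1.0, 0.05)], seed=2)
        m = local_acf_map(prof)
        centers = m.window_centers_um
        flagged = centers[m.periodic_flags]
        boundary = 50.0
        # last flagged window center within half a window of the boundary
        assert abs(flagged.max() - boundary) <= m.window_um / 2 + 1e-9

    def test_profile_shorter_than_window_raises(self):
        prof = IntensityProfile(np.arange(50) * 0.083,
                                np.random.default_rng(0).standard_normal(50),
                                0.083)
        with pytest.raises(ValueError):
            local_acf_map(prof, window_um=10.0)


class TestRegionRules:
    def test_short_run_discarded(self):
        # 5 µm of periodic windows -> shorter than the 6 µm floor
        m = classify_periodic_regions(make_map([0] * 5 + [1] * 6 + [0] * 5))
        assert m.regions == []

    def test_exactly_min_region_survives(self):
        # run spanning exactly 6 µm (centers 0..6) is kept (< rule discards)
        m = classify_periodic_regions(make_map([1] * 7 + [0] * 20))
        assert len(m.regions) == 1

    def test_gap_below_merge_threshold_connected(self):
        flags = [1] * 21 + [0] * 7 + [1] * 21  # 8 µm gap between run ends
        m = classify_periodic_regions(make_map(flags))
        assert len(m.regions) == 1

    def test_gap_at_exactly_merge_threshold_not_connected(self):
        flags = [1] * 21 + [0] * 9 + [1] * 21  # gap exactly 10 µm
        m = classify_periodic_regions(make_map(flags))
        assert len(m.regions) == 2

    def test_gap_above_merge_threshold_not_connected(self):
        flags = [1] * 21 + [0] * 14 + [1] * 21  # 15 µm gap
        m = classify_periodic_regions(make_map(flags))
        assert len(m.regions) == 2

    def test_merge_then_discard_can_rescue_fragments(self):
        # two 4 µm fragments, 2 µm apart: merged 10 µm region survives,
        # but discard-first drops both
        flags = [1] * 5 + [0] * 1 + [1] * 5 + [0] * 20
        m1 = classify_periodic_regions(make_map(flags), order="merge_then_discard")
        m2 = classify_periodic_regions(make_map(flags), order="discard_then_merge")
        assert len(m1.regions) == 1
        assert m2.regions == []

    def test_idempotent(self):
        flags = [1] * 21 + [0] * 7 + [1] * 21 + [0] * 30 + [1] * 10
        m1 = classify_periodic_regions(make_map(flags))
        m2 = classify_periodic_regions(m1)
        assert m1.regions == m2.regions

    def test_matches_brute_force_run_scan(self, rng):
        for k in range(20):
            flags = rng.random(80) < 0.4
            m = classify_periodic_regions(make_map(flags))
            # hand-applied rules on the run-length encoding
            runs, start = [], None
            for i, fl in enumerate(flags):
                if fl and start is None:
                    start = i
                elif not fl and start is not None:
                    runs.append((float(start), float(i - 1)))
                    start = None
            if start is not None:
                runs.append((float(start), float(len(flags) - 1)))
            merged = []
            for r in runs:
                if merged and r[0] - merged[-1][1] < 10.0:
                    merged[-1] = (merged[-1][0], r[1])
                else:
                    merged.append(r)
            expect = [r for r in merged if r[1] - r[0] >= 6.0]
            assert m.regions == expect


class TestMetrics:
    def test_single_full_length_region(self):
        m = make_map([1] * 101)
        m = classify_periodic_regions(m)
        met = periodicity_metrics(m, 100.0)
        assert met.proportion_periodic == pytest.approx(1.0)
        assert met.regions_per_100um == pytest.approx(1.0)

    def test_no_regions(self):
        m = classify_periodic_regions(make_map([0] * 50))
        met = periodicity_metrics(m, 50.0)
        assert met.proportion_periodic == 0.0
        assert met.n_regions == 0
        assert np.isnan(met.homogeneity_um)

    def test_two_regions_brute_force(self):
        flags = [1] * 21 + [0] * 59 + [1] * 21
        m = classify_periodic_regions(make_map(flags))
        met = periodicity_metrics(m, 100.0)
        assert met.proportion_periodic == pytest.approx(0.4)
        assert met.regions_per_100um == pytest.approx(2.0)
        centers = np.arange(101.0)[np.asarray(flags, bool)]
        assert met.homogeneity_um == pytest.approx(np.std(centers), abs=1e-12)
        assert met.homogeneity_normalized == pytest.approx(np.std(centers) / 100)

    def test_invalid_fiber_length(self):
        m = classify_periodic_regions(make_map([1] * 20))
        with pytest.raises(ValueError):
            periodicity_metrics(m, 0.0)
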