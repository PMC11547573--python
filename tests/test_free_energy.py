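"""Umbrella windows, WHAM, and the profile analytics."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tapspath as tp
from tapspath.constants import KB, KJ_PER_KCAL
from tapspath.errors import SupportError, ValidationError
from tapspath.free_energy import (
    FEProfile,
    StationaryPoint,
    StationaryPointReport,
    WindowSamples,
)


class TestMakeWindows:
    @pytest.mark.parametrize("n_nodes,expected", [(64, 256), (66, 264), (55, 220)])
    def test_tiling_counts(self, n_nodes, expected):
        windows = tp.make_windows(n_nodes, gap=0.25)
        assert len(windows) == expected

    def test_centers_at_gap_multiples(self):
        windows = tp.make_windows(4, gap=0.5)
        assert [w.center_s for w in windows] == pytest.approx(
            [0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0]
        )

    def test_default_force_constant(self):
        assert tp.make_windows(4, gap=1.0)[0].k_s == 200.0

    def test_degenerate_single_window(self):
        with pytest.warns(UserWarning, match="degenerate"):
            windows = tp.make_windows(2, gap=5.0)
        assert len(windows) == 1

    def test_seeds_deterministic_and_distinct(self):
        w1 = tp.make_windows(4, gap=0.5, master_seed=9)
        w2 = tp.make_windows(4, gap=0.5, master_seed=9)
        assert [w.seed for w in w1] == [w.seed for w in w2]
        assert len({w.seed for w in w1}) == len(w1)

    def test_validation(self):
        with pytest.raises(ValidationError):
            tp.make_windows(1, gap=0.5)
        with pytest.raises(ValidationError):
            tp.make_windows(4, gap=-1.0)


def flat_line_path(n=5):
    nodes = np.arange(float(n))[:, None]
    return tp.PathDefinition(nodes=nodes, lam=1.5)


class TestRunUmbrella:
    def test_determinism(self):
        system = tp.get_potential("harmonic", {"k": 2.0, "center": 2.0})
        path = flat_line_path()
        windows = tp.make_windows(5, gap=0.5, wall=None, sampling_time=5.0, master_seed=4)
        params = tp.LangevinParams(friction=5.0, timestep=5e-4, n_steps=1, seed=0, record_every=10)
        s1 = tp.run_umbrella(windows, path, system, params)
        s2 = tp.run_umbrella(windows, path, system, params)
        for a, b in zip(s1.s_samples, s2.s_samples):
            assert np.array_equal(a, b)

    def test_stiff_spring_variance(self):
        """A very stiff window concentrates s at its center with variance
        close to kB T / k_s."""
        system = tp.get_potential("harmonic", {"k": 0.001, "center": 2.0})
        path = flat_line_path()
        k_s = 4000.0
        windows = [
            tp.UmbrellaWindow(center_s=3.0, k_s=k_s, wall=None, sampling_time=80.0, seed=13),
            tp.UmbrellaWindow(center_s=3.0, k_s=k_s, wall=None, sampling_time=80.0, seed=14),
        ]
        params = tp.LangevinParams(
            temperature=310.0, friction=2.0, timestep=5e-5, n_steps=1, seed=0, record_every=20
        )
        samples = tp.run_umbrella(windows, path, system, params, burn_in=0.2)
        s = np.concatenate(samples.s_samples)
        # the soft progress index compresses distances slightly; allow 15%
        assert s.mean() == pytest.approx(3.0, abs=0.02)
        assert s.var() == pytest.approx(KB * 310.0 / k_s, rel=0.15)


class TestAdaptiveWindows:
    def test_bridging_window_inserted_at_gap(self, rng):
        """A pair of windows with no histogram overlap gets one bridging
        window midway, inheriting the stiffer spring."""
        from tapspath.free_energy import adaptive_windows, merge_window_samples

        w = [
            tp.UmbrellaWindow(center_s=0.0, k_s=50.0, wall=None, seed=0),
            tp.UmbrellaWindow(center_s=2.0, k_s=100.0, wall=None, seed=1),
        ]
        ws = WindowSamples(
            windows=w,
            s_samples=[rng.normal(0, 0.1, 500), rng.normal(2, 0.1, 500)],
            z_samples=[np.zeros(500)] * 2,
            wall_violations=[0.0, 0.0],
        )
        extra = adaptive_windows(ws, min_overlap=0.1, master_seed=3)
        assert len(extra) == 1
        assert extra[0].center_s == pytest.approx(1.0)
        assert extra[0].k_s == 100.0
        bridge = WindowSamples(
            windows=extra, s_samples=[rng.normal(1, 0.1, 500)],
            z_samples=[np.zeros(500)], wall_violations=[0.0],
        )
        merged = merge_window_samples(ws, bridge)
        assert [win.center_s for win in merged.windows] == [0.0, 1.0, 2.0]

    def test_no_insertion_when_overlapping(self, rng):
        from tapspath.free_energy import adaptive_windows

        w = [
            tp.UmbrellaWindow(center_s=0.0, k_s=50.0, wall=None, seed=0),
            tp.UmbrellaWindow(center_s=0.3, k_s=50.0, wall=None, seed=1),
        ]
        ws = WindowSamples(
            windows=w,
            s_samples=[rng.normal(0, 0.3, 500), rng.normal(0.3, 0.3, 500)],
            z_samples=[np.zeros(500)] * 2,
            wall_violations=[0.0, 0.0],
        )
        assert adaptive_windows(ws, min_overlap=0.1) == []


def gaussian_window_samples(k_harm, windows, rng, n=4000, temperature=310.0):
    """iid samples from the exact biased densities of a harmonic F(s):
    independent-route input for WHAM."""
    kt = KB * temperature
    out = []
    for w in windows:
        prec = (k_harm + w.k_s) / kt
        mean = (w.k_s * w.center_s) / (k_harm + w.k_s)
        out.append(rng.normal(mean, np.sqrt(1.0 / prec), size=n))
    return WindowSamples(
        windows=list(windows), s_samples=out, z_samples=[np.zeros(n)] * len(windows)
    )


class TestWham:
    def test_flat_density_gives_flat_profile(self, rng):
        windows = [tp.UmbrellaWindow(center_s=1.0, k_s=1e-9, wall=None, seed=0)]
        s = rng.uniform(0.0, 2.0, size=200_000)
        samples = WindowSamples(windows=windows, s_samples=[s], z_samples=[np.zeros(s.size)])
        profile = tp.wham(samples, temperature=310.0, n_bins=40, reference="min")
        kt_kcal = KB * 310.0 / KJ_PER_KCAL
        spread = np.sqrt(np.mean((profile.f - np.nanmean(profile.f)) ** 2))
        assert spread < 0.3 * kt_kcal

    def test_harmonic_free_energy_recovered(self, rng):
        """WHAM on exact samples from overlapping biased windows of a
        harmonic free energy reproduces the parabola."""
        k_harm = 8.0
        centers = np.arange(-2.0, 2.01, 0.4)
        windows = [
            tp.UmbrellaWindow(center_s=c, k_s=20.0, wall=None, seed=i)
            for i, c in enumerate(centers)
        ]
        samples = gaussian_window_samples(k_harm, windows, rng)
        profile = tp.wham(samples, temperature=310.0, n_bins=80, reference="min")
        kt = KB * 310.0
        ref = 0.5 * k_harm * profile.s_grid**2 / KJ_PER_KCAL
        mask = np.isfinite(profile.f) & (np.abs(profile.s_grid) < 1.8)
        diff = (profile.f - ref)[mask]
        diff -= diff.mean()
        assert np.sqrt(np.mean(diff**2)) < 0.2 * kt / KJ_PER_KCAL

    def test_bin_doubling_invariance(self, rng):
        k_harm = 8.0
        centers = np.arange(-1.6, 1.61, 0.4)
        windows = [
            tp.UmbrellaWindow(center_s=c, k_s=20.0, wall=None, seed=i)
            for i, c in enumerate(centers)
        ]
        samples = gaussian_window_samples(k_harm, windows, rng, n=8000)
        p1 = tp.wham(samples, temperature=310.0, n_bins=60, reference="min")
        p2 = tp.wham(samples, temperature=310.0, n_bins=120, reference="min")
        f2_on_1 = np.interp(p1.s_grid, p2.s_grid, p2.f)
        mask = np.isfinite(p1.f) & (np.abs(p1.s_grid) < 1.5)
        kt_kcal = KB * 310.0 / KJ_PER_KCAL
        assert np.nanmax(np.abs((p1.f - f2_on_1)[mask])) < 0.25 * kt_kcal

    def test_disconnected_support_reported(self, rng):
        windows = [
            tp.UmbrellaWindow(center_s=0.0, k_s=50.0, wall=None, seed=0),
            tp.UmbrellaWindow(center_s=10.0, k_s=50.0, wall=None, seed=1),
        ]
        samples = WindowSamples(
            windows=windows,
            s_samples=[rng.normal(0, 0.2, 1000), rng.normal(10, 0.2, 1000)],
            z_samples=[np.zeros(1000)] * 2,
        )
        with pytest.raises(SupportError, match="disconnected"):
            tp.wham(samples, temperature=310.0, n_bins=100)

    def test_needs_enough_bins(self, rng):
        windows = [tp.UmbrellaWindow(center_s=float(i), wall=None, seed=i) for i in range(5)]
        samples = WindowSamples(
            windows=windows,
            s_samples=[rng.normal(i, 0.5, 100) for i in range(5)],
            z_samples=[np.zeros(100)] * 5,
        )
        with pytest.raises(ValidationError):
            tp.wham(samples, n_bins=3)


def profile_from_energy(system, lo, hi, n=600, s_of_x=lambda x: x):
    x = np.linspace(lo, hi, n)
    f = system.energy(x[:, None]) / KJ_PER_KCAL
    return FEProfile(
        s_grid=s_of_x(x), f=f - f.min(), bin_width=(hi - lo) / n, temperature=310.0
    )


class TestLocateStates:
    def test_monotone_profile_has_no_interior_states(self):
        profile = FEProfile(
            s_grid=np.linspace(0, 1, 100), f=np.linspace(0, 5, 100),
            bin_width=0.01, temperature=310.0,
        )
        report = tp.locate_states(profile, smoothing_window=3, min_depth=0.5)
        assert report.n_is == 0
        assert report.n_ts == 0
        assert [p.label for p in report.minima] == ["Ini", "Fin"]

    def test_staircase_profile_recovers_five_is_six_ts(self, staircase):
        """The six-step ladder yields exactly 5 intermediate and 6 transition
        states when analyzed as a profile."""
        system, spec = staircase
        profile = profile_from_energy(system, 0.0, 12.0)
        report = tp.locate_states(profile, smoothing_window=3, min_depth=0.5)
        assert report.n_is == 5
        assert report.n_ts == 6
        labels = [p.label for p in report.minima]
        assert labels == ["Ini", "IS1", "IS2", "IS3", "IS4", "IS5", "Fin"]

    def test_noisy_profile_positions_within_smoothing_window(self, staircase, rng):
        system, spec = staircase
        clean = profile_from_energy(system, 0.0, 12.0, n=600)
        noisy = dataclasses.replace(
            clean, f=clean.f + rng.normal(0.0, 0.05, size=clean.f.size)
        )
        window = 9
        report = tp.locate_states(noisy, smoothing_window=window, min_depth=0.5)
        assert report.n_is == 5 and report.n_ts == 6
        truth_min = np.asarray(spec.minima_positions, dtype=float)
        found_min = np.array([p.s for p in report.minima])
        assert np.abs(found_min - truth_min).max() <= window * clean.bin_width * 2

    def test_shallow_features_merged(self):
        s = np.linspace(0, 10, 500)
        f = 0.5 * (s - 5.0) ** 2 * 0.2
        f += 0.2 * np.sin(8 * s)  # ripples well below min_depth
        profile = FEProfile(s_grid=s, f=f - f.min(), bin_width=s[1] - s[0], temperature=310.0)
        report = tp.locate_states(profile, smoothing_window=3, min_depth=0.6)
        assert report.n_is <= 1  # the central basin only


class TestBarrierTable:
    @staticmethod
    def report_from(minima, maxima):
        mins = [
            StationaryPoint(lbl, float(i), float(v))
            for i, (lbl, v) in enumerate(
                zip(["Ini"] + [f"IS{k}" for k in range(1, len(minima) - 1)] + ["Fin"], minima)
            )
        ]
        maxs = [
            StationaryPoint(f"TS{k + 1}", k + 0.5, float(v)) for k, v in enumerate(maxima)
        ]
        return StationaryPointReport(minima=mins, maxima=maxs)

    def test_hand_arithmetic(self):
        stats = tp.barrier_table(self.report_from([0.0, 2.0, 1.0], [5.0, 6.0]))
        assert list(stats.forward_barriers) == [5.0, 4.0]
        assert list(stats.backward_barriers) == [3.0, 5.0]
        assert stats.delta == 1.0
        assert stats.total_forward == 9.0

    def test_symmetric_double_well(self):
        stats = tp.barrier_table(self.report_from([0.0, 0.0], [4.0]))
        assert np.array_equal(stats.forward_barriers, stats.backward_barriers)
        assert stats.delta == 0.0

    @settings(deadline=None, max_examples=50)
    @given(
        mins=st.lists(st.floats(-10, 10, allow_nan=False), min_size=2, max_size=8),
        rises=st.lists(st.floats(0.1, 10, allow_nan=False), min_size=1, max_size=7),
    )
    def test_telescoping_identity(self, mins, rises):
        """delta = sum(forward) - sum(backward) holds exactly for every
        alternating report."""
        n = min(len(mins), len(rises) + 1)
        if n < 2:
            return
        mins = mins[:n]
        maxima = [max(mins[i], mins[i + 1]) + rises[i] for i in range(n - 1)]
        stats = tp.barrier_table(self.report_from(mins, maxima))
        assert stats.delta == pytest.approx(
            stats.forward_barriers.sum() - stats.backward_barriers.sum(), abs=1e-9
        )

    def test_non_alternating_rejected(self):
        report = self.report_from([0.0, 1.0], [])
        with pytest.raises(ValidationError):
            tp.barrier_table(report)
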