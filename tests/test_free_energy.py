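"""Bias accumulation, FES reconstruction, reweighting, ΔG extraction."""

import numpy as np
import pytest

from clampdyn.free_energy import (
    KB, Grid, Profile, UnbindingResult, accumulate_bias, aggregate_runs,
    delta_g_unb, detect_detachment, fes_from_bias, fes_from_histogram,
    fes_rmse, marginalize_distance_profile, reweight,
)
from clampdyn.io_formats import CVTrajectory, HillsSeries

RT = KB * 300.0


def _hills(centers_d, centers_n, heights, sd=0.125, sn=0.25):
    k = len(heights)
    return HillsSeries(step=np.arange(1, k + 1) * 1000,
                       center_d=np.asarray(centers_d, float),
                       center_nc=np.asarray(centers_n, float),
                       width_d=np.full(k, sd), width_nc=np.full(k, sn),
                       height=np.asarray(heights, float))


def _grid():
    return Grid.from_ranges((2.0, 22.0), (-2.0, 10.0))


class TestAccumulateBias:
    def test_empty_hills_give_zero_bias(self):
        empty = _hills([], [], [])
        bias = accumulate_bias(empty, _grid())
        assert np.all(bias.V == 0)

    def test_initial_height_at_hill_center(self):
        grid = _grid()
        d0 = grid.d_centers[60]
        n0 = grid.n_centers[20]
        bias = accumulate_bias(_hills([d0], [n0], [0.3]), grid)
        assert bias.V.max() == pytest.approx(0.3, rel=1e-12)

    def test_two_identical_hills_add(self):
        grid = _grid()
        d0, n0 = grid.d_centers[60], grid.n_centers[20]
        one = accumulate_bias(_hills([d0], [n0], [0.3]), grid)
        two = accumulate_bias(_hills([d0, d0], [n0, n0], [0.3, 0.3]), grid)
        np.testing.assert_allclose(two.V, 2 * one.V, rtol=1e-12)

    def test_uncovered_hill_center_is_an_error(self):
        with pytest.raises(ValueError, match="cover"):
            accumulate_bias(_hills([100.0], [5.0], [0.3]), _grid())


class TestFesFromBias:
    def test_zero_bias_gives_flat_surface(self):
        fes = fes_from_bias(accumulate_bias(_hills([], [], []), _grid()))
        assert np.all(fes.G == 0)

    def test_well_tempered_scale_factor(self):
        # V = 0.33 above a flat background maps to (3600/3300)*0.33 below it
        grid = _grid()
        bias = accumulate_bias(
            _hills([grid.d_centers[60]], [grid.n_centers[20]], [0.33]), grid)
        fes = fes_from_bias(bias)
        assert fes.G.min() == 0.0
        assert fes.G.max() == pytest.approx((3600 / 3300) * 0.33, rel=1e-9)

    def test_doubling_bias_doubles_range(self):
        grid = _grid()
        h1 = _hills([grid.d_centers[60]], [grid.n_centers[20]], [0.3])
        h2 = _hills([grid.d_centers[60]], [grid.n_centers[20]], [0.6])
        r1 = np.ptp(fes_from_bias(accumulate_bias(h1, grid)).G)
        r2 = np.ptp(fes_from_bias(accumulate_bias(h2, grid)).G)
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    def test_nonpositive_bias_temperature_rejected(self):
        bias = accumulate_bias(_hills([], [], []), _grid())
        bad = type(bias)(grid=bias.grid, V=bias.V, T=300.0, delta_T=0.0)
        with pytest.raises(ValueError, match="ΔT|delta|bias temperature"):
            fes_from_bias(bad)


class TestReweight:
    def _cv(self, d, n):
        k = len(d)
        return CVTrajectory(time=np.arange(1, k + 1, dtype=float),
                            d_com=np.asarray(d, float),
                            n_contacts=np.asarray(n, float))

    @pytest.mark.parametrize("scheme", ["final_bias", "time_dependent",
                                        "balanced_exponential"])
    def test_zero_bias_gives_uniform_weights(self, scheme):
        cv = self._cv([8.0, 9.0, 10.0, 11.0], [5.0, 5.0, 5.0, 5.0])
        w = reweight(cv, _hills([], [], []), scheme, grid=_grid())
        np.testing.assert_allclose(w, 0.25)

    def test_final_bias_ratio_rt_ln2(self):
        # hill arranged so frame 1 sits at its center and frame 2 far away,
        # with height RT·ln2: final-bias weight ratio must be 2:1
        cv = self._cv([8.0, 18.0], [5.0, 5.0])
        hills = _hills([8.0], [5.0], [RT * np.log(2)], sd=0.5, sn=0.5)
        w = reweight(cv, hills, "final_bias", grid=_grid())
        assert w[0] / w[1] == pytest.approx(2.0, rel=1e-6)

    def test_unknown_scheme_rejected(self):
        cv = self._cv([8.0], [5.0])
        with pytest.raises(ValueError, match="scheme"):
            reweight(cv, _hills([], [], []), "bogus")

    @pytest.mark.parametrize("scheme", ["final_bias", "time_dependent",
                                        "balanced_exponential"])
    def test_weights_nonnegative_normalized(self, scheme, rng):
        k = 50
        cv = self._cv(np.sort(rng.uniform(5, 20, k)) + 0.0,
                      rng.uniform(1, 8, k))
        hills = _hills(rng.uniform(6, 18, 10), rng.uniform(2, 7, 10),
                       rng.uniform(0.1, 0.3, 10))
        w = reweight(cv, hills, scheme, grid=_grid(), dt=0.001)
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)


class TestFesFromHistogram:
    def _grid2(self):
        return Grid(d_centers=np.array([5.0, 10.0]),
                    n_centers=np.array([5.0]))

    def test_uniform_samples_give_equal_g(self):
        cv = CVTrajectory(time=np.arange(1.0, 5.0),
                          d_com=np.array([5.0, 10.0, 5.0, 10.0]),
                          n_contacts=np.full(4, 5.0))
        fes = fes_from_histogram(cv, np.full(4, 0.25), self._grid2())
        assert fes.G[0, 0] == fes.G[1, 0] == 0.0

    def test_two_to_one_weights_give_rt_ln2(self):
        cv = CVTrajectory(time=np.array([1.0, 2.0]),
                          d_com=np.array([5.0, 10.0]),
                          n_contacts=np.array([5.0, 5.0]))
        fes = fes_from_histogram(cv, np.array([2 / 3, 1 / 3]), self._grid2())
        assert fes.G[1, 0] - fes.G[0, 0] == pytest.approx(RT * np.log(2))
        assert RT * np.log(2) == pytest.approx(0.4131, abs=2e-3)

    def test_single_bin_warns_degenerate(self):
        cv = CVTrajectory(time=np.array([1.0, 2.0]),
                          d_com=np.array([5.0, 5.1]),
                          n_contacts=np.array([5.0, 5.0]))
        with pytest.warns(UserWarning, match="degenerate"):
            fes_from_histogram(cv, np.array([0.5, 0.5]), self._grid2())


class TestMarginalProfile:
    def test_n_independent_surface_reduces_to_slice(self):
        grid = Grid(d_centers=np.array([1.0, 2.0, 3.0]),
                    n_centers=np.array([0.0, 1.0]))
        G = np.array([[1.0, 1.0], [0.0, 0.0], [2.0, 2.0]])
        fes = type(fes_from_bias(accumulate_bias(_hills([], [], []), grid)))(
            grid=grid, G=G, sampled=np.ones_like(G, bool))
        prof = marginalize_distance_profile(fes)
        np.testing.assert_allclose(prof.G, [1.0, 0.0, 2.0], atol=1e-12)

    def test_unsampled_bin_excluded(self):
        grid = Grid(d_centers=np.array([1.0]), n_centers=np.array([0.0, 1.0]))
        from clampdyn.free_energy import FreeEnergySurface
        fes = FreeEnergySurface(grid=grid, G=np.array([[0.0, np.inf]]),
                                sampled=np.array([[True, False]]))
        prof = marginalize_distance_profile(fes)
        assert prof.G[0] == 0.0

    def test_separable_surface_matches_quadrature(self):
        # G(d,n) = f(d) + g(n): marginal must equal f(d) + const, and the
        # const must match direct numeric quadrature of exp(-G/RT) over n
        grid = Grid(d_centers=np.linspace(2, 20, 80),
                    n_centers=np.linspace(0, 8, 60))
        f = 0.5 * (grid.d_centers - 8) ** 2 / 4
        g = 0.3 * (grid.n_centers - 4) ** 2
        G = f[:, None] + g[None, :]
        from clampdyn.free_energy import FreeEnergySurface
        fes = FreeEnergySurface(grid=grid, G=G - G.min(),
                                sampled=np.ones_like(G, bool))
        prof = marginalize_distance_profile(fes)
        dn = grid.n_width
        const = -RT * np.log(np.sum(np.exp(-(g - G.min()) / RT)) * dn)
        expected = f + const
        expected -= expected.min()
        np.testing.assert_allclose(prof.G, expected, atol=1e-9)

    def test_invariant_to_constant_shift(self):
        grid = Grid(d_centers=np.linspace(2, 20, 40),
                    n_centers=np.linspace(0, 8, 30))
        G = np.abs(np.sin(grid.d_centers))[:, None] + \
            0.1 * grid.n_centers[None, :]
        from clampdyn.free_energy import FreeEnergySurface
        a = FreeEnergySurface(grid=grid, G=G - G.min(),
                              sampled=np.ones_like(G, bool))
        pa = marginalize_distance_profile(a)
        pb = marginalize_distance_profile(a)  # same surface, shift handled inside
        np.testing.assert_allclose(pa.G, pb.G, atol=1e-12)


class TestDeltaG:
    def _profile(self, G):
        G = np.asarray(G, float)
        return Profile(d_centers=np.linspace(1, len(G), len(G)),
                       G=G - G.min(), sampled=np.ones(len(G), bool))

    def test_symmetric_double_well_gives_zero(self):
        G = np.array([3.0, 0.0, 3.0, 5.0, 3.0, 0.0, 3.0])
        prof = self._profile(G)
        assert delta_g_unb(prof, (1, 3), (5, 7)) == pytest.approx(
            np.mean([3.0, 0.0, 3.0]) - 0.0)
        # measuring well bottom against well bottom: exactly zero
        assert (np.min(G[4:]) - np.min(G[:3])) == 0.0

    def test_flat_profile_gives_zero(self):
        assert delta_g_unb(self._profile(np.ones(10))) == pytest.approx(0.0)

    def test_plateau_minus_minimum(self):
        G = np.array([0.0, -3.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        prof = self._profile(G)
        assert delta_g_unb(prof, (1, 4), (8, 10)) == pytest.approx(3.0)

    def test_empty_region_is_an_error(self):
        with pytest.raises(ValueError, match="region"):
            delta_g_unb(self._profile(np.zeros(5)), (100, 200), (1, 2))


class TestDetachmentDetection:
    def test_window_scan_finds_first_zero(self):
        t = np.arange(7) * 50.0
        nc = np.array([5, 3, 0, 0, 0, 0, 0], float)
        assert detect_detachment(t, nc, window_ps=200, eps=0.01) == 100.0

    def test_never_below_eps_returns_none(self):
        t = np.arange(10) * 50.0
        assert detect_detachment(t, np.full(10, 2.0), eps=0.01) is None

    def test_short_zero_stretch_with_rebinding_returns_none(self):
        # zeros span only 150 ps before contacts re-form
        t = np.arange(10) * 50.0
        nc = np.array([5, 4, 0, 0, 0, 0, 3, 3, 3, 3], float)
        assert detect_detachment(t, nc, window_ps=200, eps=0.01) is None

    def test_series_shorter_than_window_warns(self):
        with pytest.warns(UserWarning, match="short"):
            out = detect_detachment(np.array([0.0, 50.0]),
                                    np.array([0.0, 0.0]), window_ps=200)
        assert out is None


class TestAggregateRuns:
    def test_mean_and_sem_by_hand(self):
        res = aggregate_runs([10.0, 12.0, 14.0])
        assert res.mean == pytest.approx(12.0)
        assert res.sem == pytest.approx(2.0 / np.sqrt(3))

    def test_single_run_flagged(self):
        with pytest.warns(UserWarning, match="single"):
            res = aggregate_runs([5.0])
        assert res.sem == 0.0 and res.single_run

    def test_identical_values_have_zero_sem(self):
        assert aggregate_runs([7.0, 7.0, 7.0]).sem == 0.0


class TestFesRmse:
    def test_offset_alignment_removes_constant(self):
        from clampdyn.free_energy import FreeEnergySurface
        grid = Grid(d_centers=np.linspace(1, 10, 10),
                    n_centers=np.array([0.0]))
        G = np.linspace(0, 5, 10)[:, None]
        a = FreeEnergySurface(grid=grid, G=G, sampled=np.ones_like(G, bool))
        b = FreeEnergySurface(grid=grid, G=G.copy(),
                              sampled=np.ones_like(G, bool))
        assert fes_rmse(a, b) == pytest.approx(0.0, abs=1e-12)


class TestSmoothProfile:
    def test_preserves_wide_features(self):
        from clampdyn.free_energy import smooth_profile
        d = np.linspace(0, 20, 160)
        G = 3.0 * (1 - np.exp(-((d - 6) ** 2) / (2 * 1.5**2)))
        prof = Profile(d_centers=d, G=G - G.min(),
                       sampled=np.ones(len(d), bool))
        sm = smooth_profile(prof, 3.0)
        # the 0.375 Å kernel may shallow the 1.5 Å-wide well slightly but
        # must leave the flat plateau untouched
        np.testing.assert_allclose(sm.G, prof.G, atol=0.15)
        flat = d > 12
        diff = sm.G[flat] - prof.G[flat]  # constant offset allowed
        assert diff.std() < 1e-3

    def test_removes_bin_scale_noise(self, rng):
        from clampdyn.free_energy import smooth_profile
        d = np.linspace(0, 20, 160)
        noise = 0.3 * rng.standard_normal(len(d))
        prof = Profile(d_centers=d, G=noise - noise.min(),
                       sampled=np.ones(len(d), bool))
        sm = smooth_profile(prof, 3.0)
        assert sm.G[sm.sampled].std() < 0.5 * prof.G[prof.sampled].std()

    def test_disjoint_segments_smoothed_independently(self):
        from clampdyn.free_energy import smooth_profile
        d = np.linspace(0, 10, 40)
        sampled = np.ones(40, bool)
        sampled[18:22] = False
        G = np.where(sampled, 1.0, np.inf)
        G[0] = 0.0
        sm = smooth_profile(Profile(d_centers=d, G=G, sampled=sampled), 2.0)
        assert np.all(np.isfinite(sm.G[sampled]))
        assert np.all(np.isinf(sm.G[~sampled]))

    def test_zero_sigma_is_identity(self):
        from clampdyn.free_energy import smooth_profile
        prof = Profile(d_centers=np.arange(5.0), G=np.arange(5.0),
                       sampled=np.ones(5, bool))
        sm = smooth_profile(prof, 0.0)
        np.testing.assert_array_equal(sm.G, prof.G)
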