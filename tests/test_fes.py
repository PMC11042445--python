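"""Umbrella windows, bias energies, WHAM and Boltzmann-inversion PMFs."""

import numpy as np
import pytest

from kinrank.fes import (
    KT_300K,
    PMFGrid,
    UmbrellaWindow,
    assign_window_seeds,
    bias_energy,
    exclude_windows,
    make_window_grid,
    unbiased_pmf,
    wham,
)
from kinrank.synthetic import (
    LangevinConfig,
    double_well_potential,
    simulate_langevin,
)


class TestWindowGrid:
    def test_default_grid_121_windows(self):
        wins = make_window_grid()
        assert len(wins) == 121
        assert wins[0].center == pytest.approx((-0.8, 0.0))
        assert wins[-1].center == pytest.approx((-0.1, 0.8))
        # spacing between successive sigma2 centers and sigma1 blocks
        assert wins[1].center[1] - wins[0].center[1] == pytest.approx(0.08)
        assert wins[11].center[0] - wins[0].center[0] == pytest.approx(0.07)
        assert all(w.force_constant == 1000.0 for w in wins)

    def test_two_by_two_unit_square_corners(self):
        wins = make_window_grid(((0, 1), (0, 1)), shape=(2, 2))
        centers = {w.center for w in wins}
        assert centers == {(0, 0), (0, 1), (1, 0), (1, 1)}

    def test_centers_inside_closed_ranges(self):
        wins = make_window_grid(((-2, 3), (1, 4)), shape=(7, 5))
        for w in wins:
            assert -2 <= w.center[0] <= 3 and 1 <= w.center[1] <= 4

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            make_window_grid(((0, 0), (0, 1)))


class TestSeedAssignment:
    def test_single_candidate_gets_all_windows(self):
        wins = make_window_grid(((0, 1), (0, 1)), shape=(3, 3))
        mapping = assign_window_seeds(wins, [("only", 0.5, 0.5)])
        assert set(mapping.values()) == {"only"}

    def test_candidate_at_center_claims_it(self):
        wins = make_window_grid(((0, 1), (0, 1)), shape=(3, 3))
        cands = [("far", 10.0, 10.0), ("home", 0.5, 0.5)]
        mapping = assign_window_seeds(wins, cands)
        center_win = next(w for w in wins if w.center == (0.5, 0.5))
        assert mapping[center_win.id] == "home"

    def test_matches_brute_force_nearest_neighbor(self):
        rng = np.random.default_rng(4)
        wins = make_window_grid(((-1, 1), (-1, 1)), shape=(5, 5))
        cands = [(f"c{i}", *rng.uniform(-1, 1, 2)) for i in range(12)]
        mapping = assign_window_seeds(wins, cands)
        for w in wins:
            d = [np.hypot(w.center[0] - c[1], w.center[1] - c[2]) for c in cands]
            assert mapping[w.id] == cands[int(np.argmin(d))][0]


class TestBiasEnergy:
    def test_zero_at_center(self):
        w = UmbrellaWindow("w", (0.3, -0.2), force_constant=1000.0)
        assert bias_energy(w, (0.3, -0.2)) == 0.0

    def test_printed_arithmetic(self):
        w = UmbrellaWindow("w", (0.0, 0.0), force_constant=1000.0)
        assert bias_energy(w, (0.1, 0.0)) == pytest.approx(5.0)

    def test_additive_over_axes(self):
        w = UmbrellaWindow("w", (0.0, 0.0), force_constant=700.0)
        rng = np.random.default_rng(2)
        for d1, d2 in rng.uniform(-1, 1, size=(10, 2)):
            assert bias_energy(w, (d1, d2)) == pytest.approx(
                bias_energy(w, (d1, 0.0)) + bias_energy(w, (0.0, d2))
            )


def _unbiased_window(n_steps=40_000, seed=3, kT=KT_300K):
    pot = double_well_potential(kT=kT)
    traj = simulate_langevin(
        pot, LangevinConfig(kT=kT, dt=2e-3, n_steps=n_steps, seed=seed, start=(-1, 0))
    )
    return pot, UmbrellaWindow("w0", (0.0, 0.0), force_constant=0.0,
                               trajectory=traj, burn_in=n_steps // 10)


class TestWham:
    def test_zero_bias_window_degenerates_to_boltzmann_inversion(self):
        _, w = _unbiased_window()
        g_wham = wham([w], bins=20)
        g_inv = unbiased_pmf([w.trajectory], bins=20, burn_in=w.burn_in)
        np.testing.assert_array_equal(g_wham.sampled_mask, g_inv.sampled_mask)
        m = g_wham.sampled_mask
        np.testing.assert_allclose(g_wham.pmf[m], g_inv.pmf[m], atol=1e-9)

    def test_flat_potential_gives_flat_pmf(self):
        from kinrank.synthetic import ModelPotential

        flat = ModelPotential(centers=[(0, 0)], depths=[0.0], widths=[1.0])
        kT = KT_300K
        wins = []
        for i, c in enumerate(np.linspace(-1, 1, 3)):
            traj = simulate_langevin(
                flat,
                LangevinConfig(kT=kT, dt=2e-3, n_steps=60_000, seed=10 + i,
                               start=(c, 0.0), bias_center=(c, 0.0), bias_k=2.0 * kT),
            )
            wins.append(UmbrellaWindow(f"w{i}", (c, 0.0), force_constant=2.0 * kT,
                                       trajectory=traj, burn_in=6000))
        grid = wham(wins, bins=20, kT=kT)
        # judge the window-covered region (within one bias sd of a center);
        # reweighting noise blows up in bins no window sampled well
        c1, c2 = grid.centers
        G1, G2 = np.meshgrid(c1, c2, indexing="ij")
        near = np.full(G1.shape, np.inf)
        for w in wins:
            near = np.minimum(near, np.hypot(G1 - w.center[0], G2 - w.center[1]))
        good = grid.sampled_mask & (near < np.sqrt(kT / (2.0 * kT)))
        spread = grid.pmf[good].max() - grid.pmf[good].min()
        assert spread < 0.5 * kT

    def test_recovers_double_well_pmf(self):
        kT = KT_300K
        pot = double_well_potential(kT=kT)
        k_bias = 3.0 * kT
        wins = []
        for i, c1 in enumerate(np.linspace(-1.5, 1.5, 3)):
            for j, c2 in enumerate(np.linspace(-0.75, 0.75, 3)):
                traj = simulate_langevin(
                    pot,
                    LangevinConfig(kT=kT, dt=2e-3, n_steps=40_000,
                                   seed=100 + 10 * i + j, start=(c1, c2),
                                   bias_center=(c1, c2), bias_k=k_bias),
                )
                wins.append(UmbrellaWindow(f"w{i}{j}", (c1, c2),
                                           force_constant=k_bias,
                                           trajectory=traj, burn_in=4000))
        grid = wham(wins, bins=25, kT=kT)
        ref = pot.analytic_pmf(grid.edges, kT)
        mask = grid.sampled_mask & (ref < 3 * kT)
        rmse = np.sqrt(np.mean((grid.pmf[mask] - ref[mask]) ** 2))
        assert rmse < 0.5 * kT

    def test_invariant_to_window_order_and_duplication(self):
        kT = KT_300K
        pot = double_well_potential(kT=kT)
        wins = []
        for i, c in enumerate([(-1.0, 0.0), (1.0, 0.0)]):
            traj = simulate_langevin(
                pot, LangevinConfig(kT=kT, dt=2e-3, n_steps=30_000, seed=20 + i,
                                    start=c, bias_center=c, bias_k=2 * kT))
            wins.append(UmbrellaWindow(f"w{i}", c, force_constant=2 * kT,
                                       trajectory=traj, burn_in=3000))
        edges = (np.linspace(-2, 2, 21), np.linspace(-1.5, 1.5, 21))
        g1 = wham(wins, bins=edges, kT=kT)
        g2 = wham(wins[::-1], bins=edges, kT=kT)
        m = g1.sampled_mask
        np.testing.assert_allclose(g1.pmf[m], g2.pmf[m], atol=1e-6)

        # duplication leaves the PMF unchanged when the duplicated window's
        # histogram is WHAM-consistent — exactly the single-window case
        solo = wins[:1]
        dup = solo + [UmbrellaWindow("w0b", solo[0].center,
                                     force_constant=solo[0].force_constant,
                                     trajectory=solo[0].trajectory,
                                     burn_in=solo[0].burn_in)]
        g_solo = wham(solo, bins=edges, kT=kT)
        g_dup = wham(dup, bins=edges, kT=kT)
        ms = g_solo.sampled_mask
        np.testing.assert_allclose(g_solo.pmf[ms], g_dup.pmf[ms], atol=1e-6)

    def test_gauge_fixed_window_free_energies(self):
        _, w = _unbiased_window(n_steps=20_000)
        grid = wham([w], bins=15)
        assert grid.window_free_energies[0] == 0.0

    def test_no_included_windows_rejected(self):
        _, w = _unbiased_window(n_steps=5_000)
        w.excluded = True
        with pytest.raises(ValueError, match="included"):
            wham([w])


class TestUnbiasedPmf:
    def test_uniform_samples_near_flat(self):
        rng = np.random.default_rng(0)
        samples = rng.uniform(0, 1, size=(100_000, 2))
        grid = unbiased_pmf([samples], bins=(np.linspace(0, 1, 11),
                                             np.linspace(0, 1, 11)), burn_in=0)
        assert grid.pmf[grid.sampled_mask].max() < 0.3 * grid.kT

    def test_single_occupied_bin(self):
        samples = np.tile([[0.5, 0.5]], (100, 1))
        grid = unbiased_pmf([samples], bins=(np.linspace(0, 1, 5),
                                             np.linspace(0, 1, 5)), burn_in=0)
        assert grid.sampled_mask.sum() == 1
        assert grid.pmf[grid.sampled_mask][0] == 0.0
        assert np.isinf(grid.pmf[~grid.sampled_mask]).all()

    def test_duplication_invariance(self):
        rng = np.random.default_rng(1)
        samples = rng.normal(size=(5000, 2))
        edges = (np.linspace(-3, 3, 16), np.linspace(-3, 3, 16))
        g1 = unbiased_pmf([samples], bins=edges, burn_in=0)
        g2 = unbiased_pmf([samples, samples], bins=edges, burn_in=0)
        m = g1.sampled_mask
        np.testing.assert_allclose(g1.pmf[m], g2.pmf[m], atol=1e-12)

    def test_burn_in_fraction_and_count_agree(self):
        rng = np.random.default_rng(2)
        samples = rng.normal(size=(1000, 2))
        edges = (np.linspace(-3, 3, 11), np.linspace(-3, 3, 11))
        g_frac = unbiased_pmf([samples], bins=edges, burn_in=0.1)
        g_count = unbiased_pmf([samples], bins=edges, burn_in=100)
        np.testing.assert_array_equal(g_frac.counts, g_count.counts)


class TestExcludeWindows:
    def _wins(self, n):
        return [UmbrellaWindow(f"w{i}", (0.0, 0.0)) for i in range(n)]

    def test_threshold_split(self):
        wins = exclude_windows(self._wins(2), [0.10, 0.25])
        assert [w.excluded for w in wins] == [False, True]
        assert "25" in wins[1].exclusion_reason

    def test_exact_threshold_included(self):
        wins = exclude_windows(self._wins(1), [0.20])
        assert not wins[0].excluded

    def test_threshold_one_excludes_nothing(self):
        wins = exclude_windows(self._wins(3), [0.5, 0.9, 1.0], threshold=1.0)
        assert not any(w.excluded for w in wins)


class TestPmfGridContract:
    def test_sampled_min_is_zero_and_serialization_round_trips(self, tmp_path):
        _, w = _unbiased_window(n_steps=20_000)
        grid = wham([w], bins=15)
        assert grid.pmf[grid.sampled_mask].min() == 0.0
        grid.save(tmp_path / "pmf")
        loaded = PMFGrid.load(tmp_path / "pmf")
        np.testing.assert_array_equal(loaded.sampled_mask, grid.sampled_mask)
        m = grid.sampled_mask
        np.testing.assert_allclose(loaded.pmf[m], grid.pmf[m], atol=1e-9)
        assert loaded.kT == grid.kT

    def test_lookup_off_grid_is_infinite(self):
        _, w = _unbiased_window(n_steps=10_000)
        grid = wham([w], bins=10)
        assert np.isinf(grid.lookup((99.0, 99.0)))
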