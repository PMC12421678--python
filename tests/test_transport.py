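"""MSD, Einstein diffusivity, Arrhenius fits, distributions, density maps."""

import numpy as np
import pytest

from lignotherm.constants import N_AVOGADRO, NM3_TO_CM3, WATER_MOLAR_MASS
from lignotherm.exceptions import DataError, DomainError, FitFailureError
from lignotherm.synthetic import WalkerParams, gen_random_walks
from lignotherm.transport import (
    ArrheniusModel,
    DiffusionModel,
    MSDSeries,
    TrajectorySet,
    arrhenius_fit,
    compute_msd,
    diffusivity_distribution_summary,
    einstein_diffusivity,
    per_molecule_diffusivity,
    water_density_map,
)


def _static_traj(n_mol=4, n_t=50):
    times = np.arange(n_t) * 0.1
    positions = np.tile(np.arange(n_mol)[:, None, None], (1, n_t, 3)).astype(float)
    return TrajectorySet(times=times, positions=positions, box=np.full(3, 10.0))


class TestComputeMsd:
    def test_stationary_molecules(self):
        msd = compute_msd(_static_traj())
        np.testing.assert_array_equal(msd.msd, 0.0)

    def test_msd_zero_at_zero_lag(self):
        traj = gen_random_walks(WalkerParams(n_walkers=10, n_steps=50, seed=0))
        msd = compute_msd(traj)
        assert msd.lag[0] == 0.0
        assert msd.msd[0] == 0.0

    def test_ballistic_closed_form(self):
        """Deterministic motion at speed v gives MSD(tau) = (v tau)^2."""
        v = 0.02  # nm/ns, small enough to stay unwrapped-looking
        times = np.arange(200) * 0.1
        pos = np.zeros((3, 200, 3))
        pos[:, :, 0] = v * times
        traj = TrajectorySet(times=times, positions=pos, box=np.full(3, 10.0))
        msd = compute_msd(traj, origin_stride=1)
        np.testing.assert_allclose(msd.msd, (v * msd.lag) ** 2, rtol=1e-10)

    def test_pair_counts_non_increasing(self):
        traj = gen_random_walks(WalkerParams(n_walkers=10, n_steps=100, seed=1))
        msd = compute_msd(traj)
        assert np.all(np.diff(msd.n_pairs[1:]) <= 0)

    def test_wrapped_coordinates_rejected(self):
        times = np.array([0.0, 0.1, 0.2])
        pos = np.zeros((1, 3, 3))
        pos[0, 1, 0] = 9.0  # jump of 9 nm in a 10 nm box
        traj = TrajectorySet(times=times, positions=pos, box=np.full(3, 10.0))
        with pytest.raises(DataError):
            compute_msd(traj)

    def test_max_lag_beyond_span_rejected(self):
        with pytest.raises(DomainError):
            compute_msd(_static_traj(), max_lag=100.0)


class TestEinstein:
    def test_exact_linear_msd(self):
        """MSD = 6 D tau with D = 1e-12 m^2/s gives D back exactly."""
        lag = np.linspace(0.0, 10.0, 51)
        d_nm = 1e-12 / 1e-9  # nm^2/ns
        msd = MSDSeries(lag=lag, msd=6.0 * d_nm * lag,
                        n_pairs=np.full(51, 100))
        est = einstein_diffusivity(msd)
        assert est.D == pytest.approx(1e-12, rel=1e-12)

    def test_average_then_fit_equals_fit_then_average(self):
        """On noise-free input, averaging two replica MSDs before fitting and
        averaging the two fitted D values agree (linearity)."""
        lag = np.linspace(0.0, 10.0, 51)
        m1 = MSDSeries(lag=lag, msd=6.0 * lag, n_pairs=np.full(51, 10))
        m2 = MSDSeries(lag=lag, msd=12.0 * lag, n_pairs=np.full(51, 10))
        avg = MSDSeries(lag=lag, msd=0.5 * (m1.msd + m2.msd),
                        n_pairs=np.full(51, 20))
        d_fit_avg = einstein_diffusivity(avg).D
        d_avg_fit = 0.5 * (einstein_diffusivity(m1).D
                           + einstein_diffusivity(m2).D)
        assert d_fit_avg == pytest.approx(d_avg_fit, rel=1e-12)

    def test_seeded_walkers_within_tolerance(self):
        D = 2e-13
        traj = gen_random_walks(WalkerParams.single(D, n_walkers=300,
                                                    n_steps=800, seed=5))
        res = DiffusionModel(traj).fit()
        assert res.D == pytest.approx(D, rel=0.05)

    def test_negative_slope_clamped(self):
        lag = np.linspace(0.0, 10.0, 51)
        rng = np.random.default_rng(0)
        msd = MSDSeries(lag=lag, msd=-1.0 * lag + rng.normal(0, 1e-4, 51),
                        n_pairs=np.full(51, 10))
        with pytest.warns(UserWarning, match="clamping"):
            est = einstein_diffusivity(msd)
        assert est.D == 0.0 and est.clamped

    def test_window_outside_span_rejected(self):
        lag = np.linspace(0.0, 10.0, 51)
        msd = MSDSeries(lag=lag, msd=lag, n_pairs=np.full(51, 10))
        with pytest.raises(DomainError):
            einstein_diffusivity(msd, fit_window=(5.0, 20.0))


class TestArrhenius:
    def test_two_point_closed_form(self):
        """D(300 K) = 1e-12, D(600 K) = 1e-6: Ed = R ln(1e6) * 600 J/mol."""
        fit = arrhenius_fit([300.0, 600.0], [1e-12, 1e-6])
        expected = 8.314 * np.log(1e6) * 600.0 / 1000.0  # ~68.9 kJ/mol
        assert fit.Ed == pytest.approx(expected, rel=1e-12)

    def test_noise_free_round_trip_exact(self):
        from lignotherm.synthetic import ArrheniusParams, gen_arrhenius_series

        frame = gen_arrhenius_series(ArrheniusParams(Ed_true=50.0,
                                                     lognoise_sd=0.0))
        fit = arrhenius_fit(frame["T_K"], frame["D_m2_s"])
        assert fit.Ed == pytest.approx(50.0, rel=1e-10)
        assert fit.D0 == pytest.approx(1e-7, rel=1e-8)

    def test_zero_activation_energy(self):
        T = np.array([300.0, 400.0, 500.0])
        fit = arrhenius_fit(T, np.full(3, 1e-10))
        assert fit.Ed == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_points_excluded(self):
        with pytest.warns(UserWarning, match="non-positive"):
            fit = arrhenius_fit([300.0, 400.0, 500.0], [1e-12, 0.0, 1e-10])
        assert fit.n_points == 2

    def test_too_few_points_rejected(self):
        with pytest.raises(FitFailureError):
            arrhenius_fit([300.0], [1e-12])

    def test_branch_split_returns_two_fits(self):
        from lignotherm.synthetic import ArrheniusParams, gen_arrhenius_series

        frame = gen_arrhenius_series(ArrheniusParams(lognoise_sd=0.0))
        results = ArrheniusModel.from_dataframe(frame).fit(branch_split=450.0)
        assert set(results.fits) == {"below_Tg", "above_Tg"}
        assert results["below_Tg"].Ed == pytest.approx(50.0, rel=1e-8)
        assert results["above_Tg"].Ed == pytest.approx(50.0, rel=1e-8)

    def test_ci_covers_truth_at_stated_noise(self):
        """95% interval coverage near nominal over repeated seeded draws."""
        from lignotherm.synthetic import ArrheniusParams, gen_arrhenius_series

        hits = 0
        n = 200
        for seed in range(n):
            frame = gen_arrhenius_series(ArrheniusParams(
                Ed_true=50.0, lognoise_sd=0.1, seed=seed))
            lo, hi = arrhenius_fit(frame["T_K"], frame["D_m2_s"]).ci(0.95)
            hits += lo <= 50.0 <= hi
        assert 0.90 <= hits / n <= 0.99


class TestPerMolecule:
    def test_zero_tau_rejected(self):
        traj = gen_random_walks(WalkerParams(n_walkers=5, n_steps=50, seed=0))
        with pytest.raises(DomainError):
            per_molecule_diffusivity(traj, [0.0])

    def test_identical_walkers_concentrate_around_common_d(self):
        """For a single-component ensemble the per-molecule distribution is
        centered on the common D at every sampling time, and tightens as the
        number of independent displacement windows per molecule grows
        (i.e. at shorter tau for a fixed record length)."""
        D = 5e-12
        traj = gen_random_walks(WalkerParams.single(D, n_walkers=100,
                                                    n_steps=1000, seed=3))
        table = per_molecule_diffusivity(traj, [1.0, 50.0])
        summary = diffusivity_distribution_summary(table).set_index("tau_ns")
        for tau in (1.0, 50.0):
            assert summary.loc[tau, "median"] == pytest.approx(D, rel=0.4)
        rel_iqr = (summary["q75"] - summary["q25"]) / summary["median"]
        assert rel_iqr.loc[1.0] < rel_iqr.loc[50.0]
        assert rel_iqr.loc[1.0] < 0.5

    def test_bimodal_mixture_detectable(self):
        """A 50/50 mixture with a 100x diffusivity ratio shows two separated
        populations at short sampling times, with a valley between the
        component medians."""
        p = WalkerParams(components=((1e-13, 0.5), (1e-11, 0.5)),
                         n_walkers=300, n_steps=500, seed=7)
        traj = gen_random_walks(p)
        labels = np.array(traj.ground_truth["labels"])
        table = per_molecule_diffusivity(traj, [1.0])
        d = table["D_eff_m2_s"].to_numpy()
        med_slow = np.median(d[labels == 0])
        med_fast = np.median(d[labels == 1])
        assert 30 < med_fast / med_slow < 300
        mid = np.sqrt(med_slow * med_fast)
        in_valley = np.mean((d > mid / 2) & (d < mid * 2))
        near_modes = np.mean((d > med_slow / 2) & (d < med_slow * 2)) \
            + np.mean((d > med_fast / 2) & (d < med_fast * 2))
        assert in_valley < near_modes / 2

    def test_ensemble_mean_approaches_einstein(self):
        traj = gen_random_walks(WalkerParams.single(5e-12, n_walkers=200,
                                                    n_steps=800, seed=9))
        einstein = DiffusionModel(traj).fit().D
        tau = 0.9 * traj.span
        table = per_molecule_diffusivity(traj, [tau])
        assert table["D_eff_m2_s"].mean() == pytest.approx(einstein, rel=0.10)


class TestDensityMap:
    def _uniform_traj(self, n_mol=400, n_t=5, seed=0):
        rng = np.random.default_rng(seed)
        times = np.arange(n_t) * 1.0
        pos = rng.uniform(0, 10.0, (n_mol, n_t, 3))
        # keep steps small so the unwrap check passes
        pos = np.cumsum(np.full((n_mol, n_t, 3), 0.0), axis=1) + pos[:, :1, :]
        return TrajectorySet(times=times, positions=pos,
                             box=np.full(3, 10.0), species="water")

    def test_mass_conservation(self):
        traj = self._uniform_traj()
        dmap = water_density_map(traj, grid_n=8)
        expected = traj.n_molecules * WATER_MOLAR_MASS / N_AVOGADRO
        assert dmap.total_mass_g() == pytest.approx(expected, rel=1e-6)

    def test_single_cell_equals_bulk_density(self):
        traj = self._uniform_traj()
        dmap = water_density_map(traj, grid_n=1)
        bulk = (traj.n_molecules * WATER_MOLAR_MASS / N_AVOGADRO
                / (10.0 ** 3 * NM3_TO_CM3))
        assert dmap.grid[0, 0] == pytest.approx(bulk, rel=1e-9)

    def test_octant_concentration(self):
        """All molecules in one octant puts >= 99% of mass in one quadrant."""
        times = np.arange(3) * 1.0
        rng = np.random.default_rng(1)
        pos = rng.uniform(0.0, 5.0, (200, 3, 3))  # lower octant of 10 nm box
        pos = pos[:, :1, :] + 0 * pos  # static
        traj = TrajectorySet(times=times, positions=pos,
                             box=np.full(3, 10.0))
        dmap = water_density_map(traj, grid_n=4)
        cell_mass = dmap.grid * np.outer(np.diff(dmap.edges_a),
                                         np.diff(dmap.edges_b)) * 10.0
        quadrant = cell_mass[:2, :2].sum()
        assert quadrant / cell_mass.sum() >= 0.99

    def test_uniform_points_statistically_flat(self):
        traj = self._uniform_traj(n_mol=2000, n_t=1, seed=3)
        dmap = water_density_map(traj, grid_n=4)
        counts = dmap.grid / dmap.grid.mean()
        expected_per_cell = 2000 / 16
        sigma = 1.0 / np.sqrt(expected_per_cell)
        assert np.all(np.abs(counts - 1.0) < 3.5 * sigma)

    def test_empty_selection_flagged(self):
        traj = self._uniform_traj()
        dmap = water_density_map(traj, grid_n=4, time_window=(100.0, 200.0))
        assert dmap.empty
        np.testing.assert_array_equal(dmap.grid, 0.0)

    def test_invalid_grid_rejected(self):
        with pytest.raises(DomainError):
            water_density_map(self._uniform_traj(), grid_n=0)


class TestTrajectoryIO:
    def test_csv_round_trip(self, tmp_path):
        traj = gen_random_walks(WalkerParams(n_walkers=4, n_steps=10, seed=2,
                                             temperature=400.0))
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        loaded = TrajectorySet.from_csv(path)
        np.testing.assert_allclose(loaded.positions, traj.positions)
        np.testing.assert_allclose(loaded.box, traj.box)
        assert loaded.temperature == 400.0
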