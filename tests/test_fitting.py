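"""Gaussian pulse fitting, window selection, and kinetics regression."""

import numpy as np
import pytest

from conftest import make_single_channel

from auxinpulse.fitting import (
    FitError,
    GaussianFit,
    empirical_spreading_rate,
    estimate_kinetics,
    gaussian_least_squares,
    maximal_fit,
    profile_moments,
    surrogate_spreading_rate,
)
from auxinpulse.profiles import PulseProfile
from auxinpulse.scenarios import kinetics_from_trajectory
from auxinpulse.simulator import (
    ChannelSpec,
    DiscretizationParams,
    LoadingProtocol,
    TissueModel,
    bin_profile,
    initial_field,
    simulate,
)
from auxinpulse.flux import LinearFluxParams
from auxinpulse.units import cm2s_to_mm2hr


def gaussian_profile(A=1000.0, mu=20.0, var=9.0, n=30, width=2.0, floor=0.0):
    x = (np.arange(n) + 0.5) * width
    y = A * np.exp(-((x - mu) ** 2) / (2 * var)) + floor
    return PulseProfile(x, y, bin_width_mm=width)


def two_component_profile():
    """Gaussian core plus a heavy exponential trailing shoulder."""
    x = np.arange(1.0, 60.0, 2.0)
    core = 1000.0 * np.exp(-((x - 30.0) ** 2) / (2 * 2.5**2))
    tail = np.exp(-x / 8.0)
    tail = tail / tail.sum() * 0.45 * core.sum()
    return PulseProfile(x, core + tail, bin_width_mm=2.0), 2.5**2


class TestProfileMoments:
    def test_symmetric_profile_mean(self):
        prof = gaussian_profile(mu=21.0)
        mean, _ = profile_moments(prof)
        assert mean == pytest.approx(21.0, abs=1e-6)

    def test_two_point_masses(self):
        prof = PulseProfile(np.array([10.0, 20.0]), np.array([1.0, 1.0]),
                            bin_width_mm=10.0)
        mean, var = profile_moments(prof)
        assert (mean, var) == (pytest.approx(15.0), pytest.approx(25.0))

    def test_zero_total_rejected(self):
        prof = PulseProfile(np.arange(4.0), np.zeros(4))
        with pytest.raises(ValueError):
            profile_moments(prof)


class TestGaussianLeastSquares:
    def test_exact_gaussian_recovered(self):
        prof = gaussian_profile(A=123.0, mu=19.3, var=7.7)
        fit = gaussian_least_squares(prof)
        assert fit.amplitude == pytest.approx(123.0, rel=1e-6)
        assert fit.mean_mm == pytest.approx(19.3, rel=1e-6)
        assert fit.variance_mm2 == pytest.approx(7.7, rel=1e-6)
        assert fit.variance_mm2 == pytest.approx(profile_moments(prof)[1], rel=0.05)

    def test_uniform_floor_inflates_variance(self):
        """A 10% uniform floor drags the whole-profile fit wide: the least-
        squares weakness that motivates the peak-window procedure."""
        clean = gaussian_least_squares(gaussian_profile())
        dirty = gaussian_least_squares(gaussian_profile(floor=100.0))
        assert dirty.variance_mm2 > clean.variance_mm2 * 1.2

    def test_single_nonzero_bin_fails(self):
        amounts = np.zeros(12)
        amounts[5] = 10.0
        prof = PulseProfile((np.arange(12) + 0.5) * 2.0, amounts)
        with pytest.raises(FitError):
            gaussian_least_squares(prof)

    def test_all_zero_fails(self):
        prof = PulseProfile(np.arange(6.0), np.zeros(6))
        with pytest.raises(FitError):
            gaussian_least_squares(prof)


class TestMaximalFit:
    def test_clean_gaussian_matches_least_squares(self):
        prof = gaussian_profile()
        mf = maximal_fit(prof)
        ls = gaussian_least_squares(prof)
        assert mf.mean_mm == pytest.approx(ls.mean_mm, rel=0.01)
        assert mf.variance_mm2 == pytest.approx(ls.variance_mm2, rel=0.01)

    def test_trailing_shoulder_is_ignored(self):
        """The selected peak window recovers the core component's variance
        while the whole-profile moment variance is inflated many-fold."""
        prof, core_var = two_component_profile()
        fit = maximal_fit(prof)
        assert fit.variance_mm2 == pytest.approx(core_var, rel=0.15)
        assert profile_moments(prof)[1] > 2 * core_var

    def test_window_contains_global_maximum(self):
        prof, _ = two_component_profile()
        fit = maximal_fit(prof)
        imax = int(np.argmax(prof.amounts))
        assert fit.window[0] <= imax <= fit.window[1]

    def test_deterministic(self):
        prof, _ = two_component_profile()
        assert maximal_fit(prof) == maximal_fit(prof)

    def test_monotone_profile_rejected(self):
        x = (np.arange(10) + 0.5) * 2.0
        prof = PulseProfile(x, np.exp(-x / 5.0))
        with pytest.raises(FitError):
            maximal_fit(prof)


class TestEstimateKinetics:
    def _fit(self, mean, var):
        return GaussianFit(1.0, mean, var, (0, 4), 0.0)

    def test_exact_linear_series(self):
        fits = [(t, self._fit(5 + 9 * t, 2 + 12 * t)) for t in (0.0, 0.5, 1.0, 1.5)]
        kin = estimate_kinetics(fits)
        assert (kin.v, kin.rho) == (pytest.approx(9.0), pytest.approx(12.0))
        assert kin.v_se == pytest.approx(0.0, abs=1e-9)
        assert kin.rho_se == pytest.approx(0.0, abs=1e-9)

    def test_two_points_exact(self):
        kin = estimate_kinetics([(0.0, self._fit(5, 2)), (1.0, self._fit(14, 14))])
        assert (kin.v, kin.rho) == (pytest.approx(9.0), pytest.approx(12.0))
        assert kin.v_se == 0.0

    def test_variance_offset_leaves_rho_unchanged(self):
        """A constant loading-distribution variance is additive and drops out
        of the slope."""
        base = [(t, self._fit(9 * t, 1 + 10 * t)) for t in (0.0, 0.7, 1.3)]
        shifted = [(t, self._fit(9 * t, 6 + 10 * t)) for t in (0.0, 0.7, 1.3)]
        assert estimate_kinetics(base).rho == pytest.approx(
            estimate_kinetics(shifted).rho
        )

    def test_shift_and_scale_equivariance(self):
        rng = np.random.default_rng(3)
        times = (0.0, 0.5, 1.0, 1.5, 2.0)
        means = 4 + 9 * np.array(times) + rng.normal(0, 0.2, 5)
        variances = 3 + 11 * np.array(times) + rng.normal(0, 0.5, 5)
        base = [(t, self._fit(m, v)) for t, m, v in zip(times, means, variances)]
        shifted = [(t, self._fit(m + 7.0, v)) for t, m, v in zip(times, means, variances)]
        kin0, kin1 = estimate_kinetics(base), estimate_kinetics(shifted)
        assert kin1.v == pytest.approx(kin0.v)
        assert kin1.rho == pytest.approx(kin0.rho)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            estimate_kinetics([(0.0, self._fit(1, 1))])


class TestEmpiricalSpreadingRate:
    def test_pure_diffusion_approaches_2D(self):
        """With no carriers at all, variance grows at 2D (continuum limit).

        A single long 'cell' with many compartments is an unobstructed
        diffusing medium; the discrete exchange convention carries a
        (1 - 1/N) factor relative to the continuum.
        """
        D = 5e-6
        N = 80
        model = TissueModel(
            channels=(ChannelSpec(face_law=LinearFluxParams(0.0, 0.0), D=D),),
            couplings=(),
            cell_length=0.2,  # 2 mm cells: walls stay ~3 sigma away
            n_cells=2,
            disc=DiscretizationParams(n_compartments=N, delta_t=0.02),
        )
        state = initial_field(model)
        state.conc[N // 2, 0] = 1.0  # pulse mid-way through the first cell
        traj = simulate(model, None, 120.0, [40.0, 120.0], initial=state)
        rho = (traj[1].moments()[1] - traj[0].moments()[1]) / (80.0 / 3600.0)
        expected = cm2s_to_mm2hr(2 * D) * (1 - 1 / N)
        assert rho == pytest.approx(expected, rel=0.02)

    def test_stays_below_spreading_bound(self, single_channel_fig3):
        from auxinpulse.analytics import spreading_bound

        rho = empirical_spreading_rate(single_channel_fig3)
        assert rho <= spreading_bound(9.99, 0.1, 0.052) * 1.001

    def test_agrees_with_fitted_kinetics(self, single_channel_fig3):
        """The two-time variance shortcut and the full fit-then-regress
        pipeline agree on the same trajectory."""
        rho_moments = empirical_spreading_rate(single_channel_fig3, 1800.0, 3600.0)
        traj = simulate(
            single_channel_fig3,
            LoadingProtocol(mode="instantaneous"),
            3600.0,
            [1800.0, 2250.0, 2700.0, 3150.0, 3600.0],
        )
        fits = [(f.time / 3600.0, maximal_fit(bin_profile(f, 1.0))) for f in traj]
        kin = estimate_kinetics(fits)
        assert kin.rho == pytest.approx(rho_moments, rel=0.05)


class TestSurrogateSpreadingRate:
    def test_equals_rho_for_linear_variance_growth(self, single_channel_fig3):
        traj = simulate(
            single_channel_fig3,
            LoadingProtocol(mode="instantaneous"),
            5400.0,
            [1800.0, 2700.0, 3600.0, 5400.0],
        )
        rho = kinetics_from_trajectory(traj)[1]
        assert surrogate_spreading_rate(traj, 1800.0) == pytest.approx(rho, rel=0.02)

    def test_time_choice_invariant_in_linear_regime(self, single_channel_fig3):
        traj = simulate(
            single_channel_fig3,
            LoadingProtocol(mode="instantaneous"),
            3600.0,
            [1800.0, 2700.0, 3600.0],
        )
        s15 = surrogate_spreading_rate(traj, 900.0)
        s30 = surrogate_spreading_rate(traj, 1800.0)
        assert s15 == pytest.approx(s30, rel=0.02)

    def test_defined_in_weak_coupling_regime(self):
        """Below the coupling threshold the variance grows superlinearly and
        rho proper is undefined; the surrogate is still computable."""
        from conftest import make_minimal_two_channel

        model = make_minimal_two_channel(s=1e-7, n_cells=350)
        traj = simulate(
            model, LoadingProtocol(mode="instantaneous"), 3600.0,
            [1800.0, 3600.0],
        )
        value = surrogate_spreading_rate(traj, 1800.0)
        assert np.isfinite(value) and value > 0
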