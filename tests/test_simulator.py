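"""Compartmental simulator: conservation, stability, and closed-form checks."""

import numpy as np
import pytest

from conftest import make_minimal_two_channel, make_single_channel

from auxinpulse.analytics import spreading_bound, velocity_with_diffusion
from auxinpulse.flux import LinearFluxParams
from auxinpulse.scenarios import kinetics_from_trajectory
from auxinpulse.simulator import (
    ChannelSpec,
    DiscretizationParams,
    LoadingProtocol,
    StabilityError,
    TissueModel,
    _Grid,
    bin_profile,
    convert_computational_diffusion,
    convert_computational_permeability,
    goldsmith_protocol,
    initial_field,
    invert_computational_permeability,
    randomize_model,
    simulate,
    step,
)
from auxinpulse.units import cms_to_mmhr


class TestComputationalConversions:
    def test_permeability_formula(self):
        assert convert_computational_permeability(1.0, 0.01, 5, 0.05) == pytest.approx(
            0.04
        )

    def test_halving_time_step_doubles_permeability(self):
        p1 = convert_computational_permeability(1.0, 0.01, 5, 0.05)
        p2 = convert_computational_permeability(1.0, 0.01, 5, 0.025)
        assert p2 == pytest.approx(2 * p1)

    def test_round_trip(self):
        p = convert_computational_permeability(0.37, 0.01, 5, 0.05)
        assert invert_computational_permeability(p, 0.01, 5, 0.05) == pytest.approx(
            0.37
        )

    def test_diffusion_formula_and_minimum_n(self):
        assert convert_computational_diffusion(1.0, 0.01, 5, 0.05) == pytest.approx(
            1e-4
        )
        assert np.isfinite(convert_computational_diffusion(1.0, 0.01, 2, 0.05))
        with pytest.raises(ValueError):
            convert_computational_diffusion(1.0, 0.01, 1, 0.05)

    @pytest.mark.parametrize(
        "p_c,q_c,D_c,N", [(0.02, 0.0, 0.5, 5), (0.01, 0.002, 0.3, 8), (0.05, 0.01, 1.0, 3)]
    )
    def test_discrete_velocity_relation_maps_to_continuum(self, p_c, q_c, D_c, N):
        """1/v' = 1/p' + (N-1)/(2D')(1+2q'/p') is the computational-unit
        version of the diffusive velocity relation under both conversions."""
        L, dt = 0.01, 0.05
        p = convert_computational_permeability(p_c, L, N, dt)
        q = convert_computational_permeability(q_c, L, N, dt)
        D = convert_computational_diffusion(D_c, L, N, dt)
        v_cont = velocity_with_diffusion(p, q, L, D)
        v_comp = 1.0 / (1.0 / p_c + (N - 1) / (2 * D_c) * (1 + 2 * q_c / p_c))
        assert v_cont == pytest.approx(v_comp * L / (N * dt), rel=1e-12)


class TestStep:
    def test_mass_conserved_per_step(self, minimal_two_channel):
        state = initial_field(minimal_two_channel)
        rng = np.random.default_rng(0)
        state.conc[:] = rng.random(state.conc.shape)
        m0 = state.total_mass
        new = step(state, minimal_two_channel)
        assert new.total_mass == pytest.approx(m0, rel=1e-12)

    def test_single_face_polar_transfer(self):
        """Across one cell face with pure polar p, the amount moved in one
        step is p * a * area * dt."""
        p, dt = 4e-4, 0.05
        model = make_single_channel(p=p, q=0.0, n_cells=2, N=2, dt=dt)
        state = initial_field(model)
        a0 = 3.0
        state.conc[1, 0] = a0  # compartment just above the cell face
        new = step(state, model)
        width = model.channels[0].width
        ell = model.cell_length / 2
        expected_amount = p * a0 * width * dt
        gained = (new.conc[2, 0] - state.conc[2, 0]) * ell * width
        assert gained == pytest.approx(expected_amount, rel=1e-12)

    def test_uniform_diffusive_state_is_stationary(self):
        model = make_single_channel(p=0.0, q=1e-4, n_cells=5)
        state = initial_field(model)
        state.conc[:] = 0.7
        new = step(state, model)
        assert np.allclose(new.conc, 0.7, rtol=0, atol=1e-15)

    def test_negative_concentration_rejected(self, single_channel_fig3):
        state = initial_field(single_channel_fig3)
        state.conc[0, 0] = -1.0
        with pytest.raises(ValueError):
            step(state, single_channel_fig3)


class TestKernel:
    def test_kernel_matches_numpy_reference(self):
        """The compiled long-run kernel and the readable numpy step agree."""
        model = make_minimal_two_channel(n_cells=8)
        g = _Grid(model)
        rng = np.random.default_rng(1)
        a0 = rng.random((g.n_ax, g.n_col))
        a_ref = a0.copy()
        for _ in range(150):
            a_ref = g.step_numpy(a_ref)
        a_fast = a0.copy()
        g.run(a_fast, 150)
        np.testing.assert_allclose(a_fast, a_ref, rtol=0, atol=1e-14)

    def test_mass_conservation_long_run(self):
        """Closed system conserves mass to better than 1e-9 over 1e5 steps."""
        model = make_minimal_two_channel(n_cells=6)
        g = _Grid(model)
        rng = np.random.default_rng(2)
        a = rng.random((g.n_ax, g.n_col))
        m0 = (a * g.volumes).sum()
        g.run(a, 100_000)
        assert (a * g.volumes).sum() == pytest.approx(m0, rel=1e-9)
        assert a.min() >= 0.0

    def test_stability_guard_aborts_with_diagnostic(self):
        model = make_single_channel(p=0.1, dt=0.05)  # huge outflow per step
        with pytest.raises(StabilityError, match="fractional outflow"):
            initial_field(model)

    def test_unequal_width_lateral_exchange_conserves_mass(self):
        model = TissueModel(
            channels=(
                ChannelSpec(face_law=LinearFluxParams(0.0, 0.0), width=1e-4),
                ChannelSpec(face_law=LinearFluxParams(0.0, 0.0), width=9e-4),
            ),
            couplings=(5e-6,),
            n_cells=4,
        )
        g = _Grid(model)
        a = np.zeros((g.n_ax, g.n_col))
        a[:, 0] = 1.0
        m0 = (a * g.volumes).sum()
        g.run(a, 20_000)
        assert (a * g.volumes).sum() == pytest.approx(m0, rel=1e-10)
        # equilibrium concentration ratio across the interface -> s_fwd/s_rev
        assert np.median(a[:, 1] / a[:, 0]) == pytest.approx(1.0, rel=1e-3)


class TestSimulate:
    def test_zero_loading_stays_zero(self, single_channel_fig3):
        traj = simulate(single_channel_fig3, None, 10.0, [5.0, 10.0])
        assert all(f.total_mass == 0.0 for f in traj)

    def test_velocity_matches_closed_form(self, single_channel_fig3):
        """Single channel with p = 4e-4, q/p = 0.05, D = 5e-6: the measured
        peak velocity agrees with the diffusive velocity relation within 3%."""
        traj = simulate(
            single_channel_fig3,
            LoadingProtocol(mode="instantaneous"),
            3600.0,
            [1800.0, 2700.0, 3600.0],
        )
        v, rho = kinetics_from_trajectory(traj)
        v_theory = cms_to_mmhr(velocity_with_diffusion(4e-4, 2.08e-5, 100e-4, 5e-6))
        assert v == pytest.approx(v_theory, rel=0.03)
        assert rho <= spreading_bound(v, 0.1, 0.052) * 1.001

    def test_two_channel_synchronised_at_strong_coupling(self):
        """At s = 1e-3 the polar and apolar pulses travel as one."""
        from auxinpulse.scenarios import channel_velocity

        model = make_minimal_two_channel(s=1e-3, n_cells=300)
        traj = goldsmith_protocol(model, extra_record_times=(2700.0,))
        v0 = channel_velocity(traj, 0)
        v1 = channel_velocity(traj, 1)
        assert abs(v0 - v1) / v0 < 0.05

    def test_symmetric_channels_stay_identical(self):
        """Identical channels coupled by any s keep identical profiles."""
        law = LinearFluxParams(5e-4, 1e-5)
        model = TissueModel(
            channels=(ChannelSpec(face_law=law), ChannelSpec(face_law=law)),
            couplings=(1e-5,),
            n_cells=100,
        )
        traj = simulate(
            model, LoadingProtocol(mode="instantaneous"), 900.0, [450.0, 900.0]
        )
        for f in traj:
            np.testing.assert_allclose(f.conc[:, 0], f.conc[:, 1], rtol=1e-12)

    def test_grid_refinement_consistency(self, single_channel_fig3):
        """Doubling N changes the measured v and rho by < 3%."""
        model10 = make_single_channel(N=10)
        kin5 = kinetics_from_trajectory(
            goldsmith_protocol(single_channel_fig3, extra_record_times=(2700.0,))
        )
        kin10 = kinetics_from_trajectory(
            goldsmith_protocol(model10, extra_record_times=(2700.0,))
        )
        assert kin10[0] == pytest.approx(kin5[0], rel=0.03)
        assert kin10[1] == pytest.approx(kin5[1], rel=0.03)

    def test_basal_boundary_warning(self):
        model = make_single_channel(n_cells=30)  # only 3 mm of stem
        with pytest.warns(UserWarning, match="basal"):
            simulate(
                model, LoadingProtocol(mode="instantaneous"), 3600.0, [3600.0]
            )

    def test_nonnegative_concentrations(self, minimal_two_channel):
        traj = goldsmith_protocol(minimal_two_channel)
        for f in traj:
            assert f.conc.min() >= 0.0


class TestBinProfile:
    def test_total_mass_preserved(self, minimal_two_channel):
        traj = goldsmith_protocol(minimal_two_channel)
        prof = bin_profile(traj[-1])
        assert prof.total == pytest.approx(traj[-1].total_mass, rel=1e-12)

    def test_point_mass_single_bin(self, single_channel_fig3):
        state = initial_field(single_channel_fig3)
        state.conc[12, 0] = 4.0
        prof = bin_profile(state, 2.0)
        assert np.count_nonzero(prof.amounts) == 1

    def test_uniform_field_gives_equal_bins(self):
        model = make_single_channel(n_cells=200)  # 20 mm = 10 whole bins
        state = initial_field(model)
        state.conc[:] = 1.0
        prof = bin_profile(state, 2.0)
        assert np.allclose(prof.amounts, prof.amounts[0], rtol=1e-9)


class TestGoldsmithProtocol:
    def test_zero_time_profile_is_apical(self, single_channel_fig3):
        traj = goldsmith_protocol(single_channel_fig3)
        prof = bin_profile(traj[0])
        mean, _ = prof.moments()
        assert mean < 10.0  # mm; pulse still near the apical end
        assert prof.total == pytest.approx(1.0, rel=1e-9)

    def test_loading_invariance_of_spreading_rate(self, single_channel_fig3):
        """rho is the same for 15-min constant-rate and instantaneous loading."""
        from auxinpulse.fitting import empirical_spreading_rate

        traj = goldsmith_protocol(single_channel_fig3, extra_record_times=(2700.0,))
        _, rho_protocol = kinetics_from_trajectory(traj)
        rho_instant = empirical_spreading_rate(single_channel_fig3, 1800.0, 3600.0)
        assert rho_protocol == pytest.approx(rho_instant, rel=0.10)

    def test_single_channel_pulse_too_narrow(self, single_channel_fig3):
        """The 30-min single-channel pulse falls far short of the measured
        spreading (16-26 mm^2/hr): the central failure it demonstrates."""
        traj = goldsmith_protocol(single_channel_fig3, extra_record_times=(2700.0,))
        _, rho = kinetics_from_trajectory(traj)
        assert rho < 5.0


class TestNoiseRobustness:
    def test_randomised_lengths_and_permeabilities_barely_move_rho(
        self, single_channel_fig3
    ):
        """+/-20% cell-length and p randomisation leaves the spreading deficit:
        rho changes by a few percent, nowhere near the ~20x gap to the data."""
        from auxinpulse.fitting import empirical_spreading_rate

        rho0 = empirical_spreading_rate(single_channel_fig3, 1800.0, 3600.0)
        for seed in (1, 2):
            noisy = randomize_model(single_channel_fig3, 0.2, 0.2, seed=seed)
            rho = empirical_spreading_rate(noisy, 1800.0, 3600.0)
            assert rho == pytest.approx(rho0, rel=0.5)
            assert rho < 5.0  # still several-fold below the measured range
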