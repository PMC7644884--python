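"""Full time-dependent system: fluxes, integration, blockade, sweeps."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from avdsim.dynamics import (
    CellState,
    IntegrationOptions,
    QssNotReachedError,
    Schedule,
    detect_qss,
    equilibrium_blocked,
    equilibrium_state,
    integrate,
    integrate_delta_c,
    qss_relaxation_time,
    rhs_delta_c,
    rhs_volume_osmolyte,
    sweep,
)
from avdsim.model_core import (
    ModelParameters,
    qss_delta_c,
    qss_relative_rate,
    qss_relative_rate_high_pw,
)

# hand arithmetic: at dC=0, dV/dt = -rho*S*A*Pw with A = 4*pi*(5e-4)^2
DVDT_INITIAL = -4.5238934211693017e-14  # cm3/s
DNDT_INITIAL = -1.2566370614359172e-17  # mol/s


def plateau_rate_per_hour(params: ModelParameters, t_max: float = 1800.0) -> float:
    """Instantaneous relative shrinkage rate once dC has plateaued."""
    traj = integrate(params, t_max)
    onset, _ = detect_qss(traj)
    v0 = traj.volume[0]
    mask = (traj.times >= onset) & (traj.volume >= 0.95 * v0)
    i = int(np.argmax(mask))
    dv, _ = rhs_volume_osmolyte(CellState(traj.volume[i], traj.osmolyte[i]), params)
    return dv / v0 * 3600.0


class TestRightHandSides:
    def test_gradient_balancing_pressure_stops_everything_when_blocked(
        self, default_params
    ):
        p = default_params.with_(ion_permeability=0.0)
        state = equilibrium_state(p, delta_c0=p.pressure_equivalent)
        dv, dn = rhs_volume_osmolyte(state, p)
        # dC is reconstructed as N/V - C0, so balance holds to rounding
        assert abs(dv) < 1e-12 * abs(DVDT_INITIAL)
        assert dn == pytest.approx(0.0, abs=1e-12 * abs(DNDT_INITIAL))

    def test_initial_fluxes_match_hand_arithmetic(self, default_params):
        state = equilibrium_state(default_params)  # dC = 0
        dv, dn = rhs_volume_osmolyte(state, default_params)
        assert dv == pytest.approx(DVDT_INITIAL, rel=1e-12)
        assert dn == pytest.approx(DNDT_INITIAL, rel=1e-12)

    def test_true_equilibrium_is_stationary(self, default_params):
        p = default_params.with_(pressure=0.0)
        state = equilibrium_state(p)
        assert rhs_volume_osmolyte(state, p) == (0.0, 0.0)
        assert rhs_delta_c(state, p) == 0.0

    @given(
        v_scale=st.floats(0.5, 1.5),
        n_scale=st.floats(0.9, 1.1),
        pressure=st.floats(0.0, 2000.0),
        pi=st.floats(1e-7, 5e-5),
        pw=st.floats(2e-4, 1e-2),
    )
    def test_delta_c_equation_equals_chain_rule(self, v_scale, n_scale, pressure, pi, pw):
        # d(N/V)/dt = dN/dt / V - N dV/dt / V^2 must equal the dC-form
        # right-hand side exactly (it is derived from it)
        p = ModelParameters(pressure=pressure, ion_permeability=pi, water_permeability=pw)
        v = p.initial_volume * v_scale
        n = p.external_osmolarity * p.initial_volume * n_scale
        state = CellState(v, n)
        dv, dn = rhs_volume_osmolyte(state, p)
        chain = dn / v - n * dv / v**2
        direct = rhs_delta_c(state, p)
        assert direct == pytest.approx(chain, rel=1e-12, abs=1e-25)

    def test_residual_at_linearized_fixed_point_is_quadratic_small(
        self, default_params
    ):
        # at the linearized quasi-steady dC the remaining drift is the
        # neglected quadratic term rho*Pw*dC*(S-dC)*A/V
        p = default_params
        dc = qss_delta_c(p)
        state = equilibrium_state(p, delta_c0=dc)
        residual = abs(rhs_delta_c(state, p))
        area_over_v = p.initial_area / p.initial_volume
        rho = p.constants.water_molar_volume
        bound = (
            rho * p.water_permeability * abs(dc) * (p.pressure_equivalent + abs(dc))
            * area_over_v * 1.01
        )
        assert residual <= bound
        initial_drift = abs(rhs_delta_c(equilibrium_state(p), p))
        assert residual < 0.01 * initial_drift


class TestIntegrate:
    def test_no_pressure_preserves_state(self, default_params):
        p = default_params.with_(pressure=0.0)
        traj = integrate(p, 3600.0)
        np.testing.assert_allclose(traj.volume, p.initial_volume, rtol=1e-8)
        np.testing.assert_allclose(
            traj.osmolyte, p.external_osmolarity * p.initial_volume, rtol=1e-8
        )

    def test_blocked_channels_converge_to_closed_form(self, default_params):
        p = default_params.with_(ion_permeability=0.0)
        traj = integrate(p, 2.0e5)
        final_fraction = traj.volume[-1] / traj.volume[0]
        assert final_fraction == pytest.approx(equilibrium_blocked(p), abs=1e-6)
        # total water loss ~0.398 % of V0
        assert 1.0 - final_fraction == pytest.approx(0.0039840637, abs=1e-6)
        # osmolyte amount conserved with channels blocked
        np.testing.assert_allclose(traj.osmolyte, traj.osmolyte[0], rtol=1e-9)

    def test_plateau_rate_matches_closed_form(self, default_params):
        rate = plateau_rate_per_hour(default_params)
        expected = qss_relative_rate(default_params)
        assert rate == pytest.approx(expected, rel=0.02)

    def test_positivity_and_monotone_shrinkage(self, param_sampler):
        rng = np.random.default_rng(7)
        for _ in range(5):
            p = param_sampler(rng)
            traj = integrate(p, 1800.0)
            assert np.all(traj.volume > 0)
            assert np.all(traj.osmolyte >= 0)
            assert np.all(np.diff(traj.volume) <= 1e-18)

    def test_deterministic(self, default_params):
        a = integrate(default_params, 1800.0)
        b = integrate(default_params, 1800.0)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.volume, b.volume)
        assert np.array_equal(a.osmolyte, b.osmolyte)

    def test_min_volume_stop_condition(self, default_params):
        traj = integrate(default_params, 10800.0)  # would lose >100 % if unchecked
        assert traj.metadata["stopped_at_min_volume"]
        assert traj.volume[-1] / traj.volume[0] == pytest.approx(0.5, abs=1e-6)
        assert traj.times[-1] < 10800.0

    def test_formulation_equivalence(self, param_sampler):
        # the (V, N) and (V, dC) systems are the same dynamics
        rng = np.random.default_rng(21)
        for _ in range(3):
            p = param_sampler(rng)
            t, v_alt, _ = integrate_delta_c(p, 1200.0)
            traj = integrate(p, 1200.0, t_eval=t)
            v_main = np.interp(t, traj.times, traj.volume)
            np.testing.assert_allclose(v_main, v_alt, rtol=1e-6)

    def test_invalid_horizon_rejected(self, default_params):
        with pytest.raises(ValueError):
            integrate(default_params, 0.0)


class TestEquilibriumBlocked:
    def test_worked_example_fraction(self, default_params):
        assert equilibrium_blocked(default_params) == pytest.approx(
            0.9960159362549801, rel=1e-12
        )

    def test_no_pressure_full_volume(self, default_params):
        assert equilibrium_blocked(default_params.with_(pressure=0.0)) == 1.0

    def test_ignores_ion_permeability(self, default_params):
        assert equilibrium_blocked(default_params) == equilibrium_blocked(
            default_params.with_(ion_permeability=0.0)
        )


class TestDetectQss:
    def test_onset_within_tens_of_seconds_and_plateau_value(self, default_params):
        # linearized relaxation time (r/3)/(Pi + C0*rho*Pw) ~ 12 s
        assert qss_relaxation_time(default_params) == pytest.approx(12.255, abs=0.01)
        traj = integrate(default_params, 1800.0)
        onset, plateau = detect_qss(traj)
        assert 5.0 < onset < 300.0
        # plateau agrees with the linearized closed form to its O(S/C0) error
        assert plateau == pytest.approx(qss_delta_c(default_params), rel=5e-3)

    def test_blocked_channels_plateau_at_pressure(self, default_params):
        p = default_params.with_(ion_permeability=0.0)
        traj = integrate(p, 2.0e5)
        _, plateau = detect_qss(traj)
        assert plateau == pytest.approx(p.pressure_equivalent, rel=1e-3)

    def test_no_plateau_reported_not_defaulted(self, default_params):
        traj = integrate(default_params, 5.0)  # far shorter than relaxation
        with pytest.raises(QssNotReachedError):
            detect_qss(traj, tol=1e-4)

    def test_requires_constant_parameters(self, default_params):
        traj = integrate(
            default_params, 1800.0,
            schedule=Schedule.step(600.0, ion_permeability=0.0),
        )
        with pytest.raises(ValueError, match="constant-parameter"):
            detect_qss(traj)


class TestSchedule:
    def test_validation(self):
        with pytest.raises(ValueError, match="t=0"):
            Schedule(segments=((5.0, {}),))
        with pytest.raises(ValueError, match="strictly increase"):
            Schedule(segments=((0.0, {}), (10.0, {}), (10.0, {})))

    def test_params_at_piecewise_constant(self, default_params):
        sch = Schedule.step(600.0, ion_permeability=0.0)
        assert sch.params_at(0.0, default_params).ion_permeability == 1e-5
        assert sch.params_at(599.9, default_params).ion_permeability == 1e-5
        assert sch.params_at(600.0, default_params).ion_permeability == 0.0

    def test_channel_blockade_halts_shrinkage(self, default_params):
        # block channels mid-run: volume settles at the conserved-osmolyte
        # equilibrium of the state at the blockade time
        t_block = 600.0
        traj = integrate(
            default_params, 3.0e4,
            schedule=Schedule.step(t_block, ion_permeability=0.0),
        )
        i = int(np.searchsorted(traj.times, t_block))
        state = CellState(traj.volume[i], traj.osmolyte[i])
        expected_final = (
            traj.volume[i] / traj.volume[0]
            * equilibrium_blocked(default_params, init=state)
        )
        assert traj.volume[-1] / traj.volume[0] == pytest.approx(
            expected_final, abs=1e-5
        )
        # and it is well above the unblocked outcome at the same horizon
        unblocked = integrate(default_params, 3.0e4)
        assert traj.volume[-1] > unblocked.volume[-1]


class TestSweep:
    def test_rate_proportional_to_pressure(self, default_params):
        table = sweep(default_params, "pressure", [500.0, 1000.0, 2000.0])
        rates = table["qss_rate_per_h"].to_numpy()
        np.testing.assert_allclose(rates / rates[0], [1.0, 2.0, 4.0], rtol=1e-12)
        assert (table["error"] == "").all()

    def test_rate_decreasing_in_osmolarity(self, default_params):
        table = sweep(
            default_params, "external_osmolarity", [1e-4, 2e-4, 3e-4], t_max=900.0
        )
        rates = np.abs(table["ode_rate_per_h"].to_numpy())
        assert np.all(np.diff(rates) < 0)

    def test_rate_approaches_high_pw_limit_from_below(self, default_params):
        table = sweep(
            default_params, "water_permeability", [1e-4, 1e-2, 1.0], t_max=900.0
        )
        limit = abs(qss_relative_rate_high_pw(default_params))
        rates = np.abs(table["qss_rate_per_h"].to_numpy())
        assert np.all(np.diff(rates) > 0)
        assert np.all(rates < limit)
        assert rates[-1] == pytest.approx(limit, rel=1e-2)

    def test_individual_failures_recorded_not_fatal(self, default_params):
        table = sweep(default_params, "pressure", [1000.0, -50.0])
        assert table.loc[0, "error"] == ""
        assert "non-negative" in table.loc[1, "error"]

    def test_unknown_parameter_rejected(self, default_params):
        with pytest.raises(ValueError, match="parameter"):
            sweep(default_params, "temperature", [300.0])
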