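"""Dynamic canopy model: FvCB oracle, relaxation closed forms, limits,
monotonicity and aggregation linearity."""

import numpy as np
import pytest

import npqdyn as nd
from npqdyn.canopy import (
    AcSummary,
    LeafConstants,
    LeafPixelLight,
    LeafState,
    NPQKinetics,
    activation_steady_state,
    npq_steady_state,
    simulate_canopy,
    steady_state_leaf,
    step_dynamics,
)

CONST = LeafConstants()
KIN = NPQKinetics()
INSTANT = NPQKinetics(tau_qe=1e-4, tau_qm=2e-4, tau_qi=3e-4, tau_act=1e-4)


def fvcb_oracle(ppfd, act=1.0):
    """Hand-evaluated FvCB rates (closed form, no shared code path)."""
    c = CONST
    wc = c.vcmax25 * act * (c.ci - c.gamma_star) / (c.ci + c.kco)
    i2 = 0.5 * c.phi_psii_max * ppfd
    b = i2 + c.jmax25
    j = (b - np.sqrt(b * b - 4 * c.theta * i2 * c.jmax25)) / (2 * c.theta)
    wj = j * (c.ci - c.gamma_star) / (4 * c.ci + 8 * c.gamma_star)
    return min(wc, wj) - c.rd


class TestSteadyState:
    def test_darkness_gives_dark_respiration(self):
        a, npq, act = steady_state_leaf(0.0, CONST, KIN)
        assert np.isclose(a, -CONST.rd)
        assert np.isclose(npq, 0.0)

    def test_matches_hand_fvcb_to_1e9(self):
        for ppfd in (50.0, 300.0, 900.0, 2000.0):
            a, _, act = steady_state_leaf(ppfd, CONST, KIN)
            assert np.isclose(a, fvcb_oracle(ppfd, act), atol=1e-9)

    def test_saturating_light_is_rubisco_limited(self):
        big = LeafConstants(jmax25=4000.0)
        a, _, act = steady_state_leaf(5000.0, big, KIN)
        wc = big.vcmax25 * act * (big.ci - big.gamma_star) / (big.ci + big.kco)
        assert np.isclose(a, wc - big.rd, rtol=1e-6)

    def test_npq_scaled_to_amplitude_sum_at_reference(self):
        assert np.isclose(npq_steady_state(2000.0, KIN, CONST), KIN.amplitude_sum)

    def test_nonphysical_constants_rejected(self):
        with pytest.raises(ValueError):
            LeafConstants(gamma_star=300.0, ci=270.0)


class TestStepDynamics:
    def test_constant_light_is_fixed_point(self):
        state = LeafState.at_steady_state(800.0, KIN, CONST)
        new, _ = step_dynamics(state, 800.0, KIN, CONST, dt_s=10.0)
        np.testing.assert_allclose(new.npq_pools, state.npq_pools, atol=1e-12)
        np.testing.assert_allclose(new.act, state.act, atol=1e-12)

    def test_step_down_excess_matches_closed_form(self):
        """After a 2000 -> 50 step, each pool's excess over its new target
        decays as excess0 * exp(-t/tau); the summed excess therefore follows
        the weighted double (plus slow) exponential."""
        kin = KIN
        state = LeafState.at_steady_state(2000.0, kin, CONST)
        target = npq_steady_state(50.0, kin, CONST) * kin.pool_weights()
        excess0 = state.npq_pools - target
        dt, total = 1.0, 600.0
        s = state
        for _ in range(int(total / dt)):
            s, _ = step_dynamics(s, 50.0, kin, CONST, dt_s=dt)
        taus = np.array([kin.tau_qe, kin.tau_qm, kin.tau_qi]) * 60.0
        expected = excess0 * np.exp(-total / taus)
        np.testing.assert_allclose(s.npq_pools - target, expected, atol=1e-6)

    def test_rubisco_deactivation_twice_as_slow(self):
        kin = KIN
        up = LeafState(npq_pools=np.zeros(3), act=np.array(0.4))
        dn = LeafState(npq_pools=np.zeros(3), act=np.array(0.9))
        tgt = activation_steady_state(800.0, CONST)
        up2, _ = step_dynamics(up, 800.0, kin, CONST, dt_s=30.0)
        dn2, _ = step_dynamics(dn, 0.0, kin, CONST, dt_s=30.0)
        lam_up = np.log((0.4 - tgt) / (up2.act - tgt)) / 30.0
        tgt_dn = activation_steady_state(0.0, CONST)
        lam_dn = np.log((0.9 - tgt_dn) / (dn2.act - tgt_dn)) / 30.0
        assert np.isclose(lam_up / lam_dn, 2.0, rtol=1e-9)

    def test_never_exceeds_instantaneous_steady_state(self):
        rng = np.random.default_rng(0)
        state = LeafState.at_steady_state(1500.0, KIN, CONST)
        for _ in range(200):
            ppfd = float(rng.uniform(0, 2000))
            state, a = step_dynamics(state, ppfd, KIN, CONST, dt_s=10.0)
            a_ss, _, _ = steady_state_leaf(ppfd, CONST, KIN)
            assert a <= a_ss + 1e-9


def _pixels(n=8, seed=0, cloudy=True):
    t_s, par = nd.synthetic_day_par(cloudy=cloudy, seed=seed)
    rng = np.random.default_rng(seed)
    pixels = [
        LeafPixelLight(f"p{i}", 1e-5, t_s, par * rng.uniform(0.1, 0.9)) for i in range(n)
    ]
    return pixels


class TestSimulateCanopy:
    def test_constant_light_instant_kinetics_equals_steady_state(self):
        t_s = np.arange(5 * 3600.0, 19 * 3600.0 + 1, 60.0)
        px = [LeafPixelLight("p", 1.0, t_s, np.full(t_s.size, 700.0))]
        sim = simulate_canopy(px, 1.0, INSTANT, CONST)
        a_ss, _, _ = steady_state_leaf(700.0, CONST, INSTANT)
        expect = a_ss * (t_s[-1] - t_s[0]) * 1e-6
        assert np.isclose(sim.daily_mol, expect, rtol=1e-6)

    def test_two_identical_pixels_double_one(self):
        px = _pixels(1)
        one = simulate_canopy(px, 1.0, KIN, CONST)
        two = simulate_canopy(
            px + [LeafPixelLight("p2", px[0].area_m2, px[0].t_s, px[0].ppfd)], 1.0, KIN, CONST
        )
        assert np.isclose(two.daily_mol, 2 * one.daily_mol, rtol=1e-9)

    def test_instant_kinetics_track_steady_state_integral(self):
        px = _pixels(4)
        sim = simulate_canopy(px, 1e-4, INSTANT, CONST, dt_s=5.0)
        # steady-state-tracking reference on the same grid
        tgrid = sim.t_s
        ac = np.zeros_like(tgrid)
        for p in px:
            light = np.interp(tgrid, p.t_s, p.ppfd)
            a = np.array([steady_state_leaf(l, CONST, INSTANT)[0] for l in light])
            ac += a * p.area_m2 / 1e-4
        ref = float(np.trapezoid(ac, tgrid)) * 1e-6
        assert abs(sim.daily_mol - ref) / abs(ref) < 1e-3

    def test_timestep_convergence(self):
        px = _pixels(4)
        a10 = simulate_canopy(px, 1e-4, KIN, CONST, dt_s=10.0)
        a1 = simulate_canopy(px, 1e-4, KIN, CONST, dt_s=1.0)
        assert abs(a10.daily_mol - a1.daily_mol) / abs(a1.daily_mol) < 0.002

    def test_daily_ac_non_increasing_in_relaxation_taus(self):
        px = _pixels(6)
        prev = None
        for scale in (0.25, 0.5, 1.0, 2.0, 4.0):
            kin = NPQKinetics(tau_qe=1.05 * scale, tau_qm=23.51 * scale)
            daily = simulate_canopy(px, 1e-4, kin, CONST).daily_mol
            if prev is not None:
                assert daily <= prev + 1e-9
            prev = daily

    def test_mismatched_pixel_ranges_rejected(self):
        px = _pixels(2)
        short = LeafPixelLight("s", 1e-5, px[0].t_s[:-10], px[0].ppfd[:-10])
        with pytest.raises(ValueError):
            simulate_canopy(px + [short], 1.0, KIN, CONST)


class TestLossReport:
    def test_reference_scenario_has_zero_loss(self):
        px = _pixels(4)
        rep = nd.loss_report({"ref": KIN, "slow": NPQKinetics(tau_qe=2.0, tau_qm=40.0)},
                             {"day": px}, 1e-4, reference="ref")
        ref_rows = rep[rep["scenario"] == "ref"]
        assert np.allclose(ref_rows["loss_pct"], 0.0)

    def test_slower_relaxation_never_gains(self):
        px = _pixels(4)
        rep = nd.loss_report(
            {"fast": NPQKinetics(tau_qe=0.93, tau_qm=19.95), "slow": NPQKinetics(tau_qe=1.29, tau_qm=29.23)},
            {"day": px}, 1e-4, reference="fast",
        )
        assert (rep["loss_pct"] >= -1e-9).all()

    def test_constant_light_day_has_negligible_loss(self):
        t_s = np.arange(5 * 3600.0, 19 * 3600.0 + 1, 60.0)
        px = [LeafPixelLight("p", 1e-5, t_s, np.full(t_s.size, 600.0))]
        rep = nd.loss_report(
            {"fast": NPQKinetics(tau_qe=0.93, tau_qm=19.95), "slow": NPQKinetics(tau_qe=1.29, tau_qm=29.23)},
            {"flat": px}, 1e-5, reference="fast",
        )
        assert rep["loss_pct"].abs().max() < 0.01

    def test_daily_integral_matches_series(self):
        px = _pixels(3)
        sim = simulate_canopy(px, 1e-4, KIN, CONST)
        assert np.isclose(sim.daily_mol, np.trapezoid(sim.ac, sim.t_s) * 1e-6)


class TestLightDrivers:
    def test_cloudy_day_reduces_total_light(self):
        t, clear = nd.synthetic_day_par(cloudy=False)
        t, cloudy = nd.synthetic_day_par(cloudy=True, seed=1)
        assert cloudy.sum() < clear.sum()
        assert (cloudy <= clear + 1e-9).all()

    def test_light_field_seeded_and_positive(self):
        t, par = nd.synthetic_day_par(cloudy=False)
        a, sa = nd.canopy_light_field(t, par, n_pixels=10, seed=3)
        b, sb = nd.canopy_light_field(t, par, n_pixels=10, seed=3)
        assert sa == sb
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.ppfd, pb.ppfd)
            assert (pa.ppfd >= 0).all()
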