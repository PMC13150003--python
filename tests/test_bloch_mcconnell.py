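import math

import numpy as np
import pytest

from r1rho import (
    DipolarPartner,
    ExchangeNetwork,
    SiteState,
    SpinlockSchedule,
    build_generator,
    propagate,
    propagate_trajectory,
    r1rho_from_decay,
    r1rho_from_eigenvalue,
    r2eff_transform,
    simulate_spinlock_experiment,
    tilted_frame_geometry,
)
from conftest import make_two_state, trott_palmer_r1rho


def make_triangular(p_b=0.006, p_c=0.009):
    a = SiteState("WCF", 1 - p_b - p_c, 0.0, 2.5, 22.5)
    b = SiteState("HG", p_b, -593.0, 2.5, 22.5)
    c = SiteState("ES2", p_c, 288.0, 2.5, 22.5)
    return ExchangeNetwork(
        [a, b, c],
        {("WCF", "HG"): 2700.0, ("WCF", "ES2"): 500.0, ("HG", "ES2"): 3200.0},
        topology_tag="triangular",
    )


class TestGeneratorStructure:
    def test_dimensions(self, fig2_network, fig2_partner, tumbling):
        assert build_generator(fig2_network, 1000.0, 0.0).shape == (6, 6)
        L = build_generator(fig2_network, 1000.0, 0.0, partner=fig2_partner, tumbling=tumbling)
        assert L.shape == (12, 12)

    def test_exchange_subblocks_conserve_magnetisation(self):
        net = make_triangular()
        E = net.kinetic_matrix()
        assert np.allclose(E.sum(axis=0), 0.0, atol=1e-12)

    def test_detailed_balance_stationary_populations(self):
        net = make_triangular()
        assert np.allclose(net.kinetic_matrix() @ net.populations, 0.0, atol=1e-9)

    def test_zeroed_cross_relaxation_embeds_exchange_only_dynamics(
        self, fig2_network, fig2_partner, tumbling
    ):
        # with sigma = mu = 0 the observed-spin block evolves exactly as the
        # partner-free system
        taus = np.linspace(0.0, 0.2, 6)
        sched = SpinlockSchedule(500.0, -200.0, tuple(taus))
        alone = simulate_spinlock_experiment(fig2_network, sched)
        embedded = simulate_spinlock_experiment(
            fig2_network, sched, partner=fig2_partner, tumbling=tumbling,
            sigma_scale=0.0, mu_scale=0.0,
        )
        assert np.allclose(alone, embedded, atol=1e-10)

    def test_partner_missing_distance_rejected(self, fig2_network, tumbling):
        partner = DipolarPartner(-600.0, 2.5, 22.5, {"GS": 3.0})
        with pytest.raises(ValueError, match="ES"):
            build_generator(fig2_network, 1000.0, 0.0, partner=partner, tumbling=tumbling)

    def test_network_validation(self):
        gs = SiteState("GS", 0.9, 0.0, 2.5, 22.5)
        es = SiteState("ES", 0.05, 600.0, 2.5, 22.5)
        with pytest.raises(ValueError, match="sum"):
            ExchangeNetwork([gs, es], {("GS", "ES"): 2000.0})
        with pytest.raises(ValueError, match="k_ex"):
            make_two_state(kex=-5.0)


class TestPropagation:
    def test_zero_duration_is_identity(self, fig2_network):
        L = build_generator(fig2_network, 1000.0, 0.0)
        m0 = np.arange(6, dtype=float)
        assert np.allclose(propagate(L, m0, 0.0), m0)

    def test_diagonal_generator_closed_form(self):
        L = np.diag([-22.5, -22.5, -2.5])
        m0 = np.array([1.0, 0.5, 0.25])
        out = propagate(L, m0, 0.1)
        assert np.allclose(out, m0 * np.exp(np.diag(L) * 0.1), rtol=1e-12)

    def test_two_state_exchange_approaches_weighted_average(self):
        # z-only symmetric exchange relaxes the population difference at k_ex
        kex = 800.0
        E = np.array([[-kex / 2, kex / 2], [kex / 2, -kex / 2]])
        m0 = np.array([1.0, 0.0])
        for tau in (1e-4, 1e-3, 5e-3):
            expected = 0.5 + (m0 - 0.5) * math.exp(-kex * tau)
            assert np.allclose(propagate(E, m0, tau), expected, rtol=1e-9)

    def test_thermal_recovery_restores_equilibrium(self, fig2_network):
        # augmented generator: long free evolution returns z magnetisation
        # to the population-weighted equilibrium instead of zero
        aug = build_generator(fig2_network, 1e-6, 1e9, thermal_recovery=True)
        m0 = np.zeros(7)
        m0[-1] = 1.0  # start saturated, only the affine component set
        out = propagate(aug, m0, 10.0)
        assert out[2] == pytest.approx(0.995, rel=1e-6)
        assert out[5] == pytest.approx(0.005, rel=1e-6)

    def test_trajectory_matches_expm(self, fig2_network):
        L = build_generator(fig2_network, 800.0, -300.0)
        m0 = np.ones(6) / 6
        taus = np.array([0.0, 0.01, 0.05, 0.2])
        traj = propagate_trajectory(L, m0, taus)
        for t, row in zip(taus, traj):
            assert np.allclose(row, propagate(L, m0, t), atol=1e-10)


class TestSpinlockExperiment:
    def test_single_state_on_resonance_pure_r2_decay(self):
        lone = ExchangeNetwork([SiteState("GS", 1.0, 0.0, 2.5, 22.5)], {}, "generic")
        taus = np.linspace(0.0, 0.1, 6)
        intens = simulate_spinlock_experiment(lone, SpinlockSchedule(1000.0, 0.0, tuple(taus)))
        assert np.allclose(intens, np.exp(-22.5 * taus), rtol=1e-10)

    def test_far_off_resonance_decays_at_r1(self, fig2_network):
        taus = np.linspace(0.0, 1.0, 8)
        intens = simulate_spinlock_experiment(
            fig2_network, SpinlockSchedule(100.0, 80000.0, tuple(taus))
        )
        assert r1rho_from_decay(intens, taus) == pytest.approx(2.5, rel=2e-3)

    def test_distant_partner_leaves_decay_unchanged(self, fig2_network, tumbling):
        far = DipolarPartner(-600.0, 2.5, 22.5, {"GS": 40.0, "ES": 40.0})
        taus = np.linspace(0.0, 0.06, 8)
        sched = SpinlockSchedule(1000.0, 0.0, tuple(taus))
        with_partner = simulate_spinlock_experiment(
            fig2_network, sched, partner=far, tumbling=tumbling
        )
        without = simulate_spinlock_experiment(fig2_network, sched)
        r_with = r1rho_from_decay(with_partner, taus)
        r_without = r1rho_from_decay(without, taus)
        assert r_with == pytest.approx(r_without, rel=1e-3)


class TestEigenvalueR1rho:
    def test_no_exchange_on_resonance_equals_r2(self):
        net = make_two_state(p_es=0.0)
        assert r1rho_from_eigenvalue(net, 1000.0, 0.0) == pytest.approx(22.5, abs=1e-9)

    def test_far_off_resonance_approaches_r1(self, fig2_network):
        assert r1rho_from_eigenvalue(fig2_network, 100.0, 2e5) == pytest.approx(2.5, rel=1e-3)

    def test_exchange_free_tilted_frame_closed_form(self):
        # R1rho(theta) = R1 cos^2 theta + R2 sin^2 theta; exact on resonance,
        # first-order in (R2 - R1)/omega_eff off resonance (the Bloch
        # eigenvalue carries a second-order relaxation-anisotropy correction)
        net = make_two_state(p_es=0.0)
        assert r1rho_from_eigenvalue(net, 1000.0, 0.0) == pytest.approx(22.5, abs=1e-12)
        for power, carrier in [(250.0, -600.0), (500.0, 300.0), (2000.0, 1500.0)]:
            geom = tilted_frame_geometry(net, power, carrier)
            expected = 2.5 * math.cos(geom.theta) ** 2 + 22.5 * math.sin(geom.theta) ** 2
            assert r1rho_from_eigenvalue(net, power, carrier) == pytest.approx(
                expected, rel=1e-4
            )

    def test_trott_palmer_agreement(self, fig2_network):
        # closed-form oracle within 2% across the spinlock range
        for nu in np.linspace(500.0, 6000.0, 12):
            bm = r1rho_from_eigenvalue(fig2_network, nu, 0.0)
            tp = trott_palmer_r1rho(0.995, 0.005, 600.0, 2000.0, 2.5, 22.5, nu, 0.0)
            assert bm == pytest.approx(tp, rel=0.02)

    def test_rotating_frame_mirror_symmetry(self):
        # flipping the sign of every offset leaves R1rho unchanged
        for carrier in (-450.0, 0.0, 350.0):
            plus = r1rho_from_eigenvalue(make_two_state(dw=600.0), 400.0, carrier)
            minus = r1rho_from_eigenvalue(make_two_state(dw=-600.0), 400.0, -carrier)
            assert plus == pytest.approx(minus, rel=1e-10)

    def test_on_resonance_rex_quenching_monotone(self, fig2_network):
        powers = np.geomspace(200.0, 8000.0, 15)
        values = [r1rho_from_eigenvalue(fig2_network, nu, 0.0) for nu in powers]
        assert np.all(np.diff(values) <= 1e-9)

    def test_decay_rate_matches_eigenvalue_after_transients(self, fig2_network):
        # propagation oracle equivalence (<= 1%) once tau exceeds 3 transient
        # lifetimes (~3 / R2)
        for power, carrier in [(1000.0, 0.0), (250.0, -400.0), (500.0, 700.0)]:
            r_eig = r1rho_from_eigenvalue(fig2_network, power, carrier)
            taus = np.linspace(3.0 / 22.5, 3.0 / 22.5 + 1.5 / r_eig, 8)
            intens = simulate_spinlock_experiment(
                fig2_network, SpinlockSchedule(power, carrier, tuple(taus))
            )
            assert r1rho_from_decay(intens, taus) == pytest.approx(r_eig, rel=0.01)


class TestR2effTransform:
    def test_right_angle_identity(self):
        geom = tilted_frame_geometry(make_two_state(p_es=0.0), 1000.0, 0.0)
        assert geom.theta == pytest.approx(math.pi / 2, abs=1e-6)
        assert r2eff_transform(22.5, 2.5, geom) == pytest.approx(22.5, rel=1e-9)

    def test_r1_fixed_point(self):
        geom = tilted_frame_geometry(make_two_state(p_es=0.0), 300.0, 900.0)
        assert r2eff_transform(2.5, 2.5, geom) == pytest.approx(2.5, rel=1e-12)

    def test_round_trip_identity(self):
        from r1rho import TiltedFrameGeometry
        from r1rho.bloch_mcconnell import r1rho_from_r2eff

        geom = TiltedFrameGeometry(omega_eff=5000.0, theta=0.7)
        r2eff = r2eff_transform(12.0, 2.5, geom)
        assert r1rho_from_r2eff(r2eff, 2.5, geom) == pytest.approx(12.0, abs=1e-12)

    def test_zero_tilt_rejected(self):
        from r1rho import TiltedFrameGeometry

        with pytest.raises(ValueError):
            r2eff_transform(10.0, 2.5, TiltedFrameGeometry(omega_eff=100.0, theta=0.0))


class TestDecayExtraction:
    def test_noiseless_rate(self):
        taus = np.arange(0.0, 0.08, 0.01)
        assert r1rho_from_decay(100.0 * np.exp(-20.0 * taus), taus) == pytest.approx(
            20.0, abs=1e-9
        )

    def test_too_few_durations_rejected(self):
        with pytest.raises(ValueError):
            r1rho_from_decay(np.array([1.0, 0.5]), np.array([0.0, 0.1]))
        with pytest.raises(ValueError):
            r1rho_from_decay(np.array([1.0, 0.5, 0.4]), np.array([0.0, 0.1, 0.1]))
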