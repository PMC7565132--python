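"""Forced penetration: chain forces, cross-link resultants, damage, sweeps."""

import math

import numpy as np
import pytest

from biogel import (
    ChainSpec,
    DamageEvent,
    DamageThresholds,
    DomainError,
    FiniteExtensibilityError,
    Outcome,
    ParticleShape,
    Regime,
    average_chain_force,
    check_damage,
    contributing_chain_stretches,
    crosslink_resultant,
    inverse_langevin,
    rhombus_vertex_angle,
    simulate_penetration,
    trapezoid_angle,
)


def sphere_with_eta(eta_value: float) -> tuple[ParticleShape, float]:
    shape = ParticleShape(rho=1.0, xi=1.0)
    return shape, 2.0 * eta_value  # R = 2*rho*eta for a sphere


def ellipsoid_with_eta(eta_value: float, xi: float) -> tuple[ParticleShape, float]:
    shape = ParticleShape(rho=1.0, xi=xi)
    return shape, eta_value * math.sqrt(2.0 * (xi**2 + 1.0))


class TestContributingChains:
    def test_reference_state(self):
        assert contributing_chain_stretches(1.0) == [(1.0, 4), (1.0, 12)]

    def test_neighbors_idle_pre_collapse(self):
        assert contributing_chain_stretches(2.5) == [(2.5, 4), (1.0, 12)]

    def test_neighbor_stretch_continuous_at_collapse(self):
        below = contributing_chain_stretches(3.0)
        above = contributing_chain_stretches(3.0 + 1e-12)
        assert below[1][0] == pytest.approx(above[1][0], abs=1e-12)

    def test_series_compatibility_post_collapse(self):
        assert contributing_chain_stretches(4.5) == [(4.5, 4), (1.5, 12)]


class TestAverageChainForce:
    def test_reference_state_is_reference_tension(self, soft_chain):
        assert average_chain_force(1.0, soft_chain) == pytest.approx(
            inverse_langevin(0.1), rel=1e-12
        )

    def test_pre_collapse_value(self, soft_chain):
        # 4 contact chains at lam=2 plus 12 neighbors at reference tension
        expected = (4 * inverse_langevin(0.2) + 12 * inverse_langevin(0.1)) / 16
        assert average_chain_force(2.0, soft_chain) == pytest.approx(
            expected, rel=1e-12
        )

    def test_continuous_at_collapse(self, soft_chain):
        assert average_chain_force(3.0 - 1e-10, soft_chain) == pytest.approx(
            average_chain_force(3.0 + 1e-10, soft_chain), abs=1e-8
        )

    def test_slope_jump_at_collapse_matches_closed_form(self, soft_chain):
        # the 12 neighbors switch on at lam=3 with stretch lam/3, adding
        # (12/16)*(kappa/3)*beta'(kappa) to the slope
        kappa = soft_chain.kappa
        h = 1e-6
        left = (
            average_chain_force(3.0, soft_chain)
            - average_chain_force(3.0 - h, soft_chain)
        ) / h
        right = (
            average_chain_force(3.0 + h, soft_chain)
            - average_chain_force(3.0, soft_chain)
        ) / h
        beta_prime = (
            inverse_langevin(kappa + h) - inverse_langevin(kappa - h)
        ) / (2 * h)
        expected_jump = (12 / 16) * (kappa / 3) * beta_prime
        assert expected_jump > 0
        assert right - left == pytest.approx(expected_jump, rel=1e-3)

    def test_monotone_nondecreasing(self, soft_chain):
        lams = np.linspace(1.0, 9.0, 500)
        forces = [average_chain_force(l, soft_chain) for l in lams]
        assert np.all(np.diff(forces) > -1e-15)

    def test_extensibility_error_names_chain_class(self):
        chain = ChainSpec.from_kappa(0.4)  # contact chains lock at lam=2.5
        with pytest.raises(FiniteExtensibilityError, match="contact"):
            average_chain_force(2.6, chain)


def vector_sum_resultant(lam, chain, xi, vertex_angle):
    """Independent oracle: explicit in-plane vector sum at a cross-link.

    Two stretched cell sides with tension beta(kappa*lam) leave the vertex
    along unit vectors separated by the vertex angle; each adjacent
    trapezoid leg (tension: reference pre-collapse, beta(kappa*lam/3)
    after) leaves at the base angle alpha below its own side, i.e. with
    components cos(alpha) along that side and -sin(alpha) along the other.
    """
    alpha = trapezoid_angle(lam, degrees=False)
    f = inverse_langevin(chain.kappa * lam)
    leg_stretch = 1.0 if lam <= 3.0 else lam / 3.0
    f_leg = inverse_langevin(chain.kappa * leg_stretch)
    half = vertex_angle / 2.0
    u1 = np.array([math.cos(half), math.sin(half)])
    u2 = np.array([math.cos(half), -math.sin(half)])
    leg1 = math.cos(alpha) * u1 - math.sin(alpha) * u2
    leg2 = math.cos(alpha) * u2 - math.sin(alpha) * u1
    total = f * (u1 + u2) + f_leg * (leg1 + leg2)
    return float(np.linalg.norm(total))


class TestCrosslinkResultant:
    @pytest.mark.parametrize("xi", [1.0, 2.0, 3.0])
    def test_reference_state_equilibrium(self, soft_chain, xi):
        f1, f2 = crosslink_resultant(1.0, soft_chain, xi)
        assert f1 == pytest.approx(0.0, abs=1e-12)
        assert f2 == pytest.approx(0.0, abs=1e-12)

    def test_ratio_equals_aspect_ratio(self, soft_chain):
        for xi in (2.0, 3.0, 5.0):
            for lam in (1.5, 2.5, 4.0):
                f1, f2 = crosslink_resultant(lam, soft_chain, xi)
                assert f1 / f2 == pytest.approx(xi, rel=1e-12)

    def test_sphere_sites_equal(self, soft_chain):
        f1, f2 = crosslink_resultant(2.0, soft_chain, 1.0)
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_matches_vector_sum_oracle(self, soft_chain):
        for xi in (1.0, 2.0, 3.0):
            gamma = rhombus_vertex_angle(xi, degrees=False)
            for lam in np.linspace(1.0, 6.0, 25):
                f1, f2 = crosslink_resultant(lam, soft_chain, xi)
                assert f1 == pytest.approx(
                    vector_sum_resultant(lam, soft_chain, xi, gamma), abs=1e-10
                )
                assert f2 == pytest.approx(
                    vector_sum_resultant(
                        lam, soft_chain, xi, math.pi - gamma
                    ),
                    abs=1e-10,
                )

    def test_ellipsoid_exceeds_sphere_by_fixed_factor(self, soft_chain):
        # at equal lam and kappa: factor 2*cos(gamma/2)/sqrt(2), ~1.342 at xi=3
        gamma = rhombus_vertex_angle(3.0, degrees=False)
        factor = 2.0 * math.cos(gamma / 2.0) / math.sqrt(2.0)
        assert factor == pytest.approx(1.34164, abs=1e-4)
        for lam in (1.2, 2.0, 3.5, 5.0):
            sphere_f1, _ = crosslink_resultant(lam, soft_chain, 1.0)
            ellip_f1, _ = crosslink_resultant(lam, soft_chain, 3.0)
            assert ellip_f1 > sphere_f1
            assert ellip_f1 / sphere_f1 == pytest.approx(factor, rel=1e-10)

    def test_nondecreasing_along_sweep(self, soft_chain):
        lams = np.linspace(1.0, 9.0, 400)
        f1s = [crosslink_resultant(l, soft_chain, 3.0)[0] for l in lams]
        assert np.all(np.diff(f1s) > -1e-15)


class TestCheckDamage:
    def test_indestructible_by_default(self):
        thresholds = DamageThresholds()
        assert check_damage(1e9, 1e9, thresholds) is None

    def test_single_threshold_crossed(self):
        thresholds = DamageThresholds(f_rup=1.5, f_dis=10.0)
        assert check_damage(2.0, 1.0, thresholds) == DamageEvent.CHAIN_RUPTURE

    def test_larger_relative_exceedance_wins(self):
        thresholds = DamageThresholds(f_rup=1.0, f_dis=1.0)
        assert check_damage(1.5, 2.0, thresholds) == (
            DamageEvent.CROSSLINK_DISSOCIATION
        )
        assert check_damage(2.0, 1.5, thresholds) == DamageEvent.CHAIN_RUPTURE

    def test_tie_goes_to_crosslink_dissociation(self):
        thresholds = DamageThresholds(f_rup=1.0, f_dis=2.0)
        assert check_damage(1.5, 3.0, thresholds) == (
            DamageEvent.CROSSLINK_DISSOCIATION
        )

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(DomainError):
            DamageThresholds(f_rup=0.0)


class TestSimulatePenetration:
    def test_open_mesh_short_circuits_to_spontaneous(self, soft_chain):
        shape, R = sphere_with_eta(1.5)
        trajectory = simulate_penetration(shape, soft_chain, R)
        assert trajectory.outcome == Outcome.SPONTANEOUS
        assert trajectory.records == []

    def test_penetration_at_collapse_for_eta_one_third(self, soft_chain):
        shape, R = sphere_with_eta(1 / 3)
        trajectory = simulate_penetration(shape, soft_chain, R, steps=200)
        assert trajectory.outcome == Outcome.ELASTIC_PENETRATION
        assert trajectory.records[-1].lam == pytest.approx(3.0)
        assert trajectory.records[-1].y_over_rho == pytest.approx(1.0)
        regimes = {r.regime for r in trajectory.records}
        assert Regime.POST_COLLAPSE not in regimes

    def test_stiffened_states_for_eta_one_fifth(self, soft_chain):
        shape, R = sphere_with_eta(1 / 5)
        trajectory = simulate_penetration(shape, soft_chain, R, steps=200)
        assert trajectory.outcome == Outcome.ELASTIC_PENETRATION
        assert trajectory.records[-1].lam == pytest.approx(5.0)
        assert any(r.regime == Regime.POST_COLLAPSE for r in trajectory.records)

    def test_crosslink_dissociation_interrupts_sweep(self, soft_chain):
        shape, R = sphere_with_eta(1 / 4)
        thresholds = DamageThresholds(f_dis=0.2)
        trajectory = simulate_penetration(
            shape, soft_chain, R, thresholds=thresholds, steps=200
        )
        assert trajectory.outcome == Outcome.CROSSLINK_DISSOCIATION
        assert trajectory.records[-1].y_over_rho < 1.0
        assert trajectory.records[-1].damage == DamageEvent.CROSSLINK_DISSOCIATION
        assert all(r.damage is None for r in trajectory.records[:-1])

    def test_jammed_when_chains_lock_first(self):
        stiff_chain = ChainSpec.from_kappa(0.5)  # lam_max = 2 < 1/eta = 4
        shape, R = sphere_with_eta(1 / 4)
        trajectory = simulate_penetration(shape, stiff_chain, R, steps=100)
        assert trajectory.outcome == Outcome.JAMMED
        assert trajectory.records[-1].y_over_rho < 1.0

    def test_lower_threshold_never_delays_damage(self, soft_chain):
        shape, R = sphere_with_eta(1 / 5)
        lam_of_damage = []
        for f_dis in (0.3, 0.6, 1.2):
            trajectory = simulate_penetration(
                shape, soft_chain, R,
                thresholds=DamageThresholds(f_dis=f_dis), steps=300,
            )
            assert trajectory.outcome == Outcome.CROSSLINK_DISSOCIATION
            lam_of_damage.append(trajectory.records[-1].lam)
        assert lam_of_damage == sorted(lam_of_damage)

    def test_unit_aspect_ratio_reproduces_sphere_exactly(self, soft_chain):
        sphere, R_s = sphere_with_eta(1 / 4)
        ellip, R_e = ellipsoid_with_eta(1 / 4, xi=1.0)
        t_sphere = simulate_penetration(sphere, soft_chain, R_s, steps=50)
        t_ellip = simulate_penetration(ellip, soft_chain, R_e, steps=50)
        for a, b in zip(t_sphere.records, t_ellip.records):
            assert a == b

    def test_forces_monotone_with_kink_only_at_collapse(self, soft_chain):
        shape, R = sphere_with_eta(1 / 5)
        trajectory = simulate_penetration(shape, soft_chain, R, steps=400)
        frame = trajectory.to_dataframe()
        assert np.all(np.diff(frame["avg_chain_force"]) > -1e-15)
        assert np.all(np.diff(frame["f_cl_1"]) > -1e-15)
        # slope of the average force changes appreciably only across lam=3
        lams = frame["lambda"].to_numpy()
        slopes = np.diff(frame["avg_chain_force"]) / np.diff(lams)
        jumps = np.abs(np.diff(slopes))
        kink = np.argmax(jumps)
        assert lams[kink + 1] == pytest.approx(3.0, abs=0.05)

    def test_subtract_reference_zeroes_initial_force(self, soft_chain):
        shape, R = sphere_with_eta(1 / 3)
        trajectory = simulate_penetration(
            shape, soft_chain, R, steps=50, subtract_reference=True
        )
        assert trajectory.records[0].avg_chain_force == pytest.approx(0.0, abs=1e-12)

    def test_deterministic(self, soft_chain):
        shape, R = sphere_with_eta(1 / 4)
        a = simulate_penetration(shape, soft_chain, R, steps=100)
        b = simulate_penetration(shape, soft_chain, R, steps=100)
        assert a.records == b.records and a.outcome == b.outcome
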