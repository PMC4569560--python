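import math

import numpy as np
import pytest

from adhesim import fixtures as fx
from adhesim.adhesion import (
    Bond,
    KineticEnvironment,
    LedgerError,
    MoleculeLedger,
    MoleculeSpecies,
    bond_coordinate,
    bond_loads,
    breakage_step,
    conservation_violation,
    correction_factor,
    event_probability,
    expected_new_bonds,
    formation_step,
    koff,
    local_kon,
    molecules_per_face,
)
from adhesim.geometry import gated_face_pairs

UM = 1.0e-6
KB = 1.380649e-23


def boltzmann_exponent(stiffness, strain, temperature):
    """Independent scalar evaluation of stiffness*strain^2 / (2 k_b T)."""
    return stiffness * strain ** 2 / (2 * KB * temperature)


class TestMoleculeAllocation:
    def test_density_times_area(self):
        tc, _ = fx.make_parallel_planes(4, 2.5e-13, 0.05 * UM)
        sp = MoleculeSpecies("ICAM-1", 13.0e12, "tc")
        counts = molecules_per_face(sp, tc)
        np.testing.assert_allclose(counts, 3.25)  # 13e12 * 2.5e-13, fractional

    def test_zero_density(self):
        tc, _ = fx.make_parallel_planes(4, 1e-12, 0.05 * UM)
        counts = molecules_per_face(MoleculeSpecies("X", 0.0, "tc"), tc)
        assert np.all(counts == 0.0)

    def test_total_is_density_times_total_area(self):
        tc, _ = fx.make_parallel_planes(7, 0.7e-12, 0.05 * UM)
        sp = MoleculeSpecies("ICAM-1", 13.0e12, "tc")
        assert molecules_per_face(sp, tc).sum() == pytest.approx(
            13.0e12 * tc.total_area(), rel=1e-12
        )


class TestBondCoordinate:
    @pytest.mark.parametrize(
        "eps_mv,d_face,expected",
        [(1.2 * UM, 1.2 * UM, 0.0), (1.2 * UM, 1.25 * UM, 0.05 * UM), (0.0, 0.3 * UM, 0.3 * UM)],
    )
    def test_offset(self, eps_mv, d_face, expected):
        env = KineticEnvironment(eps_mv=eps_mv)
        assert bond_coordinate(d_face, env) == pytest.approx(expected, abs=1e-18)


class TestKineticRates:
    def test_kon_at_equilibrium_length(self, lfa_icam, env):
        # exponent vanishes: k_on0 * n_avail
        assert local_kon(0.05 * UM, 11.0, lfa_icam, env) == pytest.approx(3.3e4)

    def test_kon_zero_availability(self, lfa_icam, env):
        assert local_kon(0.05 * UM, 0.0, lfa_icam, env) == 0.0

    def test_kon_5nm_strain_factor(self, lfa_icam, env):
        expo = boltzmann_exponent(1.0e-3, 5.0e-9, 310.15)
        ratio = local_kon(0.05 * UM + 5e-9, 1.0, lfa_icam, env) / local_kon(
            0.05 * UM, 1.0, lfa_icam, env
        )
        assert expo == pytest.approx(2.919, rel=1e-3)
        assert ratio == pytest.approx(math.exp(-expo), rel=1e-12)

    def test_kon_gated_outside_twice_lambda(self, lfa_icam, env):
        assert local_kon(0.0, 5.0, lfa_icam, env) == 0.0
        assert local_kon(-0.02 * UM, 5.0, lfa_icam, env) == 0.0
        assert local_kon(0.10 * UM, 5.0, lfa_icam, env) == 0.0
        assert local_kon(0.0999 * UM, 5.0, lfa_icam, env) > 0.0

    def test_kon_monotone_decreasing_in_strain(self, lfa_icam, env):
        strains = np.linspace(0, 0.04 * UM, 10)
        up = [local_kon(0.05 * UM + s, 1.0, lfa_icam, env) for s in strains]
        down = [local_kon(0.05 * UM - s, 1.0, lfa_icam, env) for s in strains]
        assert all(b < a for a, b in zip(up, up[1:]))
        assert all(b < a for a, b in zip(down, down[1:]))

    def test_kon_negative_availability_rejected(self, lfa_icam, env):
        with pytest.raises(LedgerError):
            local_kon(0.05 * UM, -1.0, lfa_icam, env)

    def test_koff_equilibrium_values(self, lfa_icam, mac_icam, env):
        assert koff(0.05 * UM, lfa_icam, env) == pytest.approx(0.3, rel=1e-12)
        assert koff(0.05 * UM, mac_icam, env) == pytest.approx(0.29, rel=1e-12)

    def test_koff_5nm_strain(self, lfa_icam, env):
        expo = boltzmann_exponent(2.0e-3 - 1.0e-3, 5.0e-9, 310.15)
        assert koff(0.05 * UM + 5e-9, lfa_icam, env) == pytest.approx(
            0.3 * math.exp(expo), rel=1e-12
        )
        assert koff(0.05 * UM + 5e-9, lfa_icam, env) == pytest.approx(5.56, rel=1e-2)

    def test_koff_slip_bond_monotone(self, lfa_icam, env):
        strains = np.linspace(0, 0.05 * UM, 8)
        rates = [koff(0.05 * UM + s, lfa_icam, env) for s in strains]
        assert all(b > a for a, b in zip(rates, rates[1:]))

    def test_koff_constant_when_spring_equals_transition(self, env):
        import dataclasses

        p = dataclasses.replace(
            fx.default_bond_types()[0], transition_spring=2.0e-3
        )  # s == s_ts
        for d in (0.01 * UM, 0.05 * UM, 0.2 * UM):
            assert koff(d, p, env) == pytest.approx(0.3, rel=1e-12)


class TestEventProbability:
    def test_limits(self):
        assert event_probability(0.0, 1e-3) == 0.0
        assert event_probability(math.log(2) / 1e-3, 1e-3) == pytest.approx(0.5)
        assert event_probability(1e9, 1e-3) == pytest.approx(1.0)

    def test_monotone_bounded(self):
        probs = [event_probability(r, 1e-3) for r in np.logspace(0, 8, 30)]
        assert all(0.0 <= p <= 1.0 for p in probs)
        assert all(b >= a for a, b in zip(probs, probs[1:]))  # saturates at 1
        assert probs[-1] == pytest.approx(1.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            event_probability(-1.0, 1e-3)


class TestCorrectionFactor:
    def test_single_pair_corrected_to_global(self, lfa_icam, env):
        local = np.array([123.0])
        g_total = 5000.0
        factor = correction_factor(local, g_total, 0.05 * UM, lfa_icam, env)
        assert local[0] * factor == pytest.approx(3000.0 * g_total, rel=1e-12)

    def test_uniform_locals(self, lfa_icam, env):
        local = np.full(6, 42.0)
        factor = correction_factor(local, 10.0, 0.05 * UM, lfa_icam, env)
        assert factor == pytest.approx(3000.0 * 10.0 / 42.0, rel=1e-12)

    def test_mean_corrected_equals_global(self, lfa_icam, env, rng):
        local = rng.uniform(10.0, 1e4, 50)
        local[rng.random(50) < 0.3] = 0.0  # ungated entries excluded from the mean
        g_total = 321.0
        factor = correction_factor(local, g_total, 0.06 * UM, lfa_icam, env)
        corrected = local * factor
        kon_global = 3000.0 * g_total * math.exp(
            -boltzmann_exponent(1.0e-3, 0.01 * UM, 310.15)
        )
        assert corrected[local > 0].mean() == pytest.approx(kon_global, rel=1e-12)

    def test_underflow_forces_unity(self, lfa_icam, env, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="adhesim.adhesion"):
            factor = correction_factor(
                np.array([5.0]), 1e6, 8.0 * UM, lfa_icam, env
            )
        assert factor == 1.0
        assert any("forced to 1" in r.message for r in caplog.records)


def planar_setup(tc_per_face, pmn_per_face, n=8, species=("LFA-1",), gap=0.05 * UM):
    tc_faces, pmn_faces = fx.make_parallel_planes(n, 1e-12, gap)
    tc_ledger = fx.uniform_ledger(tc_faces, ["ICAM-1"], tc_per_face)
    pmn_ledger = fx.uniform_ledger(pmn_faces, list(species), pmn_per_face)
    bond_types = [bt for bt in fx.default_bond_types() if bt.pmn_species in species]
    return tc_faces, pmn_faces, tc_ledger, pmn_ledger, bond_types


class TestFormationStep:
    def test_partner_limited_forced(self, env, rng):
        tc_f, pmn_f, tcl, pml, bts = planar_setup(3.0, 2.0, n=1)
        pairs = gated_face_pairs(tc_f, pmn_f, 0.1 * UM)
        bonds = formation_step(pairs, tcl, pml, bts, env, rng, forced_probability=1.0)
        assert len(bonds) == 2  # PMN face holds only 2 molecules
        assert tcl.get(0, "ICAM-1") == pytest.approx(1.0)
        assert pml.get(0, "LFA-1") == pytest.approx(0.0)

    def test_fractional_molecule_rule_mean(self, env):
        # 8.3 molecules at P=1: 8 certain bonds + Bernoulli(0.3)
        counts = []
        for seed in range(2000):
            tc_f, pmn_f, tcl, pml, bts = planar_setup(8.3, 1000.0, n=1)
            pairs = gated_face_pairs(tc_f, pmn_f, 0.1 * UM)
            rng = np.random.default_rng(seed)
            counts.append(
                len(formation_step(pairs, tcl, pml, bts, env, rng, forced_probability=1.0))
            )
        counts = np.asarray(counts, dtype=float)
        se = math.sqrt(0.3 * 0.7 / len(counts))
        assert counts.min() >= 8 and counts.max() <= 9
        assert counts.mean() == pytest.approx(8.3, abs=3 * se)

    def test_zero_rates_no_bonds(self, env, rng):
        tc_f, pmn_f, tcl, pml, bts = planar_setup(5.0, 5.0, gap=0.5 * UM)  # outside gate
        pairs = gated_face_pairs(tc_f, pmn_f, 1.0 * UM)
        before = tcl.available.copy()
        bonds = formation_step(pairs, tcl, pml, bts, env, rng)
        assert bonds == []
        np.testing.assert_array_equal(tcl.available, before)

    def test_no_double_booking_across_species(self, env, rng):
        # 1 ICAM per TC face, both integrin types present and forced:
        # total bonds cannot exceed the ICAM budget
        tc_f, pmn_f, tcl, pml, bts = planar_setup(
            1.0, 100.0, species=("LFA-1", "Mac-1")
        )
        pairs = gated_face_pairs(tc_f, pmn_f, 0.1 * UM)
        bonds = formation_step(pairs, tcl, pml, bts, env, rng, forced_probability=1.0)
        assert len(bonds) == 8
        assert all(b.bond_type == "LFA-1-ICAM-1" for b in bonds)  # first loop wins
        assert np.all(tcl.column("ICAM-1") == 0.0)

    def test_expected_count_matches_monte_carlo(self, env):
        """One-step mean over seeds within 3 SE of the closed-form sum n*P."""
        import dataclasses

        counts = []
        tc_f, pmn_f, tcl0, pml0, bts = planar_setup(8.3, 1.0e5)
        # moderate per-draw probability with an effectively unlimited partner
        # pool (depletion ~1e-4), so the no-depletion expectation is exact
        bts = [dataclasses.replace(bts[0], kon0=1.0e-3)]
        pairs = gated_face_pairs(tc_f, pmn_f, 0.1 * UM)
        expected = expected_new_bonds(pairs, tcl0, pml0, bts, env)
        assert 0.02 < expected / (8 * 8.3) < 0.5  # genuinely stochastic regime
        for seed in range(300):
            _, _, tcl, pml, _ = planar_setup(8.3, 1.0e5)
            rng = np.random.default_rng(seed)
            counts.append(len(formation_step(pairs, tcl, pml, bts, env, rng)))
        counts = np.asarray(counts, dtype=float)
        se = counts.std(ddof=1) / math.sqrt(len(counts))
        assert counts.mean() == pytest.approx(expected, abs=3 * se)


class TestBreakageStep:
    def test_zero_rate_all_survive(self, env, rng):
        import dataclasses

        tc_f, pmn_f, tcl, pml, bts = planar_setup(5.0, 5.0)
        no_break = [dataclasses.replace(bts[0], koff0=1e-300)]
        bonds = [Bond(i, i, no_break[0].name, 0.0) for i in range(8)]
        survivors, broken = breakage_step(
            bonds, tc_f, pmn_f, tcl, pml, no_break, env, rng
        )
        assert len(survivors) == 8 and broken == []

    def test_binomial_survival(self, env):
        """1000 bonds at fixed strain with P=0.25 leave ~750 survivors."""
        import dataclasses

        tc_f, pmn_f, tcl, pml, bts = planar_setup(2000.0, 2000.0, n=1)
        # choose koff so that P = 1 - exp(-koff dt) = 0.25 at zero strain
        koff0 = -math.log(0.75) / env.dt
        bt = dataclasses.replace(bts[0], koff0=koff0)
        totals = []
        for seed in range(40):
            bonds = [Bond(0, 0, bt.name, 0.0) for _ in range(1000)]
            survivors, _ = breakage_step(
                bonds, tc_f, pmn_f, tcl, pml, [bt], env, np.random.default_rng(seed)
            )
            totals.append(len(survivors))
        mean = np.mean(totals)
        se = math.sqrt(1000 * 0.25 * 0.75) / math.sqrt(len(totals))
        assert mean == pytest.approx(750.0, abs=3 * se)

    def test_break_reform_conservation(self, env):
        tc_f, pmn_f, tcl, pml, bts = planar_setup(8.3, 6.7)
        pairs = gated_face_pairs(tc_f, pmn_f, 0.1 * UM)
        rng = np.random.default_rng(7)
        bonds = []
        for step in range(50):
            bonds, _ = breakage_step(bonds, tc_f, pmn_f, tcl, pml, bts, env, rng)
            bonds += formation_step(
                pairs, tcl, pml, bts, env, rng, forced_probability=0.4
            )
            assert conservation_violation(tcl, pml, bonds, bts) < 1e-9


class TestBondLoads:
    def test_zero_force_at_equilibrium_length(self, env):
        tc_f, pmn_f, tcl, pml, bts = planar_setup(1.0, 1.0, n=1, gap=0.05 * UM)
        bonds = [Bond(0, 0, bts[0].name, 0.0)]
        tc_load, pmn_load = bond_loads(bonds, tc_f, pmn_f, bts, env)
        np.testing.assert_allclose(tc_load.force, 0.0, atol=1e-20)

    def test_tensile_magnitude_50nm(self, env):
        # s * (d_kin - lambda) with s = 2e-3 N/m and 50 nm stretch -> 1e-10 N
        tc_f, pmn_f, tcl, pml, bts = planar_setup(1.0, 1.0, n=1, gap=0.1 * UM)
        bonds = [Bond(0, 0, bts[0].name, 0.0)]
        tc_load, pmn_load = bond_loads(bonds, tc_f, pmn_f, bts, env)
        assert np.linalg.norm(tc_load.force) == pytest.approx(1.0e-10, rel=1e-9)
        # tensile: pulls the TC (at y=gap) toward the PMN (at y=0)
        assert tc_load.force[1] < 0.0
        np.testing.assert_allclose(pmn_load.force, -tc_load.force)

    def test_mirror_symmetric_bonds_cancel_torque(self, env):
        tc_f, pmn_f, tcl, pml, bts = planar_setup(1.0, 1.0, n=3, gap=0.08 * UM)
        bonds = [Bond(0, 0, bts[0].name, 0.0), Bond(2, 2, bts[0].name, 0.0)]
        tc_load, _ = bond_loads(bonds, tc_f, pmn_f, bts, env)
        np.testing.assert_allclose(tc_load.torque, 0.0, atol=1e-25)


class TestLedger:
    def test_underflow_guard(self):
        ledger = MoleculeLedger(np.array([0]), ["A"], np.array([[0.5]]))
        with pytest.raises(LedgerError):
            ledger.take(0, "A", 1.0)

    def test_negative_initial_rejected(self):
        with pytest.raises(LedgerError):
            MoleculeLedger(np.array([0]), ["A"], np.array([[-1.0]]))
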