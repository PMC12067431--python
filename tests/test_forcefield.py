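"""Potential functions and the pairwise force kernel."""

import math

import numpy as np
import pytest

from dendrisurf.forcefield import (
    RC_WCA,
    BondOverstretchError,
    ForceFieldParams,
    build_pair_lists,
    compute_forces,
    coulomb_energy,
    evaluate,
    fene_energy,
    lj_ts_energy,
)
from tests.conftest import make_gas


def u_lj(r, eps=1.0):
    return 4.0 * eps * (r**-12 - r**-6)


class TestLennardJones:
    def test_zero_at_and_beyond_cutoff(self):
        assert lj_ts_energy(2.5, 1.0, 2.5) == 0.0
        assert lj_ts_energy(3.0, 1.0, 2.5) == 0.0

    def test_shifted_minimum_value(self):
        # at the LJ minimum r = 2^(1/6) the well depth is -eps, raised by
        # the shift -U_LJ(rc)
        expected = -1.0 - u_lj(2.5)
        assert lj_ts_energy(RC_WCA, 1.0, 2.5) == pytest.approx(expected)

    def test_wca_variant_is_repulsive(self):
        assert lj_ts_energy(1.2, 1.0, RC_WCA) == 0.0
        rs = np.linspace(0.85, 1.3, 50)
        vals = [lj_ts_energy(r, 1.0, RC_WCA) for r in rs]
        assert all(v >= 0.0 for v in vals)
        assert lj_ts_energy(RC_WCA - 1e-9, 1.0, RC_WCA) == pytest.approx(0.0, abs=1e-6)

    def test_continuity_at_cutoff(self):
        for delta in (1e-3, 1e-5, 1e-7):
            assert abs(lj_ts_energy(2.5 - delta, 1.5, 2.5)) < 10 * delta

    def test_diverges_at_zero(self):
        with pytest.raises(ValueError):
            lj_ts_energy(0.0, 1.0, 2.5)


class TestFene:
    def test_zero_at_origin(self):
        assert fene_energy(0.0) == 0.0

    def test_hand_evaluated_value(self):
        expected = -33.75 * math.log(1.0 - 1.0 / 2.25)
        assert fene_energy(1.0, 30.0, 1.5) == pytest.approx(expected)

    def test_monotonically_increasing(self):
        rs = np.linspace(0.0, 1.49, 200)
        vals = [fene_energy(r) for r in rs]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_domain_error_at_maximum_extension(self):
        with pytest.raises(BondOverstretchError):
            fene_energy(1.5, 30.0, 1.5)


class TestCoulomb:
    @pytest.mark.parametrize(
        "r,zi,zj,expected",
        [(1.0, 1, 1, 1.0), (2.0, 1, -1, -0.5), (1.0, 0, 1, 0.0)],
    )
    def test_pair_energies(self, r, zi, zj, expected):
        assert coulomb_energy(r, zi, zj, 1.0) == pytest.approx(expected)

    def test_diverges_at_zero(self):
        with pytest.raises(ValueError):
            coulomb_energy(0.0, 1, 1)


class TestKernel:
    def test_matches_scalar_potentials_on_a_triangle(self):
        """Kernel energy equals the sum of the scalar pair potentials on a
        hand-built three-bead configuration with one bond."""
        from dendrisurf.topology import Frame, MolecularSystem, Species

        L = 50.0
        pos = np.array([[10.0, 10, 10], [11.1, 10, 10], [10.0, 11.3, 10]])
        system = MolecularSystem(
            species=np.array(
                [Species.SURFACTANT_HEAD, Species.SURFACTANT_COUNTERION,
                 Species.DENDRIMER_INTERIOR],
                dtype=np.int8,
            ),
            charge=np.array([-1, 1, 0], dtype=np.int8),
            bonds=np.array([[0, 2]], dtype=np.int64),
            molecule_id=np.zeros(3, dtype=np.int64),
            dendrimer_id=np.full(3, -1, dtype=np.int64),
            n_d=0, n_s=0, N_t=0, N_d=0,
        )
        params = ForceFieldParams(rc_coul=10.0)
        is_tail = np.zeros(3, dtype=np.uint8)
        e, f = compute_forces(pos, L, is_tail, system.charge, system.bonds, params)
        d01 = 1.1
        d02 = 1.3
        d12 = math.hypot(1.1, 1.3)
        expected = (
            lj_ts_energy(d01, 1.0, RC_WCA)
            + lj_ts_energy(d02, 1.0, RC_WCA)
            + lj_ts_energy(d12, 1.0, RC_WCA)
            + coulomb_energy(d01, -1, 1)
            + coulomb_energy(d12, 0, 1)
            + fene_energy(d02)
        )
        assert e == pytest.approx(expected, rel=1e-12)

    def test_forces_are_negative_energy_gradient(self, rng):
        """Central-difference check to 1e-6 relative accuracy on a random
        mixed configuration with bonds and charges."""
        system, frame = make_gas(30, 9.0, seed=3, charged=10)
        bonds = np.array([[20, 21], [22, 23]], dtype=np.int64)
        # pull bonded beads to sensible bond lengths
        pos = frame.positions.copy()
        for i, j in bonds:
            pos[j] = pos[i] + np.array([0.97, 0, 0])
        params = ForceFieldParams(eps_tt=1.5, rc_coul=4.0)
        is_tail = np.zeros(30, dtype=np.uint8)
        is_tail[5:15] = 1
        _, forces = compute_forces(pos, 9.0, is_tail, system.charge, bonds, params)
        h = 1e-5
        fmax = np.abs(forces).max()
        for bead in [0, 7, 20, 23]:
            for axis in range(3):
                for sign, store in ((1, "up"), (-1, "down")):
                    p = pos.copy()
                    p[bead, axis] += sign * h
                    e, _ = compute_forces(p, 9.0, is_tail, system.charge, bonds, params)
                    if sign == 1:
                        e_up = e
                    else:
                        e_dn = e
                numeric = -(e_up - e_dn) / (2 * h)
                assert numeric == pytest.approx(
                    forces[bead, axis], rel=1e-6, abs=1e-6 * fmax
                )

    def test_newtons_third_law(self, rng):
        system, frame = make_gas(40, 10.0, seed=4, charged=12)
        params = ForceFieldParams(rc_coul=5.0)
        is_tail = np.zeros(40, dtype=np.uint8)
        _, forces = compute_forces(
            frame.positions, 10.0, is_tail, system.charge,
            np.empty((0, 2), np.int64), params,
        )
        assert np.allclose(forces.sum(axis=0), 0.0, atol=1e-10)

    def test_skinned_lists_reproduce_fresh_lists(self):
        system, frame = make_gas(40, 10.0, seed=5, charged=8)
        params = ForceFieldParams(rc_coul=4.0)
        is_tail = np.zeros(40, dtype=np.uint8)
        bonds = np.empty((0, 2), np.int64)
        lists = build_pair_lists(frame.positions, 10.0, system.charge, params, skin=0.5)
        # displace every bead by less than skin/2
        rng = np.random.default_rng(0)
        pos = np.mod(frame.positions + rng.uniform(-0.1, 0.1, (40, 3)), 10.0)
        e_list, f_list = evaluate(pos, 10.0, is_tail, system.charge, bonds, params, lists)
        e_ref, f_ref = compute_forces(pos, 10.0, is_tail, system.charge, bonds, params)
        assert e_list == pytest.approx(e_ref, rel=1e-12)
        assert np.allclose(f_list, f_ref, rtol=1e-12, atol=1e-12)
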