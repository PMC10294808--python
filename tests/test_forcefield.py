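import math

import numpy as np
import pytest
from scipy.special import erf

from ldhsim import forcefield as ff
from ldhsim.structure import Framework, GuestMolecule, UnitCell
from ldhsim.units import COULOMB_EV, COULOMB_KCAL


class TestMixing:
    def test_self_mixing_identity(self):
        t = ff.uff_table()["O_3"]
        p = ff.mix_lorentz_berthelot(t, t)
        assert p.sigma == pytest.approx(t.sigma)
        assert p.epsilon == pytest.approx(t.D_i)

    def test_symmetry(self):
        tab = ff.uff_table()
        for a, b in [("C_3", "O_3"), ("H_", "Mg3+2"), ("Fe3+2", "N_3")]:
            p1 = ff.mix_lorentz_berthelot(tab[a], tab[b])
            p2 = ff.mix_lorentz_berthelot(tab[b], tab[a])
            assert p1.sigma == p2.sigma and p1.epsilon == p2.epsilon

    def test_carbon_oxygen_hand_arithmetic(self):
        # sigma_i = x_i / 2^(1/6); arithmetic/geometric means from the table
        tab = ff.uff_table()
        p = ff.mix_lorentz_berthelot(tab["C_3"], tab["O_3"])
        sixth = 2 ** (1 / 6)
        assert p.sigma == pytest.approx(0.5 * (3.851 / sixth + 3.500 / sixth), abs=1e-12)
        assert p.epsilon == pytest.approx(math.sqrt(0.105 * 0.060), abs=1e-12)

    def test_unknown_element_named_in_error(self):
        with pytest.raises(KeyError, match="Zz"):
            ff.uff_for_element("Zz")


def _shielded(r, J1, J2):
    """Independent oracle for the Gaussian-shielded pair coupling (eV)."""
    s1 = COULOMB_EV / (J1 * math.sqrt(math.pi))
    s2 = COULOMB_EV / (J2 * math.sqrt(math.pi))
    return COULOMB_EV * erf(r / math.sqrt(2 * (s1**2 + s2**2))) / r


class TestEqeq:
    def test_single_neutral_atom(self):
        assert ff.eqeq_charges(["C"], [[0, 0, 0]], 0.0) == pytest.approx([0.0])

    def test_single_atom_carries_total(self):
        assert ff.eqeq_charges(["Na"], [[0, 0, 0]], 1.0) == pytest.approx([1.0])

    def test_homonuclear_pair_zero(self):
        q = ff.eqeq_charges(["O", "O"], [[0, 0, 0], [1.3, 0, 0]], 0.0)
        assert np.allclose(q, 0.0, atol=1e-12)

    @pytest.mark.parametrize("r", [0.96, 1.5, 3.0])
    def test_two_site_closed_form(self, r):
        # stationarity of chi1 q + chi2(-q) + (J1+J2)/2 q^2 - J12 q^2
        tab = ff.eqeq_table()
        chi1, J1 = tab["O"]
        chi2, J2 = tab["H"]
        J12 = _shielded(r, J1, J2)
        expect = (chi2 - chi1) / (J1 + J2 - 2 * J12)
        q = ff.eqeq_charges(["O", "H"], [[0, 0, 0], [r, 0, 0]], 0.0)
        assert q[0] == pytest.approx(expect, rel=1e-10)
        assert q.sum() == pytest.approx(0.0, abs=1e-12)

    def test_sum_constraint_and_site_symmetry(self, rng):
        coords = np.array(
            [[0, 0, 0], [1.0, 0, 0], [-1.0, 0, 0], [0, 1.6, 0]], dtype=float
        )
        q = ff.eqeq_charges(["C", "O", "O", "H"], coords, -1.0)
        assert q.sum() == pytest.approx(-1.0, abs=1e-9)
        # the two O sites are mirror images: identical charges
        assert q[1] == pytest.approx(q[2], abs=1e-10)

    def test_periodic_charges_deterministic(self):
        cell = UnitCell(10, 10, 10)
        coords = np.array([[0, 0, 0], [2.0, 0, 0]])
        q1 = ff.eqeq_charges(["Na", "Cl"], coords, 0.0, cell=cell.matrix)
        q2 = ff.eqeq_charges(["Na", "Cl"], coords, 0.0, cell=cell.matrix)
        assert np.array_equal(q1, q2)
        assert q1[0] > 0 > q1[1]


class TestLJ:
    def test_analytic_roots(self):
        t = ff.uff_table()["O_3"]
        sigma, eps = t.sigma, t.D_i
        e_at_sigma = ff.lj_energy([[0, 0, 0], [sigma, 0, 0]], ["O", "O"])
        assert e_at_sigma == pytest.approx(0.0, abs=1e-12)
        rmin = 2 ** (1 / 6) * sigma
        e_min = ff.lj_energy([[0, 0, 0], [rmin, 0, 0]], ["O", "O"])
        assert e_min == pytest.approx(-eps, rel=1e-12)

    def test_truncation_beyond_cutoff(self):
        assert ff.lj_energy([[0, 0, 0], [12.6, 0, 0]], ["O", "O"]) == 0.0

    def test_kernel_matches_reference_on_random_box(self, rng):
        # independent route: the numba simulation kernel vs the vectorised
        # reference on 50 atoms in a periodic box
        from ldhsim import _kernels as K

        cell = UnitCell(26.0, 26.0, 26.0)
        xyz = rng.random((50, 3)) * 26.0
        els = ["C", "O", "H", "N", "S"] * 10
        ref = ff.lj_energy(xyz, els, cell.matrix, cutoff=12.5)
        tab = ff.uff_table()
        sig = np.array([tab[ff.DEFAULT_UFF_LABEL[e]].sigma for e in els])
        eps = np.array([tab[ff.DEFAULT_UFF_LABEL[e]].D_i for e in els])
        zeros = np.zeros(50)
        half = 25
        e_ab = K.env_energy(
            xyz[:half], zeros[:half], sig[:half], eps[:half],
            xyz[half:], zeros[half:], sig[half:], eps[half:],
            26.0, 0.0, 26.0, 26.0, 12.5, 0.3, COULOMB_KCAL,
        )[0]
        e_aa = ff.lj_energy(xyz[:half], els[:half], cell.matrix, 12.5)
        e_bb = ff.lj_energy(xyz[half:], els[half:], cell.matrix, 12.5)
        assert e_ab == pytest.approx(ref - e_aa - e_bb, rel=1e-10)

    def test_small_cell_rejected(self):
        with pytest.raises(ValueError, match="minimum image"):
            ff.lj_energy([[0, 0, 0], [3, 0, 0]], ["O", "O"], UnitCell(10, 10, 10).matrix)


def rocksalt(a=5.0):
    cell = np.eye(3) * a
    frac = np.array(
        [
            [0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5],
            [0.5, 0, 0], [0, 0.5, 0], [0, 0, 0.5], [0.5, 0.5, 0.5],
        ]
    )
    q = np.array([1.0, 1, 1, 1, -1, -1, -1, -1])
    return frac @ cell, q, cell


def madelung_direct_sum(nmax=8):
    """Evjen-weighted direct lattice sum for the rock-salt Madelung
    constant — independent of the Ewald machinery."""
    total = 0.0
    for i in range(-nmax, nmax + 1):
        for j in range(-nmax, nmax + 1):
            for k in range(-nmax, nmax + 1):
                if i == j == k == 0:
                    continue
                w = 1.0
                for t in (i, j, k):
                    if abs(t) == nmax:
                        w *= 0.5
                total += w * (-1.0) ** (i + j + k) / math.sqrt(i * i + j * j + k * k)
    return -total


class TestEwald:
    def test_zero_charges(self):
        xyz, _, cell = rocksalt()
        e = ff.ewald_energy(xyz, np.zeros(8), cell)
        assert e.total == 0.0

    def test_madelung_vs_direct_sum_oracle(self):
        xyz, q, cell = rocksalt(5.0)
        params = ff.EwaldParams.from_accuracy(1e-7, r_cut=2.49)
        e = ff.ewald_energy(xyz, q, cell, params)
        M_ewald = -e.total * 2.5 / (4 * COULOMB_KCAL)
        M_direct = madelung_direct_sum(10)
        assert M_ewald == pytest.approx(M_direct, abs=1e-4)
        assert M_ewald == pytest.approx(1.747565, abs=1e-4)

    def test_alpha_independence(self):
        xyz, q, cell = rocksalt(5.0)
        vals = [
            ff.ewald_energy(
                xyz, q, cell, ff.EwaldParams.from_accuracy(1e-6, 2.49, alpha_scale=s)
            ).total
            for s in (0.8, 1.0, 1.2)
        ]
        spread = (max(vals) - min(vals)) / abs(np.mean(vals))
        assert spread < 1e-6

    def test_translation_invariance(self, rng):
        xyz, q, cell = rocksalt(5.0)
        e0 = ff.ewald_energy(xyz, q, cell).total
        e1 = ff.ewald_energy(xyz + rng.random(3) * 3, q, cell).total
        assert e1 == pytest.approx(e0, rel=1e-9)

    def test_relabeling_invariance(self, rng):
        xyz, q, cell = rocksalt(5.0)
        perm = rng.permutation(8)
        e0 = ff.ewald_energy(xyz, q, cell).total
        e1 = ff.ewald_energy(xyz[perm], q[perm], cell).total
        assert e1 == pytest.approx(e0, rel=1e-12)

    def test_non_neutral_rejected(self):
        xyz, q, cell = rocksalt()
        with pytest.raises(ValueError, match="non-neutral"):
            ff.ewald_energy(xyz, np.abs(q), cell)

    def test_breakdown_sums_to_total(self):
        xyz, q, cell = rocksalt()
        e = ff.ewald_energy(xyz, q, cell)
        assert e.total == pytest.approx(
            e.coul_real + e.coul_recip + e.coul_self, rel=1e-14
        )


def _guest(seed, net=0.0, n=4, center=(13.0, 13.0, 13.0)):
    r = np.random.default_rng(seed)
    local = r.normal(0, 1.0, (n, 3))
    local -= local.mean(axis=0)
    q = r.normal(0, 0.2, n)
    q += (net - q.sum()) / n
    return GuestMolecule(
        f"g{seed}", ["C", "O", "H", "N"][:n], local, q, net, center=np.array(center, float)
    )


class TestTotalEnergy:
    cell = UnitCell(26, 26, 26)

    def _framework(self, rng, n=10):
        frac = rng.random((n, 3))
        q = rng.normal(0, 0.3, n)
        q -= q.mean()
        return Framework(self.cell, frac, ["O", "Mg", "H", "C", "N"] * 2, q)

    def test_no_guests_zero(self, rng):
        fw = self._framework(rng)
        assert ff.total_energy(fw, []).total == 0.0

    def test_ghost_guest_zero(self, rng):
        fw = self._framework(rng)
        ghost = GuestMolecule("ghost", ["X"], [[0.0, 0.0, 0.0]], [0.0], 0.0,
                              center=np.array([5.0, 5, 5]))
        e = ff.total_energy(fw, [ghost])
        assert e.total == pytest.approx(0.0, abs=1e-10)

    def test_two_guest_decomposition(self, rng):
        fw = self._framework(rng)
        g1 = _guest(1, center=(6.0, 6, 6))
        g2 = _guest(2, center=(18.0, 18, 18))
        empty = Framework(self.cell, np.zeros((0, 3)), [])
        params = ff.EwaldParams.from_accuracy(1e-6, 12.5)

        def T(f, gs):
            return ff.total_energy(f, gs, ewald_params=params).total

        pair_term = T(empty, [g1, g2]) - T(empty, [g1]) - T(empty, [g2])
        lhs = T(fw, [g1, g2])
        rhs = T(fw, [g1]) + T(fw, [g2]) + pair_term
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)

    def test_untyped_atom_named(self, rng):
        fw = self._framework(rng)
        fw.elements[3] = "Qq"
        with pytest.raises(KeyError, match="Qq"):
            ff.total_energy(fw, [_guest(1)])

    def test_rigid_translation_invariance(self, rng):
        fw = self._framework(rng)
        g = _guest(3, center=(6.0, 6, 6))
        e0 = ff.total_energy(fw, [g]).total
        shift = rng.random(3) * 4
        fw2 = Framework(
            self.cell,
            (fw.cartesian_coords + shift) @ np.linalg.inv(self.cell.matrix),
            fw.elements,
            fw.charges,
        )
        g2 = g.with_pose(center=g.center + shift)
        e1 = ff.total_energy(fw2, [g2]).total
        assert e1 == pytest.approx(e0, rel=1e-9)
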