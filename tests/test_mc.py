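import math

import numpy as np
import pytest

from ldhsim import forcefield as ff
from ldhsim import mc
from ldhsim import synthetic as syn
from ldhsim.structure import Framework, GuestMolecule, UnitCell
from ldhsim.units import KB_KCAL


def box(a=26.0):
    return Framework(UnitCell(a, a, a), np.zeros((0, 3)), [])


def atom_guest(element="S", charge=0.0, center=(13.0, 13.0, 13.0), name=None):
    return GuestMolecule(
        name or element,
        [element],
        np.zeros((1, 3)),
        np.array([charge]),
        charge,
        center=np.array(center, float),
    )


def lj_fluid_system(n=8, a=26.0, seed=0):
    rng = np.random.default_rng(seed)
    guests = [
        atom_guest("S", center=rng.random(3) * a, name=f"S{i}") for i in range(n)
    ]
    return mc.System(box(a), guests)


class TestParams:
    def test_production_defaults(self):
        p = mc.MCParams()
        assert p.temperature == 300.0
        assert p.n_equilibration == 20_000_000
        assert p.n_production == 10_000_000

    def test_scaled_down_preset(self):
        p = mc.MCParams.scaled_down(seed=7)
        assert (p.n_equilibration, p.n_production) == (100_000, 100_000)
        assert p.seed == 7

    def test_validation(self):
        with pytest.raises(ValueError):
            mc.MCParams(temperature=-5)
        with pytest.raises(ValueError):
            mc.MCParams(n_production=-1)


class TestMetropolisRule:
    def test_downhill_always_accepted(self):
        # two LJ atoms far up the repulsive wall: almost every move that
        # increases separation is downhill and must be accepted
        g1 = atom_guest("S", center=(10.0, 13, 13))
        g2 = atom_guest("S", center=(13.0, 13, 13))
        system = mc.System(box(), [g1, g2])
        params = mc.MCParams(seed=3, temperature=1e-6, max_translation=0.05)
        state = system.initial_state(params)
        e0 = state.energy().total
        for _ in range(2000):
            mc.metropolis_step(state, params)
        # at T -> 0 only downhill moves pass, so energy never increases
        assert state.energy().total <= e0 + 1e-9

    def test_infinite_temperature_accepts_everything(self):
        system = lj_fluid_system(n=6)
        params = mc.MCParams(temperature=math.inf, seed=1, max_translation=3.0)
        state = system.initial_state(params)
        for _ in range(3000):
            mc.metropolis_step(state, params)
        assert state.acceptance_fraction() == 1.0

    def test_zero_guest_state_is_noop(self):
        system = mc.System(box(), [])
        state = system.initial_state(mc.MCParams(seed=0))
        out = mc.metropolis_step(state)
        assert out.step == 1 and out.attempted == {"translation": 0, "rotation": 0}

    def test_boltzmann_shell_occupancy(self):
        """Long-run radial occupancy around an attractive site matches the
        Boltzmann weight from direct quadrature of the pair potential."""
        a = 26.0
        fw = Framework(UnitCell(a, a, a), np.array([[0.5, 0.5, 0.5]]), ["S"])
        guest = atom_guest("S", center=(15.0, 13, 13))
        system = mc.System(fw, [guest])
        T = 150.0
        params = mc.MCParams(temperature=T, seed=11, max_translation=1.6,
                             n_equilibration=2000, n_production=120_000, sample_every=2)
        traj = mc.run_simulation(system, params)
        center = np.array([a / 2, a / 2, a / 2])
        r = np.linalg.norm(traj.centers[:, 0, :] - center, axis=1)
        shell_a, shell_b = (3.9, 4.6), (5.2, 6.5)
        n_a = int(np.sum((r >= shell_a[0]) & (r < shell_a[1])))
        n_b = int(np.sum((r >= shell_b[0]) & (r < shell_b[1])))
        assert n_b > 0

        t = ff.uff_table()["S_3+4"]
        pair = ff.mix_lorentz_berthelot(t, t)
        beta = 1.0 / (KB_KCAL * T)

        def weight(lo, hi):
            rr = np.linspace(lo, hi, 2000)
            return np.trapezoid(np.exp(-beta * np.array([pair.energy(x) for x in rr])) * rr**2, rr)

        expect = weight(*shell_a) / weight(*shell_b)
        got = n_a / n_b
        # 3-sigma binomial band on the observed ratio
        p = expect / (1 + expect)
        n_tot = n_a + n_b
        sd_ratio = 3 * math.sqrt(p * (1 - p) / n_tot) / (1 - p) ** 2
        assert abs(got - expect) < sd_ratio * (1 + expect)


class TestRunSimulation:
    def test_zero_production_empty_trajectory(self):
        system = lj_fluid_system(4)
        params = mc.MCParams(seed=2, n_equilibration=500, n_production=0)
        traj = mc.run_simulation(system, params)
        assert traj.n_frames == 0
        assert traj.final_state.step == 500

    def test_sample_count_contract(self):
        system = lj_fluid_system(4)
        params = mc.MCParams(seed=2, n_equilibration=0, n_production=2500, sample_every=100)
        traj = mc.run_simulation(system, params)
        assert traj.n_frames == 2500 // 100

    def test_seed_determinism_bitwise(self):
        p = mc.MCParams(seed=9, n_equilibration=1000, n_production=2000, sample_every=100)
        t1 = mc.run_simulation(lj_fluid_system(5), p)
        t2 = mc.run_simulation(lj_fluid_system(5), p)
        assert np.array_equal(t1.centers, t2.centers)
        assert np.array_equal(t1.quats, t2.quats)
        assert np.array_equal(t1.energies, t2.energies)
        t3 = mc.run_simulation(lj_fluid_system(5), mc.MCParams(seed=10, n_equilibration=1000,
                                                               n_production=2000, sample_every=100))
        assert not np.array_equal(t1.centers, t3.centers)

    def test_ghost_guest_samples_uniformly(self):
        """Ideal-gas oracle: a non-interacting guest visits the box
        uniformly (chi-square over 3x3x3 bins)."""
        from scipy.stats import chi2

        a = 26.0
        ghost = syn.get_fixture("ghost").as_guest(center=(13.0, 13, 13))
        system = mc.System(box(a), [ghost])
        params = mc.MCParams(seed=21, n_equilibration=2000, n_production=100_000,
                             sample_every=20, max_translation=3.0)
        traj = mc.run_simulation(system, params)
        pos = traj.centers[:, 0, :]
        bins = np.floor(pos / (a / 3)).astype(int) % 3
        flat = bins[:, 0] * 9 + bins[:, 1] * 3 + bins[:, 2]
        counts = np.bincount(flat, minlength=27)
        expect = len(pos) / 27
        stat = float(np.sum((counts - expect) ** 2 / expect))
        # positions are autocorrelated; scale dof conservatively
        p_value = 1 - chi2.cdf(stat / 10, df=26)
        assert p_value > 0.01

    def test_energy_cache_drift(self):
        """After 1e5 steps the incrementally updated energy matches a full
        recomputation to better than 1e-6 relative."""
        rng = np.random.default_rng(4)
        fw_frac = rng.random((16, 3))
        q = rng.normal(0, 0.3, 16)
        q -= q.mean()
        fw = Framework(UnitCell(26, 26, 26), fw_frac, ["O", "Mg", "H", "C"] * 4, q)
        guests = []
        for i in range(3):
            guests.append(syn.get_fixture("water").as_guest(center=rng.random(3) * 26))
        system = mc.System(fw, guests)
        params = mc.MCParams(seed=5, max_translation=1.0)
        state = system.initial_state(params)
        for _ in range(100_000):
            mc.metropolis_step(state, params)
        e_inc = state.energy().total
        e_full = state.recompute().total
        assert abs(e_inc - e_full) / max(abs(e_full), 1e-12) < 1e-6

    def test_acceptance_decreases_with_amplitude(self):
        """On a dense LJ fluid larger trial displacements are rejected more
        often (monotonic at three amplitudes)."""
        fracs = []
        for amp in (0.3, 1.5, 6.0):
            system = lj_fluid_system(n=14, a=26.0, seed=6)
            params = mc.MCParams(seed=6, max_translation=amp, n_equilibration=0,
                                 n_production=0)
            state = system.initial_state(params)
            for _ in range(6000):
                mc.metropolis_step(state, params)
            fracs.append(state.acceptance_fraction("translation"))
        assert fracs[0] > fracs[1] > fracs[2]


class TestSaturationLoading:
    def test_oversized_guest_scores_zero(self):
        # two rigid walls 2.5 A apart; a sulfur-sized guest needs ~2.5 A
        # clearance to every wall atom, impossible inside the gap
        xs = np.linspace(0.05, 0.95, 10)
        frac = [[x, y, 0.45] for x in xs for y in xs] + [[x, y, 0.55] for x in xs for y in xs]
        fw = Framework(UnitCell(26, 26, 26), np.array(frac), ["O"] * len(frac))
        guest = atom_guest("S")
        n = mc.saturation_loading(
            fw, guest, mc.MCParams.scaled_down(seed=1), z_range=(11.7, 14.3),
            max_failed_rounds=5, tries_per_round=100, relax_steps=0,
        )
        assert n == 0

    def test_hard_sphere_packing_matches_lattice_oracle(self):
        # quasi-1D periodic tube 13.2 x 1.0 x 1.0: transverse min-image
        # offsets are at most 0.5 per axis, so the packing bound is exactly
        # enumerable: floor(L/d) <= n_max <= floor(L/sqrt(d^2 - W^2/2))
        L, W = 13.2, 1.0
        fw = Framework(UnitCell(L, W, W), np.zeros((0, 3)), [])
        guest = atom_guest("S")
        d = 0.7 * ff.uff_table()["S_3+4"].sigma  # contact distance 2.516 A
        lower = math.floor(L / d)
        upper = math.floor(L / math.sqrt(d**2 - W**2 / 2))
        assert lower == upper == 5  # the bounds pin the exact optimum
        n = mc.saturation_loading(
            fw, guest, mc.MCParams.scaled_down(seed=2),
            max_failed_rounds=40, tries_per_round=300, relax_steps=800,
        )
        assert abs(n - 5) <= 1

    def test_stoichiometric_carbonate_count_fits(self, hex_cell):
        # the gallery accommodates at least the charge-balance carbonate
        # count (it does so during construction); verify via insertion into
        # the anhydrous layer-only framework
        from ldhsim.structure import build_pyroaurite, detach_molecules

        fw = build_pyroaurite(0.25, 0.0, hex_cell, seed=3)
        layers_only, removed = detach_molecules(fw, "carbonate")
        want = fw.count("Fe") // 2
        carb = syn.get_fixture("carbonate").as_guest()
        got = mc.saturation_loading(
            layers_only, carb, mc.MCParams.scaled_down(seed=3),
            max_failed_rounds=30, tries_per_round=300, relax_steps=200,
        )
        assert got >= want


class TestInsertionScan:
    def test_ghost_probe_feasible_everywhere(self, unit_framework):
        from ldhsim.structure import build_supercell

        sc = build_supercell(unit_framework, (3, 3, 2))
        ghost = syn.get_fixture("ghost").as_guest()
        res = mc.interlayer_insertion_scan(sc, ghost, grid_spacing=8.0, n_orientations=1)
        assert res.feasible
        assert res.min_energy == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(res.energies, 0.0, atol=1e-10)

    def test_scan_minimum_matches_grid_enumeration(self, unit_framework):
        from ldhsim.structure import build_supercell

        sc = build_supercell(unit_framework, (3, 3, 2))
        probe = atom_guest("O")
        res = mc.interlayer_insertion_scan(
            sc, probe, grid_spacing=9.0, n_orientations=1, z_fracs=[0.0], seed=5
        )
        # exhaustive oracle over the same poses through the reference kernel
        alpha = ff.EwaldParams.for_simulation(1e-4, 12.5).alpha
        from ldhsim import _kernels as K
        from ldhsim.units import COULOMB_KCAL

        tab = ff.uff_table()
        m = sc.cell.matrix
        fw_sig = np.array([tab[l].sigma for l in sc.uff_labels])
        fw_eps = np.array([tab[l].D_i for l in sc.uff_labels])
        expect = []
        for pos in res.positions:
            lj, real = K.env_energy(
                np.array([pos]), np.array([0.0]), np.array([tab["O_3"].sigma]),
                np.array([tab["O_3"].D_i]), sc.cartesian_coords, sc.charges,
                fw_sig, fw_eps, m[0, 0], m[1, 0], m[1, 1], m[2, 2],
                12.5, alpha, COULOMB_KCAL,
            )
            expect.append(lj + real)
        assert res.min_energy == pytest.approx(min(expect), rel=1e-10)

    def test_empty_grid_rejected(self, unit_framework):
        from ldhsim.structure import build_supercell

        sc = build_supercell(unit_framework, (3, 3, 2))
        with pytest.raises(ValueError, match="empty"):
            mc.interlayer_insertion_scan(
                sc, atom_guest("O"), grid_spacing=9.0, n_orientations=0
            )


class TestSystemContracts:
    def test_non_neutral_rejected(self):
        g = atom_guest("Na", charge=1.0)
        with pytest.raises(ValueError, match="neutral"):
            mc.System(box(), [g])

    def test_small_cell_rejected(self):
        fw = Framework(UnitCell(10, 10, 10), np.zeros((0, 3)), [])
        with pytest.raises(ValueError, match="minimum image"):
            mc.System(fw, [atom_guest("S", center=(5, 5, 5))])

    def test_energy_matches_reference_total_energy(self, rng):
        fw_frac = rng.random((10, 3))
        q = rng.normal(0, 0.2, 10)
        q -= q.mean()
        fw = Framework(UnitCell(26, 26, 26), fw_frac, ["O", "Mg"] * 5, q)
        w = syn.get_fixture("water").as_guest(center=(6.0, 7, 8))
        params = ff.EwaldParams.from_accuracy(1e-6, 12.5)
        system = mc.System(fw, [w], ewald_params=params)
        e_mc = system.initial_state(mc.MCParams(seed=1)).energy()
        e_ref = ff.total_energy(fw, [w], ewald_params=params)
        assert e_mc.total == pytest.approx(e_ref.total, rel=1e-9, abs=1e-9)
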