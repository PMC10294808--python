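"""Rigid-molecule canonical Metropolis Monte Carlo on the LDH framework.

The framework (layers, gallery water, any carbonate not explicitly made
mobile) is rigid; guests are rigid molecules undergoing random translations
and rotations, accepted with probability ``min(1, exp(-dE/kT))``.  Energies
are UFF Lennard-Jones (12.5 A truncation) plus Ewald electrostatics; the
constant framework-framework energy is excluded throughout.

Besides plain sampling the module implements the two study-specific
procedures: saturation loading (insert-and-relax until the gallery or
surface cannot take another guest) and the rigid-insertion scan that probes
whether a molecule fits into the carbonate-bearing interlayer at the
experimental spacing.

The printed production protocol (2e7 equilibration + 1e7 production steps
at 300 K) is the default parameter set; the ``scaled_down`` preset
(1e5 + 1e5) is the desk-scale profile used by the test-suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels as K
from . import forcefield as ff
from .analysis import Frame
from .structure import (
    Framework,
    GuestMolecule,
    SlabModel,
    axis_angle_quat,
    detach_molecules,
    quat_multiply,
    quat_normalize,
    quat_to_matrix,
    random_rotation_quat,
    wrap_frac,
)
from .units import COULOMB_KCAL, KB_KCAL

__all__ = [
    "MCParams",
    "System",
    "MCState",
    "Trajectory",
    "metropolis_step",
    "run_simulation",
    "saturation_loading",
    "interlayer_insertion_scan",
    "slab_adsorption_system",
    "InsertionScanResult",
]


@dataclass(frozen=True)
class MCParams:
    """Monte Carlo run parameters.

    Defaults follow the production protocol (300 K, 2e7 equilibration and
    1e7 production steps).  Move amplitudes are fixed (no auto-tuning);
    the 0.2 A / 0.2 rad defaults put the acceptance fraction of a dense
    surface system in the conventional 30-50% window.
    """

    temperature: float = 300.0
    n_equilibration: int = 20_000_000
    n_production: int = 10_000_000
    max_translation: float = 0.2
    max_rotation: float = 0.2
    sample_every: int = 1000
    seed: int = 0
    cutoff: float = 12.5
    ewald_accuracy: float = 1e-4

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_equilibration < 0 or self.n_production < 0:
            raise ValueError("step counts must be non-negative")
        if self.max_translation <= 0 or self.max_rotation <= 0:
            raise ValueError("move amplitudes must be positive")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")

    @classmethod
    def production(cls, **kw) -> "MCParams":
        return cls(**kw)

    @classmethod
    def scaled_down(cls, seed: int = 0, **kw) -> "MCParams":
        """Desk-scale preset: 1e5 + 1e5 steps, samples every 1e3 steps."""
        kw.setdefault("n_equilibration", 100_000)
        kw.setdefault("n_production", 100_000)
        kw.setdefault("sample_every", 1000)
        return cls(seed=seed, **kw)

    @property
    def beta(self) -> float:
        return 0.0 if math.isinf(self.temperature) else 1.0 / (KB_KCAL * self.temperature)


# ---------------------------------------------------------------------------
# system


def _lj_arrays(labels) -> tuple[np.ndarray, np.ndarray]:
    table = ff.uff_table()
    sig = np.array([table[l].sigma for l in labels])
    eps = np.array([table[l].D_i for l in labels])
    return sig, eps


class System:
    """A rigid framework plus rigid guests, with precomputed energy tables.

    The cell must have alpha = beta = 90 degrees and every periodic width
    must accommodate the minimum image at the chosen cutoff.
    """

    def __init__(
        self,
        framework: Framework,
        guests: list[GuestMolecule],
        cutoff: float = 12.5,
        ewald_accuracy: float = 1e-4,
        ewald_params: ff.EwaldParams | None = None,
    ):
        cell = framework.cell
        if abs(cell.alpha - 90) > 1e-6 or abs(cell.beta - 90) > 1e-6:
            raise ValueError("the MC kernels require alpha = beta = 90 degrees")
        m = cell.matrix
        if ff.min_width(m) < 2.0 * cutoff:
            raise ValueError(
                f"cell width {ff.min_width(m):.2f} A < 2 x cutoff "
                f"({2*cutoff} A); minimum image invalid"
            )
        self.framework = framework
        self.guests = [g.with_pose() for g in guests]
        self.cutoff = cutoff
        self.cell = m
        self.cell_params = (m[0, 0], m[1, 0], m[1, 1], m[2, 2])
        self.volume = cell.volume

        self.fw_xyz = np.ascontiguousarray(framework.cartesian_coords)
        self.fw_q = np.ascontiguousarray(framework.charges)
        self.fw_sig, self.fw_eps = _lj_arrays(framework.uff_labels)

        self.g_sig, self.g_eps = [], []
        for g in self.guests:
            s, e = _lj_arrays([ff.DEFAULT_UFF_LABEL[el] for el in g.elements])
            self.g_sig.append(s)
            self.g_eps.append(e)

        total_q = self.fw_q.sum() + sum(g.charges.sum() for g in self.guests)
        if abs(total_q) > 1e-6:
            raise ValueError(f"framework plus guests not neutral (net {total_q:.4g} e)")

        self.params = ewald_params or ff.EwaldParams.for_simulation(ewald_accuracy, cutoff)
        self._charged = bool(np.any(self.fw_q) or any(np.any(g.charges) for g in self.guests))
        if self._charged:
            kv, coeff = ff._k_vectors(self.cell, self.params)
        else:
            kv, coeff = np.zeros((0, 3)), np.zeros(0)
        self.kvecs = np.ascontiguousarray(kv)
        self.kcoeff = np.ascontiguousarray(coeff)
        self.recip_prefactor = COULOMB_KCAL * 2.0 * math.pi / self.volume
        # framework structure factor and its (constant) reciprocal energy
        self.S_fw_re = np.zeros(len(self.kvecs))
        self.S_fw_im = np.zeros(len(self.kvecs))
        if len(self.kvecs):
            K.update_structure_factor(
                self.kvecs, self.S_fw_re, self.S_fw_im, np.zeros((0, 3)), self.fw_xyz, self.fw_q
            )
        self.recip_fw = K.recip_energy(self.kcoeff, self.S_fw_re, self.S_fw_im, self.recip_prefactor)

        # constant per-guest terms (rigid molecules): self + intramolecular
        a = self.params.alpha
        self.self_guests = -COULOMB_KCAL * a / math.sqrt(math.pi) * sum(
            float(np.sum(g.charges**2)) for g in self.guests
        )
        self.intra_lj = 0.0
        self.intra_real = 0.0
        for gi, g in enumerate(self.guests):
            xyz = g.local_coords
            for i in range(g.n_atoms):
                for j in range(i + 1, g.n_atoms):
                    r = float(np.linalg.norm(xyz[i] - xyz[j]))
                    if r < 1e-9 or r >= cutoff:
                        continue
                    e = math.sqrt(self.g_eps[gi][i] * self.g_eps[gi][j])
                    if e > 0:
                        s = 0.5 * (self.g_sig[gi][i] + self.g_sig[gi][j])
                        sr6 = (s / r) ** 6
                        self.intra_lj += 4 * e * (sr6 * sr6 - sr6)
                    qq = g.charges[i] * g.charges[j]
                    if qq:
                        self.intra_real += COULOMB_KCAL * qq * math.erfc(a * r) / r

    @property
    def n_guests(self) -> int:
        return len(self.guests)

    # -- energy pieces ----------------------------------------------------

    def _env_energy(self, xyz, q, sig, eps, other_xyz, other_q, other_sig, other_eps):
        ax, bx, by, cz = self.cell_params
        return K.env_energy(
            xyz, q, sig, eps, other_xyz, other_q, other_sig, other_eps,
            ax, bx, by, cz, self.cutoff, self.params.alpha, COULOMB_KCAL,
        )

    def guest_pair_energies(self, gi: int, xyz, centers, quats):
        """(lj, real) of guest gi at coordinates ``xyz`` against the
        framework (row 0) and every other guest (rows 1..G)."""
        g = self.guests[gi]
        out_lj = np.zeros(self.n_guests + 1)
        out_real = np.zeros(self.n_guests + 1)
        out_lj[0], out_real[0] = self._env_energy(
            xyz, g.charges, self.g_sig[gi], self.g_eps[gi],
            self.fw_xyz, self.fw_q, self.fw_sig, self.fw_eps,
        )
        for h in range(self.n_guests):
            if h == gi:
                continue
            hxyz = self.guest_coords(h, centers, quats)
            out_lj[h + 1], out_real[h + 1] = self._env_energy(
                xyz, g.charges, self.g_sig[gi], self.g_eps[gi],
                hxyz, self.guests[h].charges, self.g_sig[h], self.g_eps[h],
            )
        return out_lj, out_real

    def guest_coords(self, gi: int, centers, quats) -> np.ndarray:
        g = self.guests[gi]
        return np.ascontiguousarray(
            centers[gi] + g.local_coords @ quat_to_matrix(quats[gi]).T
        )

    def initial_state(self, params: MCParams) -> "MCState":
        return MCState(self, params)


class MCState:
    """Current configuration: guest poses, cached energies, counters, rng.

    The cached tables are exact up to floating accumulation; ``recompute``
    rebuilds them from scratch (used for the drift invariant).
    """

    def __init__(self, system: System, params: MCParams):
        self.system = system
        self.params = params
        self.rng = np.random.default_rng(params.seed)
        self.centers = np.array([g.center for g in system.guests], dtype=float).reshape(-1, 3)
        self.quats = np.array(
            [quat_normalize(g.orientation) for g in system.guests], dtype=float
        ).reshape(-1, 4)
        self.accepted = {"translation": 0, "rotation": 0}
        self.attempted = {"translation": 0, "rotation": 0}
        self.step = 0
        self._build_caches()

    def _build_caches(self):
        sys = self.system
        G = sys.n_guests
        self.A_lj = np.zeros((G + 1, G + 1))
        self.A_real = np.zeros((G + 1, G + 1))
        self.S_re = sys.S_fw_re.copy()
        self.S_im = sys.S_fw_im.copy()
        for gi in range(G):
            xyz = sys.guest_coords(gi, self.centers, self.quats)
            lj0, real0 = sys._env_energy(
                xyz, sys.guests[gi].charges, sys.g_sig[gi], sys.g_eps[gi],
                sys.fw_xyz, sys.fw_q, sys.fw_sig, sys.fw_eps,
            )
            self.A_lj[0, gi + 1] = self.A_lj[gi + 1, 0] = lj0
            self.A_real[0, gi + 1] = self.A_real[gi + 1, 0] = real0
            for h in range(gi):
                hxyz = sys.guest_coords(h, self.centers, self.quats)
                lj, real = sys._env_energy(
                    xyz, sys.guests[gi].charges, sys.g_sig[gi], sys.g_eps[gi],
                    hxyz, sys.guests[h].charges, sys.g_sig[h], sys.g_eps[h],
                )
                self.A_lj[gi + 1, h + 1] = self.A_lj[h + 1, gi + 1] = lj
                self.A_real[gi + 1, h + 1] = self.A_real[h + 1, gi + 1] = real
            if len(sys.kvecs):
                K.update_structure_factor(
                    sys.kvecs, self.S_re, self.S_im, np.zeros((0, 3)), xyz,
                    np.ascontiguousarray(sys.guests[gi].charges),
                )
        self._recip = (
            K.recip_energy(sys.kcoeff, self.S_re, self.S_im, sys.recip_prefactor)
            if len(sys.kvecs)
            else 0.0
        )

    # -- energy reporting --------------------------------------------------

    def energy(self) -> ff.EnergyBreakdown:
        """Interaction energy of the current configuration (framework
        internal energy excluded; rigid intramolecular terms included as
        constants, so this matches :func:`ldhsim.forcefield.total_energy`
        up to Ewald truncation)."""
        sys = self.system
        iu = np.triu_indices(sys.n_guests + 1, k=1)
        return ff.EnergyBreakdown(
            lj=float(self.A_lj[iu].sum()) + sys.intra_lj,
            coul_real=float(self.A_real[iu].sum()) + sys.intra_real,
            coul_recip=self._recip - sys.recip_fw,
            coul_self=sys.self_guests,
        )

    def recompute(self) -> ff.EnergyBreakdown:
        """Full from-scratch rebuild of all caches; returns the energy."""
        self._build_caches()
        return self.energy()

    def acceptance_fraction(self, move: str | None = None) -> float:
        if move is None:
            att = sum(self.attempted.values())
            acc = sum(self.accepted.values())
        else:
            att, acc = self.attempted[move], self.accepted[move]
        return acc / att if att else 0.0

    def guest_world_coords(self, gi: int) -> np.ndarray:
        return self.system.guest_coords(gi, self.centers, self.quats)


def metropolis_step(state: MCState, params: MCParams | None = None) -> MCState:
    """One Metropolis move: pick a random guest, propose a translation or a
    rotation (50/50), accept with min(1, exp(-dE/kT)).  The state is
    modified in place and returned; a guest-free state is a no-op."""
    params = params or state.params
    sys = state.system
    if sys.n_guests == 0:
        state.step += 1
        return state
    rng = state.rng
    gi = int(rng.integers(sys.n_guests))
    g = sys.guests[gi]
    rotate = bool(rng.random() < 0.5)
    move = "rotation" if rotate else "translation"
    state.attempted[move] += 1

    old_center = state.centers[gi].copy()
    old_quat = state.quats[gi].copy()
    old_xyz = sys.guest_coords(gi, state.centers, state.quats)
    if rotate:
        axis = rng.standard_normal(3)
        while np.linalg.norm(axis) < 1e-12:
            axis = rng.standard_normal(3)
        dq = axis_angle_quat(axis, float(rng.uniform(-params.max_rotation, params.max_rotation)))
        new_quat = quat_normalize(quat_multiply(dq, old_quat))
        new_center = old_center
    else:
        new_center = old_center + rng.uniform(-params.max_translation, params.max_translation, 3)
        new_quat = old_quat

    state.centers[gi] = new_center
    state.quats[gi] = new_quat
    new_xyz = sys.guest_coords(gi, state.centers, state.quats)

    new_lj, new_real = sys.guest_pair_energies(gi, new_xyz, state.centers, state.quats)
    row = gi + 1
    d_pair = (new_lj.sum() - state.A_lj[row].sum()) + (new_real.sum() - state.A_real[row].sum())

    d_recip = 0.0
    q = np.ascontiguousarray(g.charges)
    if len(sys.kvecs) and np.any(q):
        K.update_structure_factor(sys.kvecs, state.S_re, state.S_im, old_xyz, new_xyz, q)
        new_recip = K.recip_energy(sys.kcoeff, state.S_re, state.S_im, sys.recip_prefactor)
        d_recip = new_recip - state._recip

    dE = d_pair + d_recip
    accept = dE <= 0.0 or rng.random() < math.exp(-params.beta * dE)
    if accept:
        state.accepted[move] += 1
        state.A_lj[row, :] = new_lj
        state.A_lj[:, row] = new_lj
        state.A_real[row, :] = new_real
        state.A_real[:, row] = new_real
        state.A_lj[row, row] = state.A_real[row, row] = 0.0
        if len(sys.kvecs) and np.any(q):
            state._recip += d_recip
        # wrap the center back into the cell to keep coordinates bounded
        frac = wrap_frac(state.centers[gi] @ np.linalg.inv(sys.cell))
        state.centers[gi] = frac @ sys.cell
    else:
        state.centers[gi] = old_center
        state.quats[gi] = old_quat
        if len(sys.kvecs) and np.any(q):
            K.update_structure_factor(sys.kvecs, state.S_re, state.S_im, new_xyz, old_xyz, q)
    state.step += 1
    return state


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class Trajectory:
    """Sampled production configurations with energies.

    ``centers``/``quats`` have shape (n_frames, n_guests, ...); energies
    are rows of (lj, coul_real, coul_recip, coul_self).
    """

    system: System
    step_indices: np.ndarray
    centers: np.ndarray
    quats: np.ndarray
    energies: np.ndarray
    acceptance: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.step_indices)

    def energy_breakdown(self, i: int) -> ff.EnergyBreakdown:
        return ff.EnergyBreakdown(*self.energies[i])

    def frames(self, extra_groups: dict | None = None):
        """Yield :class:`ldhsim.analysis.Frame` objects: framework atoms
        first, then each guest; groups cover framework species, each guest
        by name and index, and any caller-supplied framework groups."""
        sys = self.system
        fw = sys.framework
        n_fw = len(fw)
        base_groups: dict[str, np.ndarray] = {"framework": np.arange(n_fw)}
        for sp in sorted(set(fw.species)):
            base_groups[sp] = np.array([i for i, s in enumerate(fw.species) if s == sp], int)
        for name, idx in (extra_groups or {}).items():
            base_groups[name] = np.asarray(idx, dtype=int)
        offset = n_fw
        guest_spans = []
        for gi, g in enumerate(sys.guests):
            span = np.arange(offset, offset + g.n_atoms)
            guest_spans.append(span)
            base_groups[f"guest_{gi}"] = span
            base_groups.setdefault(f"guest:{g.name}", np.zeros(0, int))
            base_groups[f"guest:{g.name}"] = np.concatenate(
                [base_groups[f"guest:{g.name}"], span]
            )
            offset += g.n_atoms
        elements = list(fw.elements) + sum((list(g.elements) for g in sys.guests), [])
        for i in range(self.n_frames):
            coords = [sys.fw_xyz]
            for gi, g in enumerate(sys.guests):
                coords.append(
                    self.centers[i, gi] + g.local_coords @ quat_to_matrix(self.quats[i, gi]).T
                )
            yield Frame(
                np.vstack(coords), elements, sys.cell, dict(base_groups), int(self.step_indices[i])
            )

    def guest_molecule_map(self) -> dict[int, np.ndarray]:
        """mol_id -> atom indices (in frame numbering) for each guest."""
        n_fw = len(self.system.framework)
        out = {}
        off = n_fw
        for gi, g in enumerate(self.system.guests):
            out[gi] = np.arange(off, off + g.n_atoms)
            off += g.n_atoms
        return out

    def write_xyz(self, path) -> None:
        """Multi-frame extended XYZ of the sampled configurations."""
        with open(path, "w") as fh:
            for frame in self.frames():
                n = len(frame.coords)
                lattice = " ".join(f"{x:.6f}" for x in self.system.cell.reshape(-1))
                fh.write(f"{n}\n")
                fh.write(f'Lattice="{lattice}" step={frame.index}\n')
                for el, (x, y, z) in zip(frame.elements, frame.coords):
                    fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")

    def energy_log_csv(self, path) -> None:
        import pandas as pd

        e = self.energies
        pd.DataFrame(
            {
                "step": self.step_indices,
                "lj": e[:, 0],
                "coul": e[:, 1] + e[:, 2] + e[:, 3],
                "total": e.sum(axis=1),
                "acceptance": self.acceptance.get("overall", np.nan),
            }
        ).to_csv(path, index=False)


def run_simulation(system: System, params: MCParams) -> Trajectory:
    """Equilibration followed by production; samples every
    ``sample_every`` production steps (never during equilibration).
    Fully reproducible from ``params.seed``."""
    state = system.initial_state(params)
    for _ in range(params.n_equilibration):
        metropolis_step(state, params)
    steps, centers, quats, energies = [], [], [], []
    for i in range(params.n_production):
        metropolis_step(state, params)
        if (i + 1) % params.sample_every == 0:
            e = state.energy()
            steps.append(i + 1)
            centers.append(state.centers.copy())
            quats.append(state.quats.copy())
            energies.append([e.lj, e.coul_real, e.coul_recip, e.coul_self])
    G = system.n_guests
    traj = Trajectory(
        system,
        np.array(steps, dtype=int),
        np.array(centers).reshape(len(steps), G, 3) if steps else np.zeros((0, G, 3)),
        np.array(quats).reshape(len(steps), G, 4) if steps else np.zeros((0, G, 4)),
        np.array(energies).reshape(len(steps), 4) if steps else np.zeros((0, 4)),
        {
            "overall": state.acceptance_fraction(),
            "translation": state.acceptance_fraction("translation"),
            "rotation": state.acceptance_fraction("rotation"),
        },
    )
    traj.final_state = state
    return traj


# ---------------------------------------------------------------------------
# saturation loading


def saturation_loading(
    framework: Framework,
    guest: GuestMolecule,
    params: MCParams | None = None,
    z_range: tuple[float, float] | None = None,
    max_failed_rounds: int = 50,
    tries_per_round: int = 200,
    relax_steps: int = 500,
    overlap_factor: float = 0.7,
    charge_tolerance: bool = True,
) -> int:
    """Maximum number of guests that fit by iterative insertion.

    Each round proposes up to ``tries_per_round`` random poses (optionally
    restricted to a cartesian z window); a pose is feasible when no
    heavy-atom pair comes closer than ``overlap_factor`` times the mixed LJ
    sigma.  After each successful insertion the guest set is relaxed by a
    short Monte Carlo run.  The procedure stops after
    ``max_failed_rounds`` consecutive failed rounds and returns the count
    (zero is a valid result).

    Charged guests make the running system non-neutral; the electrostatics
    of the insertion decision then use the screened real-space part only
    (``charge_tolerance``), which is the physically dominant term at
    contact distances.
    """
    params = params or MCParams.scaled_down()
    rng = np.random.default_rng(params.seed)
    sys_cell = framework.cell.matrix
    inv = np.linalg.inv(sys_cell)
    ax, bx, by, cz = sys_cell[0, 0], sys_cell[1, 0], sys_cell[1, 1], sys_cell[2, 2]

    table = ff.uff_table()
    fw_sig = np.array([table[l].sigma for l in framework.uff_labels])
    fw_xyz = framework.cartesian_coords
    g_sig = np.array([table[ff.DEFAULT_UFF_LABEL[e]].sigma for e in guest.elements])
    g_heavy = np.asarray(guest.heavy_mask, dtype=bool)
    fw_heavy = np.array([e != "H" for e in framework.elements], dtype=bool)

    placed: list[GuestMolecule] = []
    placed_xyz: list[np.ndarray] = []
    failed_rounds = 0
    local = guest.local_coords - guest.local_coords.mean(axis=0)

    def pose_ok(xyz) -> bool:
        # against framework
        if len(fw_xyz):
            if not _no_overlap(
                xyz[g_heavy], g_sig[g_heavy], fw_xyz[fw_heavy], fw_sig[fw_heavy],
                ax, bx, by, cz, overlap_factor,
            ):
                return False
        for other, og in zip(placed_xyz, placed):
            if not _no_overlap(
                xyz[g_heavy], g_sig[g_heavy], other[og.heavy_mask], g_sig[og.heavy_mask],
                ax, bx, by, cz, overlap_factor,
            ):
                return False
        return True

    while failed_rounds < max_failed_rounds:
        success = False
        for _ in range(tries_per_round):
            f = rng.random(3)
            center = f @ sys_cell
            if z_range is not None:
                center[2] = rng.uniform(*z_range)
            q = random_rotation_quat(rng)
            xyz = center + local @ quat_to_matrix(q).T
            if pose_ok(xyz):
                placed.append(
                    replace(guest, center=center, orientation=q, local_coords=local.copy())
                )
                placed_xyz.append(xyz)
                success = True
                break
        if not success:
            failed_rounds += 1
            continue
        failed_rounds = 0
        if relax_steps > 0 and len(placed) > 1:
            placed, placed_xyz = _relax_hard(
                placed, placed_xyz, local, g_sig, g_heavy, fw_xyz[fw_heavy],
                fw_sig[fw_heavy], ax, bx, by, cz, overlap_factor, relax_steps, rng, z_range,
            )
    return len(placed)


def _no_overlap(xyz_a, sig_a, xyz_b, sig_b, ax, bx, by, cz, factor) -> bool:
    if len(xyz_a) == 0 or len(xyz_b) == 0:
        return True
    r = K.min_pair_distance(
        np.ascontiguousarray(xyz_a), np.ascontiguousarray(xyz_b), ax, bx, by, cz
    )
    return r >= factor * 0.5 * (sig_a.max() + sig_b.max())


def _relax_hard(
    placed, placed_xyz, local, g_sig, g_heavy, fw_xyz_h, fw_sig_h,
    ax, bx, by, cz, factor, steps, rng, z_range
):
    """Hard-sphere Monte Carlo shuffling to open space between insertions."""
    n = len(placed)
    for _ in range(steps):
        i = int(rng.integers(n))
        g = placed[i]
        new_center = g.center + rng.uniform(-0.4, 0.4, 3)
        if z_range is not None:
            new_center[2] = min(max(new_center[2], z_range[0]), z_range[1])
        dq = axis_angle_quat(rng.standard_normal(3) + 1e-12, float(rng.uniform(-0.3, 0.3)))
        new_q = quat_normalize(quat_multiply(dq, g.orientation))
        xyz = new_center + local @ quat_to_matrix(new_q).T
        ok = True
        if len(fw_xyz_h) and not _no_overlap(
            xyz[g_heavy], g_sig[g_heavy], fw_xyz_h, fw_sig_h, ax, bx, by, cz, factor
        ):
            ok = False
        if ok:
            for j in range(n):
                if j == i:
                    continue
                if not _no_overlap(
                    xyz[g_heavy], g_sig[g_heavy], placed_xyz[j][g_heavy], g_sig[g_heavy],
                    ax, bx, by, cz, factor,
                ):
                    ok = False
                    break
        if ok:
            placed[i] = replace(g, center=new_center, orientation=new_q)
            placed_xyz[i] = xyz
    return placed, placed_xyz


# ---------------------------------------------------------------------------
# rigid-insertion scan


@dataclass
class InsertionScanResult:
    """Grid x orientation scan of the rigid-insertion energy."""

    min_energy: float
    feasible: bool
    energies: np.ndarray  # (n_positions, n_orientations)
    positions: np.ndarray
    threshold: float

    @property
    def argmin(self):
        return np.unravel_index(int(np.argmin(self.energies)), self.energies.shape)


def interlayer_insertion_scan(
    framework: Framework,
    guest: GuestMolecule,
    grid_spacing: float = 3.0,
    n_orientations: int = 8,
    z_fracs=None,
    threshold: float = 10.0,
    cutoff: float = 12.5,
    seed: int = 0,
) -> InsertionScanResult:
    """Probe whether a rigid guest fits into the gallery at the imposed
    interlayer spacing.

    The guest is placed on an in-plane grid (spacing ``grid_spacing`` A) at
    the gallery midplane(s), in ``n_orientations`` seeded random rigid
    orientations; at each pose the guest-framework LJ plus screened
    real-space Coulomb energy is evaluated.  The insertion is ``feasible``
    iff the scan minimum lies below ``threshold`` (kcal/mol).  A ghost
    probe scores zero everywhere, hence feasible.
    """
    cellm = framework.cell.matrix
    if ff.min_width(cellm) < 2 * cutoff:
        raise ValueError(
            "cell too small for the scan cutoff; build a supercell first"
        )
    na = max(1, int(round(cellm[0, 0] / grid_spacing)))
    nb = max(1, int(round(cellm[1, 1] / grid_spacing)))
    if na * nb == 0 or n_orientations < 1:
        raise ValueError("empty scan grid")
    from .structure import LAYERS_PER_CELL

    if z_fracs is None:
        nc = framework.metadata.get("supercell", (1, 1, 1))[2]
        n_gal = LAYERS_PER_CELL * max(1, nc)
        z_fracs = [k / n_gal for k in range(n_gal)]

    rng = np.random.default_rng(seed)
    quats = [np.array([1.0, 0, 0, 0])] + [random_rotation_quat(rng) for _ in range(n_orientations - 1)]

    table = ff.uff_table()
    fw_xyz = np.ascontiguousarray(framework.cartesian_coords)
    fw_q = np.ascontiguousarray(framework.charges)
    fw_sig = np.array([table[l].sigma for l in framework.uff_labels])
    fw_eps = np.array([table[l].D_i for l in framework.uff_labels])
    g_sig = np.array([table[ff.DEFAULT_UFF_LABEL[e]].sigma for e in guest.elements])
    g_eps = np.array([table[ff.DEFAULT_UFF_LABEL[e]].D_i for e in guest.elements])
    g_q = np.ascontiguousarray(guest.charges)
    local = guest.local_coords - guest.local_coords.mean(axis=0)
    ax, bx, by, cz = cellm[0, 0], cellm[1, 0], cellm[1, 1], cellm[2, 2]
    alpha = ff.EwaldParams.for_simulation(1e-4, cutoff).alpha

    positions = []
    for zf in z_fracs:
        for i in range(na):
            for j in range(nb):
                positions.append(np.array([(i + 0.5) / na, (j + 0.5) / nb, zf]) @ cellm)
    positions = np.array(positions)
    energies = np.empty((len(positions), len(quats)))
    for p, pos in enumerate(positions):
        for o, q in enumerate(quats):
            xyz = np.ascontiguousarray(pos + local @ quat_to_matrix(q).T)
            lj, real = K.env_energy(
                xyz, g_q, g_sig, g_eps, fw_xyz, fw_q, fw_sig, fw_eps,
                ax, bx, by, cz, cutoff, alpha, COULOMB_KCAL,
            )
            energies[p, o] = lj + real
    emin = float(energies.min())
    return InsertionScanResult(emin, emin < threshold, energies, positions, threshold)


# ---------------------------------------------------------------------------
# slab adsorption setup


def slab_adsorption_system(
    slab: SlabModel,
    adsorbates: list[GuestMolecule] | None = None,
    mobile_species: tuple = ("carbonate",),
    strip_species: tuple = ("water",),
    approach_distance: float = 2.0,
    cutoff: float = 12.5,
    ewald_accuracy: float = 1e-4,
    seed: int = 0,
) -> System:
    """Build a Monte Carlo system for guests on the external LDH surface.

    Gallery molecules of ``mobile_species`` sitting on the exposed face
    (outside the outermost metal planes) are detached from the rigid
    framework and become mobile guests; face molecules of ``strip_species``
    (by default the cleaved gallery's water, which in contact with solution
    exchanges with the bulk rather than forming a frozen blanket) are
    removed so the hydroxyl surface is accessible.  Each ``adsorbate`` (for
    example one tetracycline molecule) is placed ``approach_distance`` A
    outside the exposed face, at a seeded random in-plane position.
    """
    fw = slab.framework
    z = fw.cartesian_coords[:, 2]
    metal = np.array([e in ("Mg", "Fe") for e in fw.elements])
    z_lo, z_hi = z[metal].min(), z[metal].max()
    guests: list[GuestMolecule] = []
    for sp in mobile_species:
        fw, detached = detach_molecules(fw, sp, z_range=(-1e9, z_lo))
        guests += detached
        fw, detached = detach_molecules(fw, sp, z_range=(z_hi, 1e9))
        guests += detached
    for sp in strip_species:
        if sp in mobile_species:
            continue
        fw, dropped = detach_molecules(fw, sp, z_range=(-1e9, z_lo))
        fw, dropped2 = detach_molecules(fw, sp, z_range=(z_hi, 1e9))
        if any(abs(g.net_charge) > 1e-9 for g in dropped + dropped2):
            raise ValueError("cannot strip charged species; neutrality would break")
    rng = np.random.default_rng(seed)
    for g in adsorbates or []:
        guests.append(
            _dock_adsorbate(fw, guests, g, rng, approach_distance, cutoff)
        )
    return System(fw, guests, cutoff=cutoff, ewald_accuracy=ewald_accuracy)


def _dock_adsorbate(
    fw: Framework,
    placed: list[GuestMolecule],
    guest: GuestMolecule,
    rng: np.random.Generator,
    approach_distance: float,
    cutoff: float,
    n_candidates: int = 150,
) -> GuestMolecule:
    """Seeded rigid docking of an adsorbate onto the exposed (low-z) face.

    Random in-plane positions and orientations are dropped toward the
    surface until the closest heavy-atom approach reaches van der Waals
    contact; the candidate with the lowest LJ + screened-Coulomb energy
    against framework plus already-placed guests becomes the initial pose.
    The Monte Carlo run then relaxes (or rejects) it.
    """
    m = fw.cell.matrix
    ax, bx, by, cz = m[0, 0], m[1, 0], m[1, 1], m[2, 2]
    alpha = ff.EwaldParams.for_simulation(1e-4, cutoff).alpha
    env_xyz = [fw.cartesian_coords]
    env_q = [fw.charges]
    env_sig = [_lj_arrays(fw.uff_labels)[0]]
    env_eps = [_lj_arrays(fw.uff_labels)[1]]
    for p in placed:
        env_xyz.append(p.world_coords)
        env_q.append(p.charges)
        s, e = _lj_arrays([ff.DEFAULT_UFF_LABEL[el] for el in p.elements])
        env_sig.append(s)
        env_eps.append(e)
    env_xyz = np.ascontiguousarray(np.vstack(env_xyz))
    env_q = np.ascontiguousarray(np.concatenate(env_q))
    env_sig = np.concatenate(env_sig)
    env_eps = np.concatenate(env_eps)
    g_sig, g_eps = _lj_arrays([ff.DEFAULT_UFF_LABEL[el] for el in guest.elements])
    g_q = np.ascontiguousarray(guest.charges)
    local = guest.local_coords - guest.local_coords.mean(axis=0)
    face_z = float(env_xyz[:, 2].min())

    best_pose, best_e = None, np.inf
    for _ in range(n_candidates):
        u, v = rng.random(2)
        q = random_rotation_quat(rng)
        xyz0 = local @ quat_to_matrix(q).T
        center = np.array([u, v, 0.0]) @ m
        center[2] = face_z - approach_distance - float(xyz0[:, 2].max())
        # march toward the face until van der Waals contact
        pose_xyz = None
        for _step in range(60):
            xyz = np.ascontiguousarray(center + xyz0)
            d = K.min_pair_distance(xyz, env_xyz, ax, bx, by, cz)
            if d < 1.9:
                break
            if d <= 2.6:
                pose_xyz = xyz
                break
            center[2] += min(d - 2.3, 1.0)
        if pose_xyz is None:
            continue
        lj, real = K.env_energy(
            pose_xyz, g_q, g_sig, g_eps, env_xyz, env_q, env_sig, env_eps,
            ax, bx, by, cz, cutoff, alpha, COULOMB_KCAL,
        )
        if lj + real < best_e:
            best_e = lj + real
            best_pose = (center.copy(), q.copy())
    if best_pose is None:
        raise RuntimeError("docking failed: no contact pose found for the adsorbate")
    return guest.with_pose(center=best_pose[0], orientation=best_pose[1])
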