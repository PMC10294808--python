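"""Nonbonded energy model: UFF Lennard-Jones, Ewald electrostatics and
charge-equilibration partial charges.

Energy conventions
------------------
* LJ pair energy ``4 eps [(sigma/r)^12 - (sigma/r)^6]`` truncated (unshifted)
  at the cutoff, 12.5 A by default.
* Coulomb energy through 3D Ewald summation; slab systems are handled as 3D
  periodic systems with a large vacuum gap.
* Charges come from charge equilibration (electronegativity equalization)
  with fixed per-element electronegativity/hardness and Gaussian-shielded
  interactions, solved as one linear system.

Internal units: angstrom, kcal/mol, elementary charge.  The charge
equilibration works in eV internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from functools import lru_cache

import numpy as np
from scipy.special import erf, erfc, erfcinv

from .units import COULOMB_EV, COULOMB_KCAL

__all__ = [
    "UFFAtomType",
    "PairPotential",
    "EwaldParams",
    "EnergyBreakdown",
    "uff_table",
    "uff_for_element",
    "eqeq_table",
    "mix_lorentz_berthelot",
    "eqeq_charges",
    "lj_energy",
    "ewald_energy",
    "total_energy",
]

#: default element -> UFF label mapping (UFF LJ parameters are element-wise)
DEFAULT_UFF_LABEL = {
    "H": "H_",
    "C": "C_3",
    "N": "N_3",
    "O": "O_3",
    "Na": "Na",
    "Mg": "Mg3+2",
    "S": "S_3+4",
    "Cl": "Cl",
    "Fe": "Fe3+2",
    "X": "Xx",  # non-interacting ghost probe
}

_SIXTH_ROOT_2 = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class UFFAtomType:
    """One UFF nonbonded atom type plus charge-equilibration parameters.

    ``x_i`` is the van der Waals minimum distance (A), ``D_i`` the well depth
    (kcal/mol); ``chi`` and ``J`` are the electronegativity and idempotential
    (eV) used by :func:`eqeq_charges`.
    """

    label: str
    x_i: float
    D_i: float
    chi: float = 0.0
    J: float = 0.0

    def __post_init__(self):
        if self.x_i <= 0:
            raise ValueError(f"{self.label}: x_i must be positive")
        if self.D_i < 0:
            raise ValueError(f"{self.label}: D_i must be non-negative")

    @property
    def sigma(self) -> float:
        """LJ zero-crossing distance, x_i / 2^(1/6)."""
        return self.x_i / _SIXTH_ROOT_2


@dataclass(frozen=True)
class PairPotential:
    """Mixed LJ pair interaction, zero beyond ``cutoff``."""

    sigma: float
    epsilon: float
    cutoff: float = 12.5

    def energy(self, r: float) -> float:
        if r >= self.cutoff:
            return 0.0
        sr6 = (self.sigma / r) ** 6
        return 4.0 * self.epsilon * (sr6 * sr6 - sr6)


@dataclass(frozen=True)
class EwaldParams:
    """Ewald splitting parameters.

    ``alpha`` (1/A) splits real and reciprocal space, ``kmax`` (1/A) bounds
    reciprocal vectors, ``r_cut`` (A) bounds the real-space sum.  Use
    :meth:`from_accuracy` to derive a consistent (alpha, kmax) pair; the
    computed energy then varies by less than ~``accuracy`` (relative) when
    alpha is perturbed by +-20% with kmax adjusted accordingly.
    """

    alpha: float
    kmax: float
    r_cut: float = 12.5
    accuracy: float = 1e-6

    @classmethod
    def from_accuracy(
        cls, accuracy: float = 1e-6, r_cut: float = 12.5, alpha_scale: float = 1.0
    ) -> "EwaldParams":
        """Choose (alpha, kmax) for a target relative accuracy.

        Both bounds carry a safety margin so that scaling alpha by +-20%
        (``alpha_scale``) leaves the truncation errors at or below
        ``accuracy``.
        """
        alpha0 = float(erfcinv(accuracy)) / r_cut
        alpha = 1.4 * alpha0 * alpha_scale
        kmax = 2.0 * (1.8 * alpha0) * math.sqrt(math.log(1.0 / accuracy))
        return cls(alpha=alpha, kmax=kmax, r_cut=r_cut, accuracy=accuracy)

    @classmethod
    def for_simulation(cls, accuracy: float = 1e-4, r_cut: float = 12.5) -> "EwaldParams":
        """Minimal (alpha, kmax) for a target accuracy, without the
        perturbation-robustness margins; used by the Monte Carlo engine
        where the reciprocal-space cost matters."""
        alpha = float(erfcinv(accuracy)) / r_cut
        kmax = 2.0 * alpha * math.sqrt(math.log(1.0 / accuracy))
        return cls(alpha=alpha, kmax=kmax, r_cut=r_cut, accuracy=accuracy)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Energy components in kcal/mol; ``total`` is their exact sum."""

    lj: float = 0.0
    coul_real: float = 0.0
    coul_recip: float = 0.0
    coul_self: float = 0.0

    @property
    def coulomb(self) -> float:
        return self.coul_real + self.coul_recip + self.coul_self

    @property
    def total(self) -> float:
        return self.lj + self.coul_real + self.coul_recip + self.coul_self

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(
            self.lj + other.lj,
            self.coul_real + other.coul_real,
            self.coul_recip + other.coul_recip,
            self.coul_self + other.coul_self,
        )

    def __sub__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(
            self.lj - other.lj,
            self.coul_real - other.coul_real,
            self.coul_recip - other.coul_recip,
            self.coul_self - other.coul_self,
        )


# ---------------------------------------------------------------------------
# parameter tables


def _read_table(name: str) -> list[list[str]]:
    text = resources.files("ldhsim.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            rows.append(line.split())
    return rows


@lru_cache(maxsize=1)
def uff_table() -> dict:
    """UFF atom types keyed by label, with charge-equilibration parameters."""
    eq = eqeq_table()
    table = {}
    for label, x_i, D_i in _read_table("uff_lj.dat"):
        element = _element_of_label(label)
        chi, J = eq[element]
        table[label] = UFFAtomType(label, float(x_i), float(D_i), chi, J)
    # non-interacting probe used by tests and feasibility scans
    table["Xx"] = UFFAtomType("Xx", 0.1, 0.0, 0.0, 0.0)
    return table


def _element_of_label(label: str) -> str:
    sym = label[:2]
    if sym[-1:] in ("_", "3") or sym[-1:].isdigit() or len(label) == 1:
        sym = label[0]
    if sym in ("Na", "Mg", "Fe", "Cl"):
        return sym
    return label[0]


@lru_cache(maxsize=1)
def eqeq_table() -> dict:
    """Per-element (electronegativity chi, idempotential J), in eV."""
    return {el: (float(chi), float(J)) for el, chi, J in _read_table("eqeq.dat")}


def uff_for_element(element: str) -> UFFAtomType:
    """UFF atom type for a bare element symbol."""
    try:
        return uff_table()[DEFAULT_UFF_LABEL[element]]
    except KeyError:
        raise KeyError(
            f"no UFF parameters for element {element!r}; known: "
            f"{sorted(DEFAULT_UFF_LABEL)}"
        ) from None


def mix_lorentz_berthelot(t1: UFFAtomType, t2: UFFAtomType, cutoff: float = 12.5) -> PairPotential:
    """Lorentz-Berthelot mixing: arithmetic sigma, geometric epsilon."""
    for t in (t1, t2):
        if t.x_i <= 0 or t.D_i < 0:
            raise ValueError(f"atom type {t.label} lacks LJ parameters")
    return PairPotential(
        sigma=0.5 * (t1.sigma + t2.sigma),
        epsilon=math.sqrt(t1.D_i * t2.D_i),
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# geometry helpers shared by the exact (reference) energy routines


def _as_cell_matrix(cell) -> np.ndarray:
    """Accept a 3x3 row-vector matrix or an object with .matrix."""
    if cell is None:
        return None
    m = getattr(cell, "matrix", cell)
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise ValueError("cell must be a 3x3 matrix of row lattice vectors")
    return m


def _image_shifts(cell: np.ndarray, r_cut: float) -> np.ndarray:
    """Integer lattice shifts whose cells can hold a pair within r_cut."""
    recip = np.linalg.inv(cell.T)  # rows: reciprocal vectors /(2 pi)
    widths = 1.0 / np.linalg.norm(recip, axis=1)  # perpendicular widths
    nmax = np.ceil(r_cut / widths).astype(int)
    rng = [np.arange(-n, n + 1) for n in nmax]
    grid = np.stack(np.meshgrid(*rng, indexing="ij"), axis=-1).reshape(-1, 3)
    return grid


def min_width(cell: np.ndarray) -> float:
    """Smallest perpendicular width of the cell."""
    recip = np.linalg.inv(cell.T)
    return float(np.min(1.0 / np.linalg.norm(recip, axis=1)))


# ---------------------------------------------------------------------------
# charge equilibration


def _gaussian_widths(J: np.ndarray) -> np.ndarray:
    # hardness J equals the Coulomb self-energy of a Gaussian charge of
    # width s: J = k / (s sqrt(pi))
    return COULOMB_EV / (J * math.sqrt(math.pi))


def _shielded_coulomb(r: np.ndarray, s2_sum: np.ndarray) -> np.ndarray:
    """Interaction (eV/e^2) of two unit Gaussian charges at distance r."""
    return COULOMB_EV * erf(r / np.sqrt(2.0 * s2_sum)) / r


def _ewald_potential_matrix(coords: np.ndarray, cell: np.ndarray, params: EwaldParams) -> np.ndarray:
    """phi[i,j]: Ewald lattice potential (1/A units, multiply by k) between
    unit point charges, including each site's interaction with its own
    periodic images on the diagonal."""
    n = len(coords)
    alpha = params.alpha
    # real part
    shifts = _image_shifts(cell, params.r_cut) @ cell
    phi = np.zeros((n, n))
    d = coords[:, None, :] - coords[None, :, :]
    for s in shifts:
        r = np.linalg.norm(d + s, axis=-1)
        central = np.all(s == 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(r < params.r_cut, erfc(alpha * r) / r, 0.0)
        if central:
            np.fill_diagonal(term, 0.0)
        else:
            term[r >= params.r_cut] = 0.0
        phi += np.nan_to_num(term)
    # reciprocal part
    volume = abs(np.linalg.det(cell))
    kvecs, coeff = _k_vectors(cell, params)
    # phi_recip[i,j] = (4 pi / V) sum_k coeff_k cos(k.(ri-rj))
    phase = coords @ kvecs.T  # (n, nk)
    cosk, sink = np.cos(phase), np.sin(phase)
    w = coeff * (4.0 * math.pi / volume)
    phi += (cosk * w) @ cosk.T + (sink * w) @ sink.T
    # self (diagonal) correction
    phi[np.diag_indices(n)] -= 2.0 * alpha / math.sqrt(math.pi)
    return phi


def _k_vectors(cell: np.ndarray, params: EwaldParams):
    """Non-zero reciprocal vectors below kmax and Ewald coefficients
    exp(-k^2/4 a^2)/k^2 (full sphere)."""
    b = 2.0 * math.pi * np.linalg.inv(cell.T)  # rows: reciprocal vectors
    # bound per axis: kmax over the reciprocal-lattice row spacing
    widths = np.linalg.norm(b, axis=1)
    nmax = np.ceil(params.kmax / widths).astype(int) + 1
    rng = [np.arange(-n, n + 1) for n in nmax]
    grid = np.stack(np.meshgrid(*rng, indexing="ij"), axis=-1).reshape(-1, 3)
    grid = grid[np.any(grid != 0, axis=1)]
    kvecs = grid @ b
    k2 = np.einsum("ij,ij->i", kvecs, kvecs)
    mask = k2 <= params.kmax**2
    kvecs, k2 = kvecs[mask], k2[mask]
    coeff = np.exp(-k2 / (4.0 * params.alpha**2)) / k2
    return kvecs, coeff


def eqeq_charges(
    elements,
    coords,
    total_charge: float = 0.0,
    cell=None,
    params: EwaldParams | None = None,
) -> np.ndarray:
    """Charge-equilibration partial charges.

    Minimises ``sum_i (chi_i q_i + 1/2 J_i q_i^2) + sum_{i<j} J_ij(r) q_i q_j``
    subject to ``sum q_i = total_charge``, solved as a single linear system.
    ``J_ij`` is the Gaussian-shielded Coulomb interaction, which keeps the
    quadratic form positive definite for any geometry.  With ``cell`` given,
    the long-range part of the coupling is evaluated by Ewald summation over
    the lattice.

    Parameters are per-element (chi, J) from the packaged table.

    Returns the per-site charges; deterministic.
    """
    elements = list(elements)
    coords = np.asarray(coords, dtype=float)
    n = len(elements)
    if n == 0:
        raise ValueError("empty system")
    table = eqeq_table()
    try:
        chi = np.array([table[e][0] for e in elements])
        J = np.array([table[e][1] for e in elements])
    except KeyError as exc:
        raise KeyError(f"no charge-equilibration parameters for element {exc}") from None
    if n == 1:
        return np.array([float(total_charge)])

    s = _gaussian_widths(J)
    s2 = s**2
    cellm = _as_cell_matrix(cell)
    if cellm is None:
        d = coords[:, None, :] - coords[None, :, :]
        r = np.linalg.norm(d, axis=-1)
        iu = ~np.eye(n, dtype=bool)
        A = np.zeros((n, n))
        A[iu] = _shielded_coulomb(r[iu], (s2[:, None] + s2[None, :])[iu])
    else:
        if params is None:
            params = EwaldParams.from_accuracy(1e-5, r_cut=min(12.5, 0.49 * min_width(cellm)))
        A = COULOMB_EV * _ewald_potential_matrix(coords, cellm, params)
        # short-range shielding correction on the nearest image
        d = coords[:, None, :] - coords[None, :, :]
        frac = d @ np.linalg.inv(cellm)
        frac -= np.round(frac)
        r = np.linalg.norm(frac @ cellm, axis=-1)
        near = (r < 8.0) & ~np.eye(n, dtype=bool)
        s2sum = s2[:, None] + s2[None, :]
        corr = np.zeros((n, n))
        corr[near] = _shielded_coulomb(r[near], s2sum[near]) - COULOMB_EV / r[near]
        A += corr
    A[np.diag_indices(n)] += J

    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = A
    M[:n, n] = 1.0
    M[n, :n] = 1.0
    rhs = np.concatenate([-chi, [total_charge]])
    try:
        sol = np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError(
            "singular charge-equilibration system; geometry may be degenerate "
            "(coincident sites)"
        ) from None
    return sol[:n]


# ---------------------------------------------------------------------------
# exact (reference) energies


def _lj_params_for(types) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom (sigma, epsilon) arrays from labels/elements/UFFAtomTypes."""
    table = uff_table()
    sig, eps = [], []
    for i, t in enumerate(types):
        if isinstance(t, UFFAtomType):
            at = t
        elif t in table:
            at = table[t]
        elif t in DEFAULT_UFF_LABEL:
            at = table[DEFAULT_UFF_LABEL[t]]
        else:
            raise KeyError(f"atom {i}: unknown UFF type {t!r}")
        sig.append(at.sigma)
        eps.append(at.D_i)
    return np.array(sig), np.array(eps)


def lj_energy(coords, types, cell=None, cutoff: float = 12.5) -> float:
    """Total truncated LJ energy (kcal/mol), Lorentz-Berthelot mixed.

    Periodic systems require every periodic direction to accommodate the
    minimum-image convention (cell width >= 2*cutoff).
    """
    coords = np.asarray(coords, dtype=float)
    sig, eps = _lj_params_for(types)
    cellm = _as_cell_matrix(cell)
    if cellm is not None and min_width(cellm) < 2.0 * cutoff:
        raise ValueError(
            f"cell too small for minimum image at cutoff {cutoff} A "
            f"(smallest width {min_width(cellm):.2f} < {2*cutoff} A)"
        )
    d = coords[:, None, :] - coords[None, :, :]
    if cellm is not None:
        frac = d @ np.linalg.inv(cellm)
        frac -= np.round(frac)
        d = frac @ cellm
    r = np.linalg.norm(d, axis=-1)
    iu = np.triu_indices(len(coords), k=1)
    r = r[iu]
    smix = 0.5 * (sig[iu[0]] + sig[iu[1]])
    emix = np.sqrt(eps[iu[0]] * eps[iu[1]])
    mask = r < cutoff
    sr6 = (smix[mask] / r[mask]) ** 6
    return float(np.sum(4.0 * emix[mask] * (sr6 * sr6 - sr6)))


def ewald_energy(coords, charges, cell, params: EwaldParams | None = None) -> EnergyBreakdown:
    """Full Ewald Coulomb energy of a neutral periodic system (kcal/mol).

    Slab models are treated as 3D periodic with their vacuum gap; no
    background correction is applied, so non-neutral systems are rejected.
    """
    charges = np.asarray(charges, dtype=float)
    if abs(charges.sum()) > 1e-8:
        raise ValueError(
            f"non-neutral periodic system (net charge {charges.sum():.3g} e); "
            "no background correction is implemented"
        )
    return _ewald_raw(coords, charges, cell, params)


def _ewald_raw(coords, charges, cell, params: EwaldParams | None = None) -> EnergyBreakdown:
    """Ewald sum without the neutrality check.

    For a net-charged set of sites this is the energy in a uniform
    neutralising background (the k=0 term is dropped); differences of such
    terms for subsystems of one neutral system are well defined.
    """
    coords = np.asarray(coords, dtype=float)
    charges = np.asarray(charges, dtype=float)
    cellm = _as_cell_matrix(cell)
    if params is None:
        params = EwaldParams.from_accuracy(1e-6, r_cut=min(12.5, 0.49 * min_width(cellm)))
    if not np.any(charges):
        return EnergyBreakdown()
    alpha = params.alpha
    n = len(coords)

    # real space over images
    shifts = _image_shifts(cellm, params.r_cut) @ cellm
    e_real = 0.0
    d = coords[:, None, :] - coords[None, :, :]
    qq = charges[:, None] * charges[None, :]
    for svec in shifts:
        r = np.linalg.norm(d + svec, axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where((r < params.r_cut) & (r > 1e-12), erfc(alpha * r) / r, 0.0)
        e_real += 0.5 * float(np.sum(qq * term))

    # reciprocal space
    volume = abs(np.linalg.det(cellm))
    kvecs, coeff = _k_vectors(cellm, params)
    phase = coords @ kvecs.T
    S_re = charges @ np.cos(phase)
    S_im = charges @ np.sin(phase)
    e_recip = (2.0 * math.pi / volume) * float(np.sum(coeff * (S_re**2 + S_im**2)))

    e_self = -alpha / math.sqrt(math.pi) * float(np.sum(charges**2))
    C = COULOMB_KCAL
    return EnergyBreakdown(0.0, C * e_real, C * e_recip, C * e_self)


def total_energy(framework, guests, ewald_params: EwaldParams | None = None, cutoff: float = 12.5) -> EnergyBreakdown:
    """Host-guest interaction energy: framework-guest plus guest-guest LJ and
    Coulomb.  The framework-framework internal energy is excluded (the
    framework is rigid, so it is an additive constant).

    ``framework`` must expose ``cartesian_coords``, ``charges``, ``elements``
    and a ``cell`` (3x3 or UnitCell); guests expose ``world_coords``,
    ``charges`` and ``elements`` (see :class:`ldhsim.structure.GuestMolecule`).
    """
    cellm = _as_cell_matrix(framework.cell)
    fw_xyz = np.asarray(framework.cartesian_coords, dtype=float)
    fw_q = np.asarray(framework.charges, dtype=float)
    fw_el = list(framework.elements)
    for i, e in enumerate(fw_el):
        if e not in DEFAULT_UFF_LABEL:
            raise KeyError(f"framework atom {i} has untyped element {e!r}")
    if not guests:
        return EnergyBreakdown()

    def stacked(items):
        xyz = np.vstack([fw_xyz] + [np.asarray(g.world_coords, float) for g in items])
        q = np.concatenate([fw_q] + [np.asarray(g.charges, float) for g in items])
        el = fw_el + sum((list(g.elements) for g in items), [])
        return xyz, q, el

    xyz_all, q_all, el_all = stacked(guests)
    if ewald_params is None:
        ewald_params = EwaldParams.from_accuracy(1e-5, r_cut=min(cutoff, 0.49 * min_width(cellm)))
    if abs(q_all.sum()) > 1e-8:
        raise ValueError(
            f"framework plus guests is non-neutral (net {q_all.sum():.3g} e)"
        )
    # subsystem terms may individually be net-charged (e.g. a bare layer
    # framework); their background-corrected difference is well defined
    e_c = _ewald_raw(xyz_all, q_all, cellm, ewald_params) - _ewald_raw(
        fw_xyz, fw_q, cellm, ewald_params
    )
    e_lj_all = lj_energy(xyz_all, el_all, cellm, cutoff)
    e_lj_fw = lj_energy(fw_xyz, fw_el, cellm, cutoff)
    return EnergyBreakdown(e_lj_all - e_lj_fw, e_c.coul_real, e_c.coul_recip, e_c.coul_self)
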