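"""Pyroaurite-type layered double hydroxide structure builder.

Builds periodic atomistic models of MgFe-carbonate LDH
([Mg(1-x)Fe(x)(OH)2]^(x+) brucite-like layers with charge-compensating
carbonate and water in the interlayer galleries), plus supercells and
vacuum slabs for external-surface work.

Geometry conventions: hexagonal setting (alpha=beta=90, gamma=120), right
handed cells, three metal layers per cell along c (rhombohedral stacking),
fractional coordinates internally and cartesian angstroms at interfaces.
The printed lattice constant of the real material (a = 12.4 A) is an
integer multiple of the ~3.1 A metal-metal spacing; the builder tiles metal
sites at that spacing to fill whatever `a` is supplied.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import forcefield as ff
from .units import ATOMIC_MASS

__all__ = [
    "UnitCell",
    "AtomSite",
    "Framework",
    "SlabModel",
    "GuestMolecule",
    "build_pyroaurite",
    "build_supercell",
    "build_slab",
    "place_compensating_anions",
    "detach_molecules",
    "surface_hydroxyl_indices",
]

#: ideal metal-metal spacing within a brucite-like layer (A)
METAL_SPACING = 3.1
#: metal-oxygen bond length in the octahedral layer (A)
M_O_BOND = 2.10
#: hydroxyl O-H bond length (A)
O_H_BOND = 0.96
#: metal layers per hexagonal cell (rhombohedral stacking)
LAYERS_PER_CELL = 3

_CHARGE_TOL = 1e-9


# ---------------------------------------------------------------------------
# cells and sites


@dataclass(frozen=True)
class UnitCell:
    """Lattice lengths (A) and angles (deg)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("lattice lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")

    @classmethod
    def hexagonal(cls, a: float, c: float) -> "UnitCell":
        return cls(a, a, c, 90.0, 90.0, 120.0)

    @property
    def is_hexagonal(self) -> bool:
        return (
            abs(self.a - self.b) < 1e-6
            and abs(self.alpha - 90.0) < 1e-6
            and abs(self.beta - 90.0) < 1e-6
            and abs(self.gamma - 120.0) < 1e-6
        )

    @property
    def matrix(self) -> np.ndarray:
        """3x3 matrix of row lattice vectors (right handed)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v1 = [self.a, 0.0, 0.0]
        v2 = [self.b * cg, self.b * sg, 0.0]
        cx = self.c * cb
        cy = self.c * (ca - cb * cg) / sg
        cz = self.c * math.sqrt(max(0.0, 1.0 - cb**2 - ((ca - cb * cg) / sg) ** 2))
        return np.array([v1, v2, [cx, cy, cz]])

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.matrix)))


@dataclass
class AtomSite:
    """One framework site: element, wrapped fractional coordinates, partial
    charge (e) and UFF label, plus bookkeeping tags (species, molecule id)."""

    element: str
    frac: np.ndarray
    charge: float = 0.0
    uff_type: str = ""
    species: str = "layer"
    mol_id: int = -1


def wrap_frac(frac: np.ndarray) -> np.ndarray:
    """Wrap fractional coordinates into [0, 1). Idempotent."""
    out = np.mod(np.asarray(frac, dtype=float), 1.0)
    out[out >= 1.0] = 0.0  # np.mod(-tiny, 1) rounds to exactly 1.0
    return out


class Framework:
    """A periodic LDH model: cell, sites, periodicity flags and metadata.

    Stored internally as flat arrays for speed; :attr:`sites` exposes the
    per-atom view.  Molecular species in the galleries carry a ``mol_id``
    so they can be manipulated (or detached as rigid guests) as units.
    """

    def __init__(
        self,
        cell: UnitCell,
        frac_coords,
        elements,
        charges=None,
        uff_labels=None,
        species=None,
        mol_ids=None,
        periodic=(True, True, True),
        metadata=None,
    ):
        self.cell = cell
        self.frac_coords = wrap_frac(np.atleast_2d(np.asarray(frac_coords, dtype=float)))
        n = len(self.frac_coords)
        self.elements = list(elements)
        if len(self.elements) != n:
            raise ValueError("elements/coords length mismatch")
        self.charges = (
            np.zeros(n) if charges is None else np.asarray(charges, dtype=float).copy()
        )
        self.uff_labels = (
            [ff.DEFAULT_UFF_LABEL[e] for e in self.elements]
            if uff_labels is None
            else list(uff_labels)
        )
        self.species = ["layer"] * n if species is None else list(species)
        self.mol_ids = (
            np.full(n, -1, dtype=int) if mol_ids is None else np.asarray(mol_ids, dtype=int).copy()
        )
        self.periodic = tuple(periodic)
        self.metadata = dict(metadata or {})

    # -- views ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.frac_coords)

    @property
    def sites(self) -> list[AtomSite]:
        return [
            AtomSite(
                self.elements[i],
                self.frac_coords[i].copy(),
                float(self.charges[i]),
                self.uff_labels[i],
                self.species[i],
                int(self.mol_ids[i]),
            )
            for i in range(len(self))
        ]

    @property
    def cartesian_coords(self) -> np.ndarray:
        return self.frac_coords @ self.cell.matrix

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def count(self, element: str) -> int:
        return self.elements.count(element)

    def copy(self) -> "Framework":
        return Framework(
            self.cell,
            self.frac_coords.copy(),
            list(self.elements),
            self.charges.copy(),
            list(self.uff_labels),
            list(self.species),
            self.mol_ids.copy(),
            self.periodic,
            dict(self.metadata),
        )

    def wrap(self) -> "Framework":
        """Re-wrap all fractional coordinates into the primary cell."""
        self.frac_coords = wrap_frac(self.frac_coords)
        return self

    # -- molecule-aware helpers -------------------------------------------

    def molecule_indices(self, species: str | None = None) -> dict[int, np.ndarray]:
        """Map mol_id -> atom index array, optionally restricted by species."""
        out: dict[int, list[int]] = {}
        for i, m in enumerate(self.mol_ids):
            if m < 0:
                continue
            if species is not None and self.species[i] != species:
                continue
            out.setdefault(int(m), []).append(i)
        return {k: np.array(v) for k, v in out.items()}

    def unwrapped_cartesian(self) -> np.ndarray:
        """Cartesian coordinates with each gallery molecule made whole
        (atoms pulled to the periodic image nearest the molecule's first
        atom)."""
        frac = self.frac_coords.copy()
        for idx in self.molecule_indices().values():
            ref = frac[idx[0]]
            d = frac[idx] - ref
            frac[idx] = ref + (d - np.round(d))
        return frac @ self.cell.matrix

    # -- I/O ----------------------------------------------------------------

    def to_cif(self, path_or_buf) -> None:
        """Write a P1 CIF with fractional coordinates and per-site charges."""
        m = self.cell
        buf = io.StringIO()
        buf.write("data_ldhsim\n")
        buf.write(f"_cell_length_a {m.a:.6f}\n_cell_length_b {m.b:.6f}\n")
        buf.write(f"_cell_length_c {m.c:.6f}\n_cell_angle_alpha {m.alpha:.4f}\n")
        buf.write(f"_cell_angle_beta {m.beta:.4f}\n_cell_angle_gamma {m.gamma:.4f}\n")
        buf.write("_symmetry_space_group_name_H-M 'P 1'\n_symmetry_Int_Tables_number 1\n")
        buf.write(
            "loop_\n_atom_site_label\n_atom_site_type_symbol\n"
            "_atom_site_fract_x\n_atom_site_fract_y\n_atom_site_fract_z\n"
            "_atom_site_charge\n"
        )
        for i in range(len(self)):
            f = self.frac_coords[i]
            buf.write(
                f"{self.elements[i]}{i+1} {self.elements[i]} "
                f"{f[0]:.6f} {f[1]:.6f} {f[2]:.6f} {self.charges[i]:.6f}\n"
            )
        text = buf.getvalue()
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_cif(cls, path) -> "Framework":
        import gemmi

        doc = gemmi.cif.read(str(path))
        block = doc.sole_block()
        cell = UnitCell(
            *(float(block.find_value(f"_cell_length_{x}")) for x in ("a", "b", "c")),
            *(
                float(block.find_value(f"_cell_angle_{x}"))
                for x in ("alpha", "beta", "gamma")
            ),
        )
        els, fracs, charges = [], [], []
        table = block.find(
            "_atom_site_",
            ["type_symbol", "fract_x", "fract_y", "fract_z", "charge"],
        )
        for row in table:
            els.append(row[0])
            fracs.append([float(row[1]), float(row[2]), float(row[3])])
            charges.append(float(row[4]))
        return cls(cell, np.array(fracs), els, np.array(charges))

    def to_xyz(self, path_or_buf, comment: str = "") -> None:
        """Extended XYZ with the lattice in the comment line."""
        m = self.cell.matrix.reshape(-1)
        lattice = " ".join(f"{x:.6f}" for x in m)
        lines = [
            str(len(self)),
            f'Lattice="{lattice}" Properties=species:S:1:pos:R:3:charge:R:1 {comment}'.rstrip(),
        ]
        xyz = self.cartesian_coords
        for i in range(len(self)):
            x, y, z = xyz[i]
            lines.append(f"{self.elements[i]} {x:.6f} {y:.6f} {z:.6f} {self.charges[i]:.6f}")
        text = "\n".join(lines) + "\n"
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)


@dataclass
class SlabModel:
    """A framework with a vacuum gap along one axis (default c).

    The vacuum must be at least twice the LJ cutoff so that periodic images
    do not interact through the gap.
    """

    framework: Framework
    vacuum: float
    surface_normal: int = 2


# ---------------------------------------------------------------------------
# rigid guests


def quat_normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q / np.linalg.norm(q)


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a unit quaternion (w, x, y, z)."""
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def random_rotation_quat(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation (Shoemake)."""
    u1, u2, u3 = rng.random(3)
    a, b = math.sqrt(1 - u1), math.sqrt(u1)
    return np.array(
        [
            a * math.sin(2 * math.pi * u2),
            a * math.cos(2 * math.pi * u2),
            b * math.sin(2 * math.pi * u3),
            b * math.cos(2 * math.pi * u3),
        ]
    )


def axis_angle_quat(axis, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return np.concatenate([[math.cos(angle / 2)], math.sin(angle / 2) * axis])


@dataclass
class GuestMolecule:
    """A rigid molecular adsorbate.

    ``local_coords`` are body-frame cartesian coordinates (A); the world
    pose is given by ``center`` and the unit quaternion ``orientation``.
    """

    name: str
    elements: list
    local_coords: np.ndarray
    charges: np.ndarray
    net_charge: float
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0]))

    def __post_init__(self):
        self.local_coords = np.atleast_2d(np.asarray(self.local_coords, dtype=float))
        self.charges = np.asarray(self.charges, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if abs(self.charges.sum() - self.net_charge) > _CHARGE_TOL:
            raise ValueError(
                f"{self.name}: charges sum to {self.charges.sum():.12f}, "
                f"declared net charge {self.net_charge}"
            )
        if abs(np.linalg.norm(self.orientation) - 1.0) > 1e-12:
            raise ValueError(f"{self.name}: orientation quaternion not normalized")

    @property
    def n_atoms(self) -> int:
        return len(self.local_coords)

    @property
    def world_coords(self) -> np.ndarray:
        return self.center + self.local_coords @ quat_to_matrix(self.orientation).T

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([e != "H" for e in self.elements])

    def with_pose(self, center=None, orientation=None) -> "GuestMolecule":
        return replace(
            self,
            center=self.center if center is None else np.asarray(center, float),
            orientation=(
                self.orientation if orientation is None else quat_normalize(orientation)
            ),
        )

    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASS[e] for e in self.elements])


# ---------------------------------------------------------------------------
# builders


def _layer_geometry(cell: UnitCell):
    """Per-layer geometry: in-plane divisions and hydroxyl O height."""
    n_div = max(1, round(cell.a / METAL_SPACING))
    a0 = cell.a / n_div
    in_plane = a0 / math.sqrt(3.0)  # metal->hollow in-plane distance
    dz_o = math.sqrt(max(0.0, M_O_BOND**2 - in_plane**2))
    return n_div, dz_o


#: balanced layer charge set: hydroxyl values of CLAYFF-like magnitude,
#: metal charges then fixed exactly by the layer charge (+1 per Fe)
LAYER_CHARGE_O = -0.95
LAYER_CHARGE_H = 0.425


def build_pyroaurite(
    x: float,
    n_water: float,
    cell: UnitCell,
    seed: int = 0,
    charge_method: str = "balanced",
) -> Framework:
    """Build one hexagonal cell of MgFe-carbonate LDH.

    Parameters
    ----------
    x : trivalent (Fe) cation fraction, 0 < x < 1/2.  Fe sites are chosen on
        a sublattice with no Fe-Fe nearest neighbours, deterministically for
        a given ``seed``.
    n_water : water molecules per M8(OH)16-type formula unit (8 metals).
    cell : hexagonal cell; ``a`` is tiled with metal sites at ~3.1 A
        spacing, three metal layers stack along ``c``.
    charge_method : ``"balanced"`` (default) assigns hydroxyl O/H charges of
        hydroxide-force-field magnitude and solves the metal charges from
        exact layer charge balance (Mg +1.05, Fe +2.05 at x=1/4);
        ``"eqeq"`` runs periodic charge equilibration instead (which
        over-polarizes dense ionic layers with the shipped generic
        parameters — see the methods note).

    The interlayer holds one carbonate per two Fe (charge balance) and the
    requested water, placed at seeded random non-overlapping positions at
    the gallery midplanes.  Molecular species carry their fixture charge
    sets, so the total system charge is zero by construction.
    """
    if not 0.0 < x < 0.5:
        raise ValueError(f"trivalent fraction x={x} outside (0, 1/2)")
    if not cell.is_hexagonal:
        raise ValueError("build_pyroaurite requires a hexagonal cell (a=b, 90/90/120)")

    n_div, dz_o = _layer_geometry(cell)
    n_metal_layer = n_div * n_div
    n_metals = n_metal_layer * LAYERS_PER_CELL
    n_fe_f = x * n_metals
    if abs(n_fe_f - round(n_fe_f)) > 1e-9:
        raise ValueError(
            f"x={x} gives a non-integer Fe count ({n_fe_f:.3f}) for "
            f"{n_metals} metal sites; choose x = k/{n_metals}"
        )
    n_fe = round(n_fe_f)
    if n_fe % 2:
        raise ValueError(
            f"x={x} gives {n_fe} Fe per cell, an odd number; carbonate "
            "charge balance needs an even Fe count"
        )
    if n_fe % LAYERS_PER_CELL:
        raise ValueError(
            f"{n_fe} Fe per cell does not distribute evenly over "
            f"{LAYERS_PER_CELL} layers"
        )
    n_carb = n_fe // 2
    n_fu = n_metals / 8.0
    n_wat_f = n_water * n_fu
    if abs(n_wat_f - round(n_wat_f)) > 1e-9:
        raise ValueError(
            f"n_water={n_water} gives a non-integer water count "
            f"({n_wat_f:.3f}) for {n_fu} formula units"
        )
    n_wat = round(n_wat_f)

    rng = np.random.default_rng(seed)
    dz_o_frac = dz_o / cell.c
    dz_h_frac = (dz_o + O_H_BOND) / cell.c

    frac, elements, species = [], [], []
    fe_per_layer = n_fe // LAYERS_PER_CELL

    for k in range(LAYERS_PER_CELL):
        zc = (k + 0.5) / LAYERS_PER_CELL
        # rhombohedral-like lateral shift per layer, in cell fractions
        su, sv = (2 * k) / (3 * n_div), k / (3 * n_div)
        fe_flags = _choose_fe_sites(n_div, fe_per_layer, rng)
        for i in range(n_div):
            for j in range(n_div):
                u, v = (i + su) / n_div, (j + sv) / n_div
                elements.append("Fe" if fe_flags[i, j] else "Mg")
                species.append("layer")
                frac.append([u, v, zc])
        for i in range(n_div):
            for j in range(n_div):
                # hollow sites of the triangular metal lattice
                uo_up = (i + su + 2.0 / 3.0) / n_div
                vo_up = (j + sv + 1.0 / 3.0) / n_div
                uo_dn = (i + su + 1.0 / 3.0) / n_div
                vo_dn = (j + sv + 2.0 / 3.0) / n_div
                for (u, v, sgn) in ((uo_up, vo_up, 1.0), (uo_dn, vo_dn, -1.0)):
                    frac.append([u, v, zc + sgn * dz_o_frac])
                    elements.append("O")
                    species.append("layer")
                    frac.append([u, v, zc + sgn * dz_h_frac])
                    elements.append("H")
                    species.append("layer")

    frac = np.array(frac)
    n_layer_atoms = len(frac)
    fw = Framework(
        cell,
        frac,
        elements,
        species=species,
        metadata={
            "x": x,
            "n_water_per_fu": n_water,
            "composition": f"Mg{n_metals-n_fe}Fe{n_fe}(OH){2*n_metals}"
            f"(CO3){n_carb}(H2O){n_wat}",
            "seed": seed,
        },
    )

    if charge_method == "eqeq":
        fw.charges[:n_layer_atoms] = ff.eqeq_charges(
            fw.elements, fw.cartesian_coords, total_charge=float(n_fe), cell=cell.matrix
        )
    elif charge_method == "balanced":
        # layer charge +1 per Fe; qFe = qMg + 1 (formal difference), so
        # n_metals*qMg + n_fe + n_OH*(qO+qH) = n_fe
        q_mg = -2.0 * (LAYER_CHARGE_O + LAYER_CHARGE_H)
        lut = {"Mg": q_mg, "Fe": q_mg + 1.0, "O": LAYER_CHARGE_O, "H": LAYER_CHARGE_H}
        fw.charges[:n_layer_atoms] = [lut[e] for e in fw.elements[:n_layer_atoms]]
    else:
        raise ValueError(f"unknown charge_method {charge_method!r}")

    _place_gallery_molecules(fw, n_carb, n_wat, rng)
    if abs(fw.net_charge) > 1e-6:
        raise AssertionError("charge bookkeeping error in builder")
    # spread residual solver noise so neutrality is exact
    fw.charges[:n_layer_atoms] -= fw.net_charge / n_layer_atoms
    return fw


def _choose_fe_sites(n_div: int, n_fe: int, rng: np.random.Generator) -> np.ndarray:
    """Fe occupancy on an n_div x n_div periodic triangular lattice with no
    Fe-Fe nearest neighbours; deterministic for a given rng state."""
    if n_fe == 0:
        return np.zeros((n_div, n_div), dtype=bool)
    # nearest neighbours of (i,j) on the triangular lattice in this setting
    nbrs = [(1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (-1, -1)]
    sites = [(i, j) for i in range(n_div) for j in range(n_div)]
    for _attempt in range(500):
        order = rng.permutation(len(sites))
        flags = np.zeros((n_div, n_div), dtype=bool)
        placed = 0
        for idx in order:
            i, j = sites[idx]
            if any(flags[(i + di) % n_div, (j + dj) % n_div] for di, dj in nbrs):
                continue
            flags[i, j] = True
            placed += 1
            if placed == n_fe:
                return flags
    raise ValueError(
        f"cannot place {n_fe} Fe on a {n_div}x{n_div} layer without "
        "Fe-Fe nearest neighbours"
    )


def _molecule_templates():
    """Local geometries/charges for gallery species (fixture charge sets)."""
    from .synthetic import get_fixture

    return {"carbonate": get_fixture("carbonate"), "water": get_fixture("water")}


def _place_gallery_molecules(fw: Framework, n_carb: int, n_wat: int, rng) -> None:
    """Random, non-overlapping placement of carbonate + water at the gallery
    midplanes (carbonates flat-lying), split evenly across galleries."""
    tmpl = _molecule_templates()
    cellm = fw.cell.matrix
    inv = np.linalg.inv(cellm)
    existing = [fw.cartesian_coords]
    existing_is_h = [np.array([e == "H" for e in fw.elements])]

    plan = []
    for k in range(LAYERS_PER_CELL):
        gz = k / LAYERS_PER_CELL  # gallery midplane (layer centers at k+1/2)
        plan += [("carbonate", gz)] * (n_carb // LAYERS_PER_CELL)
    for r in range(n_carb % LAYERS_PER_CELL):
        plan.append(("carbonate", r / LAYERS_PER_CELL))
    for k in range(LAYERS_PER_CELL):
        plan += [("water", k / LAYERS_PER_CELL)] * (n_wat // LAYERS_PER_CELL)
    for r in range(n_wat % LAYERS_PER_CELL):
        plan.append(("water", r / LAYERS_PER_CELL))

    mol_id = int(fw.mol_ids.max()) + 1 if len(fw.mol_ids) else 0
    placed_counts = {"carbonate": 0, "water": 0}
    for species, gz in plan:
        g = tmpl[species]
        local = g.local_coords - g.local_coords.mean(axis=0)
        ok = False
        for _ in range(5000):
            u, v = rng.random(2)
            if species == "carbonate":
                # flat-lying, random azimuthal rotation, small z jitter
                q = axis_angle_quat([0, 0, 1.0], rng.random() * 2 * math.pi)
                dz = rng.uniform(-0.4, 0.4)
            else:
                q = random_rotation_quat(rng)
                dz = rng.uniform(-0.85, 0.85)
            center = np.array([u, v, gz]) @ cellm + np.array([0.0, 0.0, dz])
            xyz = center + local @ quat_to_matrix(q).T
            if _overlaps(xyz, g.elements, existing, existing_is_h, cellm, inv):
                continue
            ok = True
            break
        if not ok:
            raise RuntimeError(
                f"could not place {species} #{placed_counts[species]+1} "
                f"without overlap (placed so far: {placed_counts})"
            )
        placed_counts[species] += 1
        frac_new = wrap_frac(xyz @ inv)
        fw.frac_coords = np.vstack([fw.frac_coords, frac_new])
        fw.elements += list(g.elements)
        fw.charges = np.concatenate([fw.charges, g.charges])
        fw.uff_labels += [ff.DEFAULT_UFF_LABEL[e] for e in g.elements]
        fw.species += [species] * len(g.elements)
        fw.mol_ids = np.concatenate([fw.mol_ids, np.full(len(g.elements), mol_id)])
        mol_id += 1
        existing.append(xyz)
        existing_is_h.append(np.array([e == "H" for e in g.elements]))


def _overlaps(xyz, elements, existing, existing_is_h, cellm, inv) -> bool:
    is_h_new = np.array([e == "H" for e in elements])
    for other, other_h in zip(existing, existing_is_h):
        d = xyz[:, None, :] - other[None, :, :]
        f = d @ inv
        f -= np.round(f)
        r = np.linalg.norm(f @ cellm, axis=-1)
        heavy_pair = (~is_h_new[:, None]) & (~other_h[None, :])
        if np.any(r[heavy_pair] < 2.3) or np.any(r[~heavy_pair] < 1.7):
            return True
    return False


def build_supercell(f: Framework, reps) -> Framework:
    """Tile a framework by (na, nb, nc); charges and tags are preserved."""
    na, nb, nc = (int(r) for r in reps)
    if min(na, nb, nc) < 1:
        raise ValueError(f"supercell repetitions must be >= 1, got {reps}")
    cell = f.cell
    new_cell = UnitCell(
        cell.a * na, cell.b * nb, cell.c * nc, cell.alpha, cell.beta, cell.gamma
    )
    if (na, nb, nc) == (1, 1, 1):
        out = f.copy()
        out.metadata = {**f.metadata, "supercell": (1, 1, 1)}
        return out
    fracs, charges, mol_ids = [], [], []
    elements, labels, species = [], [], []
    n_mols = int(f.mol_ids.max()) + 1 if np.any(f.mol_ids >= 0) else 0
    # tile molecule-unwrapped coordinates so gallery molecules that straddle
    # the unit-cell boundary stay whole within each copy
    base_frac = f.unwrapped_cartesian() @ np.linalg.inv(f.cell.matrix)
    block = 0
    for i in range(na):
        for j in range(nb):
            for k in range(nc):
                shift = np.array([i, j, k], dtype=float)
                fracs.append((base_frac + shift) / np.array([na, nb, nc]))
                charges.append(f.charges)
                elements += f.elements
                labels += f.uff_labels
                species += f.species
                mids = f.mol_ids.copy()
                mids[mids >= 0] += block * n_mols
                mol_ids.append(mids)
                block += 1
    return Framework(
        new_cell,
        np.vstack(fracs),
        elements,
        np.concatenate(charges),
        labels,
        species,
        np.concatenate(mol_ids),
        f.periodic,
        {**f.metadata, "supercell": (na, nb, nc)},
    )


def build_slab(
    f: Framework,
    n_layers: int | None = None,
    vacuum: float = 30.0,
    cutoff: float = 12.5,
) -> SlabModel:
    """Open a vacuum gap along c, exposing the outer hydroxyl layers.

    The cell stays periodic in a and b; c is extended by ``vacuum``.  The
    gallery cut by the cell boundary keeps its molecules whole; they end up
    lying on the exposed low-z face.  ``n_layers`` restricts how many metal
    layers are kept (default: all), counted from the bottom.

    ``vacuum`` must be at least twice the LJ cutoff so that periodic images
    cannot interact through the gap.
    """
    if vacuum < 2.0 * cutoff:
        raise ValueError(
            f"vacuum={vacuum} A violates the slab contract: the gap must be "
            f">= 2 x cutoff = {2*cutoff} A so periodic images cannot "
            "interact through it"
        )
    if n_layers is not None and n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    xyz = f.unwrapped_cartesian().copy()
    cell = f.cell
    # pull molecules whose unwrapped center lies in the top half-gallery
    # down by c, making the boundary gallery contiguous around z ~ 0
    nc = f.metadata.get("supercell", (1, 1, 1))[2]
    half_gap = 0.5 * cell.c / (LAYERS_PER_CELL * max(1, nc))
    for idx in f.molecule_indices().values():
        if xyz[idx, 2].mean() > cell.c - half_gap:
            xyz[idx, 2] -= cell.c

    keep = np.ones(len(xyz), dtype=bool)
    total_layers = _count_metal_layers(f)
    if n_layers is not None and n_layers < total_layers:
        z_metal = np.sort(np.unique(np.round(xyz[_metal_mask(f), 2], 3)))
        z_cut = 0.5 * (z_metal[n_layers - 1] + z_metal[n_layers])
        keep = xyz[:, 2] < z_cut

    xyz = xyz[keep]
    xyz[:, 2] -= xyz[:, 2].min()

    # the gap is measured from the actual content extent (gallery molecules
    # on the exposed face protrude slightly past the bulk c), so the
    # periodic-image separation across the gap is exactly `vacuum`
    thickness = float(xyz[:, 2].max())
    new_cell = UnitCell(
        cell.a, cell.b, thickness + vacuum, cell.alpha, cell.beta, cell.gamma
    )
    frac = xyz @ np.linalg.inv(new_cell.matrix)
    slab_fw = Framework(
        new_cell,
        frac,
        [e for e, k in zip(f.elements, keep) if k],
        f.charges[keep],
        [lbl for lbl, k in zip(f.uff_labels, keep) if k],
        [s for s, k in zip(f.species, keep) if k],
        f.mol_ids[keep],
        (True, True, True),
        {**f.metadata, "slab_vacuum": vacuum},
    )
    return SlabModel(slab_fw, vacuum, 2)


def _metal_mask(f: Framework) -> np.ndarray:
    return np.array([e in ("Mg", "Fe") for e in f.elements])


def _count_metal_layers(f: Framework) -> int:
    z = f.frac_coords[_metal_mask(f), 2]
    return len(np.unique(np.round(z, 4)))


def place_compensating_anions(
    f: Framework,
    anion: GuestMolecule | None = None,
    variant: str = "carbonate_only",
    n_units: int = 1,
    seed: int = 0,
) -> Framework:
    """Adjust the gallery anion content under one of the neutrality schemes.

    ``carbonate_only``
        ensure the stoichiometric carbonate content (one CO3 per two Fe),
        placing any missing carbonates.
    ``alginate_with_sodium``
        add ``n_units`` alginate monomers (2-) each accompanied by two Na+,
        a net-neutral addition alongside the existing carbonate.
    ``alginate_replacing_carbonate``
        remove ``n_units`` carbonates and add the same number of alginate
        monomers as compensating anions.

    The returned framework is exactly neutral; placement fails with an
    error reporting the achieved count if no overlap-free position exists.
    """
    from .synthetic import get_fixture

    variants = ("carbonate_only", "alginate_with_sodium", "alginate_replacing_carbonate")
    if variant not in variants:
        raise ValueError(f"variant must be one of {variants}")
    out = f.copy()
    rng = np.random.default_rng(seed)

    if variant == "carbonate_only":
        n_fe = out.count("Fe")
        have = len(out.molecule_indices("carbonate"))
        want = n_fe // 2
        if have < want:
            _place_gallery_molecules(out, want - have, 0, rng)
        return out

    if variant == "alginate_replacing_carbonate":
        carbs = out.molecule_indices("carbonate")
        if len(carbs) < n_units:
            raise ValueError(
                f"only {len(carbs)} carbonates available, cannot replace {n_units}"
            )
        drop = np.concatenate([carbs[k] for k in sorted(carbs)[:n_units]])
        keep = np.ones(len(out), dtype=bool)
        keep[drop] = False
        out = Framework(
            out.cell,
            out.frac_coords[keep],
            [e for e, k in zip(out.elements, keep) if k],
            out.charges[keep],
            [l for l, k in zip(out.uff_labels, keep) if k],
            [s for s, k in zip(out.species, keep) if k],
            out.mol_ids[keep],
            out.periodic,
            out.metadata,
        )
        additions = ["alginate_monomer"] * n_units
    else:
        additions = ["alginate_monomer"] * n_units + ["sodium"] * (2 * n_units)

    placed = 0
    for name in additions:
        g = anion if (name == "alginate_monomer" and anion is not None) else get_fixture(name)
        try:
            _place_single(out, g, rng)
            placed += 1
        except RuntimeError as exc:
            raise RuntimeError(
                f"placed {placed}/{len(additions)} species before failing: {exc}"
            ) from exc
    if abs(out.net_charge) > 1e-6:
        raise AssertionError("neutrality scheme failed to balance charge")
    return out


def _place_single(fw: Framework, g, rng) -> None:
    """Place one guest at a seeded random overlap-free position: in the
    gallery midplanes for a bulk framework, just outside the exposed faces
    for a slab (where bulky species such as the alginate monomer fit)."""
    cellm = fw.cell.matrix
    inv = np.linalg.inv(cellm)
    local = g.local_coords - g.local_coords.mean(axis=0)
    existing = [fw.cartesian_coords]
    existing_is_h = [np.array([e == "H" for e in fw.elements])]
    radius = float(np.linalg.norm(local, axis=1).max()) if len(local) > 1 else 0.0
    is_slab = "slab_vacuum" in fw.metadata
    if is_slab:
        z_all = fw.cartesian_coords[:, 2]
        z_faces = (z_all.min(), z_all.max())
    gz_choices = [k / LAYERS_PER_CELL for k in range(LAYERS_PER_CELL)]
    for _ in range(8000):
        u, v = rng.random(2)
        q = random_rotation_quat(rng)
        if is_slab:
            face = z_faces[int(rng.integers(2))]
            sign = -1.0 if face == z_faces[0] else 1.0
            center = np.array([u, v, 0.0]) @ cellm
            center[2] = face + sign * (radius + rng.uniform(1.0, 3.0))
        else:
            gz = gz_choices[rng.integers(len(gz_choices))]
            dz = rng.uniform(-0.8, 0.8)
            center = np.array([u, v, gz]) @ cellm + np.array([0, 0, dz])
        xyz = center + local @ quat_to_matrix(q).T
        if _overlaps(xyz, g.elements, existing, existing_is_h, cellm, inv):
            continue
        mol_id = int(fw.mol_ids.max()) + 1 if len(fw.mol_ids) else 0
        fw.frac_coords = np.vstack([fw.frac_coords, wrap_frac(xyz @ inv)])
        fw.elements += list(g.elements)
        fw.charges = np.concatenate([fw.charges, g.charges])
        fw.uff_labels += [ff.DEFAULT_UFF_LABEL[e] for e in g.elements]
        fw.species += [g.name] * len(g.elements)
        fw.mol_ids = np.concatenate([fw.mol_ids, np.full(len(g.elements), mol_id)])
        return
    raise RuntimeError(f"no overlap-free position found for {g.name}")


# ---------------------------------------------------------------------------
# slab utilities used by the Monte Carlo layer


def detach_molecules(
    f: Framework, species: str, z_range: tuple[float, float] | None = None
) -> tuple[Framework, list[GuestMolecule]]:
    """Remove gallery molecules of one species (optionally only those whose
    center lies in a cartesian z window) and return them as rigid guests.

    The remaining framework keeps its charges, so framework plus detached
    guests is exactly as neutral as the input.
    """
    mols = f.molecule_indices(species)
    xyz = f.unwrapped_cartesian()
    drop: list[np.ndarray] = []
    guests: list[GuestMolecule] = []
    for mid in sorted(mols):
        idx = mols[mid]
        zc = xyz[idx, 2].mean()
        if z_range is not None and not (z_range[0] <= zc <= z_range[1]):
            continue
        center = xyz[idx].mean(axis=0)
        guests.append(
            GuestMolecule(
                name=species,
                elements=[f.elements[i] for i in idx],
                local_coords=xyz[idx] - center,
                charges=f.charges[idx],
                net_charge=float(f.charges[idx].sum()),
                center=center,
            )
        )
        drop.append(idx)
    if not drop:
        return f.copy(), []
    dropset = np.concatenate(drop)
    keep = np.ones(len(f), dtype=bool)
    keep[dropset] = False
    fw = Framework(
        f.cell,
        f.frac_coords[keep],
        [e for e, k in zip(f.elements, keep) if k],
        f.charges[keep],
        [l for l, k in zip(f.uff_labels, keep) if k],
        [s for s, k in zip(f.species, keep) if k],
        f.mol_ids[keep],
        f.periodic,
        dict(f.metadata),
    )
    return fw, guests


def surface_hydroxyl_indices(slab: SlabModel | Framework, side: str = "both") -> np.ndarray:
    """Indices of the exposed hydroxyl O/H atoms of a slab (the layer O/H
    beyond the outermost metal planes)."""
    fw = slab.framework if isinstance(slab, SlabModel) else slab
    z = fw.cartesian_coords[:, 2]
    metal = _metal_mask(fw)
    z_lo, z_hi = z[metal].min(), z[metal].max()
    out = []
    for i in range(len(fw)):
        if fw.species[i] != "layer" or fw.elements[i] not in ("O", "H"):
            continue
        if (side in ("both", "bottom") and z[i] < z_lo) or (
            side in ("both", "top") and z[i] > z_hi
        ):
            out.append(i)
    return np.array(out, dtype=int)
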