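"""Materials-characterization formulas for powders and sintered monoliths.

Covers the quantities typically tabulated for an LDH before/after
consolidation: Scherrer crystallite sizes from XRD line broadening, basal
d-spacings and Bragg angles, BET specific surface area and Gurvich total
pore volume from N2 isotherms at 77 K, crystallographic (theoretical)
density, densification rate and mercury-intrusion porosity.

All operations are pure functions of their inputs.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .units import (
    ATOMIC_MASS,
    CU_KALPHA,
    N2_CROSS_SECTION_M2,
    N2_LIQUID_MOLAR_VOLUME,
    N_AVOGADRO,
)
from .structure import UnitCell

__all__ = [
    "CharacterizationRecord",
    "N2Isotherm",
    "scherrer_size",
    "d_spacing",
    "bragg_two_theta",
    "theoretical_density",
    "densification_rate",
    "bet_surface_area",
    "gurvich_pore_volume",
    "pore_volume_retention",
    "hg_porosity",
    "parse_formula",
]


@dataclass
class N2Isotherm:
    """N2 adsorption data: relative pressure p/p0 in (0,1) versus adsorbed
    quantity (mmol/g), one monotone branch at a time."""

    p_over_p0: np.ndarray
    n_ads: np.ndarray
    branch: str = "adsorption"

    def __post_init__(self):
        self.p_over_p0 = np.asarray(self.p_over_p0, dtype=float)
        self.n_ads = np.asarray(self.n_ads, dtype=float)
        if len(self.p_over_p0) != len(self.n_ads):
            raise ValueError("p/p0 and n_ads length mismatch")
        if np.any(self.p_over_p0 <= 0) or np.any(self.p_over_p0 >= 1):
            raise ValueError("relative pressures must lie in (0, 1)")
        if np.any(np.diff(self.p_over_p0) <= 0):
            raise ValueError("p/p0 must be strictly increasing within a branch")
        if self.branch not in ("adsorption", "desorption"):
            raise ValueError("branch must be adsorption or desorption")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"p_over_p0": self.p_over_p0, "n_mmol_per_g": self.n_ads, "branch": self.branch}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "N2Isotherm":
        df = pd.read_csv(path)
        branch = df["branch"].iloc[0] if "branch" in df else "adsorption"
        return cls(df["p_over_p0"].to_numpy(), df["n_mmol_per_g"].to_numpy(), branch)


@dataclass
class CharacterizationRecord:
    """The tabulated summary of one sample: cell, crystallite sizes per
    reflection (A), S_BET (m2/g), pore volume (cm3/g), densities (g/cm3)
    and total porosity (%)."""

    cell: UnitCell | None = None
    crystallite_sizes: dict = field(default_factory=dict)
    s_bet: float | None = None
    v_pore: float | None = None
    apparent_density: float | None = None
    theoretical_density: float | None = None
    porosity: float | None = None

    def __post_init__(self):
        for label, value in (
            ("S_BET", self.s_bet),
            ("V_P", self.v_pore),
            ("apparent density", self.apparent_density),
            ("theoretical density", self.theoretical_density),
            ("porosity", self.porosity),
        ):
            if value is not None and value < 0:
                raise ValueError(f"{label} must be non-negative")
        if any(v < 0 for v in self.crystallite_sizes.values()):
            raise ValueError("crystallite sizes must be non-negative")

    @property
    def densification(self) -> float | None:
        if self.apparent_density is None or not self.theoretical_density:
            return None
        d = densification_rate(self.apparent_density, self.theoretical_density)
        if d > 100.0 + 1e-9:
            raise ValueError("densification above 100%")
        return d

    def as_dict(self) -> dict:
        out = {
            "crystallite_sizes_A": dict(self.crystallite_sizes),
            "S_BET_m2_per_g": self.s_bet,
            "V_P_cm3_per_g": self.v_pore,
            "apparent_density_g_cm3": self.apparent_density,
            "theoretical_density_g_cm3": self.theoretical_density,
            "porosity_pct": self.porosity,
            "densification_pct": self.densification,
        }
        if self.cell is not None:
            out["cell_A"] = {"a": self.cell.a, "c": self.cell.c}
        return out


# ---------------------------------------------------------------------------
# XRD


def scherrer_size(
    lam: float, fwhm: float, two_theta: float, K: float = 0.9
) -> float:
    """Scherrer crystallite size D = K lambda / (beta cos theta), in the
    units of ``lam`` (A for Cu K-alpha 1.5406 A).

    ``fwhm`` is the peak full width at half maximum in radians (no
    instrumental-broadening correction applied); ``two_theta`` in degrees.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive (zero width has no Scherrer size)")
    if not 0.0 < two_theta < 180.0:
        raise ValueError("two_theta must lie in (0, 180) degrees")
    theta = math.radians(two_theta / 2.0)
    return K * lam / (fwhm * math.cos(theta))


def d_spacing(cell: UnitCell, l: int) -> float:
    """Basal-plane spacing d(00l) = c/l of a hexagonal cell (A)."""
    if l == 0:
        raise ValueError("reflection order l must be non-zero")
    if not cell.is_hexagonal:
        raise ValueError("d(00l) = c/l requires a hexagonal cell")
    return cell.c / l


def bragg_two_theta(d: float, lam: float = CU_KALPHA) -> float:
    """Bragg angle 2*theta (degrees) of a spacing d at wavelength lam."""
    s = lam / (2.0 * d)
    if not 0 < s <= 1:
        raise ValueError(f"no Bragg reflection: lambda/2d = {s:.3f} outside (0, 1]")
    return 2.0 * math.degrees(math.asin(s))


# ---------------------------------------------------------------------------
# densities and porosity


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(formula: str) -> dict:
    """Element counts of a simple formula string, e.g. 'Mg6Fe2O16H2' or
    'Mg6Fe2(OH)16CO3(H2O)4.5' (one level of parentheses)."""
    counts: dict[str, float] = {}

    def add(sym, n, mult=1.0):
        counts[sym] = counts.get(sym, 0.0) + n * mult

    pos = 0
    while pos < len(formula):
        ch = formula[pos]
        if ch == "(":
            close = formula.index(")", pos)
            inner = formula[pos + 1 : close]
            after = re.match(r"(\d*\.?\d*)", formula[close + 1 :]).group(1)
            mult = float(after) if after else 1.0
            for sym, num in _FORMULA_TOKEN.findall(inner):
                if sym:
                    add(sym, float(num) if num else 1.0, mult)
            pos = close + 1 + len(after)
        else:
            m = _FORMULA_TOKEN.match(formula, pos)
            if not m or not m.group(1):
                raise ValueError(f"cannot parse formula at {formula[pos:]!r}")
            add(m.group(1), float(m.group(2)) if m.group(2) else 1.0)
            pos = m.end()
    return counts


def formula_mass(formula: str | dict) -> float:
    """Molar mass (g/mol) of a formula string or element-count mapping."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    try:
        return sum(ATOMIC_MASS[el] * n for el, n in counts.items())
    except KeyError as exc:
        raise KeyError(f"unknown element symbol {exc} in formula") from None


def theoretical_density(formula: str | dict, cell: UnitCell, Z: float) -> float:
    """Crystallographic density rho = Z M / (N_A V_cell) in g/cm3.

    ``Z`` (formula units per cell) is an explicit argument, never inferred.
    """
    if Z <= 0:
        raise ValueError("Z must be positive")
    M = formula_mass(formula)
    v_cm3 = cell.volume * 1e-24  # A^3 -> cm^3
    return Z * M / (N_AVOGADRO * v_cm3)


def densification_rate(d_app: float, d_th: float) -> float:
    """Densification in percent: 100 * d_app / d_th."""
    if d_th <= 0:
        raise ValueError("theoretical density must be positive")
    return 100.0 * d_app / d_th


def hg_porosity(d_app: float, V_Hg: float) -> float:
    """Total porosity (%) from mercury intrusion: P_tot = d_app * V_Hg * 100
    with d_app in g/cm3 and V_Hg in cm3/g."""
    if d_app < 0 or V_Hg < 0:
        raise ValueError("inputs must be non-negative")
    return d_app * V_Hg * 100.0


# ---------------------------------------------------------------------------
# gas adsorption


def bet_surface_area(
    iso: N2Isotherm, p_range: tuple[float, float] = (0.05, 0.30)
) -> tuple[float, float, float]:
    """BET analysis of an N2 isotherm (77 K).

    Linear regression of the BET transform ``x / (n (1 - x))`` against
    ``x = p/p0`` over ``p_range`` yields the monolayer capacity n_m
    (mmol/g) and the C constant; the area is
    ``S = n_m N_A * 0.162 nm2`` per gram.

    Returns ``(S_BET in m2/g, C, n_m in mmol/g)``.  A non-positive C
    (invalid pressure range) raises.
    """
    x = iso.p_over_p0
    n = iso.n_ads
    sel = (x >= p_range[0]) & (x <= p_range[1])
    if sel.sum() < 3:
        raise ValueError(
            f"need >= 3 isotherm points with p/p0 in {p_range}, have {int(sel.sum())}"
        )
    if np.all(n[sel] == 0):
        return 0.0, float("nan"), 0.0
    y = x[sel] / (n[sel] * (1.0 - x[sel]))
    slope, intercept = np.polyfit(x[sel], y, 1)
    n_m = 1.0 / (slope + intercept)
    C = slope / intercept + 1.0 if intercept != 0 else float("inf")
    if C <= 0 or n_m <= 0:
        raise ValueError(
            f"BET transform gives C={C:.3g}, n_m={n_m:.3g}; pressure range "
            "outside the validity window"
        )
    s = n_m * 1e-3 * N_AVOGADRO * N2_CROSS_SECTION_M2  # m2/g
    return float(s), float(C), float(n_m)


def gurvich_pore_volume(iso: N2Isotherm, p_over_p0: float = 0.99) -> float:
    """Total pore volume (cm3/g) by the Gurvich rule: the amount adsorbed
    at ``p_over_p0`` converted to liquid N2 volume (34.67 cm3/mol)."""
    if iso.p_over_p0[-1] < p_over_p0 - 1e-9:
        raise ValueError(
            f"isotherm truncated at p/p0 = {iso.p_over_p0[-1]:.3f} < {p_over_p0}"
        )
    n_at = float(np.interp(p_over_p0, iso.p_over_p0, iso.n_ads))
    return n_at * 1e-3 * N2_LIQUID_MOLAR_VOLUME


def pore_volume_retention(v_before: float, v_after: float) -> float:
    """Pore volume retained after consolidation, in percent."""
    if v_before <= 0:
        raise ValueError("reference pore volume must be positive")
    return 100.0 * v_after / v_before
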